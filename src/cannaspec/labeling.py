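"""Drying quantities, cannabinoid ratios, and quality-class assignment.

Two drying quantities are derived from tray weights:

    relative weight change (%) = w_t / w_0 * 100
    RWC (%)                    = (w_t - w_0 * DM) / w_t * 100

where w_t is the weight at time t, w_0 the fresh weight at harvest, and DM
the dry-matter ratio of fresh weight (0.21894 for the study cultivar).
RWC is the fraction of the current weight that is water; at harvest it
equals 100 * (1 - DM) = 78.1 %.

Cannabinoid conversion ratios come from the four UHPLC-quantified
compounds (concentrations in ug/mg):

    total CBD = CBD + CBDA        C/TC = 100 * CBD / total CBD
    total THC = THC + THCA        T/TT = 100 * THC / total THC
    C/T = total CBD / total THC

Four categorical quality targets are assigned from fixed intervals:

    dryness          extreme_dried (0, 10] | dried (10, 40] | fresh (40, 100]   on RWC
    cbda_conversion  low (0, 20] | middle (20, 60] | high (60, 100]             on C/TC
    thca_conversion  low (0, 20] | middle (20, 50] | high (50, 100]             on T/TT
    cbd_thc          high (0, 20) | extreme_high [20, 100]                      on C/T

All intervals are open at 0; a quantity of exactly 0 (or outside (0, 100])
is out of range and raises rather than being silently binned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "DM_DEFAULT",
    "QUALITIES",
    "CLASS_ORDER",
    "DryingRecord",
    "CannabinoidProfile",
    "QualityLabel",
    "relative_weight_change",
    "compute_rwc",
    "assign_quality_classes",
    "content_binary_label",
]

#: Dry-matter ratio of fresh flower weight for the study cultivar.
DM_DEFAULT = 0.21894

#: The four quality targets, in reporting order.
QUALITIES = ("dryness", "cbda_conversion", "thca_conversion", "cbd_thc")

#: Class order per quality (driest/lowest first); fixes confusion-matrix
#: and one-vs-rest class ordering everywhere downstream.
CLASS_ORDER = {
    "dryness": ("extreme_dried", "dried", "fresh"),
    "cbda_conversion": ("low", "middle", "high"),
    "thca_conversion": ("low", "middle", "high"),
    "cbd_thc": ("high", "extreme_high"),
}


@dataclass
class DryingRecord:
    """Tray weights for one sample at one time point."""

    w_t: float                 # weight at time t [g]
    w_0: float                 # fresh weight at harvest [g]
    dm: float = DM_DEFAULT     # dry-matter ratio, dimensionless
    method: str = "hot_air"    # {"hot_air", "cool_air"}
    day: float = 0.0

    def __post_init__(self) -> None:
        if self.w_0 <= 0:
            raise ValueError(f"fresh weight w_0 must be positive; got {self.w_0}")
        if self.w_t <= 0:
            raise ValueError(f"weight w_t must be positive; got {self.w_t}")
        if not 0 < self.dm < 1:
            raise ValueError(f"dry-matter ratio must lie in (0, 1); got {self.dm}")


@dataclass
class CannabinoidProfile:
    """CBDA/CBD/THCA/THC concentrations (ug/mg) with derived ratios."""

    cbda: float
    cbd: float
    thca: float
    thc: float

    def __post_init__(self) -> None:
        for name in ("cbda", "cbd", "thca", "thc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be nonnegative")

    @property
    def total_cbd(self) -> float:
        return self.cbd + self.cbda

    @property
    def total_thc(self) -> float:
        return self.thc + self.thca

    @property
    def c_tc(self) -> float:
        """CBD as a percentage of total CBD (conversion ratio)."""
        if self.total_cbd <= 0:
            raise ValueError("C/TC undefined: total CBD is zero")
        return 100.0 * self.cbd / self.total_cbd

    @property
    def t_tt(self) -> float:
        """THC as a percentage of total THC (conversion ratio)."""
        if self.total_thc <= 0:
            raise ValueError("T/TT undefined: total THC is zero")
        return 100.0 * self.thc / self.total_thc

    @property
    def c_t(self) -> float:
        """Ratio of total CBD to total THC (chemotype indicator)."""
        if self.total_thc <= 0:
            raise ValueError("C/T undefined: total THC is zero")
        return self.total_cbd / self.total_thc


@dataclass(frozen=True)
class QualityLabel:
    """The four categorical quality targets for one sample."""

    dryness: str
    cbda_conversion: str
    thca_conversion: str
    cbd_thc: str

    def __getitem__(self, quality: str) -> str:
        if quality not in QUALITIES:
            raise KeyError(quality)
        return getattr(self, quality)


def relative_weight_change(rec: DryingRecord) -> float:
    """Relative weight change in percent: 100 * w_t / w_0."""
    return 100.0 * rec.w_t / rec.w_0


def compute_rwc(rec: DryingRecord) -> float:
    """Relative water content in percent: 100 * (w_t - w_0 * DM) / w_t.

    A negative value means the sample weighs less than its estimated dry
    mass (over-drying or a DM mismatch); it is reported as-is with a
    warning rather than clamped, so data problems stay visible.
    """
    rwc = 100.0 * (rec.w_t - rec.w_0 * rec.dm) / rec.w_t
    if rwc < 0:
        warnings.warn(
            f"RWC = {rwc:.2f}% is negative (w_t below estimated dry mass); "
            "reported unclamped",
            stacklevel=2,
        )
    return rwc


def _bin_three(value: float, quantity: str, edges: tuple[float, float]) -> int:
    """Index into lower/middle/upper classes for (0,e1] / (e1,e2] / (e2,100]."""
    if not 0 < value <= 100 or math.isnan(value):
        raise ValueError(f"{quantity} = {value} outside the labelable range (0, 100]")
    e1, e2 = edges
    if value <= e1:
        return 0
    if value <= e2:
        return 1
    return 2


def assign_quality_classes(
    rwc: float,
    profile: CannabinoidProfile,
    dryness_edges: tuple[float, float] = (10.0, 40.0),
    cbda_edges: tuple[float, float] = (20.0, 60.0),
    thca_edges: tuple[float, float] = (20.0, 50.0),
    cbd_thc_edge: float = 20.0,
) -> QualityLabel:
    """Assign the four quality classes from RWC and cannabinoid ratios.

    Interval membership follows the class-definition table exactly,
    including the asymmetric C/T rows: high C:T on (0, 20) is open at 20,
    extreme-high C:T on [20, 100] is closed at both ends.
    """
    dryness = CLASS_ORDER["dryness"][_bin_three(rwc, "RWC", dryness_edges)]
    cbda = CLASS_ORDER["cbda_conversion"][_bin_three(profile.c_tc, "C/TC", cbda_edges)]
    thca = CLASS_ORDER["thca_conversion"][_bin_three(profile.t_tt, "T/TT", thca_edges)]
    c_t = profile.c_t
    if not 0 < c_t <= 100 or math.isnan(c_t):
        raise ValueError(f"C/T = {c_t} outside the labelable range (0, 100]")
    cbd_thc = "extreme_high" if c_t >= cbd_thc_edge else "high"
    return QualityLabel(
        dryness=dryness, cbda_conversion=cbda, thca_conversion=thca, cbd_thc=cbd_thc
    )


def content_binary_label(
    profile: CannabinoidProfile,
    cbd_threshold: float = 90.0,
    thc_threshold: float = 3.0,
    inclusive: bool = True,
) -> tuple[bool, bool]:
    """High/low flags for absolute total CBD and total THC content.

    Thresholds default to 90 ug/mg (total CBD) and 3 ug/mg (total THC);
    comparison is inclusive on the high side by default.
    """
    if inclusive:
        return profile.total_cbd >= cbd_threshold, profile.total_thc >= thc_threshold
    return profile.total_cbd > cbd_threshold, profile.total_thc > thc_threshold
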