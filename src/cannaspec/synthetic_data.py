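"""Synthetic hyperspectral benchmark with known ground truth.

No public image data accompany the drying study this package implements,
so the generator re-creates the *statistical structure* the analysis
relies on rather than any particular image:

* flower-shaped foreground (union of rough-edged random ellipses) on a
  soil-like background, separable by the NBD index by construction;
* a smooth vegetation endmember (green bump, sharp red edge near 720 nm,
  NIR plateau) deformed by a latent drying state ``d`` in [0, 1] and the
  drying method, so that the four empirically observed wavelength regimes
  order correctly as drying progresses:

    - below 552.61 nm: hot-air drying lowers reflectance relative to
      fresh and cool-air material;
    - 556.61-612.65 nm: cool-air drying gives the highest reflectance;
    - 616.65-708.7 nm: cool-dried > hot-dried > fresh;
    - 720.71-884.81 nm: both methods lower reflectance, hot-air faster;

* per-pixel multiplicative gain and additive offset drawn from smooth
  spatial random fields (uniform marginals), plus i.i.d. additive Gaussian
  band noise -- exactly the distortions MSC and smoothing are designed to
  remove, so the preprocessing comparison is meaningful;
* first-order (exponential-approach) kinetics for water loss,
  decarboxylation of CBDA and THCA, and THC-total growth, driven by a
  single per-sample latent exposure so that weights, cannabinoid profiles,
  spectra, and hence all four quality labels stay mutually consistent.

Every stochastic choice flows from one integer seed; a fixed seed yields a
bit-identical benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.special import erf

from cannaspec.cube_io import HyperspectralCube, default_wavelength_grid
from cannaspec.labeling import (
    DM_DEFAULT,
    CannabinoidProfile,
    DryingRecord,
    QualityLabel,
    assign_quality_classes,
    compute_rwc,
    QUALITIES,
    CLASS_ORDER,
)

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "REGIMES_NM",
    "generate_flower_mask",
    "endmember_spectrum",
    "background_spectrum",
    "simulate_kinetics",
    "generate_cube",
    "generate_dataset",
    "class_coverage",
    "DEFAULT_DAYS",
    "DEFAULT_METHODS",
]

DEFAULT_DAYS = (0, 2, 4, 7, 9)
DEFAULT_METHODS = ("hot_air", "cool_air")

#: The four drying-sensitive wavelength regimes (nm).
REGIMES_NM = {
    "blue_green": (400.53, 552.61),
    "green_yellow": (556.61, 612.65),
    "red": (616.65, 708.7),
    "nir": (720.71, 884.81),
}


@dataclass
class GeneratorParams:
    """Benchmark-generator configuration.

    The spectral-deformation gains and kinetic rates are calibrated once
    so that (a) the regime orderings above hold, (b) a hot-air day-9
    sample reaches a CBDA conversion near the observed 83 %, (c) cool-air
    conversions stay below 6 % throughout, and (d) the two-method x
    five-day condition grid populates every quality class.
    """

    shape: tuple[int, int] = (300, 300)
    n_flowers: tuple[int, int] = (4, 6)          # inclusive range
    flower_axes_px: tuple[float, float] = (25.0, 50.0)
    edge_roughness: float = 0.10                 # relative radial modulation
    # noise model
    noise_sd: float = 0.005                      # additive, reflectance units
    gain_range: tuple[float, float] = (0.8, 1.2)
    offset_range: tuple[float, float] = (-0.05, 0.05)
    scatter_corr_px: float = 30.0                # correlation length of scatter fields
    # within-flower drying heterogeneity: smooth per-pixel perturbation of
    # the drying state (drying never progresses uniformly across a flower)
    d_noise_sd: float = 0.045
    d_noise_corr_px: float = 15.0
    # residual spectral variability: random smooth band components (pigment
    # and structural variation between and within flowers), modulated by
    # smooth spatial fields; windowed off the red edge so the NBD bands
    # stay clean.  This is the high-dimensional nuisance that makes the
    # classifier comparison non-trivial.
    n_spectral_components: int = 6
    component_amplitude: float = 0.004
    component_smoothness_bands: float = 8.0
    # band-incoherent striping: locally smooth in space, independent across
    # bands (push-broom sensor artifact); survives patch averaging and is
    # exactly the noise that derivative pre-treatments amplify
    striping_sd: float = 0.014
    striping_corr_px: float = 12.0
    # sample-level variability
    tau_jitter_sd: float = 0.06                  # lognormal sd of latent exposure
    w0_mean_g: float = 100.0
    w0_sd_g: float = 5.0
    total_cbd0_mean: float = 110.0               # ug/mg
    total_cbd0_sd: float = 5.0
    ct_ratio0_mean: float = 36.0                 # CBD:THC at harvest
    ct_ratio0_sd: float = 1.5
    dm: float = DM_DEFAULT
    # water-loss kinetics (day^-1) and residual water fraction
    r_water: dict = field(default_factory=lambda: {"hot_air": 2.5, "cool_air": 0.385})
    eps_water: dict = field(default_factory=lambda: {"hot_air": 0.0104, "cool_air": 0.01})
    # spectral drying-state kinetics (day^-1)
    r_spectral: dict = field(default_factory=lambda: {"hot_air": 0.35, "cool_air": 0.25})
    # decarboxylation kinetics (day^-1) and baseline conversion at harvest
    k_cbd: dict = field(default_factory=lambda: {"hot_air": 0.2, "cool_air": 0.005})
    k_thc: dict = field(default_factory=lambda: {"hot_air": 0.15, "cool_air": 0.005})
    baseline_conversion: float = 0.01
    # THC-total growth during drying (drives the CBD:THC trajectory)
    thc_growth: dict = field(default_factory=lambda: {"hot_air": 1.7, "cool_air": 0.2})
    k_thc_growth: dict = field(default_factory=lambda: {"hot_air": 0.5, "cool_air": 0.3})
    # optional early synthesis growth of total CBD (off by default)
    cbd_growth: dict = field(default_factory=lambda: {"hot_air": 0.0, "cool_air": 0.0})
    k_cbd_growth: dict = field(default_factory=lambda: {"hot_air": 0.8, "cool_air": 0.4})
    n_bands: int = 150

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for rates in (self.r_water, self.r_spectral, self.k_cbd, self.k_thc):
            if any(v < 0 for v in rates.values()):
                raise ValueError("kinetic rates must be nonnegative")
        if self.k_cbd["hot_air"] <= self.k_cbd["cool_air"]:
            raise ValueError("hot-air conversion must be faster than cool-air")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return default_wavelength_grid(self.n_bands)


@dataclass
class GroundTruth:
    """Everything the generator knows about one synthetic sample."""

    flower_mask: np.ndarray
    d_spectral: float
    record: DryingRecord
    profile: CannabinoidProfile
    label: QualityLabel
    rwc: float
    method: str
    day: float
    sample_id: str


# ---------------------------------------------------------------------------
# geometry


def generate_flower_mask(
    shape: tuple[int, int], params: GeneratorParams | None = None, seed: int = 0
) -> np.ndarray:
    """Union of random rough-edged ellipses, sized so patch extraction on
    the default 300 x 300 image yields a per-sample patch count inside the
    27-73 range observed on real tray images."""
    params = params or GeneratorParams(shape=shape)
    rows, cols = shape
    if rows < 60 or cols < 60:
        raise ValueError(f"shape must be at least 60 x 60; got {shape}")
    rng = np.random.default_rng(seed)
    n_lo, n_hi = params.n_flowers
    n = int(rng.integers(n_lo, n_hi + 1))
    ax_lo, ax_hi = params.flower_axes_px
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = np.zeros(shape, dtype=bool)
    margin = ax_hi * 0.6
    for _ in range(n):
        cy = rng.uniform(margin, rows - margin)
        cx = rng.uniform(margin, cols - margin)
        a = rng.uniform(ax_lo, ax_hi)
        b = rng.uniform(ax_lo, ax_hi)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        # radial edge roughness: low-order angular harmonics
        ang = np.arctan2(yr, xr)
        amp1, amp2 = rng.uniform(0.3, 1.0, size=2) * params.edge_roughness
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        wobble = 1.0 + amp1 * np.sin(2 * ang + ph1) + amp2 * np.sin(3 * ang + ph2)
        mask |= (xr / a) ** 2 + (yr / b) ** 2 <= wobble**2
    return mask


# ---------------------------------------------------------------------------
# spectra


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def base_flower_spectrum(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Fresh-flower endmember: green bump, sharp red edge, NIR plateau."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return (
        0.08
        + 0.12 * np.exp(-(((wl - 550.0) / 38.0) ** 2))
        + 0.49 * _sigmoid((wl - 722.0) / 11.0)
        - 0.04 * _sigmoid((wl - 940.0) / 25.0)
    )


#: Relative deformation gains per wavelength regime at full drying (d = 1).
_REGIME_GAINS = {
    "hot_air": {"blue_green": -0.20, "green_yellow": 0.25, "red": 0.45, "nir": -0.38},
    "cool_air": {"blue_green": 0.02, "green_yellow": 1.0, "red": 0.9, "nir": -0.30},
}

#: Temporal response shape per regime: monotone, 0 at d = 0, 1 at d = 1.
#: Pigment regimes respond at different speeds than the water-dominated NIR,
#: which curves the drying trajectory in spectral space the way measured
#: reflectance trajectories curve (a straight-line trajectory would be an
#: unrealistic degenerate case).
_REGIME_RESPONSE = {
    "blue_green": lambda d: d,
    "green_yellow": lambda d: np.sqrt(d),
    "red": lambda d: d**2,
    "nir": lambda d: d,
}


def _regime_masks(wl: np.ndarray) -> dict[str, np.ndarray]:
    lo_a, hi_a = REGIMES_NM["blue_green"]
    masks = {"blue_green": _sigmoid((hi_a - wl) / 10.0)}
    for name in ("green_yellow", "nir"):
        lo, hi = REGIMES_NM[name]
        masks[name] = _sigmoid((wl - lo) / 8.0) * _sigmoid((hi - wl) / 8.0)
    # the red-regime deformation concentrates in the lower part of the
    # regime, tapering off before the 684.69 nm NBD band so segmentation
    # stays reliable at every drying state
    lo, _ = REGIMES_NM["red"]
    masks["red"] = _sigmoid((wl - lo) / 8.0) * _sigmoid((675.0 - wl) / 8.0)
    return masks


def _endmember_batch(d: np.ndarray, method: str, wl: np.ndarray) -> np.ndarray:
    """Endmembers for a vector of drying states: (n_pixels, n_bands)."""
    base = base_flower_spectrum(wl)
    masks = _regime_masks(wl)
    gains = _REGIME_GAINS[method]
    deform = np.zeros((d.size, wl.size))
    for name, mask in masks.items():
        deform += np.outer(_REGIME_RESPONSE[name](d), gains[name] * mask)
    return base * (1.0 + deform)


def endmember_spectrum(
    d: float, method: str, wavelengths_nm: np.ndarray | None = None
) -> np.ndarray:
    """Flower endmember at drying state ``d`` in [0, 1] for a drying method.

    ``d = 0`` is the shared fresh state; as ``d`` grows each regime's
    deformation approaches its full-drying gain along its own monotone
    response curve, preserving the orderings listed in the module
    docstring at every ``d``.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"drying state d must lie in [0, 1]; got {d}")
    if method not in _REGIME_GAINS:
        raise ValueError(f"unknown drying method {method!r}")
    wl = default_wavelength_grid() if wavelengths_nm is None else np.asarray(wavelengths_nm)
    base = base_flower_spectrum(wl)
    masks = _regime_masks(wl)
    gains = _REGIME_GAINS[method]
    deform = sum(
        gains[name] * masks[name] * _REGIME_RESPONSE[name](d) for name in masks
    )
    return base * (1.0 + deform)


def background_spectrum(wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
    """Soil-like background: featureless, slowly rising, NBD well below 0.3."""
    wl = default_wavelength_grid() if wavelengths_nm is None else np.asarray(wavelengths_nm)
    return 0.16 + 0.13 * (wl - 400.0) / 600.0


# ---------------------------------------------------------------------------
# kinetics


def _saturating(rate: float, tau: float) -> float:
    return 1.0 - math.exp(-rate * tau)


def simulate_kinetics(
    method: str,
    t: float,
    params: GeneratorParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DryingRecord, CannabinoidProfile, float]:
    """Drying record, cannabinoid profile, and spectral state at day ``t``.

    All processes share one latent exposure ``tau = t * J`` (``J`` a
    per-sample lognormal jitter; ``J = 1`` when no ``rng`` is given, making
    the call deterministic):

    * residual water fraction ``rho = eps + (1 - eps) exp(-r_w tau)``
      interpolates the weight from ``w_0`` down to about ``w_0 * DM``;
    * the spectral drying state is ``d = 1 - exp(-r_s tau)``;
    * conversion fractions ``c = c0 + (1 - c0)(1 - exp(-k tau))`` split
      each cannabinoid total into neutral and acidic forms;
    * the THC total grows by a saturating factor, pulling the CBD:THC
      ratio down from its harvest value (about 36:1) under hot air.
    """
    params = params or GeneratorParams()
    if method not in DEFAULT_METHODS:
        raise ValueError(f"unknown drying method {method!r}")
    if t < 0:
        raise ValueError(f"drying time must be nonnegative; got {t}")
    if rng is None:
        jitter = 1.0
        w0 = params.w0_mean_g
        total_cbd0 = params.total_cbd0_mean
        ratio0 = params.ct_ratio0_mean
    else:
        jitter = float(np.exp(rng.normal(0.0, params.tau_jitter_sd)))
        w0 = float(rng.normal(params.w0_mean_g, params.w0_sd_g))
        total_cbd0 = float(rng.normal(params.total_cbd0_mean, params.total_cbd0_sd))
        ratio0 = float(rng.normal(params.ct_ratio0_mean, params.ct_ratio0_sd))
    tau = t * jitter

    rho = params.eps_water[method] + (1 - params.eps_water[method]) * math.exp(
        -params.r_water[method] * tau
    )
    w_t = w0 * (params.dm + (1 - params.dm) * rho)
    record = DryingRecord(w_t=w_t, w_0=w0, dm=params.dm, method=method, day=t)

    d_spectral = _saturating(params.r_spectral[method], tau)

    c0 = params.baseline_conversion
    c_cbd = c0 + (1 - c0) * _saturating(params.k_cbd[method], tau)
    c_thc = c0 + (1 - c0) * _saturating(params.k_thc[method], tau)
    total_cbd = total_cbd0 * (
        1 + params.cbd_growth[method] * _saturating(params.k_cbd_growth[method], tau)
    )
    total_thc = (total_cbd0 / ratio0) * (
        1 + params.thc_growth[method] * _saturating(params.k_thc_growth[method], tau)
    )
    profile = CannabinoidProfile(
        cbda=(1 - c_cbd) * total_cbd,
        cbd=c_cbd * total_cbd,
        thca=(1 - c_thc) * total_thc,
        thc=c_thc * total_thc,
    )
    return record, profile, d_spectral


# ---------------------------------------------------------------------------
# cube assembly


def _smooth_uniform_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    lo: float,
    hi: float,
    corr_px: float,
) -> np.ndarray:
    """Spatially correlated field with Uniform[lo, hi] marginals."""
    if hi == lo:
        return np.full(shape, lo)
    z = gaussian_filter(rng.standard_normal(shape), sigma=corr_px, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = z / sd
    u = 0.5 * (1.0 + erf(z / math.sqrt(2.0)))  # probability-integral transform
    return lo + (hi - lo) * u


def generate_cube(
    params: GeneratorParams | None = None,
    seed: int = 0,
    method: str = "hot_air",
    day: float = 0.0,
    sample_id: str | None = None,
) -> tuple[HyperspectralCube, GroundTruth]:
    """One synthetic cube plus its ground truth.

    Flower pixels carry the endmember for the sample's drying state; every
    pixel (flower and background) is perturbed by the smooth gain/offset
    scatter fields and i.i.d. additive Gaussian noise, then clipped at
    zero.  The ground-truth label is computed with the labeling module
    from the simulated weights and cannabinoid profile, so generator and
    labeler cannot drift apart.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    sample_id = sample_id or f"{method}_d{day:g}_s{seed}"

    record, profile, d_spectral = simulate_kinetics(method, day, params, rng=rng)
    rwc = compute_rwc(record)
    label = assign_quality_classes(rwc, profile)

    mask = generate_flower_mask(params.shape, params, seed=int(rng.integers(2**31)))
    wl = params.wavelengths_nm
    bg = background_spectrum(wl)

    data = np.empty((*params.shape, params.n_bands))
    data[:] = bg
    if mask.any():
        d_pixel = np.full(params.shape, d_spectral)
        if params.d_noise_sd > 0:
            eta = gaussian_filter(
                rng.standard_normal(params.shape), sigma=params.d_noise_corr_px,
                mode="reflect",
            )
            sd_eta = eta.std()
            if sd_eta > 0:
                eta *= params.d_noise_sd / sd_eta
            d_pixel = np.clip(d_pixel + eta, 0.0, 1.0)
        data[mask] = _endmember_batch(d_pixel[mask], method, wl)

    # keep 670-780 nm untouched so the NBD index is never corrupted by the
    # additive nuisance terms below
    band_window = 1.0 - _sigmoid((wl - 670.0) / 6.0) * _sigmoid((780.0 - wl) / 6.0)
    if params.n_spectral_components > 0 and params.component_amplitude > 0:
        window = band_window
        for _ in range(params.n_spectral_components):
            comp = gaussian_filter1d(
                rng.standard_normal(params.n_bands),
                sigma=params.component_smoothness_bands,
                mode="reflect",
            )
            comp_sd = comp.std()
            if comp_sd > 0:
                comp *= params.component_amplitude / comp_sd
            amplitude = gaussian_filter(
                rng.standard_normal(params.shape), sigma=params.scatter_corr_px,
                mode="reflect",
            )
            amp_sd = amplitude.std()
            if amp_sd > 0:
                amplitude /= amp_sd
            data += amplitude[:, :, None] * (comp * window)

    if params.striping_sd > 0:
        # coarse spatial grid (one cell per correlation length) upsampled
        # bilinearly: smooth in space, independent across bands, and cheap
        from scipy.ndimage import zoom

        cells = (
            max(2, int(np.ceil(params.shape[0] / params.striping_corr_px)) + 1),
            max(2, int(np.ceil(params.shape[1] / params.striping_corr_px)) + 1),
        )
        coarse = rng.standard_normal((*cells, params.n_bands)) * params.striping_sd
        factors = (
            (params.shape[0] + 1) / cells[0],
            (params.shape[1] + 1) / cells[1],
            1.0,
        )
        stripes = zoom(coarse, factors, order=1, grid_mode=True, mode="nearest")
        data += stripes[: params.shape[0], : params.shape[1], :] * band_window

    gain = _smooth_uniform_field(
        rng, params.shape, *params.gain_range, params.scatter_corr_px
    )
    offset = _smooth_uniform_field(
        rng, params.shape, *params.offset_range, params.scatter_corr_px
    )
    data *= gain[:, :, None]
    data += offset[:, :, None]
    if params.noise_sd > 0:
        data += rng.normal(0.0, params.noise_sd, size=data.shape)
    np.clip(data, 0.0, None, out=data)

    cube = HyperspectralCube(
        data,
        wl,
        metadata={
            "sample_id": sample_id,
            "cube_id": sample_id,
            "drying_method": method,
            "day": float(day),
            "seed": int(seed),
        },
    )
    truth = GroundTruth(
        flower_mask=mask,
        d_spectral=d_spectral,
        record=record,
        profile=profile,
        label=label,
        rwc=rwc,
        method=method,
        day=day,
        sample_id=sample_id,
    )
    return cube, truth


def generate_dataset(
    n_per_condition: int = 6,
    days: Sequence[float] = DEFAULT_DAYS,
    methods: Sequence[str] = DEFAULT_METHODS,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> Iterator[tuple[HyperspectralCube, GroundTruth]]:
    """Yield cubes lazily over the condition grid (methods x days).

    Cube seeds derive deterministically from ``seed`` so the benchmark is
    reproducible; cubes are yielded one at a time because a full grid of
    300 x 300 x 150 cubes would not fit comfortably in memory.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be at least 1")
    params = params or GeneratorParams()
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(methods) * len(days) * n_per_condition)
    i = 0
    for method in methods:
        for day in days:
            for rep in range(n_per_condition):
                cube_seed = int(children[i].generate_state(1)[0] % (2**31))
                i += 1
                yield generate_cube(
                    params,
                    seed=cube_seed,
                    method=method,
                    day=day,
                    sample_id=f"{method}_d{day:g}_r{rep}",
                )


def truth_table(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    """Tabulate ground truths: one row per sample with labels and quantities."""
    rows = []
    for t in truths:
        rows.append(
            {
                "sample_id": t.sample_id,
                "drying_method": t.method,
                "day": t.day,
                "rwc": t.rwc,
                "c_tc": t.profile.c_tc,
                "t_tt": t.profile.t_tt,
                "c_t": t.profile.c_t,
                "total_cbd": t.profile.total_cbd,
                "total_thc": t.profile.total_thc,
                "d_spectral": t.d_spectral,
                **{q: t.label[q] for q in QUALITIES},
            }
        )
    return pd.DataFrame(rows)


def benchmark_spectrum_table(
    n_per_condition: int = 6,
    days: Sequence[float] = DEFAULT_DAYS,
    methods: Sequence[str] = DEFAULT_METHODS,
    params: GeneratorParams | None = None,
    seed: int = 0,
    check_coverage: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and label the full benchmark into one feature table.

    Cubes are generated, segmented (NBD threshold, patch extraction, patch
    means), and discarded one at a time, so the full benchmark never sits
    in memory.  Returns ``(table, truths)`` where ``table`` has provenance
    columns, one label column per quality, and the spectral columns, and
    ``truths`` is the per-sample ground-truth table.
    """
    from cannaspec.segmentation import (
        compute_nbd,
        extract_patches,
        patch_mean_spectra,
        threshold_roi,
    )

    pieces = []
    truths: list[GroundTruth] = []
    for cube, truth in generate_dataset(n_per_condition, days, methods, params, seed):
        mask = threshold_roi(compute_nbd(cube))
        patches = extract_patches(mask)
        if len(patches) == 0:
            continue
        spectra = patch_mean_spectra(cube, patches, mask)
        for quality in QUALITIES:
            spectra.insert(len(spectra.columns) - cube.n_bands, quality, truth.label[quality])
        pieces.append(spectra)
        truths.append(truth)
    if not pieces:
        raise ValueError("benchmark produced no patches; check generator parameters")
    table = pd.concat(pieces, ignore_index=True)
    truth_df = truth_table(truths)
    if check_coverage:
        class_coverage(truth_df)
    return table, truth_df


def class_coverage(table: pd.DataFrame, min_count: int = 2) -> pd.DataFrame:
    """Per-quality class counts; raises if any defined class is under-filled."""
    rows = []
    problems = []
    for quality in QUALITIES:
        counts = table[quality].value_counts()
        for cls in CLASS_ORDER[quality]:
            n = int(counts.get(cls, 0))
            rows.append({"quality": quality, "class": cls, "count": n})
            if n < min_count:
                problems.append(f"{quality}/{cls}: {n} < {min_count}")
    summary = pd.DataFrame(rows)
    if problems:
        raise ValueError("class coverage failure: " + "; ".join(problems))
    return summary
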