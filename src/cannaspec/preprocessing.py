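"""Chemometric spectral pre-treatments.

Five methods are compared throughout the package, each operating on an
``N x B`` matrix of spectra (rows are observations, columns are bands):

``raw``
    identity (no treatment);
``sg``
    Savitzky-Golay smoothing, third-order polynomial over a five-point
    window;
``der1`` / ``der2``
    first and second spectral derivatives, computed as Savitzky-Golay
    derivatives with the same window/order (a plain finite-difference
    variant is available behind a flag) and scaled by the band spacing;
``msc``
    multiplicative scatter correction: each spectrum x is regressed on a
    reference spectrum (the calibration-set mean), x = a + b * ref, and
    corrected to (x - a) / b, removing per-spectrum additive offset and
    multiplicative gain.

MSC is the only stateful method: its reference is fitted once on
calibration data and reused unchanged for validation, prediction, and
pixel-level data, so no information leaks from evaluation rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PREPROCESS_METHODS",
    "PreprocessState",
    "sg_smooth",
    "derivative",
    "fit_msc",
    "apply_msc",
    "fit_preprocess",
    "apply_pipeline",
]

#: Fixed method order; also the tie-break order during model selection.
PREPROCESS_METHODS = ("raw", "sg", "der1", "der2", "msc")

SG_WINDOW = 5
SG_POLYORDER = 3


@dataclass
class PreprocessState:
    """Fitted state of a pre-treatment.

    Only MSC carries state (the reference spectrum); the other methods are
    stateless but share this container so pipelines serialize uniformly.
    """

    method: str
    window: int = SG_WINDOW
    polyorder: int = SG_POLYORDER
    reference_spectrum: np.ndarray | None = None
    band_spacing_nm: float = 1.0
    sg_derivatives: bool = True

    def __post_init__(self) -> None:
        if self.method not in PREPROCESS_METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError(
                f"window must be odd and greater than polyorder; got "
                f"window={self.window}, polyorder={self.polyorder}"
            )
        if (self.reference_spectrum is not None) != (self.method == "msc"):
            raise ValueError("reference_spectrum must be present iff method is 'msc'")


def _as_matrix(spectra: np.ndarray) -> np.ndarray:
    arr = np.asarray(spectra, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ValueError(f"spectra must be 1-D or 2-D; got {arr.ndim}-D")
    return arr


def sg_smooth(
    spectra: np.ndarray, window: int = SG_WINDOW, polyorder: int = SG_POLYORDER
) -> np.ndarray:
    """Savitzky-Golay smoothing along the band axis, length preserving.

    Band ends are handled by evaluating the terminal window's fitted
    polynomial at the edge positions, so every method keeps the full band
    count as its feature dimension.
    """
    arr = _as_matrix(spectra)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"window must be odd and greater than polyorder; got "
            f"window={window}, polyorder={polyorder}"
        )
    if arr.shape[1] < window:
        raise ValueError(f"need at least {window} bands; got {arr.shape[1]}")
    out = savgol_filter(arr, window_length=window, polyorder=polyorder, axis=1, mode="interp")
    return out.reshape(np.shape(spectra)) if np.ndim(spectra) == 1 else out


def derivative(
    spectra: np.ndarray,
    order: int,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
    band_spacing_nm: float = 1.0,
    sg: bool = True,
) -> np.ndarray:
    """First or second spectral derivative along the band axis.

    By default the derivative of the local Savitzky-Golay polynomial fit is
    used (standard chemometric practice; far less noise-amplifying than
    differencing).  ``sg=False`` switches to ``np.gradient``-style central
    finite differences.  Output is scaled by ``band_spacing_nm`` so units
    are reflectance per nm, and band count is preserved.
    """
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2; got {order}")
    arr = _as_matrix(spectra)
    if sg:
        out = savgol_filter(
            arr,
            window_length=window,
            polyorder=polyorder,
            deriv=order,
            delta=band_spacing_nm,
            axis=1,
            mode="interp",
        )
    else:
        out = arr
        for _ in range(order):
            out = np.gradient(out, band_spacing_nm, axis=1)
    return out.reshape(np.shape(spectra)) if np.ndim(spectra) == 1 else out


def fit_msc(calibration_spectra: np.ndarray, **state_kwargs) -> PreprocessState:
    """Fit an MSC state: reference spectrum = mean of the calibration set."""
    arr = _as_matrix(calibration_spectra)
    if arr.shape[0] < 1:
        raise ValueError("MSC fitting requires at least one calibration spectrum")
    return PreprocessState(method="msc", reference_spectrum=arr.mean(axis=0), **state_kwargs)


def apply_msc(spectra: np.ndarray, state: PreprocessState) -> np.ndarray:
    """Correct spectra against the fitted reference: x -> (x - a) / b.

    (a, b) is the per-spectrum ordinary least-squares fit of x on the
    reference.  A spectrum whose fitted gain b is numerically zero (flat
    against the reference) is passed through unchanged with a warning.
    """
    if state.method != "msc" or state.reference_spectrum is None:
        raise ValueError("apply_msc requires a fitted MSC state")
    arr = _as_matrix(spectra)
    ref = state.reference_spectrum
    if arr.shape[1] != ref.size:
        raise ValueError(
            f"band count {arr.shape[1]} does not match MSC reference length {ref.size}"
        )
    ref_centered = ref - ref.mean()
    ss_ref = float(ref_centered @ ref_centered)
    if ss_ref == 0.0:
        raise ValueError("MSC reference spectrum is constant; gain is unidentifiable")
    x_mean = arr.mean(axis=1)
    b = (arr - x_mean[:, None]) @ ref_centered / ss_ref
    a = x_mean - b * ref.mean()
    degenerate = np.abs(b) < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} spectra have ~zero MSC gain; passed through uncorrected",
            stacklevel=2,
        )
        b = np.where(degenerate, 1.0, b)
        a = np.where(degenerate, 0.0, a)
    out = (arr - a[:, None]) / b[:, None]
    return out.reshape(np.shape(spectra)) if np.ndim(spectra) == 1 else out


def fit_preprocess(
    method: str,
    calibration_spectra: np.ndarray,
    band_spacing_nm: float = 1.0,
    sg_derivatives: bool = True,
) -> PreprocessState:
    """Fit whatever state ``method`` needs on calibration spectra only."""
    if method == "msc":
        return fit_msc(
            calibration_spectra,
            band_spacing_nm=band_spacing_nm,
            sg_derivatives=sg_derivatives,
        )
    return PreprocessState(
        method=method, band_spacing_nm=band_spacing_nm, sg_derivatives=sg_derivatives
    )


def apply_pipeline(
    method: str, spectra: np.ndarray, state: PreprocessState | None = None
) -> np.ndarray:
    """Dispatch a pre-treatment by name (``raw`` is the identity)."""
    if method not in PREPROCESS_METHODS:
        raise ValueError(f"unknown preprocessing method {method!r}")
    if state is not None and state.method != method:
        raise ValueError(f"state was fitted for {state.method!r}, not {method!r}")
    if method == "raw":
        return np.asarray(spectra, dtype=float).copy()
    if method == "sg":
        win = state.window if state else SG_WINDOW
        poly = state.polyorder if state else SG_POLYORDER
        return sg_smooth(spectra, window=win, polyorder=poly)
    if method in ("der1", "der2"):
        order = 1 if method == "der1" else 2
        win = state.window if state else SG_WINDOW
        poly = state.polyorder if state else SG_POLYORDER
        spacing = state.band_spacing_nm if state else 1.0
        use_sg = state.sg_derivatives if state else True
        return derivative(
            spectra, order, window=win, polyorder=poly, band_spacing_nm=spacing, sg=use_sg
        )
    # msc
    if state is None:
        raise ValueError("MSC requires a fitted state (use fit_preprocess)")
    return apply_msc(spectra, state)
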