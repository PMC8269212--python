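"""Single-cell Raman spectrum container and preprocessing.

The preprocessing contract mirrors standard single-cell Raman
microspectroscopy practice: dark/background subtraction, baseline
(fluorescence) removal, and normalization of each spectrum to the area of
the C-H stretching band so that band areas are comparable across cells.

The processing state of a spectrum is tracked explicitly and transitions
only forward: raw -> dark_subtracted -> baseline_corrected -> ch_normalized.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve


class ProcessingState(enum.IntEnum):
    """Forward-only preprocessing stages of a Raman spectrum."""

    RAW = 0
    DARK_SUBTRACTED = 1
    BASELINE_CORRECTED = 2
    CH_NORMALIZED = 3


@dataclass(frozen=True)
class BandWindow:
    """A named wavenumber interval used for band-area integration."""

    name: str
    lo_cm1: float
    hi_cm1: float

    def __post_init__(self) -> None:
        if not self.lo_cm1 < self.hi_cm1:
            raise ValueError(
                f"band window {self.name!r}: lo ({self.lo_cm1}) must be < hi ({self.hi_cm1})"
            )

    @property
    def width(self) -> float:
        return self.hi_cm1 - self.lo_cm1

    def contains(self, wavenumber: float) -> bool:
        return self.lo_cm1 <= wavenumber <= self.hi_cm1


#: C-D stretching band formed by deuterium incorporation from heavy water.
CD_WINDOW = BandWindow("CD", 2040.0, 2300.0)
#: C-H stretching band; the normalization reference.
CH_WINDOW = BandWindow("CH", 2800.0, 3100.0)
#: Carotenoid resonance bands of the polyene chain.
CAROT_V1_WINDOW = BandWindow("CAROT_V1", 1000.0, 1020.0)  # CH3 in-plane rocking
CAROT_V2_WINDOW = BandWindow("CAROT_V2", 1150.0, 1170.0)  # C-C stretch
CAROT_V3_WINDOW = BandWindow("CAROT_V3", 1500.0, 1550.0)  # C=C stretch
#: Biologically silent region used for noise estimation.
NOISE_WINDOW = BandWindow("NOISE", 1800.0, 1900.0)

CANONICAL_WINDOWS = {
    w.name: w
    for w in (CD_WINDOW, CH_WINDOW, CAROT_V1_WINDOW, CAROT_V2_WINDOW, CAROT_V3_WINDOW)
}


@dataclass
class RamanSpectrum:
    """One cell's wavenumber/intensity trace plus its processing state.

    Parameters
    ----------
    wavenumbers
        Strictly increasing axis in cm^-1.
    intensities
        Intensity per axis point, arbitrary units.
    state
        Current preprocessing stage.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    state: ProcessingState = ProcessingState.RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError(
                f"axis length {self.wavenumbers.size} != intensity length {self.intensities.size}"
            )
        if self.wavenumbers.size < 2:
            raise ValueError("spectrum needs at least two points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def copy_with(self, intensities: np.ndarray, state: ProcessingState) -> "RamanSpectrum":
        if state < self.state:
            raise ValueError(
                f"processing state may only advance (have {self.state.name}, got {state.name})"
            )
        return replace(self, intensities=np.asarray(intensities, dtype=float), state=state)


def subtract_dark(spectrum: RamanSpectrum, dark: RamanSpectrum) -> RamanSpectrum:
    """Subtract a dark/background trace point by point.

    Both spectra must share an identical wavenumber axis and the input must
    still be raw.
    """
    if spectrum.state != ProcessingState.RAW:
        raise ValueError(f"expected a raw spectrum, got state {spectrum.state.name}")
    if spectrum.wavenumbers.size != dark.wavenumbers.size or not np.array_equal(
        spectrum.wavenumbers, dark.wavenumbers
    ):
        mismatch = _first_axis_mismatch(spectrum.wavenumbers, dark.wavenumbers)
        raise ValueError(f"axis mismatch between spectrum and dark trace at {mismatch}")
    return spectrum.copy_with(
        spectrum.intensities - dark.intensities, ProcessingState.DARK_SUBTRACTED
    )


def _first_axis_mismatch(a: np.ndarray, b: np.ndarray) -> str:
    n = min(a.size, b.size)
    neq = np.nonzero(a[:n] != b[:n])[0]
    if neq.size:
        i = int(neq[0])
        return f"index {i}: {a[i]} vs {b[i]} cm^-1"
    return f"length {a.size} vs {b.size}"


def als_baseline(
    y: np.ndarray, lam: float = 1e8, p: float = 0.01, n_iter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate (Whittaker smoother with
    asymmetric weights).

    Minimizes sum(w_i (y_i - z_i)^2) + lam * sum((Delta^2 z)^2) where points
    above the current baseline get weight ``p`` and points below ``1 - p``,
    so peaks are ignored while the smooth background is tracked.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("asymmetry p must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        wmat = sparse.diags(w)
        z = spsolve((wmat + dtd).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def correct_baseline(
    spectrum: RamanSpectrum,
    smoothness_lambda: float = 1e8,
    asymmetry_p: float = 0.01,
    n_iter: int = 10,
) -> tuple[RamanSpectrum, RamanSpectrum]:
    """Estimate and remove the fluorescence baseline.

    Returns ``(corrected, baseline)``; the corrected spectrum advances to the
    baseline_corrected state.
    """
    if spectrum.state not in (ProcessingState.RAW, ProcessingState.DARK_SUBTRACTED):
        raise ValueError(
            f"baseline correction expects a raw or dark-subtracted spectrum, got {spectrum.state.name}"
        )
    z = als_baseline(spectrum.intensities, smoothness_lambda, asymmetry_p, n_iter)
    corrected = spectrum.copy_with(spectrum.intensities - z, ProcessingState.BASELINE_CORRECTED)
    baseline = RamanSpectrum(spectrum.wavenumbers, z, spectrum.state, dict(spectrum.meta))
    return corrected, baseline


def band_area(
    spectrum: RamanSpectrum, window: BandWindow, clip_negative: bool = True
) -> float:
    """Trapezoidal integral of intensity over a wavenumber window (a.u.*cm^-1).

    Integration runs on the native axis points inside [lo, hi]; no
    resampling. With ``clip_negative`` (default), negative intensities are
    treated as zero first, so residual noise around zero after baseline
    removal cannot produce negative band areas.
    """
    w = spectrum.wavenumbers
    if window.hi_cm1 < w[0] or window.lo_cm1 > w[-1]:
        raise ValueError(
            f"window {window.name!r} [{window.lo_cm1}, {window.hi_cm1}] lies outside axis "
            f"[{w[0]}, {w[-1]}]"
        )
    mask = (w >= window.lo_cm1) & (w <= window.hi_cm1)
    if mask.sum() < 2:
        raise ValueError(f"window {window.name!r} covers fewer than two axis points")
    y = spectrum.intensities[mask]
    if clip_negative:
        y = np.clip(y, 0.0, None)
    return float(np.trapezoid(y, w[mask]))


def normalize_ch(spectrum: RamanSpectrum, ch_window: BandWindow = CH_WINDOW) -> RamanSpectrum:
    """Normalize intensities so the C-H band area equals one.

    Requires a baseline-corrected spectrum; re-normalizing an already
    normalized spectrum is the identity.
    """
    if spectrum.state not in (ProcessingState.BASELINE_CORRECTED, ProcessingState.CH_NORMALIZED):
        raise ValueError(
            f"normalization expects a baseline-corrected spectrum, got {spectrum.state.name}"
        )
    area = band_area(spectrum, ch_window)
    if area <= 0:
        raise ValueError("no C-H signal: C-H band area is not positive (dead pixels or empty trap?)")
    return spectrum.copy_with(spectrum.intensities / area, ProcessingState.CH_NORMALIZED)


def smooth(spectrum: RamanSpectrum, window_length: int = 9, polyorder: int = 3) -> RamanSpectrum:
    """Optional Savitzky-Golay smoothing; off the default pipeline."""
    y = savgol_filter(spectrum.intensities, window_length, polyorder)
    return replace(spectrum, intensities=y)
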