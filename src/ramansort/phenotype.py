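"""Metabolic phenotyping from preprocessed single-cell Raman spectra.

The C-D ratio (CDR) — area of the C-D band over the summed C-D and C-H band
areas — quantifies deuterium incorporation from heavy-water incubation and
is the standard proxy for single-cell metabolic activity. Carotenoid
producers are called from the three polyene resonance bands. The two
booleans define a four-way joint phenotype class, and sorting decisions are
taken against a named criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import (
    CAROT_V1_WINDOW,
    CAROT_V2_WINDOW,
    CAROT_V3_WINDOW,
    CD_WINDOW,
    CH_WINDOW,
    NOISE_WINDOW,
    BandWindow,
    ProcessingState,
    RamanSpectrum,
    band_area,
)

#: Default CDR positivity threshold; see calibrate_cdr_threshold for the
#: control-population rule this default stands in for.
DEFAULT_CDR_THRESHOLD = 0.05
#: Default per-band signal-to-noise threshold for carotenoid calls.
DEFAULT_SNR_THRESHOLD = 5.0

JOINT_CLASSES = ("CD+CAR+", "CD-CAR+", "CD+CAR-", "CD-CAR-")

SORT_CRITERIA = ("cd_band", "carotenoid", "morphology_passthrough")


@dataclass
class CellPhenotype:
    """Per-cell phenotype call: CDR, carotenoid status, joint class."""

    cell_id: str
    cdr: float
    cd_positive: bool
    carotenoid_positive: bool
    band_snr: dict[str, float] = field(default_factory=dict)
    sort_target: bool = False
    #: CAR+ cells' CDR is read through strong carotenoid resonance; flagged
    #: because instruments photobleach carotenoids before a clean C-D read.
    cdr_flag: str = "ok"

    @property
    def joint_class(self) -> str:
        cd = "CD+" if self.cd_positive else "CD-"
        car = "CAR+" if self.carotenoid_positive else "CAR-"
        return cd + car


def compute_cdr(
    spectrum: RamanSpectrum,
    cd_window: BandWindow = CD_WINDOW,
    ch_window: BandWindow = CH_WINDOW,
) -> float:
    """C-D ratio: area(C-D) / (area(C-D) + area(C-H)).

    Requires at least a baseline-corrected spectrum. The ratio is invariant
    to C-H normalization (any overall scale cancels), so it may be computed
    before or after that step.
    """
    if spectrum.state < ProcessingState.BASELINE_CORRECTED:
        raise ValueError(
            f"CDR needs a baseline-corrected spectrum, got state {spectrum.state.name}"
        )
    cd = band_area(spectrum, cd_window)
    ch = band_area(spectrum, ch_window)
    if cd + ch == 0:
        raise ValueError("empty spectrum: both C-D and C-H band areas are zero")
    return cd / (cd + ch)


def estimate_noise_sd(
    spectrum: RamanSpectrum, noise_window: BandWindow = NOISE_WINDOW
) -> float:
    """Noise level from a biologically silent region (default 1800-1900 cm^-1)."""
    w = spectrum.wavenumbers
    mask = (w >= noise_window.lo_cm1) & (w <= noise_window.hi_cm1)
    if mask.sum() < 3:
        raise ValueError("noise window covers too few axis points")
    return float(np.std(spectrum.intensities[mask], ddof=1))


def detect_carotenoid(
    spectrum: RamanSpectrum,
    noise_sd_estimate: float | None = None,
    snr_threshold_k: float = DEFAULT_SNR_THRESHOLD,
    noise_window: BandWindow = NOISE_WINDOW,
) -> tuple[bool, dict[str, float]]:
    """Call carotenoid presence from the v1/v2/v3 resonance bands.

    Per band, SNR = band prominence / noise sd, where prominence is the
    maximum intensity in the window above the local background interpolated
    from just outside the window edges (for a perfectly flat corrected
    baseline this reduces to the in-window maximum). The noise sd comes from
    the silent region when not supplied. The call is positive when the v3
    (C=C stretch, the strongest resonance band) SNR reaches the threshold
    and at least one of v1/v2 does too.
    """
    if spectrum.state < ProcessingState.BASELINE_CORRECTED:
        raise ValueError(
            f"carotenoid detection needs a baseline-corrected spectrum, got {spectrum.state.name}"
        )
    noise_sd = estimate_noise_sd(spectrum, noise_window) if noise_sd_estimate is None else noise_sd_estimate
    if noise_sd <= 0:
        raise ValueError("noise sd must be positive")
    snr = {}
    w = spectrum.wavenumbers
    y = spectrum.intensities
    for window in (CAROT_V1_WINDOW, CAROT_V2_WINDOW, CAROT_V3_WINDOW):
        mask = (w >= window.lo_cm1) & (w <= window.hi_cm1)
        idx = np.nonzero(mask)[0]
        # local background: median of a few points flanking each window edge,
        # linearly interpolated to the peak position; immunizes the call
        # against smooth baseline-correction residual
        left = y[max(idx[0] - 5, 0) : idx[0]]
        right = y[idx[-1] + 1 : idx[-1] + 6]
        bg_left = float(np.median(left)) if left.size else 0.0
        bg_right = float(np.median(right)) if right.size else 0.0
        peak_pos = idx[np.argmax(y[idx])]
        frac = (peak_pos - idx[0]) / max(idx[-1] - idx[0], 1)
        background = bg_left + frac * (bg_right - bg_left)
        snr[window.name] = float(max(y[idx].max() - background, 0.0) / noise_sd)
    positive = snr["CAROT_V3"] >= snr_threshold_k and (
        snr["CAROT_V1"] >= snr_threshold_k or snr["CAROT_V2"] >= snr_threshold_k
    )
    return positive, snr


def classify_cell(
    spectrum: RamanSpectrum,
    cell_id: str = "",
    cdr_threshold: float = DEFAULT_CDR_THRESHOLD,
    snr_threshold_k: float = DEFAULT_SNR_THRESHOLD,
    noise_sd_estimate: float | None = None,
    sort_criterion: str = "cd_band",
) -> CellPhenotype:
    """Joint four-way phenotype call for one preprocessed cell."""
    cdr = compute_cdr(spectrum)
    car_positive, snr = detect_carotenoid(
        spectrum, noise_sd_estimate=noise_sd_estimate, snr_threshold_k=snr_threshold_k
    )
    phenotype = CellPhenotype(
        cell_id=cell_id,
        cdr=cdr,
        cd_positive=cdr >= cdr_threshold,
        carotenoid_positive=car_positive,
        band_snr=snr,
        cdr_flag="post_quench_unavailable" if car_positive else "ok",
    )
    phenotype.sort_target = sort_decision(phenotype, sort_criterion)
    return phenotype


def sort_decision(phenotype: CellPhenotype, criterion: str = "cd_band") -> bool:
    """Would this cell be sorted under the named criterion?

    ``morphology_passthrough`` is always true: shape-based selection happens
    upstream of spectral acquisition.
    """
    if criterion == "cd_band":
        return phenotype.cd_positive
    if criterion == "carotenoid":
        return phenotype.carotenoid_positive
    if criterion == "morphology_passthrough":
        return True
    raise ValueError(f"unknown sorting criterion {criterion!r}; known: {SORT_CRITERIA}")


def calibrate_cdr_threshold(
    control_cdrs: Sequence[float],
    rule: str = "mean_plus_k_sd",
    sd_multiplier: float = 3.0,
    fixed_value: float | None = None,
) -> float:
    """CDR positivity threshold from an unlabeled control population.

    Default rule: mean + 3 sd of control CDRs, the usual stable-isotope
    Raman convention; alternatives are the control maximum or a fixed value.
    Fewer than 20 controls triggers a warning (the estimate is noisy) but
    still computes.
    """
    values = np.asarray(list(control_cdrs), dtype=float)
    if rule == "fixed":
        if fixed_value is None:
            raise ValueError("fixed rule requires fixed_value")
        return float(fixed_value)
    if values.size == 0:
        raise ValueError("no control CDR values")
    if values.size < 20:
        warnings.warn(
            f"only {values.size} control cells (< 20); threshold estimate is unstable",
            stacklevel=2,
        )
    if rule == "mean_plus_k_sd":
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        return float(np.mean(values)) + sd_multiplier * sd
    if rule == "max":
        return float(np.max(values))
    raise ValueError(f"unknown calibration rule {rule!r}")


# ---------------------------------------------------------------------------
# heavy-water incubation time courses

@dataclass
class TimeCoursePoint:
    """Per-cell CDR values observed at one incubation time point."""

    time_h: float
    cdr_values: np.ndarray

    def __post_init__(self) -> None:
        self.cdr_values = np.asarray(self.cdr_values, dtype=float)
        if self.cdr_values.size < 2:
            raise ValueError(f"time point {self.time_h} h needs >= 2 cells")

    @property
    def mean_cdr(self) -> float:
        return float(np.mean(self.cdr_values))

    @property
    def median_cdr(self) -> float:
        return float(np.median(self.cdr_values))

    @property
    def sd_cdr(self) -> float:
        return float(np.std(self.cdr_values, ddof=1))


@dataclass
class TimeCourseSummary:
    """Per-time summary of a labeling time course plus the plateau call."""

    table: pd.DataFrame
    plateau: bool
    replicate_correlations: list[float] | None = None


def summarize_timecourse(
    points: Sequence[TimeCoursePoint],
    replicates: Sequence[Sequence[TimeCoursePoint]] | None = None,
    plateau_fraction: float = 0.10,
) -> TimeCourseSummary:
    """Summarize a labeling time course and flag saturation.

    The plateau flag is true when the final inter-timepoint increase of the
    mean CDR is below ``plateau_fraction`` of the total rise, allowing two
    standard errors of the final increase so sampling noise at the plateau
    does not flip the call (a flat course counts as plateaued). When
    replicate profiles are supplied (on the same time grid), pairwise
    Pearson correlations of their mean-CDR profiles are reported.
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need >= 2 time points")
    points.sort(key=lambda p: p.time_h)
    table = pd.DataFrame(
        {
            "time_h": [p.time_h for p in points],
            "n_cells": [p.cdr_values.size for p in points],
            "mean_cdr": [p.mean_cdr for p in points],
            "median_cdr": [p.median_cdr for p in points],
            "sd_cdr": [p.sd_cdr for p in points],
        }
    )
    means = table["mean_cdr"].to_numpy()
    total_rise = means[-1] - means[0]
    last_increase = means[-1] - means[-2]
    se_last = math.hypot(
        points[-1].sd_cdr / math.sqrt(points[-1].cdr_values.size),
        points[-2].sd_cdr / math.sqrt(points[-2].cdr_values.size),
    )
    if abs(total_rise) < 1e-12:
        plateau = True
    else:
        plateau = last_increase < plateau_fraction * total_rise + 2.0 * se_last

    correlations = None
    if replicates is not None:
        profiles = []
        grids = []
        for rep in replicates:
            rep = sorted(rep, key=lambda p: p.time_h)
            grids.append(tuple(p.time_h for p in rep))
            profiles.append([p.mean_cdr for p in rep])
        if len(set(grids)) > 1:
            raise ValueError(f"replicate time grids differ: {sorted(set(grids))}")
        correlations = []
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                r, _ = stats.pearsonr(profiles[i], profiles[j])
                correlations.append(float(r))
    return TimeCourseSummary(table=table, plateau=plateau, replicate_correlations=correlations)


def phenotype_table(phenotypes: Iterable[CellPhenotype]) -> pd.DataFrame:
    """Tabulate phenotype calls in the standard column layout."""
    rows = [
        {
            "cell_id": p.cell_id,
            "cdr": p.cdr,
            "cd_positive": p.cd_positive,
            "carotenoid_positive": p.carotenoid_positive,
            "v1_snr": p.band_snr.get("CAROT_V1", np.nan),
            "v2_snr": p.band_snr.get("CAROT_V2", np.nan),
            "v3_snr": p.band_snr.get("CAROT_V3", np.nan),
            "joint_class": p.joint_class,
            "sort_target": p.sort_target,
            "cdr_flag": p.cdr_flag,
        }
        for p in phenotypes
    ]
    return pd.DataFrame(rows)
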