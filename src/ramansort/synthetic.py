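"""Ground-truth synthetic data: spectra, mock communities, contigs, batches.

Every generated object carries a :class:`SyntheticTruth` so downstream
stages (preprocessing, phenotyping, QC statistics) can be tested for
parameter recovery without any external data. Bands are Gaussian, which
gives closed-form areas (amplitude * sigma * sqrt(2*pi)) and hence an
analytic ground-truth C-D ratio; baselines are low-order polynomials plus an
optional broad fluorescence hump, the typical Raman background shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .seqqc import CellSeqRecord
from .spectra import (
    CAROT_V1_WINDOW,
    CAROT_V2_WINDOW,
    CAROT_V3_WINDOW,
    CD_WINDOW,
    CH_WINDOW,
    ProcessingState,
    RamanSpectrum,
)

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class SpectrumAxis:
    """Wavenumber grid for generated spectra (default 400-3200 cm^-1, 1 cm^-1)."""

    start_cm1: float = 400.0
    stop_cm1: float = 3200.0
    step_cm1: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_cm1 < self.stop_cm1:
            raise ValueError("axis start must be < stop")
        if self.step_cm1 <= 0:
            raise ValueError("axis step must be positive")

    def grid(self) -> np.ndarray:
        n = int(round((self.stop_cm1 - self.start_cm1) / self.step_cm1)) + 1
        return self.start_cm1 + self.step_cm1 * np.arange(n)


@dataclass(frozen=True)
class BandModel:
    """A Gaussian Raman band: center, sigma width, peak amplitude (a.u.)."""

    center_cm1: float
    width_cm1: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_cm1 <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")

    @property
    def area(self) -> float:
        """Closed-form area under the Gaussian over the full line."""
        return self.amplitude * self.width_cm1 * SQRT_2PI

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        z = (wavenumbers - self.center_cm1) / self.width_cm1
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters attached to every generated spectrum."""

    true_cdr: float
    carotenoid_present: bool
    species_label: str = ""
    baseline_params: tuple[float, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SpeciesSpec:
    """One mock-community member and its phenotype flags."""

    label: str
    proportion: float
    d2o_labeled: bool = False
    carotenoid_producer: bool = False


@dataclass(frozen=True)
class MockCommunitySpec:
    """Defined mixture of species with known phenotypes."""

    species: tuple[SpeciesSpec, ...]
    n_cells: int

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("mock community needs at least one species")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        total = sum(s.proportion for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species proportions must sum to 1, got {total}")


def four_species_mock(n_cells: int = 20) -> MockCommunitySpec:
    """The benchmark four-member community, mixed 1:1:1:1.

    Only Ec is heavy-water labeled and only Se contains carotenoids, so C-D
    and carotenoid sorting each have exactly one true-positive species.
    """
    q = 0.25
    return MockCommunitySpec(
        species=(
            SpeciesSpec("Ec", q, d2o_labeled=True),
            SpeciesSpec("Hp", q),
            SpeciesSpec("Se", q, carotenoid_producer=True),
            SpeciesSpec("Sc", q),
        ),
        n_cells=n_cells,
    )


# ---------------------------------------------------------------------------
# spectra

def _truth_cdr(bands: Sequence[BandModel]) -> float:
    cd = sum(b.area for b in bands if CD_WINDOW.contains(b.center_cm1))
    ch = sum(b.area for b in bands if CH_WINDOW.contains(b.center_cm1))
    if cd + ch == 0:
        return 0.0
    return cd / (cd + ch)


def _truth_carotenoid(bands: Sequence[BandModel]) -> bool:
    v3 = any(CAROT_V3_WINDOW.contains(b.center_cm1) for b in bands)
    v12 = any(
        CAROT_V1_WINDOW.contains(b.center_cm1) or CAROT_V2_WINDOW.contains(b.center_cm1)
        for b in bands
    )
    return v3 and v12


def make_spectrum(
    axis: SpectrumAxis,
    bands: Sequence[BandModel],
    baseline_params: Sequence[float] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
    fluorescence: BandModel | None = None,
    species_label: str = "",
) -> tuple[RamanSpectrum, SyntheticTruth]:
    """Generate one raw spectrum: Gaussian bands + polynomial baseline + noise.

    ``baseline_params`` are polynomial coefficients in increasing degree
    evaluated on a [0, 1]-rescaled axis (keeps magnitudes interpretable);
    ``fluorescence`` optionally adds a broad background Gaussian. The
    returned truth carries the analytic C-D ratio computed from band areas
    before baseline and noise.
    """
    w = axis.grid()
    for b in bands:
        if not (w[0] <= b.center_cm1 - 4 * b.width_cm1 and b.center_cm1 + 4 * b.width_cm1 <= w[-1]):
            raise ValueError(
                f"band at {b.center_cm1} cm^-1 (sigma {b.width_cm1}) not covered by axis "
                f"[{w[0]}, {w[-1]}] with 4-sigma margin"
            )
    if len(baseline_params) > 6:
        raise ValueError("baseline polynomial degree is capped at 5")
    y = np.zeros_like(w)
    for b in bands:
        y += b.evaluate(w)
    if baseline_params:
        x = (w - w[0]) / (w[-1] - w[0])
        y += np.polynomial.polynomial.polyval(x, np.asarray(baseline_params, dtype=float))
    if fluorescence is not None:
        y += fluorescence.evaluate(w)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=w.size)
    truth = SyntheticTruth(
        true_cdr=_truth_cdr(bands),
        carotenoid_present=_truth_carotenoid(bands),
        species_label=species_label,
        baseline_params=tuple(baseline_params),
        noise_sd=noise_sd,
        seed=seed,
    )
    return RamanSpectrum(w, y, ProcessingState.RAW), truth


# ---------------------------------------------------------------------------
# mock communities

@dataclass(frozen=True)
class CellTemplate:
    """Band recipe for one species' cells.

    The C-H band is always present; a C-D band is added for heavy-water
    labeled cells with amplitude chosen so the analytic C-D ratio equals
    ``target_cdr``; carotenoid producers get all three resonance bands,
    which in real cells are resonance-enhanced well above the C-H signal.
    """

    ch_amplitude: float = 3.0
    ch_center: float = 2930.0
    ch_sigma: float = 60.0
    target_cdr: float = 0.18
    cd_center: float = 2157.0
    cd_sigma: float = 40.0
    carotenoid_amplitude: float = 6.0
    amplitude_cv: float = 0.10  # per-cell lognormal-ish jitter

    def bands(self, d2o_labeled: bool, carotenoid_producer: bool, rng: np.random.Generator) -> list[BandModel]:
        scale = float(np.exp(rng.normal(0.0, self.amplitude_cv)))
        ch_amp = self.ch_amplitude * scale
        out = [BandModel(self.ch_center, self.ch_sigma, ch_amp)]
        if d2o_labeled:
            # cd_amp*cd_sigma / (cd_amp*cd_sigma + ch_amp*ch_sigma) = target_cdr
            r = self.target_cdr
            cd_amp = r / (1.0 - r) * ch_amp * self.ch_sigma / self.cd_sigma
            out.append(BandModel(self.cd_center, self.cd_sigma, cd_amp))
        if carotenoid_producer:
            amp = self.carotenoid_amplitude * scale
            out.append(BandModel(1008.0, 4.0, amp))            # v1, CH3 rock
            out.append(BandModel(1158.0, 5.0, 1.2 * amp))      # v2, C-C stretch
            out.append(BandModel(1523.0, 10.0, 1.5 * amp))     # v3, C=C stretch
        return out


def largest_remainder_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Integer counts summing to n, apportioned by largest remainder."""
    exact = [p * n for p in proportions]
    counts = [int(math.floor(e)) for e in exact]
    short = n - sum(counts)
    remainders = sorted(
        range(len(exact)), key=lambda i: (-(exact[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


DEFAULT_BASELINE = (8.0, -6.0, 10.0, -4.0)  # gentle cubic fluorescence ramp
DEFAULT_FLUORESCENCE = BandModel(1450.0, 500.0, 4.0)
DEFAULT_NOISE_SD = 0.05


def make_mock_community(
    spec: MockCommunitySpec,
    templates: dict[str, CellTemplate] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    axis: SpectrumAxis | None = None,
    seed: int = 0,
    baseline_params: Sequence[float] = DEFAULT_BASELINE,
    fluorescence: BandModel | None = DEFAULT_FLUORESCENCE,
) -> list[tuple[str, RamanSpectrum, SyntheticTruth]]:
    """Generate per-cell spectra for a mock community.

    Species counts follow the proportions by largest-remainder rounding, so
    they sum exactly to ``spec.n_cells``. Returns (cell_id, spectrum, truth)
    triples; truths carry the species label and phenotype ground truth.
    """
    axis = axis or SpectrumAxis()
    templates = templates if templates is not None else {}
    for s in spec.species:
        templates.setdefault(s.label, CellTemplate())
    rng = np.random.default_rng(seed)
    counts = largest_remainder_counts([s.proportion for s in spec.species], spec.n_cells)
    cells = []
    idx = 0
    for s, count in zip(spec.species, counts):
        tmpl = templates[s.label]
        for j in range(count):
            cell_seed = int(rng.integers(0, 2**31 - 1))
            bands = tmpl.bands(s.d2o_labeled, s.carotenoid_producer, rng)
            spectrum, truth = make_spectrum(
                axis,
                bands,
                baseline_params=baseline_params,
                noise_sd=noise_sd,
                seed=cell_seed,
                fluorescence=fluorescence,
                species_label=s.label,
            )
            cells.append((f"cell{idx:04d}_{s.label}", spectrum, truth))
            idx += 1
    return cells


# ---------------------------------------------------------------------------
# genomes and contigs

@dataclass(frozen=True)
class SyntheticGenome:
    """An order-0 composition model for one species' genome."""

    label: str
    length_bp: int
    gc_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("genome length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")

    def sequence(self) -> str:
        rng = np.random.default_rng(self.seed)
        g = self.gc_fraction / 2.0
        a = (1.0 - self.gc_fraction) / 2.0
        bases = rng.choice(np.array(list("ACGT")), size=self.length_bp, p=[a, g, g, a])
        return "".join(bases)


def make_contigs(
    genome: SyntheticGenome,
    n_contigs: int,
    length_distribution: int | tuple[int, int] | Sequence[int] = (1501, 5000),
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Cut contigs out of a synthetic genome.

    ``length_distribution`` is a fixed length, a (lo, hi) range sampled
    uniformly, or an explicit length per contig. Contigs are substrings of
    the genome (so alignment-based completeness is well defined) at random
    start positions; deterministic given the seed.
    """
    rng = np.random.default_rng(genome.seed + 1 if seed is None else seed)
    if isinstance(length_distribution, int):
        lengths = [length_distribution] * n_contigs
    elif isinstance(length_distribution, tuple) and len(length_distribution) == 2:
        lo, hi = length_distribution
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_contigs)]
    else:
        lengths = [int(x) for x in length_distribution]
        if len(lengths) != n_contigs:
            raise ValueError("explicit length list must have n_contigs entries")
    if any(L < 1 for L in lengths):
        raise ValueError("contig lengths must be >= 1")
    if max(lengths, default=0) > genome.length_bp:
        raise ValueError("contig longer than the genome")
    seq = genome.sequence()
    contigs = []
    for i, L in enumerate(lengths):
        start = int(rng.integers(0, genome.length_bp - L + 1))
        contigs.append((f"{genome.label}_contig{i:04d}", seq[start : start + L]))
    return contigs


# ---------------------------------------------------------------------------
# sorting / MDA outcome batches

def simulate_batch(
    cells: Sequence[tuple[str, SyntheticTruth]],
    experiment_id: str,
    references: Sequence[str],
    p_mda_success: float = 0.43,
    nonspecific_max: float = 35.0,
    contamination_max: float = 1.5,
    completeness_range: tuple[float, float] = (20.0, 99.0),
    seed: int = 0,
) -> list[CellSeqRecord]:
    """Stochastic sorting/MDA/sequencing outcome table for sorted cells.

    Each sorted cell succeeds at MDA with probability ``p_mda_success``;
    failures yield no record but stay in the success-rate denominator (kept
    by the caller as the sorted count). A successful record maps mostly to
    its own reference, loses a uniform(0, ``nonspecific_max``)% slice to
    nonspecific amplification, and picks up a small uniform(0,
    ``contamination_max``)% cross-contamination from one random non-self
    reference — mirroring benchmark batches where cross-contamination is
    mostly below half a percent. Row percentages are rounded to 2 decimals
    and closed to sum to 100.
    """
    if not 0.0 <= p_mda_success <= 1.0:
        raise ValueError("p_mda_success must be in [0, 1]")
    if nonspecific_max < 0 or contamination_max < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for cell_id, truth in cells:
        if rng.random() >= p_mda_success:
            continue  # MDA-negative: no sequencing record
        own = truth.species_label
        if own not in references:
            raise ValueError(f"cell {cell_id}: species {own!r} not among references {references}")
        nonspecific = float(rng.uniform(0.0, nonspecific_max))
        mapped = {ref: 0.0 for ref in references}
        contamination = 0.0
        others = [ref for ref in references if ref != own]
        if others and contamination_max > 0:
            victim = others[int(rng.integers(len(others)))]
            contamination = float(rng.uniform(0.0, contamination_max))
            mapped[victim] = contamination
        mapped[own] = 100.0 - nonspecific - contamination
        mapped = {ref: round(v, 2) for ref, v in mapped.items()}
        hit_no = round(100.0 - sum(mapped.values()), 2)
        lo, hi = completeness_range
        records.append(
            CellSeqRecord(
                sample_id=cell_id,
                experiment_id=experiment_id,
                mapped_pct=mapped,
                hit_no_genomes_pct=hit_no,
                taxonomy_bin=own,
                completeness_pct=round(float(rng.uniform(lo, hi)), 2),
                contaminant_bins_pct_bound=round(contamination, 2),
                is_negative_control=False,
                consistent_with_sort=True,
            )
        )
    return records


# ---------------------------------------------------------------------------
# heavy-water incubation time courses

def make_timecourse(
    times_h: Sequence[float] = (6.0, 12.0, 18.0, 24.0),
    n_cells: int = 100,
    plateau_cdr: float = 0.2,
    tau_h: float = 6.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[tuple[float, np.ndarray]], np.ndarray]:
    """Saturating-uptake C-D ratio time course with per-cell noise.

    Mean CDR follows plateau * (1 - exp(-t / tau)); per-cell values add
    Gaussian noise, clipped to [0, 1]. Returns ((time, per-cell CDRs), ...)
    plus the noiseless mean truth per time point.
    """
    rng = np.random.default_rng(seed)
    truth = plateau_cdr * (1.0 - np.exp(-np.asarray(times_h, dtype=float) / tau_h))
    points = []
    for t, mu in zip(times_h, truth):
        vals = np.clip(rng.normal(mu, noise_sd, size=n_cells), 0.0, 1.0)
        points.append((float(t), vals))
    return points, truth
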