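# Methods

## Scope and model

The package implements the computational layer of a Raman-activated
cell-sorting-and-sequencing workflow in five parts: (i) a synthetic-data
generator with analytic ground truth, (ii) spectral preprocessing, (iii)
metabolic phenotyping and sorting decisions, (iv) sequencing-QC statistics
for sorted-cell genomes, and (v) a thin CLI. Wet-lab stages (microfluidics,
MDA chemistry, library preparation) and external tools (assemblers,
taxonomic classifiers, marker-gene completeness estimators) are out of
scope; their outputs are modeled as input records.

## Synthetic spectra

A generated spectrum is a sum of Gaussian bands, a polynomial baseline
(degree ≤ 5, evaluated on a [0, 1]-rescaled axis), an optional broad
fluorescence Gaussian, and i.i.d. Gaussian noise, on a default axis of
400–3,200 cm⁻¹ at 1 cm⁻¹ (2,801 points), which covers every band window
used anywhere in the package. Gaussians were chosen because their area has
the closed form amplitude · σ · √(2π), which makes the ground-truth C-D
ratio of a generated cell exact by construction:

true CDR = Σ area(C-D bands) / (Σ area(C-D) + Σ area(C-H)),

computed from full-line analytic areas before baseline and noise are added.
Note the band *windows* used by the measurement clip the Gaussian tails
(the C-H window keeps ≈ 98.3 % of a σ = 60 band at 2,930 cm⁻¹, the C-D
window ≈ 99.8 % of a σ = 40 band at 2,157 cm⁻¹), so even a perfect
measurement sits ≈ 1.3 % relative above the analytic truth at default band
shapes. Tolerances in the tests account for this known, deterministic bias.

Default study conditions (one choice, fixed): C-H band at 2,930 cm⁻¹
(σ = 60), C-D at 2,157 cm⁻¹ (σ = 40) with amplitude set from a target CDR
of 0.18 for labeled cells, carotenoid bands at 1,008/1,158/1,523 cm⁻¹ with
resonance-scale amplitudes (≈ 2–3× the C-H peak height), per-cell lognormal
amplitude jitter (CV 10 %), noise σ = 0.05 a.u. (C-H peak SNR ≈ 60; no
published SNR figure exists for the instrument class, so this is a typical
confocal-Raman value), and a gentle cubic baseline plus a broad
fluorescence hump (σ = 500 cm⁻¹, amplitude ≈ 1.3× the C-H peak). The mock
community is the benchmark four-species 1:1:1:1 design — *E. coli*
(D₂O-labeled), *H. pylori*, *S. elongatus* (carotenoid-containing),
*S. cerevisiae* — with largest-remainder rounding of species counts so they
sum exactly to the requested cell number.

What the generator does **not** emulate: cosmic-ray spikes, detector
etaloning, wavenumber-calibration drift, cell-to-cell variation in band
positions/shapes, and carotenoid resonance swamping the C-H region. Passing
recovery tests therefore demonstrate correctness of the computational
contract under a clean, plausible spectral model — not robustness to every
instrumental artifact of real spectra.

## Preprocessing

The pipeline is dark/background subtraction (pointwise), baseline
correction, and normalization to unit C-H band area; the processing state
is tracked and transitions only forward. Baseline estimation is asymmetric
least squares (Whittaker smoother with asymmetric weights, p = 0.01, 10
iterations). The smoothness parameter defaults to λ = 1e8: the ALS
smoothing length grows as λ^(1/4) points, and at 1 cm⁻¹ sampling a λ near
1e5 (a common literature default for coarser axes) absorbs the broad C-H
and C-D bands themselves — measured CDR error ≈ +0.12 absolute — whereas
λ = 1e8 keeps a flat-input spectrum within 1e-4 a.u., removes a linear ramp
to the same precision, recovers a σ = 20 peak on a cubic baseline to 0.2 %
area error, and inflates a noiseless peak-on-flat area by < 1 %.

Band areas are trapezoidal integrals on the native axis (no resampling, so
results are bit-reproducible), with negative intensities clipped to zero by
default so post-correction noise cannot produce negative areas feeding the
CDR. Savitzky–Golay smoothing (window 9, order 3) is available but off by
default.

## Phenotyping

**CDR** is computed on baseline-corrected (or C-H-normalized — the ratio is
scale-invariant) spectra over the canonical windows C-D = [2,040, 2,300]
and C-H = [2,800, 3,100] cm⁻¹. The positivity threshold defaults to 0.05
and should be calibrated per dataset with `calibrate_cdr_threshold`
(default rule: mean + 3 sd of an unlabeled control population, the standard
stable-isotope-probing convention; alternatives: control maximum or a fixed
value).

**Carotenoid calls** estimate noise from the biologically silent
1,800–1,900 cm⁻¹ region and compute a per-band SNR as band *prominence*
divided by noise σ, where prominence is the in-window maximum minus the
local background linearly interpolated from 5-point medians just outside
the window edges. With a perfectly flat corrected baseline this reduces to
the plain in-window maximum; the local-background term exists because any
baseline stiff enough to preserve the broad C-H/C-D band areas leaves a
smooth residual (~0.3–0.6 a.u. under the default fluorescence hump) that a
raw maximum would misread as signal. A cell is positive when SNR(*v*₃) ≥ k
and SNR(*v*₁) or SNR(*v*₂) ≥ k, with k = 5; *v*₃ anchors the rule because
the C=C stretch is the strongest resonance band. Carotenoid-positive cells'
CDR values are flagged `post_quench_unavailable` in phenotype tables, since
instruments photobleach carotenoids before reading C-D in practice.

**Time courses** are summarized per time point (mean/median/sd of per-cell
CDR). The plateau flag is true when the final inter-timepoint mean increase
falls below 10 % of the total rise plus two standard errors of that final
increase; the uncertainty allowance prevents sampling noise from flipping
the call exactly at saturation, and vanishes for noiseless input. A flat
course counts as plateaued. Replicate profiles on a shared time grid get
pairwise Pearson correlations.

## Sequencing-QC statistics

Percentage statistics (per-species mean mapping rate and completeness,
success rates) use exact rational arithmetic with half-up rounding to the
printed precision (2 decimals for table statistics, fewer where published
values are printed so), so bundled benchmark tables reproduce their derived
columns exactly. Success rates support both published numerator
definitions — validated sequencing records, or externally supplied
MDA-positive counts — via an explicit argument; neither is guessed as
canonical. Row-sum validation of QC records warns rather than fails outside
[99, 101] because published benchmark rows themselves stray to ≈ 96–106.

**Completeness by aligned bases** is the fraction of reference positions
covered by ≥ 1 contig alignment (union of intervals), using a simplified
exact 31-mer anchor + ungapped extension aligner. This is exact for
synthetic contigs drawn as reference substrings and is *not* a
general-purpose aligner; marker-gene completeness estimation on real data
is out of scope.

**GC profiles** tile 200-bp windows (step = window by default; the tiling
choice gives independent windows for moment tests, a true sliding step is
configurable). N and other ambiguity codes are excluded from numerator and
denominator; all-ambiguous windows are skipped; the trailing partial window
is dropped. Profiles report mean, sd, skewness and excess kurtosis plus the
matched normal parameters for overlay.

**Tetranucleotide signatures** count canonical (strand-merged) 4-mers —
136 features — over contigs longer than 1,500 bp, row-normalized to the
simplex; k-mers containing non-ACGT characters are skipped.
Canonicalization is used because contig strand is arbitrary. The 2-D
embedding delegates to scikit-learn's t-SNE (PCA initialization, seeded,
deterministic per seed); the package's contract is the feature computation
and the separation property, not the embedding algorithm.

**Pathway modules** are bundled static step lists: MEP (dxs, dxr, ispD,
ispE, ispF, ispG, ispH, idi, ispA — the canonical methylerythritol-
phosphate chain through the FPP prenyltransferase), β-carotene (crtE, crtB,
crtI, lcyB) and astaxanthin (crtW, crtZ). Coverage is the fraction of steps
present in a sample's gene calls, with a union mode for collective coverage
across samples; no database queries are made.

## Problem sizes and numerical choices

Stochastic checks use 200 cells for CDR recovery and joint classification,
three 400-kb genomes × 100 contigs of 2 kb for the embedding, and 200
replicate batches for MDA-outcome means — sizes at which the tested
properties are stable across seeds while the whole suite stays fast.
Half-up rounding is implemented with exact `Fraction`/`Decimal` arithmetic
(never binary-float rounding) because several published averages sit
exactly on a .005 boundary. Ties in top-bin taxonomy break alphabetically
with a warning. Degenerate inputs (empty spectra, zero C-H area, all-N
windows, empty communities) raise descriptive errors rather than
propagating NaNs.

## Known limitations

- The ALS corrector cannot simultaneously hug a strongly curved
  fluorescence background and preserve very broad bands perfectly; the
  residual is handled at the detector level (prominence), and CDR carries a
  small positive bias (≈ +0.01 absolute at default conditions) that stays
  well inside the 0.02 recovery tolerance.
- The exact-anchor completeness aligner assumes contigs are substrings of
  the reference (no sequencing error, no SNVs); it under-covers diverged
  sequence by design.
- Order-0 genome models reproduce GC-driven 4-mer separation but not
  higher-order codon or repeat structure of real genomes.
- Area (not peak-height) normalization to the C-H band is assumed; the two
  conventions differ by a band-shape factor that cancels in the CDR.
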