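# Methods

## Model

The package models nonspecific ("nonconsensus") protein–DNA attraction with
an ensemble of random binders. Each binder carries one Gaussian energy
constant per nucleotide, K_α ~ N(0, σ²), α ∈ {A, T, C, G}, and contacts
M consecutive base pairs; its energy at start position i is
U(i) = −Σ_j K_{base(j)} over the footprint. Within a sliding window of
width L the binder equilibrates over all fully contained starts, giving
Z = Σ exp(−U/k_BT) and F = −k_BT ln Z. The reported quantity is the
ensemble mean ⟨F⟩ (or per-bp f = ⟨F⟩/M) assigned to the window centre.

The physics is entropic: a repeat-rich window makes the U(i) values more
dispersed across binders and positions (for long alternating two-nucleotide
tracts the spectrum width is σ_U = Mσ versus σ√((M²+3M)/4) for i.i.d.
sequence, a ratio 2/√(1+3/M) → 2), and a wider spectrum always lowers the
free energy. No motif information or fitted parameter enters anywhere; the
DNA sequence is the only input.

### Parameters and units

| parameter | default | meaning |
|---|---|---|
| M | 8 bp | contacts per binding event (typical TFBS size) |
| L | 50 bp (36 for PBM probes) | sliding-window width; ~one protein sliding event |
| σ | 2 k_BT | std of the energy constants (≈1.2 kcal/mol at 300 K) |
| k_BT | 1 (internal unit) | thermal energy; kcal/mol conversion uses k_B = 1.987×10⁻³ kcal/(mol·K), default T = 300 K |
| n_binders | 250 | ensemble size (genomic analyses) |
| n_shuffles | 25 | shuffle realizations for δF = F − F_rand |

All energies are in k_BT; tracks are k_BT per bp.

## Numerical and design choices

* **Footprint containment.** Binder starts are restricted to lie entirely
  inside the window: n_starts = L − M + 1 (43 for genomic windows, 29 for
  36-bp probes). Allowing overhang would make window values depend on
  sequence outside the nominal window; full containment gives one rule for
  genomic windows and fixed-length probes alike. The robustness sweep guards
  the qualitative conclusions against this and the other discretization
  choices.
* **Log-sum-exp stabilization** is mandatory in every partition-function
  evaluation: energies scale with Mσ, so raw exponentials overflow at large
  footprints. An exhaustive-enumeration oracle (windows ≤ 12 bp, M ≤ 4)
  pins the stabilized path to the naive sum at 10⁻¹⁰.
* **One shared ensemble per run.** All windows of a run are scored with the
  same seeded ensemble, which makes tracks bitwise reproducible and lets
  ensemble noise cancel in comparisons between positions.
* **Coordinates.** 0-based half-open everywhere; window values sit on the
  centre bp (even L: the left-of-middle base, offset L/2 − 1). Window
  centres are anchored to the absolute grid {0, stride, 2·stride, …} so
  tracks computed with different L remain position-comparable.
* **Missing data.** Windows containing ambiguous bases and windows that do
  not fit the chromosome yield missing values (NaN), not errors, in track
  mode; metagene rows with out-of-bounds grids are excluded and counted.
* **Shuffle normalization.** F_rand averages uniform permutations of the
  window's own bases (fixed nucleotide content; dinucleotide-preserving
  shuffles are out of scope). Each window's shuffles are seeded from
  (run seed, window centre), so results are independent of evaluation order.
  A homopolymer window gives δF = 0 identically.
* **Binned statistics** use equal-count (quantile) bins with stable-sort tie
  breaking; bin sizes differ by at most one. Correlations are Pearson R with
  the standard two-sided t-test p-value. PBM classification uses the binned
  R/p (50 bins) as the headline statistic, with the unbinned values kept for
  diagnostics; a factor is "negative"/"positive" when p < 0.05 with the
  corresponding sign, else "ns". Intensities are z-scored per factor before
  panel-level pooling (raw pooling is available).
* **Permutation test.** Group labels are permuted over precomputed
  per-window integrated free energies (a property test verifies this equals
  naive recomputation). The default alternative is *less* — the model's
  a-priori direction, bound group lower. Choosing the direction from the
  observed sign instead would compress null p-values onto (0, 0.5) and break
  calibration; with the fixed direction the null p-value distribution is
  uniform, which the test suite checks. No pseudo-count is added: a zero
  exceedance count is reported as the bound p < 1/n_perm.
* **Robustness sweep.** Tracks across (M, L) settings are compared by
  Spearman correlation on commonly defined positions. Tracks with different
  window widths resolve different scales, so their *raw* per-bp rank
  agreement is intrinsically limited (measured ≈0.3–0.6 between L = 30 and
  L = 100 even on noise-free, strongly tract-enriched sequence). The sweep
  therefore offers an optional common-resolution smoothing (NaN-aware moving
  average, ≥ the largest L) that compares the landscapes like-for-like;
  footprint (M) sweeps at fixed L need no smoothing.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume, plus machine-readable truth; every generator is a pure function of
(spec, seed), with per-module child seeds.

* **Genomes**: i.i.d. background (uniform by default) interleaved with
  homonucleotide tracts of geometric length (mean 12 bp, matching the rapid
  length decay of natural poly(dA:dT) tracts), alternating through a tract
  alphabet ({A, T} by default). A block variant alternates kb-scale
  tract-rich and plain blocks, mimicking the concentration of
  low-complexity sequence in promoter/NFR regions — this provides the
  landscape structure above window scale that the robustness sweep needs.
* **Genes and tracks**: TSSs on a jittered grid with random strands; each
  upstream (−300, −50) region receives planted tracts scaled by a boost
  parameter. Occupancy is a monotone transform of the *true* f landscape:
  per-factor propensity exp(β_TF·z(f) + smoothed noise) thresholded at the
  0.9 quantile gives peak intervals (β_TF < 0 enforced), and the combined
  occupancy counts factors per bp; the nucleosome surrogate is
  β_nuc·z(f) + noise with β_nuc > 0. The exponential-threshold construction
  keeps counts non-negative and the coupling monotone; no claim is made that
  it reproduces ChIP-seq noise statistics.
* **PBM panels**: probes mix i.i.d. 36-mers with tract-bearing ones
  (planted 8–24 bp runs) to spread the true ⟨f⟩; class fractions default to
  (0.76, 0.13, 0.11) negative/positive/null with intensity slopes ∓2 noise
  SD against the z-scored true ⟨f⟩. Truth energies use a generator-private
  ensemble seed so analysis ensembles are never reused as truth.
* **Protein groups**: background residues i.i.d. from a TF-like composition
  (basic residues Lys/Arg and low-complexity-prone Ser/Pro/Gln enriched over
  uniform, as in eukaryotic DNA-binding proteins); group 1 receives planted
  a···a pairs with Poisson-distributed extra counts reaching the requested
  enrichment over the background expectation.

What passing tests on these data do **not** show: real chromatin effects
(nucleosome positioning sequence preferences, chromatin remodellers, steric
competition), ChIP-seq read-level artefacts, PBM probe-design structure
(de Bruijn 8-mer coverage), isoform-resolved TSS annotation, or evolutionary
correlation between repeats and function. The synthetic recovery results
demonstrate correctness of the computations and calibration of the
statistics, not biological effect sizes.

## Problem sizes

Analyses are sized for a single CPU: spectrum-width ratios use 10⁶–4×10⁸
energy draws; shuffle-normalization calibration uses 20 seeds × 2-kb
genomes; the robustness sweep a 100-kb block genome at 8-bp stride; sign
recovery a 60-kb genome with 30 genes; PBM recovery 30 factors × 200 probes
with 200-run null calibration; the permutation test 150 windows × 1000
permutations × 200 null runs; repeat-detection power 100 runs of 41 + 41
proteins of length 400. Error tolerances in the tests follow the analytic
standard errors of the corresponding estimators (e.g. the ensemble-mean F
of a homopolymer has SE = Mσ/√n_binders).

## Known limitations

* Exact-match motif scanning only (no PWMs or IUPAC degeneracy).
* Fixed-content shuffles only; no dinucleotide preservation or GC-isochore
  correction.
* The binder model ignores protein conformational states and
  sequence-independent electrostatics; it is a statistical, not atomistic,
  description.
* KS p-values in the protein-pattern sweep are reported raw, without
  multiple-testing correction (the output notes this); the null
  false-positive rate of the full 100-feature sweep is checked to stay near
  the nominal 5%.
* Multiple annotated TSSs per gene are not collapsed; the annotation is
  taken as given, one TSS per record.
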