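# ncbind — nonconsensus protein–DNA binding free-energy landscapes

Transcription factors (TFs) bind many genomic regions that contain no
recognizable consensus motif. A statistical-mechanics explanation is
*nonconsensus* binding: repetitive, low-complexity DNA — most prominently
poly(dA:dT) tracts — widens the spectrum of binding energies available to an
arbitrary DNA-binding protein and therefore lowers its binding free energy,
without any sequence-specific recognition. `ncbind` implements this
random-binder model and the analyses built on it: genome-wide free-energy
landscapes, TSS metagene profiles, occupancy correlations, protein-binding
microarray (PBM) panel classification, bound-vs-unbound motif-context
permutation tests, and protein-sequence repeat statistics — all driven by
synthetic data with known ground truth, so every stage is testable offline.

## The model

A *random binder* is a model TF defined by four energy constants
K_A, K_T, K_C, K_G, drawn i.i.d. from a zero-mean Gaussian with standard
deviation σ = 2 k_BT (≈ 1.2 kcal/mol at 300 K, a typical hydrogen-bond
scale). Contacting M = 8 consecutive base pairs starting at position i, its
energy is

    U(i) = − Σ_{j=i}^{i+M−1} K_{base(j)}        [k_BT]

Within a sliding window of width L = 50 bp the binder samples every fully
contained start (L − M + 1 = 43 of them), giving a partition function and
free energy

    Z = Σ_i exp(−U(i)/k_BT),    F = −k_BT ln Z

Averaging F over an ensemble of 250 random binders and assigning ⟨F⟩/M to
the window centre yields the per-bp nonconsensus free-energy track f.
Homo-oligonucleotide tracts widen the U spectrum (σ_U on long alternating
two-nucleotide tracts approaches twice the i.i.d. value as M grows; the
finite-M ratio is 2/√(1+3/M)), so repeat-rich sequence has low f. A
shuffle-normalized variant δf = (⟨F⟩ − ⟨F_rand⟩)/M, with F_rand averaged
over 25 within-window composition-preserving shuffles, isolates the effect
of sequence *arrangement* from plain nucleotide content. For 36-bp PBM
probes the probe itself is the window (29 binder positions, no sliding).

## Worked example

```python
from ncbind import ModelParams, sample_binder_ensemble, mean_free_energy
from ncbind.simulate import GenomeSpec, gen_genome, gen_genes_and_tracks
from ncbind.tss import gene_aligned_matrix, average_profile
from ncbind.assoc import linear_association

params = ModelParams()                      # M=8, L=50, sigma=2 kBT, 250 binders
ensemble = sample_binder_ensemble(params)

F, f = mean_free_energy(ensemble, "A" * 25 + "T" * 25, params)
print(f"alternating poly(A)/poly(T) window: <F> = {F:.3f} kBT, f = {f:.4f} kBT/bp")
F, f = mean_free_energy(ensemble, ("ACGT" * 13)[:50], params)
print(f"periodic mixed window:              <F> = {F:.3f} kBT, f = {f:.4f} kBT/bp")

genome = gen_genome(GenomeSpec(length=60_000, tract_fraction=0.02, seed=23))
bundle = gen_genes_and_tracks(genome, n_genes=30, seed=23)
mat_f = gene_aligned_matrix(bundle.f_track, bundle.genes, flank=500, step=4)
mat_o = gene_aligned_matrix({bundle.genome.chrom: bundle.tf_occupancy.astype(float)},
                            bundle.genes, flank=500, step=4)
prof_f = average_profile(mat_f, n_subgroups=10, seed=1)
prof_o = average_profile(mat_o, n_subgroups=10, seed=1)
R, p, n = linear_association(prof_f["mean"], prof_o["mean"])
pos_min = prof_f.loc[prof_f["mean"].idxmin(), "position"]
print(f"metagene <f> minimum at TSS-relative position {pos_min:+d} bp")
print(f"<f> vs combined occupancy: R = {R:.3f}, p = {p:.2e} (n = {n} positions)")
```

Output:

```
alternating poly(A)/poly(T) window: <F> = -11.700 kBT, f = -1.4624 kBT/bp
periodic mixed window:              <F> = -2.993 kBT, f = -0.3741 kBT/bp
metagene <f> minimum at TSS-relative position -124 bp
<f> vs combined occupancy: R = -0.977, p = 3.56e-170 (n = 251 positions)
```

The tract-rich window sits far below the mixed-sequence window (repeats
widen the energy spectrum and lower F). On the synthetic bundle — whose
genes carry upstream tract enrichment and whose occupancy tracks were
generated with negative coupling to the true landscape — the metagene free
energy dips upstream of the TSS and anti-correlates with combined TF
occupancy, the model's two genomic signatures.

## Command line

A thin CLI wraps the library (`ncbind --help`): `simulate` writes a full
synthetic bundle (FASTA/BED/bedGraph + truth manifest), `landscape` computes
f or δf tracks, `tss-profile` builds metagene tables, `correlate` reports
track associations, `pbm` classifies probe panels, `motif-context` runs the
bound/unbound permutation test, and `protein-patterns` compares protein
groups. Any flag can come from a YAML config via `--config`.

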