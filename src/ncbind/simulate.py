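"""Synthetic-data generators with machine-readable ground truth.

Every analysis stage in this package can be exercised without any external
download: these generators produce genomes with planted homonucleotide
tracts, gene sets whose upstream regions are tract-enriched, occupancy
tracks coupled (with known sign) to the true free-energy landscape, PBM
probe panels with planted negative/positive/null factor classes, and protein
groups with planted residue-repeat enrichments.  Each generator is a pure
function of its spec and seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import BASES, ModelParams, decode_sequence, encode_sequence, sample_binder_ensemble
from .landscape import FreeEnergyTrack, landscape_track
from .pbm import probe_free_energies
from .proteins import AMINO_ACIDS, PatternSpec

logger = logging.getLogger(__name__)

#: Background amino-acid composition used for synthetic transcription factors.
#: Basic residues (Lys, Arg) and low-complexity-prone residues (Ser, Pro, Gln)
#: are enriched relative to a uniform alphabet, as is typical of eukaryotic
#: DNA-binding proteins.
TF_COMPOSITION = {
    "A": 0.070, "C": 0.015, "D": 0.050, "E": 0.065, "F": 0.030,
    "G": 0.060, "H": 0.025, "I": 0.045, "K": 0.070, "L": 0.090,
    "M": 0.020, "N": 0.045, "P": 0.060, "Q": 0.055, "R": 0.060,
    "S": 0.085, "T": 0.060, "V": 0.060, "W": 0.010, "Y": 0.025,
}


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for a synthetic genome: iid background plus planted tracts.

    ``tract_fraction`` is the expected fraction of bases inside
    homonucleotide tracts; tract lengths are geometric with mean
    ``tract_mean_len`` (12 bp default, mimicking the rapid length decay of
    natural poly(dA:dT) tracts); tract types alternate through
    ``tract_alphabet``.
    """

    length: int = 100_000
    tract_fraction: float = 0.0
    tract_mean_len: float = 12.0
    tract_alphabet: tuple[str, ...] = ("A", "T")
    background_comp: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if not 0.0 <= self.tract_fraction <= 1.0:
            raise ValueError("tract_fraction must be in [0, 1]")
        if self.tract_mean_len < 1:
            raise ValueError("tract_mean_len must be >= 1")
        if abs(sum(self.background_comp) - 1.0) > 1e-9 or min(self.background_comp) < 0:
            raise ValueError("background_comp must be non-negative and sum to 1")
        if any(b not in BASES for b in self.tract_alphabet):
            raise ValueError("tract_alphabet entries must be A/C/G/T")


@dataclass
class SyntheticGenome:
    sequence: str
    tracts: pd.DataFrame  # chrom, start, end, base
    spec: GenomeSpec
    chrom: str = "chrS"


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(1.0 / mean))


def gen_genome(spec: GenomeSpec) -> SyntheticGenome:
    """iid background interleaved with geometric-length homonucleotide tracts."""
    rng = np.random.default_rng(spec.seed)
    codes = rng.choice(4, size=spec.length, p=spec.background_comp).astype(np.int8)
    tracts = []
    if spec.tract_fraction > 0:
        f = spec.tract_fraction
        mean_gap = spec.tract_mean_len * (1.0 - f) / f if f < 1 else 0.0
        pos, t = 0, 0
        if mean_gap > 0:
            pos = _geometric_len(rng, mean_gap)
        while pos < spec.length:
            tlen = min(_geometric_len(rng, spec.tract_mean_len), spec.length - pos)
            base = spec.tract_alphabet[t % len(spec.tract_alphabet)]
            codes[pos : pos + tlen] = BASES.index(base)
            tracts.append(("chrS", pos, pos + tlen, base))
            t += 1
            pos += tlen
            pos += _geometric_len(rng, mean_gap) if mean_gap > 0 else 0
    tract_df = pd.DataFrame(tracts, columns=["chrom", "start", "end", "base"])
    return SyntheticGenome(decode_sequence(codes), tract_df, spec)


def gen_block_genome(
    n_blocks: int = 50,
    block_length: int = 2000,
    tract_fraction: float = 0.7,
    tract_mean_len: float = 14.0,
    seed: int = 0,
) -> SyntheticGenome:
    """Genome of alternating tract-rich and plain iid blocks.

    Odd blocks are iid; even blocks carry homonucleotide tracts at
    ``tract_fraction``.  The kb-scale alternation mimics how low-complexity
    (poly(dA:dT)-rich) sequence concentrates in promoter/NFR regions while
    gene bodies stay closer to iid -- giving the free-energy landscape
    genuine structure at scales larger than any analysis window.
    """
    parts, tracts, offset = [], [], 0
    for b in range(n_blocks):
        frac = tract_fraction if b % 2 == 0 else 0.0
        spec = GenomeSpec(
            length=block_length, tract_fraction=frac,
            tract_mean_len=tract_mean_len, seed=seed * 1000 + b,
        )
        g = gen_genome(spec)
        parts.append(g.sequence)
        if len(g.tracts):
            t = g.tracts.copy()
            t["start"] += offset
            t["end"] += offset
            tracts.append(t)
        offset += block_length
    tract_df = (
        pd.concat(tracts, ignore_index=True)
        if tracts
        else pd.DataFrame(columns=["chrom", "start", "end", "base"])
    )
    spec = GenomeSpec(length=offset, tract_fraction=tract_fraction / 2,
                      tract_mean_len=tract_mean_len, seed=seed)
    return SyntheticGenome("".join(parts), tract_df, spec)


@dataclass
class SimBundle:
    """A full synthetic study: genome, genes, tracks, peaks, and truth."""

    genome: SyntheticGenome
    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    f_track: FreeEnergyTrack
    tf_occupancy: np.ndarray = field(repr=False)
    nucleosome: np.ndarray = field(repr=False)
    tf_peaks: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    params: ModelParams = field(default_factory=ModelParams)


def _plant_upstream_tracts(
    codes: np.ndarray,
    tss: int,
    strand: str,
    boost: float,
    rng: np.random.Generator,
    region: tuple[int, int] = (-300, -50),
    tract_mean_len: float = 15.0,
) -> None:
    """Write alternating poly(A)/poly(T) tracts into a gene's upstream region.

    Total planted bases scale with ``boost`` (120 bp at boost=1 for the
    default 250-bp region).
    """
    lo, hi = region
    if strand == "+":
        a, b = tss + lo, tss + hi
    else:
        a, b = tss - hi, tss - lo
    a, b = max(a, 0), min(b, len(codes))
    if b - a < 2:
        return
    target = min(int(boost * 120), b - a)
    planted, t = 0, int(rng.integers(2))
    while planted < target:
        tlen = min(_geometric_len(rng, tract_mean_len), target - planted)
        start = int(rng.integers(a, b - tlen + 1)) if b - tlen + 1 > a else a
        codes[start : start + tlen] = 0 if t % 2 == 0 else 3
        planted += tlen
        t += 1


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, scale: int = 25) -> np.ndarray:
    """Gaussian noise smoothed with a moving average of width ``scale`` bp."""
    eps = rng.normal(0.0, 1.0, n + scale)
    kernel = np.ones(scale) / scale
    sm = np.convolve(eps, kernel, mode="valid")[:n]
    return sd * sm / sm.std()


def gen_genes_and_tracks(
    genome: SyntheticGenome,
    n_genes: int = 80,
    upstream_tract_boost: float = 1.0,
    beta_tf: float = -1.0,
    beta_nuc: float = 1.0,
    noise_sd: float = 0.5,
    n_tfs: int = 10,
    peak_quantile: float = 0.9,
    params: ModelParams | None = None,
    seed: int = 0,
) -> SimBundle:
    """Plant TSS-proximal tracts and couple occupancy tracks to the f landscape.

    TSSs are placed on a jittered regular grid with random strands; each
    gene's upstream (-300,-50) region receives poly(A)/poly(T) tracts scaled
    by ``upstream_tract_boost``.  The true per-bp free-energy track f is then
    computed, standardized to z, and occupancy is generated as a monotone
    transform of it: per-factor binding propensity ``exp(beta_tf * z + noise)``
    thresholded at ``peak_quantile`` gives that factor's peak intervals
    (combined occupancy = number of factors bound per bp, negative coupling
    required); the nucleosome surrogate is ``beta_nuc * z + noise`` (positive
    coupling required).
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if beta_tf >= 0:
        raise ValueError("beta_tf must be negative (factors prefer low f)")
    if beta_nuc <= 0:
        raise ValueError("beta_nuc must be positive (nucleosomes prefer high f)")
    if params is None:
        params = ModelParams()
    rng = np.random.default_rng(seed)
    codes = encode_sequence(genome.sequence).copy()
    n = len(codes)
    margin = 1600
    if n < 2 * margin + n_genes:
        raise ValueError("genome too short for the requested gene count")
    grid = np.linspace(margin, n - margin, n_genes)
    tss = (grid + rng.integers(-200, 201, size=n_genes)).astype(int)
    strands = rng.choice(["+", "-"], size=n_genes)
    for t, s in zip(tss, strands):
        _plant_upstream_tracts(codes, int(t), s, upstream_tract_boost, rng)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "chrom": genome.chrom,
            "tss": tss,
            "strand": strands,
        }
    )
    seq = decode_sequence(codes)
    f_track = landscape_track(seq, params, stride=1, chrom=genome.chrom)
    fv = f_track.values
    defined = ~np.isnan(fv)
    z = np.zeros(n)
    z[defined] = (fv[defined] - fv[defined].mean()) / fv[defined].std()

    tf_peaks: dict[str, list[tuple[str, int, int]]] = {}
    occupancy = np.zeros(n, dtype=np.int32)
    for t in range(n_tfs):
        propensity = beta_tf * z + _smooth_noise(rng, n, noise_sd)
        thresh = np.quantile(propensity[defined], peak_quantile)
        bound = (propensity > thresh) & defined
        edges = np.flatnonzero(np.diff(np.concatenate([[0], bound.view(np.int8), [0]])))
        ivs = [
            (genome.chrom, int(s), int(e))
            for s, e in zip(edges[::2], edges[1::2])
            if e - s >= 10
        ]
        tf_peaks[f"tf{t:02d}"] = ivs
        for _, s, e in ivs:
            occupancy[s:e] += 1
    nucleosome = beta_nuc * z + _smooth_noise(rng, n, noise_sd)
    nucleosome[~defined] = np.nan

    genome = SyntheticGenome(seq, genome.tracts, genome.spec, genome.chrom)
    return SimBundle(genome, genes, f_track, occupancy, nucleosome, tf_peaks, params)


def gen_pbm_panel(
    n_tfs: int = 30,
    class_fractions: tuple[float, float, float] = (0.76, 0.13, 0.11),
    probes_per_tf: int = 200,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    probe_length: int = 36,
    params: ModelParams | None = None,
    seed: int = 0,
):
    """Synthetic PBM panel with planted (negative, positive, null) classes.

    Probes mix iid 36-mers with tract-bearing ones (a planted 8-24 bp
    homonucleotide run), spreading the true <f>.  Intensities couple to the
    true <f> with slope ``-effect`` (negative class), ``+effect`` (positive)
    or 0 (null), in units of the <f> z-score, plus Gaussian noise.  Returns
    ``(tables, truth)``: {tf_id: DataFrame(probe_id, sequence, intensity)}
    and {tf_id: true class}.
    """
    if abs(sum(class_fractions) - 1.0) > 1e-9:
        raise ValueError("class_fractions must sum to 1")
    if probes_per_tf < 100:
        raise ValueError("probes_per_tf must be >= 100")
    if params is None:
        params = ModelParams().pbm(probe_length)
    rng = np.random.default_rng(seed)
    # largest-remainder apportionment of classes
    raw = np.array(class_fractions) * n_tfs
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n_tfs - counts.sum()]:
        counts[i] += 1
    labels = ["negative"] * counts[0] + ["positive"] * counts[1] + ["ns"] * counts[2]
    # truth free energies use a generator-private ensemble seed
    truth_params = ModelParams(
        M=params.M, L=probe_length, sigma=params.sigma, kBT=params.kBT,
        n_binders=params.n_binders, seed=int(rng.integers(2**31)),
    )
    ensemble = sample_binder_ensemble(truth_params)

    tables, truth = {}, {}
    for t in range(n_tfs):
        tf = f"tf{t:03d}"
        probes = []
        for _ in range(probes_per_tf):
            codes = rng.integers(0, 4, size=probe_length, dtype=np.int8)
            if rng.random() < 0.5:
                tlen = int(rng.integers(8, 25))
                start = int(rng.integers(0, probe_length - tlen + 1))
                codes[start : start + tlen] = rng.choice([0, 3])
            probes.append(decode_sequence(codes))
        f = probe_free_energies(probes, ensemble, truth_params)
        zf = (f - f.mean()) / f.std()
        label = labels[t]
        slope = {"negative": -effect, "positive": effect, "ns": 0.0}[label]
        intensity = 20.0 + slope * zf + rng.normal(0.0, noise_sd, probes_per_tf)
        intensity = np.clip(intensity, 0.0, None)
        tables[tf] = pd.DataFrame(
            {
                "probe_id": [f"{tf}_p{i:05d}" for i in range(probes_per_tf)],
                "sequence": probes,
                "intensity": intensity,
            }
        )
        truth[tf] = label
    return tables, truth


def gen_protein_groups(
    n_per_group: int = 41,
    length: int = 400,
    planted: PatternSpec = PatternSpec("K", 2),
    enrichment: float = 2.0,
    composition: dict[str, float] | None = None,
    seed: int = 0,
):
    """Two synthetic protein groups; group 1 carries a planted repeat enrichment.

    Background residues are iid from ``composition`` (default: the TF-like
    composition ``TF_COMPOSITION``).  Group 1 receives extra planted a..a
    pairs so its expected pattern count is ``enrichment`` times the
    background expectation; group 2 is pure background.  Returns
    ``(group1, group2, truth)`` with groups as {protein_id: sequence}.
    """
    if n_per_group < 5:
        raise ValueError("n_per_group must be >= 5")
    if enrichment < 1.0:
        raise ValueError("enrichment must be >= 1 (swap the groups for depletion)")
    comp = TF_COMPOSITION if composition is None else composition
    aas = list(comp)
    probs = np.array([comp[a] for a in aas])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    span = planted.gap + 1
    p_a = comp.get(planted.residue, 0.0)
    expected = (length - span) * p_a**2

    def make(n: int, plant: bool) -> dict[str, str]:
        group = {}
        for i in range(n):
            residues = rng.choice(aas, size=length, p=probs)
            if plant:
                n_extra = rng.poisson((enrichment - 1.0) * expected)
                for _ in range(n_extra):
                    pos = int(rng.integers(0, length - span))
                    residues[pos] = planted.residue
                    residues[pos + span] = planted.residue
            group[f"{'grp1' if plant else 'grp2'}_{i:03d}"] = "".join(residues)
        return group

    group1 = make(n_per_group, True)
    group2 = make(n_per_group, False)
    truth = {
        "planted_pattern": planted.name,
        "enrichment": enrichment,
        "expected_background_count": expected,
    }
    return group1, group2, truth


def write_bundle(bundle: SimBundle, outdir: str | Path, seed: int | None = None) -> Path:
    """Write a SimBundle as FASTA/BED/bedGraph/TSV plus a truth manifest."""
    from . import io as ncio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = bundle.genome.chrom
    ncio.write_fasta({chrom: bundle.genome.sequence}, outdir / "genome.fa")
    genes_bed = pd.DataFrame(
        {
            "chrom": bundle.genes["chrom"],
            "start": np.where(
                bundle.genes["strand"] == "+", bundle.genes["tss"], bundle.genes["tss"]
            ),
            "end": bundle.genes["tss"] + 1,
            "name": bundle.genes["gene_id"],
            "score": 0,
            "strand": bundle.genes["strand"],
        }
    )
    ncio.write_bed(genes_bed, outdir / "genes.bed")
    bundle.genome.tracts.to_csv(outdir / "tracts.bed", sep="\t", header=False, index=False)
    ncio.write_bedgraph(bundle.f_track, outdir / "f.bedgraph")
    ncio.write_bedgraph(
        FreeEnergyTrack(chrom, 0, bundle.tf_occupancy.astype(float)), outdir / "tf_occupancy.bedgraph"
    )
    ncio.write_bedgraph(
        FreeEnergyTrack(chrom, 0, bundle.nucleosome), outdir / "nucleosome.bedgraph"
    )
    for tf, ivs in bundle.tf_peaks.items():
        ncio.write_bed(
            pd.DataFrame(ivs, columns=["chrom", "start", "end"]), outdir / f"peaks_{tf}.bed"
        )
    manifest = {
        "chrom": chrom,
        "genome_spec": asdict(bundle.genome.spec),
        "n_genes": int(len(bundle.genes)),
        "model_params": asdict(bundle.params),
        "seed": seed,
        "tf_peak_files": sorted(f"peaks_{tf}.bed" for tf in bundle.tf_peaks),
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))
    return outdir
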