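"""Genome-wide free-energy tracks, shuffle normalization, robustness."""
import math

import numpy as np
import pytest
from scipy import stats

from ncbind.energy import ModelParams, sample_binder_ensemble
from ncbind.landscape import (
    landscape_track,
    normalized_track,
    robustness_sweep,
    window_center_offset,
)
from ncbind.motif import reverse_complement
from ncbind.simulate import GenomeSpec, gen_block_genome, gen_genome

from conftest import random_dna


def test_center_offset_convention():
    assert window_center_offset(50) == 24  # even L: left of middle
    assert window_center_offset(51) == 25


class TestLandscapeTrack:
    def test_homopolymer_interior_matches_closed_form(self):
        p = ModelParams(n_binders=4000, seed=9)
        track = landscape_track("A" * 10_000, p)
        vals = track.defined_values()
        expected = -math.log(43) / 8
        se = p.sigma / math.sqrt(p.n_binders)  # per-bp: M sigma / (M sqrt(n))
        assert np.allclose(vals, vals[0])  # constant interior
        assert abs(vals[0] - expected) < 3 * se

    def test_flanks_are_missing(self, default_params, default_ensemble):
        track = landscape_track("ACGT" * 50, default_params, ensemble=default_ensemble)
        assert np.isnan(track.values[:24]).all()
        assert np.isnan(track.values[-25:]).all()
        assert track.defined().sum() == 200 - 50 + 1

    def test_determinism(self, rng, default_params):
        seq = random_dna(rng, 500)
        t1 = landscape_track(seq, default_params)
        t2 = landscape_track(seq, default_params)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_short_sequence_gives_empty_track(self, default_params):
        track = landscape_track("ACGT", default_params)
        assert np.isnan(track.values).all()

    def test_ambiguous_bases_yield_missing_not_error(self, rng, default_params, default_ensemble):
        seq = random_dna(rng, 300)
        seq = seq[:150] + "N" + seq[151:]
        track = landscape_track(seq, default_params, ensemble=default_ensemble)
        # every window overlapping the N is undefined, others defined
        assert np.isnan(track.values[150 - 25 : 150 + 25]).all()
        assert track.defined().sum() == (300 - 50 + 1) - 50

    def test_track_minimum_falls_in_planted_tract(self, rng, default_params):
        seq = random_dna(rng, 3000)
        seq = seq[:1400] + "A" * 200 + seq[1600:]
        track = landscape_track(seq, default_params)
        argmin = np.nanargmin(track.values)
        # the minimizing window must overlap the planted tract
        assert 1400 - 25 <= argmin < 1600 + 25

    def test_translation_equivariance(self, rng, default_params, default_ensemble):
        seq = random_dna(rng, 400)
        k = 7
        shifted = random_dna(rng, k) + seq
        t1 = landscape_track(seq, default_params, ensemble=default_ensemble)
        t2 = landscape_track(shifted, default_params, ensemble=default_ensemble)
        d1 = t1.defined()
        np.testing.assert_allclose(t2.values[k:][d1], t1.values[d1], atol=1e-12)

    def test_reverse_complement_leaves_value_distribution_unchanged(self):
        # per-seed two-sample KS on decorrelated (every L bp) samples
        pvals = []
        for seed in range(3):
            g = np.random.default_rng(seed)
            seq = random_dna(g, 20_000)
            p = ModelParams(n_binders=100, seed=seed)
            ens = sample_binder_ensemble(p)
            v1 = landscape_track(seq, p, ensemble=ens).defined_values()[::50]
            v2 = landscape_track(reverse_complement(seq), p, ensemble=ens).defined_values()[::50]
            pvals.append(stats.ks_2samp(v1, v2).pvalue)
        assert sum(pv > 0.01 for pv in pvals) >= 2


class TestNormalizedTrack:
    def test_homopolymer_delta_is_exactly_zero(self):
        p = ModelParams(n_binders=50, seed=1)
        track = normalized_track("A" * 200, p, stride=10, n_shuffles=5)
        np.testing.assert_array_equal(track.defined_values(), 0.0)

    def test_iid_genome_centered_on_zero(self, rng):
        p = ModelParams(n_binders=150, seed=4)
        seq = random_dna(rng, 2000)
        track = normalized_track(seq, p, stride=10, n_shuffles=25)
        vals = track.defined_values()
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_planted_tracts_go_negative_while_flanks_stay_flat(self, rng):
        p = ModelParams(n_binders=150, seed=4)
        flank = random_dna(rng, 800)
        tract = ("A" * 12 + "T" * 12) * 20  # 480 bp of alternating tracts
        seq = flank + tract + random_dna(rng, 800)
        track = normalized_track(seq, p, stride=10, n_shuffles=25)
        tract_vals = track.values[800:1280]
        # keep flank positions whose windows cannot touch the tract
        flank_vals = np.concatenate([track.values[:750], track.values[1330:]])
        # tract windows are strongly negative; flank windows scatter around 0
        # with intrinsic per-window sd ~0.1 (sequence-driven, not MC error)
        assert np.nanmean(tract_vals) < -0.2
        assert abs(np.nanmean(flank_vals)) < 0.05

    def test_determinism_and_seed_sensitivity(self, rng):
        p = ModelParams(n_binders=30, seed=2)
        seq = random_dna(rng, 300)
        t1 = normalized_track(seq, p, stride=20, n_shuffles=10)
        t2 = normalized_track(seq, p, stride=20, n_shuffles=10)
        np.testing.assert_array_equal(t1.values, t2.values)


class TestRobustnessSweep:
    def test_self_correlation_is_one(self, rng):
        seq = random_dna(rng, 2000)
        p = ModelParams(n_binders=50)
        sw = robustness_sweep(seq, [8], [50], stride=4, base_params=p)
        assert sw.shape == (1, 1) and sw.iloc[0, 0] == 1.0

    def test_invalid_pair_rejected(self, rng):
        with pytest.raises(ValueError):
            robustness_sweep(random_dna(rng, 2000), [8, 40], [30, 50])

    def test_tract_enriched_landscape_is_parameter_robust(self):
        # promoter-like block genome; common-resolution smoothing for the
        # cross-window-width comparison
        g = gen_block_genome(n_blocks=16, block_length=2000, seed=6)
        p = ModelParams(n_binders=250, seed=6)
        sw_m = robustness_sweep(g.sequence, [6, 8, 10], [50], stride=8, base_params=p)
        sw_l = robustness_sweep(
            g.sequence, [8], [30, 50, 100], stride=8, base_params=p, smooth=300
        )
        assert sw_m.to_numpy().min() > 0.8
        assert sw_l.to_numpy().min() > 0.8
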