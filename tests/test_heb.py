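"""HEB computation, five-state HMM segmentation, breakpoint and R2 summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from homeobias import (
    CopyNumberSegmentation,
    HEBTrack,
    HMMParams,
    GeneAnnotation,
    NATURAL_PRESET,
    PhasedCounts,
    RESYNTHESIZED_PRESET,
    breakpoint_stats,
    compute_heb,
    hmm_segment,
    simulate_heb_track,
    variance_explained,
)
from homeobias.heb import _log_emissions, viterbi


def _make_track(heb, chromosome="chr1"):
    heb = np.asarray(heb, dtype=float)
    return HEBTrack(
        individual="ind",
        chromosome=chromosome,
        genes=pd.RangeIndex(len(heb)),
        heb=heb,
        cg=np.round(heb * 100),
        co=np.round((1 - heb) * 100),
    )


def _phased_single(cg, co, individual="t1"):
    idx = pd.Index([f"g{i + 1:03d}" for i in range(len(cg))], name="gene")
    mk = lambda v: pd.DataFrame({individual: v}, index=idx)
    meta = pd.DataFrame({"group": ["Sd"]}, index=pd.Index([individual]))
    return PhasedCounts(mk(cg), mk(co), mk(np.zeros(len(cg))), meta)


def _annotation(n, chromosome="chr1"):
    return GeneAnnotation(
        pd.DataFrame(
            {"chromosome": chromosome, "start": np.arange(n) * 100 + 1},
            index=pd.Index([f"g{i + 1:03d}" for i in range(n)], name="gene"),
        )
    )


class TestComputeHeb:
    def test_heb_arithmetic(self):
        phased = _phased_single([30, 0, 25], [10, 50, 25])
        tracks = compute_heb(phased, _annotation(3), min_cpm=0.0)
        np.testing.assert_allclose(tracks[0].heb, [0.75, 0.0, 0.5])

    def test_conservation_under_subgenome_swap(self):
        cg = np.array([30.0, 5.0, 80.0])
        co = np.array([10.0, 45.0, 20.0])
        t1 = compute_heb(_phased_single(cg, co), _annotation(3), 0.0)[0]
        t2 = compute_heb(_phased_single(co, cg), _annotation(3), 0.0)[0]
        np.testing.assert_allclose(t1.heb + t2.heb, 1.0)

    def test_low_cpm_gene_excluded_across_all_individuals(self):
        idx = pd.Index(["g001", "g002"], name="gene")
        meta = pd.DataFrame({"group": ["Sd", "Sd"]}, index=["t1", "t2"])
        # g002 is weak in t2 only: excluded from every track
        cg = pd.DataFrame({"t1": [5000, 5000], "t2": [9999, 1]}, index=idx)
        co = pd.DataFrame({"t1": [5000, 5000], "t2": [0, 0]}, index=idx)
        un = pd.DataFrame(0, index=idx, columns=["t1", "t2"])
        phased = PhasedCounts(cg, co, un, meta)
        tracks = compute_heb(phased, _annotation(2), min_cpm=1000.0)
        assert all(list(t.genes) == ["g001"] for t in tracks)

    def test_tracks_follow_annotation_order(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                {"chromosome": "chr1", "start": [300, 100, 200]},
                index=pd.Index(["g001", "g002", "g003"], name="gene"),
            )
        )
        phased = _phased_single([10, 20, 30], [10, 20, 30])
        track = compute_heb(phased, ann, 0.0)[0]
        assert list(track.genes) == ["g002", "g003", "g001"]


class TestHmmSegment:
    def test_constant_half_track_is_state_two(self, rng):
        heb = simulate_heb_track(np.full(300, 2), 0.05, rng)
        seg = hmm_segment(_make_track(heb), RESYNTHESIZED_PRESET)
        assert (seg.states == 2).all()
        assert seg.breakpoints == []

    def test_two_segment_track_finds_one_breakpoint(self, rng):
        states = np.array([3] * 200 + [2] * 200)
        heb = simulate_heb_track(states, 0.05, rng)
        seg = hmm_segment(_make_track(heb), RESYNTHESIZED_PRESET)
        assert len(seg.breakpoints) == 1
        assert abs(seg.breakpoints[0] - 200) <= 2
        assert (seg.states[:198] == 3).all() and (seg.states[202:] == 2).all()

    def test_homoeolog_replacement_track_is_state_four(self, rng):
        heb = simulate_heb_track(np.full(250, 4), 0.05, rng)
        seg = hmm_segment(_make_track(heb), RESYNTHESIZED_PRESET)
        assert (seg.states == 4).all()

    def test_mirror_symmetry(self, rng):
        states = np.array([1] * 150 + [3] * 150)
        heb = simulate_heb_track(states, 0.05, rng)
        seg = hmm_segment(_make_track(heb), RESYNTHESIZED_PRESET)
        mirrored = hmm_segment(_make_track(1.0 - heb), RESYNTHESIZED_PRESET)
        np.testing.assert_array_equal(mirrored.states, 4 - seg.states)
        assert mirrored.breakpoints == seg.breakpoints

    def test_near_fixed_transitions_give_single_best_state(self, rng):
        # e -> 1 with huge strength: decoding degenerates to one constant state
        heb = np.concatenate([np.full(34, 0.75), np.full(6, 0.5)])
        heb = expit(logit(heb) + rng.normal(0, 0.02, heb.size))
        params = HMMParams(e=1 - 1e-15, strength=1e15)
        seg = hmm_segment(_make_track(heb), params)
        assert len(np.unique(seg.states)) == 1
        assert seg.states[0] == 3  # majority state wins globally

    def test_single_gene_track(self):
        seg = hmm_segment(_make_track([0.74]), RESYNTHESIZED_PRESET)
        assert list(seg.states) == [3]
        assert seg.breakpoints == []

    def test_natural_preset_marks_candidates(self, rng):
        heb = simulate_heb_track(np.full(100, 2), 0.05, rng)
        seg = hmm_segment(_make_track(heb), NATURAL_PRESET, candidate_only=True)
        assert seg.candidate_only

    def test_em_refines_and_still_decodes(self, rng):
        states = np.array([2] * 150 + [4] * 150)
        heb = simulate_heb_track(states, 0.08, rng)
        params = HMMParams(e=1 - 1e-7, strength=1e7, em_iterations=3)
        seg = hmm_segment(_make_track(heb), params)
        assert (seg.states[:148] == 2).all() and (seg.states[152:] == 4).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HMMParams(m=(0.5, 0.4, 0.3, 0.2, 0.1))
        with pytest.raises(ValueError):
            HMMParams(e=1.0)


class TestViterbiOptimality:
    def _brute_force(self, log_em, log_trans, log_init):
        n, k = log_em.shape
        best, best_lp = None, -np.inf
        for path in itertools.product(range(k), repeat=n):
            lp = log_init[path[0]] + log_em[0, path[0]]
            for t in range(1, n):
                lp += log_trans[path[t - 1], path[t]] + log_em[t, path[t]]
            if lp > best_lp:
                best, best_lp = path, lp
        return np.array(best), best_lp

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        heb = rng.uniform(0.01, 0.99, size=7)
        params = HMMParams(e=0.9, strength=10.0, scale=0.3)
        log_em = _log_emissions(heb, params)
        log_trans = np.log(params.transition_matrix())
        log_init = np.full(5, -np.log(5))
        path, lp = viterbi(log_em, log_trans, log_init)
        b_path, b_lp = self._brute_force(log_em, log_trans, log_init)
        assert lp == pytest.approx(b_lp, abs=1e-9)
        np.testing.assert_array_equal(path, b_path)

    def test_beats_handcrafted_alternatives(self, rng):
        heb = simulate_heb_track(np.array([2] * 6 + [3] * 6), 0.1, rng)
        params = RESYNTHESIZED_PRESET
        log_em = _log_emissions(heb, params)
        log_trans = np.log(params.transition_matrix())
        log_init = np.full(5, -np.log(5))
        path, lp = viterbi(log_em, log_trans, log_init)
        for _ in range(200):
            alt = rng.integers(0, 5, size=len(heb))
            alt_lp = log_init[alt[0]] + log_em[0, alt[0]]
            for t in range(1, len(alt)):
                alt_lp += log_trans[alt[t - 1], alt[t]] + log_em[t, alt[t]]
            assert lp >= alt_lp - 1e-9


class TestBreakpointStats:
    def _seg(self, states, ind="i1", chrom="chr1"):
        states = np.asarray(states)
        changes = [int(b) for b in np.flatnonzero(np.diff(states) != 0) + 1]
        return CopyNumberSegmentation(
            ind, chrom, pd.RangeIndex(len(states)), states, changes, [], 0.0
        )

    def test_all_balanced_means_no_signal(self):
        segs = [self._seg([2] * 50, chrom=f"chr{i}") for i in range(4)]
        out = breakpoint_stats(segs)
        assert out["mean_breakpoints"] == 0.0
        assert out["n_no_signal"] == 4
        assert out["fraction_unbalanced"] == 0.0

    def test_unbalanced_fraction_is_direct_tally(self):
        segs = [self._seg([2] * 30 + [3] * 10)]
        out = breakpoint_stats(segs)
        assert out["fraction_unbalanced"] == pytest.approx(0.25)
        assert out["mean_breakpoints"] == 1.0
        assert out["n_no_signal"] == 0

    def test_constant_nonbalanced_chromosome_is_signal(self):
        # whole-chromosome replacement: no breakpoint but clearly unbalanced
        out = breakpoint_stats([self._seg([4] * 20)])
        assert out["n_no_signal"] == 0


class TestVarianceExplained:
    def test_states_determine_heb(self, rng):
        states = rng.integers(0, 5, size=4000)
        m = np.array([0.01, 0.25, 0.5, 0.75, 0.99])[states]
        total = np.full(4000, 400.0)
        cg = rng.binomial(400, m)
        assert variance_explained(cg, total, states) >= 0.9

    def test_shuffled_states_explain_nothing(self, rng):
        states = rng.integers(0, 5, size=5000)
        m = np.array([0.01, 0.25, 0.5, 0.75, 0.99])[states]
        cg = rng.binomial(300, m)
        shuffled = rng.permutation(states)
        assert variance_explained(cg, np.full(5000, 300.0), shuffled) <= 0.02

    def test_monotone_decreasing_in_regulatory_noise(self, rng):
        states = rng.integers(1, 4, size=3000)
        m = np.array([0.01, 0.25, 0.5, 0.75, 0.99])[states]
        r2 = []
        for sd in (0.1, 0.6, 1.5):
            p = expit(logit(m) + rng.normal(0, sd, states.size))
            cg = rng.binomial(300, p)
            r2.append(variance_explained(cg, np.full(3000, 300.0), states))
        assert r2[0] > r2[1] > r2[2]

    def test_single_state_returns_zero(self):
        assert variance_explained([10, 20], [40, 40], [2, 2]) == 0.0
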