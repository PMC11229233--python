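import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import column_walk_events, sliding_mean
from promevol.coords import AnalysisWindow
from promevol.events import (
    EVENT_BASE_CHANGE,
    EVENT_INDEL,
    call_events,
    concatenate_group,
    control_baseline,
    d_score,
    d_score_conservation,
    sliding_score,
    sum_events,
)
from promevol.ingest import ConservationTrack, CoverageError, InputError, alignment_from_strings

W4 = AnalysisWindow(upstream=4, downstream=0, promoter_start=-4, promoter_end=-1)


def aln(ref, *others, upstream=None):
    n_ref = sum(c != "-" for c in ref)
    species = ["ref"] + [f"sp{i}" for i in range(len(others))]
    seqs = {"ref": ref, **{f"sp{i}": s for i, s in enumerate(others)}}
    return alignment_from_strings("g", species, seqs, tss_index=upstream or n_ref)


def window_for(ref):
    n_ref = sum(c != "-" for c in ref)
    return AnalysisWindow(upstream=n_ref, downstream=0, promoter_start=-n_ref, promoter_end=-1)


class TestCallEvents:
    def test_identity_gives_no_events(self):
        t = call_events(aln("ACGT", "ACGT"), W4)
        assert t.events.sum() == 0

    def test_single_base_change(self):
        t = call_events(aln("ACGT", "AGGT"), W4)
        assert list(t.events[:, 0]) == [0, 1, 0, 0]
        assert t.classes[1, 0] == EVENT_BASE_CHANGE

    def test_deletion_scores_each_missing_reference_base(self):
        t = call_events(aln("ACGT", "A--T"), W4)
        assert list(t.classes[:, 0]) == [0, EVENT_INDEL, EVENT_INDEL, 0]

    def test_insertion_run_is_single_event_at_anchor(self):
        w = window_for("AC-GT")
        t = call_events(aln("AC-GT", "ACTGT"), w)
        assert list(t.events[:, 0]) == [0, 1, 0, 0]
        assert t.classes[1, 0] == EVENT_INDEL

    def test_case_insensitive_and_n_policy(self):
        t = call_events(aln("ACGT", "acNT"), W4)
        # a==A conserved, c==C conserved, N vs G is a base change
        assert list(t.events[:, 0]) == [0, 0, 1, 0]

    @given(st.data())
    def test_class_sums_decompose(self, data):
        ref = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=20))
        other = "".join(
            data.draw(st.sampled_from("ACGT-")) for _ in ref
        )
        w = window_for(ref)
        t = call_events(aln(ref, other), w)
        total = sum_events(t, "all").sums
        parts = sum_events(t, "base_change").sums + sum_events(t, "indel").sums
        np.testing.assert_array_equal(total, parts)


class TestOracleEquivalence:
    """Random alignments vs the naive column-walk oracle, exact agreement."""

    @pytest.mark.parametrize("seed", range(5))
    def test_events_and_se_match_column_walk(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n_ref = int(rng.integers(5, 50))
            ref_chars = list(rng.choice(list("ACGT"), size=n_ref))
            # sprinkle insertion columns into the reference
            cols = []
            for ch in ref_chars:
                cols.append(ch)
                while rng.random() < 0.1:
                    cols.append("-")
            ref = "".join(cols)
            others = []
            for _s in range(3):
                other = []
                for rc in ref:
                    if rc == "-":
                        other.append(rng.choice(list("ACGT-")))
                    else:
                        other.append(rng.choice(list("ACGT-"), p=[0.2, 0.2, 0.2, 0.2, 0.2]))
                others.append("".join(other))
            w = window_for(ref)
            a = aln(ref, *others)
            track = call_events(a, w)
            expected = np.array(column_walk_events([ref] + others, w.upstream, w.downstream))
            np.testing.assert_array_equal(track.classes, expected)
            sums = sum_events(track)
            se = sliding_score(sums, 5)
            np.testing.assert_array_equal(se.values, sliding_mean(list(sums.sums), 5))


class TestSlidingScore:
    def test_truncated_ends(self):
        from promevol.events import SummedEventTrack

        w = AnalysisWindow(upstream=5, downstream=0, promoter_start=-5, promoter_end=-1)
        track = SummedEventTrack("g", np.array([0, 0, 5, 0, 0.0]), w)
        se = sliding_score(track, 5)
        np.testing.assert_allclose(se.values, [5 / 3, 5 / 4, 1, 5 / 4, 5 / 3])

    def test_window_one_is_identity(self):
        from promevol.events import SummedEventTrack

        w = AnalysisWindow(upstream=5, downstream=0, promoter_start=-5, promoter_end=-1)
        sums = np.array([1, 0, 3, 2, 0.0])
        se = sliding_score(SummedEventTrack("g", sums, w), 1)
        np.testing.assert_array_equal(se.values, sums)

    def test_even_window_rejected(self):
        from promevol.events import SummedEventTrack

        w = AnalysisWindow(upstream=5, downstream=0, promoter_start=-5, promoter_end=-1)
        with pytest.raises(InputError):
            sliding_score(SummedEventTrack("g", np.zeros(5), w), 4)


class TestGroupConcatenation:
    def make(self, sums, w):
        from promevol.events import SummedEventTrack

        return SummedEventTrack("g", np.asarray(sums, dtype=float), w)

    def test_positionwise_sum(self):
        w = AnalysisWindow(upstream=3, downstream=0, promoter_start=-3, promoter_end=-1)
        combined = concatenate_group([self.make([1, 0, 2], w), self.make([0, 0, 1], w)])
        np.testing.assert_array_equal(combined.sums, [1, 0, 3])

    def test_single_gene_unchanged(self):
        w = AnalysisWindow(upstream=3, downstream=0, promoter_start=-3, promoter_end=-1)
        track = self.make([1, 2, 3], w)
        np.testing.assert_array_equal(concatenate_group([track]).sums, track.sums)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            concatenate_group([])

    def test_mixed_windows_rejected(self):
        w1 = AnalysisWindow(upstream=3, downstream=0, promoter_start=-3, promoter_end=-1)
        w2 = AnalysisWindow(upstream=3, downstream=1, promoter_start=-3, promoter_end=-1)
        with pytest.raises(InputError):
            concatenate_group([self.make([1, 0, 2], w1), self.make([0, 0, 1, 1], w2)])


class TestBaselineAndD:
    def se(self, values, w, gene="g"):
        from promevol.events import SlidingScore

        return SlidingScore(gene, np.asarray(values, dtype=float), w)

    def test_baseline_is_pooled_promoter_mean(self, small_window):
        w = small_window
        flat2 = self.se(np.full(w.length, 2.0), w, "a")
        assert control_baseline([flat2], w) == 2.0
        flat1 = self.se(np.full(w.length, 1.0), w, "b")
        flat3 = self.se(np.full(w.length, 3.0), w, "c")
        assert control_baseline([flat1, flat3], w) == 2.0

    def test_empty_control_rejected(self, small_window):
        with pytest.raises(InputError):
            control_baseline([], small_window)

    def test_d_is_percentage_of_exceedances(self):
        from promevol.coords import DEFAULT_WINDOW as W

        values = np.zeros(W.length)
        mask = W.promoter_mask()
        idx = np.flatnonzero(mask)[:70]
        values[idx] = 5.0
        d = d_score(self.se(values, W), baseline=1.0)
        assert d.value == 20.0 and d.n_exceed == 70 and d.N == 350

    def test_ties_do_not_count(self, small_window):
        w = small_window
        d = d_score(self.se(np.full(w.length, 1.5), w), baseline=1.5)
        assert d.value == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_d_invariant_under_promoter_permutation(self, seed):
        from promevol.coords import DEFAULT_WINDOW as W

        rng = np.random.default_rng(seed)
        values = rng.poisson(2.0, W.length).astype(float)
        base = d_score(self.se(values, W), baseline=2.0).value
        mask = W.promoter_mask()
        shuffled = values.copy()
        shuffled[mask] = rng.permutation(values[mask])
        assert d_score(self.se(shuffled, W), baseline=2.0).value == base

    @given(st.floats(0, 5), st.floats(0, 5))
    def test_raising_baseline_never_increases_d(self, b1, b2):
        from promevol.coords import DEFAULT_WINDOW as W

        rng = np.random.default_rng(0)
        values = rng.poisson(2.0, W.length).astype(float)
        lo, hi = sorted([b1, b2])
        track = self.se(values, W)
        assert d_score(track, hi).value <= d_score(track, lo).value


class TestDConservation:
    def test_extremes_and_half(self, small_window):
        w = small_window
        n = w.length
        low = ConservationTrack("low", np.zeros(n))
        assert d_score_conservation(low, baseline=1.0, window=w).value == 100.0
        high = ConservationTrack("high", np.full(n, 2.0))
        assert d_score_conservation(high, baseline=1.0, window=w).value == 0.0

    def test_half_below(self):
        from promevol.coords import DEFAULT_WINDOW as W

        scores = np.ones(W.length)
        mask = W.promoter_mask()
        idx = np.flatnonzero(mask)[:175]
        scores[idx] = -1.0
        d = d_score_conservation(ConservationTrack("g", scores), baseline=0.0, window=W)
        assert d.value == 50.0

    def test_missing_promoter_coverage_raises(self, small_window):
        scores = np.ones(small_window.length)
        scores[small_window.offset_to_index(-5)] = np.nan
        with pytest.raises(CoverageError):
            d_score_conservation(ConservationTrack("g", scores), 0.0, small_window)
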