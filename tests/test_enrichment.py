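"""Contingency construction, exact Fisher right tail, BH adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screendeconv import (ContingencyTable, bh_adjust, build_contingency,
                          enrich_targets, fisher_right_tail)
from screendeconv.collate import CompoundTargetPair
from screendeconv.synthetic import associations_to_pairs


def hypergeom_tail_oracle(nb, nhl, tic, tihlc):
    """Brute-force right tail by integer pmf summation (independent of scipy)."""
    total = math.comb(nb, nhl)
    acc = 0
    for k in range(tihlc, min(tic, nhl) + 1):
        if nhl - k <= nb - tic:
            acc += math.comb(tic, k) * math.comb(nb - tic, nhl - k)
    return acc / total


def bh_oracle(pvals):
    """Hand-coded step-up: q(i) = min_{j>=i} m p(j)/j on the sorted scale."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = running
    return q


def pairs_from(assoc):
    return associations_to_pairs(assoc)


class TestContingency:
    def test_direct_counting(self):
        pairs = pairs_from([("c1", "A"), ("c2", "A"), ("c3", "A"),
                            ("c1", "B"), ("c4", "B"), ("c5", "C")])
        t = build_contingency(pairs, {"c1", "c2"}, "A")
        assert (t.NB, t.Nhl, t.Tic, t.Tihlc) == (6, 3, 3, 2)
        t = build_contingency(pairs, {"c1", "c2"}, "C")
        assert (t.NB, t.Nhl, t.Tic, t.Tihlc) == (6, 3, 1, 0)

    def test_all_compounds_hits_degenerate(self):
        pairs = pairs_from([("c1", "A"), ("c2", "A"), ("c3", "B")])
        t = build_contingency(pairs, {"c1", "c2", "c3"}, "A")
        assert t.Nhl == t.NB and t.Tihlc == t.Tic

    def test_unknown_hit_id_raises_with_name(self):
        pairs = pairs_from([("c1", "A")])
        with pytest.raises(ValueError, match="cX"):
            build_contingency(pairs, {"c1", "cX"}, "A", library_ids={"c1"})

    def test_margins_and_cells_consistent(self):
        t = ContingencyTable(NB=100, Nhl=10, Tic=5, Tihlc=3)
        a, b, c, d = t.cells
        assert a + b == t.Tic and a + c == t.Nhl and a + b + c + d == t.NB

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(NB=10, Nhl=5, Tic=3, Tihlc=4)
        with pytest.raises(ValueError):
            ContingencyTable(NB=10, Nhl=9, Tic=9, Tihlc=1)  # d would be negative


class TestFisherRightTail:
    def test_enumeration_example(self):
        # all C(4,2)=6 equally likely draws; only one contains both successes
        p = fisher_right_tail(ContingencyTable(NB=4, Nhl=2, Tic=2, Tihlc=2))
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        p = fisher_right_tail(ContingencyTable(NB=50, Nhl=10, Tic=5, Tihlc=0))
        assert p == pytest.approx(1.0)

    def test_pmf_summation_example(self):
        expected = hypergeom_tail_oracle(100, 10, 5, 3)
        p = fisher_right_tail(ContingencyTable(NB=100, Nhl=10, Tic=5, Tihlc=3))
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(0.0066379129, abs=1e-9)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_on_random_tables(self, data):
        nb = data.draw(st.integers(1, 80))
        nhl = data.draw(st.integers(0, nb))
        tic = data.draw(st.integers(0, nb))
        lo, hi = max(0, nhl + tic - nb), min(tic, nhl)
        tihlc = data.draw(st.integers(lo, hi))
        t = ContingencyTable(NB=nb, Nhl=nhl, Tic=tic, Tihlc=tihlc)
        assert fisher_right_tail(t) == pytest.approx(
            hypergeom_tail_oracle(nb, nhl, tic, tihlc), abs=1e-9)

    def test_monotone_in_overlap(self):
        ps = [fisher_right_tail(ContingencyTable(NB=60, Nhl=12, Tic=8, Tihlc=k))
              for k in range(0, 9)]
        assert all(ps[i] >= ps[i + 1] for i in range(len(ps) - 1))


class TestBHAdjust:
    def test_hand_evaluated_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_ties_collapse(self):
        assert np.allclose(bh_adjust([0.2] * 6), [0.2] * 6)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_bounds(self, pvals):
        q = bh_adjust(pvals)
        expected = bh_oracle(pvals)
        assert np.allclose(q, expected, atol=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)

    def test_rejection_set_matches_classical_bh(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        for alpha in (0.01, 0.05, 0.1):
            q = bh_adjust(p)
            # classical BH: largest k with p_(k) <= alpha k / m
            order = np.argsort(p)
            thresh = alpha * (np.arange(1, 41)) / 40
            passed = np.nonzero(p[order] <= thresh)[0]
            classical = set(order[:passed.max() + 1]) if len(passed) else set()
            assert set(np.nonzero(q <= alpha)[0]) == classical


class TestEnrichTargets:
    def test_planted_target_usually_ranks_first(self):
        from screendeconv import SyntheticScreenSpec, sample_associations
        top = significant = 0
        for seed in range(10):
            spec = SyntheticScreenSpec(n_compounds=2000, n_targets=100, seed=seed)
            assoc, hit_ids, planted = sample_associations(spec)
            results = enrich_targets(pairs_from(assoc), hit_ids)
            top += results[0].uniprot_acc == planted[0]
            by_acc = {r.uniprot_acc: r for r in results}
            significant += by_acc[planted[0]].p_value < 0.05
        assert top >= 6
        assert significant >= 8

    def test_whole_library_as_hits_all_p_one(self):
        pairs = pairs_from([("c1", "A"), ("c2", "A"), ("c3", "B")])
        results = enrich_targets(pairs, {"c1", "c2", "c3"})
        assert all(r.p_value == pytest.approx(1.0) for r in results)
        assert not any(r.enriched_fdr or r.enriched_p for r in results)

    def test_empty_hit_list_is_error(self):
        pairs = pairs_from([("c1", "A")])
        with pytest.raises(ValueError, match="empty hit list"):
            enrich_targets(pairs, set())

    def test_hits_without_pairs_is_error(self):
        pairs = pairs_from([("c1", "A")])
        with pytest.raises(ValueError, match="no compound-target pairs"):
            enrich_targets(pairs, {"c2"}, library_ids={"c1", "c2"})

    def test_only_hit_associated_targets_tested(self):
        pairs = pairs_from([("c1", "A"), ("c2", "B"), ("c3", "B")])
        results = enrich_targets(pairs, {"c1"})
        assert [r.uniprot_acc for r in results] == ["A"]

    def test_q_at_least_p(self, small_bundle_run):
        from screendeconv.pipeline import read_output_csv
        _, out, _ = small_bundle_run
        df = read_output_csv(out / "target_enrichment.csv")
        assert (df.q_value >= df.p_value - 1e-12).all()
        assert (df.q_value <= 1.0).all()
        assert df.p_value.is_monotonic_increasing
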