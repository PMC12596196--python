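from math import comb

import numpy as np
import pandas as pd
import pytest

from modulome.enrichment import (
    TRN,
    classify_quadrant,
    compute_recalls,
    count_trn_expansion,
    enrich_all,
    fdr_adjust,
    fisher_enrichment,
)
from modulome.membership import IModulon


def brute_force_overrep_p(universe, n_members, n_regulon, overlap):
    """Oracle: P(overlap >= observed) by explicit hypergeometric summation."""
    total = comb(universe, n_members)
    return sum(
        comb(n_regulon, j) * comb(universe - n_regulon, n_members - j)
        for j in range(overlap, min(n_members, n_regulon) + 1)
    ) / total


def _sets(universe, n_members, n_regulon, overlap):
    genes = [f"g{i}" for i in range(universe)]
    members = set(genes[:n_members])
    regulon = set(genes[n_members - overlap : n_members - overlap + n_regulon])
    return members, regulon


class TestFisherEnrichment:
    def test_perfect_overlap_closed_form(self):
        members, regulon = _sets(100, 10, 10, 10)
        assert fisher_enrichment(members, regulon, 100) == pytest.approx(
            1 / comb(100, 10), rel=1e-10
        )

    def test_zero_overlap_is_one(self):
        members, regulon = _sets(50, 5, 5, 0)
        assert fisher_enrichment(members, regulon, 50) == pytest.approx(1.0)

    def test_partial_overlap_matches_enumeration(self):
        members, regulon = _sets(20, 5, 5, 3)
        assert fisher_enrichment(members, regulon, 20) == pytest.approx(
            brute_force_overrep_p(20, 5, 5, 3), rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        universe = int(rng.integers(10, 51))
        n_mem = int(rng.integers(1, universe // 2 + 1))
        n_reg = int(rng.integers(1, universe // 2 + 1))
        overlap = int(rng.integers(0, min(n_mem, n_reg) + 1))
        if universe < n_mem + n_reg - overlap:
            overlap = n_mem + n_reg - universe
        members, regulon = _sets(universe, n_mem, n_reg, overlap)
        assert fisher_enrichment(members, regulon, universe) == pytest.approx(
            brute_force_overrep_p(universe, n_mem, n_reg, overlap), rel=1e-10
        )

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(set(), {"a"}, 10)


class TestFdrAdjust:
    def test_hand_computed_examples(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_with_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])


class TestRecallsAndQuadrants:
    @pytest.mark.parametrize(
        "members,regulon,expected",
        [
            ({"a", "b", "c"}, {"a", "b", "c"}, (1.0, 1.0)),
            ({"a", "b", "c", "d"}, {"a", "b"}, (0.5, 1.0)),
            ({"a"}, {"b"}, (0.0, 0.0)),
        ],
    )
    def test_recall_arithmetic(self, members, regulon, expected):
        assert compute_recalls(members, regulon) == pytest.approx(expected)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            compute_recalls(set(), {"a"})

    @pytest.mark.parametrize(
        "ir,rr,label",
        [
            (0.8, 0.9, "well-matched"),
            (0.9, 0.3, "regulon subset"),
            (0.3, 0.9, "unknown-containing"),
            (0.3, 0.3, "closest match"),
            (0.7, 0.7, "well-matched"),  # boundary inclusive
            (0.7, 0.0, "regulon subset"),
            (0.0, 0.7, "unknown-containing"),
        ],
    )
    def test_quadrant_semantics(self, ir, rr, label):
        assert classify_quadrant(ir, rr) == label

    def test_quadrants_partition_unit_square(self):
        labels = {
            classify_quadrant(ir, rr)
            for ir in np.linspace(0, 1, 21)
            for rr in np.linspace(0, 1, 21)
        }
        assert labels == {"well-matched", "regulon subset",
                          "unknown-containing", "closest match"}
        # every point receives exactly one label by construction; check a
        # boundary point is classified deterministically
        assert classify_quadrant(0.7, 0.69999) == "regulon subset"


def _imod(cid, members, universe):
    w = pd.Series(0.0, index=sorted(universe))
    w[sorted(members)] = 1.0
    return IModulon(cid, w, 0.5, frozenset(members))


def _trn(regulons, universe):
    rows = [(r, t, "lit") for r, ts in regulons.items() for t in ts]
    return TRN(pd.DataFrame(rows, columns=["regulator", "target", "evidence"]),
               frozenset(universe))


class TestEnrichAll:
    def test_exact_matches_flagged_regulatory(self):
        universe = {f"g{i}" for i in range(1000)}
        genes = sorted(universe)
        mods = {f"c{j}": set(genes[j * 10 : (j + 1) * 10]) for j in range(8)}
        regulons = {f"R{j}": mods[f"c{j}"] for j in range(5)}  # 5 of 8 exact
        regulons["Rx"] = set(genes[900:910])
        trn = _trn(regulons, universe)
        results = enrich_all([_imod(c, ms, universe) for c, ms in mods.items()], trn)
        flagged = [r for r in results if r.is_regulatory]
        assert len(flagged) == 5
        assert all(r.quadrant == "well-matched" for r in flagged)
        assert {r.component_id for r in flagged} == {f"c{j}" for j in range(5)}

    def test_shared_regulator_reported_with_distinct_recalls(self):
        universe = {f"g{i}" for i in range(500)}
        genes = sorted(universe)
        m1, m2 = set(genes[:10]), set(genes[10:30])
        trn = _trn({"R": m1 | m2}, universe)
        results = enrich_all([_imod("c1", m1, universe), _imod("c2", m2, universe)], trn)
        assert [r.regulator for r in results] == ["R", "R"]
        rr = {r.component_id: r.regulon_recall for r in results}
        assert rr["c1"] == pytest.approx(10 / 30)
        assert rr["c2"] == pytest.approx(20 / 30)

    def test_zero_fdr_threshold_flags_nothing(self):
        universe = {f"g{i}" for i in range(100)}
        m1 = set(sorted(universe)[:10])
        trn = _trn({"R": m1}, universe)
        results = enrich_all([_imod("c1", m1, universe)], trn, regulatory_fdr=0.0)
        assert not any(r.is_regulatory for r in results)

    def test_null_false_positive_rate_controlled(self):
        """Random member sets vs random regulons: the BH-adjusted
        discovery rate at q < 0.05 stays within binomial noise of 0.05."""
        rng = np.random.default_rng(42)
        n_reps, universe_size = 1000, 200
        genes = np.array([f"g{i}" for i in range(universe_size)])
        hits = 0
        for _ in range(n_reps):
            members = set(rng.choice(genes, 10, replace=False))
            regulons = {
                f"R{j}": set(rng.choice(genes, 12, replace=False)) for j in range(5)
            }
            trn = _trn(regulons, set(genes))
            results = enrich_all([_imod("c", members, set(genes))], trn)
            if results and results[0].q_value < 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert hits / n_reps <= 0.05 + 2 * se


class TestTrnExpansion:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(50)}
        genes = sorted(universe)
        regulon = set(genes[:10])
        trn = _trn({"R": regulon}, universe)
        members = regulon | set(genes[10:13])  # adds 3 novel targets
        im = _imod("c1", members, universe)
        results = enrich_all([im], trn)
        total, novel, frac = count_trn_expansion(results, [im], trn)
        assert (total, novel) == (13, 3)
        assert frac == pytest.approx(0.30)

    def test_no_novel_when_members_within_regulon(self):
        universe = {f"g{i}" for i in range(50)}
        genes = sorted(universe)
        regulon = set(genes[:10])
        trn = _trn({"R": regulon}, universe)
        im = _imod("c1", set(genes[:5]), universe)
        results = enrich_all([im], trn)
        total, novel, _ = count_trn_expansion(results, [im], trn)
        assert novel == 0
        assert total == len(trn)

    def test_accounting_identity(self, small_dataset):
        ds = small_dataset
        ims = [
            _imod(mid, ds.module_members[mid], set(ds.X.gene_ids))
            for mid in ds.module_ids
        ]
        results = enrich_all(ims, ds.trn_star)
        total, novel, frac = count_trn_expansion(results, ims, ds.trn_star)
        assert total == len(ds.trn_star) + novel
        assert frac * len(ds.trn_star) == pytest.approx(novel)


def test_duplicate_associations_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        TRN(pd.DataFrame([("R", "a", ""), ("R", "a", "")],
                         columns=["regulator", "target", "evidence"]),
            frozenset({"a"}))


def test_targets_outside_universe_rejected():
    with pytest.raises(ValueError, match="universe"):
        TRN(pd.DataFrame([("R", "zzz", "")],
                         columns=["regulator", "target", "evidence"]),
            frozenset({"a"}))
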