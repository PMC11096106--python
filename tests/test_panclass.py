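"""Gene-family classification, fusion, split-merge flagging and rarefaction."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pansynkit.panclass import (
    CATEGORY_ORDER,
    ClassificationRules,
    classify,
    composition,
    flag_split_merge,
    fuse_orthogroups,
    matrix_from_orthogroups,
    presence_counts,
    rarefaction_exact,
    rarefaction_mc,
)
from pansynkit.records import GeneModel, HomologyHit, OrthogroupTable


def matrix_from_presence(rows: dict[str, list[int]], n: int) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"a{i}" for i in range(n)]
    )


class TestClassify:
    @pytest.mark.parametrize(
        "m,expected",
        [(69, "core"), (68, "softcore"), (63, "softcore"), (62, "dispensable"),
         (2, "dispensable"), (1, "private"), (0, "absent")],
    )
    def test_category_bounds_at_69_accessions(self, m, expected):
        """At n=69 the 90% strict rule gives softcore 63-68, dispensable 2-62."""
        assert ClassificationRules().category(m, 69) == expected

    def test_softcore_empty_at_ten_accessions(self):
        """m > 9.0 and m < 10 has no integer solution: every m maps elsewhere."""
        rules = ClassificationRules()
        cats = {rules.category(m, 10) for m in range(1, 11)}
        assert "softcore" not in cats
        assert rules.softcore_range(10) is None

    def test_exact_boundary_arithmetic(self):
        # 0.9 * 60 is exactly 54: strict inequality excludes m = 54
        assert ClassificationRules().category(54, 60) == "dispensable"
        assert ClassificationRules().category(55, 60) == "softcore"

    def test_counts_sum_and_absent_excluded(self):
        mat = matrix_from_presence(
            {"f1": [1, 1, 1, 1], "f2": [1, 0, 1, 0], "f3": [0, 0, 0, 0]}, 4
        )
        labels, counts = classify(mat)
        assert labels["f3"] == "absent"
        assert sum(counts.values()) == 2

    @given(st.integers(min_value=3, max_value=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_presence_count(self, n):
        """Increasing m_f never moves a family down the category order."""
        rules = ClassificationRules()
        ranks = [CATEGORY_ORDER[rules.category(m, n)] for m in range(n + 1)]
        assert ranks == sorted(ranks)


class TestComposition:
    def test_all_core_gives_unit_fraction(self):
        mat = matrix_from_presence({"f1": [1, 1, 1], "f2": [2, 1, 1]}, 3)
        labels, _ = classify(mat)
        comp = composition(mat, labels)
        assert np.allclose(comp["core"], 1.0)
        assert np.allclose(comp[["softcore", "dispensable", "private"]], 0.0)

    def test_gene_level_fractions(self):
        """9 core genes and 1 private gene in one accession -> (0.9, 0, 0, 0.1)."""
        mat = pd.DataFrame(
            {"a0": [9, 1], "a1": [9, 0], "a2": [9, 0]},
            index=["core_fam", "priv_fam"],
        )
        labels, _ = classify(mat)
        comp = composition(mat, labels)
        assert comp.loc["a0", "core"] == pytest.approx(0.9)
        assert comp.loc["a0", "private"] == pytest.approx(0.1)
        assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-12)


def _two_family_table() -> OrthogroupTable:
    return OrthogroupTable(
        families={
            "OG_a": {"acc1": ["acc1_g1"], "acc2": ["acc2_g1"]},
            "OG_b": {"acc3": ["acc3_g1"]},
        },
        accessions=["acc1", "acc2", "acc3"],
    )


def _rbh(q, t, cq, ct, score=100.0):
    return [
        HomologyHit(q, t, cq, ct, score, 1, 100),
        HomologyHit(t, q, ct, cq, score, 1, 100),
    ]


class TestFusion:
    def test_no_qualifying_hits_leaves_table_unchanged(self):
        table = _two_family_table()
        fused = fuse_orthogroups(table, [])
        assert fused.families == table.families

    def test_rbh_above_threshold_fuses(self):
        table = _two_family_table()
        fused = fuse_orthogroups(table, _rbh("acc1_g1", "acc3_g1", 0.96, 0.97))
        assert fused.n_families == 1
        genes = {
            g for per in fused.families.values() for gl in per.values() for g in gl
        }
        assert genes == {"acc1_g1", "acc2_g1", "acc3_g1"}

    def test_coverage_below_threshold_on_either_side_blocks_fusion(self):
        table = _two_family_table()
        fused = fuse_orthogroups(table, _rbh("acc1_g1", "acc3_g1", 0.94, 0.99))
        assert fused.n_families == 2

    def test_non_reciprocal_hit_blocks_fusion(self):
        table = _two_family_table()
        one_way = [HomologyHit("acc1_g1", "acc3_g1", 0.99, 0.99, 100.0, 1, 100)]
        assert fuse_orthogroups(table, one_way).n_families == 2

    def test_unknown_gene_raises(self):
        with pytest.raises(ValueError, match="unknown genes"):
            fuse_orthogroups(_two_family_table(), _rbh("acc1_g1", "ghost", 0.99, 0.99))

    def test_idempotent_and_order_independent(self):
        table = OrthogroupTable(
            families={
                "OG_a": {"acc1": ["acc1_g1"]},
                "OG_b": {"acc2": ["acc2_g1"]},
                "OG_c": {"acc3": ["acc3_g1"]},
            },
            accessions=["acc1", "acc2", "acc3"],
        )
        hits = _rbh("acc1_g1", "acc2_g1", 0.99, 0.99) + _rbh(
            "acc2_g1", "acc3_g1", 0.98, 0.98
        )
        fused = fuse_orthogroups(table, hits)
        assert fused.n_families == 1  # transitive closure
        again = fuse_orthogroups(fused, hits)
        assert again.families == fused.families
        reversed_hits = list(reversed(hits))
        assert fuse_orthogroups(table, reversed_hits).families == fused.families

    def test_family_count_never_increases_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_fam = int(rng.integers(2, 6))
            fams = {
                f"OG{i}": {f"acc{i}": [f"acc{i}_g0"]} for i in range(n_fam)
            }
            table = OrthogroupTable(
                families=fams, accessions=[f"acc{i}" for i in range(n_fam)]
            )
            i, j = rng.choice(n_fam, 2, replace=False)
            cov = float(rng.uniform(0.5, 1.0))
            hits = _rbh(f"acc{i}_g0", f"acc{j}_g0", cov, cov)
            fused = fuse_orthogroups(table, hits)
            assert fused.n_families <= table.n_families
            expected = n_fam - 1 if cov >= 0.95 else n_fam
            assert fused.n_families == expected


def _split_case(cov1, cov2, joint_end_frac):
    """One family: representative in accA (len 1000), two adjacent genes in accB."""
    table = OrthogroupTable(
        families={"OG0": {"accA": ["accA_g0"], "accB": ["accB_g0", "accB_g1"]}},
        accessions=["accA", "accB"],
    )
    gm = {
        "accA_g0": GeneModel("accA", "accA_g0", "chr1", 1, 1000),
        "accB_g0": GeneModel("accB", "accB_g0", "chr1", 1, 450),
        "accB_g1": GeneModel("accB", "accB_g1", "chr1", 500, 1020),
    }
    cut = int(cov1 * 1000)
    end2 = int(joint_end_frac * 1000)
    hits = [
        HomologyHit("accB_g0", "accA_g0", 0.97, cut / 1000, 50.0, 1, cut),
        HomologyHit("accB_g1", "accA_g0", 0.97, cov2, 50.0,
                    end2 - int(cov2 * 1000) + 1, end2),
    ]
    return table, gm, hits


class TestSplitMerge:
    def test_planted_split_flagged(self):
        table, gm, hits = _split_case(0.45, 0.53, 0.98)
        flags = flag_split_merge(table, gm, hits)
        assert bool(flags["OG0"])

    def test_same_half_union_below_threshold_not_flagged(self):
        """Two genes covering the same 50% of the representative: union 0.5."""
        table, gm, _ = _split_case(0.5, 0.5, 0.5)
        hits = [
            HomologyHit("accB_g0", "accA_g0", 0.97, 0.5, 50.0, 1, 500),
            HomologyHit("accB_g1", "accA_g0", 0.97, 0.5, 50.0, 1, 500),
        ]
        assert not bool(flag_split_merge(table, gm, hits)["OG0"])

    def test_individually_covering_gene_not_flagged(self):
        table, gm, _ = _split_case(0.45, 0.53, 0.98)
        hits = [
            HomologyHit("accB_g0", "accA_g0", 0.97, 0.98, 50.0, 1, 980),
            HomologyHit("accB_g1", "accA_g0", 0.97, 0.98, 50.0, 1, 980),
        ]
        assert not bool(flag_split_merge(table, gm, hits)["OG0"])

    def test_single_gene_families_never_flagged(self):
        table = OrthogroupTable(
            families={"OG0": {"accA": ["accA_g0"]}}, accessions=["accA"]
        )
        gm = {"accA_g0": GeneModel("accA", "accA_g0", "chr1", 1, 1000)}
        assert not flag_split_merge(table, gm, []).any()

    def test_non_adjacent_genes_not_flagged(self):
        table, gm, hits = _split_case(0.45, 0.53, 0.98)
        # a third gene between them in accB's genome order breaks adjacency
        gm["accB_gx"] = GeneModel("accB", "accB_gx", "chr1", 460, 490)
        assert not bool(flag_split_merge(table, gm, hits)["OG0"])

    def test_missing_coordinates_raise(self):
        table, gm, hits = _split_case(0.45, 0.53, 0.98)
        del gm["accB_g1"]
        with pytest.raises(ValueError, match="without coordinates"):
            flag_split_merge(table, gm, hits)


class TestRarefaction:
    def test_three_accession_example(self):
        """{f1: all, f2: acc1 only}, k=2: pan over the 3 subsets is 5/3, core 1."""
        mat = matrix_from_presence({"f1": [1, 1, 1], "f2": [1, 0, 0]}, 3)
        exact = rarefaction_exact(mat, [2])
        assert exact.loc[2, "pan_mean"] == pytest.approx(5 / 3, abs=1e-12)
        assert exact.loc[2, "core_mean"] == pytest.approx(1.0, abs=1e-12)

    def test_exact_matches_exhaustive_enumeration(self):
        """Closed form equals brute-force subset enumeration on a random matrix."""
        rng = np.random.default_rng(11)
        n, fam = 8, 60
        presence = rng.random((fam, n)) < rng.uniform(0.1, 0.9, size=(fam, 1))
        mat = pd.DataFrame(presence.astype(int), columns=[f"a{i}" for i in range(n)])
        exact = rarefaction_exact(mat, range(1, n + 1))
        for k in range(1, n + 1):
            pans, cores = [], []
            for subset in itertools.combinations(range(n), k):
                sub = presence[:, list(subset)]
                pans.append(sub.any(axis=1).sum())
                cores.append(sub.all(axis=1).sum())
            assert exact.loc[k, "pan_mean"] == pytest.approx(np.mean(pans), abs=1e-9)
            assert exact.loc[k, "core_mean"] == pytest.approx(np.mean(cores), abs=1e-9)

    def test_k_equals_n_and_k_equals_one(self):
        mat = matrix_from_presence({"f1": [1, 1, 1], "f2": [1, 0, 0], "f3": [0, 0, 0]}, 3)
        mc = rarefaction_mc(mat, sizes=[1, 3], replicates=100, seed=0)
        assert mc.loc[3, "pan_mean"] == 2  # families with m_f >= 1
        assert mc.loc[3, "core_mean"] == 1
        assert mc.loc[3, "pan_sd"] == 0
        # k=1: pan = core = mean per-accession family count = (2+1+1)/3
        assert mc.loc[1, "pan_mean"] == pytest.approx(mc.loc[1, "core_mean"])
        exact = rarefaction_exact(mat, [1])
        assert exact.loc[1, "pan_mean"] == pytest.approx(4 / 3, abs=1e-12)

    def test_mc_agrees_with_exact_within_clt_bound(self):
        rng = np.random.default_rng(5)
        n, fam, reps = 10, 200, 2000
        presence = rng.random((fam, n)) < rng.uniform(0.05, 0.95, size=(fam, 1))
        mat = pd.DataFrame(presence.astype(int), columns=[f"a{i}" for i in range(n)])
        exact = rarefaction_exact(mat, range(1, n + 1))
        mc = rarefaction_mc(mat, sizes=range(1, n + 1), replicates=reps, seed=3)
        for k in range(1, n + 1):
            for stat in ("pan", "core"):
                sd = mc.loc[k, f"{stat}_sd"]
                tol = max(4 * sd / np.sqrt(reps), 1e-9)
                assert abs(mc.loc[k, f"{stat}_mean"] - exact.loc[k, f"{stat}_mean"]) <= tol

    def test_exact_curves_are_monotone(self):
        rng = np.random.default_rng(2)
        presence = (rng.random((100, 12)) < 0.5).astype(int)
        mat = pd.DataFrame(presence, columns=[f"a{i}" for i in range(12)])
        exact = rarefaction_exact(mat)
        assert (np.diff(exact["pan_mean"]) >= -1e-12).all()
        assert (np.diff(exact["core_mean"]) <= 1e-12).all()

    def test_pan_mean_at_least_core_mean(self):
        rng = np.random.default_rng(4)
        presence = (rng.random((80, 9)) < 0.6).astype(int)
        mat = pd.DataFrame(presence, columns=[f"a{i}" for i in range(9)])
        mc = rarefaction_mc(mat, sizes=range(1, 10), replicates=200, seed=1)
        assert (mc["pan_mean"] >= mc["core_mean"] - 1e-12).all()

    def test_oversized_subset_raises(self):
        mat = matrix_from_presence({"f1": [1, 1, 1]}, 3)
        with pytest.raises(ValueError):
            rarefaction_mc(mat, sizes=[4], replicates=10, seed=0)
        with pytest.raises(ValueError):
            rarefaction_exact(mat, [0])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        presence = (rng.random((50, 8)) < 0.5).astype(int)
        mat = pd.DataFrame(presence, columns=[f"a{i}" for i in range(8)])
        a = rarefaction_mc(mat, sizes=[3, 5], replicates=50, seed=42)
        b = rarefaction_mc(mat, sizes=[3, 5], replicates=50, seed=42)
        pd.testing.assert_frame_equal(a, b)
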