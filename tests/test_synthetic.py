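"""Generator ground truth: category structure, planted artifacts, determinism."""

import numpy as np
import pandas as pd
import pytest

from pansynkit import intervals as iv
from pansynkit.censize import RepeatParams, find_repeat_arrays
from pansynkit.panclass import (
    ClassificationRules,
    classify,
    flag_split_merge,
    fuse_orthogroups,
    matrix_from_orthogroups,
    presence_counts,
)
from pansynkit.syndiv import WindowSpec, project_synteny, synteny_diversity
from pansynkit.synthetic import (
    SimConfig,
    SimulationConfigError,
    simulate_homology,
    simulate_pav,
    simulate_repeats_and_depth,
    simulate_synteny,
    truth_from_json,
    truth_to_json,
)


class TestSimulatePav:
    def test_degenerate_all_core(self):
        cfg = SimConfig(n_accessions=5, n_families=100, category_props=(1, 0, 0, 0), seed=0)
        pav, truth = simulate_pav(cfg)
        assert (presence_counts(pav) == 5).all()
        assert (truth.family_category == "core").all()

    def test_degenerate_all_private(self):
        cfg = SimConfig(n_accessions=10, n_families=10, category_props=(0, 0, 0, 1), seed=0)
        pav, _ = simulate_pav(cfg)
        assert (pav.sum(axis=1) == 1).all()

    def test_presence_counts_respect_category_ranges(self, small_sim, small_config):
        pav, truth, _ = small_sim
        n = small_config.n_accessions
        m = presence_counts(pav)
        rules = ClassificationRules()
        lo, hi = rules.softcore_range(n)
        for fam, cat in truth.family_category.items():
            if cat == "core":
                assert m[fam] == n
            elif cat == "softcore":
                assert lo <= m[fam] <= hi
            elif cat == "dispensable":
                assert 2 <= m[fam] < lo
            else:
                assert m[fam] == 1

    def test_softcore_infeasible_at_small_n_raises(self):
        with pytest.raises(SimulationConfigError, match="softcore"):
            simulate_pav(SimConfig(n_accessions=10, n_families=50, seed=0))

    def test_invalid_proportions_rejected(self):
        with pytest.raises(SimulationConfigError):
            SimConfig(category_props=(0.5, 0.5, 0.5, 0.5))

    def test_classification_recovers_truth_without_artifacts(self):
        """Label-identity: re-classifying the true matrix recovers every label."""
        rng = np.random.default_rng(123)
        for _ in range(15):
            props = rng.dirichlet([5, 1, 2, 2])
            cfg = SimConfig(
                n_accessions=int(rng.integers(15, 60)),
                n_families=int(rng.integers(50, 400)),
                category_props=tuple(props / props.sum()),
                split_merge_rate=0.0,
                oversplit_rate=0.0,
                seed=int(rng.integers(2**31)),
            )
            pav, truth = simulate_pav(cfg)
            labels, _ = classify(pav)
            pd.testing.assert_series_equal(
                labels.sort_index(), truth.family_category.sort_index(),
                check_names=False,
            )

    def test_byte_identical_across_runs(self, small_config):
        a, _ = simulate_pav(small_config)
        b, _ = simulate_pav(small_config)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateHomology:
    def test_no_split_merge_planted_when_rate_zero(self):
        cfg = SimConfig(n_accessions=20, n_families=100, split_merge_rate=0.0, seed=1)
        pav, truth = simulate_pav(cfg)
        assert not truth.split_merge_flag.any()
        hits = simulate_homology(pav, truth, cfg)
        flags = flag_split_merge(truth.orthogroups_true, truth.gene_models, hits)
        assert not flags.any()

    def test_fusion_restores_true_family_structure(self, small_sim):
        pav, truth, hits = small_sim
        obs = truth.orthogroups_observed
        assert obs.n_families == truth.orthogroups_true.n_families + len(
            truth.oversplit_pairs
        )
        fused = fuse_orthogroups(obs, hits)
        assert fused.n_families == truth.orthogroups_true.n_families
        # gene content of each fused family matches a true family exactly
        true_sets = {
            frozenset(g for gl in per.values() for g in gl)
            for per in truth.orthogroups_true.families.values()
        }
        fused_sets = {
            frozenset(g for gl in per.values() for g in gl)
            for per in fused.families.values()
        }
        assert fused_sets == true_sets

    def test_split_merge_flags_match_truth_exactly(self, small_sim):
        pav, truth, hits = small_sim
        fused = fuse_orthogroups(truth.orthogroups_observed, hits)
        flags = flag_split_merge(fused, truth.gene_models, hits)
        common = flags.index.intersection(truth.split_merge_flag.index)
        planted = truth.split_merge_flag[common]
        assert planted.sum() > 0
        assert flags[common][planted].all()  # sensitivity 1
        assert not flags[common][~planted].any()  # false-positive rate 0


@pytest.fixture(scope="module")
def synteny():
    cfg = SimConfig(n_accessions=12, n_families=10, seed=9)
    blocks, truth = simulate_synteny(cfg)
    return cfg, blocks, truth


@pytest.fixture(scope="module")
def repeats():
    cfg = SimConfig(seed=4)
    return cfg, simulate_repeats_and_depth(cfg, n_accessions=4)


class TestSimulateSynteny:
    def test_blocks_tile_reference(self, synteny):
        cfg, blocks, _ = synteny
        for acc, blist in blocks.items():
            per_chrom: dict[str, list] = {}
            for b in blist:
                per_chrom.setdefault(b.ref_chrom, []).append((b.ref_start, b.ref_end))
            for chrom, spans in per_chrom.items():
                spans.sort()
                assert spans[0][0] == 1
                assert spans[-1][1] == cfg.ref_chrom_lengths[chrom]
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert s2 == e1 + 1  # contiguous, no overlap

    def test_indicator_gap_exactly_at_planted_inversion(self, synteny):
        cfg, blocks, truth = synteny
        ind = project_synteny(blocks, cfg.ref_chrom_lengths)
        for acc, svs in truth.planted_svs.items():
            for sv in svs:
                if sv.sv_type != "INV":
                    continue
                syn = ind[acc][sv.chrom]
                assert iv.total_length(iv.intersect(syn, [(sv.start, sv.end)])) == 0

    def test_centromere_spans_never_syntenic(self, synteny):
        cfg, blocks, _ = synteny
        ind = project_synteny(blocks, cfg.ref_chrom_lengths)
        for acc in ind:
            for chrom, (cs, ce) in cfg.centromere_spans.items():
                assert iv.total_length(iv.intersect(ind[acc][chrom], [(cs, ce)])) == 0

    def test_shared_inversion_carried_by_configured_count(self, synteny):
        cfg, _, truth = synteny
        sh = truth.shared_inversion
        assert len(sh["carriers"]) == cfg.shared_inversion_carriers
        for acc in sh["carriers"]:
            assert any(
                sv.sv_type == "INV"
                and sv.chrom == sh["chrom"]
                and abs(sv.start - sh["start"]) <= 2000
                for sv in truth.planted_svs[acc]
            )

    def test_no_events_means_all_syntenic_and_zero_diversity(self):
        cfg = SimConfig(
            n_accessions=5,
            n_families=10,
            inversion_rate_per_genome=0.0,
            indel_rate_per_genome=0.0,
            shared_inversion_carriers=0,
            ref_chrom_lengths={"Chr1": 1_000_000},
            centromere_spans={},
            seed=2,
        )
        blocks, _ = simulate_synteny(cfg)
        ind = project_synteny(blocks, cfg.ref_chrom_lengths)
        stats = synteny_diversity(ind, cfg.ref_chrom_lengths, WindowSpec(100_000, 50_000))
        assert (stats["pi_syn"] == 0.0).all()

    def test_oversized_inversion_rejected(self):
        cfg = SimConfig(
            n_accessions=5,
            n_families=10,
            ref_chrom_lengths={"Chr1": 500_000},
            centromere_spans={"Chr1": (200_000, 300_000)},
            shared_inversion_chrom="Chr1",
            shared_inversion_size=100_000,
            inversion_size_range=(1_000_000, 2_000_000),
            seed=3,
        )
        with pytest.raises(SimulationConfigError, match="inversion"):
            simulate_synteny(cfg)


class TestSimulateRepeats:
    def test_repeat_length_coupled_to_genome_size(self, repeats):
        cfg, sim = repeats
        sizes = pd.Series(sim.truth.true_genome_size)
        repeat_totals = pd.Series(
            {a: sum(v.values()) for a, v in sim.truth.true_repeat_length.items()}
        )
        # noise sd is small relative to repeat variance: strong positive coupling
        assert sizes.corr(repeat_totals) > 0.5

    def test_zero_noise_gives_perfect_correlation(self):
        cfg = SimConfig(size_coupling_noise_sd=0.0, seed=5)
        sim = simulate_repeats_and_depth(cfg, n_accessions=5, noise=False)
        sizes = pd.Series(sim.truth.true_genome_size).astype(float)
        totals = pd.Series(
            {a: float(sum(v.values())) for a, v in sim.truth.true_repeat_length.items()}
        )
        assert sizes.corr(totals) == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_concatemer_depth_is_exact(self):
        cfg = SimConfig(size_coupling_noise_sd=0.0, seed=6)
        sim = simulate_repeats_and_depth(cfg, n_accessions=2, noise=False)
        for acc, track in sim.concatemer_depth.items():
            true_total = sum(sim.truth.true_repeat_length[acc].values())
            assert track.total == pytest.approx(cfg.depth_mean * true_total)

    def test_assembled_arrays_match_truth(self, repeats):
        cfg, sim = repeats
        acc = next(iter(sim.sequences))
        params = RepeatParams(motif=cfg.motif_cen)
        for chrom, seq in sim.sequences[acc].items():
            found = sum(a.length for a in find_repeat_arrays(seq, params, chrom))
            truth_len = sim.truth.assembled_repeat_length[acc][chrom]
            assert abs(found - truth_len) <= len(cfg.motif_cen)

    def test_truncation_shrinks_assembled_not_true(self):
        cfg = SimConfig(seed=7)
        sim = simulate_repeats_and_depth(cfg, n_accessions=2, truncation=0.9)
        for acc in sim.truth.assembled_repeat_length:
            assembled = sum(sim.truth.assembled_repeat_length[acc].values())
            true = sum(sim.truth.true_repeat_length[acc].values())
            assert assembled / true == pytest.approx(0.9, abs=0.02)

    def test_invalid_truncation_rejected(self):
        with pytest.raises(SimulationConfigError):
            simulate_repeats_and_depth(SimConfig(seed=0), truncation=0.0)


class TestTruthJson:
    def test_round_trip(self, tmp_path):
        cfg = SimConfig(n_accessions=8, n_families=40, category_props=(0.6, 0, 0.2, 0.2), seed=8)
        pav, truth = simulate_pav(cfg)
        _, truth = simulate_synteny(cfg, truth)
        path = tmp_path / "truth.json"
        truth_to_json(truth, path)
        back = truth_from_json(path)
        pd.testing.assert_series_equal(back.family_category, truth.family_category)
        assert back.planted_svs == truth.planted_svs
        assert back.shared_inversion == truth.shared_inversion
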