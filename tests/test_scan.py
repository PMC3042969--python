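"""The mapping pipeline: screening, scans, peak calling, full-model
assembly, and the variant contract (backend injection)."""

import numpy as np
import pytest

from silkqtl.genmap import Chromosome, GeneticMap, uniform_map
from silkqtl.scan import (
    ModelVariant,
    assemble_full_model,
    run_pipeline,
    scan_epistasis,
    scan_main,
    select_background_markers,
    select_interval_pairs,
)
from silkqtl.simulate import simulate_null

N_PERM = 100


@pytest.fixture(scope="module")
def strong_scan(strong_pop):
    bg = select_background_markers(strong_pop, "I", n_perm=N_PERM, seed=1)
    profile, qtls = scan_main(strong_pop, "I", bg, n_perm=N_PERM, seed=2)
    return bg, profile, qtls


class TestVariants:
    def test_tags(self):
        assert ModelVariant.from_tag("I").design == "achiasmate"
        assert ModelVariant.from_tag("II").design == "chiasmate"
        assert ModelVariant.from_tag("III").epistasis is False
        with pytest.raises(ValueError):
            ModelVariant.from_tag("IV")

    def test_backend_injection_bitwise_identity(self, strong_pop):
        """Variant II with the achiasmate backend injected reproduces
        variant I bit for bit: the variants differ only in the
        conditional-probability backend."""
        v1 = ModelVariant.from_tag("I")
        v2 = ModelVariant.from_tag("II").with_design("achiasmate")
        r1 = run_pipeline(strong_pop, v1, n_perm=N_PERM, seed=5, fit=False)
        r2 = run_pipeline(strong_pop, v2, n_perm=N_PERM, seed=5, fit=False)
        np.testing.assert_array_equal(r1.profile.table["F"].to_numpy(),
                                      r2.profile.table["F"].to_numpy())
        assert r1.profile.threshold == r2.profile.threshold
        assert [(q.chrom, q.pos_cM) for q in r1.qtls] == \
            [(q.chrom, q.pos_cM) for q in r2.qtls]


class TestBackgroundSelection:
    def test_finds_strong_qtl_intervals(self, strong_scan, strong_pop):
        bg, _, _ = strong_scan
        assert bg.intervals, "strong QTLs must yield a non-empty background"
        chroms = {c for c, _ in bg.intervals}
        assert 0 in chroms and 1 in chroms

    def test_single_marker_chromosome_rejected(self):
        gmap = GeneticMap(chromosomes=(
            Chromosome("1", ("a",), np.array([0.0])),))
        pop = simulate_null(gmap, n=40, seed=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            select_background_markers(pop, "I", n_perm=10, seed=0)

    def test_threshold_reproducible(self, strong_pop):
        a = select_background_markers(strong_pop, "I", n_perm=50, seed=9)
        b = select_background_markers(strong_pop, "I", n_perm=50, seed=9)
        assert a.threshold == b.threshold
        assert a.intervals == b.intervals


class TestScanMain:
    def test_detects_planted_qtls_near_truth(self, strong_scan):
        _, profile, qtls = strong_scan
        found = {(q.chrom, q.pos_cM) for q in qtls}
        assert any(c == "1" and abs(p - 18.0) <= 10 for c, p in found)
        assert any(c == "2" and abs(p - 12.0) <= 10 for c, p in found)

    def test_effect_signs_recovered(self, strong_scan):
        _, _, qtls = strong_scan
        for q in qtls:
            if q.chrom == "1" and abs(q.pos_cM - 18.0) <= 10:
                assert q.a > 0
            if q.chrom == "2" and abs(q.pos_cM - 12.0) <= 10:
                assert q.a < 0

    def test_profile_nonnegative_and_threshold(self, strong_scan):
        _, profile, qtls = strong_scan
        assert (profile.table["F"] >= 0).all()
        for q in qtls:
            assert q.F > profile.threshold

    def test_highest_peak_survives_elimination(self, strong_scan):
        _, profile, qtls = strong_scan
        top = profile.table.loc[profile.table["F"].idxmax()]
        assert any(q.chrom == top["chrom"]
                   and abs(q.pos_cM - top["pos_cM"]) <= 15 for q in qtls)

    def test_affine_invariance_of_detections(self, strong_pop):
        import copy

        res1 = run_pipeline(strong_pop, "I", n_perm=N_PERM, seed=6, fit=False)
        pop2 = copy.copy(strong_pop)
        pop2.y = 3.0 * strong_pop.y - 7.0
        pop2._coeff_cache = {}
        res2 = run_pipeline(pop2, "I", n_perm=N_PERM, seed=6, fit=False)
        assert [(q.chrom, q.pos_cM) for q in res1.qtls] == \
            [(q.chrom, q.pos_cM) for q in res2.qtls]
        np.testing.assert_allclose(res1.profile.table["F"],
                                   res2.profile.table["F"], atol=1e-8)

    def test_grid_refinement_stability(self, strong_pop):
        bg = select_background_markers(strong_pop, "I", n_perm=N_PERM, seed=1)
        _, q1 = scan_main(strong_pop, "I", bg, step_cM=1.0, n_perm=N_PERM,
                          seed=2)
        _, q2 = scan_main(strong_pop, "I", bg, step_cM=0.5, n_perm=N_PERM,
                          seed=2)
        pos1 = sorted(q.pos_cM for q in q1)
        pos2 = sorted(q.pos_cM for q in q2)
        assert len(pos1) == len(pos2)
        assert all(abs(a - b) < 1.0 for a, b in zip(pos1, pos2))

    def test_step_must_be_positive(self, strong_pop, strong_scan):
        with pytest.raises(ValueError):
            scan_main(strong_pop, "I", strong_scan[0], step_cM=0.0,
                      n_perm=10, seed=0)


class TestEpistasisStages:
    def test_pair_enumeration_single_chromosome(self):
        gmap = uniform_map(n_chrom=1, n_markers=3, spacing_cM=10.0)
        pop = simulate_null(gmap, n=60, seed=3)
        bg = select_background_markers(pop, "I", n_perm=20, seed=0)
        sel = select_interval_pairs(pop, "I", bg, n_perm=20, seed=0)
        assert len(sel.f_stats) == 1  # two intervals -> exactly one pair

    def test_variant_iii_skips_epistasis(self, strong_pop, strong_scan):
        bg, _, qtls = strong_scan
        sel = select_interval_pairs(strong_pop, "I", bg, n_perm=20, seed=0)
        out = scan_epistasis(strong_pop, "III", sel, qtls, n_perm=20, seed=0)
        assert out == []

    def test_pipeline_variant_iii_has_no_pair_stage(self, strong_pop):
        res = run_pipeline(strong_pop, "III", n_perm=30, seed=4, fit=False)
        assert res.pair_selection is None
        assert res.epistases == []


class TestFullModel:
    def test_block_counting(self, strong_pop, strong_scan):
        _, _, qtls = strong_scan
        assert len(qtls) >= 2
        from silkqtl.scan import DetectedEpistasis

        epi = DetectedEpistasis(
            chrom_i=qtls[0].chrom, pos_i=qtls[0].pos_cM,
            chrom_j=qtls[1].chrom, pos_j=qtls[1].pos_cM,
            intervals=(qtls[0].interval, qtls[1].interval), F=5.0,
            aa_by_sex=np.zeros(2), ad_by_sex=np.zeros(2),
            da_by_sex=np.zeros(2), dd_by_sex=np.zeros(2))
        dm = assemble_full_model(strong_pop, "I", qtls[:2], [epi])
        assert dm.X.shape[1] == 1 + 4 + 4  # mean, 2x(a,d), aa/ad/da/dd
        assert len(dm.U_list) == 7  # S, AS, DS, AAS, ADS, DAS, DDS
        assert dm.U_list[0].shape[1] == 2
        assert dm.U_list[1].shape[1] == 4  # 2 QTLs x 2 sexes

    def test_no_detections_mean_sex_model(self, strong_pop):
        dm = assemble_full_model(strong_pop, "I", [], [])
        assert dm.x_labels == ["mu"]
        assert dm.u_terms == ["S"]

    def test_full_fit_recovers_strong_effects(self, strong_pop, strong_scan):
        from silkqtl.scan import fit_full_model

        _, _, qtls = strong_scan
        rep = fit_full_model(strong_pop, "I", qtls, [], n_iter=1500,
                             burn_in=300, seed=1)
        for q in qtls:
            if q.chrom == "1" and abs(q.pos_cM - 18.0) <= 10:
                est = rep.fixed_estimate(f"a[{q.label()}]")
                assert est == pytest.approx(2.5, abs=1.0)
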