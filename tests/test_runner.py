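"""Experiment orchestration: fixation summaries, responses, determinism."""
import numpy as np
import pandas as pd
import pytest

from heterosim.config import (ChainConfig, GenomeConfig, SelectionConfig,
                              StudyConfig, load_study_config,
                              save_study_config, trait_config_for_model)
from heterosim.errors import ConfigurationError
from heterosim.genome import QTLEffects
from heterosim.population import HaplotypePanel, _alternating_sexes
from heterosim.runner import (aggregate_replicates, cumulative_response,
                              default_study_config, fixation_summary,
                              overdominant_fixation_summary,
                              relative_response, run_replicate, run_scenario)


def _fixed_panel(freqs, n=10):
    """Panel with every locus fixed (freq 0 or 1) or heterozygous 0.5."""
    m = len(freqs)
    haps = np.zeros((n, 2, m), dtype=np.uint8)
    for j, f in enumerate(freqs):
        if f == 1.0:
            haps[:, :, j] = 1
        elif f == 0.5:
            haps[:, 0, j] = 1
    return HaplotypePanel(ids=np.arange(n), sire=np.full(n, -1),
                          dam=np.full(n, -1), sex=_alternating_sexes(n),
                          breed=np.zeros(n, dtype=np.int8), generation=0,
                          haplotypes=haps)


class TestFixationSummary:
    def test_fully_alternate(self):
        eff = QTLEffects(a=np.array([1.0, 1.0]), d=np.zeros(2))
        a_panel = _fixed_panel([1.0, 1.0])
        b_panel = _fixed_panel([0.0, 0.0])
        fx = fixation_summary(a_panel, b_panel, eff, np.arange(2))
        assert fx.total == 100.0
        assert fx.common == 0.0 and fx.alternate == 100.0

    def test_common_favorable(self):
        eff = QTLEffects(a=np.array([1.0, 2.0]), d=np.zeros(2))
        a_panel = _fixed_panel([1.0, 1.0])
        b_panel = _fixed_panel([1.0, 1.0])
        fx = fixation_summary(a_panel, b_panel, eff, np.arange(2))
        assert fx.common == 100.0 and fx.favorable == 100.0

    def test_unfavorable_allele(self):
        # fixed for allele whose homozygote is -|a|
        eff = QTLEffects(a=np.array([1.0]), d=np.zeros(1))
        fx = fixation_summary(_fixed_panel([0.0]), _fixed_panel([0.0]),
                              eff, np.arange(1))
        assert fx.favorable == 0.0 and fx.unfavorable == 100.0
        # same state but negative additive effect: now favorable
        eff2 = QTLEffects(a=np.array([-1.0]), d=np.zeros(1))
        fx2 = fixation_summary(_fixed_panel([0.0]), _fixed_panel([0.0]),
                               eff2, np.arange(1))
        assert fx2.favorable == 100.0

    def test_nothing_fixed_reports_missing(self):
        eff = QTLEffects(a=np.ones(3), d=np.zeros(3))
        fx = fixation_summary(_fixed_panel([0.5, 0.5, 0.5]),
                              _fixed_panel([0.5, 0.5, 0.5]), eff, np.arange(3))
        assert fx.total == 0.0
        assert np.isnan(fx.common) and np.isnan(fx.favorable)

    def test_partial_counting(self):
        """3 of 4 over-dominant QTL fixed in both breeds -> 75% total."""
        eff = QTLEffects(a=np.full(4, 0.1), d=np.full(4, 1.0))  # all OD
        assert eff.overdominant.all()
        a_panel = _fixed_panel([1.0, 1.0, 0.0, 0.5])
        b_panel = _fixed_panel([1.0, 0.0, 0.0, 0.5])
        od = overdominant_fixation_summary(a_panel, b_panel, eff, np.arange(4))
        assert od.total == 75.0
        assert od.common == pytest.approx(100 * 2 / 3)

    def test_no_overdominant_set_not_applicable(self):
        eff = QTLEffects(a=np.ones(3), d=np.zeros(3), model_id=3)
        od = overdominant_fixation_summary(_fixed_panel([1.0, 1.0, 0.0]),
                                           _fixed_panel([1.0, 1.0, 0.0]),
                                           eff, np.arange(3))
        assert not od.applicable
        assert np.isnan(od.total)


class TestResponses:
    @staticmethod
    def _toy_stats():
        rows = []
        for rep in range(3):
            for w in (0.0, 1.0):
                for gen in range(3):
                    rows.append(dict(replicate=rep, w=w, generation=gen,
                                     cp=gen + (1.0 if w else 0.0) + 0.1 * rep))
        return pd.DataFrame(rows)

    def test_reference_curve_is_zero(self):
        rel = relative_response(self._toy_stats(), reference_w=0.0)
        zero = rel[rel.w == 0.0]
        assert np.allclose(zero.relative_cp, 0.0)

    def test_constant_offset_recovered(self):
        rel = relative_response(self._toy_stats(), reference_w=0.0)
        one = rel[rel.w == 1.0]
        assert np.allclose(one.relative_cp, 1.0)

    def test_ratio_mode(self):
        df = self._toy_stats()
        df["cp"] += 1.0  # avoid zero baseline
        rel = relative_response(df, reference_w=0.0, mode="ratio")
        assert np.allclose(rel[rel.w == 0.0].relative_cp, 1.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            relative_response(self._toy_stats(), reference_w=0.5)

    def test_cumulative_response(self):
        df = self._toy_stats()
        cum = cumulative_response(df)
        first = cum[cum.generation == 0]
        assert np.allclose(first.cumulative_cp, 0.0)
        last = cum[(cum.generation == 2) & (cum.w == 0.0)]
        assert np.allclose(last.cumulative_cp, 2.0)

    def test_aggregate_matches_direct_recomputation(self):
        df = self._toy_stats()
        agg = aggregate_replicates(df, "cp")
        cell = agg[(agg.w == 1.0) & (agg.generation == 2)].iloc[0]
        vals = df[(df.w == 1.0) & (df.generation == 2)].cp
        assert cell.cp_mean == pytest.approx(vals.mean())
        assert cell.cp_se == pytest.approx(vals.std(ddof=1) / np.sqrt(3))
        assert cell.cp_n == 3

    def test_single_replicate_has_missing_se(self):
        df = self._toy_stats()
        agg = aggregate_replicates(df[df.replicate == 0], "cp")
        assert agg.cp_se.isna().all()
        assert (agg.cp_n == 1).all()

    def test_equal_replicates_zero_se(self):
        df = pd.DataFrame(dict(replicate=[0, 1], w=[0.0, 0.0],
                               generation=[1, 1], cp=[2.0, 2.0]))
        agg = aggregate_replicates(df, "cp")
        assert agg.cp_se.iloc[0] == 0.0


@pytest.fixture(scope="module")
def tiny_study_cfg():
    genome = GenomeConfig(n_chromosomes=4, n_snps_target=80, n_qtl_target=16,
                          n_candidate_loci=192, historical_size=120,
                          historical_generations=80)
    sel = SelectionConfig(n_founders=40, n_expansion_generations=10,
                          n_candidates=60, n_males_selected=6,
                          n_females_selected=12, n_purebred_offspring=60,
                          n_crossbred_offspring=60)
    return StudyConfig(model_id=1, training_mode="purebred",
                       w_values=(0.0, 1.0), n_generations=2, n_replicates=1,
                       master_seed=3, genome=genome,
                       trait=trait_config_for_model(1), selection=sel,
                       chain=ChainConfig(n_iter=300, burn_in=100))


class TestProgram:
    def test_smoke_run_and_row_counts(self, tiny_study_cfg):
        res = run_replicate(tiny_study_cfg, 77)
        stats = res["stats"]
        # generations 0..2 for each of two w values
        assert len(stats) == 2 * (tiny_study_cfg.n_generations + 1)
        assert set(stats.w) == {0.0, 1.0}
        assert np.isfinite(stats[stats.generation > 0].cp).all()

    def test_h_identity_holds_rowwise(self, tiny_study_cfg):
        stats = run_replicate(tiny_study_cfg, 78)["stats"]
        recomputed = stats.cp - 0.5 * (stats.mean_a + stats.mean_b)
        assert np.allclose(stats.h.dropna(), recomputed.dropna())

    def test_scenarios_share_generation_zero(self, tiny_study_cfg):
        """Common-random-numbers design: w = 0 and w = 1 branch only after
        the shared base state."""
        stats = run_replicate(tiny_study_cfg, 79)["stats"]
        g0 = stats[stats.generation == 0]
        assert g0.mean_a.nunique() == 1
        assert g0.mean_b.nunique() == 1

    def test_replicate_determinism(self, tiny_study_cfg):
        r1 = run_replicate(tiny_study_cfg, 80)
        r2 = run_replicate(tiny_study_cfg, 80)
        pd.testing.assert_frame_equal(r1["stats"], r2["stats"])
        pd.testing.assert_frame_equal(r1["fixation"], r2["fixation"])

    def test_crossbred_training_mode_runs(self, tiny_study_cfg):
        import dataclasses
        cfg = dataclasses.replace(tiny_study_cfg, training_mode="crossbred",
                                  w_values=(0.5,))
        res = run_replicate(cfg, 81)
        stats = res["stats"]
        # crossbred mode phenotypes a generation-0 crossbred cohort too
        assert np.isfinite(stats.cp).all()

    def test_invalid_weight_rejected(self, tiny_study_cfg, small_world):
        with pytest.raises(ConfigurationError):
            run_scenario(small_world, tiny_study_cfg, 1.5, 1)


@pytest.fixture(scope="module")
def true_bv_program(small_selection_cfg):
    """Mini selection program ranking candidates on true breeding values
    (the estimation-free limit of the genomic program)."""
    from heterosim.population import BREED_AB, mate, select_top
    from heterosim.runner import build_base_world
    from heterosim.selection import selection_criterion
    from heterosim.values import genotypic_value, true_breeding_values
    genome = GenomeConfig(n_chromosomes=4, n_snps_target=400,
                          n_qtl_target=40, n_candidate_loci=1320,
                          historical_size=200, historical_generations=200)
    rows = []
    sel = small_selection_cfg
    for seed in (1, 2, 3):
        world = build_base_world(genome, trait_config_for_model(1), 1,
                                 sel, seed=4000 + seed)
        for w in (0.0, 1.0):
            rng = np.random.default_rng(100 * seed + int(w))
            pa, pb = world.panel_a, world.panel_b
            for gen in range(1, 17):
                qa = pa.allele_frequencies(world.qtl_indices)
                qb = pb.allele_frequencies(world.qtl_indices)
                tbv = {}
                for key, pan, own, oth in (("a", pa, qa, qb),
                                           ("b", pb, qb, qa)):
                    tp = true_breeding_values(pan, world.effects,
                                              world.qtl_indices, own)
                    tc = true_breeding_values(pan, world.effects,
                                              world.qtl_indices, oth)
                    tbv[key] = selection_criterion(tp, tc, w)
                sa = select_top(pa, tbv["a"], sel.n_males_selected,
                                sel.n_females_selected)
                sb = select_top(pb, tbv["b"], sel.n_males_selected,
                                sel.n_females_selected)
                nm = sel.n_males_selected
                xb = mate(pa, sa[:nm], pb, sb[nm:],
                          sel.n_crossbred_offspring, world.gmap, rng,
                          BREED_AB, generation=gen)
                pa = mate(pa, sa[:nm], pa, sa[nm:],
                          sel.n_purebred_offspring, world.gmap, rng,
                          pa.breed[0], generation=gen)
                pb = mate(pb, sb[:nm], pb, sb[nm:],
                          sel.n_purebred_offspring, world.gmap, rng,
                          pb.breed[0], generation=gen)
            gv = lambda p: genotypic_value(p, world.effects,
                                           world.qtl_indices).mean()
            ba = 0.5 * (gv(pa) + gv(pb))
            rows.append(dict(
                seed=seed, w=w, ba=ba, h=gv(xb) - ba,
                fix=fixation_summary(pa, pb, world.effects,
                                     world.qtl_indices),
                od=overdominant_fixation_summary(pa, pb, world.effects,
                                                 world.qtl_indices)))
    return pd.DataFrame(rows)


class TestDominanceMechanism:
    """Selection directly on true breeding values expresses the
    crossbred-selection mechanism: w = 1 drives the breeds toward
    alternate alleles at over-dominant QTL, building heterosis at the cost
    of purebred response.  This is the estimation-free limit of the
    program; genomic selection recovers it to the extent the dominance
    contrast is estimable."""

    @staticmethod
    def _mean(df, w, field, kind):
        return np.mean([getattr(r[kind], field) for _, r in
                        df[df.w == w].iterrows()])

    def test_crossbred_selection_builds_heterosis(self, true_bv_program):
        df = true_bv_program
        assert df[df.w == 1.0].h.mean() > df[df.w == 0.0].h.mean()
        assert df[df.w == 0.0].ba.mean() > df[df.w == 1.0].ba.mean()

    def test_crossbred_selection_fixes_alternate_alleles(self, true_bv_program):
        df = true_bv_program
        assert self._mean(df, 1.0, "total", "fix") > \
            self._mean(df, 0.0, "total", "fix")
        assert self._mean(df, 1.0, "common", "fix") < \
            self._mean(df, 0.0, "common", "fix")
        assert self._mean(df, 1.0, "alternate", "od") > \
            self._mean(df, 0.0, "alternate", "od")


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path, tiny_study_cfg):
        path = tmp_path / "study.yaml"
        save_study_config(tiny_study_cfg, path)
        back = load_study_config(path)
        assert back == tiny_study_cfg

    def test_full_profile_config_matches_study_conditions(self):
        """The shipped full-scale configuration encodes the published study:
        50 replicates x 40 generations, 20000/3000 chains, five weights."""
        import pathlib
        cfg = load_study_config(pathlib.Path(__file__).resolve().parents[1]
                                / "configs" / "full_model1_purebred.yaml")
        assert cfg.n_replicates == 50 and cfg.n_generations == 40
        assert cfg.chain.n_iter == 20000 and cfg.chain.burn_in == 3000
        assert cfg.w_values == (0.0, 0.25, 0.5, 0.75, 1.0)
        assert cfg.genome.n_snps_target == 4000
        assert cfg.genome.n_qtl_target == 400
        assert cfg.selection.n_candidates == 1000

    def test_default_study_config_crossbred_cohort(self):
        cfg = default_study_config(1, "crossbred")
        assert cfg.selection.n_crossbred_offspring == 2000
        assert default_study_config(2).trait.sigma2_d_target == 0.05
        assert not default_study_config(3).trait.overdominance_allowed

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("genome:\n  bogus_key: 3\n")
        with pytest.raises(ConfigurationError):
            load_study_config(p)
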