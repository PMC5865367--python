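"""Orchestration of the two-way crossbreeding selection study.

One replicate builds a base world (historical population, breeds A and B,
trait architecture, generation-0 candidates with phenotypes) and then runs
each selection-weight scenario forward from that shared state: the base
population and architecture act as common random numbers across w values,
so scenarios differ only through selection decisions.

Each generation of a scenario: estimate marker effects on the current
training cohort (one model per breed in purebred mode, one model on the
crossbreds in crossbred mode), compute GEBV-P / GEBV-C / SC for every
candidate, select the top males and females per breed, and breed the next
purebred cohorts plus the crossbred progeny (A sires x B dams).
"""
from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .brr import MarkerEstimates, fit_brr_gibbs, make_training_data
from .config import (ChainConfig, GenomeConfig, SelectionConfig, StudyConfig,
                     TraitConfig, trait_config_for_model)
from .errors import ConfigurationError
from .genome import (GeneticMap, QTLEffects, sample_architecture,
                     sample_effects, scale_effects, simulate_historical)
from .population import BREED_AB, HaplotypePanel, found_breeds, mate, select_top
from .selection import gebv, selection_accuracy, selection_criterion
from .values import genotypic_value, heterosis, simulate_phenotypes, \
    true_breeding_values

__all__ = [
    "BaseWorld", "FixationStats", "build_base_world", "make_f1",
    "run_scenario", "run_replicate", "run_study", "fixation_summary",
    "overdominant_fixation_summary", "relative_response",
    "cumulative_response", "aggregate_replicates", "default_study_config",
]


def default_study_config(model_id: int = 1, training_mode: str = "purebred",
                         **overrides) -> StudyConfig:
    """Study configuration for one of the four published scenarios.

    In crossbred-training mode 2000 crossbred progeny are produced per
    generation so that a 2000-animal crossbred training set exists.
    """
    sel = SelectionConfig()
    if training_mode == "crossbred":
        sel = dc_replace(sel, n_crossbred_offspring=2000)
    cfg = StudyConfig(model_id=model_id, training_mode=training_mode,
                      trait=trait_config_for_model(model_id),
                      selection=sel, **overrides)
    cfg.validate()
    return cfg


@dataclass
class BaseWorld:
    """Shared per-replicate state from which every scenario starts."""
    gmap: GeneticMap
    effects: QTLEffects
    base_freqs: np.ndarray           # QTL frequencies in the historical panel
    panel_a: HaplotypePanel          # generation-0 candidates, breed A
    panel_b: HaplotypePanel
    y_a: np.ndarray                  # generation-0 phenotypes
    y_b: np.ndarray
    trait: TraitConfig
    crossbreds: HaplotypePanel | None = None   # generation-0 AB cohort
    y_x: np.ndarray | None = None
    historical: HaplotypePanel | None = None

    @property
    def snp_indices(self) -> np.ndarray:
        return self.gmap.snp_indices

    @property
    def qtl_indices(self) -> np.ndarray:
        return self.gmap.qtl_indices


def build_base_world(genome: GenomeConfig, trait: TraitConfig,
                     model_id: int, selection: SelectionConfig,
                     seed, keep_historical: bool = False,
                     with_f1: bool = False) -> BaseWorld:
    """Historical population, architecture, founded breeds, phenotypes."""
    rng = np.random.default_rng(seed)
    hist, gmap = simulate_historical(genome, rng)
    gmap = sample_architecture(hist, gmap, genome, rng)
    raw = sample_effects(genome.n_qtl_target, model_id, rng)
    base_freqs = hist.allele_frequencies(gmap.qtl_indices)
    effects = scale_effects(raw, base_freqs, trait)
    panel_a, panel_b = found_breeds(
        hist, gmap, rng, n_founders=selection.n_founders,
        n_expansion_generations=selection.n_expansion_generations,
        n_candidates=selection.n_candidates)
    g_a = genotypic_value(panel_a, effects, gmap.qtl_indices)
    g_b = genotypic_value(panel_b, effects, gmap.qtl_indices)
    y_a = simulate_phenotypes(g_a, trait.sigma2_e, rng)
    y_b = simulate_phenotypes(g_b, trait.sigma2_e, rng)
    world = BaseWorld(gmap=gmap, effects=effects, base_freqs=base_freqs,
                      panel_a=panel_a, panel_b=panel_b, y_a=y_a, y_b=y_b,
                      trait=trait,
                      historical=hist if keep_historical else None)
    if with_f1:
        xb = make_f1(world, rng, selection)
        world.crossbreds = xb
        world.y_x = simulate_phenotypes(
            genotypic_value(xb, effects, gmap.qtl_indices), trait.sigma2_e, rng)
    return world


def make_f1(world: BaseWorld, rng: np.random.Generator,
            selection: SelectionConfig) -> HaplotypePanel:
    """F1 AB cohort from randomly chosen A sires and B dams (no selection)."""
    sires = rng.choice(world.panel_a.males, selection.n_males_selected,
                       replace=False)
    dams = rng.choice(world.panel_b.females, selection.n_females_selected,
                      replace=False)
    return mate(world.panel_a, sires, world.panel_b, dams,
                selection.n_crossbred_offspring, world.gmap, rng, BREED_AB)


def _train(panel, y, snp_idx, chain: ChainConfig, rng, breed: str,
           generation: int) -> MarkerEstimates:
    data = make_training_data(panel, snp_idx, y, breed=breed,
                              generation=generation)
    return fit_brr_gibbs(data, chain, seed=int(rng.integers(0, 2**31 - 1)))


def run_scenario(world: BaseWorld, cfg: StudyConfig, w: float, seed) -> dict:
    """Run one selection-weight scenario forward from the base world.

    Returns a dict with a per-generation ``stats`` DataFrame, the final
    purebred panels, and fixation summaries.  The stats row of generation g
    describes the cohorts bred by the parents selected in generation g - 1;
    its ``accuracy`` is corr(SC, TBV-C) among the breed-A candidates that
    were scored to select those parents.
    """
    cfg.validate()
    if not 0.0 <= w <= 1.0:
        raise ConfigurationError(f"selection weight w={w} outside [0, 1]")
    rng = np.random.default_rng(seed)
    gmap, effects = world.gmap, world.effects
    snp_idx, qtl_idx = world.snp_indices, world.qtl_indices
    sel = cfg.selection
    pa, pb, ya, yb = world.panel_a, world.panel_b, world.y_a, world.y_b
    xb, yx = world.crossbreds, world.y_x
    if cfg.training_mode == "crossbred" and xb is None:
        raise ConfigurationError(
            "crossbred training requires a generation-0 crossbred cohort "
            "(build the base world with with_f1=True)")
    rows = [{
        "generation": 0, "w": w,
        "mean_a": float(np.mean(ya)), "mean_b": float(np.mean(yb)),
        "cp": float(np.mean(yx)) if yx is not None else np.nan,
        "accuracy": np.nan,
        "n_fixed_qtl_a": int(_n_fixed(pa, qtl_idx)),
        "n_fixed_qtl_b": int(_n_fixed(pb, qtl_idx)),
    }]
    for gen in range(1, cfg.n_generations + 1):
        if cfg.training_mode == "purebred":
            est_a = _train(pa, ya, snp_idx, cfg.chain, rng, "A", gen - 1)
            est_b = _train(pb, yb, snp_idx, cfg.chain, rng, "B", gen - 1)
        else:
            est = _train(xb, yx, snp_idx, cfg.chain, rng, "AB", gen - 1)
            est_a = est_b = est
        fq_a = pa.allele_frequencies(snp_idx)
        fq_b = pb.allele_frequencies(snp_idx)
        sc_a = selection_criterion(gebv(pa, est_a, snp_idx, fq_a),
                                   gebv(pa, est_a, snp_idx, fq_b), w)
        sc_b = selection_criterion(gebv(pb, est_b, snp_idx, fq_b),
                                   gebv(pb, est_b, snp_idx, fq_a), w)
        tbv_c_a = true_breeding_values(pa, effects, qtl_idx,
                                       pb.allele_frequencies(qtl_idx))
        acc = selection_accuracy(sc_a, tbv_c_a)
        sel_a = select_top(pa, sc_a, sel.n_males_selected, sel.n_females_selected)
        sel_b = select_top(pb, sc_b, sel.n_males_selected, sel.n_females_selected)
        sires_a = sel_a[:sel.n_males_selected]
        dams_a = sel_a[sel.n_males_selected:]
        sires_b = sel_b[:sel.n_males_selected]
        dams_b = sel_b[sel.n_males_selected:]
        xb = mate(pa, sires_a, pb, dams_b, sel.n_crossbred_offspring,
                  gmap, rng, BREED_AB, generation=gen)
        pa = mate(pa, sires_a, pa, dams_a, sel.n_purebred_offspring,
                  gmap, rng, pa.breed[0], generation=gen)
        pb = mate(pb, sires_b, pb, dams_b, sel.n_purebred_offspring,
                  gmap, rng, pb.breed[0], generation=gen)
        ya = simulate_phenotypes(genotypic_value(pa, effects, qtl_idx),
                                 world.trait.sigma2_e, rng)
        yb = simulate_phenotypes(genotypic_value(pb, effects, qtl_idx),
                                 world.trait.sigma2_e, rng)
        yx = simulate_phenotypes(genotypic_value(xb, effects, qtl_idx),
                                 world.trait.sigma2_e, rng)
        rows.append({
            "generation": gen, "w": w,
            "mean_a": float(np.mean(ya)), "mean_b": float(np.mean(yb)),
            "cp": float(np.mean(yx)), "accuracy": acc,
            "n_fixed_qtl_a": int(_n_fixed(pa, qtl_idx)),
            "n_fixed_qtl_b": int(_n_fixed(pb, qtl_idx)),
        })
    stats = pd.DataFrame(rows)
    stats["ba"] = 0.5 * (stats["mean_a"] + stats["mean_b"])
    stats["h"] = stats["cp"] - stats["ba"]
    return {
        "stats": stats,
        "panel_a": pa, "panel_b": pb, "crossbreds": xb,
        "fixation": fixation_summary(pa, pb, effects, qtl_idx),
        "od_fixation": overdominant_fixation_summary(pa, pb, effects, qtl_idx),
    }


def _n_fixed(panel, qtl_idx) -> int:
    f = panel.allele_frequencies(qtl_idx)
    return int(np.sum((f == 0.0) | (f == 1.0)))


@dataclass
class FixationStats:
    """QTL fixation percentages in the final generation (NaN = undefined)."""
    total: float
    common: float
    alternate: float
    favorable: float
    unfavorable: float
    applicable: bool = True

    def as_dict(self) -> dict:
        return {"total": self.total, "common": self.common,
                "alternate": self.alternate, "favorable": self.favorable,
                "unfavorable": self.unfavorable, "applicable": self.applicable}


def _fixation(panel_a, panel_b, a_eff: np.ndarray, qtl_subset: np.ndarray,
              qtl_idx: np.ndarray) -> FixationStats:
    if qtl_subset.size == 0:
        return FixationStats(np.nan, np.nan, np.nan, np.nan, np.nan,
                             applicable=False)
    fa = panel_a.allele_frequencies(qtl_idx)[qtl_subset]
    fb = panel_b.allele_frequencies(qtl_idx)[qtl_subset]
    a = a_eff[qtl_subset]
    fixed_a = (fa == 0.0) | (fa == 1.0)
    fixed_b = (fb == 0.0) | (fb == 1.0)
    total = 100.0 * 0.5 * (fixed_a.mean() + fixed_b.mean())
    both = fixed_a & fixed_b
    if both.any():
        same = fa[both] == fb[both]
        common = 100.0 * same.mean()
        alternate = 100.0 - common
    else:
        common = alternate = np.nan
    fav_shares = []
    for f, fixed in ((fa, fixed_a), (fb, fixed_b)):
        if fixed.any():
            fav = ((f[fixed] == 1.0) & (a[fixed] > 0)) | \
                  ((f[fixed] == 0.0) & (a[fixed] < 0))
            fav_shares.append(fav.mean())
    if fav_shares:
        favorable = 100.0 * float(np.mean(fav_shares))
        unfavorable = 100.0 - favorable
    else:
        favorable = unfavorable = np.nan
    return FixationStats(total, common, alternate, favorable, unfavorable)


def fixation_summary(panel_a, panel_b, effects: QTLEffects,
                     qtl_idx: np.ndarray) -> FixationStats:
    """Final-generation QTL fixation, averaged over the two breeds.

    Total: share of QTL fixed for either allele.  Common/alternate: among
    QTL fixed in both breeds, fixed for the same vs different alleles.
    Favorable: among each breed's fixed QTL, share fixed for the allele
    whose homozygote has value +a, averaged over breeds.
    """
    return _fixation(panel_a, panel_b, effects.a,
                     np.arange(effects.n_qtl), qtl_idx)


def overdominant_fixation_summary(panel_a, panel_b, effects: QTLEffects,
                                  qtl_idx: np.ndarray) -> FixationStats:
    """Fixation restricted to over-dominant QTL (|d| > |a|).

    Not applicable (all NaN, applicable=False) when the architecture has no
    over-dominant QTL, as under model 3.
    """
    return _fixation(panel_a, panel_b, effects.a,
                     np.flatnonzero(effects.overdominant), qtl_idx)


def run_replicate(cfg: StudyConfig, replicate_seed) -> dict:
    """Build one base world and run every w scenario from it."""
    cfg.validate()
    if isinstance(replicate_seed, np.random.SeedSequence):
        ss = replicate_seed
    else:
        ss = np.random.SeedSequence(replicate_seed)
    world_seed, *w_seeds = ss.spawn(1 + len(cfg.w_values))
    world = build_base_world(cfg.genome, cfg.trait, cfg.model_id,
                             cfg.selection, world_seed,
                             with_f1=cfg.training_mode == "crossbred")
    stats, fix_rows, od_rows = [], [], []
    for w, wseed in zip(cfg.w_values, w_seeds):
        res = run_scenario(world, cfg, w, wseed)
        stats.append(res["stats"])
        fix_rows.append({"w": w, **res["fixation"].as_dict()})
        od_rows.append({"w": w, **res["od_fixation"].as_dict()})
    return {"stats": pd.concat(stats, ignore_index=True),
            "fixation": pd.DataFrame(fix_rows),
            "od_fixation": pd.DataFrame(od_rows)}


def run_study(cfg: StudyConfig, out_dir=None) -> dict:
    """All replicates of one scenario grid; optionally write CSV outputs."""
    cfg.validate()
    rep_seeds = np.random.SeedSequence(cfg.master_seed).spawn(cfg.n_replicates)
    stats, fixation, od = [], [], []
    for rep, seed in enumerate(rep_seeds):
        res = run_replicate(cfg, seed)
        for key, acc in (("stats", stats), ("fixation", fixation),
                         ("od_fixation", od)):
            df = res[key].copy()
            df.insert(0, "replicate", rep)
            acc.append(df)
    out = {"stats": pd.concat(stats, ignore_index=True),
           "fixation": pd.concat(fixation, ignore_index=True),
           "od_fixation": pd.concat(od, ignore_index=True)}
    if out_dir is not None:
        import pathlib
        out_path = pathlib.Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        out["stats"].to_csv(out_path / "generation_stats.csv", index=False)
        out["fixation"].to_csv(out_path / "fixation.csv", index=False)
        out["od_fixation"].to_csv(out_path / "overdominant_fixation.csv",
                                  index=False)
    return out


def relative_response(stats: pd.DataFrame, reference_w: float = 0.0,
                      value: str = "cp", mode: str = "difference") -> pd.DataFrame:
    """Replicate-mean response of each w relative to the reference criterion.

    ``mode`` is "difference" (default) or "ratio"; replicates are matched
    (common random numbers) before averaging.
    """
    if reference_w not in set(stats["w"]):
        raise ConfigurationError(f"reference w={reference_w} not present")
    need_rep = "replicate" in stats.columns
    keys = ["replicate", "generation"] if need_rep else ["generation"]
    wide = stats.pivot_table(index=keys, columns="w", values=value)
    ref = wide[reference_w]
    if mode == "difference":
        rel = wide.sub(ref, axis=0)
    elif mode == "ratio":
        rel = wide.div(ref, axis=0)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    rel = rel.reset_index()
    out = rel.groupby("generation").mean()
    if need_rep:
        out = out.drop(columns="replicate")
    return out.reset_index().melt(id_vars="generation", var_name="w",
                                  value_name=f"relative_{value}")


def cumulative_response(stats: pd.DataFrame, value: str = "cp") -> pd.DataFrame:
    """Response relative to the first generation with a defined value."""
    def _one(group):
        g = group.sort_values("generation")
        base = g[value].dropna()
        g = g.assign(**{f"cumulative_{value}":
                        g[value] - (base.iloc[0] if len(base) else np.nan)})
        return g
    keys = [k for k in ("replicate", "w") if k in stats.columns]
    return stats.groupby(keys, group_keys=False)[stats.columns].apply(_one)


def aggregate_replicates(stats: pd.DataFrame, value_cols,
                         group_cols=("w", "generation")) -> pd.DataFrame:
    """Mean, standard error and replicate count per scenario cell."""
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    g = stats.groupby(list(group_cols))
    pieces = {}
    for col in value_cols:
        pieces[f"{col}_mean"] = g[col].mean()
        n = g[col].count()
        sd = g[col].std(ddof=1)
        pieces[f"{col}_se"] = sd / np.sqrt(n)
        pieces[f"{col}_n"] = n
    return pd.DataFrame(pieces).reset_index()
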