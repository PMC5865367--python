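"""Desk-scale reproductions of the study's base-population statistics.

These helpers rebuild the base populations at the full stated conditions
(historical N = 2000 for 2000 generations, ~8800 loci, breeds founded from
100 animals and expanded for 100 generations) and compute the summary
statistics the study reports for them: LD-phase correlation curves between
breeds and their F1 crossbreds, the purebred-crossbred genetic correlation
r_pc, first-generation selection accuracy, and post-scaling over-dominance
fractions.  They are used by the acceptance script and the acceptance test
suite; the full 40-generation factorial lives in :mod:`heterosim.runner`.
"""
from __future__ import annotations

import numpy as np

from .brr import fit_brr_gibbs, make_training_data
from .config import ChainConfig, GenomeConfig, SelectionConfig, \
    trait_config_for_model
from .genome import sample_effects, scale_effects
from .ldphase import haplotype_ld_r, phase_correlation, snp_pair_table
from .runner import BaseWorld, build_base_world, make_f1
from .selection import gebv, selection_accuracy, selection_criterion
from .values import rpc, simulate_phenotypes, true_breeding_values, \
    genotypic_value

__all__ = [
    "build_replicate_world", "ld_phase_statistics", "rpc_across_models",
    "generation1_accuracies", "overdominance_fraction",
    "desk_program_config",
]

W_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def desk_program_config(n_generations: int = 20, n_replicates: int = 5,
                        w_values=(0.0, 1.0), master_seed: int = 11):
    """Reduced selection-program profile for desk-scale runs.

    Keeps the full historical phase and the 400-QTL trait architecture
    (the exploitable heterosis pool scales like sqrt(n_QTL), so shrinking
    the QTL panel suppresses the selection-criterion contrasts), but
    reduces the marker panel to 1000 SNPs, the cohorts to 500 candidates
    per breed (50 males + 100 females selected) and the Gibbs chain to
    800/200.
    """
    from .config import StudyConfig
    genome = GenomeConfig(n_chromosomes=4, n_snps_target=1000,
                          n_qtl_target=400, n_candidate_loci=2800,
                          historical_size=2000, historical_generations=2000)
    sel = SelectionConfig(n_candidates=500, n_males_selected=50,
                          n_females_selected=100, n_purebred_offspring=500,
                          n_crossbred_offspring=500)
    return StudyConfig(model_id=1, training_mode="purebred",
                       w_values=tuple(w_values), n_generations=n_generations,
                       n_replicates=n_replicates, master_seed=master_seed,
                       genome=genome, trait=trait_config_for_model(1),
                       selection=sel,
                       chain=ChainConfig(n_iter=800, burn_in=200))


def build_replicate_world(seed, genome: GenomeConfig | None = None,
                          selection: SelectionConfig | None = None,
                          model_id: int = 1) -> BaseWorld:
    """One base world at the study's stated conditions, with an F1 cohort."""
    genome = genome or GenomeConfig()
    selection = selection or SelectionConfig()
    world = build_base_world(genome, trait_config_for_model(model_id),
                             model_id, selection, seed, with_f1=True)
    return world


def ld_phase_statistics(world: BaseWorld, max_distance_cM: float = 10.0,
                        near_cM: float = 0.5) -> dict:
    """R_XY summaries for (A, B), (A, F1) and (B, F1).

    Returns means of the binned R_XY over bins below ``near_cM`` and the
    value in the terminal bin near ``max_distance_cM``.
    """
    pi, pj, dist = snp_pair_table(world.gmap, max_distance_cM)
    r, v = {}, {}
    for name, panel in (("A", world.panel_a), ("B", world.panel_b),
                        ("F1", world.crossbreds)):
        r[name], v[name] = haplotype_ld_r(panel, pi, pj, maf_threshold=0.01)
    out = {}
    for x, y in (("A", "B"), ("A", "F1"), ("B", "F1")):
        curve = phase_correlation(r[x], v[x], r[y], v[y], dist,
                                  max_distance_cM=max_distance_cM)
        near = curve[curve.bin_high_cM <= near_cM].R.mean()
        far = curve.R.iloc[-1]
        out[f"R_{x}{y}_near"] = float(near)
        out[f"R_{x}{y}_far"] = float(far)
        out["n_pairs"] = int(curve.n_pairs.sum())
    return out


def rpc_across_models(world: BaseWorld, rng: np.random.Generator,
                      model_ids=(1, 2, 3)) -> float:
    """r_pc among generation-0 candidates, averaged over breeds and models.

    Effects are re-sampled and re-scaled per model on the world's base
    frequencies, so all models share the same genomes (the study's own
    common-random-numbers design).
    """
    qa = world.panel_a.allele_frequencies(world.qtl_indices)
    qb = world.panel_b.allele_frequencies(world.qtl_indices)
    vals = []
    for m in model_ids:
        eff = scale_effects(sample_effects(world.qtl_indices.size, m, rng),
                            world.base_freqs, trait_config_for_model(m))
        for panel, own, other in ((world.panel_a, qa, qb),
                                  (world.panel_b, qb, qa)):
            tbv_p = true_breeding_values(panel, eff, world.qtl_indices, own)
            tbv_c = true_breeding_values(panel, eff, world.qtl_indices, other)
            vals.append(rpc(tbv_p, tbv_c))
    return float(np.mean(vals))


def generation1_accuracies(world: BaseWorld, chain: ChainConfig, seed,
                           w_grid=W_GRID) -> dict:
    """First-generation accuracy corr(SC, TBV-C) for breed A, per weight.

    Trains on the breed-A generation-0 candidates (purebred design) and
    scores the same cohort, as in the first round of selection.
    """
    data = make_training_data(world.panel_a, world.snp_indices, world.y_a,
                              breed="A", generation=0)
    est = fit_brr_gibbs(data, chain, seed=seed)
    fa = world.panel_a.allele_frequencies(world.snp_indices)
    fb = world.panel_b.allele_frequencies(world.snp_indices)
    gebv_p = gebv(world.panel_a, est, world.snp_indices, fa)
    gebv_c = gebv(world.panel_a, est, world.snp_indices, fb)
    tbv_c = true_breeding_values(
        world.panel_a, world.effects, world.qtl_indices,
        world.panel_b.allele_frequencies(world.qtl_indices))
    return {w: selection_accuracy(selection_criterion(gebv_p, gebv_c, w),
                                  tbv_c) for w in w_grid}


def accuracy_world_for_model(world: BaseWorld, model_id: int,
                             rng: np.random.Generator) -> BaseWorld:
    """Re-trait an existing world under another genetic model.

    Re-samples and re-scales effects and re-draws phenotypes; genomes and
    breed structure are shared across models.
    """
    import dataclasses
    trait = trait_config_for_model(model_id)
    eff = scale_effects(sample_effects(world.qtl_indices.size, model_id, rng),
                        world.base_freqs, trait)
    w2 = dataclasses.replace(world, effects=eff, trait=trait)
    w2.y_a = simulate_phenotypes(
        genotypic_value(world.panel_a, eff, world.qtl_indices),
        trait.sigma2_e, rng)
    w2.y_b = simulate_phenotypes(
        genotypic_value(world.panel_b, eff, world.qtl_indices),
        trait.sigma2_e, rng)
    return w2


def overdominance_fraction(base_freqs: np.ndarray, model_id: int,
                           rng: np.random.Generator, n_qtl: int = 400,
                           n_draws: int = 4) -> list[float]:
    """Percent of QTL with |d| > |a| after scaling, for several draws."""
    trait = trait_config_for_model(model_id)
    out = []
    for _ in range(n_draws):
        eff = scale_effects(sample_effects(n_qtl, model_id, rng),
                            base_freqs, trait)
        out.append(100.0 * float(eff.overdominant.mean()))
    return out
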