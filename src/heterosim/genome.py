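"""Genome layout, historical population and trait architecture.

This module is the study's synthetic-data generator.  A biallelic genome of
four 1-Morgan chromosomes is seeded with ~8800 candidate loci at uniform
initial allele frequencies and drifts through 2000 generations of random
mating at N = 2000 under recurrent symmetric mutation (2.5e-5 per locus per
gamete).  From the loci still segregating at MAF > 0.05, 4000 SNPs and 400
QTL are drawn (1000 + 100 per chromosome).  QTL additive effects have
gamma(shape 0.4, scale 1.66) magnitudes with random sign, degrees of
dominance are N(0.5, 1), and effects are rescaled iteratively so that the
additive and dominance variances at base-population frequencies hit their
targets (0.3 and 0.1 or 0.05).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import GenomeConfig, TraitConfig
from .errors import (AlignmentError, ConfigurationError, ConvergenceError,
                     InsufficientPolymorphismError)

__all__ = [
    "GeneticMap", "QTLEffects", "build_genetic_map", "simulate_historical",
    "sample_architecture", "sample_effects", "compute_variances", "scale_effects",
    "LOCUS_DISCARDED", "LOCUS_SNP", "LOCUS_QTL",
]

LOCUS_DISCARDED = 0
LOCUS_SNP = 1
LOCUS_QTL = 2


@dataclass
class GeneticMap:
    """Per-locus chromosome index, position (Morgans) and class label."""
    chromosome: np.ndarray      # (L,) int32
    position: np.ndarray        # (L,) float64, within-chromosome, sorted per chrom
    locus_class: np.ndarray     # (L,) int8
    chrom_lengths: np.ndarray   # (n_chrom,) float64 Morgans

    @property
    def n_loci(self) -> int:
        return self.position.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.chrom_lengths.shape[0]

    @property
    def chrom_starts(self) -> np.ndarray:
        starts = np.searchsorted(self.chromosome,
                                 np.arange(self.n_chromosomes + 1))
        return starts.astype(np.int64)

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.locus_class == LOCUS_SNP)

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.locus_class == LOCUS_QTL)

    def distances_cM(self, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
        """Within-chromosome map distances in centimorgans."""
        if np.any(self.chromosome[idx_a] != self.chromosome[idx_b]):
            raise AlignmentError("distance requested across chromosomes")
        return np.abs(self.position[idx_a] - self.position[idx_b]) * 100.0


@dataclass
class QTLEffects:
    """Per-QTL additive effect a, dominance effect d and degree of dominance h.

    a is half the genotypic difference between alternate homozygotes, d the
    heterozygote deviation from the homozygote mean, and h = d / |a|; a QTL
    is over-dominant when |d| > |a|.
    """
    a: np.ndarray
    d: np.ndarray
    model_id: int = 1

    @property
    def h(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.a != 0, self.d / np.abs(self.a), 0.0)

    @property
    def n_qtl(self) -> int:
        return self.a.shape[0]

    @property
    def overdominant(self) -> np.ndarray:
        return np.abs(self.d) > np.abs(self.a)


def build_genetic_map(config: GenomeConfig, rng: np.random.Generator) -> GeneticMap:
    """Candidate loci at uniform random positions, equal counts per chromosome."""
    config.validate()
    if config.n_candidate_loci % config.n_chromosomes:
        raise ConfigurationError("candidate loci must divide evenly over chromosomes")
    per_chrom = config.n_candidate_loci // config.n_chromosomes
    chrom = np.repeat(np.arange(config.n_chromosomes, dtype=np.int32), per_chrom)
    pos = np.concatenate([
        np.sort(rng.uniform(0.0, config.chromosome_length, per_chrom))
        for _ in range(config.n_chromosomes)])
    return GeneticMap(
        chromosome=chrom, position=pos,
        locus_class=np.zeros(config.n_candidate_loci, dtype=np.int8),
        chrom_lengths=np.full(config.n_chromosomes, config.chromosome_length),
    )


def simulate_historical(config: GenomeConfig, rng: np.random.Generator,
                        gmap: GeneticMap | None = None):
    """Simulate the historical population and return (panel, map).

    Initial allele frequencies are uniform(0, 1); the population then mates
    randomly (random union of gametes) for ``historical_generations``
    generations at constant size with recurrent symmetric allele-flip
    mutation applied per gamete per locus.  Mutation acts only in this
    historical phase.
    """
    from ._kernels import wright_fisher_packed
    from .population import HISTORICAL, HaplotypePanel, _alternating_sexes
    config.validate()
    if gmap is None:
        gmap = build_genetic_map(config, rng)
    n, L = config.historical_size, gmap.n_loci
    p0 = rng.uniform(0.0, 1.0, L)
    haps = (rng.random((n, 2, L)) < p0).astype(np.uint8)
    # the long neutral phase runs bit-packed to stay inside the CPU caches
    packed = np.packbits(haps, axis=-1, bitorder="little")
    packed = wright_fisher_packed(
        np.ascontiguousarray(packed), config.historical_generations,
        gmap.chrom_starts, gmap.position, gmap.chrom_lengths,
        config.mutation_rate, int(rng.integers(0, 2**31 - 1)))
    haps = np.unpackbits(packed, axis=-1, bitorder="little",
                         count=L).astype(np.uint8)
    panel = HaplotypePanel(
        ids=np.arange(n, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64), dam=np.full(n, -1, dtype=np.int64),
        sex=_alternating_sexes(n), breed=np.full(n, HISTORICAL, dtype=np.int8),
        generation=config.historical_generations, haplotypes=haps,
    )
    return panel, gmap


def sample_architecture(panel, gmap: GeneticMap, config: GenomeConfig,
                        rng: np.random.Generator) -> GeneticMap:
    """Assign SNP and QTL labels among loci segregating at MAF > threshold.

    Draws are without replacement, per chromosome (1000 SNPs + 100 QTL each
    under the default genome), so SNP and QTL sets are disjoint by
    construction.
    """
    config.validate()
    p = panel.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    eligible = maf > config.maf_threshold_arch
    snp_per = config.n_snps_target // config.n_chromosomes
    qtl_per = config.n_qtl_target // config.n_chromosomes
    classes = np.zeros(gmap.n_loci, dtype=np.int8)
    for c in range(config.n_chromosomes):
        on_chrom = np.flatnonzero((gmap.chromosome == c) & eligible)
        need = snp_per + qtl_per
        if on_chrom.size < need:
            raise InsufficientPolymorphismError(
                f"chromosome {c}: {on_chrom.size} loci with MAF > "
                f"{config.maf_threshold_arch} but {need} needed "
                f"(shortfall {need - on_chrom.size})")
        chosen = rng.choice(on_chrom, size=need, replace=False)
        classes[chosen[:snp_per]] = LOCUS_SNP
        classes[chosen[snp_per:]] = LOCUS_QTL
    return replace(gmap, locus_class=classes)


def sample_effects(n_qtl: int, model_id: int, rng: np.random.Generator,
                   gamma_shape: float = 0.4, gamma_scale: float = 1.66) -> QTLEffects:
    """Sample raw (unscaled) QTL effects.

    |a| ~ gamma(shape, scale) with the increasing allele assigned at random
    (sign of a is +/- with probability 0.5); h ~ N(0.5, 1); d = h * |a|.
    Under model 3 any QTL sampled as over-dominant (|h| > 1) is clamped to
    complete dominance, d = |a|.
    """
    if n_qtl <= 0:
        raise ConfigurationError("n_qtl must be positive")
    if model_id not in (1, 2, 3):
        raise ConfigurationError(f"model_id must be 1, 2 or 3, got {model_id}")
    mag = rng.gamma(gamma_shape, gamma_scale, n_qtl)
    sign = rng.choice([-1.0, 1.0], n_qtl)
    a = sign * mag
    h = rng.normal(0.5, 1.0, n_qtl)
    d = h * mag
    if model_id == 3:
        over = np.abs(h) > 1.0
        d = np.where(over, mag, d)
    return QTLEffects(a=a, d=d, model_id=model_id)


def compute_variances(effects: QTLEffects, p: np.ndarray) -> tuple[float, float]:
    """Additive and dominance variance at the given allele frequencies.

    Under Hardy-Weinberg and linkage equilibrium, with u = 2 p q and the
    allele substitution effect alpha = a + (q - p) d,

        sigma2_a = sum_j u_j alpha_j^2          (breeding-value variance)
        sigma2_d = sum_j u_j (1 - u_j) d_j^2    (dominance-component variance)

    sigma2_a is the narrow-sense additive genetic variance (the quantity h2
    refers to); sigma2_d is the variance of the dominance component
    sum_j z_j d_j of the genotypic value, z the heterozygosity indicator.
    These are the quantities the effect scaling calibrates to the trait
    targets.  The variance of orthogonal dominance deviations,
    sum (2pq d)^2, is available as :func:`dominance_deviation_variance`.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[0] != effects.n_qtl:
        raise AlignmentError(
            f"{p.shape[0]} frequencies for {effects.n_qtl} QTL")
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("allele frequencies outside [0, 1]")
    q = 1.0 - p
    u = 2.0 * p * q
    alpha = effects.a + (q - p) * effects.d
    sigma2_a = float(np.sum(u * alpha**2))
    sigma2_d = float(np.sum(u * (1.0 - u) * effects.d**2))
    return sigma2_a, sigma2_d


def dominance_deviation_variance(effects: QTLEffects, p: np.ndarray) -> float:
    """Variance of orthogonal dominance deviations, sum (2pq d)^2 (HWE, LE)."""
    p = np.asarray(p, dtype=float)
    if p.shape[0] != effects.n_qtl:
        raise AlignmentError(
            f"{p.shape[0]} frequencies for {effects.n_qtl} QTL")
    return float(np.sum((2.0 * p * (1.0 - p) * effects.d) ** 2))


def scale_effects(effects: QTLEffects, base_freqs: np.ndarray,
                  trait: TraitConfig, tol: float = 1e-4,
                  max_iter: int = 200) -> QTLEffects:
    """Rescale a and d so the base-population variances hit their targets.

    Alternates multiplicative updates a <- a * sqrt(target_a / current_a)
    and d <- d * sqrt(target_d / current_d) until both component variances
    (see :func:`compute_variances`) are within relative tolerance.  When
    over-dominance is excluded (model 3), |d| is re-clamped to |a| after
    every update, which couples the steps and makes the iteration genuinely
    iterative.
    """
    trait.validate()
    p = np.asarray(base_freqs, dtype=float)
    segregating = (p > 0) & (p < 1)
    if not np.any(segregating):
        raise ConvergenceError("no segregating QTL: variance targets unreachable")
    a = effects.a.astype(float).copy()
    d = effects.d.astype(float).copy()
    ta, td = trait.sigma2_a_target, trait.sigma2_d_target
    clamp = effects.model_id == 3 or not trait.overdominance_allowed

    def _clamped(a, d):
        if not clamp:
            return d
        lim = np.abs(a)
        return np.sign(d) * np.minimum(np.abs(d), lim)

    d = _clamped(a, d)
    want_d = td > 0 and np.any(d[segregating] != 0)
    if td > 0 and not np.any(d[segregating] != 0):
        raise ConvergenceError("dominance target positive but all d are zero")
    va = vd = np.nan
    for _ in range(max_iter):
        cur = QTLEffects(a=a, d=d, model_id=effects.model_id)
        va, vd = compute_variances(cur, p)
        if va <= 0:
            raise ConvergenceError("additive variance is zero at base frequencies")
        ok_a = abs(va - ta) <= tol * max(ta, 1e-12)
        ok_d = (not want_d and vd <= tol) or \
            (want_d and abs(vd - td) <= tol * max(td, 1e-12))
        if ok_a and ok_d:
            return cur
        a = a * np.sqrt(ta / va)
        if want_d:
            _, vd_now = compute_variances(
                QTLEffects(a=a, d=d, model_id=effects.model_id), p)
            if vd_now > 0:
                d = d * np.sqrt(td / vd_now)
        d = _clamped(a, d)
    raise ConvergenceError(
        f"effect scaling did not converge in {max_iter} iterations "
        f"(residuals: sigma2_a {va - ta:+.3e}, sigma2_d {vd - td:+.3e})")


def architecture_frame(gmap: GeneticMap, effects: QTLEffects,
                       base_freqs: np.ndarray):
    """Tabular architecture export: one row per locus."""
    import pandas as pd
    cls = np.array(["discarded", "SNP", "QTL"])[gmap.locus_class]
    df = pd.DataFrame({
        "locus": np.arange(gmap.n_loci),
        "chromosome": gmap.chromosome,
        "position_Morgan": gmap.position,
        "class": cls,
        "base_freq": base_freqs,
        "a": np.nan, "d": np.nan, "h": np.nan,
    })
    qtl = gmap.qtl_indices
    df.loc[qtl, "a"] = effects.a
    df.loc[qtl, "d"] = effects.d
    df.loc[qtl, "h"] = effects.h
    return df
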