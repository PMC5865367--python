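"""Genotypic values, phenotypes and true breeding values.

The genotypic value of an individual sums +a for AA, d for Aa and -a for
aa over QTL.  True breeding values are defined as the expected genotypic
value of offspring under random mating: to the own breed for purebred
performance (TBV-P) or to the opposite breed for crossbred performance
(TBV-C).  With x_ij the proportion of A alleles carried (1, 0.5 or 0) and
(p, q) the allele frequencies among the mates,

    TBV_i = sum_j  x_ij (p_j a_j + q_j d_j) + (1 - x_ij)(-q_j a_j + p_j d_j).

Heterosis is the crossbred superiority over the parental breed average,
H = CP - BA; for an F1 under Hardy-Weinberg its expectation is
sum_j d_j (p_Aj - p_Bj)^2.
"""
from __future__ import annotations

import numpy as np

from .errors import AlignmentError, ConfigurationError, DataError
from .genome import QTLEffects

__all__ = [
    "genotypic_value", "simulate_phenotypes", "expected_offspring_value",
    "true_breeding_values", "heterosis", "expected_f1_heterosis", "rpc",
]


def genotypic_value(panel, effects: QTLEffects, qtl_indices: np.ndarray) -> np.ndarray:
    """Per-individual genotypic value summed over QTL."""
    X = panel.dosages(qtl_indices).astype(np.float64)
    if X.shape[1] != effects.n_qtl:
        raise AlignmentError(f"{X.shape[1]} QTL genotypes for {effects.n_qtl} effects")
    return (X - 1.0) @ effects.a + (X == 1.0) @ effects.d


def simulate_phenotypes(values: np.ndarray, sigma2_e: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Phenotype = genotypic value + N(0, sigma2_e) residual."""
    if sigma2_e < 0:
        raise ConfigurationError(f"residual variance {sigma2_e} is negative")
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise DataError("non-finite genotypic values")
    return values + rng.normal(0.0, np.sqrt(sigma2_e), values.shape[0])


def expected_offspring_value(x_prop: np.ndarray, a: np.ndarray, d: np.ndarray,
                             p_mates: np.ndarray) -> np.ndarray:
    """Core of the breeding-value formula, shared by TBV and GEBV.

    x_prop : (n, m) proportion of A alleles carried (1, 0.5, 0)
    p_mates : (m,) frequency of A among the mate population's gametes
    """
    p = np.asarray(p_mates, dtype=float)
    if x_prop.shape[1] != p.shape[0] or p.shape[0] != len(a):
        raise AlignmentError("genotypes, effects and frequencies misaligned")
    q = 1.0 - p
    return x_prop @ (p * a + q * d) + (1.0 - x_prop) @ (-q * a + p * d)


def true_breeding_values(panel, effects: QTLEffects, qtl_indices: np.ndarray,
                         mate_freqs: np.ndarray) -> np.ndarray:
    """TBV against a mate population with the given QTL allele frequencies.

    Pass the own breed's frequencies for TBV-P, the opposite breed's for
    TBV-C.
    """
    x = panel.dosages(qtl_indices).astype(np.float64) / 2.0
    return expected_offspring_value(x, effects.a, effects.d, mate_freqs)


def heterosis(crossbred_mean: float, mean_a: float, mean_b: float) -> float:
    """H = CP - BA with BA the mid-parental breed mean."""
    return float(crossbred_mean) - 0.5 * (float(mean_a) + float(mean_b))


def expected_f1_heterosis(effects: QTLEffects, p_a: np.ndarray,
                          p_b: np.ndarray) -> float:
    """Closed-form F1 heterosis sum_j d_j (p_Aj - p_Bj)^2 under HWE."""
    p_a = np.asarray(p_a, float)
    p_b = np.asarray(p_b, float)
    if p_a.shape != p_b.shape or p_a.shape[0] != effects.n_qtl:
        raise AlignmentError("frequency tables misaligned with QTL effects")
    return float(np.sum(effects.d * (p_a - p_b) ** 2))


def rpc(tbv_p: np.ndarray, tbv_c: np.ndarray) -> float:
    """Purebred-crossbred genetic correlation: Pearson corr(TBV-P, TBV-C)."""
    tbv_p = np.asarray(tbv_p, float)
    tbv_c = np.asarray(tbv_c, float)
    if tbv_p.shape != tbv_c.shape or tbv_p.shape[0] < 3:
        raise DataError("need >= 3 aligned TBV pairs")
    if np.std(tbv_p) == 0 or np.std(tbv_c) == 0:
        raise DataError("undefined correlation: zero variance in TBVs")
    return float(np.corrcoef(tbv_p, tbv_c)[0, 1])
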