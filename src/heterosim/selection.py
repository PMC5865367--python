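"""Genomic breeding values and the blended selection criterion.

GEBV-P and GEBV-C apply the TBV formula to SNPs with estimated effects:
own-breed SNP frequencies give the purebred breeding value, opposite-breed
frequencies the crossbred one.  Candidates are ranked on the affine blend
SC_i = (1 - w) GEBV_iP + w GEBV_iC; w = 0 selects for purebred and w = 1
for crossbred performance.
"""
from __future__ import annotations

import numpy as np

from .brr import MarkerEstimates
from .errors import AlignmentError, ConfigurationError, DataError
from .values import expected_offspring_value

__all__ = ["gebv", "selection_criterion", "selection_accuracy"]


def gebv(panel, estimates: MarkerEstimates, snp_indices: np.ndarray,
         mate_freqs: np.ndarray) -> np.ndarray:
    """GEBV of each candidate against a mate population.

    ``mate_freqs`` are the SNP allele frequencies among all selection
    candidates of the mate breed: the own breed for GEBV-P, the opposite
    breed for GEBV-C.  Frequencies of exactly 0 or 1 are legal.
    """
    if len(snp_indices) != estimates.n_snps:
        raise AlignmentError("SNP set does not match the marker estimates")
    x = panel.dosages(snp_indices).astype(np.float64) / 2.0
    return expected_offspring_value(x, estimates.a_hat, estimates.d_hat,
                                    mate_freqs)


def selection_criterion(gebv_p: np.ndarray, gebv_c: np.ndarray,
                        w: float) -> np.ndarray:
    """SC = (1 - w) GEBV-P + w GEBV-C, no re-scaling of either component."""
    if not 0.0 <= w <= 1.0:
        raise ConfigurationError(f"selection weight w={w} outside [0, 1]")
    gebv_p = np.asarray(gebv_p, float)
    gebv_c = np.asarray(gebv_c, float)
    if gebv_p.shape != gebv_c.shape:
        raise AlignmentError("GEBV-P and GEBV-C not aligned")
    return (1.0 - w) * gebv_p + w * gebv_c


def selection_accuracy(sc: np.ndarray, tbv_c: np.ndarray) -> float:
    """Pearson correlation between the selection criterion and TBV-C."""
    sc = np.asarray(sc, float)
    tbv_c = np.asarray(tbv_c, float)
    if sc.shape != tbv_c.shape or sc.shape[0] < 3:
        raise DataError("need >= 3 aligned candidates")
    if np.std(sc) == 0 or np.std(tbv_c) == 0:
        raise DataError("undefined correlation: zero variance")
    return float(np.corrcoef(sc, tbv_c)[0, 1])
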