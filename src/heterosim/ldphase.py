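"""Signed LD and the between-population correlation of LD phase.

LD between two SNPs is the signed Pearson correlation r of their allele
indicators across the 2n phased gametes of a population, under one global
allele labelling shared by every population (so that the sign of r is
comparable).  The correlation of LD phase R_XY in a distance bin is the
Pearson correlation, over SNP pairs in that bin, between r in population X
and r in population Y; it measures how well linkage phase persists across
populations.  Pairs are binned at 0.1 cM from 0 to 10 cM, and only SNPs
with MAF > 0.01 in the respective population enter.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .genome import GeneticMap

__all__ = ["snp_pair_table", "haplotype_ld_r", "phase_correlation",
           "ld_phase_curve"]


def snp_pair_table(gmap: GeneticMap, max_distance_cM: float = 10.0):
    """All within-chromosome SNP pairs up to ``max_distance_cM`` apart.

    Returns (i, j, dist_cM): global locus indices with position(j) >=
    position(i), enumerated chromosome by chromosome.
    """
    snp = gmap.snp_indices
    ii, jj, dd = [], [], []
    for c in range(gmap.n_chromosomes):
        on = snp[gmap.chromosome[snp] == c]
        pos = gmap.position[on] * 100.0  # cM
        hi = np.searchsorted(pos, pos + max_distance_cM, side="right")
        for k in range(on.size):
            upper = hi[k]
            if upper <= k + 1:
                continue
            ii.append(np.full(upper - k - 1, on[k]))
            jj.append(on[k + 1:upper])
            dd.append(pos[k + 1:upper] - pos[k])
    if not ii:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0),)
    return (np.concatenate(ii), np.concatenate(jj),
            np.concatenate(dd).astype(float))


def haplotype_ld_r(panel, pairs_i: np.ndarray, pairs_j: np.ndarray,
                   maf_threshold: float = 0.01, block: int = 1200):
    """Signed r for each SNP pair from the panel's phased haplotypes.

    Returns (r, valid): r is NaN where either SNP is monomorphic; valid
    additionally requires MAF > ``maf_threshold`` at both SNPs.  Pair
    correlations are read out of blockwise Gram matrices of the
    standardized 2n x S gamete matrix (one matrix product per block pair
    instead of per-pair reductions).
    """
    if pairs_i.shape != pairs_j.shape:
        raise AlignmentError("pair index arrays differ in length")
    snps = np.unique(np.concatenate([pairs_i, pairs_j]))
    col = {s: k for k, s in enumerate(snps)}
    H = panel.haplotypes[:, :, snps].reshape(-1, snps.size).astype(np.float32)
    m = H.mean(axis=0)
    sd = H.std(axis=0)
    poly = sd > 0
    Hs = np.zeros_like(H)
    Hs[:, poly] = (H[:, poly] - m[poly]) / sd[poly]
    maf = np.minimum(m, 1.0 - m)
    ok = poly & (maf > maf_threshold)
    ci = np.fromiter((col[s] for s in pairs_i), np.int64, pairs_i.size)
    cj = np.fromiter((col[s] for s in pairs_j), np.int64, pairs_j.size)
    n2 = H.shape[0]
    r = np.empty(pairs_i.size)
    # pairs are enumerated with j >= i and limited map distance, so sorting
    # by ci yields nearly-square blocks touching at most two column blocks
    order = np.argsort(ci, kind="stable")
    ci_s, cj_s = ci[order], cj[order]
    r_s = np.empty_like(r)
    for lo in range(0, snps.size, block):
        hi = min(lo + block, snps.size)
        sel = np.flatnonzero((ci_s >= lo) & (ci_s < hi))
        if sel.size == 0:
            continue
        jmax = int(cj_s[sel].max()) + 1
        G = (Hs[:, lo:hi].T @ Hs[:, lo:jmax]) / n2
        r_s[sel] = G[ci_s[sel] - lo, cj_s[sel] - lo]
    r[order] = r_s
    both_poly = poly[ci] & poly[cj]
    r[~both_poly] = np.nan
    valid = ok[ci] & ok[cj]
    return r, valid


def phase_correlation(r_x: np.ndarray, valid_x: np.ndarray,
                      r_y: np.ndarray, valid_y: np.ndarray,
                      dist_cM: np.ndarray, bin_width: float = 0.1,
                      max_distance_cM: float = 10.0,
                      min_pairs: int = 3) -> pd.DataFrame:
    """R_XY per distance bin over the pairs valid in both populations.

    Bins are half-open [k*w, (k+1)*w) cM; a bin with fewer than
    ``min_pairs`` shared pairs gets R = NaN.
    """
    if not (r_x.shape == r_y.shape == dist_cM.shape):
        raise AlignmentError("LD tables do not share the pair set")
    shared = valid_x & valid_y & (dist_cM < max_distance_cM)
    n_bins = int(round(max_distance_cM / bin_width))
    idx = np.floor(dist_cM / bin_width).astype(int)
    rows = []
    for b in range(n_bins):
        mask = shared & (idx == b)
        n = int(mask.sum())
        if n >= min_pairs:
            rx, ry = r_x[mask], r_y[mask]
            if rx.std() > 0 and ry.std() > 0:
                R = float(np.corrcoef(rx, ry)[0, 1])
            else:
                R = np.nan
        else:
            R = np.nan
        rows.append((b * bin_width, (b + 1) * bin_width, n, R))
    return pd.DataFrame(rows, columns=["bin_low_cM", "bin_high_cM",
                                       "n_pairs", "R"])


def ld_phase_curve(panel_x, panel_y, gmap: GeneticMap,
                   bin_width: float = 0.1, max_distance_cM: float = 10.0,
                   maf_threshold: float = 0.01) -> pd.DataFrame:
    """Full pipeline: pair enumeration, per-population r, binned R_XY."""
    pi, pj, dist = snp_pair_table(gmap, max_distance_cM)
    r_x, v_x = haplotype_ld_r(panel_x, pi, pj, maf_threshold)
    r_y, v_y = haplotype_ld_r(panel_y, pi, pj, maf_threshold)
    return phase_correlation(r_x, v_x, r_y, v_y, dist, bin_width,
                             max_distance_cM)
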