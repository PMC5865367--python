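"""Numba kernels for gamete dropping and the Gibbs sampler.

These are the hot loops of the simulator: meiosis over thousands of
generations, and single-site Gibbs updates over thousands of marker
effects.  Everything here is deterministic given the integer seed passed
in (numba's own np.random state, independent of the caller's Generator).

The historical population runs on bit-packed haplotypes (8 loci per byte,
LSB first) to stay inside the CPU caches; the breeding phase, which needs
per-locus genotypes anyway, uses plain uint8 alleles.
"""
import numpy as np
from numba import njit

__all__ = ["drop_gametes", "wright_fisher_packed", "gibbs_brr"]

MAX_XO = 64  # crossovers per chromosome are Poisson(~1); 64 is effectively inf


@njit(cache=True, inline="always")
def _sample_crossovers(xo, length):
    """Poisson(length) crossover positions, insertion-sorted into xo."""
    k = np.random.poisson(length)
    if k > MAX_XO - 2:
        k = MAX_XO - 2
    for x in range(k):
        v = np.random.uniform(0.0, length)
        m = x
        while m > 0 and xo[m - 1] > v:
            xo[m] = xo[m - 1]
            m -= 1
        xo[m] = v
    return k


@njit(cache=True, inline="always")
def _breakpoint(positions, lo, hi, v):
    """First locus index in [lo, hi) with position >= v (binary search)."""
    while lo < hi:
        mid = (lo + hi) >> 1
        if positions[mid] < v:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def drop_gametes(parent_haps, parent_rows, chrom_starts, positions,
                 chrom_lengths, mut_rate, seed):
    """Produce one gamete per entry of ``parent_rows``.

    parent_haps : (n_par, 2, L) uint8 phased haplotypes
    parent_rows : (n_gam,) int64, row of the parent producing each gamete
    chrom_starts : (n_chrom + 1,) int64 locus-index bounds per chromosome
    positions : (L,) float64 within-chromosome positions in Morgans, sorted
    chrom_lengths : (n_chrom,) float64 Morgans
    mut_rate : per-locus per-gamete symmetric allele-flip probability

    Crossovers per chromosome are Poisson(length in Morgans) with uniform
    positions (Haldane, no interference); chromosomes segregate
    independently.
    """
    np.random.seed(seed)
    n_gam = parent_rows.shape[0]
    L = positions.shape[0]
    n_chrom = chrom_starts.shape[0] - 1
    out = np.empty((n_gam, L), dtype=np.uint8)
    xo = np.empty(MAX_XO)
    for g in range(n_gam):
        p = parent_rows[g]
        for c in range(n_chrom):
            s = chrom_starts[c]
            e = chrom_starts[c + 1]
            h = np.random.randint(0, 2)
            k = _sample_crossovers(xo, chrom_lengths[c])
            prev = s
            for x in range(k):
                brk = _breakpoint(positions, prev, e, xo[x])
                for i in range(prev, brk):
                    out[g, i] = parent_haps[p, h, i]
                prev = brk
                h = 1 - h
            for i in range(prev, e):
                out[g, i] = parent_haps[p, h, i]
        if mut_rate > 0.0:
            j = np.random.geometric(mut_rate) - 1
            while j < L:
                out[g, j] ^= np.uint8(1)
                j += np.random.geometric(mut_rate)
    return out


@njit(cache=True, inline="always")
def _copy_bits(dst, src, lo, hi):
    """Copy bit range [lo, hi) from src to dst (same bit alignment)."""
    if hi <= lo:
        return
    b0 = lo >> 3
    b1 = (hi - 1) >> 3
    off0 = lo & 7
    rem = ((hi - 1) & 7) + 1
    if b0 == b1:
        mask = np.uint8((np.uint16(1 << (hi - lo)) - 1) << off0)
        dst[b0] = (dst[b0] & ~mask) | (src[b0] & mask)
        return
    mask0 = np.uint8(0xFF << off0)
    dst[b0] = (dst[b0] & ~mask0) | (src[b0] & mask0)
    for b in range(b0 + 1, b1):
        dst[b] = src[b]
    mask1 = np.uint8((np.uint16(1) << rem) - 1)
    dst[b1] = (dst[b1] & ~mask1) | (src[b1] & mask1)


@njit(cache=True)
def _packed_gamete(out_bits, haps, p, chrom_starts, positions,
                   chrom_lengths, mut_rate, xo):
    """One recombinant gamete from parent row p, into packed out_bits."""
    L = positions.shape[0]
    n_chrom = chrom_starts.shape[0] - 1
    for c in range(n_chrom):
        s = chrom_starts[c]
        e = chrom_starts[c + 1]
        h = np.random.randint(0, 2)
        k = _sample_crossovers(xo, chrom_lengths[c])
        prev = s
        for x in range(k):
            brk = _breakpoint(positions, prev, e, xo[x])
            _copy_bits(out_bits, haps[p, h], prev, brk)
            prev = brk
            h = 1 - h
        _copy_bits(out_bits, haps[p, h], prev, e)
    if mut_rate > 0.0:
        j = np.random.geometric(mut_rate) - 1
        while j < L:
            out_bits[j >> 3] ^= np.uint8(1 << (j & 7))
            j += np.random.geometric(mut_rate)


@njit(cache=True)
def wright_fisher_packed(haps0, n_generations, chrom_starts, positions,
                         chrom_lengths, mut_rate, seed):
    """Random union of gametes for ``n_generations`` at constant size.

    haps0 : (n, 2, n_bytes) uint8 bit-packed haplotypes (LSB first).
    Each offspring draws its two parents independently and uniformly from
    the previous generation (Wright-Fisher).  Returns the final packed
    generation.
    """
    np.random.seed(seed)
    n = haps0.shape[0]
    nb = haps0.shape[2]
    cur = haps0.copy()
    nxt = np.empty_like(cur)
    xo = np.empty(MAX_XO)
    for _ in range(n_generations):
        for i in range(n):
            for side in range(2):
                p = np.random.randint(0, n)
                _packed_gamete(nxt[i, side], cur, p, chrom_starts,
                               positions, chrom_lengths, mut_rate, xo)
        tmp = cur
        cur = nxt
        nxt = tmp
    return cur


@njit(cache=True)
def gibbs_brr(Xt, Zt, y, n_iter, burn_in,
              df_a, S_a, df_d, S_d, df_e, S_e,
              fix_variances, s2a_init, s2d_init, s2e_init, seed):
    """Single-site Gibbs sampler for y = mu + X a + Z d + e.

    Gaussian priors a_j ~ N(0, s2a), d_j ~ N(0, s2d) with one shared
    variance per effect class; scaled-inverse-chi-square hyperpriors
    (df, S) on s2a, s2d and the residual s2e unless ``fix_variances``.

    Xt, Zt : (p, n) float32, transposed design matrices (rows contiguous)
    Returns (a_mean, d_mean, mu_mean, mu_chain, s2a_chain, s2d_chain,
    s2e_chain) with posterior means over post-burn-in iterations.
    """
    np.random.seed(seed)
    p, n = Xt.shape
    xtx = np.empty(p)
    ztz = np.empty(p)
    for j in range(p):
        sx = 0.0
        sz = 0.0
        for i in range(n):
            sx += Xt[j, i] * Xt[j, i]
            sz += Zt[j, i] * Zt[j, i]
        xtx[j] = sx
        ztz[j] = sz
    a = np.zeros(p)
    d = np.zeros(p)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu
    s2a = s2a_init
    s2d = s2d_init
    s2e = s2e_init
    a_mean = np.zeros(p)
    d_mean = np.zeros(p)
    mu_mean = 0.0
    mu_chain = np.empty(n_iter)
    s2a_chain = np.empty(n_iter)
    s2d_chain = np.empty(n_iter)
    s2e_chain = np.empty(n_iter)
    n_kept = 0
    for it in range(n_iter):
        # intercept
        se = 0.0
        for i in range(n):
            se += e[i]
        mu_new = mu + se / n + np.random.normal() * np.sqrt(s2e / n)
        delta = mu_new - mu
        for i in range(n):
            e[i] -= delta
        mu = mu_new
        # additive effects
        lam_a = s2e / s2a
        for j in range(p):
            rhs = 0.0
            for i in range(n):
                rhs += Xt[j, i] * e[i]
            rhs += xtx[j] * a[j]
            C = xtx[j] + lam_a
            a_new = rhs / C + np.random.normal() * np.sqrt(s2e / C)
            diff = a_new - a[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= Xt[j, i] * diff
            a[j] = a_new
        # dominance effects
        lam_d = s2e / s2d
        for j in range(p):
            rhs = 0.0
            for i in range(n):
                rhs += Zt[j, i] * e[i]
            rhs += ztz[j] * d[j]
            C = ztz[j] + lam_d
            d_new = rhs / C + np.random.normal() * np.sqrt(s2e / C)
            diff = d_new - d[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= Zt[j, i] * diff
            d[j] = d_new
        # variance components
        if not fix_variances:
            ssa = 0.0
            ssd = 0.0
            for j in range(p):
                ssa += a[j] * a[j]
                ssd += d[j] * d[j]
            s2a = (ssa + df_a * S_a) / np.random.chisquare(df_a + p)
            s2d = (ssd + df_d * S_d) / np.random.chisquare(df_d + p)
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            s2e = (sse + df_e * S_e) / np.random.chisquare(df_e + n)
        mu_chain[it] = mu
        s2a_chain[it] = s2a
        s2d_chain[it] = s2d
        s2e_chain[it] = s2e
        if it >= burn_in:
            n_kept += 1
            for j in range(p):
                a_mean[j] += a[j]
                d_mean[j] += d[j]
            mu_mean += mu
    for j in range(p):
        a_mean[j] /= n_kept
        d_mean[j] /= n_kept
    mu_mean /= n_kept
    return a_mean, d_mean, mu_mean, mu_chain, s2a_chain, s2d_chain, s2e_chain
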