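"""Two-locus LD statistics from phased haplotypes.

Everything derives from the four phased haplotype counts (n11, n10, n01, n00)
of a SNP pair, counted over haplotypes that are non-missing at both loci:

    p_ij = n11 / n                    frequency of the 1-1 haplotype
    D    = p_ij - p_i * p_j
    r^2  = D^2 / (p_i (1-p_i) p_j (1-p_j))
    D'   = |D| / D_max
    signed r = sqrt(r^2) carrying the sign of D

plus a likelihood-based confidence interval on D' (the ingredient of the
Gabriel block classification) and a two-locus EM for unphased input.

Pairs where either marker is monomorphic are undefined (the r^2 denominator
vanishes) and raise :class:`MonomorphicPairError`; callers skip them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import MISSING, HaplotypePanel, PanelError


class MonomorphicPairError(ValueError):
    """LD is undefined when either marker is monomorphic in the counted haplotypes."""


@dataclass
class LDPair:
    """LD statistics for one SNP pair (marker indices ``i < j``)."""

    i: int
    j: int
    distance: int
    p_i: float
    p_j: float
    p_ij: float
    D: float
    r2: float
    dprime: float
    signed_r: float
    n_haplotypes: int
    ci_low: float | None = None
    ci_high: float | None = None


# ------------------------------------------------------------------- counting
def haplotype_counts(panel: HaplotypePanel, i: int, j: int):
    """Four phased haplotype counts ``(n11, n10, n01, n00)`` for markers i < j.

    Haplotypes missing at either locus are excluded from all four cells.
    """
    if not panel.phased:
        raise PanelError(
            "panel is unphased: use em_haplotype_freqs on the genotype table instead"
        )
    if not i < j:
        raise ValueError("require i < j")
    a = panel.haplotypes[:, i]
    b = panel.haplotypes[:, j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    return n11, n10, n01, n00


# ------------------------------------------------------------------ statistics
def pair_ld(counts, i: int = 0, j: int = 1, distance: int = 0) -> LDPair:
    """LD statistics from four haplotype counts ``(n11, n10, n01, n00)``.

    D is evaluated in the determinant form (n11 n00 - n10 n01) / n^2, which is
    algebraically identical to p_ij - p_i p_j but exactly antisymmetric under
    re-orienting either marker — integer products and IEEE negation are exact
    — so signed r flips sign bitwise and r^2 / D' are bitwise invariant.
    """
    n11, n10, n01, n00 = (int(c) for c in counts)
    n = n11 + n10 + n01 + n00
    if n == 0:
        raise MonomorphicPairError("no complete haplotypes for this pair")
    c1, c0 = n11 + n10, n01 + n00  # allele counts at marker i
    r1, r0 = n11 + n01, n10 + n00  # allele counts at marker j
    if 0 in (c1, c0, r1, r0):
        raise MonomorphicPairError("monomorphic marker: LD undefined")
    p_i = c1 / n
    p_j = r1 / n
    p_ij = n11 / n
    num = n11 * n00 - n10 * n01
    D = num / (n * n)
    r2 = (num * num) / ((c1 * c0) * (r1 * r0))
    if num > 0:
        dprime = num / min(c1 * r0, c0 * r1)
    elif num < 0:
        dprime = -num / min(c1 * r1, c0 * r0)
    else:
        dprime = 0.0
    signed_r = float(np.sign(D)) * np.sqrt(r2)
    return LDPair(
        i=i,
        j=j,
        distance=distance,
        p_i=p_i,
        p_j=p_j,
        p_ij=p_ij,
        D=D,
        r2=float(r2),
        dprime=float(dprime),
        signed_r=float(signed_r),
        n_haplotypes=int(n),
    )


# ----------------------------------------------------------------- D' interval
def dprime_ci(counts, grid_points: int = 101, mass: float = 0.90):
    """Likelihood-based confidence bounds on D' from four haplotype counts.

    The multinomial likelihood of the observed counts is evaluated on a
    uniform D' grid over [0, 1] with the marginal frequencies fixed at their
    observed values and the sign of D fixed at its observed sign, normalised
    to a discrete posterior under a flat prior; the bounds are the central
    *mass* quantiles of that posterior.
    """
    lows, highs = dprime_ci_many(
        *(np.asarray([c], dtype=float) for c in counts),
        grid_points=grid_points,
        mass=mass,
    )
    return float(lows[0]), float(highs[0])


def dprime_ci_many(n11, n10, n01, n00, grid_points: int = 101, mass: float = 0.90):
    """Vectorised :func:`dprime_ci` over arrays of haplotype counts."""
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    n = n11 + n10 + n01 + n00
    p_i = (n11 + n10) / n
    p_j = (n11 + n01) / n
    if np.any((p_i <= 0) | (p_i >= 1) | (p_j <= 0) | (p_j >= 1)):
        raise MonomorphicPairError("monomorphic marker: D' undefined")
    D = n11 / n - p_i * p_j
    sign = np.where(D >= 0, 1.0, -1.0)
    d_max = np.where(
        D >= 0,
        np.minimum(p_i * (1 - p_j), (1 - p_i) * p_j),
        np.minimum(p_i * p_j, (1 - p_i) * (1 - p_j)),
    )
    grid = np.linspace(0.0, 1.0, grid_points)  # (G,)
    Dg = sign[:, None] * grid[None, :] * d_max[:, None]  # (P, G)
    f11 = p_i[:, None] * p_j[:, None] + Dg
    f10 = p_i[:, None] * (1 - p_j[:, None]) - Dg
    f01 = (1 - p_i[:, None]) * p_j[:, None] - Dg
    f00 = (1 - p_i[:, None]) * (1 - p_j[:, None]) + Dg
    ll = np.zeros_like(f11)
    for cnt, freq in ((n11, f11), (n10, f10), (n01, f01), (n00, f00)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = cnt[:, None] * np.log(np.clip(freq, 0.0, None))
        term[np.asarray(cnt[:, None] == 0) & ~np.isfinite(term)] = 0.0
        ll += term
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll)
    post /= post.sum(axis=1, keepdims=True)
    cum = np.cumsum(post, axis=1)
    alpha = (1.0 - mass) / 2.0
    lo_idx = (cum >= alpha - 1e-12).argmax(axis=1)
    hi_idx = (cum >= 1.0 - alpha - 1e-12).argmax(axis=1)
    return grid[lo_idx], grid[hi_idx]


# ------------------------------------------------------------------------- EM
def em_haplotype_freqs(genotype_table, tol: float = 1e-10, max_iter: int = 1000,
                       starts=(0.5, 0.02, 0.98)):
    """Two-locus haplotype frequencies from a 3x3 genotype table by EM.

    *genotype_table*[a, b] counts samples with alt-allele dosage ``a`` at the
    first locus and ``b`` at the second.  Only the double heterozygote (1, 1)
    is phase-ambiguous; the EM splits it between the coupling (11/00) and
    repulsion (10/01) resolutions.  *starts* lists initial coupling fractions
    for the ambiguous class; the likelihood surface can hold several
    stationary points (the symmetric start alone can stall on a saddle), so
    the run with the best final log-likelihood wins.  Returns
    ``(freqs, loglik)`` with *freqs* ``[p11, p10, p01, p00]``; the
    log-likelihood is monotone non-decreasing within each run.
    """
    t = np.asarray(genotype_table, dtype=float)
    if t.shape != (3, 3) or np.any(t < 0):
        raise ValueError("genotype_table must be a non-negative 3x3 count table")
    n = t.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    dh = t[1, 1]
    # haplotypes fully determined by unambiguous genotype classes
    fixed11 = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    fixed10 = 2 * t[2, 0] + t[2, 1] + t[1, 0]
    fixed01 = 2 * t[0, 2] + t[0, 1] + t[1, 2]
    fixed00 = 2 * t[0, 0] + t[0, 1] + t[1, 0]
    total = 2.0 * n

    def run(q0):
        f = np.array(
            [fixed11 + dh * q0, fixed10 + dh * (1 - q0),
             fixed01 + dh * (1 - q0), fixed00 + dh * q0]
        ) / total
        for _ in range(max_iter):
            denom = f[0] * f[3] + f[1] * f[2]
            q = 0.5 if denom == 0 else f[0] * f[3] / denom
            new = np.array(
                [fixed11 + dh * q, fixed10 + dh * (1 - q),
                 fixed01 + dh * (1 - q), fixed00 + dh * q]
            ) / total
            if np.max(np.abs(new - f)) < tol:
                return new
            f = new
        return f

    best_f, best_ll = None, -np.inf
    for q0 in starts:
        f = run(q0)
        ll = genotype_loglik(t, f)
        if ll > best_ll:
            best_f, best_ll = f, ll
    return best_f, best_ll


def genotype_loglik(genotype_table, freqs) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under random union
    of gametes with haplotype frequencies ``[p11, p10, p01, p00]``."""
    t = np.asarray(genotype_table, dtype=float)
    p11, p10, p01, p00 = freqs
    probs = np.array(
        [
            [p00 * p00, 2 * p01 * p00, p01 * p01],
            [2 * p10 * p00, 2 * (p11 * p00 + p10 * p01), 2 * p11 * p01],
            [p10 * p10, 2 * p11 * p10, p11 * p11],
        ]
    )
    ll = 0.0
    for a in range(3):
        for b in range(3):
            if t[a, b] > 0:
                if probs[a, b] <= 0:
                    return -np.inf
                ll += t[a, b] * np.log(probs[a, b])
    return float(ll)


# ------------------------------------------------------ vectorised panel pairs
def pair_stats_table(panel: HaplotypePanel, pairs):
    """LD statistics for many pairs of one phased panel, vectorised.

    *pairs* is ``(i_idx, j_idx)`` integer arrays.  Returns a dict of arrays
    (n11, n10, n01, n00, n, p_i, p_j, p_ij, D, r2, dprime, signed_r, distance)
    plus a boolean ``defined`` mask (False where a marker is monomorphic
    within the complete haplotypes of the pair).
    """
    if not panel.phased:
        raise PanelError("panel is unphased: pairwise phased LD is unavailable")
    i_idx, j_idx = (np.asarray(p, dtype=np.intp) for p in pairs)
    H = panel.haplotypes
    A = (H == 1).astype(np.float32)
    V = (H != MISSING).astype(np.float32)
    n11_m = A.T @ A
    nv_m = V.T @ V
    a_i_m = A.T @ V  # alt at row marker among rows valid at both
    n11 = n11_m[i_idx, j_idx].astype(np.float64)
    n = nv_m[i_idx, j_idx].astype(np.float64)
    n1i = a_i_m[i_idx, j_idx].astype(np.float64)
    n1j = a_i_m[j_idx, i_idx].astype(np.float64)
    n10 = n1i - n11
    n01 = n1j - n11
    n00 = n - n1i - n01

    # determinant form: exactly antisymmetric under marker re-orientation
    # (see pair_ld); count products are integers represented exactly
    c1, c0 = n1i, n - n1i
    r1, r0 = n1j, n - n1j
    num = n11 * n00 - n10 * n01
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = c1 / n
        p_j = r1 / n
        p_ij = n11 / n
        D = num / (n * n)
        r2 = (num * num) / ((c1 * c0) * (r1 * r0))
        d_denom = np.where(
            num >= 0, np.minimum(c1 * r0, c0 * r1), np.minimum(c1 * r1, c0 * r0)
        )
        dprime = np.where(num == 0, 0.0, np.abs(num) / d_denom)
        signed_r = np.sign(D) * np.sqrt(r2)
    defined = (n > 0) & (c1 > 0) & (c0 > 0) & (r1 > 0) & (r0 > 0)
    positions = panel.positions
    distance = positions[j_idx] - positions[i_idx]
    return {
        "i": i_idx,
        "j": j_idx,
        "distance": distance,
        "n11": n11,
        "n10": n10,
        "n01": n01,
        "n00": n00,
        "n": n,
        "p_i": p_i,
        "p_j": p_j,
        "p_ij": p_ij,
        "D": D,
        "r2": r2,
        "dprime": dprime,
        "signed_r": signed_r,
        "defined": defined,
    }


def attach_dprime_ci(stats: dict, grid_points: int = 101, mass: float = 0.90,
                     chunk: int = 50_000) -> dict:
    """Add ``ci_low``/``ci_high`` arrays to a :func:`pair_stats_table` dict
    (NaN where the pair is undefined), chunked to bound memory."""
    m = len(stats["distance"])
    lo = np.full(m, np.nan)
    hi = np.full(m, np.nan)
    idx = np.flatnonzero(stats["defined"])
    for start in range(0, len(idx), chunk):
        sel = idx[start : start + chunk]
        lo[sel], hi[sel] = dprime_ci_many(
            stats["n11"][sel],
            stats["n10"][sel],
            stats["n01"][sel],
            stats["n00"][sel],
            grid_points=grid_points,
            mass=mass,
        )
    stats["ci_low"] = lo
    stats["ci_high"] = hi
    return stats
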