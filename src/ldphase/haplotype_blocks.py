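"""Gabriel confidence-interval haplotype blocks.

A pair is *strong LD* when its 90% D' confidence interval has lower bound
>= 0.70 and upper bound >= 0.98; *strong evidence of recombination* when the
upper bound is < 0.90; otherwise uninformative.  A marker interval [a, b] is
a candidate block when its endpoint pair is strong LD and at least 95% of
the informative pairs inside it are strong LD.  Overlaps are resolved
greedily by span; blocks of fewer than three SNPs are discarded to avoid
spurious two-SNP blocks.  Pairs farther apart than 500 kb never enter the
computation, which also bounds the block span.

This is the clean published definition: marker-count-dependent threshold
tweaks found in some tools are deliberately not reproduced (see the methods
note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay_profile import pairs_within
from .ld_core import attach_dprime_ci, pair_stats_table
from .panel import HaplotypePanel

STRONG_LD = "strong_ld"
STRONG_RECOMB = "strong_recombination"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class GabrielParams:
    """Block-definition thresholds (exposed for sensitivity analysis)."""

    strong_ld_low: float = 0.70
    strong_ld_high: float = 0.98
    recomb_high: float = 0.90
    min_strong_fraction: float = 0.95
    max_pair_distance: int = 500_000
    min_block_snps: int = 3
    ci_mass: float = 0.90
    ci_grid_points: int = 101

    def __post_init__(self):
        if not 0 < self.recomb_high < self.strong_ld_high <= 1:
            raise ValueError("require 0 < recomb_high < strong_ld_high <= 1")
        if not 0 < self.min_strong_fraction <= 1:
            raise ValueError("min_strong_fraction must be in (0, 1]")
        if self.min_block_snps < 2:
            raise ValueError("min_block_snps must be >= 2")


@dataclass
class HaplotypeBlock:
    chromosome: str
    start_index: int
    end_index: int
    start_pos: int
    end_pos: int

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def length(self) -> int:
        return self.end_pos - self.start_pos


@dataclass
class BlockSummary:
    """Per-chromosome block roll-up (counts, coverage, SNP capture, lengths)."""

    chromosome: str
    n_snps: int
    chrom_length: int          # span of the marker map, bp
    mean_marker_distance: float
    n_blocks: int
    total_block_length: int
    pct_chromosome_covered: float
    n_snps_in_blocks: int
    pct_snps_in_blocks: float
    max_block_length: int
    mean_block_length: float


# -------------------------------------------------------------- classification
def classify_pair(ci_low: float, ci_high: float, params: GabrielParams | None = None) -> str:
    params = params or GabrielParams()
    if ci_low >= params.strong_ld_low and ci_high >= params.strong_ld_high:
        return STRONG_LD
    if ci_high < params.recomb_high:
        return STRONG_RECOMB
    return UNINFORMATIVE


def classify_many(ci_low, ci_high, params: GabrielParams | None = None) -> np.ndarray:
    """Vectorised classification: +1 strong LD, -1 strong recombination, 0 else."""
    params = params or GabrielParams()
    ci_low = np.asarray(ci_low, dtype=float)
    ci_high = np.asarray(ci_high, dtype=float)
    out = np.zeros(ci_low.shape, dtype=np.int8)
    out[(ci_low >= params.strong_ld_low) & (ci_high >= params.strong_ld_high)] = 1
    out[ci_high < params.recomb_high] = -1
    # NaN CI (undefined pair) stays uninformative
    out[~np.isfinite(ci_low) | ~np.isfinite(ci_high)] = 0
    return out


# ------------------------------------------------------------------ candidates
def candidate_blocks(i_idx, j_idx, classes, n_markers: int,
                     params: GabrielParams | None = None) -> list[tuple[int, int]]:
    """All marker intervals [a, b] satisfying the Gabriel predicate.

    *classes* codes each classified pair +1 (strong LD) / -1 (strong
    recombination) / 0 (uninformative); unclassified pairs (monomorphic or
    beyond the distance cap) are simply absent.  The endpoint pair must be
    strong LD and strong/(strong + recomb) over all pairs inside the interval
    must reach ``min_strong_fraction``; uninformative pairs do not enter the
    denominator.  Returns intervals sorted by (a, b), including nested ones.
    """
    params = params or GabrielParams()
    i_idx = np.asarray(i_idx, dtype=np.intp)
    j_idx = np.asarray(j_idx, dtype=np.intp)
    classes = np.asarray(classes, dtype=np.int8)
    M = n_markers
    strong = np.zeros((M, M), dtype=np.int32)
    recomb = np.zeros((M, M), dtype=np.int32)
    strong[i_idx[classes == 1], j_idx[classes == 1]] = 1
    recomb[i_idx[classes == -1], j_idx[classes == -1]] = 1

    # prefix sums over the upper triangle: pairs inside [a, b] are the
    # rectangle rows<=b, cols<=b minus rows<a, cols... via 2-D inclusion-exclusion
    cs = strong.cumsum(axis=0).cumsum(axis=1)
    cr = recomb.cumsum(axis=0).cumsum(axis=1)

    def rect(c, a, b):
        # sum over i in [a, b], j in [a, b] (upper-triangular matrices only)
        total = c[b, b]
        if a > 0:
            total = total - c[a - 1, b] - c[b, a - 1] + c[a - 1, a - 1]
        return total

    ends_a = i_idx[classes == 1]
    ends_b = j_idx[classes == 1]
    out = []
    for a, b in zip(ends_a.tolist(), ends_b.tolist()):
        s = rect(cs, a, b)
        r = rect(cr, a, b)
        if s + r > 0 and s / (s + r) >= params.min_strong_fraction:
            out.append((a, b))
    out.sort()
    return out


# ------------------------------------------------------------------- selection
def select_blocks(candidates, positions, chromosome: str = "1",
                  params: GabrielParams | None = None) -> list[HaplotypeBlock]:
    """Greedy overlap resolution: longest span first (ties: more SNPs, then
    leftmost), accept if marker-disjoint from everything accepted, then drop
    blocks of fewer than ``min_block_snps`` SNPs; output in position order."""
    params = params or GabrielParams()
    positions = np.asarray(positions, dtype=np.int64)
    order = sorted(
        candidates,
        key=lambda ab: (-(positions[ab[1]] - positions[ab[0]]), -(ab[1] - ab[0]), ab[0]),
    )
    used = np.zeros(len(positions), dtype=bool)
    accepted = []
    for a, b in order:
        if used[a : b + 1].any():
            continue
        used[a : b + 1] = True
        accepted.append((a, b))
    blocks = [
        HaplotypeBlock(
            chromosome=chromosome,
            start_index=a,
            end_index=b,
            start_pos=int(positions[a]),
            end_pos=int(positions[b]),
        )
        for a, b in accepted
        if b - a + 1 >= params.min_block_snps
    ]
    blocks.sort(key=lambda blk: blk.start_index)
    return blocks


# --------------------------------------------------------------- orchestration
def find_blocks(panel: HaplotypePanel, params: GabrielParams | None = None) -> list[HaplotypeBlock]:
    """Full block scan of one phased panel: pairwise D' CIs within the
    distance cap, Gabriel classification, candidate enumeration, greedy
    selection."""
    params = params or GabrielParams()
    i_idx, j_idx = pairs_within(panel.positions, params.max_pair_distance)
    if len(i_idx) == 0:
        return []
    stats = pair_stats_table(panel, (i_idx, j_idx))
    attach_dprime_ci(stats, grid_points=params.ci_grid_points, mass=params.ci_mass)
    classes = classify_many(stats["ci_low"], stats["ci_high"], params)
    candidates = candidate_blocks(i_idx, j_idx, classes, panel.n_markers, params)
    return select_blocks(candidates, panel.positions, panel.chromosome, params)


def summarize_blocks(blocks, panel: HaplotypePanel) -> BlockSummary:
    """Per-chromosome roll-up of a block list against its marker panel."""
    pos = panel.positions
    span = int(pos[-1] - pos[0]) if len(pos) > 1 else 0
    lengths = np.asarray([b.length for b in blocks], dtype=np.int64)
    snps_in = int(sum(b.n_snps for b in blocks))
    return BlockSummary(
        chromosome=panel.chromosome,
        n_snps=panel.n_markers,
        chrom_length=span,
        mean_marker_distance=span / (len(pos) - 1) if len(pos) > 1 else np.nan,
        n_blocks=len(blocks),
        total_block_length=int(lengths.sum()),
        pct_chromosome_covered=100.0 * lengths.sum() / span if span else 0.0,
        n_snps_in_blocks=snps_in,
        pct_snps_in_blocks=100.0 * snps_in / panel.n_markers if panel.n_markers else 0.0,
        max_block_length=int(lengths.max()) if len(lengths) else 0,
        mean_block_length=float(lengths.mean()) if len(lengths) else 0.0,
    )


def summary_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "chromosome": s.chromosome,
                "n_snps": s.n_snps,
                "chrom_length_bp": s.chrom_length,
                "mean_marker_distance_bp": s.mean_marker_distance,
                "n_blocks": s.n_blocks,
                "total_block_length_bp": s.total_block_length,
                "pct_chromosome_covered": s.pct_chromosome_covered,
                "n_snps_in_blocks": s.n_snps_in_blocks,
                "pct_snps_in_blocks": s.pct_snps_in_blocks,
                "max_block_length_bp": s.max_block_length,
                "mean_block_length_bp": s.mean_block_length,
            }
        )
    return pd.DataFrame(rows)
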