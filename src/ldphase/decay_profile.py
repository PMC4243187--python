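"""Distance-binned LD-decay profiles.

SNP pairs within 500 kb are binned by physical distance on the fixed scheme
{0, 2.5, 5, 7.5, 10, 20, ..., 100, 200, 300, 400, 500} kb — half-open
[low, high) bins with the final bin closed at the cap — and r^2 is
summarised per bin (pair count, mean, sample SD, exact median).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

DEFAULT_EDGES_KB = (
    0.0, 2.5, 5.0, 7.5, 10.0, 20.0, 30.0, 40.0, 50.0,
    60.0, 70.0, 80.0, 90.0, 100.0, 200.0, 300.0, 400.0, 500.0,
)


@dataclass(frozen=True)
class DistanceBinScheme:
    """Half-open distance bins in kb; the final bin is closed at the cap."""

    edges_kb: tuple = DEFAULT_EDGES_KB

    def __post_init__(self):
        e = np.asarray(self.edges_kb, dtype=float)
        if len(e) < 2 or e[0] != 0 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must start at 0 and be strictly increasing")

    @property
    def edges_bp(self) -> np.ndarray:
        return (np.asarray(self.edges_kb, dtype=float) * 1000).round().astype(np.int64)

    @property
    def cap_bp(self) -> int:
        return int(self.edges_bp[-1])

    @property
    def n_bins(self) -> int:
        return len(self.edges_kb) - 1

    def labels(self) -> list[str]:
        fmt = lambda x: f"{x:g}"
        out = [f"< {fmt(self.edges_kb[1])}"]
        for lo, hi in zip(self.edges_kb[1:-1], self.edges_kb[2:]):
            out.append(f"{fmt(lo)} - {fmt(hi)}")
        return out

    def assign(self, distances) -> np.ndarray:
        """Vectorised bin index; errors if any distance is <= 0 or > cap."""
        d = np.asarray(distances, dtype=np.int64)
        if np.any(d <= 0) or np.any(d > self.cap_bp):
            raise ValueError("distance out of range (0, cap]")
        idx = np.searchsorted(self.edges_bp, d, side="right") - 1
        # the cap itself belongs to the last (closed) bin
        idx[d == self.cap_bp] = self.n_bins - 1
        return idx


def assign_bin(distance: int, scheme: DistanceBinScheme) -> int:
    """Bin index of one distance (boundary values fall in the upper bin)."""
    return int(scheme.assign(np.asarray([distance]))[0])


@dataclass
class DecayProfile:
    """Per-bin r^2 summaries for one scope (group x chromosome or genome-wide)."""

    scheme: DistanceBinScheme
    group: str
    chromosome: str  # "ALL" for genome-wide
    table: pd.DataFrame = field(repr=False, default=None)


# ----------------------------------------------------------------------- pairs
def enumerate_pairs(panel: HaplotypePanel, max_distance: int = 500_000):
    """Yield (i, j) index pairs with 0 < position_j - position_i <= cap.

    A sliding-window scan over the sorted positions, in (i, then j) order.
    """
    pos = panel.positions
    limits = np.searchsorted(pos, pos + max_distance, side="right")
    for i in range(len(pos)):
        for j in range(i + 1, limits[i]):
            yield i, j


def pairs_within(positions: np.ndarray, max_distance: int = 500_000):
    """Vectorised pair enumeration: returns (i_idx, j_idx) arrays."""
    pos = np.asarray(positions, dtype=np.int64)
    limits = np.searchsorted(pos, pos + max_distance, side="right")
    counts = limits - np.arange(len(pos)) - 1
    counts = np.maximum(counts, 0)
    i_idx = np.repeat(np.arange(len(pos)), counts)
    offs = np.concatenate([np.arange(1, c + 1) for c in counts]) if counts.sum() else np.empty(0, dtype=np.int64)
    j_idx = i_idx + offs.astype(np.int64)
    return i_idx, j_idx


# --------------------------------------------------------------------- profile
def build_profile(distances, r2, scheme: DistanceBinScheme | None = None,
                  group: str = "ALL", chromosome: str = "ALL") -> DecayProfile:
    """Bin pairs by distance and summarise r^2 per bin.

    Mean/median are exact; SD uses the n-1 denominator and is NaN for bins
    with fewer than two pairs; empty bins report n = 0 with NaN summaries.
    Summaries are permutation-invariant in the input order.
    """
    scheme = scheme or DistanceBinScheme()
    distances = np.asarray(distances, dtype=np.int64)
    r2 = np.asarray(r2, dtype=float)
    if distances.shape != r2.shape:
        raise ValueError("distances and r2 must align")
    bins = scheme.assign(distances) if len(distances) else np.empty(0, dtype=int)
    rows = []
    for b, label in enumerate(scheme.labels()):
        vals = r2[bins == b]
        rows.append(
            {
                "bin": label,
                "n_pairs": int(vals.size),
                "mean_r2": float(np.mean(vals)) if vals.size else np.nan,
                "sd_r2": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                "median_r2": float(np.median(vals)) if vals.size else np.nan,
            }
        )
    return DecayProfile(
        scheme=scheme, group=group, chromosome=chromosome, table=pd.DataFrame(rows)
    )
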