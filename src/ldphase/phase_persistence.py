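"""Persistence of LD phase between two genetic groups.

For every SNP pair shared by both groups (inner join on chromosome and the
two positions, under an identical allele orientation), the per-distance-bin
correlation of *signed r* — sqrt(r^2) carrying the sign of D — measures how
well marker phase transfers between the groups (the PL statistic).

PL is computed as the correlation through the origin,

    PL = sum(a b) / sqrt(sum(a^2) sum(b^2)),

because signed r has no natural location under an arbitrary (but shared)
allele orientation: jointly re-orienting any marker in both groups flips the
sign of its pairs in both vectors and must leave PL unchanged, which holds
exactly for the uncentered form and only approximately for the mean-centered
Pearson coefficient.  Signed r is mean-zero to good approximation in large
bins, where the two forms coincide; the centered Pearson value is reported
alongside as ``pl_centered``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay_profile import DistanceBinScheme


class OrientationMismatchError(ValueError):
    """The two groups' allele orientations differ; signed r is not comparable."""


@dataclass
class PairTable:
    """Pairwise LD results of one group: frame keyed by (chromosome, pos_i, pos_j)
    with at least columns distance, r2, signed_r; plus the orientation map
    (chromosome, position) -> (ref, alt) that fixed the sign of D."""

    frame: pd.DataFrame
    orientation: dict
    group: str = ""


@dataclass
class PhasePersistenceProfile:
    """Per-bin shared-pair counts and PL, with overall summaries."""

    group_a: str
    group_b: str
    table: pd.DataFrame = field(repr=False, default=None)
    overall_mean_pl: float = np.nan      # unweighted mean over defined bins
    overall_pairweighted_pl: float = np.nan  # single PL over all shared pairs


def shared_pairs(ld_a: PairTable, ld_b: PairTable) -> pd.DataFrame:
    """Inner-join the two groups' pair tables on (chromosome, pos_i, pos_j).

    Raises :class:`OrientationMismatchError` if any marker common to both
    orientation maps carries different ref/alt alleles.  Pairs present in
    only one group are dropped (their count is in the ``attrs`` of the
    result).
    """
    common = set(ld_a.orientation) & set(ld_b.orientation)
    for key in common:
        if ld_a.orientation[key] != ld_b.orientation[key]:
            raise OrientationMismatchError(
                f"marker {key}: orientation {ld_a.orientation[key]} vs "
                f"{ld_b.orientation[key]}; signed r would be meaningless"
            )
    keys = ["chromosome", "pos_i", "pos_j"]
    merged = ld_a.frame.merge(
        ld_b.frame, on=keys + ["distance"], suffixes=("_a", "_b"), how="inner"
    )
    merged.attrs["n_only_a"] = len(ld_a.frame) - len(merged)
    merged.attrs["n_only_b"] = len(ld_b.frame) - len(merged)
    return merged


def correlation_through_origin(a: np.ndarray, b: np.ndarray) -> float:
    """sum(ab) / sqrt(sum(a^2) sum(b^2)); exactly 1.0 for identical inputs."""
    num = float(np.dot(a, b))
    denom = float(np.sqrt(np.dot(a, a) * np.dot(b, b)))
    if denom == 0:
        return np.nan
    return num / denom


def persistence_profile(matched: pd.DataFrame, scheme: DistanceBinScheme | None = None,
                        group_a: str = "A", group_b: str = "B") -> PhasePersistenceProfile:
    """Per-distance-bin PL from a :func:`shared_pairs` frame.

    Bins with fewer than 3 shared pairs, or zero variation in either margin,
    report PL as NaN (undefined).  The overall mean is the unweighted mean of
    the defined per-bin values.
    """
    scheme = scheme or DistanceBinScheme()
    d = matched["distance"].to_numpy()
    sa = matched["signed_r_a"].to_numpy(dtype=float)
    sb = matched["signed_r_b"].to_numpy(dtype=float)
    bins = scheme.assign(d) if len(d) else np.empty(0, dtype=int)
    rows = []
    for b, label in enumerate(scheme.labels()):
        mask = bins == b
        xa, xb = sa[mask], sb[mask]
        pl = np.nan
        pl_centered = np.nan
        if xa.size >= 3 and np.dot(xa, xa) > 0 and np.dot(xb, xb) > 0:
            pl = correlation_through_origin(xa, xb)
            if np.ptp(xa) > 0 and np.ptp(xb) > 0:
                dxa, dxb = xa - xa.mean(), xb - xb.mean()
                pl_centered = correlation_through_origin(dxa, dxb)
        rows.append(
            {"bin": label, "n_shared_pairs": int(xa.size), "pl": pl, "pl_centered": pl_centered}
        )
    table = pd.DataFrame(rows)
    defined = table["pl"].dropna()
    overall = float(defined.mean()) if len(defined) else np.nan
    pooled = (
        correlation_through_origin(sa, sb)
        if len(sa) >= 3 and np.dot(sa, sa) > 0 and np.dot(sb, sb) > 0
        else np.nan
    )
    return PhasePersistenceProfile(
        group_a=group_a,
        group_b=group_b,
        table=table,
        overall_mean_pl=overall,
        overall_pairweighted_pl=pooled,
    )
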