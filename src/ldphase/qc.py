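"""Sample and SNP quality control.

Filters mirror standard livestock-panel practice: samples with a call rate
below 0.90 are removed first, then SNPs are filtered in the fixed order
call rate (< 0.90) -> Hardy-Weinberg exact-test p-value (< 1e-4) -> minor
allele frequency (< 0.05), each marker attributed to the first filter it
fails so the removal counts in the report are additive.

The Hardy-Weinberg test is the two-sided exact conditional test (the PLINK
default): given the allele counts, the p-value sums the probabilities of all
heterozygote counts whose conditional probability does not exceed that of
the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Filter thresholds; defaults are the conventional chip-QC values."""

    min_sample_call_rate: float = 0.90
    min_snp_call_rate: float = 0.90
    hwe_alpha: float = 1e-4
    min_maf: float = 0.05

    def __post_init__(self):
        for name in ("min_sample_call_rate", "min_snp_call_rate", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError(f"min_maf must be in [0, 0.5], got {self.min_maf}")


@dataclass
class QCReport:
    """What went in, what came out, and which filter removed each marker."""

    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    n_samples_removed_call_rate: int
    n_snps_removed_call_rate: int
    n_snps_removed_hwe: int
    n_snps_removed_maf: int
    per_marker: pd.DataFrame = field(repr=False, default=None)

    def filter_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [
                    "sample_call_rate",
                    "snp_call_rate",
                    "hwe",
                    "maf",
                ],
                "removed": [
                    self.n_samples_removed_call_rate,
                    self.n_snps_removed_call_rate,
                    self.n_snps_removed_hwe,
                    self.n_snps_removed_maf,
                ],
                "unit": ["samples", "snps", "snps", "snps"],
            }
        )


# ------------------------------------------------------------------ statistics
def sample_call_rate(panel: HaplotypePanel) -> np.ndarray:
    """Per-sample fraction of markers with both haplotype entries non-missing."""
    if panel.n_markers == 0:
        raise ValueError("panel has no markers")
    g = panel.genotypes()
    return (g != MISSING).mean(axis=1)


def snp_call_rate(panel: HaplotypePanel) -> np.ndarray:
    """Per-marker fraction of samples with a complete (both-haplotype) genotype."""
    g = panel.genotypes()
    return (g != MISSING).mean(axis=0)


def maf(panel: HaplotypePanel, marker_index=None):
    """Minor allele frequency min(p, 1-p) over non-missing haplotypes.

    Returns the per-marker array, or a scalar for *marker_index*; NaN where
    every haplotype is missing.
    """
    hap = panel.haplotypes
    obs = hap != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(obs, hap, 0).sum(axis=0) / obs.sum(axis=0)
    folded = np.minimum(p, 1.0 - p)
    if marker_index is not None:
        return float(folded[marker_index])
    return folded


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test p-value.

    Conditions on the allele counts and sums P(k heterozygotes) over every
    feasible heterozygote count k whose probability is <= that of the observed
    count (no mid-p).  Monomorphic tables give 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # feasible heterozygote counts share the parity of the rare-allele count
    ks = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - ks) // 2
    homs_common = (max(n_a, n_b) - ks) // 2
    logp = (
        -gammaln(homs_rare + 1)
        - gammaln(ks + 1)
        - gammaln(homs_common + 1)
        + ks * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(ks, n_het)]
    p = probs[probs <= p_obs * (1 + 1e-9)].sum()
    return float(min(p, 1.0))


def hwe_pvalues(panel: HaplotypePanel) -> np.ndarray:
    """Per-marker exact HWE p-values from collapsed genotypes."""
    g = panel.genotypes()
    out = np.ones(panel.n_markers)
    for j in range(panel.n_markers):
        col = g[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_exact_pvalue(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


# ---------------------------------------------------------------------- filter
def apply_qc(panel: HaplotypePanel, thresholds: QCThresholds | None = None):
    """Filter samples then SNPs; return ``(filtered_panel, QCReport)``.

    Sample call rate is applied first; SNP statistics are recomputed on the
    surviving samples and applied in the order call rate -> HWE -> MAF, each
    marker attributed to the first filter it fails.  Idempotent.
    """
    thresholds = thresholds or QCThresholds()
    n_samples_in, n_snps_in = panel.n_samples, panel.n_markers

    scr = sample_call_rate(panel)
    keep_samples = scr >= thresholds.min_sample_call_rate
    panel_s = panel.subset_samples(keep_samples)
    n_samples_removed = int((~keep_samples).sum())

    cr = snp_call_rate(panel_s)
    pvals = hwe_pvalues(panel_s)
    folded = maf(panel_s)

    fail_cr = cr < thresholds.min_snp_call_rate
    with np.errstate(invalid="ignore"):
        fail_hwe = ~fail_cr & (np.nan_to_num(pvals, nan=1.0) < thresholds.hwe_alpha)
        fail_maf = ~fail_cr & ~fail_hwe & (np.nan_to_num(folded, nan=0.0) < thresholds.min_maf)
    keep = ~(fail_cr | fail_hwe | fail_maf)

    per_marker = pd.DataFrame(
        {
            "marker_id": [m.id for m in panel_s.markers],
            "chromosome": [m.chromosome for m in panel_s.markers],
            "position": panel_s.positions,
            "call_rate": cr,
            "maf": folded,
            "hwe_p": pvals,
            "kept": keep,
        }
    )

    out_panel = panel_s.subset_markers(keep)
    report = QCReport(
        n_samples_in=n_samples_in,
        n_samples_out=out_panel.n_samples,
        n_snps_in=n_snps_in,
        n_snps_out=out_panel.n_markers,
        n_samples_removed_call_rate=n_samples_removed,
        n_snps_removed_call_rate=int(fail_cr.sum()),
        n_snps_removed_hwe=int(fail_hwe.sum()),
        n_snps_removed_maf=int(fail_maf.sum()),
        per_marker=per_marker,
    )
    if out_panel.n_markers == 0 or out_panel.n_samples == 0:
        logger.warning("QC removed every %s", "marker" if out_panel.n_markers == 0 else "sample")
    return out_panel, report
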