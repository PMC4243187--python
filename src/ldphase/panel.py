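"""Phased haplotype panels and marker metadata.

A :class:`HaplotypePanel` holds the phased alleles of ``2N`` haplotypes at
``M`` biallelic SNPs on a single chromosome, together with the marker map and
a per-sample group label.  It is the substrate of every LD computation in
this package: haplotype rows ``2k`` and ``2k + 1`` belong to diploid sample
``k``, entries are coded ``0`` (reference allele), ``1`` (alternate allele)
or ``-1`` (missing).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

#: chromosome labels discarded at load (sex chromosomes / mitochondrion)
SEX_CHROMOSOMES = frozenset({"X", "Y", "MT", "M", "XY"})


def is_autosome(label: str) -> bool:
    """True unless *label* names a sex chromosome/mitochondrion or is unplaced."""
    norm = str(label)
    if norm.lower().startswith("chr"):
        norm = norm[3:]
    if norm.upper() in SEX_CHROMOSOMES:
        return False
    if norm in {"0", ".", ""}:
        return False
    return True


@dataclass(frozen=True)
class Marker:
    """One biallelic SNP: identifier, chromosome, 1-based position, alleles."""

    id: str
    chromosome: str
    position: int
    allele_ref: str
    allele_alt: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"marker {self.id}: ref and alt alleles are equal")


class PanelError(ValueError):
    """Malformed panel or panel misuse (e.g. phased-only operation on unphased data)."""


@dataclass
class HaplotypePanel:
    """Phased alleles for ``2N`` haplotypes at ``M`` SNPs on one chromosome.

    Parameters
    ----------
    markers
        Markers sorted by strictly increasing position, all on one chromosome.
    haplotypes
        ``(2N, M)`` int8 array with entries in ``{0, 1, -1}``; rows ``2k`` and
        ``2k + 1`` are the two haplotypes of sample ``k``.
    sample_ids
        ``N`` sample labels.
    group_labels
        Per-sample genetic-group label (e.g. ``"CA"`` / ``"MA"``).
    phased
        True when loaded from a phased source ("|" separators) or simulated.
        LD from unphased panels must go through the two-locus EM.
    """

    markers: list[Marker]
    haplotypes: np.ndarray
    sample_ids: list[str]
    group_labels: list[str]
    phased: bool = True

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotypes must be a 2-D array")
        n_rows, n_cols = self.haplotypes.shape
        if n_rows % 2:
            raise PanelError("haplotype row count must be even (two rows per sample)")
        if n_cols != len(self.markers):
            raise PanelError("marker count does not match haplotype columns")
        if n_rows != 2 * len(self.sample_ids):
            raise PanelError("sample count does not match haplotype rows")
        if len(self.group_labels) != len(self.sample_ids):
            raise PanelError("group_labels must have one entry per sample")
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise PanelError("haplotype entries must be 0, 1 or -1 (missing)")
        chroms = {m.chromosome for m in self.markers}
        if len(chroms) > 1:
            raise PanelError(f"panel spans multiple chromosomes: {sorted(chroms)}")
        pos = self.positions
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise PanelError("marker positions must be strictly increasing")

    # ------------------------------------------------------------------ basic
    @property
    def chromosome(self) -> str:
        return self.markers[0].chromosome if self.markers else ""

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([m.position for m in self.markers], dtype=np.int64)

    # --------------------------------------------------------------- subsets
    def subset_markers(self, index) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            markers=[self.markers[i] for i in index],
            haplotypes=self.haplotypes[:, index],
        )

    def subset_samples(self, index) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        rows = np.stack([2 * index, 2 * index + 1], axis=1).ravel()
        return replace(
            self,
            haplotypes=self.haplotypes[rows],
            sample_ids=[self.sample_ids[i] for i in index],
            group_labels=[self.group_labels[i] for i in index],
        )

    def samples_in_group(self, group: str) -> "HaplotypePanel":
        keep = [i for i, g in enumerate(self.group_labels) if g == group]
        if not keep:
            raise PanelError(f"no samples with group label {group!r}")
        return self.subset_samples(np.asarray(keep))

    # -------------------------------------------------------------- genotypes
    def genotypes(self) -> np.ndarray:
        """``(N, M)`` alt-allele dosage (0/1/2); -1 where either haplotype is missing."""
        a = self.haplotypes[0::2].astype(np.int16)
        b = self.haplotypes[1::2].astype(np.int16)
        g = a + b
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return g.astype(np.int8)

    # ------------------------------------------------------------ orientation
    def orientation_map(self) -> dict:
        """(chromosome, position) -> (ref, alt); fixes the sign convention of D."""
        return {
            (m.chromosome, m.position): (m.allele_ref, m.allele_alt)
            for m in self.markers
        }

    def orientation_digest(self) -> str:
        h = hashlib.sha256()
        for m in self.markers:
            h.update(f"{m.chromosome}\t{m.position}\t{m.allele_ref}\t{m.allele_alt}\n".encode())
        return h.hexdigest()

    def flip_marker(self, index: int) -> "HaplotypePanel":
        """Return a panel with marker *index* re-oriented (ref/alt swapped, codes flipped)."""
        m = self.markers[index]
        new_markers = list(self.markers)
        new_markers[index] = replace(m, allele_ref=m.allele_alt, allele_alt=m.allele_ref)
        hap = self.haplotypes.copy()
        col = hap[:, index]
        obs = col != MISSING
        col[obs] = 1 - col[obs]
        return replace(self, markers=new_markers, haplotypes=hap)


def merge_groups(panel_a: HaplotypePanel, panel_b: HaplotypePanel) -> HaplotypePanel:
    """Stack two panels sample-wise into one joint panel (shared marker map required)."""
    if [
        (m.chromosome, m.position, m.allele_ref, m.allele_alt) for m in panel_a.markers
    ] != [(m.chromosome, m.position, m.allele_ref, m.allele_alt) for m in panel_b.markers]:
        raise PanelError("cannot merge panels with different marker maps")
    return HaplotypePanel(
        markers=list(panel_a.markers),
        haplotypes=np.vstack([panel_a.haplotypes, panel_b.haplotypes]),
        sample_ids=list(panel_a.sample_ids) + list(panel_b.sample_ids),
        group_labels=list(panel_a.group_labels) + list(panel_b.group_labels),
        phased=panel_a.phased and panel_b.phased,
    )
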