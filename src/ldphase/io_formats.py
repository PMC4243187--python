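"""Readers and writers for the formats the pipeline touches.

Phased genotypes come in as VCF (via cyvcf2; "|" vs "/" separators decide the
phased flag) or PLINK text PED/MAP (never phased).  Haplotype blocks go out as
BED (0-based half-open), everything else as TSV.  Internal positions are
1-based (the VCF convention); conversion to BED happens only at the boundary.

Loading drops, with a logged count: non-SNP and multiallelic records, sex
chromosomes, loci without an assigned position, and duplicate-position markers
(first kept).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .panel import MISSING, HaplotypePanel, Marker, is_autosome

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Structurally invalid input file."""


UNASSIGNED = "UNASSIGNED"


# --------------------------------------------------------------------- group map
def read_group_map(path) -> dict:
    """Two-column TSV ``sample_id<TAB>group`` -> dict; '#' lines and a header row skipped."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"group map line has fewer than 2 columns: {line!r}")
            if fields[0] == "sample_id":  # optional header
                continue
            mapping[fields[0]] = fields[1]
    return mapping


def write_group_map(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in mapping.items():
            fh.write(f"{sample}\t{group}\n")


def _assign_groups(sample_ids, group_map) -> list[str]:
    group_map = group_map or {}
    missing_from_data = set(group_map) - set(sample_ids)
    if missing_from_data:
        logger.warning(
            "%d samples in group map absent from genotype data: %s",
            len(missing_from_data),
            ", ".join(sorted(missing_from_data)[:5]),
        )
    return [group_map.get(s, UNASSIGNED) for s in sample_ids]


def _build_panels(records, sample_ids, groups, phased) -> list[HaplotypePanel]:
    """records: list of (Marker, column int8 array); split by chromosome, sort, dedup."""
    by_chrom: dict[str, list] = {}
    for marker, col in records:
        by_chrom.setdefault(marker.chromosome, []).append((marker, col))
    panels = []
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        recs = sorted(by_chrom[chrom], key=lambda mc: mc[0].position)
        seen = set()
        markers, cols = [], []
        n_dup = 0
        for marker, col in recs:
            if marker.position in seen:
                n_dup += 1
                continue
            seen.add(marker.position)
            markers.append(marker)
            cols.append(col)
        if n_dup:
            logger.warning("chromosome %s: dropped %d duplicate-position markers", chrom, n_dup)
        panels.append(
            HaplotypePanel(
                markers=markers,
                haplotypes=np.column_stack(cols),
                sample_ids=list(sample_ids),
                group_labels=list(groups),
                phased=phased,
            )
        )
    return panels


# -------------------------------------------------------------------------- VCF
def read_vcf(path, group_map=None) -> list[HaplotypePanel]:
    """Read a VCF into one :class:`HaplotypePanel` per chromosome.

    Multiallelic and non-SNP records are dropped with a logged count; any "/"
    separated genotype makes the whole load unphased.  Samples absent from
    *group_map* get group ``"UNASSIGNED"``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise FormatError(f"{path}: VCF has no sample columns")
    groups = _assign_groups(sample_ids, group_map)

    records = []
    n_dropped = 0
    n_unplaced = 0
    phased = True
    saw_gt = False
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            raise FormatError(f"{path}: record at {v.CHROM}:{v.POS} has no GT field")
        saw_gt = True
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1:
            n_dropped += 1
            continue
        if not is_autosome(v.CHROM) or v.POS < 1:
            n_unplaced += 1
            continue
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for k, gt in enumerate(v.genotypes):  # [allele_a, allele_b, phased]
            a, b = gt[0], gt[1]
            col[2 * k] = a if a in (0, 1) else MISSING
            col[2 * k + 1] = b if b in (0, 1) else MISSING
            if not gt[-1] and (a >= 0 or b >= 0):
                phased = False
        records.append(
            (Marker(v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), v.POS, v.REF, alts[0]), col)
        )
    if not saw_gt and not records:
        raise FormatError(f"{path}: VCF contains no genotype records")
    if n_dropped:
        logger.info("%s: dropped %d multiallelic/non-SNP records", path, n_dropped)
    if n_unplaced:
        logger.info("%s: dropped %d sex-chromosome/unplaced records", path, n_unplaced)
    return _build_panels(records, sample_ids, groups, phased)


def write_vcf(panels, path) -> None:
    """Write panels (same samples, one per chromosome) as a minimal VCF 4.2 file."""
    panels = list(panels)
    sample_ids = panels[0].sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for panel in panels:
            if panel.sample_ids != sample_ids:
                raise FormatError("all panels in one VCF must share the sample list")
            sep = "|" if panel.phased else "/"
            hap = panel.haplotypes
            for j, m in enumerate(panel.markers):
                col = hap[:, j]
                calls = "\t".join(
                    f"{_allele_str(col[2 * k])}{sep}{_allele_str(col[2 * k + 1])}"
                    for k in range(len(sample_ids))
                )
                fh.write(
                    f"{m.chromosome}\t{m.position}\t{m.id}\t{m.allele_ref}\t"
                    f"{m.allele_alt}\t.\tPASS\t.\tGT\t{calls}\n"
                )


def _allele_str(code) -> str:
    return "." if code == MISSING else str(int(code))


# -------------------------------------------------------------------- PLINK text
def read_plink_text(ped_path, map_path, group_map=None, allele_ref=None) -> list[HaplotypePanel]:
    """Read PLINK text PED/MAP into per-chromosome panels (phased flag False).

    Allele letters map to 0/1 with the first-observed allele per marker as
    reference, unless *allele_ref* (marker id -> (ref, alt)) overrides.  A
    ``0`` allele marks the whole genotype of that marker as missing.
    """
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise FormatError(f"{map_path}: MAP line needs 4 columns: {line!r}")
            map_rows.append((fields[0], fields[1], int(fields[3])))

    sample_ids, groups_rows, allele_cols = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(map_rows):
                raise FormatError(
                    f"{ped_path}: PED line has {len(fields)} columns, expected "
                    f"{6 + 2 * len(map_rows)} for {len(map_rows)} markers"
                )
            sample_ids.append(fields[1])
            allele_cols.append(fields[6:])
    n_samples = len(sample_ids)
    groups = _assign_groups(sample_ids, group_map)

    records = []
    n_unplaced = 0
    for j, (chrom, marker_id, pos) in enumerate(map_rows):
        raw = [(allele_cols[k][2 * j], allele_cols[k][2 * j + 1]) for k in range(n_samples)]
        observed = []
        for a, b in raw:
            if a != "0" and b != "0":
                for al in (a, b):
                    if al not in observed:
                        observed.append(al)
        if allele_ref is not None and marker_id in allele_ref:
            ref, alt = allele_ref[marker_id]
            extra = [al for al in observed if al not in (ref, alt)]
            if extra:
                raise FormatError(
                    f"marker {marker_id}: observed alleles {observed} do not match "
                    f"allele reference ({ref}, {alt})"
                )
        else:
            if len(observed) > 2:
                raise FormatError(f"marker {marker_id}: more than two alleles observed: {observed}")
            ref = observed[0] if observed else "N"
            alt = observed[1] if len(observed) > 1 else ("N" if ref != "N" else "D")
        if not is_autosome(chrom) or pos < 1:
            n_unplaced += 1
            continue
        col = np.empty(2 * n_samples, dtype=np.int8)
        for k, (a, b) in enumerate(raw):
            if a == "0" or b == "0":
                col[2 * k] = col[2 * k + 1] = MISSING
            else:
                col[2 * k] = 0 if a == ref else 1
                col[2 * k + 1] = 0 if b == ref else 1
        records.append((Marker(marker_id, chrom, pos, ref, alt), col))
    if n_unplaced:
        logger.info("%s: dropped %d sex-chromosome/unplaced markers", map_path, n_unplaced)
    return _build_panels(records, sample_ids, groups, phased=False)


# -------------------------------------------------------------------------- BED
def write_blocks_bed(blocks, path) -> None:
    """Write haplotype blocks as BED: chrom, first SNP pos - 1, last SNP pos, id, n_snps."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tblock_id\tn_snps\n")
        for k, blk in enumerate(blocks, start=1):
            fh.write(
                f"{blk.chromosome}\t{blk.start_pos - 1}\t{blk.end_pos}\t"
                f"block_{k}\t{blk.n_snps}\n"
            )
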