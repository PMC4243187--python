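"""Pipeline orchestration: QC -> pairwise LD -> decay profiles -> phase
persistence -> haplotype blocks, with table-shaped TSV outputs and a run
manifest for provenance.

Group A and group B panels are QC'd separately; the joint group (both sets
of samples pooled) is QC'd on its own and used for the block scan.  The main
summary table mirrors the classic layout: one row per distance bin with pair
counts, mean/SD/median r^2 for each group and the joint set, and the PL
column for the group pair.

Every exclusion (markers, samples, undefined pairs, dropped join pairs) is
logged so data-dependent discrepancies are diagnosable.  Rerunning with the
same config and seed reproduces every output table byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decay_profile import DistanceBinScheme, build_profile, pairs_within
from .haplotype_blocks import (
    GabrielParams,
    find_blocks,
    summarize_blocks,
    summary_frame,
)
from .io_formats import read_group_map, read_vcf, write_blocks_bed
from .ld_core import pair_stats_table
from .panel import HaplotypePanel, merge_groups
from .phase_persistence import PairTable, persistence_profile, shared_pairs
from .qc import QCThresholds, apply_qc
from .synthetic_data import SimConfig, simulate_two_groups

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    vcf: str | None = None
    group_map: str | None = None
    group_a: str = "CA"
    group_b: str = "MA"
    joint_name: str = "CAN"
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    scheme: DistanceBinScheme = field(default_factory=DistanceBinScheme)
    gabriel: GabrielParams = field(default_factory=GabrielParams)
    sim: SimConfig | None = None  # simulate instead of reading files
    out_dir: str = "ldphase_out"
    seed: int = 0
    emit_pairs: bool = False
    skip_blocks: bool = False


# ------------------------------------------------------------------- LD stage
def group_pair_table(panels, group: str, thresholds: QCThresholds,
                     max_distance: int) -> tuple[PairTable, list[HaplotypePanel], list]:
    """QC one group's panels and compute its pairwise LD table within the cap."""
    frames = []
    orientation = {}
    qc_panels = []
    reports = []
    for panel in panels:
        sub = panel.samples_in_group(group) if group in panel.group_labels else panel
        qc_panel, report = apply_qc(sub, thresholds)
        reports.append(report)
        qc_panels.append(qc_panel)
        if qc_panel.n_markers < 2:
            continue
        i_idx, j_idx = pairs_within(qc_panel.positions, max_distance)
        if len(i_idx) == 0:
            continue
        stats = pair_stats_table(qc_panel, (i_idx, j_idx))
        ok = stats["defined"]
        n_undef = int((~ok).sum())
        if n_undef:
            logger.info(
                "group %s chr %s: skipped %d monomorphic/undefined pairs",
                group, qc_panel.chromosome, n_undef,
            )
        pos = qc_panel.positions
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": qc_panel.chromosome,
                    "pos_i": pos[stats["i"][ok]],
                    "pos_j": pos[stats["j"][ok]],
                    "distance": stats["distance"][ok],
                    "p_i": stats["p_i"][ok],
                    "p_j": stats["p_j"][ok],
                    "p_ij": stats["p_ij"][ok],
                    "D": stats["D"][ok],
                    "r2": stats["r2"][ok],
                    "dprime": stats["dprime"][ok],
                    "signed_r": stats["signed_r"][ok],
                    "n": stats["n"][ok].astype(int),
                }
            )
        )
        orientation.update(qc_panel.orientation_map())
    frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["chromosome", "pos_i", "pos_j", "distance", "p_i", "p_j",
                     "p_ij", "D", "r2", "dprime", "signed_r", "n"]
        )
    )
    return PairTable(frame=frame, orientation=orientation, group=group), qc_panels, reports


# ------------------------------------------------------------------- run-all
def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle into ``config.out_dir``.

    Returns a dict with the in-memory tables and output paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": out_dir}
    input_digests = {}

    # ---- inputs -----------------------------------------------------------
    try:
        if config.sim is not None:
            panels_a, panels_b = simulate_two_groups(config.sim)
            panels = [merge_groups(pa, pb) for pa, pb in zip(panels_a, panels_b)]
        else:
            if config.vcf is None:
                raise ValueError("either a VCF or a simulation config is required")
            group_map = read_group_map(config.group_map) if config.group_map else {}
            panels = read_vcf(config.vcf, group_map)
            input_digests[Path(config.vcf).name] = _sha256(config.vcf)
            if config.group_map:
                input_digests[Path(config.group_map).name] = _sha256(config.group_map)
        for g in (config.group_a, config.group_b):
            if not any(g in p.group_labels for p in panels):
                raise ValueError(
                    f"group {g!r} has no samples; phase persistence needs both groups"
                )
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc

    # ---- QC + pairwise LD per group --------------------------------------
    try:
        cap = config.scheme.cap_bp
        table_a, panels_a, reports_a = group_pair_table(
            panels, config.group_a, config.thresholds, cap
        )
        table_b, panels_b, reports_b = group_pair_table(
            panels, config.group_b, config.thresholds, cap
        )
        joint_panels_qc = []
        joint_frames = []
        joint_reports = []
        for panel in panels:
            qc_panel, report = apply_qc(panel, config.thresholds)
            joint_panels_qc.append(qc_panel)
            joint_reports.append(report)
            if qc_panel.n_markers < 2:
                continue
            i_idx, j_idx = pairs_within(qc_panel.positions, cap)
            stats = pair_stats_table(qc_panel, (i_idx, j_idx))
            ok = stats["defined"]
            joint_frames.append(
                pd.DataFrame(
                    {
                        "chromosome": qc_panel.chromosome,
                        "distance": stats["distance"][ok],
                        "r2": stats["r2"][ok],
                    }
                )
            )
        joint_frame = pd.concat(joint_frames, ignore_index=True)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"qc/ld stage failed: {exc}") from exc

    # ---- decay profiles ---------------------------------------------------
    try:
        prof_a = build_profile(
            table_a.frame["distance"], table_a.frame["r2"], config.scheme,
            group=config.group_a,
        )
        prof_b = build_profile(
            table_b.frame["distance"], table_b.frame["r2"], config.scheme,
            group=config.group_b,
        )
        prof_joint = build_profile(
            joint_frame["distance"], joint_frame["r2"], config.scheme,
            group=config.joint_name,
        )
        per_chrom = []
        for chrom, sub in table_a.frame.groupby("chromosome"):
            per_chrom.append(
                build_profile(sub["distance"], sub["r2"], config.scheme,
                              group=config.group_a, chromosome=str(chrom))
            )
    except Exception as exc:
        raise PipelineError(f"decay stage failed: {exc}") from exc

    # ---- phase persistence -------------------------------------------------
    try:
        matched = shared_pairs(table_a, table_b)
        logger.info(
            "phase persistence: %d shared pairs (%d only in %s, %d only in %s)",
            len(matched), matched.attrs["n_only_a"], config.group_a,
            matched.attrs["n_only_b"], config.group_b,
        )
        persistence = persistence_profile(
            matched, config.scheme, config.group_a, config.group_b
        )
    except Exception as exc:
        raise PipelineError(f"phase-persistence stage failed: {exc}") from exc

    # ---- summary table (bins x groups + PL) -------------------------------
    summary = prof_a.table[["bin", "n_pairs", "mean_r2", "sd_r2", "median_r2"]].copy()
    summary.columns = ["bin"] + [f"{config.group_a}_{c}" for c in summary.columns[1:]]
    for prof, name in ((prof_b, config.group_b), (prof_joint, config.joint_name)):
        t = prof.table
        for c in ("n_pairs", "mean_r2", "sd_r2", "median_r2"):
            summary[f"{name}_{c}"] = t[c]
    summary["PL"] = persistence.table["pl"]
    summary["PL_centered"] = persistence.table["pl_centered"]
    summary["n_shared_pairs"] = persistence.table["n_shared_pairs"]

    # ---- blocks -----------------------------------------------------------
    blocks = []
    block_summaries = []
    if not config.skip_blocks:
        try:
            for qc_panel in joint_panels_qc:
                chrom_blocks = find_blocks(qc_panel, config.gabriel)
                blocks.extend(chrom_blocks)
                block_summaries.append(summarize_blocks(chrom_blocks, qc_panel))
        except Exception as exc:
            raise PipelineError(f"blocks stage failed: {exc}") from exc

    # ---- outputs ----------------------------------------------------------
    paths = {}
    paths["summary"] = _write_tsv(summary, out_dir / "ld_summary.tsv")
    paths["persistence"] = _write_tsv(persistence.table, out_dir / "phase_persistence.tsv")
    for prof, name in ((prof_a, config.group_a), (prof_b, config.group_b),
                       (prof_joint, config.joint_name)):
        paths[f"decay_{name}"] = _write_tsv(prof.table, out_dir / f"ld_decay_{name}.tsv")
    qc_rows = []
    for group, reports in (
        (config.group_a, reports_a),
        (config.group_b, reports_b),
        (config.joint_name, joint_reports),
    ):
        for rep in reports:
            row = {"group": group}
            row.update({k: v for k, v in asdict(rep).items() if k != "per_marker"})
            qc_rows.append(row)
    paths["qc_report"] = _write_tsv(pd.DataFrame(qc_rows), out_dir / "qc_report.tsv")
    if not config.skip_blocks:
        bed_path = out_dir / "blocks.bed"
        write_blocks_bed(blocks, bed_path)
        paths["blocks_bed"] = bed_path
        paths["block_summary"] = _write_tsv(
            summary_frame(block_summaries), out_dir / "block_summary.tsv"
        )
    if config.emit_pairs:
        paths["pairs_a"] = _write_tsv(table_a.frame, out_dir / f"pairs_{config.group_a}.tsv")
        paths["pairs_b"] = _write_tsv(table_b.frame, out_dir / f"pairs_{config.group_b}.tsv")

    manifest = {
        "ldphase_version": __version__,
        "config": _config_dict(config),
        "input_digests": input_digests,
        "output_digests": {p.name: _sha256(p) for p in sorted(paths.values())},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path

    bundle.update(
        {
            "summary": summary,
            "profiles": {config.group_a: prof_a, config.group_b: prof_b,
                         config.joint_name: prof_joint},
            "per_chromosome_profiles": per_chrom,
            "persistence": persistence,
            "blocks": blocks,
            "block_summaries": block_summaries,
            "qc_reports": {config.group_a: reports_a, config.group_b: reports_b,
                           config.joint_name: joint_reports},
            "pair_tables": {config.group_a: table_a, config.group_b: table_b},
            "paths": paths,
        }
    )
    return bundle


# -------------------------------------------------------------------- helpers
def _write_tsv(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="")
    return path


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    # keep the manifest free of machine-specific absolute paths
    for key in ("vcf", "group_map", "out_dir"):
        if d.get(key):
            d[key] = Path(d[key]).name
    return d
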