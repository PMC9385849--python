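"""End-to-end orchestration from a single YAML configuration.

Stages: annotate -> total/family/locus differential methylation per
comparison -> feature enrichment -> Venn partition and variant target
loci -> expression integration -> ROC -> covariate balance.  Every
intermediate table is written as TSV with a comment header recording the
thresholds that produced it; reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohorts import covariate_balance, select_variant_target_loci, venn_partition
from .diffmeth import BetaMatrix, call_dmps, family_methylation, total_re_methylation
from .enrichment import feature_enrichment
from .integration import (
    candidate_target_genes,
    flag_reference_genes,
    map_dmps_to_genes,
    simple_deg_caller,
)
from .io_annotation import (
    annotate_probes,
    annotation_frame,
    read_probe_manifest,
    read_repeat_annotation,
)
from .roc import roc_table

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline", "write_table"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    """All inputs, labels and thresholds for a full run."""

    repeats: str
    manifest: str
    beta: str
    samples: str
    control_label: str
    case_labels: list
    variant_labels: list = field(default_factory=list)
    heterogeneous_label: str = ""
    deg_tables: list = field(default_factory=list)  # TSV paths: study_id gene log2FC q
    expression_matrices: dict = field(default_factory=dict)  # study_id -> expr TSV
    expression_groups: str = ""
    gene_list: str = ""
    alpha_fdr: float = 0.05
    min_abs_delta: float = 0.05
    min_studies: int = 2
    q_max: float = 0.05
    pooled_t: bool = False
    stratify_fdr: bool = True
    ci_method: str = "delong"
    max_roc_probes: int = 25
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list:
    """Structured, non-throwing config checks; returns a list of violations."""
    violations = []
    for name in ("repeats", "manifest", "beta", "samples"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            violations.append(f"{name}: file not found: {path!r}")
    for path in config.deg_tables:
        if not Path(path).exists():
            violations.append(f"deg_tables: file not found: {path!r}")
    for study, path in config.expression_matrices.items():
        if not Path(path).exists():
            violations.append(f"expression_matrices[{study}]: file not found: {path!r}")
    if config.expression_matrices and not Path(config.expression_groups or "").exists():
        violations.append("expression_groups: required with expression_matrices")
    for key, lo, hi in (
        ("alpha_fdr", 0, 1), ("q_max", 0, 1), ("min_abs_delta", 0, 1),
    ):
        val = getattr(config, key)
        if not (lo < val < 1) if key != "min_abs_delta" else not (0 <= val <= 1):
            violations.append(f"{key}: {val} outside ({lo}, {hi})")
    if config.min_studies < 1:
        violations.append("min_studies must be >= 1")
    if config.ci_method not in ("delong", "bootstrap"):
        violations.append(f"ci_method: unknown method {config.ci_method!r}")
    if config.control_label in config.case_labels:
        violations.append("control_label must differ from every case label")
    for lab in config.variant_labels:
        if lab not in config.case_labels:
            violations.append(f"variant label {lab!r} not among case_labels")
    if config.heterogeneous_label and config.heterogeneous_label not in config.case_labels:
        violations.append("heterogeneous_label not among case_labels")
    if Path(config.samples).exists():
        sheet = pd.read_csv(config.samples)
        present = set(sheet["group"].astype(str))
        for lab in [config.control_label, *config.case_labels]:
            if lab not in present:
                violations.append(f"group label {lab!r} absent from sample sheet")
    return violations


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a TSV with '# key=value' comment headers for provenance."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# retrometh {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_deg_tables(config: PipelineConfig) -> pd.DataFrame:
    """Concatenate supplied DEG tables and/or call DEGs from raw matrices."""
    frames = []
    for path in config.deg_tables:
        frames.append(pd.read_csv(path, sep="\t", comment="#"))
    if config.expression_matrices:
        groups = pd.read_csv(config.expression_groups, dtype=str).set_index("sample_id")["group"]
        for study_id, path in sorted(config.expression_matrices.items()):
            expr = pd.read_csv(path, sep="\t", comment="#", index_col=0)
            frames.append(
                simple_deg_caller(expr, groups, "case", "control",
                                  study_id=study_id, alpha=config.q_max)
            )
    if not frames:
        return pd.DataFrame(columns=["study_id", "gene", "log2FC", "q"])
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {
        "alpha_fdr": config.alpha_fdr, "min_abs_delta": config.min_abs_delta,
        "min_studies": config.min_studies, "q_max": config.q_max,
        "pooled_t": config.pooled_t, "stratify_fdr": config.stratify_fdr,
        "ci_method": config.ci_method, "seed": config.seed,
    }
    funnel = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        stage("annotate")
        repeats = read_repeat_annotation(config.repeats)
        probes = read_probe_manifest(config.manifest)
        ann = annotation_frame(annotate_probes(probes, repeats))
        write_table(ann, outdir / "annotated.tsv", thresholds)
        funnel["probes_total"] = len(ann)
        funnel["probes_repeat_resident"] = int((ann["repeat_name"] != "").sum())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage annotate failed on {config.repeats!r}/{config.manifest!r}: {exc}") from exc

    try:
        stage("load_beta")
        beta = BetaMatrix.from_files(config.beta, config.samples)
    except Exception as exc:
        raise PipelineError(f"stage load_beta failed on {config.beta!r}: {exc}") from exc

    dmp_tables = {}
    try:
        stage("differential_methylation")
        total_rows = []
        for case in config.case_labels:
            total = total_re_methylation(beta, ann, case, config.control_label,
                                         pooled=config.pooled_t)
            total_rows.append(
                {"comparison": f"{case}_vs_{config.control_label}",
                 "delta_beta": total.delta_beta, "t": total.t, "df": total.df,
                 "p": total.p, "case_n": total.case_n, "control_n": total.control_n}
            )
            for group_by in ("family", "age_class"):
                fam = family_methylation(beta, ann, case, config.control_label,
                                         group_by=group_by, pooled=config.pooled_t)
                write_table(fam, outdir / f"{group_by}_{case}.tsv", thresholds)
            dmps = call_dmps(beta, ann, case, config.control_label,
                             alpha_fdr=config.alpha_fdr,
                             stratify_fdr=config.stratify_fdr, pooled=config.pooled_t)
            dmp_tables[case] = dmps
            write_table(dmps, outdir / f"dmps_{case}.tsv", thresholds)
            funnel[f"dmps_significant_{case}"] = int(dmps["significant"].sum())
        write_table(pd.DataFrame(total_rows), outdir / "total_methylation.tsv", thresholds)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage differential_methylation failed: {exc}") from exc

    try:
        stage("feature_enrichment")
        enr_frames = []
        for case, dmps in dmp_tables.items():
            sig = dmps.loc[dmps["significant"], "probe_id"]
            for element_class in ("LINE1", "Alu"):
                enr = feature_enrichment(sig, ann, element_class)
                enr.insert(0, "comparison", f"{case}_vs_{config.control_label}")
                enr_frames.append(enr)
        write_table(pd.concat(enr_frames, ignore_index=True),
                    outdir / "enrichment.tsv", thresholds)
    except Exception as exc:
        raise PipelineError(f"stage feature_enrichment failed: {exc}") from exc

    try:
        stage("cohort_logic")
        if len(config.case_labels) >= 3:
            a, b, c = config.case_labels[:3]
            sig = {lab: set(dmp_tables[lab].loc[dmp_tables[lab]["significant"], "probe_id"])
                   for lab in (a, b, c)}
            venn = venn_partition(sig[a], sig[b], sig[c])
            rows = [
                {"region": region, "labels": "/".join(
                    {"A": a, "B": b, "C": c}[ch] for ch in region),
                 "count": len(members),
                 "probes": ";".join(sorted(members))}
                for region, members in venn.regions.items()
            ]
            write_table(pd.DataFrame(rows), outdir / "venn.tsv", thresholds)
        targets = {}
        for variant in config.variant_labels:
            tl = select_variant_target_loci(
                dmp_tables, beta, variant, config.heterogeneous_label,
                alpha=config.alpha_fdr, pooled=config.pooled_t)
            targets[variant] = tl
            write_table(tl, outdir / f"targets_{variant}.tsv", thresholds)
            funnel[f"target_loci_{variant}"] = len(tl)
        balance = covariate_balance(
            pd.read_csv(config.samples),
            [config.control_label, *config.case_labels], config.control_label)
        (outdir / "balance.json").write_text(json.dumps(balance, indent=2, sort_keys=True))
    except Exception as exc:
        raise PipelineError(f"stage cohort_logic failed: {exc}") from exc

    try:
        stage("integration")
        degs = _load_deg_tables(config)
        write_table(degs, outdir / "degs.tsv", thresholds)
        for case in config.case_labels:
            if case in targets:
                source = dmp_tables[case][
                    dmp_tables[case]["probe_id"].isin(targets[case]["probe_id"])
                ]
            else:
                source = dmp_tables[case][dmp_tables[case]["significant"]]
            dmgs = map_dmps_to_genes(source, ann)
            cands = candidate_target_genes(
                dmgs, degs,
                min_abs_delta=config.min_abs_delta,
                min_studies=config.min_studies, q_max=config.q_max)
            if config.gene_list:
                cands = flag_reference_genes(cands, config.gene_list)
            write_table(cands, outdir / f"candidates_{case}.tsv", thresholds)
            funnel[f"candidates_{case}"] = len(cands)
    except Exception as exc:
        raise PipelineError(f"stage integration failed: {exc}") from exc

    try:
        stage("roc")
        for variant in config.variant_labels:
            probes = list(targets[variant]["probe_id"][: config.max_roc_probes])
            if not probes:
                write_table(pd.DataFrame(
                    columns=["probe_id", "auc", "ci_low", "ci_high",
                             "n_pos", "n_neg", "method", "degenerate"]),
                    outdir / f"roc_{variant}.tsv", thresholds)
                continue
            negatives = [config.control_label] + [
                v for v in config.variant_labels if v != variant]
            table = roc_table(beta, probes, variant, negatives,
                              method=config.ci_method, seed=config.seed)
            write_table(table, outdir / f"roc_{variant}.tsv", thresholds)
    except Exception as exc:
        raise PipelineError(f"stage roc failed: {exc}") from exc

    stage("summary")
    summary = pd.DataFrame(sorted(funnel.items()), columns=["metric", "value"])
    write_table(summary, outdir / "summary.tsv", thresholds)
    (outdir / "run_log.txt").write_text(
        "retrometh run\n"
        + f"version={__version__}\n"
        + "\n".join(f"{k}={v}" for k, v in thresholds.items())
        + "\n"
        + "\n".join(f"{k}={v}" for k, v in sorted(funnel.items()))
        + "\n"
    )
    return outdir
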