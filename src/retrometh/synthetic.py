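"""Seeded synthetic fixtures: repeat annotation, probe manifest, sample
sheet, beta matrix with planted methylation effects, and log2-expression
studies with planted direction-controlled effects.

The beta noise model is a Beta distribution parameterized by mean and
precision (``beta ~ Beta(mu * nu, (1 - mu) * nu)``); planted effects shift
the mean either on the logit scale (``delta_logit``) or by an exact target
difference on the beta scale (``delta_beta``).  Everything is driven by
``numpy.random.default_rng`` so identical seed + config yields byte-
identical fixture files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_annotation import (
    AGE_BY_FAMILY,
    GENE_FEATURES,
    annotate_probes,
    annotation_frame,
    classify_repeat_name,
)

__all__ = [
    "EffectSpec",
    "PlantedExpression",
    "SimConfig",
    "simulate_annotation",
    "simulate_sample_sheet",
    "simulate_beta",
    "simulate_expression_studies",
    "simulate_all",
]

_AGE_CLASSES = ("old", "intermediate", "young", "related")

#: Default repeat-name sampling pool: every named family plus decoys whose
#: names match no family rule, so annotation filtering is always exercised.
DEFAULT_FAMILY_POOL = {
    "L1M5": 2.0, "L1MC1": 2.0, "L1PB1": 1.0, "L1P1": 1.0, "L1PA3": 1.5,
    "L1HS": 0.5, "HAL1": 1.0, "AluJo": 2.0, "AluJb": 1.0, "AluSx": 3.0,
    "AluSq": 1.5, "AluSg7": 0.5, "AluY": 2.0, "FLAM_C": 0.5, "FRAM": 0.5,
    "FAM": 0.5, "MER41B": 1.0, "LTR12C": 0.5,
}

DEFAULT_GROUP_SIZES = {"control": 48, "heterogeneous": 52, "variantA": 7, "variantB": 15}


@dataclass
class EffectSpec:
    """A planted methylation effect.

    ``target`` is a family name, an age class, or an explicit list of probe
    ids.  Exactly one of ``delta_logit`` (shift of the mean on the log-odds
    scale) or ``delta_beta`` (exact shift of the mean on the beta scale)
    must be given.  ``groups_affected`` must not include the control group.
    """

    target: object
    groups_affected: tuple
    delta_logit: float = None
    delta_beta: float = None

    def __post_init__(self) -> None:
        self.groups_affected = tuple(self.groups_affected)
        if (self.delta_logit is None) == (self.delta_beta is None):
            raise ValueError("set exactly one of delta_logit / delta_beta")
        val = self.delta_logit if self.delta_logit is not None else self.delta_beta
        if not np.isfinite(val):
            raise ValueError("effect size must be finite")

    def probe_mask(self, annotation: pd.DataFrame) -> np.ndarray:
        if isinstance(self.target, str):
            if self.target in AGE_BY_FAMILY:
                return (annotation["family"] == self.target).to_numpy()
            if self.target in _AGE_CLASSES:
                return (annotation["age_class"] == self.target).to_numpy()
            raise ValueError(f"unknown effect target {self.target!r}")
        wanted = set(str(p) for p in self.target)
        return annotation["probe_id"].astype(str).isin(wanted).to_numpy()


@dataclass
class PlantedExpression:
    """A planted expression effect: mean log2-expression shift of ``gene``
    in cases of the listed study indices."""

    gene: str
    shift: float
    studies: tuple

    def __post_init__(self) -> None:
        self.studies = tuple(int(s) for s in self.studies)


@dataclass
class SimConfig:
    """Configuration for the synthetic fixture generator."""

    n_probes: int = 2000
    fraction_in_repeats: float = 0.8
    family_pool: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_POOL))
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    control_label: str = "control"
    baseline_mu_logit_mean: float = float(logit(0.8))
    baseline_mu_logit_sd: float = 0.5
    precision: float = 100.0
    effects: list = field(default_factory=list)
    # annotation details
    n_gene_pool: int = 400
    probe_spacing: int = 500
    gene_overrides: dict = field(default_factory=dict)  # probe_id -> [(gene, feature), ...]
    family_overrides: dict = field(default_factory=dict)  # probe_id -> repeat name
    # expression studies
    n_expression_studies: int = 3
    n_expression_genes: int = 300
    expression_group_sizes: dict = field(default_factory=lambda: {"case": 25, "control": 25})
    expression_sd: float = 0.25
    expression_baseline: float = 5.0
    planted_expression: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.fraction_in_repeats <= 1:
            raise ValueError("fraction_in_repeats must be in (0, 1]")
        if self.precision <= 0:
            raise ValueError("precision must be > 0")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 2")
        if self.control_label not in self.group_sizes:
            raise ValueError("control_label must appear in group_sizes")
        for eff in self.effects:
            if self.control_label in eff.groups_affected:
                raise ValueError("effects must not target the control group")

    def probe_id(self, i: int) -> str:
        return f"cg{i:06d}"


def simulate_annotation(config: SimConfig, seed: int):
    """Generate matched repeat and probe-manifest tables.

    Probes are placed along one synthetic chromosome with fixed spacing;
    ``fraction_in_repeats`` of them get a covering repeat interval named
    from the sampling pool, the rest fall outside every repeat.  Each probe
    carries 0-2 (gene, feature) pairs unless overridden.

    Returns ``(repeats_df, manifest_df)`` ready to be written as BED / CSV.
    """
    rng = np.random.default_rng([seed, 101])
    n = config.n_probes
    pool_names = sorted(config.family_pool)
    weights = np.array([config.family_pool[k] for k in pool_names], dtype=float)
    weights = weights / weights.sum()

    positions = 1000 + config.probe_spacing * np.arange(n)
    resident = rng.random(n) < config.fraction_in_repeats
    for pid in config.family_overrides:
        idx = int(pid[2:])
        resident[idx] = True

    rep_rows = []
    man_rows = []
    for i in range(n):
        pid = config.probe_id(i)
        pos = int(positions[i])
        if resident[i]:
            name = config.family_overrides.get(pid) or str(rng.choice(pool_names, p=weights))
            offset = int(rng.integers(10, 80))
            length = int(rng.integers(150, 350))
            start = pos - 1 - offset
            rep_rows.append(
                {
                    "chrom": "chrS1",
                    "start": start,
                    "end": start + length,
                    "name": name,
                    "score": 0,
                    "strand": str(rng.choice(["+", "-"])),
                }
            )
        if pid in config.gene_overrides:
            pairs = list(config.gene_overrides[pid])
        else:
            k = int(rng.integers(0, 3))
            pairs = [
                (f"GENE{int(rng.integers(0, config.n_gene_pool)):04d}",
                 str(rng.choice(GENE_FEATURES)))
                for _ in range(k)
            ]
        man_rows.append(
            {
                "probe_id": pid,
                "chrom": "chrS1",
                "pos": pos,
                "strand": str(rng.choice(["+", "-"])),
                "gene_names": ";".join(g for g, _ in pairs),
                "gene_features": ";".join(f for _, f in pairs),
            }
        )
    # a few decoy repeats covering no probe
    tail = int(positions[-1]) + 10_000
    for j in range(5):
        start = tail + 1000 * j
        rep_rows.append(
            {"chrom": "chrS1", "start": start, "end": start + 300,
             "name": str(rng.choice(pool_names, p=weights)), "score": 0, "strand": "+"}
        )
    return pd.DataFrame(rep_rows), pd.DataFrame(man_rows)


def simulate_sample_sheet(config: SimConfig, seed: int) -> pd.DataFrame:
    """Sample sheet with group labels and sex/age covariates."""
    rng = np.random.default_rng([seed, 202])
    rows = []
    i = 0
    for label, size in config.group_sizes.items():
        for _ in range(size):
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "group": label,
                    "sex": str(rng.choice(["M", "F"])),
                    "age": int(rng.integers(4, 18)),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def simulate_beta(
    config: SimConfig,
    annotation: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Beta matrix (probes x samples) with planted effects.

    Per-probe baseline means are logit-normal; effects shift the mean of
    affected (probe, sample) cells; observed values are Beta draws with
    precision ``nu``.  Effects matching no probe are skipped with a
    warning.  All values are strictly inside (0, 1).
    """
    rng = np.random.default_rng([seed, 303])
    n = len(annotation)
    samples = sample_sheet["sample_id"].to_numpy()
    groups = sample_sheet["group"].to_numpy()

    mu0 = expit(rng.normal(config.baseline_mu_logit_mean, config.baseline_mu_logit_sd, size=n))
    mu = np.repeat(mu0[:, None], len(samples), axis=1)
    for eff in config.effects:
        pmask = eff.probe_mask(annotation)
        if not pmask.any():
            warnings.warn(f"effect target {eff.target!r} names no probes; skipped")
            continue
        smask = np.isin(groups, eff.groups_affected)
        if eff.delta_beta is not None:
            shifted = np.clip(mu0[pmask] + eff.delta_beta, 1e-4, 1 - 1e-4)
        else:
            shifted = expit(logit(mu0[pmask]) + eff.delta_logit)
        mu[np.ix_(pmask, smask)] = shifted[:, None]

    nu = config.precision
    beta = rng.beta(mu * nu, (1.0 - mu) * nu)
    beta = np.clip(beta, 1e-6, 1 - 1e-6)
    return pd.DataFrame(beta, index=annotation["probe_id"].astype(str).to_numpy(), columns=samples)


def simulate_expression_studies(config: SimConfig, seed: int):
    """Per-study gene x sample log2-expression matrices with planted shifts.

    Returns ``(studies, groups, truth)`` where ``studies`` maps study id to
    a DataFrame, ``groups`` maps sample id to case/control (shared across
    studies), and ``truth`` lists every planted (gene, study) shift.
    """
    rng = np.random.default_rng([seed, 404])
    planted_genes = list(dict.fromkeys(p.gene for p in config.planted_expression))
    n_null = max(0, config.n_expression_genes - len(planted_genes))
    null_names, j = [], 0
    while len(null_names) < n_null:
        name = f"NULL{j:04d}"
        if name not in planted_genes:
            null_names.append(name)
        j += 1
    genes = planted_genes + null_names

    sample_ids, labels = [], []
    for label, size in config.expression_group_sizes.items():
        for j in range(size):
            sample_ids.append(f"E_{label}{j:03d}")
            labels.append(label)
    groups = pd.Series(labels, index=sample_ids)
    case_mask = np.array([lab == "case" for lab in labels])

    studies = {}
    truth_rows = []
    for k in range(config.n_expression_studies):
        study_id = f"STUDY{k + 1}"
        mat = config.expression_baseline + rng.normal(
            0.0, config.expression_sd, size=(len(genes), len(sample_ids))
        )
        df = pd.DataFrame(mat, index=genes, columns=sample_ids)
        for planted in config.planted_expression:
            if k in planted.studies:
                df.loc[planted.gene, case_mask] += planted.shift
                truth_rows.append(
                    {"gene": planted.gene, "study_id": study_id, "shift": planted.shift}
                )
        studies[study_id] = df
    truth = pd.DataFrame(truth_rows, columns=["gene", "study_id", "shift"])
    return studies, groups, truth


def _effects_truth(config: SimConfig, annotation: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for i, eff in enumerate(config.effects):
        pmask = eff.probe_mask(annotation)
        for pid in annotation.loc[pmask, "probe_id"].astype(str):
            rows.append(
                {
                    "effect_index": i,
                    "probe_id": pid,
                    "target": str(eff.target) if isinstance(eff.target, str) else "probes",
                    "groups_affected": ";".join(eff.groups_affected),
                    "delta_logit": "" if eff.delta_logit is None else eff.delta_logit,
                    "delta_beta": "" if eff.delta_beta is None else eff.delta_beta,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["effect_index", "probe_id", "target", "groups_affected",
                 "delta_logit", "delta_beta"],
    )


def simulate_all(config: SimConfig, seed: int, outdir) -> dict:
    """Write the full fixture set to ``outdir`` and return the file paths.

    Files: ``repeats.bed``, ``manifest.csv``, ``annotated.tsv``,
    ``samples.csv``, ``beta.tsv``, ``expr_<STUDY>.tsv``,
    ``expr_groups.csv``, ``truth_effects.tsv``, ``truth_expression.tsv``.
    Identical seed + config reproduce identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    repeats, manifest = simulate_annotation(config, seed)
    paths = {
        "repeats": outdir / "repeats.bed",
        "manifest": outdir / "manifest.csv",
        "annotated": outdir / "annotated.tsv",
        "samples": outdir / "samples.csv",
        "beta": outdir / "beta.tsv",
        "expr_groups": outdir / "expr_groups.csv",
        "truth_effects": outdir / "truth_effects.tsv",
        "truth_expression": outdir / "truth_expression.tsv",
    }
    repeats.to_csv(paths["repeats"], sep="\t", header=False, index=False)
    manifest.to_csv(paths["manifest"], index=False)

    from .io_annotation import read_probe_manifest, read_repeat_annotation

    annotated = annotate_probes(
        read_probe_manifest(paths["manifest"]), read_repeat_annotation(paths["repeats"])
    )
    ann_df = annotation_frame(annotated)
    ann_df.to_csv(paths["annotated"], sep="\t", index=False)

    sheet = simulate_sample_sheet(config, seed)
    sheet.to_csv(paths["samples"], index=False)
    beta = simulate_beta(config, ann_df, sheet, seed)
    beta.to_csv(paths["beta"], sep="\t", float_format="%.8f", index_label="probe_id")

    studies, groups, truth_expr = simulate_expression_studies(config, seed)
    for study_id, df in studies.items():
        p = outdir / f"expr_{study_id}.tsv"
        df.to_csv(p, sep="\t", float_format="%.8f", index_label="gene")
        paths[f"expr_{study_id}"] = p
    groups.rename("group").to_csv(paths["expr_groups"], index_label="sample_id")
    _effects_truth(config, ann_df).to_csv(paths["truth_effects"], sep="\t", index=False)
    truth_expr.to_csv(paths["truth_expression"], sep="\t", index=False)
    return paths
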