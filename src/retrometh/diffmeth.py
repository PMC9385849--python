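"""Total, family-level and locus-level differential methylation.

All effect sizes are reported as differences of group-mean beta values
(``delta_beta = mean(case) - mean(control)``); M values are provided only
as a display transform.  Per-probe and per-aggregate tests are two-sided
t-tests (Welch by default, pooled optionally) with Benjamini-Hochberg
false-discovery-rate adjustment for locus-level calls.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BetaMatrix",
    "TotalResult",
    "WelchResult",
    "beta_to_m",
    "welch_t_test",
    "t_test_rows",
    "bh_adjust",
    "total_re_methylation",
    "family_methylation",
    "call_dmps",
]

WelchResult = namedtuple("WelchResult", ["t", "df", "p", "degenerate"])


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with per-sample group labels.

    ``values`` is a DataFrame indexed by probe id with one column per
    sample; ``groups`` maps every sample id to its cohort label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing[:5]}")
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("beta matrix contains NaN")
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("beta values must lie in [0, 1]")

    @classmethod
    def from_files(cls, beta_tsv, sample_csv) -> "BetaMatrix":
        values = pd.read_csv(beta_tsv, sep="\t", comment="#", index_col=0)
        values.index = values.index.astype(str)
        sheet = pd.read_csv(sample_csv, dtype={"sample_id": str})
        groups = sheet.set_index("sample_id")["group"]
        return cls(values, groups)

    def samples_in(self, label: str) -> list:
        keep = self.groups[self.groups == label].index
        return [s for s in self.values.columns if s in set(keep)]

    def group_arrays(self, case_label: str, control_label: str):
        """(case, control) value arrays, probes x samples."""
        case = self.values[self.samples_in(case_label)].to_numpy()
        ctrl = self.values[self.samples_in(control_label)].to_numpy()
        if case.shape[1] < 2 or ctrl.shape[1] < 2:
            raise ValueError(
                f"need >=2 samples per group ({case_label}: {case.shape[1]}, "
                f"{control_label}: {ctrl.shape[1]})"
            )
        return case, ctrl


def beta_to_m(beta, epsilon: float = 1e-6):
    """log2 odds transform of beta, guarded at the boundaries by epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    beta = np.asarray(beta, dtype=float)
    if beta.min() < 0 or beta.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    return np.log2((beta + epsilon) / (1.0 - beta + epsilon))


def t_test_rows(x: np.ndarray, y: np.ndarray, pooled: bool = False):
    """Row-wise two-sample t-test (Welch by default).

    Parameters
    ----------
    x, y : arrays of shape (n_rows, n_samples)
    pooled : use the equal-variance statistic with n1 + n2 - 2 df.

    Returns
    -------
    (t, df, p, degenerate) arrays.  Rows where both groups have zero
    variance are degenerate: equal means give t = 0, p = 1; unequal means
    give p = 0 with an infinite statistic.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)

    if pooled:
        df = np.full(mx.shape, float(nx + ny - 2))
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1.0 / nx + 1.0 / ny)
    else:
        sx2, sy2 = vx / nx, vy / ny
        se2 = sx2 + sy2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (sx2**2 / (nx - 1) + sy2**2 / (ny - 1))

    degenerate = se2 == 0.0
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(degenerate, float(nx + ny - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, df, p, degenerate


def welch_t_test(x, y, pooled: bool = False) -> WelchResult:
    """Two-sided two-sample t-test on 1-D samples (Welch by default)."""
    t, df, p, deg = t_test_rows(np.asarray(x)[None, :], np.asarray(y)[None, :], pooled=pooled)
    return WelchResult(float(t[0]), float(df[0]), float(p[0]), bool(deg[0]))


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    q = np.maximum(q, p[order])  # guard 1-ulp rounding in p * n / i
    out = np.empty(n, dtype=float)
    out[order] = q
    return out


def _resident_probe_ids(annotation: pd.DataFrame) -> pd.Index:
    mask = annotation["repeat_name"].astype(str) != ""
    return pd.Index(annotation.loc[mask, "probe_id"].astype(str))


@dataclass
class TotalResult:
    """Group contrast of the per-sample mean beta over all repeat probes."""

    delta_beta: float
    t: float
    df: float
    p: float
    case_n: int
    control_n: int
    per_sample_means: pd.Series


def total_re_methylation(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    case_label: str,
    control_label: str,
    pooled: bool = False,
) -> TotalResult:
    """Total repeat methylation: mean beta over repeat-resident probes per
    sample, contrasted between groups."""
    resident = _resident_probe_ids(annotation)
    probes = beta.values.index.intersection(resident)
    if probes.empty:
        raise ValueError("no repeat-resident probes in the beta matrix")
    sub = BetaMatrix(beta.values.loc[probes], beta.groups)
    means = sub.values.mean(axis=0)
    case_s, ctrl_s = sub.samples_in(case_label), sub.samples_in(control_label)
    res = welch_t_test(means[case_s].to_numpy(), means[ctrl_s].to_numpy(), pooled=pooled)
    delta = float(means[case_s].mean() - means[ctrl_s].mean())
    return TotalResult(delta, res.t, res.df, res.p, len(case_s), len(ctrl_s), means)


def family_methylation(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    case_label: str,
    control_label: str,
    group_by: str = "family",
    pooled: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-family (or per-age-class) group contrast of per-sample means.

    For each named family with at least one probe: average beta over the
    family's probes within each sample, then a two-sample t-test between
    groups.  Unclassified probes are excluded from aggregation.  P values
    are unadjusted unless ``adjust`` (then a ``p_bh`` column is added).
    """
    if group_by not in ("family", "age_class"):
        raise ValueError("group_by must be 'family' or 'age_class'")
    ann = annotation[annotation["probe_id"].astype(str).isin(beta.values.index)]
    ann = ann[(ann["repeat_name"].astype(str) != "") & (ann[group_by] != "unclassified")]
    case_s, ctrl_s = beta.samples_in(case_label), beta.samples_in(control_label)
    rows = []
    for name, grp in ann.groupby(group_by, sort=True):
        probes = beta.values.index.intersection(pd.Index(grp["probe_id"].astype(str)))
        sub = beta.values.loc[probes]
        means = sub.mean(axis=0)
        res = welch_t_test(means[case_s].to_numpy(), means[ctrl_s].to_numpy(), pooled=pooled)
        rows.append(
            {
                group_by: name,
                "delta_beta": float(means[case_s].mean() - means[ctrl_s].mean()),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "n_probes": len(probes),
            }
        )
    out = pd.DataFrame(rows, columns=[group_by, "delta_beta", "t", "df", "p", "n_probes"])
    if adjust and len(out):
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def call_dmps(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    case_label: str,
    control_label: str,
    alpha_fdr: float = 0.05,
    stratify_fdr: bool = True,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-probe differential methylation over repeat-resident probes.

    BH adjustment is applied separately within each element class by
    default (LINE-1 and Alu positions analyzed separately); set
    ``stratify_fdr=False`` for a single pooled adjustment.
    """
    if not 0 < alpha_fdr < 1:
        raise ValueError("alpha_fdr must be in (0, 1)")
    resident = _resident_probe_ids(annotation)
    probes = beta.values.index.intersection(resident)
    if probes.empty:
        raise ValueError("no repeat-resident probes in the beta matrix")
    sub = BetaMatrix(beta.values.loc[probes], beta.groups)
    case, ctrl = sub.group_arrays(case_label, control_label)
    t, df, p, deg = t_test_rows(case, ctrl, pooled=pooled)
    delta = case.mean(axis=1) - ctrl.mean(axis=1)

    meta = annotation.set_index(annotation["probe_id"].astype(str))
    out = pd.DataFrame(
        {
            "probe_id": probes,
            "repeat_name": meta.loc[probes, "repeat_name"].to_numpy(),
            "element_class": meta.loc[probes, "element_class"].to_numpy(),
            "family": meta.loc[probes, "family"].to_numpy(),
            "age_class": meta.loc[probes, "age_class"].to_numpy(),
            "delta_beta": delta,
            "t": t,
            "df": df,
            "p": p,
            "degenerate": deg,
        }
    ).reset_index(drop=True)

    p_fdr = np.empty(len(out), dtype=float)
    if stratify_fdr:
        for _, idx in out.groupby("element_class").groups.items():
            p_fdr[np.asarray(idx)] = bh_adjust(out.loc[idx, "p"].to_numpy())
    else:
        p_fdr[:] = bh_adjust(out["p"].to_numpy())
    out["p_fdr"] = p_fdr
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper",
                                np.where(out["delta_beta"] < 0, "hypo", "none"))
    out["significant"] = (out["p_fdr"] < alpha_fdr) & ~out["degenerate"]
    return out
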