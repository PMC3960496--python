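"""Covariate-adjusted group comparisons of topology metrics, FDR control,
and nodal-efficiency vs clinical-score regressions.

Group effects on a metric are tested with an ANCOVA — the partial F for
the group term in the least-squares model ``metric ~ group + age + IQ +
sex`` (sex as a fixed-effect indicator). Families of tests are corrected
with Benjamini-Hochberg FDR at alpha = 0.05, with families kept within
each analysis: across nodes for nodal tests, across costs for efficiency
curves, across nodes within each clinical score for the regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortDesign",
    "ancova_metric",
    "fdr_correct",
    "clinical_regression",
    "compare_global_curves",
    "demographics_table",
]

DEFAULT_ALPHA = 0.05
GROUP_LABELS = ("control", "patient")


@dataclass
class CohortDesign:
    """Subject-level design: group labels, covariates and DSM T-scores."""

    table: pd.DataFrame  # columns: subject_id, group, age, sex, iq, dsm_* scores

    REQUIRED = ("subject_id", "group", "age", "sex", "iq")
    SCORES = ("dsm_inattentive", "dsm_hyperactive", "dsm_total")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        bad = set(self.table["group"]) - set(GROUP_LABELS)
        if bad:
            rows = self.table.index[self.table["group"].isin(bad)].tolist()
            raise ValueError(f"unknown group labels {sorted(bad)} at rows {rows}")
        if self.table["subject_id"].duplicated().any():
            dups = self.table.loc[
                self.table["subject_id"].duplicated(), "subject_id"
            ].tolist()
            raise ValueError(f"duplicate subject ids: {dups}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def group_mask(self, label: str) -> np.ndarray:
        return (self.table["group"] == label).to_numpy()

    def subset(self, mask: np.ndarray) -> "CohortDesign":
        return CohortDesign(self.table.loc[mask].reset_index(drop=True))


def _design_matrices(
    design: CohortDesign, covariates: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full and reduced (group dropped) design matrices."""
    tab = design.table
    cols = [np.ones(len(tab))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "sex":
            levels = sorted(tab["sex"].astype(str).unique())
            for lev in levels[1:]:  # first level as reference
                cols.append((tab["sex"].astype(str) == lev).astype(float).to_numpy())
                names.append(f"sex[{lev}]")
        else:
            if tab[cov].isna().any():
                raise ValueError(f"missing values in covariate {cov!r}")
            cols.append(tab[cov].to_numpy(dtype=float))
            names.append(cov)
    reduced = np.column_stack(cols)
    group_ind = (tab["group"] == "patient").astype(float).to_numpy()
    full = np.column_stack([reduced, group_ind])
    return full, reduced, names + ["group[patient]"]


def ancova_metric(
    values: np.ndarray,
    design: CohortDesign,
    covariates: tuple[str, ...] = ("age", "iq", "sex"),
) -> tuple[float, tuple[int, int], float]:
    """Partial F test for the group term, adjusting for covariates.

    Fits ``metric ~ group + covariates`` by OLS and compares against the
    model without the group term. Returns (F, (df_num, df_den), p).
    Collinear designs raise with the offending terms named.
    """
    y = np.asarray(values, dtype=float)
    if y.size != design.n_subjects:
        raise ValueError("metric vector length must match the design")
    full, reduced, names = _design_matrices(design, covariates)
    if y.size <= full.shape[1]:
        raise ValueError("too few subjects for the model terms")
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        bad, r = [], 0
        for j in range(full.shape[1]):
            rj = np.linalg.matrix_rank(full[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"collinear design terms: {bad}")
    fit_full = sm.OLS(y, full).fit()
    fit_red = sm.OLS(y, reduced).fit()
    df_num = 1
    df_den = int(fit_full.df_resid)
    if fit_full.ssr == 0:
        return np.inf, (df_num, df_den), 0.0
    f = (fit_red.ssr - fit_full.ssr) / df_num / (fit_full.ssr / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), (df_num, df_den), p


def fdr_correct(
    pvalues: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up decisions; returns (reject, adjusted p)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def clinical_regression(
    nodal_eff: np.ndarray,
    scores: pd.DataFrame,
    node_ids: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-node linear regressions of nodal efficiency on clinical T-scores.

    ``nodal_eff`` is subjects x nodes (typically the patient group only);
    ``scores`` holds one column per T-score. For each node-score pair the
    least-squares slope (efficiency units per T-score point), model F and
    p are reported; FDR is applied across nodes within each score. A
    zero-variance score column is flagged undefined for all its nodes.
    """
    e = np.asarray(nodal_eff, dtype=float)
    if e.ndim != 2:
        raise ValueError("nodal_eff must be subjects x nodes")
    n_subj, n_nodes = e.shape
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    ids = list(node_ids) if node_ids is not None else [str(i) for i in range(n_nodes)]
    rows = []
    for score_name in scores.columns:
        s = scores[score_name].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            for nid in ids:
                rows.append(
                    dict(node=nid, score=score_name, slope=np.nan, F=np.nan,
                         p=np.nan, undefined=True)
                )
            continue
        for j, nid in enumerate(ids):
            res = stats.linregress(s, e[:, j])
            f = res.rvalue**2 / (1 - res.rvalue**2) * (n_subj - 2) if abs(res.rvalue) < 1 else np.inf
            rows.append(
                dict(node=nid, score=score_name, slope=float(res.slope),
                     F=float(f), p=float(res.pvalue), undefined=False)
            )
    out = pd.DataFrame(rows)
    out["fdr_reject"] = False
    for score_name in scores.columns:
        mask = (out["score"] == score_name) & ~out["undefined"]
        if mask.any():
            reject, _ = fdr_correct(out.loc[mask, "p"].to_numpy(), alpha)
            out.loc[mask, "fdr_reject"] = reject
    return out


def compare_global_curves(
    curves: np.ndarray,
    costs: np.ndarray,
    design: CohortDesign,
    covariates: tuple[str, ...] = ("age", "iq", "sex"),
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """ANCOVA of a global metric at every cost, FDR-corrected across costs.

    ``curves`` is subjects x costs (one metric, e.g. E_loc). Returns a
    per-cost table with F, p, and the FDR decision; contiguous significant
    cost ranges can be read off the decision column.
    """
    c = np.asarray(curves, dtype=float)
    costs = np.asarray(costs, dtype=float)
    if c.ndim != 2 or c.shape[1] != costs.size:
        raise ValueError("curves must be subjects x costs, matching the grid")
    if c.shape[0] != design.n_subjects:
        raise ValueError("subject count mismatch between curves and design")
    rows = []
    for j, cost in enumerate(costs):
        f, (d1, d2), p = ancova_metric(c[:, j], design, covariates)
        rows.append(dict(cost=float(cost), F=f, df_num=d1, df_den=d2, p=p))
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_correct(out["p"].to_numpy(), alpha)
    out["p_fdr"] = p_adj
    out["fdr_reject"] = reject
    return out


def significant_ranges(table: pd.DataFrame) -> list[tuple[float, float]]:
    """Contiguous cost ranges flagged significant by :func:`compare_global_curves`."""
    ranges = []
    start = None
    flags = table["fdr_reject"].to_list() + [False]
    costs = table["cost"].to_list() + [np.nan]
    for i, flag in enumerate(flags):
        if flag and start is None:
            start = costs[i]
        elif not flag and start is not None:
            ranges.append((start, costs[i - 1]))
            start = None
    return ranges


def demographics_table(design: CohortDesign) -> pd.DataFrame:
    """Group comparison of design variables: chi-square for sex, t-tests otherwise."""
    tab = design.table
    con = tab[tab["group"] == "control"]
    pat = tab[tab["group"] == "patient"]
    rows = []
    crosstab = pd.crosstab(tab["group"], tab["sex"])
    chi2, p_sex = stats.chi2_contingency(crosstab)[:2]
    rows.append(dict(measure="sex", statistic=float(chi2), test="chi2", p=float(p_sex)))
    numeric = [
        c for c in tab.columns
        if c not in ("subject_id", "group", "sex") and pd.api.types.is_numeric_dtype(tab[c])
    ]
    for col in numeric:
        t, p = stats.ttest_ind(con[col], pat[col])
        rows.append(dict(measure=col, statistic=float(t), test="t", p=float(p)))
    return pd.DataFrame(rows)
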