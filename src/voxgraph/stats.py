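"""Group and brain-behavior statistics.

Implements the inference battery applied to ROI-level graph metrics:

* two-group MANOVA via Pillai's trace (exact F for two groups),
* one-way univariate ANOVA with eta squared,
* mixed (group x ROI) repeated-measures interaction,
* hierarchical (forced-entry block) linear regression with a
  group x metric interaction term,
* the dual-threshold rule (an effect counts only if significant at p < .05
  with consistent sign at both network density levels),
* Pearson correlations with two-tailed p-values.

"Step-wise" regression here means hierarchical forced entry in a stated
block order (demographics first, then the mean-centered metric, then the
interaction), not automatic variable selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "RoiMetricTable",
    "RegressionSpec",
    "manova_pillai",
    "univariate_anova",
    "rm_group_by_roi_interaction",
    "hierarchical_regression",
    "dual_threshold_significance",
    "pearson_correlation",
    "benjamini_hochberg",
]


@dataclass
class StatResult:
    """One test statistic with df, two-tailed p, and an effect size."""

    name: str
    value: float
    df: tuple[float, float] | tuple[float] | None
    p: float
    effect_size: float | None = None
    effect_name: str | None = None
    s_level: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class RoiMetricTable:
    """Subject x ROI matrix of mean metric values with group labels."""

    values: np.ndarray
    groups: np.ndarray
    roi_names: list[str] | None = None
    metric: str = ""
    s_level: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.ndim != 2:
            raise ValueError("values must be subject x ROI")
        if self.groups.shape[0] != self.values.shape[0]:
            raise ValueError("group labels do not match subject count")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not allowed")
        labels, counts = np.unique(self.groups, return_counts=True)
        if len(labels) != 2 or counts.min() < 2:
            raise ValueError("need exactly two groups with >= 2 subjects each")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def _sscp(table: RoiMetricTable):
    """Between- and within-group SSCP matrices (p x p)."""
    x = table.values
    grand = x.mean(axis=0)
    b = np.zeros((x.shape[1], x.shape[1]))
    w = np.zeros_like(b)
    for g in np.unique(table.groups):
        xg = x[table.groups == g]
        d = xg.mean(axis=0) - grand
        b += xg.shape[0] * np.outer(d, d)
        c = xg - xg.mean(axis=0)
        w += c.T @ c
    return b, w


def manova_pillai(table: RoiMetricTable) -> StatResult:
    """Two-group MANOVA: Pillai's trace V with its (exact) F conversion.

    ``V = trace(B (B + W)^{-1})`` from the between/within SSCP matrices.
    For two groups ``s = 1`` and the F approximation
    ``F = (V / (1 - V)) * (N - g - p + 1) / p`` on ``(p, N - g - p + 1)``
    degrees of freedom is exact; partial eta squared equals V.
    """
    p = table.n_rois
    n = table.n_subjects
    g = 2
    if p >= n - g + 1:
        raise ValueError("number of dependent variables too large for the sample")
    b, w = _sscp(table)
    total = b + w
    cond = np.linalg.cond(total)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "pooled SSCP matrix is singular; reduce the number of ROIs or "
            "remove collinear ROI columns"
        )
    v = float(np.trace(b @ np.linalg.inv(total)))
    v = min(max(v, 0.0), 1.0)
    df1, df2 = p, n - g - p + 1
    if v >= 1.0:
        f = np.inf
        pval = 0.0
    else:
        f = (v / (1 - v)) * (df2 / df1)
        pval = float(sps.f.sf(f, df1, df2))
    return StatResult(
        name="pillai_V",
        value=v,
        df=(df1, df2),
        p=pval,
        effect_size=v,
        effect_name="partial_eta_sq",
        extras={"F": f, "n": n, "metric": table.metric},
        s_level=table.s_level,
    )


def univariate_anova(values: np.ndarray, groups: np.ndarray) -> StatResult:
    """One-way two-group ANOVA: F, two-tailed p, and eta squared."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    chunks = [values[groups == g] for g in labels]
    if any(len(c) < 2 for c in chunks):
        raise ValueError("need >= 2 subjects per group")
    grand = values.mean()
    ssb = sum(len(c) * (c.mean() - grand) ** 2 for c in chunks)
    ssw = sum(((c - c.mean()) ** 2).sum() for c in chunks)
    sst = ssb + ssw
    df1 = len(labels) - 1
    df2 = values.size - len(labels)
    if ssw == 0:
        f, pval = np.inf, 0.0
    else:
        f = (ssb / df1) / (ssw / df2)
        pval = float(sps.f.sf(f, df1, df2))
    return StatResult(
        name="anova_F",
        value=float(f),
        df=(df1, df2),
        p=pval,
        effect_size=float(ssb / sst) if sst > 0 else 0.0,
        effect_name="eta_sq",
    )


def rm_group_by_roi_interaction(table: RoiMetricTable) -> StatResult:
    """Mixed two-way ANOVA: the ROI x group interaction.

    ROI is the within-subject factor, age group the between-subject factor.
    Returns the interaction F on ``((R-1), (R-1)(N-2))`` degrees of freedom
    with partial eta squared; no sphericity correction is applied.
    """
    y = table.values
    n, r = y.shape
    if r < 2:
        raise ValueError("need at least 2 ROIs")
    groups = table.groups
    labels = np.unique(groups)
    subj_means = y.mean(axis=1)

    # cell means per group x ROI; subject-weighted ROI means
    cell = np.vstack([y[groups == g].mean(axis=0) for g in labels])
    group_mean = np.array([y[groups == g].mean() for g in labels])
    n_g = np.array([(groups == g).sum() for g in labels])
    roi_mean = y.mean(axis=0)
    grand = y.mean()

    ss_inter = float(
        sum(
            n_g[k] * ((cell[k] - group_mean[k] - roi_mean + grand) ** 2).sum()
            for k in range(len(labels))
        )
    )
    # within-subject error: deviation from subject mean and the group's ROI profile
    resid = np.empty_like(y)
    for k, g in enumerate(labels):
        sel = groups == g
        resid[sel] = y[sel] - subj_means[sel][:, None] - (cell[k] - group_mean[k])
    ss_err = float((resid**2).sum())

    df1 = r - 1
    df2 = (r - 1) * (n - 2)
    f = (ss_inter / df1) / (ss_err / df2)
    pval = float(sps.f.sf(f, df1, df2))
    return StatResult(
        name="rm_interaction_F",
        value=float(f),
        df=(df1, df2),
        p=pval,
        effect_size=ss_inter / (ss_inter + ss_err),
        effect_name="partial_eta_sq",
        s_level=table.s_level,
        extras={"metric": table.metric},
    )


@dataclass
class RegressionSpec:
    """Ordered forced-entry blocks for a hierarchical regression.

    Conventional layout: block 1 demographics (group code, sex, optionally a
    processing-speed covariate), block 2 the mean-centered ROI metric,
    block 3 the group x metric interaction.
    """

    dependent: str
    blocks: list[list[str]]

    def __post_init__(self):
        if not self.blocks or any(not b for b in self.blocks):
            raise ValueError("blocks must be non-empty")
        flat = [c for b in self.blocks for c in b]
        if len(flat) != len(set(flat)):
            raise ValueError("a predictor appears in more than one block")


def build_interaction(data: pd.DataFrame, group_col: str, metric_col: str,
                      name: str | None = None) -> pd.DataFrame:
    """Append centered-metric x group-contrast interaction to a copy of ``data``.

    The group is contrast-coded +-0.5 (so the metric main effect is the
    cross-group average) and the metric mean-centered before the product.
    """
    out = data.copy()
    codes = pd.Categorical(out[group_col]).codes
    out[group_col + "_code"] = codes - 0.5
    out[metric_col + "_c"] = out[metric_col] - out[metric_col].mean()
    out[name or f"{group_col}_x_{metric_col}"] = (
        out[group_col + "_code"] * out[metric_col + "_c"]
    )
    return out


def hierarchical_regression(data: pd.DataFrame, spec: RegressionSpec) -> list[dict]:
    """OLS refit at each cumulative block of a hierarchical regression.

    All variables (outcome and predictors) are z-scored before fitting, so
    the reported coefficients are standardized betas; binary/contrast-coded
    predictors are z-scored as well.  Returns one record per step with R²,
    ΔR², the block F test of ΔR², and per-predictor beta/t/p.
    """
    cols = [spec.dependent] + [c for b in spec.blocks for c in b]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    frame = data[cols].dropna()
    n = len(frame)
    z = {}
    for c in cols:
        x = frame[c].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"predictor {c!r} has zero variance")
        z[c] = (x - x.mean()) / sd
    y = z[spec.dependent]

    results = []
    entered: list[str] = []
    prev_r2 = 0.0
    for step, block in enumerate(spec.blocks, start=1):
        # collinearity within the cumulative design
        candidate = entered + block
        x = np.column_stack([z[c] for c in candidate])
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), x]))
        if rank < x.shape[1] + 1:
            offenders = _collinear_columns(x, candidate)
            raise ValueError(f"collinear predictors in block {step}: {offenders}")
        entered = candidate
        design = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ beta
        resid = y - fitted
        sse = float(resid @ resid)
        sst = float(y @ y)  # y is z-scored: SST = n
        r2 = 1.0 - sse / sst
        df_resid = n - design.shape[1]
        mse = sse / df_resid
        cov = mse * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2 * sps.t.sf(np.abs(tvals), df_resid)
        delta_r2 = r2 - prev_r2
        k_new = len(block)
        if delta_r2 <= 0 or r2 >= 1:
            f_change, p_change = 0.0, 1.0
        else:
            f_change = (delta_r2 / k_new) / ((1 - r2) / df_resid)
            p_change = float(sps.f.sf(f_change, k_new, df_resid))
        results.append(
            {
                "step": step,
                "block": list(block),
                "n": n,
                "r2": r2,
                "delta_r2": delta_r2,
                "f_change": f_change,
                "p_change": p_change,
                "df_resid": df_resid,
                "coefficients": {
                    name: {"beta": float(b), "t": float(t), "p": float(p)}
                    for name, b, t, p in zip(entered, beta[1:], tvals[1:], pvals[1:])
                },
            }
        )
        prev_r2 = r2
    return results


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    bad: list[str] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            bad.append(names[j])
    return bad


def dual_threshold_significance(
    result_s25: StatResult, result_s30: StatResult, alpha: float = 0.05
) -> bool:
    """True iff the effect is significant with a consistent sign at both S.

    Effects whose signs disagree across density levels are rejected with a
    warning even if both p-values clear ``alpha``.
    """
    sig = result_s25.p < alpha and result_s30.p < alpha
    if not sig:
        return False
    e1 = result_s25.effect_size if result_s25.effect_size is not None else result_s25.value
    e2 = result_s30.effect_size if result_s30.effect_size is not None else result_s30.value
    if np.sign(e1) != np.sign(e2):
        warnings.warn(
            "effect signs disagree across S levels; rejecting under the dual-threshold rule",
            stacklevel=2,
        )
        return False
    return True


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Pearson r with a two-tailed p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("both samples need positive variance")
    res = sps.pearsonr(x, y)
    return StatResult(
        name="pearson_r",
        value=float(res.statistic),
        df=(float(x.size - 2),),
        p=float(res.pvalue),
        effect_size=float(res.statistic),
        effect_name="r",
        extras={"n": int(x.size)},
    )


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask (optional; off by default in the pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        reject[order[: kmax + 1]] = True
    return reject
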