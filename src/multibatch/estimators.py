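"""The four competing treatment-effect analyses for multi-batch rate data.

All four act on a per-animal growth-rate table (columns animal_id, batch_id,
group in {control, treated}, rate) and estimate the treated-minus-control
difference in growth rate (negative under inhibition), but they differ in how
they use the batch structure:

* ``analyze_pooled`` ignores batches: OLS of rate on group, equivalent to the
  equal-variance two-sample t-test.
* ``analyze_fixed`` fits the full factorial fixed-effects model
  (treatment + batch + interaction); the effect is the marginal
  (least-squares) mean difference, batches weighted equally, and significance
  is the type III F-test of the treatment main effect against residual error.
* ``analyze_random`` fits the mixed model with batch and batch-by-treatment
  random effects by REML; the t-test uses Satterthwaite degrees of freedom.
* ``analyze_meta`` is a two-stage random-effects meta-analysis: per-batch
  mean differences T_i with sampling variances v_i^2, REML between-batch
  variance tau^2, inverse-variance pooling and a z-test.

``variance_model_lrt`` is the companion likelihood-ratio test for whether the
residual variance differs across treatment groups (or batches).
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lmm import fit_mixed, membership_matrix

GROUPS = ("control", "treated")


class StructuralError(ValueError):
    """The dataset lacks the group/batch structure the method requires."""


@dataclasses.dataclass(frozen=True)
class MethodResult:
    """Treatment-effect estimate and inference from one analysis method.

    ``df`` is None for the z-based meta-analysis.  ``components`` holds the
    variance components the method estimates: ``sigma2_e`` always;
    ``sigma2_b``/``sigma2_c`` for the random-effects regression; ``tau2`` and
    ``v2_per_batch`` for the meta-analysis.
    """

    method: str
    estimate: float
    se: float
    statistic: float
    df: float | None
    p_value: float
    components: dict[str, Any]
    converged: bool = True
    boundary: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["components"] = dict(self.components)
        return d


def _validate(data: pd.DataFrame) -> pd.DataFrame:
    required = ["animal_id", "batch_id", "group", "rate"]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise StructuralError(f"rate table missing columns: {missing}")
    groups = set(data["group"].unique())
    if not groups <= set(GROUPS):
        raise StructuralError(
            f"group labels must be in {GROUPS}, got {sorted(groups)}"
        )
    if groups != set(GROUPS):
        raise StructuralError(
            f"both groups required, found only {sorted(groups)}"
        )
    if not np.all(np.isfinite(data["rate"].to_numpy(dtype=float))):
        raise StructuralError("non-finite growth rates in the dataset")
    return data


def _cell_stats(data: pd.DataFrame) -> pd.DataFrame:
    """n / mean / variance per batch-by-group cell, erroring on empty cells."""
    stats_ = (
        data.groupby(["batch_id", "group"], sort=True)["rate"]
        .agg(n="size", mean="mean", var=lambda s: s.var(ddof=1))
        .reset_index()
    )
    batches = sorted(data["batch_id"].unique())
    have = {(r.batch_id, r.group) for r in stats_.itertuples()}
    for b in batches:
        for g in GROUPS:
            if (b, g) not in have:
                raise StructuralError(f"empty cell: batch {b!r}, group {g!r}")
    return stats_


def _per_batch_diffs(cells: pd.DataFrame) -> pd.DataFrame:
    wide = cells.pivot(index="batch_id", columns="group")
    diff = wide[("mean", "treated")] - wide[("mean", "control")]
    out = pd.DataFrame(
        {
            "diff": diff,
            "n_control": wide[("n", "control")],
            "n_treated": wide[("n", "treated")],
            "var_control": wide[("var", "control")],
            "var_treated": wide[("var", "treated")],
        }
    )
    return out.sort_index()


def analyze_pooled(data: pd.DataFrame) -> MethodResult:
    """Two-group comparison ignoring batch: equal-variance t-test."""
    data = _validate(data)
    rc = data.loc[data["group"] == "control", "rate"].to_numpy(dtype=float)
    rt = data.loc[data["group"] == "treated", "rate"].to_numpy(dtype=float)
    if len(rc) < 2 or len(rt) < 2:
        raise StructuralError("each group needs >= 2 animals overall")
    n = len(rc) + len(rt)
    est = float(rt.mean() - rc.mean())
    ss = float(((rc - rc.mean()) ** 2).sum() + ((rt - rt.mean()) ** 2).sum())
    df = n - 2
    mse = ss / df
    se = float(np.sqrt(mse * (1.0 / len(rc) + 1.0 / len(rt))))
    t = est / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return MethodResult(
        method="pooled",
        estimate=est,
        se=se,
        statistic=float(t),
        df=float(df),
        p_value=p,
        components={"sigma2_e": mse},
    )


def analyze_fixed(data: pd.DataFrame) -> MethodResult:
    """Fixed-effects factorial model with a type III treatment test.

    For two groups, the type III sum of squares for treatment (sum-to-zero
    contrasts) is exactly the Wald test of the marginal-mean contrast in the
    cell-means parameterisation, so both the estimate and the F statistic are
    computed from cell means directly; the equivalence to the formula-based
    type III ANOVA is enforced in the test suite.
    """
    data = _validate(data)
    cells = _cell_stats(data)
    n_batches = cells["batch_id"].nunique()
    if n_batches < 2:
        raise StructuralError("fixed-effects model requires >= 2 batches")
    diffs = _per_batch_diffs(cells)
    n = len(data)
    resid_df = n - 2 * n_batches
    if resid_df < 1:
        raise StructuralError(
            "zero residual degrees of freedom (need >1 animal in some cell)"
        )
    ss_within = float(
        ((cells["n"] - 1) * cells["var"].fillna(0.0)).sum()
    )
    mse = ss_within / resid_df
    est = float(diffs["diff"].mean())
    se = float(
        np.sqrt(
            mse
            * (1.0 / diffs["n_treated"] + 1.0 / diffs["n_control"]).sum()
        )
        / n_batches
    )
    t = est / se
    p = 2.0 * float(stats.t.sf(abs(t), resid_df))
    return MethodResult(
        method="fixed",
        estimate=est,
        se=se,
        statistic=float(t),
        df=float(resid_df),
        p_value=p,
        components={"sigma2_e": mse},
    )


def analyze_random(data: pd.DataFrame, reml: bool = False) -> MethodResult:
    """Mixed model: treatment fixed; batch and batch-by-treatment random.

    The fit maximises the full (ML) likelihood by default and tests the
    treatment effect with a Satterthwaite-df t-test.  ML is chosen over REML
    because with as few as three batches the REML/Satterthwaite combination
    is measurably conservative under the null (type I error well below the
    nominal level once the interaction component truncates at zero), whereas
    the ML fit keeps the test close to nominal; pass ``reml=True`` for the
    restricted-likelihood variant.
    """
    data = _validate(data)
    cells = _cell_stats(data)
    if cells["batch_id"].nunique() < 2:
        raise StructuralError("random-effects model requires >= 2 batches")
    y = data["rate"].to_numpy(dtype=float)
    treated = (data["group"] == "treated").to_numpy()
    X = np.column_stack([np.ones(len(y)), treated.astype(float)])
    Zb = membership_matrix(data["batch_id"].to_numpy())
    cell_labels = (
        data["batch_id"].astype(str) + ":" + data["group"].astype(str)
    ).to_numpy()
    Zc = membership_matrix(cell_labels)
    fit = fit_mixed(y, X, Zb, Zc, contrast=np.array([0.0, 1.0]), reml=reml)
    t = fit.contrast_estimate / fit.contrast_se
    p = 2.0 * float(stats.t.sf(abs(t), fit.df))
    return MethodResult(
        method="random",
        estimate=fit.contrast_estimate,
        se=fit.contrast_se,
        statistic=float(t),
        df=fit.df,
        p_value=p,
        components={
            "sigma2_b": fit.sigma2_b,
            "sigma2_c": fit.sigma2_c,
            "sigma2_e": fit.sigma2_e,
        },
        converged=fit.converged,
        boundary=fit.boundary,
    )


def _tau2_reml(T: np.ndarray, v: np.ndarray) -> float:
    """REML estimate of the between-batch effect-size variance tau^2."""

    def neg_reml(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = float((w * T).sum() / w.sum())
        return 0.5 * (
            float(np.log(v + tau2).sum())
            + float(np.log(w.sum()))
            + float((w * (T - mu) ** 2).sum())
        )

    upper = 10.0 * (float(np.var(T, ddof=1)) if len(T) > 1 else 0.0) + float(
        v.max()
    )
    if upper <= 0:
        return 0.0
    res = optimize.minimize_scalar(
        neg_reml, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(max(res.x, 0.0))
    # snap to the zero bound when it is at least as good
    if neg_reml(0.0) <= res.fun + 1e-12:
        tau2 = 0.0
    return tau2


def analyze_meta(data: pd.DataFrame) -> MethodResult:
    """Random-effects meta-analysis of per-batch mean differences."""
    data = _validate(data)
    cells = _cell_stats(data)
    if cells["batch_id"].nunique() < 2:
        raise StructuralError("meta-analysis requires >= 2 batches")
    bad = cells[cells["n"] < 2]
    if len(bad):
        r = bad.iloc[0]
        raise StructuralError(
            f"batch {r['batch_id']!r} group {r['group']!r} has n < 2; "
            "per-batch sampling variance is inestimable"
        )
    diffs = _per_batch_diffs(cells)
    T = diffs["diff"].to_numpy(dtype=float)
    v = (
        diffs["var_control"] / diffs["n_control"]
        + diffs["var_treated"] / diffs["n_treated"]
    ).to_numpy(dtype=float)
    tau2 = _tau2_reml(T, v)
    w = 1.0 / (v + tau2)
    est = float((w * T).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    z = est / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return MethodResult(
        method="meta",
        estimate=est,
        se=se,
        statistic=float(z),
        df=None,
        p_value=p,
        components={
            "tau2": tau2,
            "v2_per_batch": dict(zip(diffs.index.astype(str), v.tolist())),
        },
        boundary=bool(tau2 == 0.0),
    )


_ANALYZERS = {
    "pooled": analyze_pooled,
    "fixed": analyze_fixed,
    "random": analyze_random,
    "meta": analyze_meta,
}


def analyze(data: pd.DataFrame, method: str) -> MethodResult:
    """Dispatch to one of the four analyses by name."""
    try:
        fn = _ANALYZERS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(_ANALYZERS)}"
        ) from None
    return fn(data)


def analyze_all(data: pd.DataFrame) -> dict[str, MethodResult]:
    """Run all four analyses on the same dataset."""
    return {name: fn(data) for name, fn in _ANALYZERS.items()}


def _grouping_column(data: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "treatment":
        return data["group"]
    if grouping == "batch":
        return data["batch_id"]
    raise ValueError(f"grouping must be 'treatment' or 'batch', got {grouping!r}")


def _heteroscedastic_loglik(
    y: np.ndarray, mean_idx: np.ndarray, var_idx: np.ndarray, n_var: int,
    equal_variance: bool,
) -> float:
    """ML log-likelihood of a Gaussian model with level-specific means and
    (optionally) level-specific variances, via iterated weighted least squares.

    Means and variances are closed-form for matching groupings; the short
    fixed-point iteration covers mean/variance groupings that cross.
    """
    n = len(y)
    n_mean = int(mean_idx.max()) + 1
    # start from unweighted level means
    mu = np.array([y[mean_idx == k].mean() for k in range(n_mean)])
    for _ in range(200):
        resid = y - mu[mean_idx]
        if equal_variance:
            s2 = np.full(n_var, float((resid**2).mean()))
        else:
            s2 = np.array(
                [float((resid[var_idx == g] ** 2).mean()) for g in range(n_var)]
            )
        if np.any(s2 <= 0):
            raise ValueError("degenerate (zero-variance) level in LRT fit")
        w = 1.0 / s2[var_idx]
        mu_new = np.array(
            [
                float((w[mean_idx == k] * y[mean_idx == k]).sum()
                      / w[mean_idx == k].sum())
                for k in range(n_mean)
            ]
        )
        if np.max(np.abs(mu_new - mu)) < 1e-12 * (1.0 + np.max(np.abs(mu))):
            mu = mu_new
            break
        mu = mu_new
    resid = y - mu[mean_idx]
    if equal_variance:
        s2 = np.full(n_var, float((resid**2).mean()))
    else:
        s2 = np.array(
            [float((resid[var_idx == g] ** 2).mean()) for g in range(n_var)]
        )
    counts = np.bincount(var_idx, minlength=n_var)
    return float(
        -0.5 * n * np.log(2.0 * np.pi)
        - 0.5 * float((counts * np.log(s2)).sum())
        - 0.5 * n
    )


def variance_model_lrt(
    data: pd.DataFrame,
    variance_by: str = "treatment",
    mean_by: str | None = None,
) -> tuple[float, int, float]:
    """Likelihood-ratio test for level-specific vs shared residual variance.

    Both models share the mean structure given by ``mean_by`` (a grand mean
    when None); they differ only in whether the residual variance is common
    or specific to the levels of ``variance_by``.  Returns
    ``(statistic, df, p_value)`` with the chi-squared reference on
    ``df = n_levels - 1``.
    """
    if "rate" not in data.columns:
        raise StructuralError("rate table missing 'rate' column")
    y = data["rate"].to_numpy(dtype=float)
    var_col = _grouping_column(data, variance_by)
    var_levels, var_idx = np.unique(var_col.to_numpy(), return_inverse=True)
    if len(var_levels) < 2:
        raise StructuralError(
            f"variance grouping {variance_by!r} has < 2 levels"
        )
    counts = np.bincount(var_idx)
    if counts.min() < 2:
        lvl = var_levels[int(np.argmin(counts))]
        raise StructuralError(
            f"level {lvl!r} of {variance_by!r} has < 2 observations; "
            "its variance is inestimable"
        )
    if mean_by is None:
        mean_idx = np.zeros(len(y), dtype=int)
    else:
        _, mean_idx = np.unique(
            _grouping_column(data, mean_by).to_numpy(), return_inverse=True
        )
    ll_full = _heteroscedastic_loglik(
        y, mean_idx, var_idx, len(var_levels), equal_variance=False
    )
    ll_null = _heteroscedastic_loglik(
        y, mean_idx, var_idx, len(var_levels), equal_variance=True
    )
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    df = len(var_levels) - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p
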