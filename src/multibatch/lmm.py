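"""REML machinery for the batch / batch-by-treatment mixed model.

The model is ``y = X beta + Zb b + Zc c + e`` with ``b ~ N(0, sigma2_b I)``
(one intercept per batch), ``c ~ N(0, sigma2_c I)`` (one intercept per
batch-by-treatment cell) and ``e ~ N(0, sigma2_e I)``.  Datasets are small
(tens of animals), so everything is done with dense linear algebra:

* the likelihood criterion (REML or ML) is profiled over ``sigma2_e`` and
  minimised over the variance ratios ``gamma = (sigma2_b, sigma2_c) /
  sigma2_e`` with bound constraints at zero, using analytic gradients;
* degrees of freedom for a fixed-effect contrast use the Satterthwaite
  approximation with the expected information matrix of the variance
  parameters, the approach used by mixed-model software for denominator df.

Variance components estimated at the zero bound are reported as boundary
fits, not errors: under a null with no batch-by-treatment heterogeneity the
interaction component sits at zero in roughly half of replicates, which is
expected behaviour for a constrained REML estimate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg, optimize

_BOUNDARY_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class MixedFit:
    """REML fit plus Satterthwaite inference for one contrast."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_b: float
    sigma2_c: float
    sigma2_e: float
    contrast_estimate: float
    contrast_se: float
    df: float
    loglik_reml: float
    converged: bool
    boundary: bool


def _profiled_neg2_loglik(gamma, y, X, Gb, Gc, reml):
    """-2 profiled (RE)ML log-likelihood (up to a constant) and its gradient
    with respect to the variance ratios ``gamma``.

    The residual variance is profiled out: for REML it is the generalised
    residual quadratic form over n - p, for ML over n, and the REML criterion
    carries the extra log-determinant of the GLS normal equations.  Gradients
    use the envelope theorem for the profiled beta and residual variance.
    """
    bad = (np.inf, np.zeros(2))
    n, p = X.shape
    W = np.eye(n) + gamma[0] * Gb + gamma[1] * Gc
    try:
        cho = linalg.cho_factor(W, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return bad
    Wi_y = linalg.cho_solve(cho, y, check_finite=False)
    Wi_X = linalg.cho_solve(cho, X, check_finite=False)
    XtWiX = X.T @ Wi_X
    try:
        beta = linalg.solve(XtWiX, X.T @ Wi_y, assume_a="pos")
        Phi_w = linalg.inv(XtWiX)
    except linalg.LinAlgError:
        return bad
    r = y - X @ beta
    u = linalg.cho_solve(cho, r, check_finite=False)
    quad = float(r @ u)
    if quad <= 0:
        return bad
    logdet_W = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Wi = linalg.cho_solve(cho, np.eye(n), check_finite=False)
    dof = (n - p) if reml else n
    value = logdet_W + dof * np.log(quad / dof)
    grad = np.empty(2)
    for k, Gk in enumerate((Gb, Gc)):
        tr_WiG = float(np.sum(Wi * Gk))
        dquad = -float(u @ Gk @ u)
        grad[k] = tr_WiG + dof * dquad / quad
        if reml:
            WiGWiX = Wi @ Gk @ Wi_X
            grad[k] -= float(np.sum(Phi_w * (X.T @ WiGWiX)))
    if reml:
        sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return bad
        value += logdet_XtWiX
    return value, grad


def fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    Zb: np.ndarray,
    Zc: np.ndarray,
    contrast: np.ndarray,
    reml: bool = True,
) -> MixedFit:
    """Fit the two-variance-component model and test one contrast.

    ``Zb``/``Zc`` are 0/1 membership matrices for batches and
    batch-by-treatment cells.  ``contrast`` is a vector on the fixed effects.
    ``reml=False`` maximises the full (ML) likelihood instead of the
    restricted one; the Satterthwaite machinery then uses the ML information.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom for the mixed model")
    Gb = Zb @ Zb.T
    Gc = Zc @ Zc.T
    c = np.asarray(contrast, dtype=float)

    # two starts guard against ridge-shaped likelihoods; on the small
    # factorial layouts this model sees, both routinely reach the same optimum
    starts = [(0.1, 0.1), (1e-4, 1e-4)]
    best = None
    converged = False
    for g0 in starts:
        res = optimize.minimize(
            _profiled_neg2_loglik,
            x0=np.array(g0),
            args=(y, X, Gb, Gc, reml),
            method="L-BFGS-B",
            jac=True,
            bounds=[(0.0, None), (0.0, None)],
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        converged = converged or bool(res.success)

    gamma = np.maximum(best.x, 0.0)

    # recover the variance components at the optimum
    W = np.eye(n) + gamma[0] * Gb + gamma[1] * Gc
    cho = linalg.cho_factor(W, lower=True, check_finite=False)
    Wi_y = linalg.cho_solve(cho, y, check_finite=False)
    Wi_X = linalg.cho_solve(cho, X, check_finite=False)
    XtWiX = X.T @ Wi_X
    beta = linalg.solve(XtWiX, X.T @ Wi_y, assume_a="pos")
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cho, r, check_finite=False))
    sigma2_e = quad / (n - p) if reml else quad / n
    sigma2_b = float(gamma[0] * sigma2_e)
    sigma2_c = float(gamma[1] * sigma2_e)

    V = sigma2_e * W
    Vi = linalg.inv(V)
    XtViX = X.T @ Vi @ X
    Phi = linalg.inv(XtViX)
    cov_beta = Phi
    est = float(c @ beta)
    var_est = float(c @ Phi @ c)
    se = float(np.sqrt(var_est))

    # Satterthwaite df: 2 f^2 / (g' A g) with f = c'Phi c, g its gradient in
    # theta, A the inverse expected REML information; P is the REML
    # projection matrix.  Components estimated at the zero bound are dropped
    # from theta: on the SD scale (which mixed-model software optimises) the
    # chain-rule factor 2*sd vanishes at zero, so a boundary component
    # contributes nothing and the df adapts toward the residual df.
    P = (Vi - Vi @ X @ Phi @ X.T @ Vi) if reml else Vi
    all_Gs = (Gb, Gc, np.eye(n))
    active = [k for k in range(2) if gamma[k] > _BOUNDARY_TOL] + [2]
    Gs = [all_Gs[k] for k in active]
    m = len(Gs)
    grad = np.empty(m)
    for k, Gk in enumerate(Gs):
        M = Phi @ (X.T @ Vi @ Gk @ Vi @ X) @ Phi
        grad[k] = float(c @ M @ c)
    info = np.empty((m, m))
    PG = [P @ Gk for Gk in Gs]
    for k in range(m):
        for l in range(k, m):
            info[k, l] = info[l, k] = 0.5 * float(np.trace(PG[k] @ PG[l]))
    A = np.linalg.pinv(info)
    denom = float(grad @ A @ grad)
    if denom > 0 and np.isfinite(denom):
        df = 2.0 * var_est**2 / denom
    else:
        df = float(n - p)
    if not np.isfinite(df) or df < 1.0:
        df = 1.0

    dof = (n - p) if reml else n
    loglik = -0.5 * (best.fun + dof * (1.0 + np.log(2.0 * np.pi)))
    boundary = bool(np.any(gamma <= _BOUNDARY_TOL))
    return MixedFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_b=sigma2_b,
        sigma2_c=sigma2_c,
        sigma2_e=sigma2_e,
        contrast_estimate=est,
        contrast_se=se,
        df=float(df),
        loglik_reml=float(loglik),
        converged=converged,
        boundary=boundary,
    )


def membership_matrix(labels: np.ndarray) -> np.ndarray:
    """0/1 matrix mapping observations to the levels of ``labels``."""
    labels = np.asarray(labels)
    levels, idx = np.unique(labels, return_inverse=True)
    Z = np.zeros((labels.shape[0], levels.shape[0]))
    Z[np.arange(labels.shape[0]), idx] = 1.0
    return Z
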