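"""Fast REML/ML fitting of the correlated random-intercept/slope model.

The longitudinal model used throughout the package is

    y_ij = x_ij' beta + b0_i + b1_i t_ij + eps_ij,
    (b0, b1) ~ N(0, G),  eps ~ N(0, sigma^2),

with G a full 2x2 covariance. Writing G = sigma^2 Psi and parameterising
Psi by (log sd0, log sd1, atanh corr), beta and sigma^2 are profiled out
analytically and the criterion is minimised over just three parameters.
Because the random-effect design has two columns, all per-subject
quantities reduce to 2x2 cross-products that are computed once, so each
criterion evaluation is a handful of vectorised einsums; a fit typically
takes tens of milliseconds regardless of optimizer path.

The profile surface can have a local optimum with the slope variance
collapsed to zero; the fitter therefore starts from a method-of-moments
estimate and one deflated fallback start and keeps the better optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

_LOG2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e12


@dataclass
class _Precomp:
    """Per-group cross-products; everything a criterion evaluation needs."""

    A: np.ndarray  # (m, 2, 2)  Z_i' Z_i
    B: np.ndarray  # (m, 2, p)  Z_i' X_i
    c: np.ndarray  # (m, 2)     Z_i' y_i
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    n: int
    p: int
    m: int
    gidx: np.ndarray  # row -> group position


def _precompute(y, X, Z, groups) -> _Precomp:
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, p = X.shape
    _, gidx = np.unique(groups, return_inverse=True)
    m = gidx.max() + 1
    A = np.zeros((m, 2, 2))
    B = np.zeros((m, 2, p))
    c = np.zeros((m, 2))
    np.add.at(A, gidx, np.einsum("ni,nj->nij", Z, Z))
    np.add.at(B, gidx, np.einsum("ni,nj->nij", Z, X))
    np.add.at(c, gidx, Z * y[:, None])
    return _Precomp(
        A=A, B=B, c=c, XtX=X.T @ X, Xty=X.T @ y, yty=float(y @ y),
        n=n, p=p, m=m, gidx=gidx,
    )


def _psi(theta) -> tuple[np.ndarray, float]:
    s0, s1 = np.exp(theta[0]), np.exp(theta[1])
    r = np.tanh(theta[2])
    psi = np.array([[s0 * s0, r * s0 * s1], [r * s0 * s1, s1 * s1]])
    det = s0 * s0 * s1 * s1 * (1.0 - r * r)
    return psi, det


def _solve_blocks(pc: _Precomp, theta):
    """GLS pieces for V = I + Z Psi Z' (Woodbury on 2x2 blocks)."""
    psi, det = _psi(theta)
    if not np.isfinite(det) or det <= 1e-300:
        return None
    pinv = np.array([[psi[1, 1], -psi[0, 1]], [-psi[0, 1], psi[0, 0]]]) / det
    K = pinv[None, :, :] + pc.A
    detK = K[:, 0, 0] * K[:, 1, 1] - K[:, 0, 1] * K[:, 1, 0]
    if not np.all(detK > 0):
        return None
    Kinv = np.empty_like(K)
    Kinv[:, 0, 0] = K[:, 1, 1]
    Kinv[:, 1, 1] = K[:, 0, 0]
    Kinv[:, 0, 1] = -K[:, 0, 1]
    Kinv[:, 1, 0] = -K[:, 1, 0]
    Kinv /= detK[:, None, None]
    logdetV = float(np.sum(np.log(det * detK)))
    XtVX = pc.XtX - np.einsum("mip,mij,mjq->pq", pc.B, Kinv, pc.B)
    XtVy = pc.Xty - np.einsum("mip,mij,mj->p", pc.B, Kinv, pc.c)
    ytVy = pc.yty - np.einsum("mi,mij,mj->", pc.c, Kinv, pc.c)
    return psi, Kinv, logdetV, XtVX, XtVy, ytVy


def _neg2ll(pc: _Precomp, theta, reml: bool) -> float:
    sol = _solve_blocks(pc, theta)
    if sol is None:
        return _PENALTY
    _, _, logdetV, XtVX, XtVy, ytVy = sol
    try:
        L = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return _PENALTY
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-300)
    if reml:
        dof = pc.n - pc.p
        val = (
            dof * np.log(rss / dof) + logdetV
            + 2.0 * np.sum(np.log(np.diag(L))) + dof * (1.0 + _LOG2PI)
        )
    else:
        val = pc.n * np.log(rss / pc.n) + logdetV + pc.n * (1.0 + _LOG2PI)
    return float(val) if np.isfinite(val) else _PENALTY


def _dpsi_dtheta(theta) -> np.ndarray:
    """Derivatives of Psi w.r.t. (log sd0, log sd1, atanh corr): (3, 2, 2)."""
    s0, s1 = np.exp(theta[0]), np.exp(theta[1])
    r = np.tanh(theta[2])
    off = r * s0 * s1
    d = np.empty((3, 2, 2))
    d[0] = [[2 * s0 * s0, off], [off, 0.0]]
    d[1] = [[0.0, off], [off, 2 * s1 * s1]]
    d[2] = (1.0 - r * r) * s0 * s1 * np.array([[0.0, 1.0], [1.0, 0.0]])
    return d


def _neg2ll_grad(pc: _Precomp, theta, reml: bool) -> tuple[float, np.ndarray]:
    """Criterion value and analytic gradient w.r.t. theta.

    With V_i = I + Z_i Psi Z_i' and the GLS residual r, the differentials
    are  d log|V| = tr(dPsi S),  d log|X'V^-1 X| = -tr(dPsi T C^-1 T'),
    d rss = -u' dPsi u,  where S = sum Z'V^-1 Z, T = stacked Z'V^-1 X,
    u = Z'V^-1 r (beta's own derivative vanishes at the GLS optimum).
    """
    sol = _solve_blocks(pc, theta)
    if sol is None:
        return _PENALTY, np.zeros(3)
    _, Kinv, logdetV, XtVX, XtVy, ytVy = sol
    try:
        L = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return _PENALTY, np.zeros(3)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-300)
    dof = pc.n - pc.p if reml else pc.n
    if reml:
        val = (
            dof * np.log(rss / dof) + logdetV
            + 2.0 * np.sum(np.log(np.diag(L))) + dof * (1.0 + _LOG2PI)
        )
    else:
        val = dof * np.log(rss / dof) + logdetV + dof * (1.0 + _LOG2PI)
    if not np.isfinite(val):
        return _PENALTY, np.zeros(3)

    AM = np.einsum("mij,mjk->mik", pc.A, Kinv)   # A_i M_i
    S = pc.A - np.einsum("mij,mjk->mik", AM, pc.A)
    T = pc.B - np.einsum("mij,mjk->mik", AM, pc.B)
    d = pc.c - np.einsum("mip,p->mi", pc.B, beta)        # Z_i' r_i
    u = d - np.einsum("mij,mj->mi", AM, d)               # Z_i' V_i^-1 r_i

    G = S.sum(axis=0)
    U = np.einsum("mi,mj->ij", u, u)
    grad_psi = G - (dof / rss) * U
    if reml:
        Cinv = np.linalg.inv(XtVX)
        grad_psi = grad_psi - np.einsum("mip,pq,mjq->ij", T, Cinv, T)
    dpsi = _dpsi_dtheta(theta)
    grad = np.einsum("ij,kij->k", grad_psi, dpsi)
    return float(val), grad


def _neg2ll_joint(pc: _Precomp, theta, log_s2, reml: bool) -> float:
    """Criterion as a function of (theta, log sigma^2), beta profiled only."""
    sol = _solve_blocks(pc, theta)
    if sol is None:
        return _PENALTY
    _, _, logdetV, XtVX, XtVy, ytVy = sol
    try:
        L = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return _PENALTY
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-300)
    s2 = np.exp(log_s2)
    if reml:
        dof = pc.n - pc.p
        val = (
            dof * (_LOG2PI + log_s2) + logdetV
            + 2.0 * np.sum(np.log(np.diag(L))) + rss / s2
        )
    else:
        val = pc.n * (_LOG2PI + log_s2) + logdetV + rss / s2
    return float(val) if np.isfinite(val) else _PENALTY


def _mom_start(pc: _Precomp, y, X, Z, groups) -> np.ndarray:
    """Method-of-moments start: per-subject lines on OLS residuals."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta0
    Zr = np.zeros((pc.m, 2))
    np.add.at(Zr, pc.gidx, np.asarray(Z, dtype=float) * r[:, None])
    Areg = pc.A + 1e-8 * np.eye(2)[None, :, :]
    u = np.linalg.solve(Areg, Zr[:, :, None])[:, :, 0]
    # within-subject residual variance after removing each subject's line
    rss_within = float(
        r @ r - 2.0 * np.einsum("mi,mi->", u, Zr)
        + np.einsum("mi,mij,mj->", u, pc.A, u)
    )
    dof = max(pc.n - 2 * pc.m, pc.m)
    s2 = max(rss_within / dof, 1e-12)
    sd = np.sqrt(s2)
    sd0 = np.clip(np.std(u[:, 0]), 1e-3 * sd, 1e3 * sd)
    sd1 = np.clip(np.std(u[:, 1]), 1e-3 * sd, 1e3 * sd)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(u[:, 0], u[:, 1])[0, 1]
    corr = float(np.clip(np.nan_to_num(corr), -0.9, 0.9))
    return np.array([np.log(sd0 / sd), np.log(sd1 / sd), np.arctanh(corr)])


@dataclass
class LMMCoreFit:
    """Raw fit of the two-random-effect model (design-matrix level)."""

    beta: np.ndarray
    cov_beta: np.ndarray
    cov_re: np.ndarray        # 2x2 random-effects covariance (data units)
    sigma2: float
    theta: np.ndarray         # (log sd0/sigma, log sd1/sigma, atanh corr)
    llf: float                # log-likelihood of the criterion used
    reml: bool
    converged: bool
    singular: bool            # variance component collapsed to ~0
    resid: np.ndarray         # conditional residuals y - X beta - Z bhat
    ranef: np.ndarray         # (m, 2) predicted random effects
    fitted: np.ndarray        # X beta + Z bhat
    n_obs: int
    n_groups: int
    _pc: _Precomp = field(repr=False)

    @property
    def sigma_e(self) -> float:
        return float(np.sqrt(self.sigma2))

    def neg2ll_joint(self, theta, log_s2) -> float:
        """Criterion at arbitrary (theta, log sigma^2); used for the
        curvature-based uncertainty of variance components."""
        return _neg2ll_joint(self._pc, np.asarray(theta, float), float(log_s2),
                             self.reml)


_BOUNDS = [(-12.0, 12.0), (-12.0, 12.0), (-6.0, 6.0)]


def fit_lmm_core(
    y, X, Z, groups, *, reml: bool = True, start: np.ndarray | None = None,
    n_starts: int = 2,
) -> LMMCoreFit:
    """Fit the model; ``start`` (a theta vector) enables warm starts.

    With a warm start only that single optimisation is run, which is what
    the bootstrap uses; otherwise a method-of-moments start plus a deflated
    fallback guard against the slope-variance-zero local optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    pc = _precompute(y, X, Z, groups)

    # exactly-degenerate data (fixed effects reproduce y to machine
    # precision) leave the variance components unidentified; return the
    # zero-variance OLS solution rather than letting the optimizer wander
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_ols = y - X @ beta_ols
    if float(resid_ols @ resid_ols) <= 1e-20 * max(pc.yty, 1.0):
        dof = pc.n - pc.p if reml else pc.n
        sigma2 = max(float(resid_ols @ resid_ols) / dof, 1e-300)
        cov_beta = sigma2 * np.linalg.pinv(pc.XtX)
        return LMMCoreFit(
            beta=beta_ols, cov_beta=cov_beta, cov_re=np.zeros((2, 2)),
            sigma2=sigma2, theta=np.array([_BOUNDS[0][0], _BOUNDS[1][0], 0.0]),
            llf=np.inf, reml=reml, converged=True, singular=True,
            resid=resid_ols, ranef=np.zeros((pc.m, 2)), fitted=X @ beta_ols,
            n_obs=pc.n, n_groups=pc.m, _pc=pc,
        )

    lo = np.array([b[0] for b in _BOUNDS])
    hi = np.array([b[1] for b in _BOUNDS])

    def _run(th0):
        return minimize(
            lambda th: _neg2ll_grad(pc, th, reml),
            np.clip(th0, lo, hi),
            jac=True, method="L-BFGS-B", bounds=_BOUNDS,
            options=dict(maxiter=150, ftol=1e-11, gtol=1e-7),
        )

    if start is not None:
        best = _run(np.asarray(start, dtype=float))
    else:
        mom = _mom_start(pc, y, X, Z, groups)
        best = _run(mom)
        # a collapsed slope variance can be a local optimum; verify against
        # a restart with the slope sd put back on an interior scale
        if n_starts > 1 and (best.x[1] < -6.0 or not best.success):
            alt = _run(np.array([best.x[0], max(mom[1], np.log(0.3)), best.x[2]]))
            if alt.fun < best.fun:
                best = alt
    theta = best.x
    converged = bool(best.fun < _PENALTY / 2 and np.isfinite(best.fun))

    sol = _solve_blocks(pc, theta)
    if sol is None:  # pragma: no cover - guarded by penalty above
        raise FloatingPointError("variance parameters left the feasible region")
    psi, Kinv, logdetV, XtVX, XtVy, ytVy = sol
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 0.0)
    dof = pc.n - pc.p if reml else pc.n
    sigma2 = max(rss / dof, 1e-300)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    cov_re = sigma2 * psi

    # predicted random effects: bhat_i = (Psi^-1 + A_i)^-1 Z_i' r_i
    r = y - X @ beta
    Zr = np.zeros((pc.m, 2))
    np.add.at(Zr, pc.gidx, Z * r[:, None])
    ranef = np.einsum("mij,mj->mi", Kinv, Zr)
    fitted_re = np.einsum("ni,ni->n", Z, ranef[pc.gidx])
    resid = r - fitted_re

    # degenerate variance components (e.g. noise-free data) are flagged, not
    # raised: the caller decides whether a collapsed component matters
    singular = bool(
        theta[0] <= _BOUNDS[0][0] + 1e-6 or theta[1] <= _BOUNDS[1][0] + 1e-6
    )
    return LMMCoreFit(
        beta=beta, cov_beta=cov_beta, cov_re=cov_re, sigma2=float(sigma2),
        theta=theta, llf=-0.5 * float(best.fun), reml=reml,
        converged=converged, singular=singular, resid=resid, ranef=ranef,
        fitted=X @ beta + fitted_re, n_obs=pc.n, n_groups=pc.m, _pc=pc,
    )


def varcomp_covariance(fit: LMMCoreFit, rel_step: float = 1e-3) -> np.ndarray:
    """Approximate covariance of (theta, log sigma^2) from the criterion's
    curvature (central-difference Hessian of the -2 log criterion / 2)."""
    x0 = np.append(fit.theta, np.log(fit.sigma2))
    k = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1.0)

    def f(x):
        return 0.5 * fit.neg2ll_joint(x[:3], x[3])

    H = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)
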