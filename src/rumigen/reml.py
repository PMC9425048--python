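"""REML estimation of variance components under pedigree animal models.

The model for a vector of records y is

    y = Xb + Z_a a + Z_m m + Z_pe p + e

with direct additive values a ~ N(0, A sigma2_a) structured by the numerator
relationship matrix A, an optional maternal effect m (A-structured dam
genetic effect by default, or i.i.d. dam environmental), an optional
permanent-environment effect for repeated records, and residual e. All such
models have a linear covariance structure V(theta) = sum_k theta_k C_k,
which is what the dense engine below maximises the restricted likelihood
over, by average-information (AI) steps with Levenberg damping, step
halving and a backtracked gradient fallback so the accepted log-likelihood
never decreases.

For the common special case of a single A-structured effect with one record
per animal (and for fully overlapping bivariate designs) the likelihood is
instead maximised in the eigenbasis of A, which is an exact
reparametrisation of the same likelihood and orders of magnitude faster.

Standard errors of heritabilities, repeatabilities and correlations come
from the delta method on the inverse average-information matrix evaluated
at the optimum.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

_PENALTY = 1e30


def significance_flag(estimate: float, se: float) -> bool:
    """True when |estimate| exceeds twice its standard error (strict)."""
    if not np.isfinite(estimate) or not np.isfinite(se) or se <= 0:
        raise ValueError("estimate and positive SE required")
    return bool(abs(estimate) > 2.0 * se)


# ---------------------------------------------------------------------------
# result containers


@dataclasses.dataclass
class VarianceComponents:
    """Fitted variance components with the derived genetic ratios."""

    components: dict[str, float]  #: sigma^2 per term (additive, residual, ...)
    se_components: dict[str, float]
    sigma_p: float  #: phenotypic variance = sum of all fitted components
    h2_direct: float
    h2_direct_se: float
    h2_maternal: float | None
    h2_maternal_se: float | None
    repeatability: float | None
    repeatability_se: float | None
    loglik: float
    converged: bool
    n_iter: int
    cov_theta: np.ndarray
    names: list[str]

    @property
    def significant(self) -> bool:
        return significance_flag(self.h2_direct, self.h2_direct_se)


@dataclasses.dataclass
class CorrelationEstimate:
    """Genetic and phenotypic correlation between a trait pair."""

    traits: tuple[str, str]
    r_g: float
    r_g_se: float
    r_p: float
    r_p_se: float
    boundary: bool  #: |r_g| projected onto [-1, 1]
    G: np.ndarray  #: 2x2 additive covariance
    R: np.ndarray  #: 2x2 residual covariance
    loglik: float
    converged: bool

    @property
    def significant_g(self) -> bool:
        return significance_flag(self.r_g, self.r_g_se)

    @property
    def significant_p(self) -> bool:
        return significance_flag(self.r_p, self.r_p_se)


# ---------------------------------------------------------------------------
# dense linear-covariance-structure engine


@dataclasses.dataclass
class REMLFit:
    names: list[str]
    theta: np.ndarray
    cov_theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    history: list[tuple[int, float]]


def _restricted_loglik(y, X, V):
    """Restricted log-likelihood (constants dropped), or None if V/B not PD."""
    try:
        c = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    vi_y = linalg.cho_solve(c, y, check_finite=False)
    vi_x = linalg.cho_solve(c, X, check_finite=False)
    B = X.T @ vi_x
    sign, logdet_b = np.linalg.slogdet(B)
    if sign <= 0:
        return None
    alpha = np.linalg.solve(B, X.T @ vi_y)
    py = vi_y - vi_x @ alpha
    ll = -0.5 * (logdet_v + logdet_b + float(y @ py))
    return ll, c, vi_x, B, py


def reml_linear_structure(
    y: np.ndarray,
    X: np.ndarray,
    C_list: list[np.ndarray],
    names: list[str],
    theta0: np.ndarray | None = None,
    is_variance: np.ndarray | None = None,
    max_iter: int = 200,
    tol_logl: float = 1e-6,
    tol_theta: float = 1e-4,
    floor_frac: float = 1e-8,
) -> REMLFit:
    """Maximise the restricted likelihood of V(theta) = sum theta_k C_k.

    The last C is conventionally the residual identity. ``is_variance``
    marks parameters floored at ``floor_frac`` times the phenotypic
    variance (covariance parameters are unrestricted; validity is enforced
    through positive-definiteness of V). Convergence: |delta logL| below
    ``tol_logl`` and maximum relative parameter change below ``tol_theta``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    m = len(C_list)
    if is_variance is None:
        is_variance = np.ones(m, dtype=bool)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    vtot = float(np.var(y - X @ beta0, ddof=X.shape[1]))
    if theta0 is None:
        theta0 = np.full(m, vtot / m)
    theta = np.asarray(theta0, dtype=float).copy()
    floor = floor_frac * vtot
    theta[is_variance] = np.maximum(theta[is_variance], floor)

    def build_v(th):
        V = np.zeros((n, n))
        for t, C in zip(th, C_list):
            V += t * C
        return V

    def full_eval(th):
        out = _restricted_loglik(y, X, build_v(th))
        if out is None:
            return None
        ll, c, vi_x, B, py = out
        vi = linalg.cho_solve(c, np.eye(n), check_finite=False)
        P = vi - vi_x @ np.linalg.solve(B, vi_x.T)
        U = np.column_stack([C @ py for C in C_list])
        grad = np.array(
            [-0.5 * (float(np.sum(P * C)) - float(py @ U[:, k])) for k, C in enumerate(C_list)]
        )
        AI = 0.5 * (U.T @ (P @ U))
        return ll, grad, AI

    def ll_only(th):
        out = _restricted_loglik(y, X, build_v(th))
        return None if out is None else out[0]

    state = full_eval(theta)
    if state is None:
        raise ValueError("starting values give a non-positive-definite system")
    ll, grad, AI = state
    history = [(0, ll)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ridge = 1e-8 * max(np.abs(np.diag(AI)).max(), 1.0)
        try:
            delta = np.linalg.solve(AI + ridge * np.eye(m), grad)
        except np.linalg.LinAlgError:
            delta = grad * vtot / max(np.abs(grad).max(), 1e-12)
        accepted = None
        for trial in range(2):
            step = 1.0
            for _ in range(30):
                cand = theta + step * delta
                cand[is_variance] = np.maximum(cand[is_variance], floor)
                ll_new = ll_only(cand)
                if ll_new is not None and ll_new >= ll - 1e-12:
                    accepted = (cand, ll_new)
                    break
                step *= 0.5
            if accepted is not None:
                break
            # fallback: scaled gradient ascent, same backtracking
            delta = grad * vtot / max(np.abs(grad).max(), 1e-12)
        if accepted is None:
            converged = True  # no ascent direction left (boundary)
            break
        new_theta, new_ll = accepted
        rel = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), vtot * 1e-3))
        d_ll = new_ll - ll
        theta = new_theta
        state = full_eval(theta)
        if state is None:  # numerically singular at accepted point
            break
        ll, grad, AI = state
        history.append((it, ll))
        if d_ll < tol_logl and rel < tol_theta:
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations (last logL %.6f)", it, ll)
    try:
        cov_theta = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(AI)
    return REMLFit(list(names), theta, cov_theta, ll, converged, it, history)


# ---------------------------------------------------------------------------
# eigenbasis fast path: one A-structured term, one record per animal


def reml_eigen_additive(y, X, A, xatol: float = 1e-12) -> REMLFit:
    """Exact REML for y = Xb + a + e with a ~ N(0, A sigma2_a).

    Rotating by the eigenvectors of A makes V diagonal, so the likelihood
    profiled over the phenotypic variance is a 1-D function of h2 which is
    maximised by bounded scalar search. Returns theta = (additive,
    residual) with the AI-based covariance evaluated at the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    d, U = np.linalg.eigh(np.asarray(A, dtype=float))
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_profile(h2):
        w = h2 * d + (1.0 - h2)
        Xw = Xt / w[:, None]
        B = Xt.T @ Xw
        sign, logdet_b = np.linalg.slogdet(B)
        if sign <= 0:
            return _PENALTY
        r = Xw.T @ yt
        quad = float(yt @ (yt / w)) - float(r @ np.linalg.solve(B, r))
        if quad <= 0:
            return _PENALTY
        sigma_p = quad / (n - p)
        return 0.5 * ((n - p) * np.log(sigma_p) + float(np.sum(np.log(w))) + logdet_b)

    res = optimize.minimize_scalar(
        neg_profile, bounds=(1e-10, 1.0 - 1e-10), method="bounded", options={"xatol": xatol}
    )
    h2 = float(res.x)
    w = h2 * d + (1.0 - h2)
    Xw = Xt / w[:, None]
    B0 = Xt.T @ Xw
    r = Xw.T @ yt
    quad = float(yt @ (yt / w)) - float(r @ np.linalg.solve(B0, r))
    sigma_p = quad / (n - p)
    theta = np.array([h2 * sigma_p, (1.0 - h2) * sigma_p])

    # AI matrix at the optimum, in the rotated (diagonal) basis
    v = theta[0] * d + theta[1]
    vi_x = Xt / v[:, None]
    B = Xt.T @ vi_x

    def apply_p(u):
        return u / v - vi_x @ np.linalg.solve(B, vi_x.T @ u)

    py = apply_p(yt)
    u_a, u_e = d * py, py
    ai = 0.5 * np.array(
        [
            [float(u_a @ apply_p(u_a)), float(u_a @ apply_p(u_e))],
            [float(u_e @ apply_p(u_a)), float(u_e @ apply_p(u_e))],
        ]
    )
    sign, logdet_b = np.linalg.slogdet(B)
    ll = -0.5 * (float(np.sum(np.log(v))) + logdet_b + float(yt @ py))
    try:
        cov_theta = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(ai)
    return REMLFit(["additive", "residual"], theta, cov_theta, ll, True, res.nfev, [(0, ll)])


# ---------------------------------------------------------------------------
# ratio helpers (delta method)


def _ratio_se(theta, cov, numerator: list[int]) -> float:
    total = float(theta.sum())
    f = float(theta[numerator].sum()) / total
    grad = np.full(len(theta), -f / total)
    grad[numerator] += 1.0 / total
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def _components_result(fit: REMLFit) -> VarianceComponents:
    names = fit.names
    theta = fit.theta
    cov = fit.cov_theta
    idx = {name: k for k, name in enumerate(names)}
    sigma_p = float(theta.sum())
    h2 = float(theta[idx["additive"]] / sigma_p)
    h2_se = _ratio_se(theta, cov, [idx["additive"]])
    h2_m = h2_m_se = None
    if "maternal" in idx:
        h2_m = float(theta[idx["maternal"]] / sigma_p)
        h2_m_se = _ratio_se(theta, cov, [idx["maternal"]])
    rep = rep_se = None
    if "permanent_env" in idx:
        num = [idx[k] for k in ("additive", "maternal", "permanent_env") if k in idx]
        rep = float(theta[num].sum() / sigma_p)
        rep_se = _ratio_se(theta, cov, num)
    se = {
        name: float(np.sqrt(max(cov[k, k], 0.0))) for name, k in idx.items()
    }
    return VarianceComponents(
        components={name: float(theta[k]) for name, k in idx.items()},
        se_components=se,
        sigma_p=sigma_p,
        h2_direct=h2,
        h2_direct_se=h2_se,
        h2_maternal=h2_m,
        h2_maternal_se=h2_m_se,
        repeatability=rep,
        repeatability_se=rep_se,
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
        cov_theta=cov,
        names=names,
    )


# ---------------------------------------------------------------------------
# univariate animal model


def reml_univariate(
    y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray,
    animal_idx: np.ndarray,
    dam_idx: np.ndarray | None = None,
    maternal: str | None = None,
    permanent_env: bool = False,
    **engine_kwargs,
) -> VarianceComponents:
    """Fit a univariate animal model by REML.

    Parameters
    ----------
    y, X
        Records and fixed-effect design (one row per record; animals may
        repeat when ``permanent_env`` models repeated measures).
    A
        Numerator relationship matrix over the pedigree.
    animal_idx
        Position of each record's animal in ``A``.
    dam_idx, maternal
        Dam position per record and maternal structure: ``"genetic"``
        (A-structured dam effect, the default when dam_idx is given) or
        ``"iid"`` (environmental dam effect).
    permanent_env
        Add an i.i.d. between-animal permanent-environment term (repeated
        records).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    animal_idx = np.asarray(animal_idx)
    n = len(y)
    simple = dam_idx is None and not permanent_env and len(np.unique(animal_idx)) == n
    if simple:
        fit = reml_eigen_additive(y, X, A[np.ix_(animal_idx, animal_idx)])
        return _components_result(fit)

    C_list = [A[np.ix_(animal_idx, animal_idx)]]
    names = ["additive"]
    if dam_idx is not None:
        dam_idx = np.asarray(dam_idx)
        structure = maternal or "genetic"
        if structure == "genetic":
            C_list.append(A[np.ix_(dam_idx, dam_idx)])
        elif structure == "iid":
            C_list.append((dam_idx[:, None] == dam_idx[None, :]).astype(float))
        else:
            raise ValueError(f"unknown maternal structure {structure!r}")
        names.append("maternal")
    if permanent_env:
        C_list.append((animal_idx[:, None] == animal_idx[None, :]).astype(float))
        names.append("permanent_env")
    C_list.append(np.eye(n))
    names.append("residual")
    fit = reml_linear_structure(y, X, C_list, names, **engine_kwargs)
    return _components_result(fit)


# ---------------------------------------------------------------------------
# bivariate: eigenbasis engine for fully overlapping designs


def _chol_unpack(x):
    Lg = np.array([[x[0], 0.0], [x[1], x[2]]])
    Lr = np.array([[x[3], 0.0], [x[4], x[5]]])
    return Lg @ Lg.T, Lr @ Lr.T


def reml_eigen_bivariate(Y, X, A):
    """REML for two traits on the same animals, same fixed design.

    Var(y) = G (x) A + R (x) I in the eigenbasis of A decomposes into 2x2
    blocks d_k G + R; the restricted likelihood is maximised over Cholesky
    factors of G and R (Nelder-Mead with a polishing restart), which keeps
    both matrices positive semi-definite by construction.

    Returns (G, R, cov_theta, loglik, converged) with cov_theta the inverse
    AI matrix over theta = (g11, g12, g22, r11, r12, r22).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    d, U = np.linalg.eigh(np.asarray(A, dtype=float))
    d = np.clip(d, 0.0, None)
    Yt = U.T @ Y
    Xt = U.T @ X
    y1, y2 = Yt[:, 0], Yt[:, 1]

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    S = np.cov((Y - X @ beta).T, ddof=p)
    S = S + 1e-8 * np.trace(S) / 2 * np.eye(2)
    L0 = np.linalg.cholesky(S / 2.0)
    x0 = np.array([L0[0, 0], L0[1, 0], L0[1, 1]] * 2)

    def negll(x):
        G, R = _chol_unpack(x)
        v11 = d * G[0, 0] + R[0, 0]
        v12 = d * G[0, 1] + R[0, 1]
        v22 = d * G[1, 1] + R[1, 1]
        det = v11 * v22 - v12**2
        if np.any(det <= 0) or np.any(v11 <= 0):
            return _PENALTY
        ia, ib, ic = v22 / det, -v12 / det, v11 / det
        w1 = ia * y1 + ib * y2
        w2 = ib * y1 + ic * y2
        quad = float(y1 @ w1 + y2 @ w2)
        B11 = Xt.T @ (ia[:, None] * Xt)
        B12 = Xt.T @ (ib[:, None] * Xt)
        B22 = Xt.T @ (ic[:, None] * Xt)
        B = np.block([[B11, B12], [B12, B22]])
        sign, logdet_b = np.linalg.slogdet(B)
        if sign <= 0:
            return _PENALTY
        r = np.concatenate([Xt.T @ w1, Xt.T @ w2])
        quad -= float(r @ np.linalg.solve(B, r))
        return 0.5 * (float(np.sum(np.log(det))) + logdet_b + quad)

    res = optimize.minimize(
        negll, x0, method="Nelder-Mead",
        options={"maxiter": 6000, "xatol": 1e-10, "fatol": 1e-10},
    )
    res = optimize.minimize(  # polishing restart from the first optimum
        negll, res.x, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-11, "fatol": 1e-11},
    )
    G, R = _chol_unpack(res.x)

    # AI matrix over theta = (g11,g12,g22,r11,r12,r22) at the optimum
    v11 = d * G[0, 0] + R[0, 0]
    v12 = d * G[0, 1] + R[0, 1]
    v22 = d * G[1, 1] + R[1, 1]
    det = v11 * v22 - v12**2
    ia, ib, ic = v22 / det, -v12 / det, v11 / det
    B11 = Xt.T @ (ia[:, None] * Xt)
    B12 = Xt.T @ (ib[:, None] * Xt)
    B22 = Xt.T @ (ic[:, None] * Xt)
    B = np.block([[B11, B12], [B12, B22]])

    def apply_vinv(u):
        return np.column_stack([ia * u[:, 0] + ib * u[:, 1], ib * u[:, 0] + ic * u[:, 1]])

    def apply_p(u):
        w = apply_vinv(u)
        s = np.concatenate([Xt.T @ w[:, 0], Xt.T @ w[:, 1]])
        bvec = np.linalg.solve(B, s)
        xb = np.column_stack([Xt @ bvec[:p], Xt @ bvec[p:]])
        return w - apply_vinv(xb)

    py = apply_p(Yt)
    ones = np.ones_like(d)
    u_list = [
        np.column_stack([d * py[:, 0], np.zeros(n)]),         # g11
        np.column_stack([d * py[:, 1], d * py[:, 0]]),        # g12
        np.column_stack([np.zeros(n), d * py[:, 1]]),         # g22
        np.column_stack([ones * py[:, 0], np.zeros(n)]),      # r11
        np.column_stack([ones * py[:, 1], ones * py[:, 0]]),  # r12
        np.column_stack([np.zeros(n), ones * py[:, 1]]),      # r22
    ]
    pu = [apply_p(u) for u in u_list]
    ai = 0.5 * np.array([[float(np.sum(ui * pj)) for pj in pu] for ui in u_list])
    try:
        cov_theta = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(ai)
    ll = -float(res.fun)
    return G, R, cov_theta, ll, bool(res.success or res.fun < _PENALTY)


def _corr_and_se(c12, v1, v2, grad_idx, cov):
    """Correlation c12/sqrt(v1 v2) with delta-method SE.

    ``grad_idx`` maps the positions of (v1, c12, v2) inside the full theta
    vector whose covariance is ``cov``; entries may be lists for summed
    components (phenotypic correlations).
    """
    r = c12 / np.sqrt(v1 * v2)
    grad = np.zeros(cov.shape[0])
    i1, i12, i2 = grad_idx
    for j in np.atleast_1d(i1):
        grad[j] += -r / (2.0 * v1)
    for j in np.atleast_1d(i12):
        grad[j] += 1.0 / np.sqrt(v1 * v2)
    for j in np.atleast_1d(i2):
        grad[j] += -r / (2.0 * v2)
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return float(r), se


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    X: np.ndarray,
    A: np.ndarray,
    animal_idx: np.ndarray,
    traits: tuple[str, str] = ("trait1", "trait2"),
) -> CorrelationEstimate:
    """Genetic and phenotypic correlation between two traits by REML.

    Both traits must be recorded on the same animals with the same fixed
    design (rows aligned). Correlations whose magnitude reaches 1 are
    projected onto the boundary and flagged; duplicated traits are detected
    up front (the restricted likelihood diverges there) and returned as a
    flagged boundary estimate.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    X = np.asarray(X, dtype=float)
    animal_idx = np.asarray(animal_idx)
    A_sub = A[np.ix_(animal_idx, animal_idx)]

    beta1, *_ = np.linalg.lstsq(X, y1, rcond=None)
    beta2, *_ = np.linalg.lstsq(X, y2, rcond=None)
    res_corr = np.corrcoef(y1 - X @ beta1, y2 - X @ beta2)[0, 1]
    if abs(res_corr) > 0.9999:
        logger.warning(
            "traits %s/%s are (anti)identical after fixed effects; returning "
            "boundary correlation",
            *traits,
        )
        uni = reml_eigen_additive(y1, X, A_sub)
        s = float(np.sign(res_corr))
        g = uni.theta[0]
        e = uni.theta[1]
        return CorrelationEstimate(
            traits=traits, r_g=s, r_g_se=0.0, r_p=s, r_p_se=0.0, boundary=True,
            G=np.array([[g, s * g], [s * g, g]]),
            R=np.array([[e, s * e], [s * e, e]]),
            loglik=uni.loglik, converged=True,
        )

    G, R, cov, ll, converged = reml_eigen_bivariate(np.column_stack([y1, y2]), X, A_sub)
    floor = 1e-10 * (np.trace(G) + np.trace(R))
    g11, g22 = max(G[0, 0], floor), max(G[1, 1], floor)
    r_g, r_g_se = _corr_and_se(G[0, 1], g11, g22, ([0], [1], [2]), cov)
    p11 = g11 + R[0, 0]
    p22 = g22 + R[1, 1]
    r_p, r_p_se = _corr_and_se(
        G[0, 1] + R[0, 1], p11, p22, ([0, 3], [1, 4], [2, 5]), cov
    )
    boundary = False
    if abs(r_g) >= 1.0 - 1e-4:
        r_g = float(np.sign(r_g))
        boundary = True
    if abs(r_p) >= 1.0 - 1e-4:
        r_p = float(np.sign(r_p))
        boundary = True
    return CorrelationEstimate(
        traits=traits, r_g=r_g, r_g_se=r_g_se, r_p=r_p, r_p_se=r_p_se,
        boundary=boundary, G=G, R=R, loglik=ll, converged=converged,
    )


# ---------------------------------------------------------------------------
# mixed-model equations (BLUE/BLUP given variance components)


@dataclasses.dataclass
class MixedModelEquations:
    """Henderson's MME for given variance ratios."""

    X: np.ndarray
    Z_list: list[np.ndarray]
    names: list[str]
    lhs: np.ndarray
    rhs: np.ndarray

    def solve(self) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        sol = np.linalg.solve(self.lhs, self.rhs)
        p = self.X.shape[1]
        beta = sol[:p]
        effects = {}
        offset = p
        for name, Z in zip(self.names, self.Z_list):
            q = Z.shape[1]
            effects[name] = sol[offset : offset + q]
            offset += q
        return beta, effects


def build_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    Kinv_list: list[np.ndarray | None],
    variances: list[float],
    residual_variance: float,
    names: list[str] | None = None,
) -> MixedModelEquations:
    """Assemble Henderson's mixed-model equations.

    ``Kinv_list`` holds the inverse covariance structure per random term
    (None = identity, e.g. the sparse A-inverse converted to dense for
    desk-scale problems); each block receives the variance ratio
    lambda_k = residual_variance / variances[k].
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"term{k}" for k in range(len(Z_list))]
    blocks_top = [X.T @ X] + [X.T @ Z for Z in Z_list]
    rows = [blocks_top]
    for i, Zi in enumerate(Z_list):
        row = [Zi.T @ X]
        for j, Zj in enumerate(Z_list):
            block = Zi.T @ Zj
            if i == j:
                lam = residual_variance / variances[i]
                Kinv = Kinv_list[i]
                block = block + lam * (np.eye(Zi.shape[1]) if Kinv is None else np.asarray(Kinv))
            row.append(block)
        rows.append(row)
    lhs = np.block(rows)
    rhs = np.concatenate([X.T @ y] + [Z.T @ y for Z in Z_list])
    return MixedModelEquations(X=X, Z_list=Z_list, names=names, lhs=lhs, rhs=rhs)
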