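"""REML variance-component estimation.

Two entry points:

* :func:`fit_reml_two_components` — the heritability-partition model

      y = 1 mu + g_A + g_X + e,
      g_A ~ N(0, G_A sigma2_A),  g_X ~ N(0, G_X sigma2_X),  e ~ N(0, I sigma2_e),

  fitted by average-information (AI) REML with an EM-REML fallback, dense
  Cholesky linear algebra (cohorts here are desk-scale, n <= ~5000), and
  GCTA-like boundary handling: negative proposals are clamped to
  1e-8 x var(y), and a genetic component clamped three iterations in a row
  is fixed at zero.

* :func:`fit_reml_single_component` — the one-GRM null model used by the
  association scan, solved by eigendecomposition of the GRM and a 1-D
  profile-likelihood search (the EMMA trick), which is both faster and
  more robust than iterating for a single ratio.

Heritabilities are variance ratios of the components; their standard
errors come from the delta method on the inverse AI matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .grm import GRMatrix

__all__ = [
    "VarianceComponents",
    "HeritabilityPartition",
    "SingleComponentFit",
    "fit_reml_two_components",
    "fit_reml_single_component",
    "heritability_from_components",
]


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_x: float
    sigma2_e: float
    se_sigma2_a: float
    se_sigma2_x: float
    se_sigma2_e: float
    loglik: float
    n_iter: int
    converged: bool
    covariance: np.ndarray  # 3x3 sampling covariance of (s2_a, s2_x, s2_e)
    loglik_history: list[float] = field(default_factory=list)
    fixed_at_zero: tuple[bool, bool, bool] = (False, False, False)
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_x": self.sigma2_x,
            "sigma2_e": self.sigma2_e,
            "se_sigma2_a": self.se_sigma2_a,
            "se_sigma2_x": self.se_sigma2_x,
            "se_sigma2_e": self.se_sigma2_e,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "note": self.note,
        }


@dataclass
class HeritabilityPartition:
    h2: float
    h2_aut: float
    h2_x: float
    se_h2_aut: float
    se_h2_x: float

    def to_dict(self) -> dict:
        return {
            "h2": self.h2,
            "h2_aut": self.h2_aut,
            "h2_x": self.h2_x,
            "se_h2_aut": self.se_h2_aut,
            "se_h2_x": self.se_h2_x,
        }


class _State:
    """Cached quantities for one evaluation of the restricted likelihood.

    The log-likelihood needs only the Cholesky factor and two solves, so
    rejected line-search candidates stay cheap; the explicit inverse
    (needed for traces in the score/AI derivatives) is formed lazily with
    LAPACK dpotri at accepted states only.
    """

    __slots__ = ("theta", "ll", "a", "d", "py", "_chol", "_vinv")

    def __init__(self, theta: np.ndarray, y: np.ndarray, mats: list[np.ndarray]):
        n = y.size
        v = theta[-1] * np.eye(n)
        for t, g in zip(theta[:-1], mats):
            v += t * g
        c, info = linalg.lapack.dpotrf(v, lower=1, overwrite_a=1)
        if info != 0:
            raise linalg.LinAlgError("V is not positive definite")
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        rhs = np.column_stack([np.ones(n), y])
        sol = linalg.cho_solve((c, True), rhs, check_finite=False)
        a, vy = sol[:, 0], sol[:, 1]
        d = a.sum()  # 1' V^-1 1
        py = vy - a * (a @ y) / d
        self.theta = theta
        self._chol = c
        self._vinv = None
        self.a = a
        self.d = d
        self.py = py
        self.ll = -0.5 * (logdet_v + np.log(d) + y @ py)

    @property
    def vinv(self) -> np.ndarray:
        if self._vinv is None:
            vi, info = linalg.lapack.dpotri(self._chol, lower=1)
            if info != 0:  # pragma: no cover
                raise linalg.LinAlgError("dpotri failed")
            self._vinv = vi + np.tril(vi, -1).T
        return self._vinv


def _derivatives(
    state: _State, y: np.ndarray, mats: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score vector, AI matrix, and y'P G_i P y for all components (+ residual)."""
    k = len(mats) + 1
    py, vinv, a, d = state.py, state.vinv, state.a, state.d
    gpy = [g @ py for g in mats] + [py]
    pgpy = [vinv @ v - a * (a @ v) / d for v in gpy]
    tr_pg = [
        float((vinv * g).sum() - (a @ g @ a) / d) for g in mats
    ] + [float(np.trace(vinv) - (a @ a) / d)]
    ypgpy = np.array([py @ v for v in gpy])
    score = -0.5 * (np.array(tr_pg) - ypgpy)
    ai = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ai[i, j] = ai[j, i] = 0.5 * (gpy[i] @ pgpy[j])
    return score, ai, ypgpy - np.array(tr_pg)


def fit_reml_two_components(
    y: np.ndarray,
    G_A: GRMatrix,
    G_X: GRMatrix,
    max_iter: int = 200,
    tol_loglik: float = 1e-6,
    tol_param: float = 1e-8,
) -> VarianceComponents:
    """AI-REML fit of (sigma2_A, sigma2_X, sigma2_e) for y = 1 mu + g_A + g_X + e.

    The two GRMs must carry the same samples in the same order as y.
    Convergence requires both |delta logL| < tol_loglik and
    max |delta theta| / var(y) < tol_param (within max_iter, default 200).
    """
    y = np.asarray(y, dtype=float)
    if G_A.sample_ids != G_X.sample_ids:
        raise ValueError("G_A and G_X sample sets/orders differ")
    n = y.size
    if n != G_A.n:
        raise ValueError(f"y has {n} entries but GRMs are {G_A.n} x {G_A.n}")
    if n < 30:
        raise ValueError("need at least 30 samples for a meaningful REML fit")

    mats = [G_A.values, G_X.values]
    vp = float(np.var(y, ddof=1))
    floor = 1e-8 * vp
    theta = np.full(3, vp / 3.0)  # neutral start: equal thirds
    fixed = np.zeros(3, dtype=bool)
    clamp_count = np.zeros(3, dtype=int)
    note = ""

    def _clamp(t: np.ndarray) -> np.ndarray:
        t = t.copy()
        t[fixed] = 0.0
        low = t < floor
        t[low & ~fixed] = floor
        return t, low

    state = _State(theta, y, mats)
    history = [state.ll]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        score, ai, em_term = _derivatives(state, y, mats)
        free = ~fixed
        # proposal: EM on the very first step (robust far from optimum),
        # AI afterwards; EM again whenever the AI system is unusable
        proposals = []
        if n_iter > 1:
            try:
                delta = np.zeros(3)
                delta[free] = linalg.solve(
                    ai[np.ix_(free, free)], score[free], assume_a="pos"
                )
                proposals.append(theta + delta)
            except linalg.LinAlgError:
                pass
        em = theta + theta**2 * em_term / n
        proposals.append(em)

        accepted = None
        for prop in proposals:
            step = prop - theta
            lam = 1.0
            while lam >= 1.0 / 64.0:
                cand, hit_low = _clamp(theta + lam * step)
                try:
                    s = _State(cand, y, mats)
                except linalg.LinAlgError:
                    lam *= 0.5
                    continue
                if s.ll >= state.ll - 1e-10:
                    accepted = (cand, s, hit_low)
                    break
                lam *= 0.5
            if accepted is not None:
                break
        if accepted is None:
            # no uphill step found: we are numerically at the optimum
            converged = True
            break

        new_theta, new_state, hit_low = accepted
        clamp_count = np.where(hit_low & ~fixed, clamp_count + 1, 0)
        newly_fixed = (clamp_count >= 3) & ~fixed
        newly_fixed[2] = False  # keep a floor, never exactly zero residual
        if newly_fixed.any():
            fixed |= newly_fixed
            new_theta = new_theta.copy()
            new_theta[fixed] = 0.0
            new_state = _State(new_theta, y, mats)

        d_ll = abs(new_state.ll - state.ll)
        d_par = np.max(np.abs(new_theta - theta))
        theta, state = new_theta, new_state
        history.append(state.ll)
        if d_ll < tol_loglik and d_par / vp < tol_param:
            converged = True
            break

    # final curvature at the solution
    score, ai, _ = _derivatives(state, y, mats)
    free = ~fixed
    cov = np.zeros((3, 3))
    se = np.zeros(3)
    ai_free = ai[np.ix_(free, free)]
    cond = np.linalg.cond(ai_free)
    if cond > 1e8:
        converged = False
        note = "unidentifiable: AI matrix is singular or near-singular"
        cov_free = np.linalg.pinv(ai_free)
    else:
        cov_free = np.linalg.inv(ai_free)
    cov[np.ix_(free, free)] = cov_free
    se[free] = np.sqrt(np.maximum(np.diag(cov_free), 0.0))
    for i in np.flatnonzero(fixed):
        # boundary component: conditional curvature from the full AI matrix
        se[i] = float(np.sqrt(max(1.0 / ai[i, i], 0.0))) if ai[i, i] > 0 else 0.0
        cov[i, i] = se[i] ** 2

    return VarianceComponents(
        sigma2_a=float(theta[0]),
        sigma2_x=float(theta[1]),
        sigma2_e=float(theta[2]),
        se_sigma2_a=float(se[0]),
        se_sigma2_x=float(se[1]),
        se_sigma2_e=float(se[2]),
        loglik=float(state.ll),
        n_iter=n_iter,
        converged=converged,
        covariance=cov,
        loglik_history=history,
        fixed_at_zero=tuple(bool(b) for b in fixed),
        note=note,
    )


def heritability_from_components(vc: VarianceComponents) -> HeritabilityPartition:
    """h2 = (s2_A + s2_X) / total, h2_AUT = s2_A / total, h2_X = s2_X / total.

    Standard errors for h2_AUT and h2_X via the delta method on the AI
    covariance of the variance components.
    """
    s = vc.sigma2_a + vc.sigma2_x + vc.sigma2_e
    if s <= 0:
        raise ValueError("total variance must be positive")
    h2_aut = vc.sigma2_a / s
    h2_x = vc.sigma2_x / s
    grad_aut = np.array([s - vc.sigma2_a, -vc.sigma2_a, -vc.sigma2_a]) / s**2
    grad_x = np.array([-vc.sigma2_x, s - vc.sigma2_x, -vc.sigma2_x]) / s**2
    c = vc.covariance
    se_aut = float(np.sqrt(max(grad_aut @ c @ grad_aut, 0.0)))
    se_x = float(np.sqrt(max(grad_x @ c @ grad_x, 0.0)))
    return HeritabilityPartition(
        h2=h2_aut + h2_x, h2_aut=h2_aut, h2_x=h2_x, se_h2_aut=se_aut, se_h2_x=se_x
    )


# ---------------------------------------------------------------------------
# single-component null model (for the association scan)
# ---------------------------------------------------------------------------


@dataclass
class SingleComponentFit:
    sigma2_g: float
    sigma2_e: float
    loglik: float
    eigvals: np.ndarray  # eigenvalues of the GRM
    eigvecs: np.ndarray  # corresponding eigenvectors (columns)


def fit_reml_single_component(y: np.ndarray, G: GRMatrix) -> SingleComponentFit:
    """REML for y = 1 mu + g + e with g ~ N(0, G sigma2_g), by eigendecomposition.

    Profiles the restricted likelihood over the ratio delta = sigma2_g /
    sigma2_e on a log grid refined by bounded scalar optimization; the
    eigendecomposition is returned for reuse by the scan.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != G.n:
        raise ValueError("y and GRM dimensions differ")
    lam, u = np.linalg.eigh(G.values)
    lam = np.maximum(lam, 0.0)
    yr = u.T @ y
    or_ = u.T @ np.ones(n)

    def negll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        d = delta * lam + 1.0
        w = 1.0 / d
        mu = (or_ * yr * w).sum() / (or_**2 * w).sum()
        r = yr - mu * or_
        rss = (r**2 * w).sum()
        s2e = rss / (n - 1)
        return 0.5 * (
            (n - 1) * (np.log(2 * np.pi * s2e) + 1)
            + np.log(d).sum()
            + np.log((or_**2 * w).sum())
        )

    grid = np.linspace(-14.0, 8.0, 45)
    vals = [negll(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    delta = float(np.exp(log_delta))
    d = delta * lam + 1.0
    w = 1.0 / d
    mu = (or_ * yr * w).sum() / (or_**2 * w).sum()
    rss = ((yr - mu * or_) ** 2 * w).sum()
    s2e = float(rss / (n - 1))
    if log_delta <= grid[0] + 1e-9:
        delta = 0.0  # boundary: no usable genetic signal
    return SingleComponentFit(
        sigma2_g=delta * s2e,
        sigma2_e=s2e,
        loglik=-float(negll(np.log(delta) if delta > 0 else grid[0])),
        eigvals=lam,
        eigvecs=u,
    )
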