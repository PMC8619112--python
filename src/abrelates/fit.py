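"""Maximum-likelihood estimation for the AbRelaTEs model.

The log-likelihood is

    l(θ) = Σ_i  y_i lp_i − log(1 + exp(lp_i)),    lp_i = m_i · v_i'β*,

with v_i = (1, T_i', x_i')', β* = (μ, τ', β')' and multiplier
m_i = 1 + R_i'δ.  The score has the weighted-residual form familiar from
GLMs; writing a_i = v_i'β*, π_i = φ(lp_i), r_i = y_i − π_i and
w_i = π_i(1 − π_i):

    ∂l/∂β*  = Σ r_i m_i v_i
    ∂l/∂δ   = Σ r_i a_i R_i

and the observed-information blocks (derived from the product form of the
linear predictor; the δ cross blocks carry a first-order residual term in
addition to the usual weighted outer product):

    ∂²l/∂β*∂β*' = −Σ w_i m_i² v_i v_i'
    ∂²l/∂δ∂δ'   = −Σ w_i a_i² R_i R_i'
    ∂²l/∂β*∂δ'  = Σ (r_i − w_i m_i a_i) v_i R_i'

Two fitting strategies are provided:

* ``newton_raphson`` — full Newton on all free parameters, by default in the
  reparameterization δ_j = (e^{η_j} − 1)/(e^{η_j} + 1) which keeps δ inside
  (−1, 1); steps are halved whenever the raw step would decrease the
  log-likelihood, and a ridge is added to near-singular Hessians.
* ``profile_fit_g2`` — for two arms: δ₁ is profiled on an equally-spaced
  grid over [−0.99, 0.99]; at each grid value the model is an ordinary
  logistic regression on the m-scaled design and is maximized by Newton
  (warm-started along the grid); the grid argmax is then polished by one
  full Newton run.

Standard errors come from the observed information (inverse negative
Hessian at the maximum, on the δ scale).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .model import ModelSpecError, Theta, TrialData

__all__ = [
    "FitOptions",
    "FitResult",
    "ConvergenceError",
    "InferenceError",
    "score",
    "hessian",
    "fit",
    "fit_logistic",
    "newton_raphson",
    "profile_fit_g2",
    "wald_inference",
]

SEPARATION_BOUND = 30.0  # |log-odds| beyond this flags quasi-separation


class ConvergenceError(RuntimeError):
    pass


class InferenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs for the maximum-likelihood fit.

    method
        ``"profile_grid"`` (two-arm default): grid-profile δ₁ then polish;
        ``"full_newton"``: joint Newton from a δ=0 warm start (required for
        g > 2).
    grid_points
        Number of equally spaced δ₁ values over [−0.99, 0.99].
    score_tol / loglik_tol
        Convergence is declared when the max-norm of the score (δ scale)
        drops below score_tol or an accepted step improves the
        log-likelihood by less than loglik_tol.
    fix_delta_zero
        Ordinary logistic regression mode (δ ≡ 0).
    fix_mu_zero
        Fit without an intercept (μ fixed at 0, kept in the parameter
        layout).
    use_eta_reparam
        Run full-Newton iterations in η-space so δ stays inside (−1, 1).
    """

    method: str = "profile_grid"
    grid_points: int = 201
    max_iter: int = 100
    score_tol: float = 1e-8
    loglik_tol: float = 1e-10
    fix_delta_zero: bool = False
    fix_mu_zero: bool = False
    use_eta_reparam: bool = True

    def __post_init__(self):
        if self.grid_points < 3:
            raise ModelSpecError("grid_points must be at least 3")
        if self.score_tol <= 0 or self.loglik_tol <= 0:
            raise ModelSpecError("tolerances must be positive")


@dataclass
class FitResult:
    """Estimates plus Wald inference and fitting diagnostics."""

    theta: Theta
    loglik: float
    param_names: list[str]
    estimates: np.ndarray
    cov: np.ndarray | None
    se: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    grid_trace: list[tuple[float, float]] | None = None
    selected_grid_delta: float | None = None
    warnings: list[str] = field(default_factory=list)
    level: float = 0.95

    def summary(self):
        """Coefficient table: variable, coefficient, standard error, p-value."""
        import pandas as pd

        return pd.DataFrame(
            {
                "variable": self.param_names,
                "coefficient": self.estimates,
                "standard_error": self.se,
                "z": self.z,
                "p_value": self.p_value,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def stderr(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])


# ----------------------------------------------------------------- internals


def _blocks(bstar: np.ndarray, delta: np.ndarray, V, R, y):
    """Log-likelihood, score and Hessian blocks at (β*, δ)."""
    m = 1.0 + R @ delta
    a = V @ bstar
    lp = m * a
    pi = expit(lp)
    r = y - pi
    w = pi * (1.0 - pi)
    ll = float(np.sum(y * lp - np.logaddexp(0.0, lp)))
    s_b = V.T @ (r * m)
    s_d = R.T @ (r * a)
    H_bb = -(V * (w * m * m)[:, None]).T @ V
    H_dd = -(R * (w * a * a)[:, None]).T @ R
    H_bd = (V * (r - w * m * a)[:, None]).T @ R
    return ll, s_b, s_d, H_bb, H_bd, H_dd, lp


def score(theta: Theta, data: TrialData) -> np.ndarray:
    """Analytic gradient of the log-likelihood, ordered (μ, τ, β, δ)."""
    V, R = data.design(), data.rel_indicators()
    _, s_b, s_d, *_ = _blocks(theta.beta_star(), theta.delta, V, R, data.y)
    return np.concatenate([s_b, s_d])


def hessian(theta: Theta, data: TrialData) -> np.ndarray:
    """Analytic Hessian of the log-likelihood, ordered (μ, τ, β, δ)."""
    V, R = data.design(), data.rel_indicators()
    _, _, _, H_bb, H_bd, H_dd, _ = _blocks(
        theta.beta_star(), theta.delta, V, R, data.y
    )
    return np.block([[H_bb, H_bd], [H_bd.T, H_dd]])


def _delta_to_eta(delta):
    return np.log1p(delta) - np.log1p(-delta)


def _eta_to_delta(eta):
    return np.tanh(np.clip(eta, -40.0, 40.0) / 2.0)


def _solve_step(H, grad, warnings_out):
    """Newton step H⁻¹ grad with escalating ridge on ill-conditioned H."""
    ridge = 0.0
    eye = np.eye(H.shape[0])
    for _ in range(8):
        try:
            step = np.linalg.solve(H - ridge * eye, grad)
        except np.linalg.LinAlgError:
            step = None
        if step is not None and np.all(np.isfinite(step)):
            if ridge > 0:
                warnings_out.append(f"ridge {ridge:.1e} applied to singular Hessian")
            return step
        ridge = 1e-8 if ridge == 0.0 else ridge * 10.0
        if ridge > 1e-2:
            break
    raise ConvergenceError("Hessian singular even after ridge attempts")


def _newton_loop(objective, psi0, options: FitOptions):
    """Generic damped Newton ascent.

    ``objective(psi) -> (ll, grad, H, score_maxnorm)`` where grad/H are in
    the iterating coordinates and score_maxnorm is measured on the original
    (δ) scale for the convergence test.
    """
    psi = np.asarray(psi0, dtype=float).copy()
    warns: list[str] = []
    ll, grad, H, smax = objective(psi)
    converged = smax < options.score_tol
    it = 0
    while not converged and it < options.max_iter:
        it += 1
        step = _solve_step(H, grad, warns)
        # step-halving: accept only non-decreasing log-likelihood
        alpha, accepted = 1.0, False
        for _ in range(20):
            cand = psi - alpha * step
            try:
                ll_new, grad_new, H_new, smax_new = objective(cand)
            except FloatingPointError:
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            warns.append("step-halving failed to improve the log-likelihood")
            break
        improvement = ll_new - ll
        psi, ll, grad, H, smax = cand, ll_new, grad_new, H_new, smax_new
        if smax < options.score_tol or (
            0.0 <= improvement < options.loglik_tol and alpha == 1.0
        ):
            converged = True
    return psi, ll, converged, it, warns


class _Problem:
    """Free-parameter bookkeeping for one dataset + options."""

    def __init__(self, data: TrialData, options: FitOptions):
        self.data = data
        self.options = options
        self.V = data.design()
        self.R = data.rel_indicators()
        self.g, self.p = data.g, data.p
        q = 1 + (self.g - 1) + self.p
        self.b_idx = np.arange(q) if not options.fix_mu_zero else np.arange(1, q)
        self.free_delta = not options.fix_delta_zero
        names = []
        if not options.fix_mu_zero:
            names.append("mu")
        names += [f"tau{j}" for j in range(1, self.g)]
        if data.covariate_names is not None:
            names += list(data.covariate_names)
        else:
            names += [f"beta{k}" for k in range(1, self.p + 1)]
        if self.free_delta:
            names += [f"delta{j}" for j in range(1, self.g)]
        self.param_names = names

    def full_bstar(self, b_free: np.ndarray) -> np.ndarray:
        q = 1 + (self.g - 1) + self.p
        b = np.zeros(q)
        b[self.b_idx] = b_free
        return b

    def theta(self, b_free: np.ndarray, delta: np.ndarray) -> Theta:
        b = self.full_bstar(b_free)
        return Theta(b[0], b[1 : self.g], b[self.g :], delta)

    def free_estimates(self, theta: Theta) -> np.ndarray:
        vec = [theta.beta_star()[self.b_idx]]
        if self.free_delta:
            vec.append(theta.delta)
        return np.concatenate(vec)

    # -- objectives ---------------------------------------------------------

    def fixed_delta_objective(self, delta: np.ndarray):
        ix = np.ix_(self.b_idx, self.b_idx)

        def obj(b_free):
            ll, s_b, _, H_bb, _, _, _ = _blocks(
                self.full_bstar(b_free), delta, self.V, self.R, self.data.y
            )
            g = s_b[self.b_idx]
            return ll, g, H_bb[ix], float(np.max(np.abs(g)))

        return obj

    def full_objective(self, use_eta: bool):
        nb = self.b_idx.size
        ix = np.ix_(self.b_idx, self.b_idx)

        def obj(psi):
            b_free, dpart = psi[:nb], psi[nb:]
            delta = _eta_to_delta(dpart) if use_eta else dpart
            if np.any(np.abs(delta) >= 1.0):
                return -np.inf, None, None, np.inf
            ll, s_b, s_d, H_bb, H_bd, H_dd, _ = _blocks(
                self.full_bstar(b_free), delta, self.V, self.R, self.data.y
            )
            sb = s_b[self.b_idx]
            Hbb = H_bb[ix]
            Hbd = H_bd[self.b_idx, :]
            smax = float(max(np.max(np.abs(sb)), np.max(np.abs(s_d))))
            if use_eta:
                J = (1.0 - delta**2) / 2.0
                grad = np.concatenate([sb, s_d * J])
                H_ee = (J[:, None] * H_dd * J[None, :]) + np.diag(
                    s_d * (-delta * J)
                )
                H = np.block([[Hbb, Hbd * J[None, :]], [(Hbd * J[None, :]).T, H_ee]])
            else:
                grad = np.concatenate([sb, s_d])
                H = np.block([[Hbb, Hbd], [Hbd.T, H_dd]])
            return ll, grad, H, smax

        return obj

    # -- covariance ---------------------------------------------------------

    def covariance(self, theta: Theta, warns: list[str]):
        """Inverse observed information over the free parameters, δ scale."""
        ll, _, _, H_bb, H_bd, H_dd, lp = _blocks(
            theta.beta_star(), theta.delta, self.V, self.R, self.data.y
        )
        if float(np.max(np.abs(lp))) > SEPARATION_BOUND:
            warns.append(
                "extreme fitted log-odds (|lp| > 30): possible separation"
            )
        ix = np.ix_(self.b_idx, self.b_idx)
        if self.free_delta:
            Hbd = H_bd[self.b_idx, :]
            H = np.block([[H_bb[ix], Hbd], [Hbd.T, H_dd]])
        else:
            H = H_bb[ix]
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            warns.append("observed information not invertible")
            return None
        d = np.diag(cov)
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            warns.append("observed information not positive definite")
            return None
        return cov


def _build_result(prob: _Problem, theta: Theta, ll, converged, n_iter, warns,
                  grid_trace=None, selected_grid_delta=None, level=0.95):
    est = prob.free_estimates(theta)
    cov = prob.covariance(theta, warns)
    k = est.size
    nanv = np.full(k, np.nan)
    res = FitResult(
        theta=theta,
        loglik=ll,
        param_names=list(prob.param_names),
        estimates=est,
        cov=cov,
        se=nanv.copy(),
        z=nanv.copy(),
        p_value=nanv.copy(),
        ci_low=nanv.copy(),
        ci_high=nanv.copy(),
        converged=converged,
        n_iter=n_iter,
        n_obs=prob.data.n,
        grid_trace=grid_trace,
        selected_grid_delta=selected_grid_delta,
        warnings=warns,
        level=level,
    )
    if cov is not None:
        wald_inference(res, level)
    return res


# ------------------------------------------------------------------- public


def wald_inference(fit: FitResult, level: float = 0.95) -> FitResult:
    """Fill standard errors, z statistics, two-sided p-values and Wald CIs.

    SEs are square roots of the diagonal of the inverse observed
    information at the maximum, on the original δ scale.
    """
    if fit.cov is None:
        raise InferenceError(
            "observed information not invertible; refit with the η "
            "reparameterization or a reduced model"
        )
    fit.level = level
    fit.se = np.sqrt(np.diag(fit.cov))
    fit.z = fit.estimates / fit.se
    fit.p_value = 2.0 * norm.sf(np.abs(fit.z))
    zc = norm.ppf(0.5 + level / 2.0)
    fit.ci_low = fit.estimates - zc * fit.se
    fit.ci_high = fit.estimates + zc * fit.se
    return fit


def fit_logistic(data: TrialData, options: FitOptions | None = None) -> FitResult:
    """Ordinary logistic regression (δ fixed at 0) by damped Newton."""
    options = dataclasses.replace(options or FitOptions(), fix_delta_zero=True)
    prob = _Problem(data, options)
    delta = np.zeros(data.g - 1)
    psi0 = np.zeros(prob.b_idx.size)
    psi, ll, conv, it, warns = _newton_loop(
        prob.fixed_delta_objective(delta), psi0, options
    )
    theta = prob.theta(psi, delta)
    return _build_result(prob, theta, ll, conv, it, warns)


def newton_raphson(
    data: TrialData, init: Theta | None = None, options: FitOptions | None = None
) -> FitResult:
    """Joint Newton–Raphson over all free parameters.

    Starts from the δ=0 logistic fit unless ``init`` is given.  With
    ``use_eta_reparam`` (default) iterations run in η-space so δ never
    leaves (−1, 1); accepted steps never decrease the log-likelihood.
    """
    options = options or FitOptions()
    if options.fix_delta_zero:
        return fit_logistic(data, options)
    prob = _Problem(data, options)
    if init is None:
        warm = fit_logistic(data, options)
        init = Theta(warm.theta.mu, warm.theta.tau, warm.theta.beta,
                     np.zeros(data.g - 1))
    b0 = init.beta_star()[prob.b_idx]
    d0 = init.delta
    dpart0 = _delta_to_eta(d0) if options.use_eta_reparam else d0
    psi0 = np.concatenate([b0, dpart0])
    psi, ll, conv, it, warns = _newton_loop(
        prob.full_objective(options.use_eta_reparam), psi0, options
    )
    nb = prob.b_idx.size
    dpart = psi[nb:]
    delta = _eta_to_delta(dpart) if options.use_eta_reparam else dpart
    theta = prob.theta(psi[:nb], delta)
    return _build_result(prob, theta, ll, conv, it, warns)


def profile_fit_g2(data: TrialData, options: FitOptions | None = None) -> FitResult:
    """Two-arm fit: profile δ₁ on a grid, then polish by full Newton.

    For each grid value of δ₁ the remaining coefficients β* = (μ, τ₁, β)
    solve an ordinary logistic problem on the multiplier-scaled design and
    are maximized by Newton, warm-started from the previous grid point.
    The (δ₁, β̂*) pair with the highest log-likelihood is selected (ties
    broken toward smaller |δ₁|) and refined by one full Newton run.
    """
    options = options or FitOptions()
    if data.g != 2:
        raise ModelSpecError("profile grid fitting requires exactly two arms")
    prob = _Problem(data, options)
    grid = np.linspace(-0.99, 0.99, options.grid_points)
    trace: list[tuple[float, float]] = []
    warm = np.zeros(prob.b_idx.size)
    best = None  # (ll, |delta|, delta, bstar)
    warns_all: list[str] = []
    for d in grid:
        delta = np.array([d])
        try:
            psi, ll, conv, _, _ = _newton_loop(
                prob.fixed_delta_objective(delta), warm, options
            )
        except ConvergenceError:
            warns_all.append(f"grid fit failed at delta1={d:.3f}; skipped")
            continue
        if conv:
            warm = psi
            trace.append((float(d), ll))
            key = (ll, -abs(d))
            if best is None or key > (best[0], -abs(best[2])):
                best = (ll, conv, float(d), psi.copy())
        else:
            warns_all.append(f"grid fit did not converge at delta1={d:.3f}; skipped")
    if best is None:
        raise ConvergenceError("every grid fit failed")
    _, _, d_sel, b_sel = best
    init = prob.theta(b_sel, np.array([d_sel]))
    polished = newton_raphson(data, init, options)
    polished.grid_trace = trace
    polished.selected_grid_delta = d_sel
    polished.warnings = warns_all + polished.warnings
    return polished


def fit(data: TrialData, options: FitOptions | None = None) -> FitResult:
    """Fit the AbRelaTEs model, dispatching on options and number of arms.

    Two arms use the grid-profile procedure by default; more than two arms
    (or ``method="full_newton"``) use joint Newton from a δ=0 warm start;
    ``fix_delta_zero`` gives ordinary logistic regression.
    """
    options = options or FitOptions()
    if options.fix_delta_zero:
        return fit_logistic(data, options)
    if options.method == "profile_grid" and data.g == 2:
        return profile_fit_g2(data, options)
    return newton_raphson(data, None, options)
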