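"""Group-based trajectory model for longitudinal binary adherence.

A finite mixture of logistic regressions: subject ``i`` belongs to latent
group ``g`` with probability ``pi_g``; given the group, the monthly binary
indicators ``y_it`` are independent Bernoulli with

    logit p_gt = beta_g0 + beta_g1 * t + beta_g2 * t^2 [+ beta_g3 * t^3]

on raw time ``t = 1..T``.  The marginal log-likelihood

    sum_i log sum_g pi_g prod_t p_gt^y_it (1 - p_gt)^(1 - y_it)

is maximised by multi-start EM (E-step: posterior responsibilities; M-step:
one weighted binomial logistic regression per group on the T period-level
sufficient statistics, plus a closed-form mixing-proportion update) followed
by a bounded quasi-Newton polish of the full parameter vector.

Group labels are made deterministic by canonical ordering: groups are sorted
by descending mean fitted adherence probability over t = 1..T, so group 0 is
always the most adherent trajectory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp, softmax

BETA_CAP = 15.0  # |beta| bound on the logit scale; keeps separated groups finite
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500
DEFAULT_N_STARTS = 20
_SHORT_EM_ITERS = 60  # burn-in length for each random start before picking the best


class IdentifiabilityError(ValueError):
    """Raised when the panel is too short for the requested polynomial order."""


class DegenerateFitWarning(UserWarning):
    """A trajectory group collapsed to (numerically) zero membership."""


@dataclass
class TrajectoryModel:
    """A fitted group-based trajectory model.

    ``beta`` has one row per group (canonical order), ``theta`` are the G-1
    membership logits relative to group 0, ``pi = softmax(0, theta)``.
    ``bic`` is the -2*logL + k*log(N) convention (smaller is better);
    ``bic_nagin`` is logL - (k/2)*log(N) (larger is better).
    """

    n_groups: int
    order: int
    beta: np.ndarray
    theta: np.ndarray
    pi: np.ndarray
    loglik: float
    n_params: int
    bic: float
    bic_nagin: float
    n_subjects: int
    converged: bool
    n_starts_used: int
    loglik_history: list[float] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "order": self.order,
            "beta": self.beta.tolist(),
            "theta": self.theta.tolist(),
            "pi": self.pi.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "bic_nagin": self.bic_nagin,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryModel":
        return cls(
            n_groups=d["n_groups"],
            order=d["order"],
            beta=np.asarray(d["beta"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
            pi=np.asarray(d["pi"], dtype=float),
            loglik=d["loglik"],
            n_params=d["n_params"],
            bic=d["bic"],
            bic_nagin=d["bic_nagin"],
            n_subjects=d["n_subjects"],
            converged=d["converged"],
            n_starts_used=d["n_starts_used"],
        )

    @classmethod
    def from_json(cls, path) -> "TrajectoryModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def time_design(n_periods: int, order: int) -> np.ndarray:
    """T x (order+1) design of raw polynomial time: columns 1, t, t^2, ..."""
    t = np.arange(1, n_periods + 1, dtype=float)
    return np.vander(t, order + 1, increasing=True)


def _validate_panel(panel: np.ndarray) -> np.ndarray:
    y = np.asarray(panel, dtype=float)
    if y.ndim != 2:
        raise ValueError("panel must be an N x T matrix")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("panel entries must be binary (0/1)")
    return y


def _component_loglik(beta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """N x G matrix of per-subject conditional log-likelihoods."""
    X = time_design(y.shape[1], beta.shape[1] - 1)
    eta = beta @ X.T  # G x T
    logp = log_expit(eta)
    logq = log_expit(-eta)
    return y @ logp.T + (1.0 - y) @ logq.T


def log_likelihood(
    beta: np.ndarray, pi: np.ndarray, panel: np.ndarray
) -> float:
    """Mixture log-likelihood of a binary panel, log-sum-exp stabilised."""
    y = _validate_panel(panel)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    pi = np.asarray(pi, dtype=float)
    if y.shape[1] < beta.shape[1]:
        raise IdentifiabilityError(
            f"panel has T={y.shape[1]} periods but the order-"
            f"{beta.shape[1] - 1} polynomial needs at least {beta.shape[1]}"
        )
    L = _component_loglik(beta, y)
    return float(logsumexp(L + np.log(pi), axis=1).sum())


def model_log_likelihood(model: TrajectoryModel, panel: np.ndarray) -> float:
    return log_likelihood(model.beta, model.pi, panel)


def posterior(model: TrajectoryModel, panel: np.ndarray) -> np.ndarray:
    """N x G posterior membership probabilities (rows sum to 1)."""
    y = _validate_panel(panel)
    A = _component_loglik(model.beta, y) + np.log(model.pi)
    return softmax(A, axis=1)


def hard_assign(posteriors: np.ndarray) -> np.ndarray:
    """Modal group per subject; ties resolve to the lowest group index."""
    return np.argmax(posteriors, axis=1)


def predicted_curve(
    model: TrajectoryModel, group: int, t_grid: np.ndarray
) -> np.ndarray:
    """Fitted adherence probability for one group on an arbitrary time grid."""
    if not 0 <= group < model.n_groups:
        raise ValueError(f"group {group} out of range for {model.n_groups} groups")
    t = np.asarray(t_grid, dtype=float)
    X = np.vander(t, model.order + 1, increasing=True)
    return expit(X @ model.beta[group])


def observed_curve(
    panel: np.ndarray, assignments: np.ndarray, n_groups: int | None = None
) -> np.ndarray:
    """G x T observed adherence proportions among hard-assigned members.

    Empty groups yield NaN rows (with a warning), never silent zeros.
    """
    y = _validate_panel(panel)
    assignments = np.asarray(assignments)
    if n_groups is None:
        n_groups = int(assignments.max()) + 1
    out = np.full((n_groups, y.shape[1]), np.nan)
    for g in range(n_groups):
        mask = assignments == g
        if mask.any():
            out[g] = y[mask].mean(axis=0)
        else:
            warnings.warn(
                f"group {g} has no assigned members; observed curve undefined",
                DegenerateFitWarning,
                stacklevel=2,
            )
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _binomial_objective(beta, X, s, n):
    eta = X @ beta
    # sum_t s_t log p_t + (n - s_t) log(1 - p_t)
    return float(s @ log_expit(eta) + (n - s) @ log_expit(-eta))


def _weighted_logistic(
    X: np.ndarray,
    s: np.ndarray,
    n: float,
    beta0: np.ndarray,
    cap: float,
    tol: float = 1e-11,
    max_iter: int = 50,
) -> np.ndarray:
    """Newton ascent (step-halving, box-projected) for a binomial logistic fit
    with T aggregated observations: ``s_t`` successes out of ``n`` trials.

    Returns a beta that never decreases the objective (generalized M-step),
    so EM monotonicity is preserved even when the cap binds.
    """
    if n <= 1e-12:
        return beta0  # empty group: nothing to fit
    beta = beta0.copy()
    f = _binomial_objective(beta, X, s, n)
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (s - n * p)
        w = np.maximum(n * p * (1.0 - p), 1e-12)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / w.sum()
        improved = False
        for _ in range(30):
            cand = np.clip(beta + step, -cap, cap)
            fc = _binomial_objective(cand, X, s, n)
            if fc >= f:
                improved = fc > f + tol * (abs(f) + 1.0)
                beta, f = cand, fc
                break
            step *= 0.5
        else:
            break
        if not improved:
            break
    return beta


def _em(
    y: np.ndarray,
    beta: np.ndarray,
    pi: np.ndarray,
    cap: float,
    tol: float,
    max_iter: int,
):
    """EM iterations; returns (beta, pi, loglik, converged, history)."""
    N, T = y.shape
    X = time_design(T, beta.shape[1] - 1)
    history: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        A = _component_loglik(beta, y) + np.log(pi)
        norm = logsumexp(A, axis=1)
        ll = float(norm.sum())
        history.append(ll)
        if abs(ll - prev) < tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
        R = np.exp(A - norm[:, None])  # responsibilities
        w = R.sum(axis=0)
        pi = np.clip(w / N, 1e-12, None)
        pi = pi / pi.sum()
        S = R.T @ y  # G x T weighted success counts
        for g in range(beta.shape[0]):
            beta[g] = _weighted_logistic(X, S[g], w[g], beta[g], cap)
    return beta, pi, history[-1], converged, history


def _polish(y, beta, theta, cap):
    """Bounded quasi-Newton ascent on the full parameter vector.

    The gradient follows from Fisher's identity: with responsibilities R,
    d/d beta_g = X' (S_g - w_g p_g) and d/d theta_h = w_h - N pi_h.
    """
    G, P = beta.shape
    N, T = y.shape
    X = time_design(T, P - 1)

    def negll_and_grad(x):
        b = x[: G * P].reshape(G, P)
        th = x[G * P:]
        pi = softmax(np.concatenate([[0.0], th]))
        A = _component_loglik(b, y) + np.log(pi)
        norm = logsumexp(A, axis=1)
        ll = norm.sum()
        R = np.exp(A - norm[:, None])
        w = R.sum(axis=0)
        S = R.T @ y
        p = expit(b @ X.T)  # G x T
        gbeta = (S - w[:, None] * p) @ X
        gtheta = w[1:] - N * pi[1:]
        return -ll, -np.concatenate([gbeta.ravel(), gtheta])

    x0 = np.concatenate([beta.ravel(), theta])
    bounds = [(-cap, cap)] * (G * P) + [(-cap, cap)] * (G - 1)
    res = minimize(
        negll_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
    )
    b = res.x[: G * P].reshape(G, P)
    th = res.x[G * P:]
    return b, th, -float(res.fun)


def _canonical_order(beta: np.ndarray, T: int) -> np.ndarray:
    """Sort groups by descending mean fitted adherence over t = 1..T."""
    X = time_design(T, beta.shape[1] - 1)
    mean_p = expit(beta @ X.T).mean(axis=1)
    return np.argsort(-mean_p, kind="stable")


def fit(
    panel: np.ndarray,
    n_groups: int,
    order: int = 2,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    polish: bool = True,
    beta_cap: float = BETA_CAP,
) -> TrajectoryModel:
    """Maximum-likelihood fit of a ``n_groups``-group trajectory model.

    Multi-start strategy: one deterministic start (subjects sorted by mean
    adherence and split into contiguous blocks) plus ``n_starts - 1`` random
    responsibility draws; each start gets a short EM burn-in, the best is run
    to convergence and then polished by bounded L-BFGS-B.  Non-convergence is
    flagged on the returned model, never raised.
    """
    y = _validate_panel(panel)
    N, T = y.shape
    if order not in (1, 2, 3):
        raise ValueError("polynomial order must be 1, 2 or 3")
    if T < order + 1:
        raise IdentifiabilityError(
            f"T={T} periods cannot identify an order-{order} polynomial"
        )
    if N < n_groups:
        raise ValueError(f"need at least {n_groups} subjects for {n_groups} groups")
    rng = np.random.default_rng(seed)
    X = time_design(T, order)
    P = order + 1

    def m_step_from_R(R):
        w = R.sum(axis=0)
        pi = np.clip(w / N, 1e-12, None)
        pi = pi / pi.sum()
        beta = np.zeros((n_groups, P))
        S = R.T @ y
        for g in range(n_groups):
            beta[g] = _weighted_logistic(X, S[g], w[g], beta[g], beta_cap)
        return beta, pi

    # build starting responsibility matrices
    starts = []
    order_idx = np.argsort(y.mean(axis=1), kind="stable")[::-1]
    R0 = np.zeros((N, n_groups))
    for g, block in enumerate(np.array_split(order_idx, n_groups)):
        R0[block, g] = 1.0
    starts.append(R0)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.dirichlet(np.full(n_groups, 0.3), size=N))

    best = None
    for R in starts:
        beta, pi = m_step_from_R(R)
        beta, pi, ll, _, _ = _em(y, beta, pi, beta_cap, tol, _SHORT_EM_ITERS)
        if best is None or ll > best[2]:
            best = (beta, pi, ll)

    beta, pi, _ = best
    beta, pi, ll, converged, history = _em(y, beta, pi, beta_cap, tol, max_iter)

    if polish and n_groups >= 1:
        with np.errstate(divide="ignore"):
            theta = np.log(pi[1:] / pi[0])
        theta = np.clip(np.nan_to_num(theta, neginf=-beta_cap), -beta_cap, beta_cap)
        b2, th2, ll2 = _polish(y, beta, theta, beta_cap)
        if ll2 > ll:
            beta = b2
            pi = softmax(np.concatenate([[0.0], th2]))
            ll = ll2
            history = history + [ll2]

    # canonical ordering and final parameters
    idx = _canonical_order(beta, T)
    beta = beta[idx]
    pi = pi[idx]
    with np.errstate(divide="ignore"):
        theta = np.log(pi[1:] / pi[0])

    if (pi < 1e-8).any():
        warnings.warn(
            "at least one trajectory group has (numerically) zero membership",
            DegenerateFitWarning,
            stacklevel=2,
        )

    k = n_groups * P + (n_groups - 1)
    return TrajectoryModel(
        n_groups=n_groups,
        order=order,
        beta=beta,
        theta=theta,
        pi=pi,
        loglik=ll,
        n_params=k,
        bic=-2.0 * ll + k * np.log(N),
        bic_nagin=ll - 0.5 * k * np.log(N),
        n_subjects=N,
        converged=converged,
        n_starts_used=len(starts),
        loglik_history=history,
    )


__all__ = [
    "TrajectoryModel",
    "IdentifiabilityError",
    "DegenerateFitWarning",
    "time_design",
    "log_likelihood",
    "model_log_likelihood",
    "posterior",
    "hard_assign",
    "predicted_curve",
    "observed_curve",
    "fit",
    "BETA_CAP",
]
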