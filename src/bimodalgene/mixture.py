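"""Maximum-likelihood fitting of unimodal and two-component Gaussian models.

The bimodal model is a mixture of two Gaussians with *unequal* variances,

    f(x) = p1 * N(x; mu1, sigma1) + (1 - p1) * N(x; mu2, sigma2),

fitted by maximum likelihood.  Because the unequal-variance mixture
likelihood is unbounded (a component may collapse onto a single point with
sigma -> 0), all component standard deviations are floored at
``SIGMA_FLOOR_REL`` times the sample standard deviation.

Convergence to the global maximum cannot be certified, so the fit follows
a systematic two-stage scheme: a large factorial grid of plausible
parameter values is scored first (budgeted number of likelihood
evaluations, 200,000 by default), and the top-ranked candidates seed a
Newton-Raphson polish on an unconstrained reparameterisation, with an EM
fallback for starts where Newton diverges.  The procedure is fully
deterministic given the data and the budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    DataError,
    DegenerateDataError,
    NonConvergenceError,
)

#: Relative standard-deviation floor: sigma >= SIGMA_FLOOR_REL * sd(data).
SIGMA_FLOOR_REL = 1e-3

_LOG_2PI = math.log(2.0 * math.pi)

# Default factorial-grid axes (see grid_initialize): 24 quantile positions
# for each mean (mu1 < mu2, endpoints included so near-floor components at
# extreme points are reachable), 10 sigma multipliers per component spanning
# floor-adjacent to above-sample-SD scales, 7 mixing proportions including
# boundary values -> 276 * 100 * 7 = 193,200 mixture evaluations, within
# the default budget of 200,000.
GRID_N_MU = 24
GRID_SIGMA_MULTIPLIERS = (0.0015, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0, 1.5)
GRID_P1 = (0.03, 0.1, 0.3, 0.5, 0.7, 0.9, 0.97)

_NEWTON_MAX_ITER = 200
_NEWTON_GTOL = 1e-8
_EM_TOL = 1e-10
_EM_MAX_ITER = 5000


@dataclass
class UnimodalFit:
    """Single-Gaussian maximum-likelihood fit."""

    mu: float
    sigma: float
    loglik: float


@dataclass
class BimodalFit:
    """Two-component Gaussian fit, canonically ordered so mu1 <= mu2."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    p1: float
    loglik: float
    converged: bool = True
    #: which optimisation path produced the result: "newton", "em", or "grid"
    path: str = "newton"
    n_grid_evals: int = 0

    @property
    def params(self) -> tuple:
        return (self.mu1, self.sigma1, self.mu2, self.sigma2, self.p1)


def sigma_floor(values) -> float:
    """Component-SD floor for this data vector."""
    sd = float(np.std(np.asarray(values, dtype=float)))
    if sd == 0.0:
        raise DegenerateDataError("constant input: sigma floor undefined")
    return SIGMA_FLOOR_REL * sd


def fit_unimodal(values) -> UnimodalFit:
    """Gaussian MLE: sample mean and n-denominator standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DataError(f"need >= 3 values, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input")
    mu = float(x.mean())
    sigma = float(x.std())  # ddof=0: maximum-likelihood estimate
    sigma = max(sigma, sigma_floor(x))
    ll = float(-0.5 * np.sum(((x - mu) / sigma) ** 2) - x.size * (math.log(sigma) + 0.5 * _LOG_2PI))
    return UnimodalFit(mu=mu, sigma=sigma, loglik=ll)


def bimodal_loglik(params, values, floor: float | None = None) -> float:
    """Log-likelihood of the five-parameter mixture at ``params``.

    ``params`` is ``(mu1, sigma1, mu2, sigma2, p1)``.  Raises
    :class:`DataError` if either sigma is below the floor for this data.
    """
    mu1, s1, mu2, s2, p1 = params
    x = np.asarray(values, dtype=float)
    if floor is None:
        floor = sigma_floor(x)
    if s1 < floor or s2 < floor:
        raise DataError(f"sigma below floor {floor:g}")
    if not (0.0 < p1 < 1.0):
        raise DataError("p1 must lie strictly inside (0, 1)")
    lp1 = math.log(p1) - math.log(s1) - 0.5 * _LOG_2PI - 0.5 * ((x - mu1) / s1) ** 2
    lp2 = math.log(1.0 - p1) - math.log(s2) - 0.5 * _LOG_2PI - 0.5 * ((x - mu2) / s2) ** 2
    return float(np.sum(np.logaddexp(lp1, lp2)))


# ---------------------------------------------------------------------------
# Batched likelihood evaluation (used by both the grid and the Newton stencil)
# ---------------------------------------------------------------------------

def _loglik_batch(mu1, s1, mu2, s2, p1, x) -> np.ndarray:
    """Vectorised mixture log-likelihood for K parameter rows at once."""
    x = x[None, :]
    lp1 = (
        np.log(p1)[:, None]
        - np.log(s1)[:, None]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x - mu1[:, None]) / s1[:, None]) ** 2
    )
    lp2 = (
        np.log1p(-p1)[:, None]
        - np.log(s2)[:, None]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x - mu2[:, None]) / s2[:, None]) ** 2
    )
    return np.logaddexp(lp1, lp2).sum(axis=1)


@dataclass
class GridCandidates:
    """Ranked initial-estimate candidates from the factorial grid."""

    candidates: list = field(default_factory=list)  # [(params tuple, loglik)]
    n_evals: int = 0

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)

    def __getitem__(self, i):
        return self.candidates[i]


def _grid_axes(n: int, budget: int):
    """Shrink the default axes until the factorial size fits the budget.

    The sigma and mixing axes give way first: Newton/EM polish travels
    easily along them, whereas the likelihood is multimodal in the
    component means, so mean-grid resolution is kept as long as possible.
    """
    n_mu = GRID_N_MU
    sig = list(GRID_SIGMA_MULTIPLIERS)
    ps = list(GRID_P1)

    def size(n_mu, n_sig, n_p):
        return (n_mu * (n_mu - 1) // 2) * n_sig * n_sig * n_p

    while size(n_mu, len(sig), len(ps)) > budget and len(sig) > 5:
        sig = [sig[0], 0.05, 0.2, 0.5, 1.0]
    while size(n_mu, len(sig), len(ps)) > budget and len(ps) > 5:
        ps = [0.05, 0.2, 0.5, 0.8, 0.95]
    while size(n_mu, len(sig), len(ps)) > budget and n_mu > 8:
        n_mu -= 1
    while size(n_mu, len(sig), len(ps)) > budget and len(sig) > 3:
        sig = [sig[0], 0.2, 1.0]
    while size(n_mu, len(sig), len(ps)) > budget and len(ps) > 3:
        ps = [0.1, 0.5, 0.9]
    while size(n_mu, len(sig), len(ps)) > budget and n_mu > 4:
        n_mu -= 1
    return n_mu, np.asarray(sig), np.asarray(ps)


def grid_initialize(values, budget: int = 200_000, top_k: int = 10) -> GridCandidates:
    """Score a factorial grid of plausible mixture parameters.

    Component means run over ``n_mu`` data quantiles with mu1 < mu2,
    component SDs over multiples of the sample SD, and the mixing
    proportion over a small interior grid.  The axes are shrunk
    deterministically until the total evaluation count fits ``budget``.
    A unimodal-equivalent candidate (both components at the single-Gaussian
    MLE) is always appended so the ranked list never falls below the
    unimodal log-likelihood.
    """
    if budget < 100:
        raise ConfigurationError(f"grid budget must be >= 100, got {budget}")
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input")
    floor = sigma_floor(x)
    sd = float(x.std())

    n_mu, sig_mult, p_grid = _grid_axes(x.size, budget)
    mu_grid = np.quantile(x, np.linspace(0.0, 1.0, n_mu))
    sig_grid = np.maximum(sig_mult * sd, floor)

    i1, i2 = np.triu_indices(n_mu, k=1)
    mu1_pairs, mu2_pairs = mu_grid[i1], mu_grid[i2]  # mu1 < mu2

    # Expand the factorial product (pairs x sigma1 x sigma2 x p1).
    P = mu1_pairs.size
    S = sig_grid.size
    K = P * S * S * p_grid.size
    mu1 = np.repeat(mu1_pairs, S * S * p_grid.size)
    mu2 = np.repeat(mu2_pairs, S * S * p_grid.size)
    s1 = np.tile(np.repeat(sig_grid, S * p_grid.size), P)
    s2 = np.tile(np.repeat(sig_grid, p_grid.size), P * S)
    p1 = np.tile(p_grid, P * S * S)

    # Score the whole grid from precomputed per-component log-densities
    # (each (mu, sigma) combo appears S * n_p times); single precision is
    # ample for ranking starts, the polish stage runs in double.
    comp_ld = np.empty((n_mu * S, x.size), dtype=np.float32)
    for im in range(n_mu):
        z = (x[None, :] - mu_grid[im]) / sig_grid[:, None]
        comp_ld[im * S:(im + 1) * S] = (
            -0.5 * z * z - np.log(sig_grid)[:, None] - 0.5 * _LOG_2PI)
    im1 = np.repeat(i1, S * S * p_grid.size)
    im2 = np.repeat(i2, S * S * p_grid.size)
    is1 = np.tile(np.repeat(np.arange(S), S * p_grid.size), P)
    is2 = np.tile(np.repeat(np.arange(S), p_grid.size), P * S)
    ip = np.tile(np.arange(p_grid.size), P * S * S)
    logp = np.log(p_grid).astype(np.float32)
    log1mp = np.log1p(-p_grid).astype(np.float32)

    lls = np.empty(K, dtype=np.float32)
    chunk = max(1, int(4_000_000 // max(x.size, 1)))
    for lo in range(0, K, chunk):
        hi = min(lo + chunk, K)
        a = comp_ld[im1[lo:hi] * S + is1[lo:hi]] + logp[ip[lo:hi], None]
        b = comp_ld[im2[lo:hi] * S + is2[lo:hi]] + log1mp[ip[lo:hi], None]
        lls[lo:hi] = np.logaddexp(a, b).sum(axis=1)

    # keep the top_k *distinct* candidates: near-duplicates of an already
    # selected start only waste polish iterations
    order = np.argsort(lls)[::-1]
    cands = []
    for i in order[: max(50 * top_k, 500)]:
        cand = (float(mu1[i]), float(s1[i]), float(mu2[i]), float(s2[i]), float(p1[i]))
        dup = any(
            abs(cand[0] - c[0]) < 0.1 * sd
            and abs(cand[2] - c[2]) < 0.1 * sd
            and 0.67 < cand[1] / c[1] < 1.5
            and 0.67 < cand[3] / c[3] < 1.5
            and abs(cand[4] - c[4]) < 0.1
            for c, _ in cands
        )
        if not dup:
            cands.append((cand, float(lls[i])))
        if len(cands) >= top_k:
            break
    # near-floor "spike" candidates can dominate the ranking; make sure at
    # least one moderate-scale two-component start survives for the polish
    moderate = (
        (s1 >= 0.1 * sd) & (s2 >= 0.1 * sd) & (p1 >= 0.1) & (p1 <= 0.9)
    )
    if moderate.any():
        j = int(np.flatnonzero(moderate)[np.argmax(lls[moderate])])
        cand = (float(mu1[j]), float(s1[j]), float(mu2[j]), float(s2[j]), float(p1[j]))
        if cand not in [c for c, _ in cands]:
            cands.append((cand, float(lls[j])))
    # re-score the selected few in double precision
    cands = [(c, bimodal_loglik(c, x, floor=floor)) for c, _ in cands]
    uni = fit_unimodal(x)
    cands.append(((uni.mu, uni.sigma, uni.mu, uni.sigma, 0.5), uni.loglik))
    cands.sort(key=lambda c: -c[1])
    return GridCandidates(candidates=cands, n_evals=int(K))


# ---------------------------------------------------------------------------
# Unconstrained reparameterisation for Newton-Raphson
# ---------------------------------------------------------------------------

def _pack(params, floor):
    mu1, s1, mu2, s2, p1 = params
    s1 = max(s1, floor * (1.0 + 1e-9))
    s2 = max(s2, floor * (1.0 + 1e-9))
    p1 = min(max(p1, 1e-9), 1.0 - 1e-9)
    return np.array(
        [mu1, math.log(s1 - floor + 1e-300), mu2, math.log(s2 - floor + 1e-300),
         math.log(p1 / (1.0 - p1))]
    )


def _unpack(theta, floor):
    mu1, t1, mu2, t2, q = theta
    s1 = floor + math.exp(min(t1, 700.0))
    s2 = floor + math.exp(min(t2, 700.0))
    p1 = 1.0 / (1.0 + math.exp(-max(min(q, 700.0), -700.0)))
    p1 = min(max(p1, 1e-12), 1.0 - 1e-12)
    return mu1, s1, mu2, s2, p1


def _theta_loglik_batch(thetas: np.ndarray, x: np.ndarray, floor: float) -> np.ndarray:
    mu1 = thetas[:, 0]
    s1 = floor + np.exp(np.minimum(thetas[:, 1], 700.0))
    mu2 = thetas[:, 2]
    s2 = floor + np.exp(np.minimum(thetas[:, 3], 700.0))
    p1 = 1.0 / (1.0 + np.exp(-np.clip(thetas[:, 4], -700.0, 700.0)))
    p1 = np.clip(p1, 1e-12, 1.0 - 1e-12)
    return _loglik_batch(mu1, s1, mu2, s2, p1, x)


def _newton_polish(theta0, x, floor):
    """Maximise the mixture log-likelihood by damped Newton-Raphson.

    Gradient and Hessian come from central finite differences evaluated in
    one batched call per iteration.  Returns (theta, loglik, converged).
    """
    d = 5
    theta = np.asarray(theta0, dtype=float).copy()
    f0 = _theta_loglik_batch(theta[None, :], x, floor)[0]
    if not np.isfinite(f0):
        return theta, -np.inf, False

    # stencil offsets: +-h e_i (grad + diag), +-h e_i +- h e_j (off-diag)
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    for _ in range(_NEWTON_MAX_ITER):
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        pts = [theta]
        for i in range(d):
            for s in (+1, -1):
                t = theta.copy()
                t[i] += s * h[i]
                pts.append(t)
        for (i, j) in pairs:
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                t = theta.copy()
                t[i] += si * h[i]
                t[j] += sj * h[j]
                pts.append(t)
        vals = _theta_loglik_batch(np.asarray(pts), x, floor)
        if not np.all(np.isfinite(vals)):
            return theta, f0, False
        fc = vals[0]
        fp = vals[1 : 1 + 2 * d : 2]
        fm = vals[2 : 2 + 2 * d : 2]
        grad = (fp - fm) / (2.0 * h)
        H = np.empty((d, d))
        H[np.arange(d), np.arange(d)] = (fp - 2.0 * fc + fm) / h**2
        off = vals[1 + 2 * d :]
        for k, (i, j) in enumerate(pairs):
            fpp, fpm, fmp, fmm = off[4 * k : 4 * k + 4]
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])

        if np.max(np.abs(grad)) < _NEWTON_GTOL:
            return theta, fc, True

        # Newton direction on the concave problem: solve (-H) step = grad,
        # ridge-damping -H until positive definite.
        ridge = 0.0
        step = None
        for _try in range(8):
            try:
                A = -H + ridge * np.eye(d)
                c = np.linalg.cholesky(A)
                step = np.linalg.solve(A, grad)
                break
            except np.linalg.LinAlgError:
                ridge = max(1e-8, ridge * 10.0 if ridge else np.abs(H).max() * 1e-6)
        if step is None or not np.all(np.isfinite(step)):
            return theta, fc, False

        # backtracking line search on the ascent direction
        new_theta, new_f = None, None
        scale = 1.0
        for _ls in range(12):
            cand = theta + scale * step
            fcand = _theta_loglik_batch(cand[None, :], x, floor)[0]
            if np.isfinite(fcand) and fcand >= fc - 1e-13:
                new_theta, new_f = cand, fcand
                break
            scale *= 0.5
        if new_theta is None:
            return theta, fc, False
        if new_f - fc < 1e-12 and np.max(np.abs(grad)) < 1e-4:
            return new_theta, new_f, True
        if new_f - fc < 1e-13:
            # cannot improve: treat as converged only if gradient is small
            return new_theta, new_f, bool(np.max(np.abs(grad)) < 1e-4)
        theta, f0 = new_theta, new_f
    return theta, f0, False


def _em_polish(params, x, floor):
    """Expectation-maximisation from ``params``; sigmas floored each step."""
    mu1, s1, mu2, s2, p1 = params
    s1, s2 = max(s1, floor), max(s2, floor)
    p1 = min(max(p1, 1e-9), 1 - 1e-9)
    prev = -np.inf
    for _ in range(_EM_MAX_ITER):
        lp1 = math.log(p1) - math.log(s1) - 0.5 * ((x - mu1) / s1) ** 2
        lp2 = math.log(1 - p1) - math.log(s2) - 0.5 * ((x - mu2) / s2) ** 2
        m = np.maximum(lp1, lp2)
        w1 = np.exp(lp1 - m)
        w2 = np.exp(lp2 - m)
        r = w1 / (w1 + w2)
        n1 = r.sum()
        n2 = x.size - n1
        if n1 < 1e-10 or n2 < 1e-10:
            break
        mu1 = float(np.dot(r, x) / n1)
        mu2 = float(np.dot(1 - r, x) / n2)
        s1 = max(math.sqrt(float(np.dot(r, (x - mu1) ** 2) / n1)), floor)
        s2 = max(math.sqrt(float(np.dot(1 - r, (x - mu2) ** 2) / n2)), floor)
        p1 = min(max(float(n1 / x.size), 1e-9), 1 - 1e-9)
        ll = bimodal_loglik((mu1, s1, mu2, s2, p1), x, floor=floor)
        if abs(ll - prev) < _EM_TOL:
            return (mu1, s1, mu2, s2, p1), ll, True
        prev = ll
    return (mu1, s1, mu2, s2, p1), prev, False


def _canonical(params):
    mu1, s1, mu2, s2, p1 = params
    if mu1 > mu2 or (mu1 == mu2 and s1 > s2):
        return (mu2, s2, mu1, s1, 1.0 - p1)
    return params


def fit_bimodal(values, budget: int = 200_000, top_k: int = 10) -> BimodalFit:
    """Fit the unequal-variance two-component Gaussian by grid + Newton.

    The top ``top_k`` grid candidates each seed a Newton-Raphson polish on
    the unconstrained scale (log sigma, logit p1); starts where Newton
    diverges fall back to EM.  The best final log-likelihood wins and the
    result is canonicalised so that mu1 <= mu2.  The returned log-likelihood
    is never below the unimodal fit's (the unimodal-equivalent grid
    candidate guarantees nestedness).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise DataError(f"need >= 10 values, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input")
    floor = sigma_floor(x)
    grid = grid_initialize(x, budget=budget, top_k=top_k)

    best_params, best_ll, best_path, any_ok = None, -np.inf, "grid", False
    for params, g_ll in grid:
        theta0 = _pack(params, floor)
        theta, ll, ok = _newton_polish(theta0, x, floor)
        path = "newton"
        if not ok:
            em_params, em_ll, em_ok = _em_polish(params, x, floor)
            if em_ll >= ll:
                ll, path, ok = em_ll, "em", em_ok
                fitted = em_params
            else:
                fitted = _unpack(theta, floor)
        else:
            fitted = _unpack(theta, floor)
        any_ok = any_ok or ok
        if ll > best_ll:
            best_params, best_ll, best_path = fitted, ll, path

    # never fall below the best raw grid candidate
    g_params, g_ll = grid[0]
    if best_params is None or g_ll > best_ll:
        best_params, best_ll, best_path = g_params, g_ll, "grid"

    if not any_ok and best_path == "grid":
        raise NonConvergenceError(
            "no start converged", best_candidate=(g_params, g_ll)
        )

    mu1, s1, mu2, s2, p1 = _canonical(best_params)
    return BimodalFit(
        mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2, p1=p1,
        loglik=float(best_ll), converged=any_ok, path=best_path,
        n_grid_evals=grid.n_evals,
    )
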