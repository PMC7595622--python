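"""Two-state hidden Markov model for sleep/wake identification.

The observed datum at epoch ``t`` is the log-transformed activity count
``O_t = log(count + 1)``.  The hidden state is sleep (``s1``) or wake
(``s2``).  Emissions are

* sleep: a zero-inflated Gaussian truncated to ``[0, inf)`` — a point mass of
  probability ``alpha`` at exactly 0 (epochs with no movement at all) mixed
  with the truncated-normal density, so

  ``b1(0) = alpha + (1 - alpha) * phi(-mu1/s1)/s1 / (1 - Phi(-mu1/s1))``
  ``b1(k) = (1 - alpha) * phi((k-mu1)/s1)/s1 / (1 - Phi(-mu1/s1))``

* wake: a plain Gaussian, ``b2(k) = phi((k - mu2)/s2) / s2``.

``emission_sleep`` evaluates the closed form above, which mixes the zero mass
with the density value at 0.  The fitting/decoding likelihood keeps the two
strictly apart — a zero under sleep contributes the mass ``alpha`` alone —
because the mixed form has no finite maximizer (see ``_log_emissions``); away
from zero the conventions coincide.

Fitting is per individual by Baum-Welch (EM); decoding by Viterbi.  All
recursions run in log space, so sequences of 10^5-10^6 epochs pose no
underflow risk.  Missing epochs inside a segment contribute an emission
factor of 1 (they are marginalized out); gaps longer than ``max_gap_minutes``
split the record into independent segments that share one parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .io import EpochSeries

__all__ = [
    "HMMParams",
    "StateSequence",
    "FitDiagnostics",
    "FitConfig",
    "log_transform",
    "emission_sleep",
    "emission_wake",
    "forward_backward",
    "baum_welch",
    "viterbi",
    "fit_individual",
    "auto_init",
    "split_segments",
    "write_state_csv",
    "write_params_csv",
]

SLEEP, WAKE, MISSING = 0, 1, -1

_LOG_ZERO = -1e30  # effective log(0) that survives arithmetic


def _safe_log(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, _LOG_ZERO)
    np.log(p, out=out, where=p > 0)
    return out


@dataclass
class HMMParams:
    """Full parameter set {A, B, Pi} of the sleep/wake HMM."""

    a: np.ndarray  # 2x2 row-stochastic transition matrix
    alpha_zero: float  # probability of extra zeros in the sleep state
    mu_sleep: float
    sigma_sleep: float
    mu_wake: float
    sigma_wake: float
    pi: np.ndarray  # initial state probabilities (sleep, wake)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.a.shape != (2, 2) or not np.allclose(self.a.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if self.pi.shape != (2,) or not math.isclose(float(self.pi.sum()), 1.0, abs_tol=1e-10):
            raise ValueError("pi must be a length-2 probability vector")
        if np.any(self.a < 0) or np.any(self.pi < 0):
            raise ValueError("probabilities must be non-negative")
        if not 0.0 <= self.alpha_zero <= 1.0:
            raise ValueError("alpha_zero must lie in [0, 1]")
        if self.sigma_sleep <= 0 or self.sigma_wake <= 0:
            raise ValueError("emission standard deviations must be positive")


@dataclass
class StateSequence:
    """Decoded per-epoch labels: 0 = sleep, 1 = wake, -1 = missing."""

    states: np.ndarray
    log_joint: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)

    def to_labels(self) -> np.ndarray:
        return np.array(["S", "W", "NA"])[np.where(self.states == MISSING, 2, self.states)]


@dataclass
class FitDiagnostics:
    log_likelihood_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


@dataclass
class FitConfig:
    """Options controlling per-individual fitting."""

    tol: float = 1e-6
    max_iter: int = 500
    min_epochs: int = 100
    max_gap_minutes: float = 60.0
    agg_minutes: float | None = None  # optional pre-aggregation of counts


# ---------------------------------------------------------------------------
# observations


def log_transform(counts) -> np.ndarray:
    """Map activity counts to observations O_t = log(count + 1).

    NaN (missing) propagates.  Raises on negative counts.
    """
    counts = np.asarray(counts, dtype=float)
    observed = counts[~np.isnan(counts)]
    if observed.size and np.any(observed < 0):
        raise ValueError("activity counts must be non-negative")
    return np.log1p(counts)


# ---------------------------------------------------------------------------
# emissions


def _trunc_log_norm_const(mu: float, sigma: float) -> float:
    """log of 1 - Phi(-mu/sigma), the mass a N(mu, sigma) keeps on [0, inf)."""
    return norm.logsf(-mu / sigma)


def emission_sleep(o, alpha_zero: float, mu_sleep: float, sigma_sleep: float):
    """Zero-inflated truncated-Gaussian emission b1(o) for the sleep state.

    At o == 0 returns mass + density, alpha + (1-alpha)*f_TN(0); elsewhere the
    truncated-normal density (1-alpha)*f_TN(o).  Vectorized over ``o``.
    """
    if sigma_sleep <= 0:
        raise ValueError("sigma_sleep must be positive")
    if not 0.0 <= alpha_zero <= 1.0:
        raise ValueError("alpha_zero must lie in [0, 1]")
    o = np.asarray(o, dtype=float)
    log_z = _trunc_log_norm_const(mu_sleep, sigma_sleep)
    dens = np.exp(norm.logpdf(o, mu_sleep, sigma_sleep) - log_z)
    out = (1.0 - alpha_zero) * dens
    out = np.where(o == 0.0, out + alpha_zero, out)
    return out if out.ndim else float(out)


def emission_wake(o, mu_wake: float, sigma_wake: float):
    """Gaussian emission b2(o) for the wake state (vectorized)."""
    if sigma_wake <= 0:
        raise ValueError("sigma_wake must be positive")
    o = np.asarray(o, dtype=float)
    out = norm.pdf(o, mu_wake, sigma_wake)
    return out if out.ndim else float(out)


def _log_emissions(obs: np.ndarray, params: HMMParams) -> np.ndarray:
    """T x 2 matrix of log b_state(o_t); missing epochs get log 1 = 0.

    In the likelihood that the EM maximizes, a zero observation under sleep
    contributes the point mass alpha alone: a continuous truncated normal
    produces an exact zero with probability zero, and adding its density
    value on top of the mass (as the closed-form ``emission_sleep`` does for
    the band emission) makes the likelihood unbounded — the density can spike
    at the origin and swallow the zeros, destroying the zero-inflation
    estimate.  Away from zero the two conventions agree exactly.
    """
    T = obs.size
    le = np.zeros((T, 2))
    seen = ~np.isnan(obs)
    o = obs[seen]
    zeros = o == 0.0
    log_z = _trunc_log_norm_const(params.mu_sleep, params.sigma_sleep)
    with np.errstate(divide="ignore"):
        sleep = np.where(
            zeros,
            _safe_log(np.array(params.alpha_zero)),
            _safe_log(np.array(1.0 - params.alpha_zero))
            + norm.logpdf(o, params.mu_sleep, params.sigma_sleep)
            - log_z,
        )
    le[seen, SLEEP] = sleep
    le[seen, WAKE] = norm.logpdf(o, params.mu_wake, params.sigma_wake)
    return np.maximum(le, _LOG_ZERO)


def _check_obs(obs) -> np.ndarray:
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("observation sequence must be a non-empty 1-D array")
    if not np.any(~np.isnan(obs)):
        raise ValueError("observation sequence is entirely missing")
    if np.nanmin(obs) < 0:
        raise ValueError("observations are log(count+1) and must be >= 0")
    return obs


# ---------------------------------------------------------------------------
# forward-backward (E-step), log-space


def forward_backward(obs, params: HMMParams):
    """Posterior state and transition probabilities given the parameters.

    Returns ``(log_likelihood, gamma, xi)`` where ``gamma`` is T x 2 with
    ``gamma[t, i] = P(X_t = i | O, params)`` and ``xi`` is (T-1) x 2 x 2 with
    ``xi[t, i, j] = P(X_t = i, X_{t+1} = j | O, params)``.
    """
    obs = _check_obs(obs)
    le = _log_emissions(obs, params)
    T = obs.size
    la = _safe_log(params.a)
    lpi = _safe_log(params.pi)

    log_alpha = np.empty((T, 2))
    log_alpha[0] = lpi + le[0]
    for t in range(1, T):
        prev = log_alpha[t - 1]
        log_alpha[t, 0] = le[t, 0] + np.logaddexp(prev[0] + la[0, 0], prev[1] + la[1, 0])
        log_alpha[t, 1] = le[t, 1] + np.logaddexp(prev[0] + la[0, 1], prev[1] + la[1, 1])
    loglik = float(np.logaddexp(log_alpha[-1, 0], log_alpha[-1, 1]))
    if not np.isfinite(loglik):
        raise FloatingPointError("non-finite log-likelihood in forward pass")

    log_beta = np.zeros((T, 2))
    for t in range(T - 2, -1, -1):
        nxt = log_beta[t + 1] + le[t + 1]
        log_beta[t, 0] = np.logaddexp(la[0, 0] + nxt[0], la[0, 1] + nxt[1])
        log_beta[t, 1] = np.logaddexp(la[1, 0] + nxt[0], la[1, 1] + nxt[1])

    gamma = np.exp(log_alpha + log_beta - loglik)
    gamma /= gamma.sum(axis=1, keepdims=True)

    if T > 1:
        lg = (
            log_alpha[:-1, :, None]
            + la[None, :, :]
            + (le[1:] + log_beta[1:])[:, None, :]
            - loglik
        )
        xi = np.exp(lg)
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = np.empty((0, 2, 2))
    return loglik, gamma, xi


# ---------------------------------------------------------------------------
# M-step pieces


def _weighted_truncnorm_mle(
    s0: float, s1: float, s2: float, mu0: float, sigma0: float
) -> tuple[float, float]:
    """Maximize the weighted log-likelihood of N(mu, sigma) truncated to [0, inf).

    ``s0, s1, s2`` are the weighted count, sum and sum of squares of the data.
    Starts from a moment-corrected guess and the current parameters and keeps
    whichever Nelder-Mead refinement scores best; never returns a point worse
    than (mu0, sigma0), so the enclosing EM step is monotone.
    """
    if s0 <= 1e-12:
        return mu0, sigma0
    m = s1 / s0
    v = max(s2 / s0 - m * m, 1e-8)

    def nll(x):
        mu, log_sig = x
        sig = math.exp(log_sig)
        quad = (s2 - 2.0 * mu * s1 + mu * mu * s0) / (2.0 * sig * sig)
        return s0 * (log_sig + _trunc_log_norm_const(mu, sig)) + quad

    # moment start: undo the truncation shift via the inverse Mills ratio at
    # the current parameters, then refine numerically
    z = -mu0 / sigma0
    mills = math.exp(norm.logpdf(z) - norm.logsf(z))
    mu_guess = m - sigma0 * mills
    starts = [(mu0, math.log(sigma0)), (mu_guess, 0.5 * math.log(v))]
    best_x, best_f = starts[0], nll(starts[0])
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, res.fun
    mu, sigma = float(best_x[0]), float(math.exp(best_x[1]))
    if not (np.isfinite(mu) and np.isfinite(sigma) and sigma > 0):
        return mu0, sigma0
    return mu, max(sigma, 1e-4)


def _m_step(segments, gammas, xis, params: HMMParams) -> HMMParams:
    xi_sum = sum(x.sum(axis=0) for x in xis) if any(x.size for x in xis) else np.zeros((2, 2))
    gamma_trans = sum(g[:-1].sum(axis=0) for g in gammas)
    if np.all(xi_sum == 0):
        a = params.a
    else:
        a = xi_sum / np.maximum(gamma_trans, 1e-300)[:, None]
        a /= a.sum(axis=1, keepdims=True)
    pi = np.mean([g[0] for g in gammas], axis=0)
    pi = np.clip(pi, 1e-12, None)
    pi /= pi.sum()

    obs = np.concatenate([np.asarray(o, dtype=float) for o in segments])
    gamma = np.vstack(gammas)
    seen = ~np.isnan(obs)
    o, g = obs[seen], gamma[seen]

    # wake state: weighted Gaussian moments
    w2 = g[:, WAKE]
    s0w = w2.sum()
    mu2 = float((w2 * o).sum() / s0w) if s0w > 0 else params.mu_wake
    var2 = float((w2 * (o - mu2) ** 2).sum() / s0w) if s0w > 0 else params.sigma_wake**2
    sigma2 = max(math.sqrt(max(var2, 0.0)), 1e-4)

    # sleep state: zeros belong to the point mass (a continuous truncated
    # normal produces an exact 0 with probability 0), positives drive the
    # weighted truncated-normal MLE.  Splitting zeros fractionally against the
    # density value f_TN(0) makes the mixed mass+density likelihood unbounded
    # (the TN can spike at 0 and swallow the zeros), so the hard split is the
    # statistically sound update.
    w1 = g[:, SLEEP]
    zeros = o == 0.0
    s0s = w1.sum()
    if s0s <= 0:
        alpha, mu1, sigma1 = params.alpha_zero, params.mu_sleep, params.sigma_sleep
    else:
        alpha = float(w1[zeros].sum() / s0s)
        alpha = min(max(alpha, 0.0), 1.0)
        w_tn = np.where(zeros, 0.0, w1)
        s0 = float(w_tn.sum())
        s1 = float((w_tn * o).sum())
        s2 = float((w_tn * o * o).sum())
        mu1, sigma1 = _weighted_truncnorm_mle(s0, s1, s2, params.mu_sleep, params.sigma_sleep)

    return HMMParams(a=a, alpha_zero=alpha, mu_sleep=mu1, sigma_sleep=sigma1,
                     mu_wake=mu2, sigma_wake=sigma2, pi=pi)


# ---------------------------------------------------------------------------
# initialization and label convention


def auto_init(segments) -> HMMParams:
    """Deterministic starting point from a 1-D two-means split of the data.

    The lower cluster seeds the sleep emission (its zero fraction seeds the
    zero-inflation mass), the upper cluster seeds the wake emission.
    """
    obs = np.concatenate([np.asarray(o, dtype=float) for o in segments])
    o = obs[~np.isnan(obs)]
    lo, hi = np.quantile(o, [0.1, 0.9])
    if hi <= lo:
        lo, hi = float(o.min()), float(o.max()) + 1.0
    c = np.array([lo, hi], dtype=float)
    for _ in range(100):
        assign = np.abs(o[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([o[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)])
        if np.allclose(new, c, atol=1e-10):
            break
        c = new
    low, high = o[assign == 0], o[assign == 1]
    if low.size == 0 or high.size == 0:  # degenerate: no separation
        low = high = o
    alpha = float(np.mean(low == 0.0))
    nz = low[low > 0]
    mu1 = float(nz.mean()) if nz.size else 0.1
    sigma1 = max(float(nz.std()) if nz.size > 1 else 0.5, 0.05)
    mu2 = float(high.mean())
    sigma2 = max(float(high.std()), 0.05)
    if mu1 >= mu2:
        mu1 = mu2 - 0.5
    return HMMParams(
        a=np.array([[0.95, 0.05], [0.05, 0.95]]),
        alpha_zero=min(alpha, 0.95),
        mu_sleep=mu1,
        sigma_sleep=sigma1,
        mu_wake=mu2,
        sigma_wake=sigma2,
        pi=np.array([0.5, 0.5]),
    )


def _enforce_labels(params: HMMParams) -> HMMParams:
    """Relabel states so the sleep mean is below the wake mean.

    EM can in principle converge with the state roles reversed; the swap
    exchanges means, SDs, transition rows/columns and initial probabilities.
    The zero-inflation mass stays attached to the (new) sleep state, since by
    convention it models motionless epochs.
    """
    if params.mu_sleep < params.mu_wake:
        return params
    perm = [1, 0]
    return HMMParams(
        a=params.a[np.ix_(perm, perm)],
        alpha_zero=params.alpha_zero,
        mu_sleep=params.mu_wake,
        sigma_sleep=params.sigma_wake,
        mu_wake=params.mu_sleep,
        sigma_wake=params.sigma_sleep,
        pi=params.pi[perm],
    )


# ---------------------------------------------------------------------------
# Baum-Welch


def baum_welch(obs, init="auto", tol: float = 1e-6, max_iter: int = 500):
    """Fit the HMM by EM on one sequence or a list of segments sharing params.

    Returns ``(HMMParams, FitDiagnostics)``.  The observed-data log-likelihood
    is non-decreasing across iterations; convergence is declared when its
    relative change falls below ``tol``.  Non-convergence is reported in the
    diagnostics, not raised.
    """
    segments = obs if isinstance(obs, (list, tuple)) else [obs]
    segments = [_check_obs(s) for s in segments]
    params = auto_init(segments) if isinstance(init, str) and init == "auto" else init

    diag = FitDiagnostics()
    prev_ll = -np.inf
    for it in range(max_iter):
        ll = 0.0
        gammas, xis = [], []
        for seg in segments:
            try:
                l, g, x = forward_backward(seg, params)
            except FloatingPointError as exc:
                raise FloatingPointError(f"non-finite likelihood at iteration {it}") from exc
            ll += l
            gammas.append(g)
            xis.append(x)
        diag.log_likelihood_trace.append(ll)
        diag.n_iterations = it + 1
        if np.isfinite(prev_ll):
            rel = abs(ll - prev_ll) / (abs(prev_ll) + 1e-12)
            if rel < tol:
                diag.converged = True
                break
        prev_ll = ll
        params = _m_step(segments, gammas, xis, params)
    return _enforce_labels(params), diag


# ---------------------------------------------------------------------------
# Viterbi


def viterbi(obs, params: HMMParams) -> StateSequence:
    """Most probable joint state path; missing epochs are labeled missing.

    Missing epochs contribute emission factor 1, so the path is bridged by the
    transition structure alone; their decoded labels are masked to missing in
    the returned sequence.
    """
    obs = _check_obs(obs)
    le = _log_emissions(obs, params)
    T = obs.size
    la = _safe_log(params.a)
    lpi = _safe_log(params.pi)

    delta = np.empty((T, 2))
    back = np.zeros((T, 2), dtype=np.int8)
    delta[0] = lpi + le[0]
    for t in range(1, T):
        for j in (0, 1):
            cand = delta[t - 1] + la[:, j]
            back[t, j] = int(cand[1] > cand[0])
            delta[t, j] = cand[back[t, j]] + le[t, j]
    states = np.empty(T, dtype=np.int8)
    states[-1] = int(delta[-1, 1] > delta[-1, 0])
    log_joint = float(delta[-1, states[-1]])
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    states[np.isnan(obs)] = MISSING
    return StateSequence(states=states, log_joint=log_joint)


# ---------------------------------------------------------------------------
# per-individual orchestration


def split_segments(obs: np.ndarray, epoch_seconds: float, max_gap_minutes: float):
    """Split at missing runs longer than ``max_gap_minutes``.

    Returns ``[(start_index, obs_slice), ...]`` covering all epochs that
    belong to some segment; shorter gaps stay inside their segment.
    """
    obs = np.asarray(obs, dtype=float)
    seen = ~np.isnan(obs)
    if not seen.any():
        return []
    max_gap = int(max_gap_minutes * 60 / epoch_seconds)
    idx = np.flatnonzero(seen)
    breaks = np.flatnonzero(np.diff(idx) - 1 > max_gap)
    bounds = [0, *list(breaks + 1), idx.size]
    return [
        (int(idx[b]), obs[idx[b] : idx[e - 1] + 1])
        for b, e in zip(bounds[:-1], bounds[1:])
    ]


def _aggregate_counts(counts: np.ndarray, factor: int) -> np.ndarray:
    """Pool epochs into coarser bins (scaled sum); bins >50% missing are NaN."""
    n = counts.size // factor
    block = counts[: n * factor].reshape(n, factor)
    frac_missing = np.isnan(block).mean(axis=1)
    with np.errstate(invalid="ignore"):
        agg = np.round(np.nanmean(block, axis=1) * factor)
    agg[frac_missing > 0.5] = np.nan
    return agg


def fit_individual(series: EpochSeries, config: FitConfig | None = None):
    """Fit the HMM to one individual's record and decode sleep/wake states.

    Pipeline: (optional) aggregate counts into coarser epochs, log-transform,
    split on long gaps, Baum-Welch over the segments with one shared parameter
    set, then a Viterbi pass per segment.  Deterministic (no randomness).

    Returns ``(HMMParams, StateSequence, FitDiagnostics)``; the state sequence
    covers the full grid with missing labels at gaps.
    """
    config = config or FitConfig()
    counts = series.counts
    epoch_seconds = series.epoch_seconds
    if config.agg_minutes is not None:
        factor = int(round(config.agg_minutes * 60 / series.epoch_seconds))
        if factor < 1 or not math.isclose(factor * series.epoch_seconds, config.agg_minutes * 60):
            raise ValueError("agg_minutes must be a multiple of the epoch length")
        if factor > 1:
            counts = _aggregate_counts(counts, factor)
            epoch_seconds = int(config.agg_minutes * 60)
    obs = log_transform(counts)
    if np.count_nonzero(~np.isnan(obs)) < config.min_epochs:
        raise ValueError(
            f"{series.individual_id}: fewer than {config.min_epochs} observed epochs"
        )
    segments = split_segments(obs, epoch_seconds, config.max_gap_minutes)
    params, diag = baum_welch(
        [seg for _, seg in segments], init="auto", tol=config.tol, max_iter=config.max_iter
    )
    states = np.full(obs.size, MISSING, dtype=np.int8)
    log_joint = 0.0
    for start, seg in segments:
        sub = viterbi(seg, params)
        states[start : start + seg.size] = sub.states
        log_joint += sub.log_joint
    return params, StateSequence(states=states, log_joint=log_joint), diag


# ---------------------------------------------------------------------------
# writers


def write_state_csv(series: EpochSeries, states: StateSequence, path: str | Path,
                    epoch_seconds: int | None = None) -> None:
    """Write the decoded sequence as ``timestamp,state`` with S/W/NA labels."""
    import pandas as pd

    step = pd.Timedelta(seconds=epoch_seconds or series.epoch_seconds)
    ts = pd.date_range(series.start_time, periods=states.states.size, freq=step)
    pd.DataFrame({"timestamp": ts, "state": states.to_labels()}).to_csv(
        path, index=False, date_format="%Y-%m-%dT%H:%M:%S"
    )


def write_params_csv(params: HMMParams, diag: FitDiagnostics, path: str | Path) -> None:
    """Flat key-value CSV of the fitted parameters and fit diagnostics."""
    import pandas as pd

    rows = {
        "a11": params.a[0, 0], "a12": params.a[0, 1],
        "a21": params.a[1, 0], "a22": params.a[1, 1],
        "alpha": params.alpha_zero,
        "mu1": params.mu_sleep, "sigma1": params.sigma_sleep,
        "mu2": params.mu_wake, "sigma2": params.sigma_wake,
        "pi1": params.pi[0], "pi2": params.pi[1],
        "loglik": diag.log_likelihood_trace[-1] if diag.log_likelihood_trace else float("nan"),
        "n_iter": diag.n_iterations,
        "converged": int(diag.converged),
    }
    pd.DataFrame({"key": list(rows), "value": list(rows.values())}).to_csv(path, index=False)
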