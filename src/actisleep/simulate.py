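"""Synthetic actigraphy cohorts with known ground truth.

The generator emulates a 7-day wrist-accelerometer extract at the count
level: per individual, a time-inhomogeneous two-state (sleep/wake) Markov
chain whose sleep-entry and sleep-exit hazards concentrate around a nightly
schedule (default 23:00-07:00), log-scale observations drawn from the HMM
emission model (zero-inflated truncated Gaussian asleep, Gaussian awake),
inverted to integer counts via ``count = round(exp(o) - 1)`` clamped at 0.

The rectangular day/night activity profile puts spectral power at the 1-day
fundamental and its harmonics, as in real data; because an exactly 8-h night
(duty cycle 1/3) nulls the 3rd harmonic, explicit sinusoidal modulation of
the wake-state mean (default log-scale amplitudes 0.5 / 0.25 / 0.15 at 1,
1/2 and 1/3 day, mimicking morning/evening activity peaks) keeps all three
bands represented with decreasing strength.

``simulate_observations`` draws from the homogeneous HMM itself on the log
scale, without count discretization — the reference for parameter-recovery
checks of the fitting code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .hmm import HMMParams, SLEEP, WAKE
from .io import EpochSeries, IndividualMeta

__all__ = [
    "GeneratorConfig",
    "default_truth",
    "generate_cohort",
    "simulate_observations",
    "generate_toy_printed_cases",
    "write_cohort",
]


def default_truth() -> HMMParams:
    """Default generating HMM: near-zero log-activity asleep, high awake."""
    return HMMParams(
        a=np.array([[0.95, 0.05], [0.03, 0.97]]),
        alpha_zero=0.4,
        mu_sleep=0.3,
        sigma_sleep=0.4,
        mu_wake=4.5,
        sigma_wake=1.0,
        pi=np.array([0.5, 0.5]),
    )


@dataclass
class GeneratorConfig:
    n_individuals: int = 50
    days: float = 7.0
    epoch_seconds: int = 300
    hmm_truth: HMMParams = field(default_factory=default_truth)
    sleep_window: tuple[float, float] = (23.0, 7.0)  # clock hours
    harmonic_amplitudes: dict[float, float] = field(
        default_factory=lambda: {1.0: 0.35, 0.5: 0.3, 1.0 / 3.0: 0.3}
    )
    # phase (radians) of each harmonic relative to mid-wake (15:00): pi on the
    # 12-h component gives the bimodal morning/evening activity peaks seen in
    # real data (and keeps it in phase with the day/night rectangle's own 2nd
    # harmonic instead of cancelling it); pi on the 8-h component puts peaks
    # near 11:00 and 19:00 and aligns it with the sidebands the multiplicative
    # 24-h x 12-h structure throws onto the same band
    harmonic_phases: dict[float, float] = field(
        default_factory=lambda: {1.0: 0.0, 0.5: math.pi, 1.0 / 3.0: math.pi}
    )
    noise_sd: float = 0.1
    missing_rate: float = 0.0
    # night-to-night variability of bed and rise times; a rigidly repeated
    # schedule would leave artifactual high-order harmonics of the day/night
    # rectangle that real records do not show
    schedule_jitter_sd_min: float = 60.0
    seed: int = 0
    start_time: str = "2013-06-03 00:00:00"
    # per-epoch switching hazards at the reference 5-min epoch
    entry_hazard: float = 0.25  # toward the scheduled state
    exit_hazard: float = 0.003  # against the scheduled state

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if any(a < 0 for a in self.harmonic_amplitudes.values()):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.n_individuals < 1 or self.days <= 0 or self.epoch_seconds <= 0:
            raise ValueError("invalid cohort dimensions")
        self.hmm_truth.validate()


def _sample_sleep_obs(n: int, p: HMMParams, rng: np.random.Generator) -> np.ndarray:
    """Zero-inflated truncated normal on the log scale."""
    o = truncnorm.rvs(
        -p.mu_sleep / p.sigma_sleep, np.inf, loc=p.mu_sleep, scale=p.sigma_sleep,
        size=n, random_state=rng,
    )
    o[rng.random(n) < p.alpha_zero] = 0.0
    return o


def simulate_observations(params: HMMParams, T: int, seed: int | np.random.Generator):
    """Homogeneous HMM draw on the log-observation scale.

    Returns ``(obs, states)``; observations are continuous (no count
    rounding), clipped at 0 where the wake Gaussian strays negative.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.empty(T, dtype=np.int8)
    states[0] = rng.choice(2, p=params.pi)
    u = rng.random(T - 1)
    for t in range(1, T):
        states[t] = int(u[t - 1] < params.a[states[t - 1], WAKE])
    obs = np.empty(T)
    sleep_mask = states == SLEEP
    n_sleep = int(sleep_mask.sum())
    obs[sleep_mask] = _sample_sleep_obs(n_sleep, params, rng)
    obs[~sleep_mask] = rng.normal(params.mu_wake, params.sigma_wake, T - n_sleep)
    return np.clip(obs, 0.0, None), states


def generate_cohort(config: GeneratorConfig):
    """Simulate a cohort of count records with per-individual ground truth.

    Returns ``(series_list, truth)`` where ``truth`` maps individual id to a
    dict with the true ``states`` array and the generating ``params``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.hmm_truth
    T = int(round(config.days * 86400 / config.epoch_seconds))
    abs_hours = np.arange(T) * config.epoch_seconds / 3600.0
    t_days = abs_hours / 24.0
    scale = config.epoch_seconds / 300.0
    entry = min(config.entry_hazard * scale, 0.95)
    exit_ = min(config.exit_hazard * scale, 0.95)
    lo, hi = config.sleep_window
    night_len = (hi - lo) % 24.0 or 24.0
    n_nights = int(np.ceil(config.days)) + 1
    jit_sd = config.schedule_jitter_sd_min / 60.0
    # harmonics referenced to mid-wake (15:00), per-period phase offsets
    modulation = np.zeros(T)
    for period, amp in config.harmonic_amplitudes.items():
        modulation += amp * np.cos(
            2.0 * np.pi * (t_days - 15.0 / 24.0) / period
            + config.harmonic_phases.get(period, 0.0)
        )

    series_list: list[EpochSeries] = []
    truth: dict[str, dict] = {}
    width = max(3, len(str(config.n_individuals)))
    for i in range(config.n_individuals):
        iid = f"sim{i:0{width}d}"
        # jittered nightly windows: night n nominally runs from 24n+lo for
        # night_len hours; bed and rise times wander independently per night
        night = np.zeros(T, dtype=bool)
        for n in range(-1, n_nights):
            start = 24.0 * n + lo + rng.normal(0.0, jit_sd)
            end = start + night_len + rng.normal(0.0, jit_sd)
            night |= (abs_hours >= start) & (abs_hours < end)
        # hazard of switching into sleep (from wake) / into wake (from sleep)
        p_ws = np.where(night, entry, exit_)
        p_sw = np.where(night, exit_, entry)
        states = np.empty(T, dtype=np.int8)
        states[0] = SLEEP if night[0] else WAKE
        u = rng.random(T)
        for t in range(1, T):
            stay = states[t - 1]
            flip = u[t] < (p_sw[t] if stay == SLEEP else p_ws[t])
            states[t] = (1 - stay) if flip else stay
        obs = np.empty(T)
        sleep_mask = states == SLEEP
        obs[sleep_mask] = _sample_sleep_obs(int(sleep_mask.sum()), p, rng)
        wake_idx = np.flatnonzero(~sleep_mask)
        obs[wake_idx] = rng.normal(p.mu_wake + modulation[wake_idx], p.sigma_wake)
        if config.noise_sd > 0:
            obs += rng.normal(0.0, config.noise_sd, T)
        counts = np.clip(np.round(np.expm1(obs)), 0.0, None)
        if config.missing_rate > 0:
            counts[rng.random(T) < config.missing_rate] = np.nan
        series_list.append(
            EpochSeries(iid, pd.Timestamp(config.start_time), config.epoch_seconds, counts)
        )
        truth[iid] = {"states": states, "params": p}
    return series_list, truth


def write_cohort(series_list, truth, out_dir: str | Path) -> None:
    """Write epoch CSVs, a metadata CSV and per-individual truth CSVs."""
    from .io import write_epoch_csv

    out = Path(out_dir)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for s in series_list:
        write_epoch_csv(s, out / "epochs" / f"{s.individual_id}.csv")
        pd.DataFrame({"state": truth[s.individual_id]["states"]}).to_csv(
            out / "truth" / f"{s.individual_id}.csv", index=False
        )
        meta_rows.append({
            "individual_id": s.individual_id,
            "flagged_problem": 0, "poor_wear_time": 0, "poor_calibration": 0,
            "interrupted": 0, "needs_external_calibration": 0, "n_errors": 0,
        })
    pd.DataFrame(meta_rows).to_csv(out / "meta.csv", index=False)


def generate_toy_printed_cases() -> dict:
    """Small deterministic fixtures with independently computed oracle outputs.

    Includes short HMM instances whose posteriors/Viterbi paths are obtained
    by brute-force enumeration over all 2^T hidden paths, a hand spectral
    matrix with hand-summed column norms, and a pure-tone series whose
    spectrum has a single A/2 peak.
    """
    from scipy.stats import norm

    params = HMMParams(
        a=np.array([[0.9, 0.1], [0.2, 0.8]]),
        alpha_zero=0.3, mu_sleep=0.2, sigma_sleep=0.5,
        mu_wake=3.0, sigma_wake=1.0,
        pi=np.array([0.6, 0.4]),
    )
    rng = np.random.default_rng(20130603)
    cases = []
    for T in (1, 3, 5, 8):
        obs = np.where(rng.random(T) < 0.4, 0.0, rng.uniform(0.1, 5.0, T))
        # sleep-state likelihood: point mass at 0, truncated normal elsewhere
        tn = norm.pdf(obs, params.mu_sleep, params.sigma_sleep) / norm.sf(
            -params.mu_sleep / params.sigma_sleep
        )
        b = np.column_stack([
            np.where(obs == 0.0, params.alpha_zero, (1.0 - params.alpha_zero) * tn),
            norm.pdf(obs, params.mu_wake, params.sigma_wake),
        ])
        # enumerate all hidden paths
        paths = np.array(np.meshgrid(*[[0, 1]] * T, indexing="ij")).reshape(T, -1).T
        probs = np.empty(len(paths))
        for k, path in enumerate(paths):
            pr = params.pi[path[0]] * b[0, path[0]]
            for t in range(1, T):
                pr *= params.a[path[t - 1], path[t]] * b[t, path[t]]
            probs[k] = pr
        total = probs.sum()
        gamma = np.zeros((T, 2))
        for k, path in enumerate(paths):
            for t in range(T):
                gamma[t, path[t]] += probs[k]
        gamma /= total
        best = int(np.argmax(probs))
        cases.append({
            "obs": obs,
            "log_likelihood": math.log(total),
            "gamma": gamma,
            "viterbi_path": paths[best].astype(np.int8),
            "viterbi_log_joint": math.log(probs[best]),
        })

    hand_X = np.array([[1.0, 2.0, 0.0, 3.0],
                       [2.0, 0.0, 1.0, 1.0],
                       [1.0, 1.0, 2.0, 0.0]])
    # column sums of squares, by hand: 1+4+1, 4+0+1, 0+1+4, 9+1+0
    hand_norms = np.array([6.0, 5.0, 5.0, 10.0])

    days, per_day, amp = 4, 288, 10.0
    n = days * per_day
    tone = amp * np.cos(2 * np.pi * days * np.arange(n) / n)  # 24-h period

    return {
        "hmm_params": params,
        "hmm_cases": cases,
        "hand_X": hand_X,
        "hand_column_norms_sq": hand_norms,
        "tone_series": tone,
        "tone_amplitude": amp,
        "tone_days": float(days),
        "tone_peak_index": days,  # f = record_days / 1-day period
    }
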