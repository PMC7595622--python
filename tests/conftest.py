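import numpy as np
import pytest
from scipy.stats import norm

from actisleep.hmm import HMMParams


def model_emission(obs: np.ndarray, params: HMMParams) -> np.ndarray:
    """T x 2 emission likelihoods of the fitting model, written directly.

    Sleep: point mass alpha at exactly 0, (1-alpha) x truncated normal on
    (0, inf) elsewhere.  Wake: Gaussian density.  Independent of the package's
    forward/Viterbi recursions; used by the enumeration oracles.
    """
    tn = norm.pdf(obs, params.mu_sleep, params.sigma_sleep) / norm.sf(
        -params.mu_sleep / params.sigma_sleep
    )
    sleep = np.where(obs == 0.0, params.alpha_zero, (1.0 - params.alpha_zero) * tn)
    wake = norm.pdf(obs, params.mu_wake, params.sigma_wake)
    return np.column_stack([sleep, wake])


def enumerate_paths(obs: np.ndarray, params: HMMParams):
    """Brute-force posterior and best path over all 2^T hidden sequences.

    Returns (log_likelihood, gamma, best_path, best_log_joint).
    """
    T = obs.size
    b = model_emission(obs, params)
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
    return float(np.log(total)), gamma, paths[best], float(np.log(probs[best]))


def random_params(rng: np.random.Generator) -> HMMParams:
    a11, a22 = rng.uniform(0.5, 0.99, 2)
    return HMMParams(
        a=np.array([[a11, 1 - a11], [1 - a22, a22]]),
        alpha_zero=rng.uniform(0.05, 0.9),
        mu_sleep=rng.uniform(-0.5, 1.0),
        sigma_sleep=rng.uniform(0.2, 1.0),
        mu_wake=rng.uniform(2.0, 6.0),
        sigma_wake=rng.uniform(0.5, 2.0),
        pi=np.array([0.5, 0.5]),
    )


def random_obs(rng: np.random.Generator, T: int) -> np.ndarray:
    return np.where(rng.random(T) < 0.3, 0.0, rng.uniform(0.05, 6.0, T))


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort: 50 individuals, 7 days, 5-min epochs."""
    from actisleep.simulate import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_fits():
    """20 seeded Baum-Welch fits of 2016-epoch sequences from known truth."""
    from actisleep.hmm import baum_welch, viterbi
    from actisleep.simulate import simulate_observations
    from actisleep.hmm import HMMParams

    truth = HMMParams(
        a=np.array([[0.95, 0.05], [0.03, 0.97]]),
        alpha_zero=0.4, mu_sleep=0.3, sigma_sleep=0.4,
        mu_wake=4.5, sigma_wake=1.0, pi=np.array([0.5, 0.5]),
    )
    fits = []
    for seed in range(20):
        obs, states = simulate_observations(truth, 2016, seed=seed)
        params, diag = baum_welch(obs, init="auto")
        path = viterbi(obs, params)
        fits.append({
            "truth": truth, "params": params, "diag": diag,
            "accuracy": float(np.mean(path.states == states)),
        })
    return fits
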