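"""Penalized Multi-band Learning (PML) for dominant circadian periodicities.

Each individual's activity-count record is aggregated to coarse bins,
mean-subtracted and Fourier-transformed; the one-sided magnitudes form a row
of the population spectral matrix X (n individuals x p frequency bands, band
f completing f cycles over the record, period = record_days / f).

Band selection shrinks a diagonal selector Theta, minimizing

    ||X - X Theta||_F^2 + lambda * ((1-alpha)/2 * sum theta_jj^2 + alpha * sum theta_jj)

over 0 <= theta_jj <= 1.  The problem separates by column; setting the
per-coordinate derivative -2||x_k||^2 + 2 theta ||x_k||^2 + (1-alpha) lambda
theta + alpha lambda to zero and clipping to [0, 1] gives

    theta_k = clip( (2||x_k||^2 - alpha*lambda) / (2||x_k||^2 + (1-alpha)*lambda), 0, 1 )

With the pure L1 penalty (alpha = 1, the default) a band's theta becomes
nonzero exactly when lambda drops below 2||x_k||^2, so bands enter the path
in descending order of spectral energy — the entry order ranks dominance.
The strengths (magnitudes) at the selected bands are the circadian
phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import EpochSeries

__all__ = [
    "Spectrum",
    "SpectralMatrix",
    "SelectionPath",
    "compute_spectrum",
    "build_spectral_matrix",
    "theta_hat",
    "mse",
    "lambda_path",
    "select_bands",
    "circadian_phenotypes",
]


@dataclass
class Spectrum:
    """One individual's one-sided FFT magnitudes (zero frequency excluded)."""

    individual_id: str
    magnitudes: np.ndarray  # length p = floor(N/2), index f-1 <-> frequency f
    record_days: float

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def p(self) -> int:
        return self.magnitudes.size

    def period_days(self, frequency_index: int) -> float:
        return self.record_days / frequency_index


@dataclass
class SpectralMatrix:
    """Population spectral matrix: row per individual, column per band."""

    ids: list[str]
    X: np.ndarray
    record_days: float
    column_norms_sq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.column_norms_sq = (self.X**2).sum(axis=0)

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class SelectionPath:
    lambdas: np.ndarray  # decreasing, ends at exactly 0
    thetas: np.ndarray  # len(lambdas) x p
    mses: np.ndarray
    entry_order: list[int]  # frequency indices (1-based), first entered first
    mixing_alpha: float
    record_days: float
    column_norms_sq: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.thetas, columns=[f"theta_{j+1}" for j in range(self.thetas.shape[1])])
        df.insert(0, "lambda", self.lambdas)
        df["mse"] = self.mses
        return df


def compute_spectrum(
    series: EpochSeries,
    agg_minutes: float = 5.0,
    max_missing_frac: float = 0.2,
) -> Spectrum:
    """FFT magnitude spectrum of one individual's aggregated count series.

    Counts are averaged into ``agg_minutes`` bins, truncated to a whole number
    of days, gaps linearly interpolated, mean-subtracted, and transformed; the
    one-sided modulus is scaled by 1/N.  A pure cosine of amplitude A with f
    cycles per record therefore shows magnitude A/2 at band f.

    Raises when the series spans under 2 days or when more than
    ``max_missing_frac`` of the bins are missing before interpolation.
    """
    bin_seconds = agg_minutes * 60.0
    factor = bin_seconds / series.epoch_seconds
    if factor < 1 or abs(factor - round(factor)) > 1e-9:
        raise ValueError("agg_minutes must be a whole multiple of the epoch length")
    factor = int(round(factor))
    bins_per_day = 86400.0 / bin_seconds
    if abs(bins_per_day - round(bins_per_day)) > 1e-9:
        raise ValueError("agg_minutes must divide 24 h evenly")
    bins_per_day = int(round(bins_per_day))

    counts = series.counts
    n_bins = counts.size // factor
    block = counts[: n_bins * factor].reshape(n_bins, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        values = np.nanmean(block, axis=1)

    whole_days = n_bins // bins_per_day
    if whole_days < 2:
        raise ValueError(f"{series.individual_id}: record must span at least 2 whole days")
    N = whole_days * bins_per_day
    values = values[:N]

    missing = np.isnan(values)
    if missing.mean() > max_missing_frac:
        raise ValueError(
            f"{series.individual_id}: {missing.mean():.0%} of bins missing exceeds "
            f"{max_missing_frac:.0%}"
        )
    if missing.any():
        values = (
            pd.Series(values).interpolate(method="linear", limit_direction="both").to_numpy()
        )

    x = values - values.mean()
    mags = np.abs(np.fft.rfft(x)) / N
    return Spectrum(series.individual_id, mags[1 : N // 2 + 1], float(whole_days))


def build_spectral_matrix(spectra: Iterable[Spectrum]) -> SpectralMatrix:
    """Stack individual spectra into X (rows ordered by individual id)."""
    spectra = sorted(spectra, key=lambda s: s.individual_id)
    if not spectra:
        raise ValueError("no spectra supplied")
    from collections import Counter

    shapes = Counter((s.p, s.record_days) for s in spectra)
    (p0, d0), _ = shapes.most_common(1)[0]
    bad = [s.individual_id for s in spectra if s.p != p0 or s.record_days != d0]
    if bad:
        raise ValueError(f"spectra with mismatched length or record span: {bad}")
    X = np.vstack([s.magnitudes for s in spectra])
    return SpectralMatrix([s.individual_id for s in spectra], X, d0)


def theta_hat(col_norm_sq: float, lam: float, mixing_alpha: float = 1.0) -> float:
    """Closed-form penalized selector weight for one spectral band.

    Minimizes the per-coordinate objective
    ``-2 theta c + theta^2 c + lambda ((1-alpha)/2 theta^2 + alpha theta)``
    over theta in [0, 1], where c is the band's squared column norm.
    """
    if not 0.0 <= mixing_alpha <= 1.0:
        raise ValueError("mixing_alpha must lie in [0, 1]")
    if col_norm_sq < 0 or lam < 0:
        raise ValueError("col_norm_sq and lam must be non-negative")
    denom = 2.0 * col_norm_sq + (1.0 - mixing_alpha) * lam
    if denom <= 0:
        return 0.0  # degenerate band with no energy and no ridge term
    return float(np.clip((2.0 * col_norm_sq - mixing_alpha * lam) / denom, 0.0, 1.0))


def mse(X: SpectralMatrix, theta: np.ndarray) -> float:
    """Reconstruction error ||X - X Theta||_F^2 = sum_j (1-theta_j)^2 ||x_j||^2."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (X.p,):
        raise ValueError("theta has wrong length")
    return float(((1.0 - theta) ** 2 * X.column_norms_sq).sum())


def lambda_path(
    X: SpectralMatrix, n_lambdas: int = 100, mixing_alpha: float = 1.0
) -> SelectionPath:
    """Trace theta and MSE along a decreasing penalty path.

    The path runs from ``2 * max_j ||x_j||^2`` (all bands suppressed when
    alpha = 1) geometrically down to 1e-4 of that, plus exactly 0 (no penalty:
    every band kept, MSE 0).  ``entry_order`` ranks bands by the penalty level
    at which they first activate; ties break toward larger column norm, then
    lower frequency index.
    """
    if n_lambdas < 2:
        raise ValueError("n_lambdas must be at least 2")
    norms = X.column_norms_sq
    lam_max = 2.0 * float(norms.max())
    if lam_max == 0.0:
        lambdas = np.zeros(2)
    else:
        lambdas = np.concatenate([
            np.geomspace(lam_max, lam_max * 1e-4, n_lambdas), [0.0]
        ])
    thetas = np.empty((lambdas.size, X.p))
    mses = np.empty(lambdas.size)
    for i, lam in enumerate(lambdas):
        thetas[i] = [theta_hat(c, lam, mixing_alpha) for c in norms]
        mses[i] = mse(X, thetas[i])

    first_nonzero = np.full(X.p, lambdas.size, dtype=int)
    for j in range(X.p):
        nz = np.flatnonzero(thetas[:, j] > 0)
        if nz.size:
            first_nonzero[j] = nz[0]
    # sort key: entry index, then larger norm, then lower frequency index
    order = sorted(range(X.p), key=lambda j: (first_nonzero[j], -norms[j], j))
    entry_order = [j + 1 for j in order if first_nonzero[j] < lambdas.size]
    return SelectionPath(lambdas, thetas, mses, entry_order, mixing_alpha,
                         X.record_days, norms.copy())


def select_bands(path: SelectionPath, k: int = 3) -> list[tuple[int, float]]:
    """First k bands on the path as (frequency_index, period_days) pairs."""
    if k < 0 or k > len(path.entry_order):
        raise ValueError("k out of range")
    return [(f, path.record_days / f) for f in path.entry_order[:k]]


def circadian_phenotypes(
    X: SpectralMatrix,
    bands: Sequence[tuple[int, float]],
    normalize: bool = False,
    squared: bool = False,
) -> pd.DataFrame:
    """Per-individual signal strength at the selected dominant bands.

    Default strength is the unsquared FFT magnitude; ``squared`` switches to
    power.  ``normalize`` divides by each individual's total (magnitude or
    power) across all bands; individuals with an all-zero spectrum get 0 with
    a warning.
    """
    if not bands:
        raise ValueError("bands must be non-empty")
    vals = X.X**2 if squared else X.X
    out = {"individual_id": X.ids}
    totals = vals.sum(axis=1)
    if normalize and np.any(totals == 0):
        warnings.warn("all-zero spectrum: normalized phenotypes set to 0")
    for f, period in bands:
        col = vals[:, f - 1]
        if normalize:
            with np.errstate(invalid="ignore", divide="ignore"):
                col = np.where(totals > 0, col / totals, 0.0)
        out[f"period_{round(period, 4):g}d"] = col
    return pd.DataFrame(out)
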