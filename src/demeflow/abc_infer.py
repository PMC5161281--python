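"""Approximate Bayesian computation over the simulator's summary vector.

Inference is likelihood-free: parameter sets drawn from uniform priors
are simulated, each run is reduced to its regional ancestry summary
vector, and the runs whose summaries fall closest (Euclidean distance)
to the observed vector are retained. The tolerance is a quantile: the
accepted set is the fraction ``tolerance`` of the reference table with
the smallest distances. Accepted continuous parameters are optionally
adjusted by local linear regression of parameter on summary statistics,
weighted by an Epanechnikov kernel on distance, and clipped back to the
prior support. The categorical start distribution is summarized by its
frequency among accepted runs.

Cross-validation treats held-out reference rows as pseudo-observed data
and reports, per parameter, the prediction error
``E_pred = sum((theta_hat - theta)^2) / sum((theta - mean(theta))^2)``,
so that an estimator no better than the prior mean scores ~1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .engine import PRIOR_BOUNDS

__all__ = [
    "CONTINUOUS_PARAMS",
    "sample_prior",
    "euclidean_distance",
    "abc_reject",
    "loclinear_adjust",
    "fit_posterior",
    "PosteriorSample",
    "cv_prediction_error",
    "select_tolerance",
    "posterior_summary",
]

CONTINUOUS_PARAMS = ("m_a", "m_p", "f_a", "f_p", "marriage_weight")


def sample_prior(n: int, rng, distribution_ids=("D000",)) -> pd.DataFrame:
    """n parameter draws: uniform on each prior range, uniform over D."""
    if n <= 0:
        raise ValueError("n must be positive")
    cols = {}
    for name in CONTINUOUS_PARAMS:
        lo, hi = PRIOR_BOUNDS[name]
        cols[name] = rng.uniform(lo, hi, n)
    ids = list(distribution_ids)
    cols["start_distribution"] = np.asarray(ids, dtype=object)[
        rng.integers(0, len(ids), n)
    ]
    return pd.DataFrame(cols)


def euclidean_distance(sim, obs) -> float:
    """Euclidean distance between summary vectors, NaNs dropped pairwise."""
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"dimension mismatch: {sim.shape} vs {obs.shape}")
    mask = np.isfinite(sim) & np.isfinite(obs)
    return float(np.sqrt(((sim[mask] - obs[mask]) ** 2).sum()))


def _distances(summaries: np.ndarray, obs: np.ndarray) -> np.ndarray:
    mask = np.isfinite(summaries) & np.isfinite(obs)[None, :]
    diff = np.where(mask, summaries - obs[None, :], 0.0)
    return np.sqrt((diff**2).sum(axis=1))


def abc_reject(summaries: np.ndarray, obs: np.ndarray, tolerance: float):
    """Indices (and distances) of the accepted tolerance-quantile.

    Keeps the ceil(tolerance * n) rows with the smallest Euclidean
    distance to the observation; ties break deterministically by row
    index.
    """
    summaries = np.asarray(summaries, dtype=float)
    if summaries.ndim != 2 or len(summaries) == 0:
        raise ValueError("reference summaries must be a non-empty 2-D array")
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    obs = np.asarray(obs, dtype=float)
    if summaries.shape[1] != obs.shape[0]:
        raise ValueError("summary dimension mismatch")
    dist = _distances(summaries, obs)
    n_keep = ceil(tolerance * len(summaries))
    order = np.lexsort((np.arange(len(dist)), dist))
    accepted = np.sort(order[:n_keep])
    return accepted, dist[accepted]


def loclinear_adjust(
    accepted_params: pd.DataFrame,
    accepted_summaries: np.ndarray,
    distances: np.ndarray,
    obs: np.ndarray,
    bounds: dict | None = None,
) -> pd.DataFrame:
    """Local-linear regression adjustment of accepted continuous draws.

    Each parameter is regressed on the (centred) summaries with
    Epanechnikov weights on distance; draws are corrected to their value
    at the observed summaries (theta - b . (s - obs)) and clipped to the
    prior support. Falls back to the unadjusted draws with a warning if
    the design is singular or too small.
    """
    bounds = bounds or PRIOR_BOUNDS
    params = accepted_params.reset_index(drop=True).copy()
    s = np.asarray(accepted_summaries, dtype=float)
    obs = np.asarray(obs, dtype=float)
    # summaries that are constant among accepted runs (e.g. regions pinned
    # at ancestry 1 next to the mainland) carry no local information and
    # would make the weighted design singular
    keep = (
        np.isfinite(obs)
        & np.isfinite(s).all(axis=0)
        & (s.std(axis=0) > 1e-9)
    )
    s = s[:, keep]
    obs_k = obs[keep]
    n, k = s.shape
    if n < k + 2:
        warnings.warn(
            "too few accepted draws for local-linear adjustment; "
            "returning rejection draws",
            stacklevel=2,
        )
        return params
    delta = float(distances.max())
    w = np.ones(n) if delta == 0 else 1.0 - (np.asarray(distances) / delta) ** 2
    w = np.maximum(w, 1e-12)
    X = np.column_stack([np.ones(n), s - obs_k[None, :]])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        warnings.warn(
            "singular design in local-linear adjustment; "
            "returning rejection draws",
            stacklevel=2,
        )
        return params
    for name in CONTINUOUS_PARAMS:
        if name not in params.columns:
            continue
        theta = params[name].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(Xw, theta * sw, rcond=None)
        fitted = X @ coef
        adjusted = coef[0] + (theta - fitted)
        lo, hi = bounds[name]
        params[name] = np.clip(adjusted, lo, hi)
    return params


@dataclass
class PosteriorSample:
    """Accepted (possibly regression-adjusted) draws and their summaries."""

    draws: pd.DataFrame
    distances: np.ndarray
    tolerance: float
    method: str

    def summary(self, bounds: dict | None = None) -> pd.DataFrame:
        bounds = bounds or PRIOR_BOUNDS
        rows = []
        for name in CONTINUOUS_PARAMS:
            if name not in self.draws.columns:
                continue
            stats = posterior_summary(
                self.draws[name].to_numpy(dtype=float), bounds[name]
            )
            rows.append((name, stats["mode"], stats["cr_low"], stats["cr_high"]))
        return pd.DataFrame(rows, columns=["parameter", "mode", "cr_low", "cr_high"])

    def distribution_frequencies(self) -> pd.Series:
        """Posterior frequency of each start distribution among accepted runs."""
        if "start_distribution" not in self.draws.columns:
            return pd.Series(dtype=float)
        freq = self.draws["start_distribution"].value_counts(normalize=True)
        return freq.sort_index()


def fit_posterior(
    params: pd.DataFrame,
    summaries: np.ndarray,
    obs: np.ndarray,
    tolerance: float = 0.01,
    method: str = "loclinear",
    bounds: dict | None = None,
) -> PosteriorSample:
    """Rejection (optionally regression-adjusted) ABC posterior."""
    accepted, dist = abc_reject(summaries, obs, tolerance)
    draws = params.iloc[accepted].reset_index(drop=True)
    if method == "loclinear":
        draws = loclinear_adjust(
            draws, np.asarray(summaries)[accepted], dist, obs, bounds=bounds
        )
    elif method != "rejection":
        raise ValueError(f"unknown method {method!r}")
    return PosteriorSample(draws=draws, distances=dist, tolerance=tolerance, method=method)


def _point_estimates(
    params: pd.DataFrame, summaries, obs, tolerance, method, bounds
) -> dict:
    post = fit_posterior(params, summaries, obs, tolerance, method=method, bounds=bounds)
    return {
        name: float(post.draws[name].mean())
        for name in CONTINUOUS_PARAMS
        if name in post.draws.columns
    }


def cv_prediction_error(
    params: pd.DataFrame,
    summaries: np.ndarray,
    tolerance: float,
    n_folds: int,
    rng,
    method: str = "loclinear",
    bounds: dict | None = None,
) -> dict:
    """Leave-one-out prediction error per continuous parameter.

    ``n_folds`` reference rows are treated in turn as pseudo-observed
    data; the posterior-mean estimate from the remaining rows is scored
    as a variance-normalized squared error, so ~1 means the summaries
    carry no information about the parameter beyond the prior.
    """
    summaries = np.asarray(summaries, dtype=float)
    n = len(summaries)
    if n_folds > n:
        raise ValueError("n_folds cannot exceed the table size")
    if n < 10:
        raise ValueError("reference table too small for cross-validation")
    held = np.sort(rng.choice(n, size=n_folds, replace=False))
    estimates: dict[str, list] = {p: [] for p in CONTINUOUS_PARAMS if p in params.columns}
    truths: dict[str, list] = {p: [] for p in estimates}
    rest_mask = np.ones(n, dtype=bool)
    for row in held:
        rest_mask[row] = False
        est = _point_estimates(
            params[rest_mask], summaries[rest_mask], summaries[row],
            tolerance, method, bounds,
        )
        rest_mask[row] = True
        for p in estimates:
            estimates[p].append(est[p])
            truths[p].append(float(params[p].iloc[row]))
    epred = {}
    for p in estimates:
        err = np.asarray(estimates[p]) - np.asarray(truths[p])
        tv = np.asarray(truths[p])
        denom = ((tv - tv.mean()) ** 2).sum()
        epred[p] = float((err**2).sum() / denom) if denom > 0 else np.inf
    return epred


def select_tolerance(
    params: pd.DataFrame,
    summaries: np.ndarray,
    candidate_tolerances,
    n_folds: int,
    rng,
    method: str = "loclinear",
) -> float:
    """Candidate tolerance minimizing the mean prediction error.

    The same held-out folds are reused for every candidate; ties break
    toward the smallest tolerance.
    """
    candidates = sorted(set(float(t) for t in candidate_tolerances))
    if not candidates:
        raise ValueError("need at least one candidate tolerance")
    seed = int(rng.integers(0, 2**31))
    best, best_score = None, np.inf
    for tol in candidates:
        epred = cv_prediction_error(
            params, summaries, tol, n_folds, np.random.default_rng(seed), method=method
        )
        score = float(np.mean(list(epred.values())))
        if score < best_score - 1e-12:
            best, best_score = tol, score
    return best


def posterior_summary(draws: np.ndarray, bounds: tuple[float, float]) -> dict:
    """Mode (boundary-reflected KDE) and central 95% credible region."""
    draws = np.asarray(draws, dtype=float)
    if len(draws) == 0:
        raise ValueError("empty posterior sample")
    lo, hi = bounds
    cr_low, cr_high = np.percentile(draws, [2.5, 97.5])
    if np.ptp(draws) < 1e-12:
        mode = float(draws[0])
    else:
        kde = gaussian_kde(draws)
        grid = np.linspace(lo, hi, 512)
        dens = kde(grid) + kde(2 * lo - grid) + kde(2 * hi - grid)
        mode = float(grid[np.argmax(dens)])
    return {"mode": mode, "cr_low": float(cr_low), "cr_high": float(cr_high)}
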