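"""The seven-parameter criterion-attraction model and its maximum-likelihood fit.

The model: an observer keeps one base set of criteria
t_i (i = -3..-1, 1..3; t_0 fixed at 0) on the low-variability scale.
Optimally the high-variability condition would use 3*t_i, but under
attraction the low-variability criteria move outward to alpha*t_i and the
high-variability criteria inward to 3*t_i/alpha.  Free parameters: the six
confidence criteria and alpha.

The likelihood is multinomial over the 16 response types (choice x
confidence x condition), evaluated on the actual stimulus orientations of
the dataset: the model's predicted probability of response type (i, j) in
condition k is the proportion of that condition's orientations falling in
the (i, j) region of the attracted criterion partition (the model has no
internal-noise parameter, so the stimulus-to-response mapping is
deterministic):

    log L = sum_ijk n_ijk * log(p_ijk)

Maximisation uses bounded derivative-free local search (Nelder-Mead on an
order-preserving reparameterisation) from multiple random starts plus one
moment-based start derived from the SDT criterion estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic_data import apply_attraction
from . import sdt_estimation

__all__ = [
    "ResponseTable",
    "AttractionFit",
    "response_regions",
    "classify_orientation",
    "build_response_table",
    "predict_response_probs",
    "log_likelihood",
    "fit_attraction",
    "attraction_to_ratio",
]

EPS_FLOOR = 1e-6  # probability floor before renormalisation

ALPHA_BOUNDS = (0.5, 3.0)
MAX_CRITERION_DEG = 60.0

CONDITIONS = ("low", "high")
#: the 8 response types per condition, in fixed order
RESPONSE_TYPES = [("D1", 4), ("D1", 3), ("D1", 2), ("D1", 1),
                  ("D2", 1), ("D2", 2), ("D2", 3), ("D2", 4)]


@dataclass
class ResponseTable:
    """Observed response counts n_ijk and the per-condition orientations.

    ``counts[k]`` is an 8-vector over :data:`RESPONSE_TYPES` for condition
    k; ``orientations[k]`` holds that condition's actual stimulus
    orientations, sorted (the model is fit on the stimuli the subject
    really saw).
    """

    counts: dict
    orientations: dict

    @property
    def n_trials(self) -> dict:
        return {k: int(v.sum()) for k, v in self.counts.items()}


@dataclass
class AttractionFit:
    """Result of the maximum-likelihood fit."""

    base_criteria: np.ndarray
    alpha: float
    log_likelihood: float
    n_restarts: int
    converged: bool
    restart_log_likelihoods: list = field(default_factory=list)


def response_regions(criteria6) -> list[tuple[float, float, str, int]]:
    """Partition of the orientation axis into the 8 (choice, confidence)
    regions induced by ordered criteria (t_-3..t_-1, t_1..t_3) with t_0 = 0.

    Intervals are half-open, lower-inclusive: [edge_k, edge_{k+1}).
    Returns (lower, upper, choice, confidence) tuples covering the real line.
    """
    crit = np.asarray(criteria6, dtype=float)
    edges = np.concatenate([[-np.inf], crit[:3], [0.0], crit[3:], [np.inf]])
    if np.any(np.diff(edges[1:-1]) < 0):
        raise ValueError("criteria must be ordered around t_0 = 0")
    regions = []
    for k, (choice, conf) in enumerate(RESPONSE_TYPES):
        regions.append((float(edges[k]), float(edges[k + 1]), choice, conf))
    return regions


def classify_orientation(orientation, criteria6):
    """(choice, confidence) of orientation(s) under one condition's criteria."""
    crit = np.asarray(criteria6, dtype=float)
    edges = np.concatenate([crit[:3], [0.0], crit[3:]])
    idx = np.searchsorted(edges, np.asarray(orientation, dtype=float), side="right")
    choice = np.where(idx >= 4, "D2", "D1")
    confidence = np.where(idx >= 4, idx - 3, 4 - idx)
    if np.isscalar(orientation):
        return str(choice.item()), int(confidence.item())
    return choice, confidence


def build_response_table(trials: pd.DataFrame) -> ResponseTable:
    """Tabulate n_ijk and collect per-condition orientations from trial data."""
    counts, orientations = {}, {}
    type_index = {t: k for k, t in enumerate(RESPONSE_TYPES)}
    for cond in CONDITIONS:
        sub = trials[trials["condition"] == cond]
        vec = np.zeros(8)
        for (choice, conf), n in sub.groupby(["choice", "confidence"]).size().items():
            vec[type_index[(choice, int(conf))]] = n
        counts[cond] = vec
        orientations[cond] = np.sort(sub["orientation_deg"].to_numpy(dtype=float))
    return ResponseTable(counts=counts, orientations=orientations)


def _region_probs(sorted_orientations: np.ndarray, criteria6: np.ndarray) -> np.ndarray:
    """Proportion of orientations in each of the 8 regions, floored at
    EPS_FLOOR and renormalised."""
    edges = np.concatenate([criteria6[:3], [0.0], criteria6[3:]])
    cuts = np.searchsorted(sorted_orientations, edges, side="left")
    counts = np.diff(np.concatenate([[0], cuts, [len(sorted_orientations)]]))
    p = counts / max(len(sorted_orientations), 1)
    p = np.maximum(p, EPS_FLOOR)
    return p / p.sum()


def predict_response_probs(table: ResponseTable, base_criteria, alpha: float) -> dict:
    """Predicted p_ijk per condition: the fraction of that condition's actual
    orientations in each (choice, confidence) region of the attracted
    criterion partition."""
    low_c, high_c = apply_attraction(np.asarray(base_criteria, dtype=float), alpha)
    return {
        "low": _region_probs(table.orientations["low"], low_c),
        "high": _region_probs(table.orientations["high"], high_c),
    }


def log_likelihood(table: ResponseTable, base_criteria, alpha: float) -> float:
    """Multinomial log-likelihood sum_ijk n_ijk log p_ijk (finite by the
    probability floor)."""
    probs = predict_response_probs(table, base_criteria, alpha)
    return float(sum(table.counts[k] @ np.log(probs[k]) for k in CONDITIONS))


def saturated_log_likelihood(table: ResponseTable) -> float:
    """Upper bound sum n log(n/N): the log-likelihood when predicted
    probabilities equal observed frequencies."""
    total = 0.0
    for k in CONDITIONS:
        n = table.counts[k]
        pos = n > 0
        total += float(n[pos] @ np.log(n[pos] / n.sum()))
    return total


def attraction_to_ratio(alpha: float) -> float:
    """Cross-condition criterion ratio implied by attraction alpha: 3/alpha^2
    (3 with no attraction, 1.94 at alpha = 1.244, 1 at full collapse)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return 3.0 / alpha**2


# ---------------------------------------------------------------------------
# fitting: order-preserving reparameterisation
#
# theta = (log alpha, log t1, log(t2-t1), log(t3-t2),
#          log(-t_-1), log(t_-1 - t_-2), log(t_-2 - t_-3))
# guarantees t_-3 <= t_-2 <= t_-1 <= 0 <= t1 <= t2 <= t3 for any theta.
# ---------------------------------------------------------------------------

_LOG_GAP_MIN, _LOG_GAP_MAX = np.log(1e-3), np.log(2 * MAX_CRITERION_DEG)


def _theta_to_params(theta: np.ndarray) -> tuple[np.ndarray, float]:
    alpha = float(np.exp(theta[0]))
    pos = np.cumsum(np.exp(theta[1:4]))
    neg = -np.cumsum(np.exp(theta[4:7]))
    return np.concatenate([neg[::-1], pos]), alpha


def _params_to_theta(base_criteria, alpha: float) -> np.ndarray:
    crit = np.asarray(base_criteria, dtype=float)
    pos_gaps = np.diff(np.concatenate([[0.0], crit[3:]]))
    neg_gaps = np.diff(np.concatenate([[0.0], -crit[:3][::-1]]))
    gaps = np.concatenate([pos_gaps, neg_gaps])
    return np.concatenate([[np.log(alpha)], np.log(np.maximum(gaps, 1e-3))])


def _neg_ll(theta: np.ndarray, table: ResponseTable) -> float:
    base, alpha = _theta_to_params(theta)
    penalty = 0.0
    if not (ALPHA_BOUNDS[0] <= alpha <= ALPHA_BOUNDS[1]):
        penalty += 1e4 * (abs(np.log(alpha) - np.clip(np.log(alpha), *np.log(ALPHA_BOUNDS))) + 1)
    extreme = max(abs(base[0]), abs(base[-1]), abs(base[0]) * alpha, base[-1] * 3 / alpha)
    if extreme > MAX_CRITERION_DEG:
        penalty += 1e2 * (extreme - MAX_CRITERION_DEG)
    return -log_likelihood(table, base, alpha) + penalty


def _quantile_start(table: ResponseTable) -> np.ndarray | None:
    """Method-of-moments start: per condition, place each region edge at the
    midpoint of the orientation gap implied by the observed response counts
    (so predicted region proportions match the counts exactly within each
    condition), then reconcile the two conditions into (base, alpha)."""
    conf_pos = [0, 1, 2, 4, 5, 6]  # confidence edges within the 7-edge vector
    edges = {}
    for k in CONDITIONS:
        ori = table.orientations[k]
        n_below = np.cumsum(table.counts[k])[:-1].astype(int)
        e = np.empty(7)
        for j, c in enumerate(n_below):
            if c <= 0:
                e[j] = ori[0] - 1.0
            elif c >= len(ori):
                e[j] = ori[-1] + 1.0
            else:
                e[j] = 0.5 * (ori[c - 1] + ori[c])
        edges[k] = e

    low_e, high_e = edges["low"][conf_pos], edges["high"][conf_pos]
    valid = (np.abs(low_e) > 1e-6) & (np.sign(low_e) == np.sign(high_e))
    if not valid.any():
        return None
    r = float(np.median(high_e[valid] / low_e[valid]))
    alpha = float(np.clip(np.sqrt(3.0 / np.clip(r, 0.3, 12.0)), *ALPHA_BOUNDS))
    base = 0.5 * (low_e / alpha + high_e * alpha / 3.0)
    # enforce strict ordering around zero before transforming
    base[3:] = np.maximum.accumulate(np.maximum(base[3:], 1e-2))
    base[3:] += 1e-3 * np.arange(3)
    base[:3] = -np.maximum.accumulate(np.maximum(-base[:3][::-1], 1e-2))[::-1]
    base[:3] -= 1e-3 * np.arange(3, 0, -1)
    return _params_to_theta(base, alpha)


def _moment_start(trials: pd.DataFrame) -> np.ndarray | None:
    """Informed start from the SDT criterion estimates: alpha from the mean
    cross-condition ratio, base criteria from the low-condition locations."""
    try:
        low = sdt_estimation.estimate_criteria(trials[trials["condition"] == "low"])
        high = sdt_estimation.estimate_criteria(trials[trials["condition"] == "high"])
        ratios = sdt_estimation.criterion_ratios(low, high)
        r = np.nanmean(list(ratios.r.values()))
        alpha = np.sqrt(3.0 / np.clip(r, 0.35, 12.0))
        alpha = float(np.clip(alpha, *ALPHA_BOUNDS))
        base = np.array([low.t[i] for i in (-3, -2, -1, 1, 2, 3)]) / alpha
        if not (base[0] < base[1] < base[2] < 0 < base[3] < base[4] < base[5]):
            return None
        return _params_to_theta(base, alpha)
    except (ValueError, KeyError):
        return None


def fit_attraction(
    trials: pd.DataFrame,
    n_restarts: int = 10,
    seed=None,
    table: ResponseTable | None = None,
) -> AttractionFit:
    """Fit the attraction model to one subject's (balanced) trials.

    Runs Nelder-Mead from ``n_restarts`` random starts in the transformed
    parameter space plus a moment-based start; returns the best restart.
    Non-convergence of every restart is flagged on the result rather than
    raised, since the best point found is still usable.
    """
    if table is None:
        table = build_response_table(trials)
    for k in CONDITIONS:
        if len(table.orientations[k]) == 0:
            raise ValueError(f"no trials in the {k} variability condition")
    rng = np.random.default_rng(seed)

    starts = []
    for informed in (_quantile_start(table),
                     _moment_start(trials) if trials is not None else None):
        if informed is not None:
            starts.append(informed)
    n_informed = len(starts)
    while len(starts) < n_restarts + n_informed:
        theta = np.empty(7)
        theta[0] = rng.uniform(*np.log(ALPHA_BOUNDS))
        theta[1:] = np.log(rng.uniform(0.5, 12.0, size=6))
        starts.append(theta)

    best = None
    restart_lls = []
    any_converged = False
    for theta0 in starts:
        simplex = np.vstack([theta0, theta0 + 0.6 * np.eye(7)])
        res = optimize.minimize(
            _neg_ll,
            theta0,
            args=(table,),
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "xatol": 1e-4,
                "fatol": 1e-7,
                "maxiter": 4000,
                "maxfev": 4000,
            },
        )
        restart_lls.append(-res.fun)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    base, alpha = _theta_to_params(best.x)
    return AttractionFit(
        base_criteria=base,
        alpha=float(np.clip(alpha, *ALPHA_BOUNDS)),
        log_likelihood=float(-best.fun),
        n_restarts=len(starts),
        converged=any_converged,
        restart_log_likelihoods=restart_lls,
    )
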