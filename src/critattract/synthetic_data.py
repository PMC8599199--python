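"""Stimulus generation and observer simulation for the external-noise design.

The task: on each trial a grating orientation is drawn from one of two
overlapping normal distributions (D1 biased counter-clockwise, D2 biased
clockwise) and the observer reports the likely generating distribution plus
a 1-4 confidence rating.  Two conditions are presented in alternating
50-trial blocks: low variability (means +-2.4 deg, SD 6 deg) and high
variability (means +-7.2 deg, SD 18 deg) — an exact 3x scaling, so maximum
attainable sensitivity is d' = 2*mu/sigma = 0.8 in both.

Simulated observers respond via criteria placed directly in orientation
space.  A single attraction factor ``alpha`` couples the two conditions'
criterion sets: the low-variability criteria are pushed outward to
``alpha * t_i`` while the high-variability criteria are pulled inward to
``3 * t_i / alpha``.  ``alpha = 1`` leaves the sets at their optimal 3x
offset; ``alpha = sqrt(3)`` makes them coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import NATIVE_COLUMNS

__all__ = [
    "ConditionDesign",
    "ExperimentLayout",
    "ObserverParams",
    "LOW_DESIGN",
    "HIGH_DESIGN",
    "apply_attraction",
    "generate_stimuli",
    "simulate_observer",
    "simulate_cohort",
    "timecourse_attraction",
]


@dataclass(frozen=True)
class ConditionDesign:
    """Generating distributions of one condition: N(-mu, sigma^2) for D1
    and N(+mu, sigma^2) for D2."""

    mu_deg: float
    sigma_deg: float
    label: str

    def __post_init__(self):
        if self.sigma_deg <= 0:
            raise ValueError(f"sigma_deg must be > 0, got {self.sigma_deg}")
        if self.mu_deg <= 0:
            raise ValueError(f"mu_deg must be > 0, got {self.mu_deg}")

    @property
    def max_dprime(self) -> float:
        """Sensitivity of an ideal observer with no internal noise: 2*mu/sigma."""
        return 2.0 * self.mu_deg / self.sigma_deg


LOW_DESIGN = ConditionDesign(mu_deg=2.4, sigma_deg=6.0, label="low")
HIGH_DESIGN = ConditionDesign(mu_deg=7.2, sigma_deg=18.0, label="high")


@dataclass(frozen=True)
class ExperimentLayout:
    """Block structure: alternating-condition blocks grouped into runs."""

    n_runs: int = 4
    blocks_per_run: int = 4
    trials_per_block: int = 50
    first_condition: str | None = None  # None: chosen from the seed

    @property
    def n_blocks(self) -> int:
        return self.n_runs * self.blocks_per_run

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class ObserverParams:
    """Criterion-based observer.

    ``base_criteria`` are the six confidence criteria
    (t_-3 <= t_-2 <= t_-1 <= 0 <= t_1 <= t_2 <= t_3) on the
    low-variability scale; the decision criterion t_0 is fixed at 0
    (vertical).  ``alpha`` is the attraction factor; ``internal_noise_deg``
    is additive Gaussian noise on the perceived orientation (default 0:
    full-contrast, long-duration gratings carry negligible internal noise,
    as borne out by near-ceiling empirical d').
    """

    base_criteria: tuple = (-9.0, -6.0, -3.0, 3.0, 6.0, 9.0)
    alpha: float = 1.0
    internal_noise_deg: float = 0.0
    rt_median_ms: float = 855.0
    rt_sigma: float = 0.3

    def __post_init__(self):
        crit = np.asarray(self.base_criteria, dtype=float)
        if crit.shape != (6,):
            raise ValueError("base_criteria must hold the six confidence criteria")
        full = np.concatenate([crit[:3], [0.0], crit[3:]])
        if np.any(np.diff(full) < 0):
            raise ValueError("criteria must satisfy t_-3<=t_-2<=t_-1<=0<=t_1<=t_2<=t_3")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.internal_noise_deg < 0:
            raise ValueError("internal_noise_deg must be >= 0")


def apply_attraction(base_criteria, alpha: float):
    """Condition-specific criterion sets under multiplicative attraction.

    The low-variability set moves outward to ``alpha * t_i``; the
    high-variability set moves inward to ``3 * t_i / alpha``.  Their
    element-wise ratio is therefore ``3 / alpha**2`` for every criterion:
    3 at ``alpha = 1`` (independent, optimally offset sets) and 1 at
    ``alpha = sqrt(3)`` (fully collapsed).

    Returns
    -------
    (low_criteria, high_criteria) : pair of ndarray
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    base = np.asarray(base_criteria, dtype=float)
    return alpha * base, 3.0 * base / alpha


def generate_stimuli(
    layout: ExperimentLayout = ExperimentLayout(),
    designs: tuple[ConditionDesign, ConditionDesign] = (LOW_DESIGN, HIGH_DESIGN),
    seed=None,
) -> pd.DataFrame:
    """Draw the stimulus sequence for one session.

    Per trial the generating distribution is D1 or D2 with probability 1/2
    and the orientation is drawn from N(+-mu, sigma^2) of the block's
    condition.  Conditions strictly alternate across blocks; the first
    block's condition is taken from ``layout.first_condition`` or chosen
    at random from the seed.

    Returns a DataFrame with columns condition, true_distribution,
    orientation_deg, run_index, block_index, trial_index.
    """
    rng = np.random.default_rng(seed)
    by_label = {d.label: d for d in designs}
    if set(by_label) != {"low", "high"}:
        raise ValueError("designs must contain one 'low' and one 'high' condition")

    n = layout.n_trials
    if n == 0:
        return pd.DataFrame(
            columns=[
                "condition", "true_distribution", "orientation_deg",
                "run_index", "block_index", "trial_index",
            ]
        )

    first = layout.first_condition or ("low", "high")[rng.integers(2)]
    order = ("low", "high") if first == "low" else ("high", "low")
    block_conditions = [order[b % 2] for b in range(layout.n_blocks)]

    cond = np.repeat(block_conditions, layout.trials_per_block)
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)  # -1 -> D1, +1 -> D2
    mu = np.array([by_label[c].mu_deg for c in cond])
    sigma = np.array([by_label[c].sigma_deg for c in cond])
    orientation = rng.normal(sign * mu, sigma)

    blocks = np.repeat(np.arange(layout.n_blocks), layout.trials_per_block)
    return pd.DataFrame(
        {
            "condition": cond,
            "true_distribution": np.where(sign < 0, "D1", "D2"),
            "orientation_deg": orientation,
            "run_index": blocks // layout.blocks_per_run + 1,
            "block_index": blocks % layout.blocks_per_run + 1,
            "trial_index": np.tile(np.arange(1, layout.trials_per_block + 1), layout.n_blocks),
        }
    )


def _rate_and_classify(percepts: np.ndarray, criteria6: np.ndarray):
    """Map percepts to (choice, confidence) through the 8-region partition.

    Regions are half-open, lower-inclusive: a percept exactly at a
    criterion falls in the region above it (a probability-zero event for
    continuous noise, fixed for reproducibility).
    """
    edges = np.concatenate([criteria6[:3], [0.0], criteria6[3:]])
    idx = np.searchsorted(edges, percepts, side="right")  # 0..7
    choice = np.where(idx >= 4, "D2", "D1")
    confidence = np.where(idx >= 4, idx - 3, 4 - idx)
    return choice, confidence


def simulate_observer(
    stimuli: pd.DataFrame,
    observer: ObserverParams = ObserverParams(),
    seed=None,
    subject_id: str = "sim",
    alpha_schedule=None,
) -> pd.DataFrame:
    """Simulate one observer's choices and confidence on a stimulus sequence.

    The percept is the orientation plus additive internal noise; the choice
    is D2 when the percept exceeds t_0 = 0 and the confidence rating is one
    plus the number of same-sign condition-specific criteria the percept
    exceeds (capped at 4).  RTs are cosmetic (lognormal, equal across
    conditions) and never used by any analysis.

    ``alpha_schedule`` optionally maps within-block trial number (1-based)
    to an effective attraction factor, emulating within-block decay of the
    carry-over from the previous block.
    """
    rng = np.random.default_rng(seed)
    n = len(stimuli)
    percept = stimuli["orientation_deg"].to_numpy(dtype=float)
    if observer.internal_noise_deg > 0:
        percept = percept + rng.normal(0.0, observer.internal_noise_deg, size=n)

    base = np.asarray(observer.base_criteria, dtype=float)
    cond = stimuli["condition"].to_numpy()
    choice = np.empty(n, dtype=object)
    confidence = np.empty(n, dtype=int)

    if alpha_schedule is None:
        low_c, high_c = apply_attraction(base, observer.alpha)
        for label, crit in (("low", low_c), ("high", high_c)):
            mask = cond == label
            choice[mask], confidence[mask] = _rate_and_classify(percept[mask], crit)
    else:
        trial_in_block = stimuli["trial_index"].to_numpy()
        for t in np.unique(trial_in_block):
            low_c, high_c = apply_attraction(base, float(alpha_schedule(int(t))))
            for label, crit in (("low", low_c), ("high", high_c)):
                mask = (cond == label) & (trial_in_block == t)
                if mask.any():
                    choice[mask], confidence[mask] = _rate_and_classify(percept[mask], crit)

    rt = rng.lognormal(np.log(observer.rt_median_ms), observer.rt_sigma, size=n)
    out = stimuli.copy()
    out["subject_id"] = subject_id
    out["choice"] = choice
    out["confidence"] = confidence
    out["rt_ms"] = rt
    return out[NATIVE_COLUMNS]


def simulate_cohort(
    n_subjects: int = 26,
    observer_sampler=None,
    layout: ExperimentLayout = ExperimentLayout(),
    designs=(LOW_DESIGN, HIGH_DESIGN),
    seed=None,
):
    """Simulate ``n_subjects`` independent sessions.

    ``observer_sampler(rng) -> ObserverParams`` draws each subject's true
    parameters (default: every subject at the default ObserverParams).

    Returns
    -------
    trials : list of DataFrame
    params : list of ObserverParams, the recorded generating parameters
    """
    rng = np.random.default_rng(seed)
    if observer_sampler is None:
        observer_sampler = lambda r: ObserverParams()  # noqa: E731
    trials, params = [], []
    for s in range(n_subjects):
        obs = observer_sampler(rng)
        stim = generate_stimuli(layout, designs, seed=rng)
        trials.append(simulate_observer(stim, obs, seed=rng, subject_id=f"s{s + 1:02d}"))
        params.append(obs)
    return trials, params


def gaussian_alpha_sampler(mean: float = 1.244, sd: float = 0.0, **observer_kwargs):
    """Sampler for :func:`simulate_cohort`: alpha ~ N(mean, sd^2) clipped
    to stay positive; other observer parameters fixed."""

    def sample(rng) -> ObserverParams:
        alpha = mean if sd == 0 else max(float(rng.normal(mean, sd)), 0.05)
        return ObserverParams(alpha=alpha, **observer_kwargs)

    return sample


def timecourse_attraction(
    alpha_start: float, alpha_end: float, decay_constant: float, trial_in_block: int
) -> float:
    """Effective attraction factor at a given within-block trial (1-based).

    Exponential relaxation from ``alpha_start`` at trial 1 toward
    ``alpha_end`` at rate ``decay_constant`` per trial:
    alpha(t) = end + (start - end) * exp(-decay * (t - 1)).
    Emulates attraction being strongest right after a block switch.
    """
    if decay_constant <= 0:
        raise ValueError("decay_constant must be > 0")
    if trial_in_block < 1:
        raise ValueError("trial_in_block is 1-based")
    return alpha_end + (alpha_start - alpha_end) * float(
        np.exp(-decay_constant * (trial_in_block - 1))
    )
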