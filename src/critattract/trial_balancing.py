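"""Congruence-based trial exclusion.

Because orientations are sampled from the generating distributions, the
realised proportion of congruent trials (orientation polarity matching the
generating mean's polarity) fluctuates between the two conditions, which
would induce spurious between-condition differences in attainable accuracy.
The remedy: if one condition ends up with m more congruent trials, drop m
congruent trials from that condition and m incongruent trials from the
other, taking the latest qualifying trials of the session first, so that
both congruence classes are exactly matched across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BalanceReport", "label_congruence", "balance_trials", "BalanceError"]


class BalanceError(ValueError):
    """Balancing is impossible (not enough removable trials)."""


@dataclass
class BalanceReport:
    """Congruent/incongruent counts before balancing and the exclusions made."""

    n_congruent_low: int
    n_congruent_high: int
    n_incongruent_low: int
    n_incongruent_high: int
    m_excess: int
    excluded_trial_ids: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return 2 * self.m_excess

    @property
    def exclusion_rate(self) -> float:
        total = (
            self.n_congruent_low + self.n_congruent_high
            + self.n_incongruent_low + self.n_incongruent_high
        )
        return self.n_excluded / total if total else 0.0


def label_congruence(trials: pd.DataFrame) -> np.ndarray:
    """True where the stimulus orientation has the same polarity as the mean
    of its generating distribution (D1 mean negative/CCW, D2 positive/CW).

    An orientation of exactly 0 deg is classed incongruent — a measure-zero
    case under continuous sampling, fixed for reproducibility.
    """
    ori = trials["orientation_deg"].to_numpy(dtype=float)
    gen_sign = np.where(trials["true_distribution"].to_numpy() == "D2", 1.0, -1.0)
    return ori * gen_sign > 0


def balance_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, BalanceReport]:
    """Equalise congruent and incongruent trial counts across conditions.

    Rows must be in session order (the order trials were experienced); the
    exclusions are made by a single backward scan so the latest qualifying
    trials are removed first.  Returns the kept trials (original order and
    index) and a :class:`BalanceReport`.  Already-balanced input is
    returned unchanged (idempotence).
    """
    congruent = label_congruence(trials)
    is_low = trials["condition"].to_numpy() == "low"

    n_cong_low = int(np.sum(congruent & is_low))
    n_cong_high = int(np.sum(congruent & ~is_low))
    n_incong_low = int(np.sum(~congruent & is_low))
    n_incong_high = int(np.sum(~congruent & ~is_low))

    m = n_cong_low - n_cong_high
    if m >= 0:
        cong_mask = congruent & is_low       # drop m congruent from low ...
        incong_mask = ~congruent & ~is_low   # ... and m incongruent from high
    else:
        m = -m
        cong_mask = congruent & ~is_low
        incong_mask = ~congruent & is_low

    report = BalanceReport(
        n_congruent_low=n_cong_low,
        n_congruent_high=n_cong_high,
        n_incongruent_low=n_incong_low,
        n_incongruent_high=n_incong_high,
        m_excess=m,
    )
    if m == 0:
        return trials, report

    if np.sum(incong_mask) < m:
        raise BalanceError(
            f"cannot balance: need to remove {m} incongruent trials but only "
            f"{int(np.sum(incong_mask))} are available"
        )

    drop = np.zeros(len(trials), dtype=bool)
    for mask in (cong_mask, incong_mask):
        positions = np.flatnonzero(mask)[-m:]  # latest-first removal
        drop[positions] = True

    report.excluded_trial_ids = list(trials.index[drop])
    return trials.loc[~drop], report
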