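"""Group-level statistics: condition comparisons, criterion-ratio tests,
within-block time courses, and individual-difference correlations.

All quantities are recomputable from a trial-level CSV alone.  Frequentist
tests are paired t-tests (Cohen's d computed on the difference scores) and
Wilcoxon signed-rank tests; Bayesian evidence uses the default JZS Bayes
factor (Cauchy prior on standardised effect size, scale sqrt(2)/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import integrate, stats

from . import sdt_estimation
from .trial_balancing import balance_trials

__all__ = [
    "SubjectSummary",
    "paired_t",
    "jzs_bf",
    "wilcoxon_signrank",
    "scaled_criteria_test",
    "timecourse",
    "confidence_effect_correlations",
    "summarize_subject",
    "group_report",
]


@dataclass
class SubjectSummary:
    """Per-subject condition means and effects (high minus low)."""

    subject_id: str
    mean_confidence: dict
    mean_rt: dict
    dprime: dict
    conf_effect: float
    dprime_effect: float
    rt_effect: float


def paired_t(x, y=None) -> dict:
    """Paired (or one-sample, when ``y`` is None) t-test with effect size.

    Cohen's d uses the paired definition mean(diff)/SD(diff); with zero
    spread in the differences the statistic is undefined and returned as
    signed infinity with a ``degenerate`` flag.
    """
    x = np.asarray(x, dtype=float)
    diff = x if y is None else x - np.asarray(y, dtype=float)
    n = len(diff)
    if n < 2:
        raise ValueError("need at least two pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:
            return {"t": 0.0, "df": n - 1, "p": 1.0, "cohen_d": 0.0, "degenerate": False}
        sign = float(np.sign(diff.mean()))
        return {"t": sign * np.inf, "df": n - 1, "p": 0.0,
                "cohen_d": sign * np.inf, "degenerate": True}
    t, p = stats.ttest_1samp(diff, 0.0)
    return {"t": float(t), "df": n - 1, "p": float(p),
            "cohen_d": float(diff.mean() / sd), "degenerate": False}


def jzs_bf(t: float, n: int, r: float = np.sqrt(2) / 2) -> float:
    """Default JZS Bayes factor BF10 for a one-sample/paired t statistic.

    The alternative places a Cauchy(0, r) prior on the standardised effect
    size delta; the marginal likelihood is the noncentral-t density averaged
    over that prior, evaluated by adaptive quadrature:

        BF10 = int T_df(t; delta*sqrt(n)) Cauchy(delta; 0, r) d delta
               / T_df(t; 0)
    """
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * np.sqrt(n)) * stats.cauchy.pdf(delta, 0, r)

    left, _ = integrate.quad(integrand, -np.inf, 0.0, limit=200)
    right, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    marginal = left + right
    return float(marginal / stats.t.pdf(t, df))


def wilcoxon_signrank(x, threshold: float = 0.0, alternative: str = "two-sided") -> dict:
    """Wilcoxon signed-rank test of a sample against a threshold (used for
    the criterion ratios r_i against the no-attraction value 3).  Values
    exactly at the threshold are dropped; an all-tie sample is an error."""
    x = np.asarray(x, dtype=float) - threshold
    x = x[x != 0]
    if len(x) == 0:
        raise ValueError("no informative pairs: all values equal the threshold")
    w, p = stats.wilcoxon(x, alternative=alternative)
    return {"W": float(w), "p": float(p), "n_informative": int(len(x))}


def scaled_criteria_test(low_t: pd.DataFrame, high_t: pd.DataFrame) -> dict:
    """Per-criterion paired t of 3*t_low against t_high.

    ``low_t``/``high_t``: one row per subject, one column per confidence
    criterion index (-3..-1, 1..3).  The difference is signed so that a
    positive mean indicates the scaled low-variability criterion is more
    extreme (further from vertical) than the high-variability one — the
    signature of attraction.
    """
    out = {}
    for i in sdt_estimation.CONFIDENCE_INDICES:
        scaled_low = 3.0 * low_t[i].to_numpy(dtype=float)
        high = high_t[i].to_numpy(dtype=float)
        sign = 1.0 if i > 0 else -1.0
        out[i] = paired_t(sign * (scaled_low - high))
    return out


def timecourse(trials: pd.DataFrame, epoch_length: int = 10) -> pd.DataFrame:
    """Mean confidence by condition and within-block epoch.

    ``epoch_length`` must divide the block length; an epoch equal to the
    block length reproduces the block mean, 25 gives the half-block split,
    10 the five-epoch profile.
    """
    trials_per_block = int(trials["trial_index"].max())
    if trials_per_block % epoch_length:
        raise ValueError(
            f"epoch_length {epoch_length} does not divide block length {trials_per_block}"
        )
    epoch = (trials["trial_index"] - 1) // epoch_length + 1
    grouped = (
        trials.assign(epoch=epoch)
        .groupby(["condition", "epoch"], sort=True)["confidence"]
        .mean()
        .unstack("epoch")
    )
    return grouped


def confidence_effect_correlations(summaries: pd.DataFrame) -> dict:
    """Pearson correlations of the per-subject confidence effect with the
    d' effect, the RT effect, and (when present) the fitted attraction
    factor alpha.  Expects one row per subject."""
    if len(summaries) < 3:
        raise ValueError("need at least three subjects")
    conf = summaries["conf_effect"].to_numpy(dtype=float)
    out = {}
    for name, col in (("dprime_effect", "dprime_effect"),
                      ("rt_effect", "rt_effect"),
                      ("alpha", "alpha")):
        if col in summaries and summaries[col].notna().all():
            r, p = stats.pearsonr(conf, summaries[col].to_numpy(dtype=float))
            out[f"conf_vs_{name}"] = {"r": float(r), "p": float(p)}
    return out


def summarize_subject(trials: pd.DataFrame) -> SubjectSummary:
    """Condition means of confidence, RT and d' for one subject."""
    mean_conf, mean_rt, dprime = {}, {}, {}
    for cond in ("low", "high"):
        sub = trials[trials["condition"] == cond]
        mean_conf[cond] = float(sub["confidence"].mean())
        mean_rt[cond] = float(sub["rt_ms"].mean()) if sub["rt_ms"].notna().any() else float("nan")
        dprime[cond] = sdt_estimation.compute_dprime(sub)
    return SubjectSummary(
        subject_id=str(trials["subject_id"].iloc[0]),
        mean_confidence=mean_conf,
        mean_rt=mean_rt,
        dprime=dprime,
        conf_effect=mean_conf["high"] - mean_conf["low"],
        dprime_effect=dprime["high"] - dprime["low"],
        rt_effect=mean_rt["high"] - mean_rt["low"],
    )


def group_report(
    trials: pd.DataFrame,
    fitted_alphas: dict | None = None,
    one_sided_ratio_test: bool = False,
    epoch_length: int = 10,
) -> dict:
    """Full statistical report for a multi-subject trial table.

    Per subject: congruence balancing, condition summaries, criterion
    locations and cross-condition ratios.  Group level: paired comparisons
    of confidence/d'/RT with JZS Bayes factors, signed-rank tests of each
    r_i against 3, the scaled-criteria t-tests, within-block time courses,
    and individual-difference correlations.
    """
    summaries, ratios_rows, low_rows, high_rows, balance_info = [], [], [], [], []
    epoch_tables = []
    for subject_id, sub in trials.groupby("subject_id", sort=True):
        kept, report = balance_trials(sub.reset_index(drop=True))
        balance_info.append(
            {"subject_id": str(subject_id), "n_excluded": report.n_excluded,
             "exclusion_rate": report.exclusion_rate}
        )
        summary = summarize_subject(kept)
        low = sdt_estimation.estimate_criteria(kept[kept["condition"] == "low"])
        high = sdt_estimation.estimate_criteria(kept[kept["condition"] == "high"])
        ratio = sdt_estimation.criterion_ratios(low, high)
        summaries.append(asdict(summary))
        ratios_rows.append({**ratio.r, "t0_difference_deg": ratio.t0_difference_deg,
                            "t0_low": low.t[0], "t0_high": high.t[0]})
        low_rows.append(low.t)
        high_rows.append(high.t)
        epoch_tables.append(timecourse(kept, epoch_length))

    summary_df = pd.DataFrame(summaries)
    for col in ("conf_effect", "dprime_effect", "rt_effect"):
        summary_df[col] = summary_df[col].astype(float)
    if fitted_alphas is not None:
        summary_df["alpha"] = summary_df["subject_id"].map(fitted_alphas)

    ratios_df = pd.DataFrame(ratios_rows)
    low_df = pd.DataFrame(low_rows)
    high_df = pd.DataFrame(high_rows)

    def _paired_with_bf(low_key, high_key, values):
        res = paired_t(values)
        res["bf10"] = jzs_bf(res["t"], len(values)) if np.isfinite(res["t"]) else float("inf")
        return res

    n = len(summary_df)
    group = {
        "n_subjects": n,
        "confidence": _paired_with_bf("low", "high", summary_df["conf_effect"].to_numpy()),
        "dprime": _paired_with_bf("low", "high", summary_df["dprime_effect"].to_numpy()),
        "mean_dprime": {
            "low": float(np.mean([s["dprime"]["low"] for s in summaries])),
            "high": float(np.mean([s["dprime"]["high"] for s in summaries])),
        },
        "mean_confidence": {
            "low": float(np.mean([s["mean_confidence"]["low"] for s in summaries])),
            "high": float(np.mean([s["mean_confidence"]["high"] for s in summaries])),
        },
        "t0_deg": {
            "low": float(np.mean(ratios_df["t0_low"])),
            "high": float(np.mean(ratios_df["t0_high"])),
        },
        "mean_ratios": {int(i): float(np.nanmean(ratios_df[i]))
                        for i in sdt_estimation.CONFIDENCE_INDICES},
    }
    if summary_df["rt_effect"].notna().all():
        group["rt"] = _paired_with_bf("low", "high", summary_df["rt_effect"].to_numpy())

    alternative = "less" if one_sided_ratio_test else "two-sided"
    if n >= 5:
        group["ratio_vs_3"] = {
            int(i): wilcoxon_signrank(ratios_df[i].dropna().to_numpy(), 3.0, alternative)
            for i in sdt_estimation.CONFIDENCE_INDICES
        }
        group["scaled_criteria"] = {
            int(i): res for i, res in scaled_criteria_test(low_df, high_df).items()
        }
    if n >= 3:
        group["correlations"] = confidence_effect_correlations(summary_df)

    epochs = sum(epoch_tables) / len(epoch_tables)
    group["timecourse"] = {
        cond: {int(e): float(v) for e, v in epochs.loc[cond].items()} for cond in epochs.index
    }
    group["timecourse_difference"] = {
        int(e): float(epochs.loc["high", e] - epochs.loc["low", e]) for e in epochs.columns
    }

    return {
        "per_subject": {
            "summaries": summaries,
            "ratios": ratios_rows,
            "criteria_low_deg": [{int(k): float(v) for k, v in row.items()} for row in low_rows],
            "criteria_high_deg": [{int(k): float(v) for k, v in row.items()} for row in high_rows],
            "balancing": balance_info,
        },
        "group": group,
    }
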