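"""Trial-level CSV input/output, run configuration, and logging.

Trial data are held in a :class:`pandas.DataFrame` with one row per trial
(the "native" schema below).  A second column dialect follows the Confidence
Database convention (``Subj_idx``, ``Stimulus``, ``Response``, ``Confidence``,
``RT_dec``, ``Condition``) so datasets can be exchanged with that repository.

Native schema
-------------
subject_id : str
condition : {"low", "high"}           external-variability condition
run_index, block_index, trial_index : int (1-based; trial_index within block)
orientation_deg : float               negative = CCW, positive = CW, 0 = vertical
true_distribution : {"D1", "D2"}      generating distribution (D1 CCW-biased)
choice : {"D1", "D2"}
confidence : int in 1..4
rt_ms : float >= 0, or missing
"""

from __future__ import annotations

import logging
import sys

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("critattract")

#: canonical column order of the native dialect
NATIVE_COLUMNS = [
    "subject_id",
    "condition",
    "run_index",
    "block_index",
    "trial_index",
    "orientation_deg",
    "true_distribution",
    "choice",
    "confidence",
    "rt_ms",
]

#: Confidence-Database column names for the shared fields; extra
#: design columns (orientation, run/block/trial) travel alongside them.
CONFDB_RENAME = {
    "subject_id": "Subj_idx",
    "true_distribution": "Stimulus",
    "choice": "Response",
    "confidence": "Confidence",
    "rt_ms": "RT_dec",
    "condition": "Condition",
    "orientation_deg": "Orientation",
    "run_index": "Run",
    "block_index": "Block",
    "trial_index": "Trial_in_block",
}

CONDITIONS = ("low", "high")
DISTRIBUTIONS = ("D1", "D2")

#: run-configuration defaults: the two-condition external-noise design
#: (means +-2.4 deg / +-7.2 deg, SDs 6 deg / 18 deg, 4 runs x 4 alternating
#: 50-trial blocks = 800 trials) plus simulator and fit options.
CONFIG_DEFAULTS = {
    "mu_low": 2.4,
    "sigma_low": 6.0,
    "mu_high": 7.2,
    "sigma_high": 18.0,
    "n_runs": 4,
    "blocks_per_run": 4,
    "trials_per_block": 50,
    "n_trials": 800,
    "n_subjects": 26,
    "base_criteria": [-9.0, -6.0, -3.0, 3.0, 6.0, 9.0],
    "alpha": 1.244,
    "alpha_sd": 0.0,
    "internal_noise_deg": 0.0,
    "seed": 0,
    "n_restarts": 10,
}


class TrialFormatError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class TrialValidationError(ValueError):
    """One or more rows violate the trial-record invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid trial rows:\n" + "\n".join(problems)
        )


def setup_logging(verbosity: int = 0) -> None:
    """Attach a stderr handler; verbosity 0 = WARNING, 1 = INFO, 2+ = DEBUG."""
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbosity, 2)]
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a native-schema trial table, returning it with clean dtypes.

    Raises
    ------
    TrialFormatError
        if a required column is absent.
    TrialValidationError
        listing every offending row (1-based CSV line numbers, counting
        the header as line 1).
    """
    missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required column(s): {', '.join(missing)}")

    df = df[NATIVE_COLUMNS].copy()
    problems: list[str] = []

    def flag(mask: pd.Series, message: str) -> None:
        for pos in np.flatnonzero(mask.to_numpy()):
            problems.append(f"line {pos + 2}: {message}")

    flag(~df["condition"].isin(CONDITIONS), "condition must be 'low' or 'high'")
    flag(~df["true_distribution"].isin(DISTRIBUTIONS), "true_distribution must be 'D1' or 'D2'")
    flag(~df["choice"].isin(DISTRIBUTIONS), "choice must be 'D1' or 'D2'")

    conf = pd.to_numeric(df["confidence"], errors="coerce")
    flag(~conf.isin([1, 2, 3, 4]), "confidence must be an integer in 1..4")

    for col in ("run_index", "block_index", "trial_index"):
        idx = pd.to_numeric(df[col], errors="coerce")
        flag(idx.isna() | (idx < 1) | (idx != idx.round()), f"{col} must be an integer >= 1")

    ori = pd.to_numeric(df["orientation_deg"], errors="coerce")
    flag(ori.isna(), "orientation_deg must be a real number")

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    flag(df["rt_ms"].notna() & rt.isna() | (rt < 0), "rt_ms must be >= 0 or empty")

    # blocked design: one condition per (subject, run, block)
    ncond = df.groupby(["subject_id", "run_index", "block_index"])["condition"].transform("nunique")
    flag(ncond > 1, "block mixes low and high variability trials")

    if problems:
        raise TrialValidationError(problems)

    out = df.copy()
    out["confidence"] = conf.astype(int)
    for col in ("run_index", "block_index", "trial_index"):
        out[col] = pd.to_numeric(out[col]).astype(int)
    out["orientation_deg"] = ori.astype(float)
    out["rt_ms"] = rt.astype(float)
    out["subject_id"] = out["subject_id"].astype(str)
    return out


def _from_confdb(df: pd.DataFrame) -> pd.DataFrame:
    inverse = {v: k for k, v in CONFDB_RENAME.items()}
    missing = [c for c in CONFDB_RENAME.values() if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=inverse)
    # Confidence-DB codes stimulus/response numerically (1, 2) and RT in seconds
    df["true_distribution"] = df["true_distribution"].map({1: "D1", 2: "D2"})
    df["choice"] = df["choice"].map({1: "D1", 2: "D2"})
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce") * 1000.0
    return df


def read_trials(path, dialect: str = "native") -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Parameters
    ----------
    path : str or path-like
    dialect : {"native", "confidence_db"}
    """
    df = pd.read_csv(path)
    if dialect == "confidence_db":
        df = _from_confdb(df)
    elif dialect != "native":
        raise ValueError(f"unknown dialect {dialect!r}")
    trials = validate_trials(df)
    logger.info("read %d trials from %s (%s dialect)", len(trials), path, dialect)
    return trials


def write_trials(trials: pd.DataFrame, path, dialect: str = "native") -> None:
    """Write validated trials to CSV with a deterministic column order."""
    trials = validate_trials(trials) if len(trials) else trials[NATIVE_COLUMNS]
    if dialect == "native":
        out = trials
    elif dialect == "confidence_db":
        out = trials.copy()
        out["true_distribution"] = out["true_distribution"].map({"D1": 1, "D2": 2})
        out["choice"] = out["choice"].map({"D1": 1, "D2": 2})
        out["rt_ms"] = out["rt_ms"] / 1000.0
        out = out.rename(columns=CONFDB_RENAME)
        out = out[[CONFDB_RENAME[c] for c in NATIVE_COLUMNS]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, index=False, float_format="%.17g")
    logger.info("wrote %d trials to %s (%s dialect)", len(trials), path, dialect)


def load_config(path=None) -> dict:
    """Load a YAML run configuration, filling defaults for absent keys.

    Defaults encode the study design (means +-2.4/+-7.2 deg, SDs 6/18 deg,
    800 trials in 16 alternating 50-trial blocks).  Unknown keys are
    rejected so typos cannot silently fall back to defaults.
    """
    config = dict(CONFIG_DEFAULTS)
    if path is None:
        return config
    with open(path) as fh:
        try:
            user = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise TrialFormatError(f"cannot parse config {path}: {exc}") from exc
    if user is None:
        return config
    if not isinstance(user, dict):
        raise TrialFormatError(f"config {path} must be a mapping")
    unknown = sorted(set(user) - set(CONFIG_DEFAULTS))
    if unknown:
        raise TrialFormatError(f"unknown config key(s): {', '.join(unknown)}")
    config.update(user)
    if "n_trials" not in user:
        config["n_trials"] = (
            config["n_runs"] * config["blocks_per_run"] * config["trials_per_block"]
        )
    return config
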