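"""Signal-detection analysis of trial logs.

Per subject and condition cell (signal category x visual field), hit and
false-alarm rates are computed with the log-linear correction
(h + 0.5)/(n + 1) applied uniformly to every cell, then transformed to
sensitivity d' = z(HR) - z(FAR) and criterion c = -(z(HR) + z(FAR))/2.
Reaction-time summaries average correct trials only (incorrect-trial means
reported separately as a speed-accuracy audit).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "compute_rates",
    "dprime",
    "criterion",
    "rt_summary",
    "subject_condition_summary",
    "loglinear_rate",
]

DEFAULT_GROUPING = ("block", "visual_field")


def loglinear_rate(count, n):
    """Log-linear corrected proportion (count + 0.5)/(n + 1): keeps rates
    strictly inside (0, 1) so the z transform is always defined."""
    return (np.asarray(count, dtype=float) + 0.5) / (np.asarray(n, dtype=float) + 1.0)


def _clean(log: pd.DataFrame) -> pd.DataFrame:
    if log.empty:
        raise ValueError("empty trial log")
    if "practice" in log.columns:
        log = log[~log["practice"].astype(bool)]
    return log


def compute_rates(log: pd.DataFrame, grouping=DEFAULT_GROUPING) -> pd.DataFrame:
    """Hit/false-alarm rate table per subject x grouping keys.

    Every group must contain at least one signal and one noise trial; rates
    are corrected, z-transformed and returned alongside the raw counts.
    """
    log = _clean(log)
    keys = ["subject_id", *grouping] if "subject_id" in log.columns else list(grouping)
    rows = []
    for key, grp in log.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        sig = grp[grp["stimulus_type"] == "signal"]
        noi = grp[grp["stimulus_type"] == "noise_only"]
        if sig.empty or noi.empty:
            raise ValueError(f"group {key}: needs both signal and noise trials")
        hits = int((sig["response"] == "present").sum())
        fas = int((noi["response"] == "present").sum())
        hr = float(loglinear_rate(hits, len(sig)))
        far = float(loglinear_rate(fas, len(noi)))
        rows.append(
            dict(zip(keys, key))
            | {
                "n_signal": len(sig),
                "n_noise": len(noi),
                "hits": hits,
                "false_alarms": fas,
                "HR": hr,
                "FAR": far,
                "zHR": float(norm.ppf(hr)),
                "zFAR": float(norm.ppf(far)),
            }
        )
    return pd.DataFrame(rows)


def _check_rate(rate: float, name: str) -> None:
    if not 0.0 < rate < 1.0:
        raise ValueError(
            f"{name} = {rate} lies on the boundary; apply the log-linear "
            "correction before transforming"
        )


def dprime(hr: float, far: float) -> float:
    """Sensitivity d' = z(HR) - z(FAR); 0 is chance performance."""
    _check_rate(hr, "HR")
    _check_rate(far, "FAR")
    return float(norm.ppf(hr) - norm.ppf(far))


def criterion(hr: float, far: float) -> float:
    """Response criterion c = -(z(HR) + z(FAR))/2; negative values mark a
    liberal ('present'-prone) observer, positive a conservative one."""
    _check_rate(hr, "HR")
    _check_rate(far, "FAR")
    return float(-(norm.ppf(hr) + norm.ppf(far)) / 2.0)


def rt_summary(log: pd.DataFrame, grouping=DEFAULT_GROUPING) -> pd.DataFrame:
    """Mean RT over correct trials per group (incorrect-trial mean kept as a
    separate column); capped forced-guess trials are excluded from RT means.
    Groups with no correct trials are flagged rather than erroring."""
    log = _clean(log)
    if "forced_guess" in log.columns:
        rt_log = log[~log["forced_guess"].astype(bool)]
    else:
        rt_log = log
    keys = ["subject_id", *grouping] if "subject_id" in log.columns else list(grouping)
    rows = []
    for key, grp in rt_log.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        correct = grp[grp["correct"].astype(bool)]
        incorrect = grp[~grp["correct"].astype(bool)]
        rows.append(
            dict(zip(keys, key))
            | {
                "mean_rt_correct": float(correct["rt_s"].mean()) if len(correct) else np.nan,
                "mean_rt_incorrect": float(incorrect["rt_s"].mean()) if len(incorrect) else np.nan,
                "n_correct": len(correct),
                "n_incorrect": len(incorrect),
                "missing": len(correct) == 0,
            }
        )
    return pd.DataFrame(rows)


def subject_condition_summary(log: pd.DataFrame, grouping=DEFAULT_GROUPING) -> pd.DataFrame:
    """One row per subject x condition with d', c and RT means."""
    rates = compute_rates(log, grouping)
    rates["dprime"] = [dprime(h, f) for h, f in zip(rates["HR"], rates["FAR"])]
    rates["criterion"] = [criterion(h, f) for h, f in zip(rates["HR"], rates["FAR"])]
    rts = rt_summary(log, grouping)
    keys = [k for k in rates.columns if k in rts.columns and k not in
            ("mean_rt_correct", "mean_rt_incorrect")]
    return rates.merge(rts, on=keys, how="left")
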