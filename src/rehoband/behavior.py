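"""Delayed-match-to-sample (DMST) scoring and brain-behaviour correlation.

Working-memory accuracy is the total hit rate (correct "match" responses to
targets) minus the total false-alarm rate ("match" responses to distractors).
RT is the mean response time over all responded test stimuli, targets and
distractors alike. Performance is accuracy divided by RT — the reciprocal of
the inverse efficiency score — so typical values sit around 1.5e-3 per ms.

State-related ReHo changes (cluster-mean z, task minus rest) are related to
performance with Pearson correlations and seeded case-resampling bootstrap
percentile confidence intervals, always within a single group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BehavioralScore:
    """Scored DMST performance for one subject."""

    hit_rate: float
    false_alarm_rate: float
    accuracy: float  # hit rate - false-alarm rate, in [-1, 1]
    rt_ms: float
    performance: float  # accuracy / RT, per ms
    n_targets: int
    n_distractors: int
    n_misses: int


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation with a bootstrap percentile confidence interval."""

    r: float
    p: float
    ci_low: float
    ci_high: float
    n_boot: int
    n: int
    ci_level: float = 0.95


def performance_index(accuracy: float, rt_ms: float) -> float:
    """Accuracy divided by mean RT (per ms); 0 accuracy maps to 0."""
    if not rt_ms > 0:
        raise ValueError(f"RT must be positive, got {rt_ms}")
    return accuracy / rt_ms


def score_dmst(responses: pd.DataFrame, schedule: pd.DataFrame) -> BehavioralScore:
    """Score a DMST response log against its trial schedule.

    ``schedule`` must carry (trial, position, is_target); ``responses`` must
    carry (trial, position, response, rt_ms) with response in
    {"match", "nonmatch", "none"}. Responses that do not map to a scheduled
    test stimulus raise an error listing the offenders. Misses ("none") count
    as non-hits and are excluded from RT averaging.
    """
    for col in ("trial", "position", "is_target"):
        if col not in schedule.columns:
            raise ValueError(f"schedule lacks column {col!r}")
    for col in ("trial", "position", "response"):
        if col not in responses.columns:
            raise ValueError(f"responses lack column {col!r}")
    merged = responses.merge(
        schedule[["trial", "position", "is_target"]],
        on=["trial", "position"],
        how="left",
        indicator=True,
        validate="one_to_one",
    )
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        keys = [
            (int(t), int(p)) for t, p in orphans[["trial", "position"]].to_numpy()
        ]
        raise ValueError(f"response rows with no scheduled stimulus: {keys}")

    is_target = merged["is_target"].astype(bool)
    responded = merged["response"] != "none"
    said_match = merged["response"] == "match"

    n_targets = int(is_target.sum())
    n_distractors = int((~is_target).sum())
    if n_targets == 0 or n_distractors == 0:
        raise ValueError("schedule must contain both targets and distractors")
    hit_rate = float((said_match & is_target).sum() / n_targets)
    fa_rate = float((said_match & ~is_target).sum() / n_distractors)
    accuracy = hit_rate - fa_rate

    rts = merged.loc[responded, "rt_ms"].to_numpy(dtype=float)
    rts = rts[np.isfinite(rts)]
    if rts.size == 0:
        raise ValueError("no responded stimuli; RT undefined")
    rt_ms = float(rts.mean())
    return BehavioralScore(
        hit_rate=hit_rate,
        false_alarm_rate=fa_rate,
        accuracy=accuracy,
        rt_ms=rt_ms,
        performance=performance_index(accuracy, rt_ms),
        n_targets=n_targets,
        n_distractors=n_distractors,
        n_misses=int((~responded).sum()),
    )


def correlate_with_bootstrap(
    x,
    y,
    n_boot: int = 1000,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    ci_level: float = 0.95,
) -> CorrelationReport:
    """Pearson r with two-tailed p and a case-resampling percentile CI.

    The p-value uses the t approximation with n - 2 degrees of freedom.
    Degenerate bootstrap resamples (zero variance) are ignored when taking
    the percentile bounds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)

    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = (xc * yc).sum(axis=1) / den
    rb = rb[np.isfinite(rb)]
    if rb.size == 0:
        raise ValueError("all bootstrap resamples degenerate")
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(rb, [100 * tail, 100 * (1 - tail)])
    return CorrelationReport(
        r=float(r),
        p=float(p),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n=n,
        ci_level=ci_level,
    )
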