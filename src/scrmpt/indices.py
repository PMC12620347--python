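"""Behavioral indices: Stroop inhibition, response proportions, AOI metrics.

The inhibition index IF combines the relative Stroop interference cost with
accuracy: IF = ACC * [2 - (RT_inconsistent - RT_consistent) / RT_consistent].
Higher values mean better inhibitory function; a perfectly accurate
participant with zero interference cost scores 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .tree import PROBE_ORDER, RESPONSE_ORDER

__all__ = [
    "InhibitionScore",
    "AOIRect",
    "inhibition_index",
    "inhibition_index_table",
    "response_proportions",
    "aoi_metrics",
    "group_effect_size",
    "bh_adjust",
]


@dataclass(frozen=True)
class InhibitionScore:
    """Per-participant Stroop summary and the derived IF index."""

    participant_id: object
    acc: float
    rt_consistent: float
    rt_inconsistent: float

    @property
    def IF(self) -> float:
        cost = (self.rt_inconsistent - self.rt_consistent) / self.rt_consistent
        return self.acc * (2.0 - cost)


def inhibition_index(
    trials: pd.DataFrame,
    participant_id: object = None,
    rt_correct_only: bool = True,
) -> InhibitionScore:
    """Compute the IF index from one participant's Stroop trials.

    Accuracy is computed over all trials; condition mean RTs over correct
    trials only by default (set ``rt_correct_only=False`` to use all
    trials).  Requires at least one trial in each condition.
    """
    for col in ("condition", "rt_ms", "correct"):
        if col not in trials.columns:
            raise ValueError(f"Stroop table is missing column {col!r}")
    rt = trials["rt_ms"].to_numpy(dtype=float)
    if np.any(~np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("rt_ms must be finite and positive")
    cond = trials["condition"].to_numpy()
    bad = set(np.unique(cond)) - {"consistent", "inconsistent"}
    if bad:
        raise ValueError(f"unknown Stroop conditions: {sorted(bad)}")
    correct = trials["correct"].astype(bool).to_numpy()
    acc = float(correct.mean())
    means = {}
    for c in ("consistent", "inconsistent"):
        sel = cond == c
        if not sel.any():
            raise ValueError(f"no trials in the {c!r} condition")
        use = sel & correct if rt_correct_only else sel
        if not use.any():  # no correct trials in a condition: fall back to all
            use = sel
        means[c] = float(rt[use].mean())
    return InhibitionScore(
        participant_id=participant_id,
        acc=acc,
        rt_consistent=means["consistent"],
        rt_inconsistent=means["inconsistent"],
    )


def inhibition_index_table(
    trials: pd.DataFrame, rt_correct_only: bool = True
) -> pd.DataFrame:
    """IF scores for every participant in a multi-participant Stroop table."""
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        s = inhibition_index(sub, participant_id=pid, rt_correct_only=rt_correct_only)
        rows.append(
            {
                "participant_id": pid,
                "acc": s.acc,
                "rt_consistent": s.rt_consistent,
                "rt_inconsistent": s.rt_inconsistent,
                "IF": s.IF,
            }
        )
    return pd.DataFrame(rows)


def response_proportions(
    trials: pd.DataFrame, by: tuple[str, ...] = ("group", "condition")
) -> pd.DataFrame:
    """Per-cell response-proportion table with R-I, R-U and accuracy.

    Returns one row per grouping cell x probe with the proportion of each
    response (rows sum to 1), plus per-cell derived quantities: ``R_I``
    (proportion of "intact" responses to related probes), ``R_U``
    ("unrelated" responses to related probes), and trial-weighted overall
    accuracy.  Probes with zero trials yield NaN proportions (missing, not
    zero).
    """
    from .io import validate_trials

    validate_trials(trials)
    keys = [k for k in by if k in trials.columns]
    records = []
    grouped = trials.groupby(list(keys), sort=True) if keys else [((), trials)]
    for key_vals, sub in grouped:
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        cell = dict(zip(keys, key_vals))
        n_correct = 0
        n_total = 0
        props = {}
        for probe in PROBE_ORDER:
            psub = sub[sub["probe"] == probe.value]
            n = len(psub)
            for resp in RESPONSE_ORDER:
                p = (
                    float((psub["response"] == resp.value).mean())
                    if n
                    else float("nan")
                )
                props[(probe.value, resp.value)] = p
            n_correct += int((psub["response"] == probe.value).sum())
            n_total += n
        for probe in PROBE_ORDER:
            rec = dict(cell)
            rec["probe"] = probe.value
            rec["n_trials"] = int((sub["probe"] == probe.value).sum())
            for resp in RESPONSE_ORDER:
                rec[f"p_{resp.value}"] = props[(probe.value, resp.value)]
            rec["R_I"] = props[("related", "intact")]
            rec["R_U"] = props[("related", "unrelated")]
            rec["accuracy"] = n_correct / n_total if n_total else float("nan")
            records.append(rec)
    return pd.DataFrame(records)


@dataclass(frozen=True)
class AOIRect:
    """Closed screen rectangle (pixels, origin top-left): edges count as inside."""

    name: str
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate AOI rectangle {self.name!r}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def overlaps(self, other: "AOIRect") -> bool:
        return not (
            self.x1 < other.x0
            or other.x1 < self.x0
            or self.y1 < other.y0
            or other.y1 < self.y0
        )


def aoi_metrics(
    fixations: pd.DataFrame,
    aois: list[AOIRect] | dict[str, tuple[float, float, float, float]],
    min_duration_ms: float = 100.0,
) -> pd.DataFrame:
    """Fixation duration/frequency metrics per AOI.

    Fixations shorter than ``min_duration_ms`` are dropped first; the
    proportion denominators (FD_P, FF_P) use the total duration/count of all
    retained fixations, inside or outside any AOI, so AOI proportions need
    not sum to 1.  AOIs must not overlap (assignment would be ambiguous).
    """
    if isinstance(aois, dict):
        aois = [AOIRect(name, *rect) for name, rect in aois.items()]
    for i, a in enumerate(aois):
        for b in aois[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"AOIs {a.name!r} and {b.name!r} overlap")
    for col in ("x", "y", "duration_ms"):
        if col not in fixations.columns:
            raise ValueError(f"fixation table is missing column {col!r}")
    dur = fixations["duration_ms"].to_numpy(dtype=float)
    if np.any(dur <= 0):
        raise ValueError("fixation durations must be positive")
    keep = dur >= min_duration_ms
    x = fixations["x"].to_numpy(dtype=float)[keep]
    y = fixations["y"].to_numpy(dtype=float)[keep]
    dur = dur[keep]
    total_dur = float(dur.sum())
    total_n = int(keep.sum())
    rows = []
    for a in aois:
        inside = a.contains(x, y)
        fd = float(dur[inside].sum())
        ff = int(inside.sum())
        rows.append(
            {
                "aoi": a.name,
                "FD": fd,
                "FF": ff,
                "FD_P": fd / total_dur if total_dur > 0 else 0.0,
                "FF_P": ff / total_n if total_n > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def group_effect_size(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-SD Cohen's d and the pooled-variance two-sample t statistic.

    Signals an infinite d explicitly when the pooled SD is zero with
    unequal means (and d = 0 when the means are also equal).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    diff = m1 - m2
    if s_pooled == 0:
        if diff == 0:
            return 0.0, 0.0
        return float(np.sign(diff) * np.inf), float(np.sign(diff) * np.inf)
    d = diff / s_pooled
    t = diff / (s_pooled * np.sqrt(1.0 / n1 + 1.0 / n2))
    return float(d), float(t)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
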