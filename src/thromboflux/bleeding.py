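"""Tail-bleeding assay endpoints.

After tail-tip amputation the tail is immersed in warm saline and
bleeding is watched for up to 20 minutes.  Bleeding typically starts and
stops in cycles; the endpoint is the *total* bleeding time — the sum of
episode durations — capped at the 20-min (1200 s) observation window.
Blood loss is estimated from the reduction in body weight over the test
(the amputated tail tip is weighed with the mouse afterwards, so the
difference reflects blood alone).  Loss is reported in grams; no
mass-to-volume conversion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .stats import (EffectSummary, GroupSummary, TTestResult, effect_summary,
                    summarize, t_test_raw)

__all__ = [
    "BleedEpisode",
    "BleedingRecord",
    "BleedingComparison",
    "DEFAULT_CAP_S",
    "total_bleeding_time",
    "blood_loss",
    "compare_bleeding",
    "read_bleeding_records",
]

#: observation cap — bleeding recorded "up to 20 min"
DEFAULT_CAP_S = 1200.0


@dataclass(frozen=True)
class BleedEpisode:
    """One start/stop bleeding cycle, in seconds from amputation."""

    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.stop_s:
            raise ValueError("episode must satisfy 0 <= start < stop")


@dataclass(frozen=True)
class BleedingRecord:
    """One subject's bleeding episodes and pre/post body weights."""

    subject: str
    group: str
    episodes: tuple[BleedEpisode, ...]
    pre_weight_g: float
    post_weight_g: float

    def __post_init__(self) -> None:
        eps = tuple(sorted(self.episodes, key=lambda e: e.start_s))
        object.__setattr__(self, "episodes", eps)
        for prev, nxt in zip(eps, eps[1:]):
            if nxt.start_s < prev.stop_s:
                raise ValueError(
                    f"overlapping episodes for subject {self.subject!r}: "
                    f"({prev.start_s}, {prev.stop_s}) and ({nxt.start_s}, {nxt.stop_s})")
        if self.post_weight_g < 0 or self.pre_weight_g < self.post_weight_g:
            raise ValueError(
                f"subject {self.subject!r}: weights must satisfy pre >= post >= 0")


@dataclass(frozen=True)
class BleedingComparison:
    """Group report for one endpoint (bleeding time or blood loss)."""

    endpoint: str
    group_a: GroupSummary
    group_b: GroupSummary
    t_test: TTestResult
    effect: EffectSummary


def total_bleeding_time(record: BleedingRecord, cap_s: float = DEFAULT_CAP_S) -> float:
    """Cumulative bleeding time across episodes, truncated at ``cap_s``.

    The sum of episode durations is capped at the observation window
    (20 min by default), so the result never exceeds ``cap_s`` and
    re-capping an already-capped record is a no-op.  Episodes are
    expected to lie within the observation window; the cap guards
    records whose raw cumulative time overruns it.
    """
    total = sum(ep.stop_s - ep.start_s for ep in record.episodes)
    return min(total, cap_s)


def blood_loss(record: BleedingRecord) -> float:
    """Blood loss in grams: pre-test minus post-test body weight."""
    return record.pre_weight_g - record.post_weight_g


def compare_bleeding(
    group_a: list[BleedingRecord],
    group_b: list[BleedingRecord],
    cap_s: float = DEFAULT_CAP_S,
) -> dict[str, BleedingComparison]:
    """Compare both endpoints between two groups.

    Returns per-endpoint summaries, Student's t-test and the effect
    summary (difference and fold-ratio of group means), keyed by
    ``"bleeding_time_s"`` and ``"blood_loss_g"``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 records")
    out: dict[str, BleedingComparison] = {}
    for endpoint, fn in (
        ("bleeding_time_s", lambda r: total_bleeding_time(r, cap_s)),
        ("blood_loss_g", blood_loss),
    ):
        va = [fn(r) for r in group_a]
        vb = [fn(r) for r in group_b]
        sa, sb = summarize(va), summarize(vb)
        out[endpoint] = BleedingComparison(
            endpoint=endpoint,
            group_a=sa,
            group_b=sb,
            t_test=t_test_raw(va, vb),
            effect=effect_summary(sa, sb),
        )
    return out


def read_bleeding_records(
    episodes_csv: str | Path, weights_csv: str | Path
) -> list[BleedingRecord]:
    """Load records from an episodes CSV and a weights CSV.

    ``episodes_csv`` columns: subject, group, episode_start_s,
    episode_stop_s (one row per episode; a subject may appear with no
    rows if it never bled).  ``weights_csv`` columns: subject, pre_g,
    post_g.  Every weighed subject yields a record.
    """
    eps = pd.read_csv(episodes_csv)
    wts = pd.read_csv(weights_csv)
    for col in ("subject", "group", "episode_start_s", "episode_stop_s"):
        if col not in eps.columns:
            raise ValueError(f"episodes CSV missing column {col!r}")
    for col in ("subject", "pre_g", "post_g"):
        if col not in wts.columns:
            raise ValueError(f"weights CSV missing column {col!r}")
    groups = eps.drop_duplicates("subject").set_index("subject")["group"].to_dict()
    records = []
    for _, row in wts.iterrows():
        subj = row["subject"]
        sub = eps[eps["subject"] == subj]
        episodes = tuple(
            BleedEpisode(float(e.episode_start_s), float(e.episode_stop_s))
            for e in sub.itertuples()
        )
        records.append(BleedingRecord(
            subject=str(subj),
            group=str(sub["group"].iloc[0] if len(sub) else groups.get(subj, "")),
            episodes=episodes,
            pre_weight_g=float(row["pre_g"]),
            post_weight_g=float(row["post_g"]),
        ))
    return records
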