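"""Cohort-level rearrangement statistics.

Aggregates per-strain event lists into the summaries used to describe a
SCRaMbLE screen: the occurrence rate (fraction of strains with at least one
event), the events-per-rearranged-strain distribution, the per-loxPsym-site
event landscape, event-type counts, the proportion of *segments* involved in
each event type (the pie-chart convention, distinct from event counts) and
per-strain chromosome retention rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refmodel import SegmentedReference
from .scramble import RearrangementEvent


@dataclass
class CohortSummary:
    n_strains: int
    n_scrambled: int
    occurrence_rate: float                       # percent
    events_per_scrambled: list[int]
    mean_events_per_scrambled: float | None
    per_site_counts: np.ndarray
    type_counts: dict[str, int]
    type_proportions: dict[str, float]
    segment_type_counts: dict[str, int]
    segment_type_proportions: dict[str, float]
    retention: list[float] = field(default_factory=list)

    @property
    def total_events(self) -> int:
        return sum(self.type_counts.values())


def map_events_to_sites(events: list[RearrangementEvent],
                        n_sites: int) -> np.ndarray:
    """Per-loxPsym-site event counts: every event increments each site among
    its junction loci (1-based site ids)."""
    counts = np.zeros(n_sites, dtype=int)
    for ev in events:
        for locus in set(ev.loci):
            if locus is None:
                continue
            if not 1 <= locus <= n_sites:
                raise ValueError(
                    f"locus {locus} outside 1..{n_sites}")
            counts[locus - 1] += 1
    return counts


def summarize_cohort(strain_events: dict[str, list[RearrangementEvent]],
                     ref: SegmentedReference,
                     retention: dict[str, float] | None = None
                     ) -> CohortSummary:
    """Aggregate a cohort's per-strain event lists into a CohortSummary."""
    if not strain_events:
        raise ValueError("empty cohort")
    n = len(strain_events)
    per_strain = {k: len(v) for k, v in strain_events.items()}
    scrambled = [k for k, c in per_strain.items() if c > 0]
    all_events = [e for evs in strain_events.values() for e in evs]
    type_counts = {t: 0 for t in ("deletion", "inversion", "duplication",
                                  "complex")}
    seg_sets: dict[str, set] = {t: set() for t in type_counts}
    for sid, evs in strain_events.items():
        for ev in evs:
            type_counts[ev.type] = type_counts.get(ev.type, 0) + 1
            seg_sets[ev.type].update((sid, s) for s in ev.segments)
    total = sum(type_counts.values())
    total_segs = sum(len(v) for v in seg_sets.values())
    counts = [per_strain[k] for k in scrambled]
    return CohortSummary(
        n_strains=n,
        n_scrambled=len(scrambled),
        occurrence_rate=round(100.0 * len(scrambled) / n, 2),
        events_per_scrambled=counts,
        mean_events_per_scrambled=(float(np.mean(counts))
                                   if counts else None),
        per_site_counts=map_events_to_sites(all_events, ref.n_sites),
        type_counts=type_counts,
        type_proportions={t: (c / total if total else 0.0)
                          for t, c in type_counts.items()},
        segment_type_counts={t: len(v) for t, v in seg_sets.items()},
        segment_type_proportions={t: (len(v) / total_segs
                                      if total_segs else 0.0)
                                  for t, v in seg_sets.items()},
        retention=sorted(retention.values()) if retention else [],
    )


def summary_table(summary: CohortSummary, condition: str) -> pd.DataFrame:
    rows = [
        (condition, "n_strains", summary.n_strains),
        (condition, "n_scrambled", summary.n_scrambled),
        (condition, "occurrence_rate", summary.occurrence_rate),
        (condition, "total_events", summary.total_events),
    ]
    if summary.mean_events_per_scrambled is not None:
        rows.append((condition, "mean_events_per_scrambled",
                     summary.mean_events_per_scrambled))
    for t, c in summary.type_counts.items():
        rows.append((condition, f"events_{t}", c))
    for t, p in summary.segment_type_proportions.items():
        rows.append((condition, f"segment_proportion_{t}", p))
    if summary.retention:
        rows.append((condition, "mean_retention",
                     float(np.mean(summary.retention))))
        rows.append((condition, "min_retention",
                     float(min(summary.retention))))
    return pd.DataFrame(rows, columns=["condition", "metric", "value"])


def compare_groups(summaries: dict[str, CohortSummary],
                   dose_order: list[str] | None = None) -> pd.DataFrame:
    """Long-format comparison table across conditions.

    With ``dose_order`` given, a ``monotone_occurrence`` row per condition
    set records whether the occurrence rate is non-decreasing along the
    stated dose ordering (the qualitative dose-response check).
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 cohorts to compare")
    frames = [summary_table(s, cond) for cond, s in summaries.items()]
    df = pd.concat(frames, ignore_index=True)
    if dose_order:
        rates = [summaries[c].occurrence_rate for c in dose_order]
        monotone = all(a <= b for a, b in zip(rates, rates[1:]))
        df = pd.concat([df, pd.DataFrame(
            [("__all__", "monotone_occurrence", float(monotone))],
            columns=df.columns)], ignore_index=True)
    return df


def landscape_plot(summary: CohortSummary, ref: SegmentedReference,
                   path) -> None:
    """Bar track of event counts per loxPsym site (SVG/PNG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2.5))
    ax.bar(np.arange(1, ref.n_sites + 1), summary.per_site_counts,
           color="#4477aa")
    ax.set_xlabel("loxPsym site")
    ax.set_ylabel("events")
    ax.set_title("rearrangement landscape")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
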