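"""Ortholog-correctness benchmarking against a gold-standard label map.

Each sequence carries a label (in real studies an orthology-database group
id; in simulations the true ancestral-lineage id).  A group whose annotated
members all share one label is *correct*; a group with two or more distinct
labels among annotated members is *incorrect*; a group with unannotated
members but no conflict is *unannotated*.  A conflict takes precedence over
missing annotation, since a conflict is positive evidence of error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .orthology import OrthologGroup

UNANNOTATED = "unannotated"

__all__ = ["UNANNOTATED", "GroupVerdict", "BenchmarkSummary",
           "classify_group", "summarize"]


@dataclass(frozen=True)
class GroupVerdict:
    group_id: str
    verdict: str  # correct | incorrect | unannotated


@dataclass
class BenchmarkSummary:
    n_groups: int
    fraction_correct: float
    fraction_incorrect: float
    fraction_unannotated: float
    ortholog_count_cv: float | None = None


def classify_group(group: OrthologGroup,
                   labels: Mapping[str, str]) -> GroupVerdict:
    """Verdict for one ortholog group given the label map (sequences
    missing from the map count as unannotated)."""
    if not group.members:
        raise ValueError(f"{group.group_id}: empty group")
    seen = {labels.get(seq_id, UNANNOTATED)
            for seq_id in group.members.values()}
    annotated = seen - {UNANNOTATED}
    if len(annotated) > 1:
        verdict = "incorrect"
    elif UNANNOTATED in seen:
        verdict = "unannotated"
    else:
        verdict = "correct"
    return GroupVerdict(group_id=group.group_id, verdict=verdict)


def summarize(verdicts: Iterable[GroupVerdict],
              counts_by_condition: Sequence[int] | None = None) -> BenchmarkSummary:
    """Verdict fractions plus, optionally, the coefficient of variation
    (population std / mean) of group counts across conditions, e.g.
    ortholog counts across tissues."""
    verdicts = list(verdicts)
    if not verdicts:
        raise ValueError("need at least one verdict")
    n = len(verdicts)
    tally = {"correct": 0, "incorrect": 0, "unannotated": 0}
    for v in verdicts:
        tally[v.verdict] += 1
    cv = None
    if counts_by_condition is not None:
        counts = np.asarray(counts_by_condition, dtype=float)
        mean = counts.mean()
        if mean == 0:
            raise ValueError("CV undefined: mean count is zero")
        cv = float(counts.std() / mean)  # population std
    return BenchmarkSummary(
        n_groups=n,
        fraction_correct=tally["correct"] / n,
        fraction_incorrect=tally["incorrect"] / n,
        fraction_unannotated=tally["unannotated"] / n,
        ortholog_count_cv=cv,
    )
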