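"""Kinase-group selectivity profiling by odds ratios.

A compound's predicted (or measured) bioactivities across a kinase panel are
thresholded into positive/negative calls at a potency cutoff (default 3.0 on
the log10(nM) scale, i.e. 1 uM; values at or below the cutoff are positive).
For each kinase group the four counts — positive/negative calls inside and
outside the group — form a 2x2 contingency table whose odds ratio

    OR = (N_GP / N_OP) / (N_GN / N_ON)

measures enrichment of the compound's hits inside the group.  The group with
the maximal OR is the compound's predicted selectivity class.  Compounds whose
calls are all-positive or all-negative carry no contrast and are skipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .curation import to_bioactivity

DEFAULT_CUTOFF = 3.0  # log10(nM) of 1 uM


def classify_activity(bioactivity: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """'positive' iff the value is at least as potent as the cutoff (<=)."""
    b = float(bioactivity)
    if not math.isfinite(b):
        raise ValueError(f"bioactivity must be finite, got {bioactivity}")
    return "positive" if b <= cutoff else "negative"


@dataclass(frozen=True)
class ContingencyTable:
    """Positive/negative interaction counts inside vs outside a group."""

    n_gp: int  # positive, inside group
    n_op: int  # positive, outside group
    n_gn: int  # negative, inside group
    n_on: int  # negative, outside group

    def __post_init__(self) -> None:
        for name in ("n_gp", "n_op", "n_gn", "n_on"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.n_gp + self.n_op + self.n_gn + self.n_on


def odds_ratio(table: ContingencyTable, zero_policy: str = "haldane") -> float:
    """(N_GP/N_OP)/(N_GN/N_ON) with a configurable zero-cell policy.

    ``haldane`` adds 0.5 to every cell when any cell is zero, keeping the
    ratio finite and rankable; ``limit`` returns the limiting value (0 or
    +inf) instead.  An all-zero table is undefined and raises.
    """
    cells = [table.n_gp, table.n_op, table.n_gn, table.n_on]
    if all(c == 0 for c in cells):
        raise ValueError("odds ratio undefined for an all-zero table")
    if any(c == 0 for c in cells):
        if zero_policy == "haldane":
            gp, op, gn, on = (c + 0.5 for c in cells)
            return (gp / op) / (gn / on)
        if zero_policy == "limit":
            num_zero = table.n_op == 0 or table.n_gn == 0  # drives OR up
            den_zero = table.n_gp == 0 or table.n_on == 0  # drives OR down
            if num_zero and den_zero:
                return math.nan
            return math.inf if num_zero else 0.0
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    return (table.n_gp / table.n_op) / (table.n_gn / table.n_on)


@dataclass(frozen=True)
class GroupOdds:
    group: str
    table: ContingencyTable
    or_value: float


@dataclass
class ProfileResult:
    """Per-group odds ratios of one compound across a kinase panel."""

    compound: str
    per_group: list[GroupOdds]
    n_kinases: int
    predicted_group: str

    def or_of(self, group: str) -> float:
        for g in self.per_group:
            if g.group == group:
                return g.or_value
        raise KeyError(group)


class ProfileEligibilityError(ValueError):
    """Compound has no contrast (all calls positive or all negative)."""


def group_profile(
    bioactivities: Mapping[str, float],
    groups: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    compound: str = "",
    zero_policy: str = "haldane",
) -> ProfileResult:
    """Odds-ratio profile of one compound over the groups of a kinase panel.

    ``bioactivities`` maps kinase id -> bioactivity (log10 nM); ``groups``
    maps kinase id -> group label.  The predicted selectivity class is the
    group with maximal OR, ties broken by group name.
    """
    kinases = [k for k in bioactivities if k in groups]
    missing = set(bioactivities) - set(kinases)
    if missing:
        warnings.warn(f"kinases without group labels ignored: {sorted(missing)}")
    if not kinases:
        raise ValueError("no kinases with group labels")
    calls = {k: classify_activity(bioactivities[k], cutoff) for k in kinases}
    n_pos = sum(1 for c in calls.values() if c == "positive")
    if n_pos == 0 or n_pos == len(calls):
        raise ProfileEligibilityError(
            f"compound {compound or '<unnamed>'} has calls in only one class "
            f"({n_pos}/{len(calls)} positive)"
        )
    per_group = []
    for group in sorted(set(groups[k] for k in kinases)):
        inside = [k for k in kinases if groups[k] == group]
        outside = [k for k in kinases if groups[k] != group]
        table = ContingencyTable(
            n_gp=sum(1 for k in inside if calls[k] == "positive"),
            n_op=sum(1 for k in outside if calls[k] == "positive"),
            n_gn=sum(1 for k in inside if calls[k] == "negative"),
            n_on=sum(1 for k in outside if calls[k] == "negative"),
        )
        per_group.append(GroupOdds(group=group, table=table, or_value=odds_ratio(table, zero_policy)))
    # per_group is sorted by group name and max keeps the first of equal keys,
    # so ties break deterministically by name
    best = max(per_group, key=lambda g: g.or_value)
    return ProfileResult(
        compound=compound,
        per_group=per_group,
        n_kinases=len(kinases),
        predicted_group=best.group,
    )


def profile_compounds(
    predictions: Mapping[str, Mapping[str, float]],
    groups: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    zero_policy: str = "haldane",
) -> tuple[list[ProfileResult], list[tuple[str, str]]]:
    """Profile many compounds; ineligible ones are skipped with a reason."""
    results, skipped = [], []
    for compound, bios in predictions.items():
        try:
            results.append(
                group_profile(bios, groups, cutoff=cutoff, compound=compound, zero_policy=zero_policy)
            )
        except ProfileEligibilityError as exc:
            skipped.append((compound, str(exc)))
    return results, skipped


def compare_methods(
    scores_a,
    scores_b,
    bioactivities,
    cutoffs_um: Sequence[float] = (0.1, 1.0, 5.0),
    method_names: tuple[str, str] = ("method_a", "method_b"),
) -> dict:
    """Classification metrics of two scoring methods against measured potency.

    Scores are oriented so that *lower means more active* (as for predicted
    bioactivities or docking scores).  Each cutoff (uM) is converted to the
    log10(nM) scale to label records positive/negative; both score vectors are
    min-max scaled to [0, 1]; AUC is computed threshold-free from ranks of the
    activity score (1 - scaled), and point metrics use a 0.5 threshold on the
    scaled score.  A single-class label vector leaves AUC and point metrics
    undefined (NaN, flagged).
    """
    from sklearn.metrics import (
        accuracy_score,
        f1_score,
        precision_score,
        recall_score,
        roc_auc_score,
    )

    scores = {
        method_names[0]: np.asarray(scores_a, dtype=np.float64),
        method_names[1]: np.asarray(scores_b, dtype=np.float64),
    }
    y = np.asarray(bioactivities, dtype=np.float64)
    for name, s in scores.items():
        if s.shape != y.shape:
            raise ValueError(f"{name} scores and bioactivities differ in length")
    out: dict = {}
    for name, s in scores.items():
        span = np.ptp(s)
        scaled = (s - s.min()) / span if span > 0 else np.zeros_like(s)
        activity_score = 1.0 - scaled  # higher = more active
        per_cutoff = {}
        for c_um in cutoffs_um:
            cutoff = to_bioactivity(c_um, "uM")
            labels = (y <= cutoff).astype(int)
            if labels.min() == labels.max():
                per_cutoff[c_um] = {
                    "precision": math.nan,
                    "recall": math.nan,
                    "f1": math.nan,
                    "auc": math.nan,
                    "accuracy": math.nan,
                    "undefined": True,
                }
                continue
            pred_pos = (scaled <= 0.5).astype(int)
            per_cutoff[c_um] = {
                "precision": float(precision_score(labels, pred_pos, zero_division=0)),
                "recall": float(recall_score(labels, pred_pos, zero_division=0)),
                "f1": float(f1_score(labels, pred_pos, zero_division=0)),
                "auc": float(roc_auc_score(labels, activity_score)),
                "accuracy": float(accuracy_score(labels, pred_pos)),
                "undefined": False,
            }
        out[name] = per_cutoff
    return out


def export_kinmap(
    per_kinase_values: Iterable[tuple[str, float]],
    path,
    size_range: tuple[float, float] = (16.0, 64.0),
    fill_color: str = "#FF0000",
) -> None:
    """Write a kinome-tree annotation TSV (columns xName, size, fill).

    Values are mapped to marker sizes by a monotone linear rule over the value
    range; a constant value set maps to the midpoint size.
    """
    rows = list(per_kinase_values)
    lo, hi = size_range
    with open(path, "w") as fh:
        fh.write("xName\tsize\tfill\n")
        if not rows:
            return
        vals = np.array([v for _, v in rows], dtype=np.float64)
        span = np.ptp(vals)
        for (name, v) in rows:
            frac = 0.5 if span == 0 else (v - vals.min()) / span
            size = lo + frac * (hi - lo)
            fh.write(f"{name}\t{size:.1f}\t{fill_color}\n")


def read_kinmap(path) -> list[tuple[str, float]]:
    """Read back an exported annotation file (name, size)."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            name, size, _fill = line.rstrip("\n").split("\t")
            out.append((name, float(size)))
    return out
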