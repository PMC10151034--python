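"""Hit-based retrieval metrics, threshold sweeps and annotator agreement.

A candidate drug-disease pairing counts as a "hit" when it has published
positive in vivo or in vitro evidence or has been tested in a clinical
trial; pairings labelled novel are not hits.  Precision is hits returned
over candidates returned, recall is hits returned over all known hits, and
the f-measure balances the two (harmonic mean by default, geometric mean
selectable).  Sweeping the joint-probability threshold or the step
allowance and maximising the f-measure selects the operating point.

Scott's Pi measures chance-corrected agreement between the two experts who
rated detection-method reliability, using pooled marginal category
proportions for the expected-agreement term.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .graph import KnowledgeGraph, ValidationError
from .pathfind import (
    DEFAULT_MAX_STEPS,
    DEFAULT_MIN_JOINT_PROBABILITY,
    CandidateTable,
    find_candidates,
)

logger = logging.getLogger(__name__)

STATUSES = frozenset({
    "approved", "phase_iii", "phase_ii", "phase_i",
    "case_study", "in_vitro", "in_vivo", "novel",
})
#: every status except "novel" counts as a validated hit
HIT_STATUSES = STATUSES - {"novel"}

DEFAULT_PROBABILITY_GRID = (
    0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.93, 0.95, 0.97, 0.99,
)
DEFAULT_STEPS_GRID = (1, 2, 3, 4, 5, 6)


@dataclass
class HitLabels:
    """Drug-discovery status per (drug, disease) pairing."""

    labels: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("label set must be non-empty")
        bad = {s for s in self.labels.values() if s not in STATUSES}
        if bad:
            raise ValidationError(f"unknown statuses {sorted(bad)}")

    @property
    def hits(self) -> set[tuple[str, str]]:
        return {pair for pair, status in self.labels.items()
                if status in HIT_STATUSES}

    def status(self, drug_id: str, disease_id: str) -> Optional[str]:
        return self.labels.get((drug_id, disease_id))

    @classmethod
    def from_tsv(cls, path) -> "HitLabels":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = ("drug_id", "disease_id", "status")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing label columns {missing}")
        return cls({(r.drug_id, r.disease_id): r.status
                    for r in df.itertuples(index=False)})

    def to_tsv(self, path) -> None:
        rows = [{"drug_id": d, "disease_id": z, "status": s}
                for (d, z), s in sorted(self.labels.items())]
        pd.DataFrame(rows, columns=["drug_id", "disease_id", "status"]).to_csv(
            path, sep="\t", index=False)


def f_measure(precision: float, recall: float, mean: str = "harmonic") -> float:
    if precision == 0.0 and recall == 0.0:
        return 0.0
    if mean == "harmonic":
        return 2.0 * precision * recall / (precision + recall)
    if mean == "geometric":
        return (precision * recall) ** 0.5
    raise ValidationError(f"unknown f-measure mean {mean!r}")


def precision_recall_f(
    candidates: CandidateTable,
    labels: HitLabels,
    f_mean: str = "harmonic",
    strict: bool = False,
) -> tuple[float, float, float]:
    """Retrieval metrics for a candidate table against the hit labels.

    Unlabelled candidate pairs are an error in strict mode; otherwise they
    count as non-hits (the case-study validation labelled every returned
    candidate, so unlabelled pairs are candidates never looked up).
    """
    returned = [(c.drug_id, c.disease_id) for c in candidates.candidates]
    unlabeled = [pair for pair in returned if pair not in labels.labels]
    if unlabeled:
        if strict:
            raise ValidationError(f"unlabeled candidate pairs: {sorted(unlabeled)}")
        logger.info("%d unlabeled candidate pairs counted as non-hits", len(unlabeled))
    known_hits = labels.hits
    hits_returned = sum(1 for pair in returned if pair in known_hits)
    if not returned or not known_hits:
        logger.warning("degenerate evaluation (no candidates or no known hits)")
        return (0.0, 0.0, 0.0)
    precision = hits_returned / len(returned)
    recall = hits_returned / len(known_hits)
    return (precision, recall, f_measure(precision, recall, f_mean))


@dataclass
class SweepPoint:
    threshold: float
    precision: float
    recall: float
    f_measure: float
    n_candidates: int


@dataclass
class SweepResult:
    """Metrics along one threshold axis, plus the f-measure-optimal point."""

    axis: str  # "joint_probability" or "steps"
    points: list[SweepPoint] = field(default_factory=list)

    @property
    def best_threshold(self) -> float:
        """Argmax of f-measure, ties broken toward the stricter threshold.

        Stricter means a higher probability cutoff but a lower step
        allowance.
        """
        if not self.points:
            raise ValidationError("empty sweep")
        stricter_last = sorted(
            self.points,
            key=lambda p: p.threshold, reverse=(self.axis == "steps"))
        best = stricter_last[0]
        for point in stricter_last[1:]:
            if point.f_measure >= best.f_measure:
                best = point
        return best.threshold

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"threshold": p.threshold, "precision": p.precision,
             "recall": p.recall, "f_measure": p.f_measure,
             "n_candidates": p.n_candidates}
            for p in self.points
        ])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def threshold_sweep(
    graph: KnowledgeGraph,
    disease_id: str,
    labels: HitLabels,
    axis: str = "joint_probability",
    grid: Optional[Sequence[float]] = None,
    f_mean: str = "harmonic",
) -> SweepResult:
    """Evaluate candidate retrieval along one threshold axis.

    The other axis is held at its default (steps <= 3 while sweeping the
    probability threshold; p >= 0.93 while sweeping the step allowance).
    """
    if axis == "joint_probability":
        grid = tuple(grid) if grid is not None else DEFAULT_PROBABILITY_GRID
    elif axis == "steps":
        grid = tuple(int(g) for g in grid) if grid is not None else DEFAULT_STEPS_GRID
    else:
        raise ValidationError(f"unknown sweep axis {axis!r}")
    if not grid or list(grid) != sorted(grid):
        raise ValidationError("grid must be non-empty and sorted ascending")

    result = SweepResult(axis=axis)
    for value in grid:
        if axis == "joint_probability":
            table = find_candidates(graph, disease_id,
                                    max_steps=DEFAULT_MAX_STEPS,
                                    min_joint_probability=value)
        else:
            table = find_candidates(graph, disease_id,
                                    max_steps=int(value),
                                    min_joint_probability=DEFAULT_MIN_JOINT_PROBABILITY)
        p, r, f = precision_recall_f(table, labels, f_mean=f_mean)
        result.points.append(SweepPoint(value, p, r, f, len(table)))
    return result


def scotts_pi(
    annotations_a: Sequence, annotations_b: Sequence
) -> tuple[float, float]:
    """Observed agreement and Scott's Pi for two annotators.

    Pi = (Ao - Ae) / (1 - Ae), with Ao the fraction of items the annotators
    agree on and Ae = sum of squared pooled marginal category proportions.
    """
    if len(annotations_a) != len(annotations_b):
        raise ValidationError("annotation lists must have equal length")
    if not annotations_a:
        raise ValidationError("annotation lists must be non-empty")
    n = len(annotations_a)
    observed = sum(1 for a, b in zip(annotations_a, annotations_b) if a == b) / n
    pooled = Counter(annotations_a) + Counter(annotations_b)
    expected = sum((count / (2 * n)) ** 2 for count in pooled.values())
    if expected >= 1.0:
        raise ValidationError(
            "expected agreement is 1 (single shared category); Pi undefined")
    pi = (observed - expected) / (1.0 - expected)
    return (observed, pi)
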