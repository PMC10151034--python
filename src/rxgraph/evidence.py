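"""Assertion probabilities and per-edge combination of redundant evidence.

Each assertion gets a probability from its provenance class: manually
curated records get a fixed high probability (default 0.999); experimental
records get a probability tied to the reliability level (1-3) of their
detection method (defaults 0.8 / 0.95 / 0.99).

When several records support the same (subject, type, object) triple they
are combined into one edge probability.  The default combiner is unweighted
Stouffer voting on composite Z-scores,

    p_combined = Phi( sum_i Phi^-1(p_i) ),

so concordant reports reinforce each other (two records at 0.8 combine to
about 0.954), unlike the geometric mean, which can never exceed its largest
input and is kept only as a selectable alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy.special import ndtr, ndtri

from .graph import KnowledgeGraph, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .ingest import EvidenceConfig
    from .graph import AssertionRecord

logger = logging.getLogger(__name__)

COMBINER_METHODS = ("composite_z", "geometric_mean")


@dataclass(frozen=True)
class CombinerSpec:
    """Choice of edge-probability combiner.

    clamp_epsilon bounds probabilities away from {0, 1} before the normal
    quantile transform (the quantile diverges at the endpoints); it must be
    small enough not to touch any probability the evidence model assigns.
    """

    method: str = "composite_z"
    clamp_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in COMBINER_METHODS:
            raise ValidationError(f"unknown combiner {self.method!r}")
        if not (0.0 < self.clamp_epsilon <= 0.01):
            raise ValidationError("clamp_epsilon must be in (0, 0.01]")

    def combine(self, probabilities: Sequence[float]) -> float:
        if self.method == "composite_z":
            return combine_composite_z(probabilities, self)
        return combine_geometric_mean(probabilities, self)


def assign_probability(record: "AssertionRecord", config: "EvidenceConfig") -> "AssertionRecord":
    """Write the evidence-model probability onto a record (in place).

    Curated records get ``config.curated_probability``; experimental records
    get the probability of their method's confidence level.  Unknown method
    codes follow ``config.unknown_method_policy`` (error, or fall back to
    level 1).
    """
    if record.evidence.kind == "curated":
        record.probability = config.curated_probability
    else:
        code = record.evidence.method_code
        level = config.method_levels.get(code)
        if level is None:
            if config.unknown_method_policy == "error":
                raise ValidationError(f"unknown detection method code {code!r}")
            level = 1
            logger.debug("method code %s not configured; defaulting to level 1", code)
        record.probability = config.level_probabilities[level]
    return record


def _validate_input(probabilities: Sequence[float]) -> np.ndarray:
    if len(probabilities) == 0:
        raise ValidationError("cannot combine an empty probability list")
    p = np.asarray(probabilities, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValidationError("probabilities must lie strictly inside (0, 1)")
    return p


def combine_composite_z(
    probabilities: Sequence[float], spec: CombinerSpec = CombinerSpec()
) -> float:
    """Stouffer combination: Phi(sum of standard-normal quantiles).

    A single input is a fixed point (Phi(Phi^-1(p)) = p); complementary
    inputs cancel (p and 1-p combine to 0.5); repeated inputs above 0.5
    reinforce.  The result is clamped back into the open interval so the
    edge probability stays usable in products.
    """
    p = _validate_input(probabilities)
    eps = spec.clamp_epsilon
    z = ndtri(np.clip(p, eps, 1.0 - eps))
    combined = float(ndtr(z.sum()))
    # keep the result usable in products: off the exact endpoints only
    return min(max(combined, 5e-324), 1.0 - 1e-16)


def combine_geometric_mean(
    probabilities: Sequence[float], spec: CombinerSpec = CombinerSpec()
) -> float:
    """Geometric mean (prod p_i)^(1/n); bounded by min and max input."""
    p = _validate_input(probabilities)
    return float(np.exp(np.mean(np.log(p))))


def deduplicate_records(records: Sequence["AssertionRecord"]) -> list["AssertionRecord"]:
    """Drop records identical in (source_db, primary_ref, method, triple).

    Mirror records of one experiment syndicated across databases inflate
    the composite Z-score; exact provenance duplicates are the cheap,
    unambiguous part of that problem and are removed before combining.
    """
    seen = set()
    out = []
    for r in records:
        key = (r.source_db, r.primary_ref, r.evidence.kind,
               r.evidence.method_code, r.triple)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def recombine_edges(
    graph: KnowledgeGraph,
    spec: CombinerSpec = CombinerSpec(),
    deduplicate: bool = True,
) -> KnowledgeGraph:
    """Set every edge's combined probability from its records' probabilities."""
    n_dropped = 0
    for edge in graph.edges.values():
        for r in edge.records:
            r.validate_probability()
        records = deduplicate_records(edge.records) if deduplicate else edge.records
        n_dropped += len(edge.records) - len(records)
        edge.combined_probability = spec.combine([r.probability for r in records])
    if n_dropped:
        logger.info("dropped %d exact provenance duplicates before combining", n_dropped)
    return graph
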