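"""Additive candidate scoring with scaled metadata terms.

Each candidate carries two core scores supplied by external tools — an
in-silico fragmenter score and a spectral-similarity score, both already
in [0, 1] — plus any number of raw metadata values (data-source counts,
reference counts, list-membership flags, percent-active assay values).
Each metadata category is scaled to [0, 1] across the candidate list
(default: divide by the category maximum; min-max as an option; missing
values score 0) and the combined score is the weighted sum of all active
terms. With unit weights, two core scores and five metadata categories
give a maximum achievable score of 7.

Candidates sharing an InChIKey first block (same skeleton, e.g. the salt
forms of one compound) can be grouped; the group reports its highest
scoring member while retaining every member identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .chem_core import first_block

__all__ = [
    "CandidateScore",
    "ScoringConfig",
    "CandidateGroup",
    "scale_metadata",
    "combined_score",
    "score_candidates",
    "group_candidates",
    "rank",
]

CORE_TERMS = ("fragmenter", "spectral_similarity")


@dataclass
class CandidateScore:
    """Per-candidate score vector."""

    identifier: str
    inchikey: str = ""
    fragmenter: float = 0.0
    spectral_similarity: float = 0.0
    metadata: Dict[str, Optional[float]] = field(default_factory=dict)
    scaled: Dict[str, float] = field(default_factory=dict)
    combined: float = 0.0


@dataclass
class ScoringConfig:
    """Active categories, weights and the scaling rule.

    The maximum achievable combined score equals the sum of the weights of
    the two core terms and all active metadata categories (7 with five
    categories at unit weights).
    """

    metadata_categories: Tuple[str, ...] = ()
    weights: Dict[str, float] = field(default_factory=dict)
    scaling: str = "divide-by-max"  # or "min-max"
    grouping: bool = True

    def __post_init__(self):
        if self.scaling not in ("divide-by-max", "min-max"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        active = set(CORE_TERMS) | set(self.metadata_categories)
        for name, w in self.weights.items():
            if name not in active:
                raise ValueError(f"weight given for inactive category {name!r}")
            if w < 0:
                raise ValueError(f"negative weight for {name!r}")

    def weight(self, name: str) -> float:
        return self.weights.get(name, 1.0)

    @property
    def max_score(self) -> float:
        return sum(self.weight(t) for t in CORE_TERMS) + sum(
            self.weight(c) for c in self.metadata_categories
        )


@dataclass
class CandidateGroup:
    group_key: str
    members: List[CandidateScore]

    @property
    def representative(self) -> CandidateScore:
        # highest combined score; ties go to the lexicographically smaller id
        return min(self.members, key=lambda c: (-c.combined, c.identifier))

    @property
    def identifiers(self) -> List[str]:
        return [m.identifier for m in self.members]


def scale_metadata(
    candidates: Sequence[CandidateScore],
    category: str,
    config: ScoringConfig,
) -> Dict[str, float]:
    """Scale one category's raw values to [0, 1] across the candidates.

    divide-by-max: x / max(values); min-max: (x - min) / (max - min).
    Missing values score 0; an all-missing category scores 0 everywhere; a
    constant non-zero category scores 1 under divide-by-max. Negative raw
    values are rejected (categories are counts, flags or percentages).
    Results are also written into each candidate's ``scaled`` map.
    """
    if category not in config.metadata_categories:
        raise ValueError(f"category {category!r} is not active")
    values = {}
    for c in candidates:
        v = c.metadata.get(category)
        if v is not None:
            v = float(v)
            if v < 0:
                raise ValueError(
                    f"negative value {v} for category {category!r} on {c.identifier}"
                )
            values[c.identifier] = v
    out: Dict[str, float] = {}
    if not values:
        for c in candidates:
            out[c.identifier] = 0.0
    elif config.scaling == "divide-by-max":
        top = max(values.values())
        for c in candidates:
            v = values.get(c.identifier)
            out[c.identifier] = 0.0 if v is None or top == 0 else v / top
    else:  # min-max
        lo, hi = min(values.values()), max(values.values())
        for c in candidates:
            v = values.get(c.identifier)
            if v is None:
                out[c.identifier] = 0.0
            elif hi == lo:
                out[c.identifier] = 1.0 if hi > 0 else 0.0
            else:
                out[c.identifier] = (v - lo) / (hi - lo)
    for c in candidates:
        c.scaled[category] = out[c.identifier]
    return out


def combined_score(candidate: CandidateScore, config: ScoringConfig) -> float:
    """Weighted sum of core and scaled metadata terms; also stored on the
    candidate. Scaled terms must already be computed for active categories."""
    total = (
        config.weight("fragmenter") * candidate.fragmenter
        + config.weight("spectral_similarity") * candidate.spectral_similarity
    )
    for cat in config.metadata_categories:
        total += config.weight(cat) * candidate.scaled.get(cat, 0.0)
    candidate.combined = total
    return total


def score_candidates(
    candidates: Sequence[CandidateScore], config: ScoringConfig
) -> List[CandidateScore]:
    """Scale every active category, then compute combined scores."""
    for cat in config.metadata_categories:
        scale_metadata(candidates, cat, config)
    for c in candidates:
        combined_score(c, config)
    return list(candidates)


def group_candidates(
    candidates: Sequence[CandidateScore],
) -> List[CandidateGroup]:
    """Partition candidates by InChIKey first block. Groups are ordered by
    their representative's score descending; a candidate without an
    InChIKey raises ``ValueError`` naming it."""
    by_block: Dict[str, List[CandidateScore]] = {}
    for c in candidates:
        if not c.inchikey:
            raise ValueError(f"candidate {c.identifier!r} has no InChIKey")
        by_block.setdefault(first_block(c.inchikey), []).append(c)
    groups = [CandidateGroup(k, v) for k, v in by_block.items()]
    groups.sort(
        key=lambda g: (-g.representative.combined, g.representative.identifier)
    )
    return groups


def rank(
    candidates: Sequence[CandidateScore],
    config: Optional[ScoringConfig] = None,
    group: Optional[bool] = None,
) -> List[CandidateScore]:
    """Order candidates (or group representatives) by combined score
    descending, ties broken by identifier."""
    if config is not None and (group if group is not None else config.grouping):
        return [g.representative for g in group_candidates(candidates)]
    ordered = sorted(candidates, key=lambda c: (-c.combined, c.identifier))
    return ordered
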