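"""Association rules {signed pathway-set} => {class} from biclusters.

Rule metrics follow the classical definitions over ALL samples:
``support = P(itemset AND class)``, ``confidence = P(class | itemset)``,
``lift = confidence / P(class)``.  Note the distinction from the
class-relative minimum support used to admit biclusters: there, support is
a fraction of the mined class's samples.  All metrics are derived from
integer counts so boundary thresholds (confidence >= 0.8, lift > 1) are
exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .activity import BinaryTransactionMatrix
from .bimax import Bicluster
from .io_formats import CASE, CONTROL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationRule:
    """Directed rule itemset => klass with exact count bookkeeping.

    ``n_cover`` samples match every item; ``n_cover_class`` of them carry
    the consequent class label; ``n_class`` / ``n_total`` describe the
    cohort.
    """

    itemset: tuple[str, ...]
    klass: str
    n_cover: int
    n_cover_class: int
    n_class: int
    n_total: int
    supporting_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "itemset", tuple(sorted(self.itemset)))
        if not (0 < self.n_cover <= self.n_total):
            raise ValueError("cover count out of range")
        if not (0 <= self.n_cover_class <= self.n_cover):
            raise ValueError("class cover exceeds cover")

    @property
    def support_frac(self) -> Fraction:
        return Fraction(self.n_cover_class, self.n_total)

    @property
    def confidence_frac(self) -> Fraction:
        return Fraction(self.n_cover_class, self.n_cover)

    @property
    def lift_frac(self) -> Fraction:
        return self.confidence_frac / Fraction(self.n_class, self.n_total)

    @property
    def support(self) -> float:
        return float(self.support_frac)

    @property
    def confidence(self) -> float:
        return float(self.confidence_frac)

    @property
    def lift(self) -> float:
        return float(self.lift_frac)

    def to_dict(self) -> dict:
        return {
            "itemset": list(self.itemset),
            "class": self.klass,
            "support": self.support,
            "confidence": self.confidence,
            "lift": self.lift,
            "n_cover": self.n_cover,
            "n_cover_class": self.n_cover_class,
            "supporting_samples": list(self.supporting_samples),
        }


@dataclass(frozen=True)
class PathwaySetMarker:
    """A ranked rule selected as a class marker."""

    rule: AssociationRule
    rank: int

    @property
    def itemset(self) -> tuple[str, ...]:
        return self.rule.itemset

    @property
    def klass(self) -> str:
        return self.rule.klass

    @property
    def pathways(self) -> tuple[str, ...]:
        from .bimax import _pathway_of

        return tuple(sorted({_pathway_of(i) for i in self.itemset}))

    def to_dict(self) -> dict:
        d = self.rule.to_dict()
        d["rank"] = self.rank
        return d


def _cover_samples(itemset: Sequence[str], states: BinaryTransactionMatrix,
                   ) -> list[str]:
    missing = [i for i in itemset if i not in states.bits.index]
    if missing:
        raise KeyError(f"items absent from the transaction matrix: {missing}")
    mask = states.bits.loc[list(itemset)].to_numpy(dtype=bool).all(axis=0)
    return [s for s, m in zip(states.samples, mask) if m]


def make_rule(itemset: Sequence[str], states: BinaryTransactionMatrix,
              labels: Mapping[str, str], klass: str) -> AssociationRule:
    """Build a rule with counts taken over ALL samples of the matrix."""
    if not itemset:
        raise ValueError("empty itemset")
    cover = _cover_samples(itemset, states)
    if not cover:
        raise ValueError("itemset covers no sample")
    n_total = len(states.samples)
    n_class = sum(1 for s in states.samples if labels[s] == klass)
    n_cover_class = sum(1 for s in cover if labels[s] == klass)
    return AssociationRule(tuple(itemset), klass, len(cover), n_cover_class,
                           n_class, n_total, tuple(cover))


def rule_metrics(itemset: Sequence[str], states: BinaryTransactionMatrix,
                 labels: Mapping[str, str], klass: str,
                 ) -> tuple[float, float, float]:
    """(support, confidence, lift) of itemset => klass over all samples."""
    r = make_rule(itemset, states, labels, klass)
    return r.support, r.confidence, r.lift


def generate_rules(biclusters: Mapping[str, Iterable[Bicluster]] | Iterable[Bicluster],
                   states: BinaryTransactionMatrix, labels: Mapping[str, str],
                   min_conf: float = 0.8, min_lift: float = 1.0,
                   ) -> list[AssociationRule]:
    """One candidate rule per bicluster itemset; keep those with
    confidence >= min_conf and lift strictly > min_lift.

    Duplicate (itemset, class) candidates from different biclusters are
    merged into a single rule.
    """
    if not (0 <= min_conf <= 1):
        raise ValueError("min_conf must be in [0, 1]")
    if min_lift < 0:
        raise ValueError("min_lift must be >= 0")
    if isinstance(biclusters, Mapping):
        flat = [b for bs in biclusters.values() for b in bs]
    else:
        flat = list(biclusters)
    seen: dict[tuple[tuple[str, ...], str], AssociationRule] = {}
    for b in flat:
        if b.klass not in (CASE, CONTROL):
            raise ValueError(f"bicluster without a mined class: {b}")
        key = (tuple(sorted(b.items)), b.klass)
        if key in seen:
            continue
        rule = make_rule(b.items, states, labels, b.klass)
        # exact boundary semantics on counts
        if rule.confidence_frac >= Fraction(min_conf).limit_denominator(10**6) \
                and rule.lift_frac > Fraction(min_lift).limit_denominator(10**6):
            seen[key] = rule
    return sorted(seen.values(), key=lambda r: (r.klass, r.itemset))


def deduplicate_cross_class(rules: Iterable[AssociationRule],
                            ) -> list[AssociationRule]:
    """When the same itemset predicts both classes keep the stronger rule:
    higher lift, then confidence, then support; full tie keeps the case rule."""
    by_itemset: dict[tuple[str, ...], list[AssociationRule]] = {}
    for r in rules:
        by_itemset.setdefault(r.itemset, []).append(r)
    kept: list[AssociationRule] = []
    for itemset, group in by_itemset.items():
        if len(group) == 1:
            kept.extend(group)
            continue
        def strength(r: AssociationRule):
            return (r.lift_frac, r.confidence_frac, r.support_frac,
                    1 if r.klass == CASE else 0)
        group = sorted(group, key=strength, reverse=True)
        a, b = group[0], group[1]
        if (a.lift_frac, a.confidence_frac, a.support_frac) == \
                (b.lift_frac, b.confidence_frac, b.support_frac):
            logger.warning("itemset %s tied across classes; keeping the case rule",
                           itemset)
        kept.append(group[0])
    return sorted(kept, key=lambda r: (r.klass, r.itemset))


def rank_and_select(rules: Iterable[AssociationRule], top_n: int = 250,
                    ) -> list[PathwaySetMarker]:
    """Per class, rank rules by (lift, confidence, support, itemset size)
    descending with a lexicographic itemset tie-break, and keep ``top_n``."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    markers: list[PathwaySetMarker] = []
    by_class: dict[str, list[AssociationRule]] = {}
    for r in rules:
        by_class.setdefault(r.klass, []).append(r)
    for klass in sorted(by_class):
        ordered = sorted(
            by_class[klass],
            key=lambda r: (-r.lift_frac, -r.confidence_frac, -r.support_frac,
                           -len(r.itemset), r.itemset),
        )
        if len(ordered) < top_n:
            logger.info("class %s: only %d rules available (top_n=%d)",
                        klass, len(ordered), top_n)
        markers.extend(PathwaySetMarker(r, rank)
                       for rank, r in enumerate(ordered[:top_n], start=1))
    return markers
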