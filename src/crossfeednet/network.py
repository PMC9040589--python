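"""Cross-feeding network construction and its summary statistics.

Two complementary network views are built from the direction calls:

* a *prediction* from fresh-medium monocultures alone — a metabolite
  secreted by at least one species and consumed by at least one other is
  potentially cross-fed, classified one-to-one / one-to-many /
  many-to-one / many-to-many by producer and consumer counts;
* *evidence-based* edges from spent-medium cultures — an edge
  (producer P, consumer C, metabolite m) requires m secreted by P in
  fresh medium and consumed by C while growing in P's spent medium.

Cross-fed metabolites are partitioned into public goods (>= 2 distinct
consumers) and private goods, species are scored by their
consumption:secretion interaction ratio, and compound classes are tested
for enrichment among public goods with a two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import DynamicCall
from .io import spent_producer

__all__ = [
    "CrossFeedEdge",
    "InteractionSummary",
    "SpeciesScore",
    "predict_fresh_crossfeeding",
    "build_spent_network",
    "goods_and_scores",
    "network_statistics",
    "interaction_type",
]


@dataclass(frozen=True)
class CrossFeedEdge:
    producer: str
    consumer: str
    metabolite: str
    medium: str = ""
    consumed_mM: float | None = None

    def __post_init__(self):
        if self.producer == self.consumer:
            raise ValueError("cross-feeding edges cannot be self-loops")


@dataclass
class InteractionSummary:
    metabolite: str
    producers: frozenset
    consumers: frozenset
    interaction_type: str
    good_class: str  # "public" | "private"
    compound_class: str = ""


@dataclass
class SpeciesScore:
    species: str
    n_consumed: int
    n_secreted: int
    ratio: float  # NaN when n_secreted == 0 and n_consumed > 0


def interaction_type(n_producers: int, n_consumers: int) -> str:
    p = "one" if n_producers == 1 else "many"
    c = "one" if n_consumers == 1 else "many"
    return f"{p}-to-{c}"


def _directional_sets(calls: list[DynamicCall]):
    """(metabolite -> producer set, metabolite -> consumer set)."""
    producers: dict[str, set] = {}
    consumers: dict[str, set] = {}
    for c in calls:
        if c.direction == "secreted":
            producers.setdefault(c.metabolite, set()).add(c.species)
        elif c.direction == "consumed":
            consumers.setdefault(c.metabolite, set()).add(c.species)
    return producers, consumers


def predict_fresh_crossfeeding(
    calls: list[DynamicCall],
    compound_classes: dict[str, str] | None = None,
) -> list[InteractionSummary]:
    """Potential cross-feeding from fresh-medium monoculture calls.

    A metabolite qualifies when it is secreted by at least one species
    and consumed by at least one *different* species (a species may
    appear in both sets, but a sole producer that is also the sole
    consumer is excluded). Self-pairs never count as interactions.
    """
    compound_classes = compound_classes or {}
    producers, consumers = _directional_sets(calls)
    out: list[InteractionSummary] = []
    for m in sorted(set(producers) & set(consumers)):
        prod, cons = producers[m], consumers[m]
        if not any(p != c for p in prod for c in cons):
            continue
        out.append(
            InteractionSummary(
                metabolite=m,
                producers=frozenset(prod),
                consumers=frozenset(cons),
                interaction_type=interaction_type(len(prod), len(cons)),
                good_class="public" if len(cons) >= 2 else "private",
                compound_class=compound_classes.get(m, ""),
            )
        )
    return out


def build_spent_network(
    fresh_secretion_calls: list[DynamicCall],
    spent_consumption_calls: list[DynamicCall],
) -> list[CrossFeedEdge]:
    """Evidence-based cross-feeding edges.

    ``fresh_secretion_calls``: calls from fresh-medium monocultures
    (only ``secreted`` entries are used). ``spent_consumption_calls``:
    calls from spent-medium cultures, whose medium id names the producer
    (``spent:<producer>``); only ``consumed`` entries are used. An edge
    (P, C, m) requires m secreted by P in fresh medium AND consumed by C
    in P's spent medium, with P != C; triples are unique.
    """
    secreted_fresh = {
        (c.species, c.metabolite)
        for c in fresh_secretion_calls
        if c.direction == "secreted"
    }
    known_producers = {c.species for c in fresh_secretion_calls}
    edges: dict[tuple, CrossFeedEdge] = {}
    for c in spent_consumption_calls:
        if c.direction != "consumed":
            continue
        producer = spent_producer(c.medium)
        if producer is None:
            continue
        if known_producers and producer not in known_producers:
            raise KeyError(
                f"spent medium {c.medium!r} references unknown producer {producer!r}"
            )
        if producer == c.species:
            continue
        if (producer, c.metabolite) in secreted_fresh:
            key = (producer, c.species, c.metabolite)
            if key not in edges:
                edges[key] = CrossFeedEdge(
                    producer=producer,
                    consumer=c.species,
                    metabolite=c.metabolite,
                    medium=c.medium,
                )
    return [edges[k] for k in sorted(edges)]


def goods_and_scores(
    edges: list[CrossFeedEdge],
    compound_classes: dict[str, str] | None = None,
) -> tuple[list[InteractionSummary], list[SpeciesScore]]:
    """Per-metabolite goods partition and per-species interaction scores."""
    compound_classes = compound_classes or {}
    by_met: dict[str, tuple[set, set]] = {}
    n_cons: dict[str, int] = {}
    n_prod: dict[str, int] = {}
    for e in edges:
        prod, cons = by_met.setdefault(e.metabolite, (set(), set()))
        prod.add(e.producer)
        cons.add(e.consumer)
        n_cons[e.consumer] = n_cons.get(e.consumer, 0) + 1
        n_prod[e.producer] = n_prod.get(e.producer, 0) + 1
        n_cons.setdefault(e.producer, n_cons.get(e.producer, 0))
        n_prod.setdefault(e.consumer, n_prod.get(e.consumer, 0))

    summaries = [
        InteractionSummary(
            metabolite=m,
            producers=frozenset(prod),
            consumers=frozenset(cons),
            interaction_type=interaction_type(len(prod), len(cons)),
            good_class="public" if len(cons) >= 2 else "private",
            compound_class=compound_classes.get(m, ""),
        )
        for m, (prod, cons) in sorted(by_met.items())
    ]
    species = sorted(set(n_cons) | set(n_prod))
    scores = []
    for s in species:
        nc, ns = n_cons.get(s, 0), n_prod.get(s, 0)
        ratio = nc / ns if ns > 0 else (0.0 if nc == 0 else float("nan"))
        scores.append(SpeciesScore(species=s, n_consumed=nc, n_secreted=ns, ratio=ratio))
    return summaries, scores


def network_statistics(
    summaries: list[InteractionSummary],
    species_covariate: dict[str, float] | None = None,
    focal_class: str | None = None,
    edges: list[CrossFeedEdge] | None = None,
):
    """Enrichment of a compound class among public goods, and the
    correlation of per-species consumed-interaction counts with a
    covariate (e.g. genome size).

    Returns a dict with ``odds_ratio`` and ``p_enrichment`` (two-sided
    Fisher exact test on the 2x2 table class-membership x public/private;
    metabolites without a compound class are excluded from the
    denominators) and, when a covariate is given, ``r_covariate``.
    """
    out: dict[str, float | str] = {}
    if focal_class is not None:
        classed = [s for s in summaries if s.compound_class]
        n_pub = sum(1 for s in classed if s.good_class == "public")
        n_priv = len(classed) - n_pub
        if n_pub == 0 or n_priv == 0:
            out["odds_ratio"] = float("nan")
            out["p_enrichment"] = float("nan")
            out["enrichment_skipped"] = "degenerate margins: all public or all private"
        else:
            a = sum(1 for s in classed
                    if s.good_class == "public" and s.compound_class == focal_class)
            b = sum(1 for s in classed
                    if s.good_class == "private" and s.compound_class == focal_class)
            c = n_pub - a
            d = n_priv - b
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            out["odds_ratio"] = float(odds)
            out["p_enrichment"] = float(p)

    if species_covariate is not None:
        counts: dict[str, int] = {}
        if edges is not None:
            for e in edges:
                counts[e.consumer] = counts.get(e.consumer, 0) + 1
        else:
            for s in summaries:
                for c in s.consumers:
                    counts[c] = counts.get(c, 0) + 1
        common = sorted(set(counts) | set(species_covariate))
        if len(common) < 3:
            raise ValueError("need at least 3 species for the covariate correlation")
        x = np.array([counts.get(s, 0) for s in common], dtype=float)
        y = np.array([species_covariate.get(s, np.nan) for s in common], dtype=float)
        mask = np.isfinite(y)
        x, y = x[mask], y[mask]
        if len(x) < 3:
            raise ValueError("need at least 3 species with covariate values")
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            raise ValueError("zero-variance covariate or counts: correlation undefined")
        out["r_covariate"] = float(stats.pearsonr(x, y).statistic)
    return out
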