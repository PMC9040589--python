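"""Element-weighted (C / N) mass-flow networks.

A quantified cross-feeding edge carries the amount of metabolite the
consumer removed from the producer's spent medium (mM). Multiplying by
the number of carbon or nitrogen atoms per molecule converts it to an
elemental flow in C-mmol/L or N-mmol/L, making chemically different
metabolites commensurable and exposing who supplies and who drains each
element in the community. Edges at or below a display cutoff
(0.1 element-mmol/L by default) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import FormulaRecord
from .network import CrossFeedEdge

__all__ = [
    "ElementalFlowEdge",
    "element_flow",
    "build_element_network",
    "consumed_amounts",
    "attach_amounts",
]


@dataclass(frozen=True)
class ElementalFlowEdge:
    producer: str
    consumer: str
    metabolite: str
    element: str  # "C" | "N"
    flow: float   # element-mmol per liter


def element_flow(delta_conc_mM: float, counts: dict[str, int], element: str) -> float:
    """Elemental flow (element-mmol/L) of a consumed amount.

    ``flow = delta_conc_mM x (atoms of element per molecule)``; a
    metabolite without the element yields 0.
    """
    if element not in ("C", "N"):
        raise ValueError("element must be 'C' or 'N'")
    if delta_conc_mM < 0:
        raise ValueError("consumed concentration must be non-negative")
    return delta_conc_mM * counts.get(element, 0)


def consumed_amounts(conc_table: pd.DataFrame) -> dict[tuple, float]:
    """Consumed amount per (species, medium, metabolite) from a
    quantified concentration time course.

    The amount consumed is the concentration at the earliest timepoint
    minus the minimum concentration reached later (floored at 0).
    """
    out: dict[tuple, float] = {}
    for (sp, med, met), grp in conc_table.groupby(
        ["species", "medium", "metabolite"], sort=True
    ):
        grp = grp.sort_values("timepoint")
        start = float(grp["conc_mM"].iloc[0])
        delta = start - float(grp["conc_mM"].min())
        out[(str(sp), str(med), str(met))] = max(delta, 0.0)
    return out


def attach_amounts(
    edges: list[CrossFeedEdge], amounts: dict[tuple, float]
) -> list[CrossFeedEdge]:
    """Attach consumer-side consumed amounts (mM) to edges when quantified."""
    out = []
    for e in edges:
        amt = amounts.get((e.consumer, e.medium, e.metabolite))
        out.append(
            CrossFeedEdge(
                producer=e.producer,
                consumer=e.consumer,
                metabolite=e.metabolite,
                medium=e.medium,
                consumed_mM=amt if amt is not None else e.consumed_mM,
            )
        )
    return out


def build_element_network(
    edges: list[CrossFeedEdge],
    database: list[FormulaRecord],
    element: str,
    min_flow: float = 0.1,
):
    """Elemental flow edges plus per-species in/out totals.

    Edges whose metabolite lacks the element, whose flow is at or below
    ``min_flow``, or that carry no quantified amount (counted, warned via
    the returned ``n_unquantified``) are excluded.

    Returns ``(flow_edges, out_totals, in_totals, n_unquantified)``.
    Conservation holds exactly: sum of out-totals = sum of in-totals =
    sum of edge flows.
    """
    by_name = {rec.name: rec for rec in database}
    flow_edges: list[ElementalFlowEdge] = []
    n_unquantified = 0
    for e in edges:
        if e.metabolite not in by_name:
            raise KeyError(f"metabolite {e.metabolite!r} missing from formula database")
        if e.consumed_mM is None:
            n_unquantified += 1
            continue
        flow = element_flow(e.consumed_mM, by_name[e.metabolite].element_counts, element)
        if flow > min_flow:
            flow_edges.append(
                ElementalFlowEdge(
                    producer=e.producer,
                    consumer=e.consumer,
                    metabolite=e.metabolite,
                    element=element,
                    flow=flow,
                )
            )
    out_totals: dict[str, float] = {}
    in_totals: dict[str, float] = {}
    for fe in flow_edges:
        out_totals[fe.producer] = out_totals.get(fe.producer, 0.0) + fe.flow
        in_totals[fe.consumer] = in_totals.get(fe.consumer, 0.0) + fe.flow
    return flow_edges, out_totals, in_totals, n_unquantified
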