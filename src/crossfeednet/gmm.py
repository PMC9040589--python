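"""Metabolic-module detection from genome ortholog content.

A metabolic module (e.g. a gut metabolic module, GMM) is an ordered list
of enzymatic steps, each satisfiable by any one of a set of alternative
orthologs. A module is called present in a genome when strictly more
than a coverage threshold (default 50%) of its steps are satisfied by
the genome's ortholog set. Nested boolean module grammars are out of
scope; definitions must be pre-flattened into alternative-ortholog sets.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModuleDefinition", "detect_modules"]


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    name: str
    steps: list  # list of frozensets of alternative ortholog ids

    def __post_init__(self):
        if not self.steps:
            raise ValueError(f"module {self.module_id!r} has no steps")
        if any(len(s) == 0 for s in self.steps):
            raise ValueError(f"module {self.module_id!r} has an empty step")

    def coverage(self, ortholog_set: set[str]) -> float:
        satisfied = sum(1 for step in self.steps if ortholog_set & set(step))
        return satisfied / len(self.steps)


def detect_modules(
    ortholog_set: set[str],
    definitions: list[ModuleDefinition],
    threshold: float = 0.5,
) -> dict[str, tuple[float, bool]]:
    """Module coverage and presence for one genome.

    Presence requires coverage strictly greater than ``threshold``
    (">50%" by default).
    """
    if not definitions:
        raise ValueError("empty module definitions list")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    out = {}
    for d in definitions:
        cov = d.coverage(ortholog_set)
        out[d.module_id] = (cov, cov > threshold)
    return out
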