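"""Tab-separated table dialects and graph export.

All tabular I/O is tab-separated UTF-8 with a header row. The central
container is the wide ion time-course table: metadata columns
``species, medium, replicate, time_h, od`` followed by one intensity
column per annotated ion. Medium identifiers follow the convention
``fresh`` for the plain growth medium and ``spent:<producer>`` for a 1:1
mix of fresh medium with the producer's culture supernatant.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .annotation import FormulaRecord

ION_META_COLS = ["species", "medium", "replicate", "time_h", "od"]

FRESH_MEDIUM = "fresh"
SPENT_PREFIX = "spent:"

#: stable float formatting so identical runs write identical bytes
FLOAT_FORMAT = "%.10g"


def spent_medium_id(producer: str) -> str:
    return f"{SPENT_PREFIX}{producer}"


def spent_producer(medium: str) -> str | None:
    """Producer species of a spent-medium id, or None for other media."""
    if medium.startswith(SPENT_PREFIX):
        return medium[len(SPENT_PREFIX):]
    return None


def ion_columns(table: pd.DataFrame) -> list[str]:
    missing = [c for c in ION_META_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"ion table is missing columns: {missing}")
    return [c for c in table.columns if c not in ION_META_COLS]


def read_ion_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    ion_columns(table)  # validates metadata columns
    if (table["od"].isna()).any():
        raise ValueError(f"{path}: every row must carry an OD value")
    ions = ion_columns(table)
    if len(ions) and (table[ions] < 0).any().any():
        raise ValueError(f"{path}: negative ion intensities")
    return table


def write_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_formula_db(path) -> list[FormulaRecord]:
    """Read a formula database TSV (``name formula class``).

    The neutral mass is always recomputed from the formula, never
    trusted from the file.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "formula"):
        if col not in df.columns:
            raise ValueError(f"{path}: formula database needs a '{col}' column")
    cls = df["class"] if "class" in df.columns else [""] * len(df)
    return [
        FormulaRecord.from_formula(str(n), str(f), "" if pd.isna(c) else str(c))
        for n, f, c in zip(df["name"], df["formula"], cls)
    ]


def bundled_formula_db() -> list[FormulaRecord]:
    """The small curated metabolite database shipped with the package."""
    ref = importlib.resources.files("crossfeednet").joinpath("data/formulas.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_formula_db(path)


def read_concentrations(path) -> pd.DataFrame:
    """Quantified concentrations: ``metabolite species medium conc_mM timepoint``."""
    df = pd.read_csv(path, sep="\t")
    needed = {"metabolite", "species", "medium", "conc_mM", "timepoint"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: concentration table missing columns {sorted(missing)}")
    return df


def read_ortholog_list(path) -> set[str]:
    """One ortholog id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_module_definitions(path):
    """Flattened module definitions TSV: ``module_id step_index ortholog_id``."""
    from .gmm import ModuleDefinition

    df = pd.read_csv(path, sep="\t")
    needed = {"module_id", "step_index", "ortholog_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: module definitions missing columns {sorted(missing)}")
    defs = []
    for mid, grp in df.groupby("module_id", sort=True):
        steps = [
            frozenset(sub["ortholog_id"].astype(str))
            for _, sub in grp.groupby("step_index", sort=True)
        ]
        defs.append(ModuleDefinition(module_id=str(mid), name=str(mid), steps=steps))
    return defs


def edges_to_graphml(edges, path, flow_attr: bool = False) -> None:
    """Write cross-feeding edges as a GraphML multigraph.

    Nodes are species; each edge carries its metabolite (and, for
    elemental-flow edges, ``element`` and ``flow`` attributes).
    """
    g = nx.MultiDiGraph()
    for e in edges:
        attrs = {"metabolite": e.metabolite}
        if flow_attr:
            attrs["element"] = e.element
            attrs["flow"] = float(e.flow)
        else:
            if getattr(e, "medium", None) is not None:
                attrs["medium"] = e.medium
            if getattr(e, "consumed_mM", None) is not None:
                attrs["consumed_mM"] = float(e.consumed_mM)
        g.add_edge(e.producer, e.consumer, **attrs)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)
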