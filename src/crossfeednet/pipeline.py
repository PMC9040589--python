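"""End-to-end orchestration: annotation -> growth -> dynamics -> network
-> elemental flows -> metabolic potential, from a flat YAML config.

Every stage is independently invocable through the library (and the
CLI); the pipeline simply chains them, writes every table as TSV into
the output directory, and records a machine-readable run manifest with
per-stage record counts, the config hash and the seed, so identical
configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dynamics import CallerConfig, calibrate_thresholds, call_dynamics, calls_to_frame
from .elemental import attach_amounts, build_element_network, consumed_amounts
from .gmm import detect_modules
from .growth import fit_logistic4
from .io import (
    FRESH_MEDIUM,
    edges_to_graphml,
    ion_columns,
    read_concentrations,
    read_formula_db,
    read_ion_table,
    read_module_definitions,
    read_ortholog_list,
    spent_producer,
    write_table,
)
from .network import build_spent_network, goods_and_scores, predict_fresh_crossfeeding

log = logging.getLogger("crossfeednet")

VALIDATION_EXIT_CODE = 2


class ConfigError(ValueError):
    """A pipeline configuration problem (maps to exit code 2 in the CLI)."""


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration.

    Required: ``ion_table`` and ``formula_db`` paths. Optional inputs
    switch on the corresponding stages (concentrations -> elemental
    flows; ortholog lists + module definitions -> metabolic potential;
    dilution series -> threshold calibration).
    """

    ion_table: str = ""
    formula_db: str = ""
    concentrations: str | None = None
    dilution_series: str | None = None
    ortholog_lists: dict = field(default_factory=dict)  # genome -> path
    module_definitions: str | None = None
    out_dir: str = "results"
    seed: int = 0
    tolerance_da: float = 0.003
    min_flow: float = 0.1
    caller: CallerConfig = field(default_factory=CallerConfig)
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        caller_keys = {
            "r_od_threshold", "p_threshold", "r2_fit_threshold",
            "fc_secreted", "fc_consumed", "dilution_corr_threshold",
        }
        caller = CallerConfig(**{k: raw.pop(k) for k in list(raw) if k in caller_keys})
        known = {
            "ion_table", "formula_db", "concentrations", "dilution_series",
            "ortholog_lists", "module_definitions", "out_dir", "seed",
            "tolerance_da", "min_flow", "force",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(caller=caller, **raw)

    def validate(self) -> None:
        if not self.ion_table:
            raise ConfigError("config field 'ion_table' is required")
        if not self.formula_db:
            raise ConfigError("config field 'formula_db' is required")
        for name, p in [
            ("ion_table", self.ion_table),
            ("formula_db", self.formula_db),
            ("concentrations", self.concentrations),
            ("dilution_series", self.dilution_series),
            ("module_definitions", self.module_definitions),
        ]:
            if p is not None and p != "" and not Path(p).exists():
                raise ConfigError(f"config field {name!r}: path {p!r} does not exist")
        for genome, p in self.ortholog_lists.items():
            if not Path(p).exists():
                raise ConfigError(f"ortholog list for {genome!r}: {p!r} does not exist")
        if self.tolerance_da <= 0:
            raise ConfigError("tolerance_da must be positive")
        if self.min_flow < 0:
            raise ConfigError("min_flow must be non-negative")

    def content_hash(self) -> str:
        # out_dir and force affect where results land, not what they are
        skip = {"caller", "out_dir", "force"}
        payload = {k: v for k, v in self.__dict__.items() if k not in skip}
        payload["caller"] = self.caller.__dict__
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All pipeline outputs, as in-memory tables plus run metadata."""

    growth_fits: pd.DataFrame
    calls: pd.DataFrame
    fresh_summaries: pd.DataFrame
    edges: list
    goods: pd.DataFrame
    species_scores: pd.DataFrame
    element_networks: dict      # element -> (flow frame, out totals, in totals)
    modules: pd.DataFrame | None
    manifest: dict


def _fit_growth_table(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (sp, med, rep), grp in table.groupby(
        ["species", "medium", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        try:
            f = fit_logistic4(grp["time_h"].to_numpy(), grp["od"].to_numpy())
        except ValueError as exc:
            log.warning("growth fit skipped for (%s, %s, rep %s): %s", sp, med, rep, exc)
            continue
        rows.append({
            "species": sp, "medium": med, "replicate": rep,
            "A": f.A, "K": f.K, "r": f.r, "t0": f.t0,
            "mu": f.mu, "max_od": f.max_od, "r_squared": f.r_squared,
            "converged": f.converged, "grew": f.grew,
        })
    fits = pd.DataFrame(rows)
    if not fits.empty:
        pooled = (
            fits.groupby(["species", "medium"], sort=True)[["mu", "max_od"]]
            .mean()
            .reset_index()
        )
        pooled["replicate"] = "mean"
        fits = pd.concat([fits, pooled], ignore_index=True)
    return fits


def _summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": s.metabolite,
                "producers": ";".join(sorted(s.producers)),
                "consumers": ";".join(sorted(s.consumers)),
                "interaction_type": s.interaction_type,
                "good_class": s.good_class,
                "compound_class": s.compound_class,
            }
            for s in summaries
        ]
    )


def _edges_frame(edges) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "producer": e.producer,
                "consumer": e.consumer,
                "metabolite": e.metabolite,
                "medium": e.medium,
                "consumed_mM": e.consumed_mM if e.consumed_mM is not None else "",
            }
            for e in edges
        ],
        columns=["producer", "consumer", "metabolite", "medium", "consumed_mM"],
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all configured stages and write outputs to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise ConfigError(
            f"output directory {out} is not empty (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "stages": {},
    }

    table = read_ion_table(config.ion_table)
    database = read_formula_db(config.formula_db)
    classes = {rec.name: rec.compound_class for rec in database}
    manifest["stages"]["input"] = {
        "rows": int(len(table)), "ions": len(ion_columns(table)),
        "db_records": len(database),
    }
    log.info("input: %d rows, %d ions, %d database records",
             len(table), len(ion_columns(table)), len(database))

    caller = config.caller
    if config.dilution_series:
        dil = pd.read_csv(config.dilution_series, sep="\t")
        fc_c, fc_s = calibrate_thresholds(dil, caller)
        caller = CallerConfig(
            r_od_threshold=caller.r_od_threshold,
            p_threshold=caller.p_threshold,
            r2_fit_threshold=caller.r2_fit_threshold,
            fc_consumed=fc_c,
            fc_secreted=fc_s,
            dilution_corr_threshold=caller.dilution_corr_threshold,
        )
        manifest["stages"]["calibration"] = {"fc_consumed": fc_c, "fc_secreted": fc_s}
        log.info("calibrated thresholds: consumed %.3f, secreted %.3f", fc_c, fc_s)

    fits = _fit_growth_table(table)
    write_table(fits, out / "growth_fits.tsv")
    manifest["stages"]["growth"] = {"fits": int(len(fits))}

    calls = call_dynamics(table, caller)
    calls_frame = calls_to_frame(calls)
    write_table(calls_frame, out / "dynamic_calls.tsv")
    n_dir = sum(1 for c in calls if c.direction != "unchanged")
    manifest["stages"]["dynamics"] = {
        "calls": len(calls), "directional": n_dir,
    }
    log.info("dynamics: %d calls, %d directional", len(calls), n_dir)

    fresh_calls = [c for c in calls if c.medium == FRESH_MEDIUM]
    spent_calls = [c for c in calls if spent_producer(c.medium) is not None]
    fresh_summaries = predict_fresh_crossfeeding(fresh_calls, classes)
    write_table(_summaries_frame(fresh_summaries), out / "fresh_interactions.tsv")

    edges = build_spent_network(fresh_calls, spent_calls)
    if config.concentrations:
        conc = read_concentrations(config.concentrations)
        edges = attach_amounts(edges, consumed_amounts(conc))
    write_table(_edges_frame(edges), out / "crossfeed_edges.tsv")
    if edges:
        edges_to_graphml(edges, out / "crossfeed_network.graphml")
    summaries, scores = goods_and_scores(edges, classes)
    write_table(_summaries_frame(summaries), out / "goods.tsv")
    write_table(
        pd.DataFrame(
            [
                {"species": s.species, "n_consumed": s.n_consumed,
                 "n_secreted": s.n_secreted, "ratio": s.ratio}
                for s in scores
            ]
        ),
        out / "species_scores.tsv",
    )
    manifest["stages"]["network"] = {
        "fresh_crossfed": len(fresh_summaries),
        "edges": len(edges),
        "crossfed_metabolites": len(summaries),
    }
    log.info("network: %d predicted metabolites, %d edges", len(fresh_summaries),
             len(edges))

    element_networks = {}
    if config.concentrations:
        for element in ("C", "N"):
            flow_edges, out_tot, in_tot, n_unq = build_element_network(
                edges, database, element, min_flow=config.min_flow
            )
            frame = pd.DataFrame(
                [
                    {"producer": fe.producer, "consumer": fe.consumer,
                     "metabolite": fe.metabolite, "element": fe.element,
                     "flow": fe.flow}
                    for fe in flow_edges
                ],
                columns=["producer", "consumer", "metabolite", "element", "flow"],
            )
            write_table(frame, out / f"element_flow_{element}.tsv")
            if flow_edges:
                edges_to_graphml(flow_edges, out / f"element_network_{element}.graphml",
                                 flow_attr=True)
            element_networks[element] = (frame, out_tot, in_tot)
            manifest["stages"][f"elemental_{element}"] = {
                "edges": len(flow_edges), "unquantified": n_unq,
            }

    modules_frame = None
    if config.ortholog_lists and config.module_definitions:
        defs = read_module_definitions(config.module_definitions)
        rows = []
        for genome, path in sorted(config.ortholog_lists.items()):
            kos = read_ortholog_list(path)
            for mid, (cov, present) in detect_modules(kos, defs).items():
                rows.append({"genome": genome, "module_id": mid,
                             "coverage": cov, "present": present})
        modules_frame = pd.DataFrame(rows)
        write_table(modules_frame, out / "metabolic_modules.tsv")
        manifest["stages"]["metabolic_potential"] = {"rows": len(modules_frame)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ReportBundle(
        growth_fits=fits,
        calls=calls_frame,
        fresh_summaries=_summaries_frame(fresh_summaries),
        edges=edges,
        goods=_summaries_frame(summaries),
        species_scores=pd.DataFrame(
            [
                {"species": s.species, "n_consumed": s.n_consumed,
                 "n_secreted": s.n_secreted, "ratio": s.ratio}
                for s in scores
            ]
        ),
        element_networks=element_networks,
        modules=modules_frame,
        manifest=manifest,
    )
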