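"""Seeded synthetic datasets with known cross-feeding ground truth.

The generator emulates the experimental design the inference pipeline
assumes: batch monocultures in a rich medium sampled 8-10 times through
the growth phase, spent-medium cultures where a consumer grows in a 1:1
mix of fresh medium and a producer's stationary-phase supernatant, and a
medium dilution series for fold-change threshold calibration.

Model assumptions
-----------------
* OD follows a four-parameter logistic curve per species.
* A consumed metabolite tracks normalized biomass gain:
  ``x(t) = x0 (1 - y (OD(t) - OD(0)) / (K - OD(0)))`` with consumption
  fraction ``y`` of the initially available amount, so exhaustion before
  stationary phase is generatable.
* A secreted metabolite is yield-coupled to growth:
  ``x(t) = x0 + s (OD(t) - OD(0))`` with secretion yield ``s`` per unit
  of OD gained.
* Measurement noise is multiplicative lognormal with mean 1 and a given
  coefficient of variation, independent per measured value (ion counts
  are positive and heteroscedastic); no batch effects.
* The spent medium is harvested at the last sampling time of the
  producer (noiselessly) and mixed 1:1 with fresh medium.

Interactions are encoded as a signed yield per (species, metabolite):
negative values are consumption fractions (``y = -yield`` in (0, 1]),
positive values are secretion yields per unit delta-OD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import logistic4
from .io import FRESH_MEDIUM, ION_META_COLS, spent_medium_id

__all__ = [
    "GrowthParams",
    "SyntheticCommunitySpec",
    "GroundTruth",
    "simulate_growth",
    "simulate_community_timecourse",
    "simulate_experiment_suite",
    "simulate_dilution_series",
    "random_community_spec",
    "truth_to_frame",
]

#: 10 sampling times, evenly log-spaced through lag/exponential/stationary.
DEFAULT_SAMPLING_TIMES = tuple(float(t) for t in np.geomspace(0.5, 24.0, 10))


@dataclass(frozen=True)
class GrowthParams:
    """4PL parameters: baseline A, asymptote K (OD), rate r (1/h), inflection t0 (h)."""

    A: float
    K: float
    r: float
    t0: float

    def __post_init__(self):
        if not self.A > 0:
            raise ValueError("baseline A must be positive")
        if self.K < self.A:
            raise ValueError("asymptote K must be >= baseline A")
        if self.r <= 0:
            raise ValueError("rate r must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    secreted: frozenset  # of (species, metabolite)
    consumed: frozenset  # of (species, metabolite)
    edges: frozenset     # of (producer, consumer, metabolite)


@dataclass
class SyntheticCommunitySpec:
    """A synthetic consortium and its measurement design."""

    species: list
    growth_params: dict          # species -> GrowthParams
    medium: dict                 # metabolite -> initial intensity (a.u.)
    interactions: dict           # species -> {metabolite -> signed yield}
    noise_cv: float = 0.0
    sampling_times: tuple = DEFAULT_SAMPLING_TIMES
    replicates: int = 3
    seed: int = 0
    metabolites: list = field(init=False)

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        times = np.asarray(self.sampling_times, dtype=float)
        if len(times) < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("sampling_times must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        missing = [s for s in self.species if s not in self.growth_params]
        if missing:
            raise ValueError(f"growth_params missing for species {missing}")
        secreted_somewhere = {
            m for inter in self.interactions.values()
            for m, y in inter.items() if y > 0
        }
        for sp, inter in self.interactions.items():
            if sp not in self.species:
                raise ValueError(f"interactions reference unknown species {sp!r}")
            for m, y in inter.items():
                if y < 0 and not 0 < -y <= 1:
                    raise ValueError(
                        f"consumption fraction for ({sp}, {m}) must be in (0, 1]"
                    )
                if y < 0 and self.medium.get(m, 0) <= 0 and m not in secreted_somewhere:
                    raise ValueError(
                        f"({sp}, {m}): consumed metabolite absent from the medium "
                        "and not secreted by any species"
                    )
        self.metabolites = sorted(set(self.medium) | {
            m for inter in self.interactions.values() for m in inter
        })

    def ground_truth(self) -> GroundTruth:
        secreted, consumed = set(), set()
        for sp, inter in self.interactions.items():
            for m, y in inter.items():
                if y > 0:
                    secreted.add((sp, m))
                elif y < 0:
                    consumed.add((sp, m))
        edges = {
            (p, c, m)
            for (p, m) in secreted
            for (c, m2) in consumed
            if m == m2 and p != c
        }
        return GroundTruth(frozenset(secreted), frozenset(consumed), frozenset(edges))


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def simulate_growth(params: GrowthParams, times, noise_cv: float = 0.0, seed=0):
    """One noisy logistic growth curve; returns (times, od) arrays."""
    t = np.asarray(times, dtype=float)
    if len(t) == 0 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("times must be non-empty and strictly increasing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    od = logistic4(t, params.A, params.K, params.r, params.t0)
    od = od * _noise(rng, noise_cv, od.shape)
    return t, od


def _endpoint_exometabolome(spec: SyntheticCommunitySpec, producer: str) -> dict:
    """Noiseless supernatant composition of the producer at harvest
    (the last sampling time), grown in fresh medium."""
    p = spec.growth_params[producer]
    t = np.asarray(spec.sampling_times, dtype=float)
    od = logistic4(t, p.A, p.K, p.r, p.t0)
    gain = od[-1] - od[0]
    denom = p.K - od[0]
    g_end = gain / denom if denom > 0 else 0.0
    inter = spec.interactions.get(producer, {})
    out = {}
    for m in spec.metabolites:
        x0 = spec.medium.get(m, 0.0)
        y = inter.get(m, 0.0)
        if y < 0:
            out[m] = x0 * (1.0 + y * g_end)  # y negative: consumption
        elif y > 0:
            out[m] = x0 + y * gain
        else:
            out[m] = x0
    return out


def _simulate_culture(
    spec: SyntheticCommunitySpec,
    species: str,
    medium_id: str,
    medium_comp: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    p = spec.growth_params[species]
    t = np.asarray(spec.sampling_times, dtype=float)
    od_true = logistic4(t, p.A, p.K, p.r, p.t0)
    gain = od_true - od_true[0]
    denom = p.K - od_true[0]
    g = gain / denom if denom > 0 else np.zeros_like(gain)
    inter = spec.interactions.get(species, {})

    rows = []
    for rep in range(1, spec.replicates + 1):
        od = od_true * _noise(rng, spec.noise_cv, od_true.shape)
        row = {
            "species": species,
            "medium": medium_id,
            "replicate": rep,
            "time_h": t,
            "od": od,
        }
        for m in spec.metabolites:
            x0 = medium_comp.get(m, 0.0)
            y = inter.get(m, 0.0)
            if y < 0:
                x = x0 * (1.0 + y * g)
            elif y > 0:
                x = x0 + y * gain
            else:
                x = np.full_like(gain, x0)
            row[m] = np.clip(x, 0.0, None) * _noise(rng, spec.noise_cv, x.shape)
        rows.append(pd.DataFrame(row))
    return pd.concat(rows, ignore_index=True)


def simulate_community_timecourse(
    spec: SyntheticCommunitySpec,
    mode: str = "fresh",
    producer: str | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate the exometabolome time course of one experiment.

    ``mode="fresh"`` runs every species as a monoculture in fresh
    medium. ``mode="spent"`` first computes the named producer's
    harvest-time supernatant (noiselessly), mixes it 1:1 with fresh
    medium, and grows every *other* species in the mixture.

    Returns ``(table, ground_truth)`` — a wide ion time-course frame and
    the spec's full ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if mode == "fresh":
        medium_id, comp = FRESH_MEDIUM, dict(spec.medium)
        runs = list(spec.species)
    elif mode == "spent":
        if producer is None or producer not in spec.species:
            raise ValueError("spent mode needs a producer from the species list")
        end = _endpoint_exometabolome(spec, producer)
        comp = {
            m: 0.5 * (spec.medium.get(m, 0.0) + end.get(m, 0.0))
            for m in spec.metabolites
        }
        medium_id = spent_medium_id(producer)
        runs = [s for s in spec.species if s != producer]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    tables = [_simulate_culture(spec, sp, medium_id, comp, rng) for sp in runs]
    table = pd.concat(tables, ignore_index=True)
    table = table[ION_META_COLS + spec.metabolites]
    return table, spec.ground_truth()


def simulate_experiment_suite(spec: SyntheticCommunitySpec):
    """The full study design: fresh monocultures of every species plus
    spent-medium cultures for every producer. One seeded RNG drives all
    draws, so identical specs give byte-identical tables."""
    rng = np.random.default_rng(spec.seed)
    tables = [simulate_community_timecourse(spec, "fresh", rng=rng)[0]]
    for producer in spec.species:
        tables.append(
            simulate_community_timecourse(spec, "spent", producer=producer, rng=rng)[0]
        )
    return pd.concat(tables, ignore_index=True), spec.ground_truth()


def simulate_dilution_series(
    medium_ions: dict,
    background_ions: dict,
    dilutions,
    replicates: int = 3,
    noise_cv: float = 0.0,
    seed=0,
) -> pd.DataFrame:
    """Medium dilution series: medium-derived ions scale as 1/dilution,
    background ions are constant. Columns: dilution, replicate, ions."""
    dil = np.asarray(sorted(dilutions), dtype=float)
    if len(np.unique(dil)) < 2:
        raise ValueError("need at least two distinct dilution factors")
    if np.any(dil <= 0):
        raise ValueError("dilution factors must be positive")
    if not medium_ions and not background_ions:
        raise ValueError("empty ion sets")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for d in dil:
        for rep in range(1, replicates + 1):
            row = {"dilution": d, "replicate": rep}
            for ion, base in medium_ions.items():
                row[ion] = (base / d) * float(_noise(rng, noise_cv, ()))
            for ion, level in background_ions.items():
                row[ion] = level * float(_noise(rng, noise_cv, ()))
            rows.append(row)
    return pd.DataFrame(rows)


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth edge list as a TSV-ready frame."""
    return pd.DataFrame(
        sorted(truth.edges), columns=["producer", "consumer", "metabolite"]
    )


def random_community_spec(
    n_species: int = 5,
    n_metabolites: int = 20,
    seed: int = 0,
    noise_cv: float = 0.0,
    replicates: int = 3,
) -> SyntheticCommunitySpec:
    """A randomized but well-posed consortium for end-to-end testing.

    Each species gets admissible logistic parameters, consumes 2-4
    metabolites (fractions 0.6-0.95 of the available amount, large
    enough to clear the calibrated fold-change cutoffs) and secretes 2-4
    (yields sized to at least match the fresh-medium baseline over the
    OD gain). Roughly a third of the medium components are inert
    background. Some secreted metabolites are absent from the fresh
    medium, so they can only be cross-fed via spent media.
    """
    rng = np.random.default_rng(seed)
    species = [f"S{i+1}" for i in range(n_species)]
    mets = [f"M{i+1:02d}" for i in range(n_metabolites)]

    growth = {}
    for sp in species:
        A = float(rng.uniform(0.03, 0.08))
        K = float(rng.uniform(0.6, 2.0))
        r = float(rng.uniform(0.8, 2.5))
        t0 = float(rng.uniform(2.0, 8.0))
        growth[sp] = GrowthParams(A=A, K=K, r=r, t0=t0)

    # ~70% of metabolites start in the fresh medium; the rest appear only
    # through secretion
    in_medium = rng.random(n_metabolites) < 0.7
    medium = {
        m: float(rng.uniform(500.0, 5000.0))
        for m, keep in zip(mets, in_medium) if keep
    }

    interactions: dict = {sp: {} for sp in species}
    for sp in species:
        k_cons = int(rng.integers(2, 5))
        k_secr = int(rng.integers(2, 5))
        choices = rng.permutation(n_metabolites)
        consumed = [mets[i] for i in choices[:k_cons]]
        secreted = [mets[i] for i in choices[k_cons:k_cons + k_secr]]
        for m in consumed:
            interactions[sp][m] = -float(rng.uniform(0.6, 0.95))
        gain = growth[sp].K - growth[sp].A
        for m in secreted:
            x0 = medium.get(m, rng.uniform(500.0, 5000.0))
            interactions[sp][m] = float(rng.uniform(1.0, 3.0)) * x0 / gain

    # drop consumption of metabolites that never become available
    secreted_somewhere = {
        m for inter in interactions.values() for m, y in inter.items() if y > 0
    }
    for sp in species:
        interactions[sp] = {
            m: y
            for m, y in interactions[sp].items()
            if y > 0 or medium.get(m, 0) > 0 or m in secreted_somewhere
        }

    return SyntheticCommunitySpec(
        species=species,
        growth_params=growth,
        medium=medium,
        interactions=interactions,
        noise_cv=noise_cv,
        replicates=replicates,
        seed=seed,
    )
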