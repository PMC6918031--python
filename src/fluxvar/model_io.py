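"""Metabolic model containers, plain-text I/O and toy community generation.

A :class:`MetabolicModel` is a minimal constraint-based model: a stoichiometric
matrix over internal metabolites, per-reaction flux bounds, one biomass
reaction, and a map from exchange reactions to metabolites of the shared
environment.  The sign convention is fixed package-wide and matches COBRA:
a *negative* exchange flux imports the metabolite from the environment
(uptake), a *positive* one secretes it.

Two interchangeable on-disk formats are provided: a single JSON document with
the stoichiometry as sparse triplets (schema version 1), and a TSV-triplet
directory dialect for workflows that prefer columnar text.  Both round-trip
bit-identically through :func:`save_model` / :func:`load_model`.

:func:`make_toy_community` builds small communities with controllable
competition (shared growth substrates) and cross-feeding (metabolites secreted
by one species and usable by another), standing in for curated genome-scale
reconstructions so that every downstream analysis is testable from scratch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MetabolicModel",
    "EnvironmentSpec",
    "ModelFormatError",
    "ModelValidationError",
    "ConfigurationError",
    "load_model",
    "save_model",
    "load_environment",
    "save_environment",
    "canonical_json",
    "make_toy_community",
]

MODEL_SCHEMA_VERSION = 1


class ModelFormatError(ValueError):
    """The on-disk representation could not be parsed."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant."""


class ConfigurationError(ValueError):
    """An infeasible generator or simulation configuration was requested."""


@dataclass
class MetabolicModel:
    """A single species' stoichiometric model.

    Parameters
    ----------
    species_id
        Identifier of the organism the model describes.
    metabolite_ids
        Internal metabolite identifiers (rows of ``S``).
    reaction_ids
        Reaction identifiers (columns of ``S``).
    S
        Dense stoichiometric matrix, metabolites x reactions.
    lower_bounds, upper_bounds
        Flux bounds per reaction (mmol / gDW / h).
    biomass_reaction
        Identifier of the growth objective reaction.
    exchange_map
        Exchange reaction id -> environment metabolite id.  Negative flux
        through an exchange reaction is uptake from the environment.
    """

    species_id: str
    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    biomass_reaction: str
    exchange_map: dict[str, str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        n_met, n_rxn = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n_met, n_rxn):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({n_met}, {n_rxn})"
            )
        if len(self.lower_bounds) != n_rxn or len(self.upper_bounds) != n_rxn:
            raise ModelValidationError("bound vectors must match reaction count")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = int(np.argmax(self.lower_bounds > self.upper_bounds))
            raise ModelValidationError(
                f"lower_bound > upper_bound for reaction {self.reaction_ids[bad]!r}"
            )
        if self.biomass_reaction not in self.reaction_ids:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )
        if self.upper_bounds[self.reaction_index(self.biomass_reaction)] <= 0:
            raise ModelValidationError("biomass reaction must have upper bound > 0")
        if len(set(self.exchange_map)) != len(self.exchange_map):
            raise ModelValidationError("duplicate exchange reaction in exchange_map")
        for rxn in self.exchange_map:
            if rxn not in self.reaction_ids:
                raise ModelValidationError(f"exchange reaction {rxn!r} not in model")
        if len(set(self.reaction_ids)) != n_rxn:
            raise ModelValidationError("reaction identifiers must be unique")
        if len(set(self.metabolite_ids)) != n_met:
            raise ModelValidationError("metabolite identifiers must be unique")

    def reaction_index(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def exchange_indices(self) -> dict[str, int]:
        """Environment metabolite id -> column index of its exchange reaction."""
        return {
            env: self.reaction_index(rxn) for rxn, env in self.exchange_map.items()
        }


@dataclass
class EnvironmentSpec:
    """The shared nutrient environment: inflow rates and initial pools.

    ``inflow_rates`` are concentration inflows (mM / h); ``initial_concentrations``
    are mM.  Every exchange target of every community model must appear in
    ``env_metabolite_ids``.
    """

    env_metabolite_ids: list[str]
    inflow_rates: np.ndarray
    initial_concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.inflow_rates = np.asarray(self.inflow_rates, dtype=float)
        self.initial_concentrations = np.asarray(
            self.initial_concentrations, dtype=float
        )
        n = len(self.env_metabolite_ids)
        if len(self.inflow_rates) != n or len(self.initial_concentrations) != n:
            raise ModelValidationError("environment vectors must match metabolite list")
        if np.any(self.inflow_rates < 0):
            raise ModelValidationError("inflow rates must be nonnegative")
        if np.any(self.initial_concentrations < 0):
            raise ModelValidationError("initial concentrations must be nonnegative")

    def index(self, metabolite_id: str) -> int:
        return self.env_metabolite_ids.index(metabolite_id)

    def check_covers(self, models: list[MetabolicModel]) -> None:
        known = set(self.env_metabolite_ids)
        for model in models:
            missing = set(model.exchange_map.values()) - known
            if missing:
                raise ModelValidationError(
                    f"model {model.species_id!r} exchanges metabolites absent from "
                    f"the environment: {sorted(missing)}"
                )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _model_payload(model: MetabolicModel) -> dict:
    rows, cols = np.nonzero(model.S)
    triplets = sorted(
        [int(i), int(j), float(model.S[i, j])] for i, j in zip(rows, cols)
    )
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "species_id": model.species_id,
        "metabolites": list(model.metabolite_ids),
        "reactions": list(model.reaction_ids),
        "stoichiometry": triplets,
        "lower_bounds": [float(x) for x in model.lower_bounds],
        "upper_bounds": [float(x) for x in model.upper_bounds],
        "biomass_reaction": model.biomass_reaction,
        "exchange_map": {k: model.exchange_map[k] for k in sorted(model.exchange_map)},
    }


def canonical_json(model: MetabolicModel) -> str:
    """Canonical serialization: the byte-identity target for round-trips."""
    return json.dumps(_model_payload(model), indent=1, sort_keys=True) + "\n"


def save_model(model: MetabolicModel, path: str | Path, format: str = "json") -> None:
    """Write ``model`` to ``path`` in the requested plain-text format."""
    path = Path(path)
    if format == "json":
        path.write_text(canonical_json(model))
    elif format == "tsv-triplet":
        _save_tsv(model, path)
    else:
        raise ConfigurationError(f"unknown model format {format!r}")


def load_model(path: str | Path, format: str = "json") -> MetabolicModel:
    """Read and validate a model from ``path``.

    Raises :class:`ModelFormatError` on parse problems and
    :class:`ModelValidationError` on structural problems.
    """
    path = Path(path)
    if format == "json":
        return _load_json(path)
    if format == "tsv-triplet":
        return _load_tsv(path)
    raise ConfigurationError(f"unknown model format {format!r}")


def _load_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        version = doc["schema_version"]
        if version != MODEL_SCHEMA_VERSION:
            raise ModelFormatError(f"{path}: unsupported schema version {version}")
        mets = list(doc["metabolites"])
        rxns = list(doc["reactions"])
        S = np.zeros((len(mets), len(rxns)))
        for i, j, coef in doc["stoichiometry"]:
            S[int(i), int(j)] = float(coef)
        return MetabolicModel(
            species_id=doc["species_id"],
            metabolite_ids=mets,
            reaction_ids=rxns,
            S=S,
            lower_bounds=np.array(doc["lower_bounds"], dtype=float),
            upper_bounds=np.array(doc["upper_bounds"], dtype=float),
            biomass_reaction=doc["biomass_reaction"],
            exchange_map=dict(doc["exchange_map"]),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ModelFormatError(f"{path}: missing or malformed field ({exc})") from exc


def _save_tsv(model: MetabolicModel, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    payload = _model_payload(model)
    lines = ["metabolite\treaction\tcoefficient"]
    for i, j, coef in payload["stoichiometry"]:
        lines.append(
            f"{model.metabolite_ids[i]}\t{model.reaction_ids[j]}\t{coef!r}"
        )
    (directory / "stoichiometry.tsv").write_text("\n".join(lines) + "\n")
    lines = ["reaction\tlower_bound\tupper_bound\tis_biomass\texchange_metabolite"]
    for j, rxn in enumerate(model.reaction_ids):
        lines.append(
            "\t".join(
                [
                    rxn,
                    repr(float(model.lower_bounds[j])),
                    repr(float(model.upper_bounds[j])),
                    "1" if rxn == model.biomass_reaction else "0",
                    model.exchange_map.get(rxn, ""),
                ]
            )
        )
    (directory / "reactions.tsv").write_text("\n".join(lines) + "\n")
    (directory / "metabolites.tsv").write_text(
        "metabolite\n" + "\n".join(model.metabolite_ids) + "\n"
    )
    (directory / "species.tsv").write_text(f"species_id\n{model.species_id}\n")


def _read_tsv(path: Path) -> list[list[str]]:
    if not path.exists():
        raise ModelFormatError(f"missing sidecar file {path}")
    rows = [line.split("\t") for line in path.read_text().splitlines() if line]
    if not rows:
        raise ModelFormatError(f"{path}: empty file")
    return rows[1:]  # drop header


def _load_tsv(directory: Path) -> MetabolicModel:
    species_rows = _read_tsv(directory / "species.tsv")
    met_rows = _read_tsv(directory / "metabolites.tsv")
    rxn_rows = _read_tsv(directory / "reactions.tsv")
    sto_rows = _read_tsv(directory / "stoichiometry.tsv")
    mets = [r[0] for r in met_rows]
    rxns, lbs, ubs, biomass, exchange_map = [], [], [], [], {}
    try:
        for row in rxn_rows:
            rxn, lb, ub, is_bio, exch = row
            rxns.append(rxn)
            lbs.append(float(lb))
            ubs.append(float(ub))
            if is_bio == "1":
                biomass.append(rxn)
            if exch:
                exchange_map[rxn] = exch
        met_idx = {m: i for i, m in enumerate(mets)}
        rxn_idx = {r: j for j, r in enumerate(rxns)}
        S = np.zeros((len(mets), len(rxns)))
        for met, rxn, coef in sto_rows:
            S[met_idx[met], rxn_idx[rxn]] = float(coef)
    except (ValueError, KeyError) as exc:
        raise ModelFormatError(f"{directory}: malformed TSV field ({exc})") from exc
    if len(biomass) != 1:
        raise ModelFormatError(
            f"{directory}: expected exactly one biomass reaction, found {len(biomass)}"
        )
    return MetabolicModel(
        species_id=species_rows[0][0],
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        biomass_reaction=biomass[0],
        exchange_map=exchange_map,
    )


def save_environment(env: EnvironmentSpec, path: str | Path) -> None:
    """Write an environment spec as a JSON document."""
    payload = {
        "env_metabolite_ids": list(env.env_metabolite_ids),
        "inflow_rates": [float(x) for x in env.inflow_rates],
        "initial_concentrations": [float(x) for x in env.initial_concentrations],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_environment(path: str | Path) -> EnvironmentSpec:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
        return EnvironmentSpec(
            env_metabolite_ids=list(doc["env_metabolite_ids"]),
            inflow_rates=np.array(doc["inflow_rates"], dtype=float),
            initial_concentrations=np.array(
                doc["initial_concentrations"], dtype=float
            ),
        )
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"{path}: missing or malformed field ({exc})") from exc


# ---------------------------------------------------------------------------
# Toy community generation
# ---------------------------------------------------------------------------

# Seeded uniform grids for stoichiometric coefficients and inflow rates.
_SUBSTRATE_COEF_GRID = np.arange(1.0, 4.25, 0.25)
_BYPRODUCT_COEF_GRID = np.arange(0.3, 1.05, 0.05)
_CONVERSION_YIELD_GRID = np.arange(0.4, 1.05, 0.05)
_INFLOW_GRID = np.arange(1.0, 5.25, 0.25)

DEFAULT_INTERNAL_BOUND = 1000.0


def make_toy_community(
    n_species: int,
    n_env_metabolites: int,
    cross_feed_fraction: float,
    seed: int,
) -> tuple[list[MetabolicModel], EnvironmentSpec]:
    """Generate a small community with competition and cross-feeding.

    Each species grows by consuming 2-4 shared environmental substrates with
    seeded stoichiometric coefficients, optionally secreting byproducts.  A
    ``cross_feed_fraction`` share of environmental metabolites is designated
    cross-fed: secreted as a growth byproduct by one species and convertible
    into a growth substrate by at least one other (a salvage-style conversion
    reaction), so cross-feeding can emerge in simulation without making any
    species obligately dependent on a partner.

    Deterministic for a fixed seed; identical arguments yield byte-identical
    serialized models.
    """
    if n_species < 1:
        raise ConfigurationError("n_species must be >= 1")
    if n_env_metabolites < 2:
        raise ConfigurationError("n_env_metabolites must be >= 2")
    if not 0 <= cross_feed_fraction <= 1:
        raise ConfigurationError("cross_feed_fraction must be in [0, 1]")
    n_cross = round(cross_feed_fraction * n_env_metabolites)
    if n_cross > 0 and n_species < 2:
        raise ConfigurationError(
            "cross-feeding requires at least two species (one producer, one consumer)"
        )
    n_primary = n_env_metabolites - n_cross
    if n_primary < 1:
        raise ConfigurationError(
            "at least one environmental metabolite must remain a primary "
            "(inflow-supplied) substrate"
        )

    rng = np.random.default_rng(seed)
    env_ids = [f"env_met_{j}" for j in range(n_env_metabolites)]
    order = rng.permutation(n_env_metabolites)
    primary = sorted(int(j) for j in order[:n_primary])
    cross = sorted(int(j) for j in order[n_primary:])

    # Producer / consumer assignment for cross-fed metabolites: at most two
    # byproducts per species, consumer always differs from producer.
    producers: dict[int, int] = {}
    consumers: dict[int, int] = {}
    producer_load = {k: 0 for k in range(n_species)}
    for j in cross:
        candidates = [k for k in range(n_species) if producer_load[k] < 2]
        prod = int(rng.choice(candidates if candidates else list(range(n_species))))
        producer_load[prod] = producer_load.get(prod, 0) + 1
        cons = int(rng.choice([k for k in range(n_species) if k != prod]))
        producers[j] = prod
        consumers[j] = cons

    models = []
    for k in range(n_species):
        n_sub = int(rng.integers(2, 5)) if n_primary >= 2 else 1
        n_sub = min(n_sub, n_primary)
        subs = sorted(int(j) for j in rng.choice(primary, size=n_sub, replace=False))
        byproducts = sorted(j for j, p in producers.items() if p == k)
        conversions = sorted(j for j, c in consumers.items() if c == k)

        used = sorted(set(subs) | set(byproducts) | set(conversions))
        met_ids = [f"{env_ids[j]}_c" for j in used]
        local = {j: i for i, j in enumerate(used)}

        rxn_ids: list[str] = []
        lbs: list[float] = []
        ubs: list[float] = []
        cols: list[dict[int, float]] = []
        exchange_map: dict[str, str] = {}

        def add_rxn(rid: str, lb: float, ub: float, stoich: dict[int, float]) -> None:
            rxn_ids.append(rid)
            lbs.append(lb)
            ubs.append(ub)
            cols.append(stoich)

        for j in subs:
            rid = f"EX_{env_ids[j]}"
            add_rxn(rid, -DEFAULT_INTERNAL_BOUND, 0.0, {local[j]: -1.0})
            exchange_map[rid] = env_ids[j]
        for j in byproducts:
            rid = f"EX_{env_ids[j]}"
            add_rxn(rid, 0.0, DEFAULT_INTERNAL_BOUND, {local[j]: -1.0})
            exchange_map[rid] = env_ids[j]
        for j in conversions:
            rid = f"EX_{env_ids[j]}"
            add_rxn(rid, -DEFAULT_INTERNAL_BOUND, 0.0, {local[j]: -1.0})
            exchange_map[rid] = env_ids[j]
            # Salvage: one unit of the cross-fed compound substitutes for a
            # seeded yield of the species' first primary substrate.
            target = subs[int(rng.integers(0, len(subs)))]
            yield_coef = float(rng.choice(_CONVERSION_YIELD_GRID))
            add_rxn(
                f"CONV_{env_ids[j]}",
                0.0,
                DEFAULT_INTERNAL_BOUND,
                {local[j]: -1.0, local[target]: yield_coef},
            )

        biomass_stoich: dict[int, float] = {}
        for j in subs:
            biomass_stoich[local[j]] = -float(rng.choice(_SUBSTRATE_COEF_GRID))
        for j in byproducts:
            biomass_stoich[local[j]] = float(rng.choice(_BYPRODUCT_COEF_GRID))
        add_rxn("biomass", 0.0, DEFAULT_INTERNAL_BOUND, biomass_stoich)

        S = np.zeros((len(met_ids), len(rxn_ids)))
        for col, stoich in enumerate(cols):
            for row, coef in stoich.items():
                S[row, col] = coef

        models.append(
            MetabolicModel(
                species_id=f"species_{k}",
                metabolite_ids=met_ids,
                reaction_ids=rxn_ids,
                S=S,
                lower_bounds=np.array(lbs),
                upper_bounds=np.array(ubs),
                biomass_reaction="biomass",
                exchange_map=exchange_map,
            )
        )

    inflow = np.zeros(n_env_metabolites)
    for j in primary:
        inflow[j] = float(rng.choice(_INFLOW_GRID))
    # Prime initial concentrations with one hour's worth of inflow.
    init = inflow * 1.0
    env = EnvironmentSpec(
        env_metabolite_ids=env_ids,
        inflow_rates=inflow,
        initial_concentrations=init,
    )
    env.check_covers(models)
    return models, env
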