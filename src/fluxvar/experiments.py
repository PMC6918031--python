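"""Experimental designs, synthetic ground truth, and end-to-end benchmarks.

Three layers:

* **Designs** — the composition sweep (one uniform community plus each
  species raised to a set of initial-abundance ratios over the rest, all
  scaled to the carrying capacity) and normally distributed nutrient-inflow
  fluctuations at configurable coefficients of variation.
* **Synthetic ground truth** — flux tables drawn from a multivariate normal
  with a specified covariance over species activities and the environmental
  inflow, for which the analytic contribution profile is known in closed form
  (each contribution is a row sum of the covariance matrix).  Helpers plant
  the canonical motifs: a sole producer, a compensating (negative
  contribution) pair, and a masked producer whose relative contribution far
  exceeds 1.
* **Benchmarks** — a full pipeline run: toy community -> chemostat
  simulations over the design -> flux tables -> contribution profiles and key
  contributors -> correlation screen -> classification metrics, plus the
  inflow-fluctuation sweep with environmental-contribution binning.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemostat import CommunityState, SimParams, SimulationTrace, run_simulation
from .contributions import (
    ContributionProfile,
    FluxTable,
    build_flux_tables,
    contribution_values,
)
from .evaluation import (
    AlphaPolicy,
    EnvironmentBinEntry,
    MetricsReport,
    PairOutcome,
    confusion_metrics,
    environment_bins,
    select_variable_metabolites,
    spearman_screen,
)
from .model_io import (
    ConfigurationError,
    EnvironmentSpec,
    MetabolicModel,
    make_toy_community,
)

__all__ = [
    "CompositionDesign",
    "SyntheticFluxSpec",
    "BenchmarkConfig",
    "BenchmarkResult",
    "DEFAULT_RATIOS",
    "FLUCTUATION_LEVELS",
    "composition_design",
    "sample_inflow_fluctuations",
    "synthetic_flux_dataset",
    "sole_producer_spec",
    "compensating_pair_spec",
    "masked_producer_spec",
    "estimate_carrying_capacity",
    "run_benchmark",
    "run_fluctuation_sweep",
    "most_abundant_initial_species",
]

#: Initial-abundance ratios of the perturbed species to every other species.
DEFAULT_RATIOS = (2.0, 3.0, 4.5, 6.0, 9.0, 13.0)

#: Inflow fluctuation levels (coefficients of variation) of the sweep design,
#: applied on top of the constant-inflow baseline.
FLUCTUATION_LEVELS = (0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.08, 0.10)

#: Fluctuation levels of the desk-scale mini sweep (baseline + two levels).
MINI_SWEEP_CVS = (0.0, 0.05, 0.10)


def mini_sweep_config() -> "BenchmarkConfig":
    """The desk-scale fluctuation-sweep experiment: a 6-species, 12-metabolite
    community over a 19-composition design, simulated for 75 h so communities
    approach steady state and inflow fluctuation becomes a substantial
    variance source."""
    return BenchmarkConfig(
        n_species=6, n_env_metabolites=12, ratios=(2.0, 4.5, 13.0),
        n_steps=300,
    )


@dataclass
class CompositionDesign:
    """Initial community compositions for a sweep.

    ``compositions`` holds absolute biomass vectors (each summing to the
    carrying capacity); ``labels`` records which species was perturbed and at
    what ratio (``(None, None)`` for the uniform start).
    """

    compositions: list[np.ndarray]
    labels: list[tuple[str | None, float | None]]
    capacity: float
    species_ids: list[str]

    def __len__(self) -> int:
        return len(self.compositions)

    def sample_ids(self) -> list[str]:
        return [f"run_{i}" for i in range(len(self))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.array(self.compositions), columns=self.species_ids,
            index=self.sample_ids(),
        )
        df["perturbed_species"] = [lbl[0] for lbl in self.labels]
        df["ratio"] = [lbl[1] for lbl in self.labels]
        df.index.name = "sample"
        return df


def composition_design(
    n_species: int = 10,
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
    capacity: float = 1.0,
    species_ids: list[str] | None = None,
) -> CompositionDesign:
    """The composition sweep: 1 uniform start + one perturbed composition per
    (species, ratio) pair, giving ``1 + n_species * len(ratios)`` runs.

    At ratio r the perturbed species starts at relative abundance
    ``r / (r + n_species - 1)`` with all other species equal; every
    composition's total equals the carrying capacity.
    """
    if n_species < 2:
        raise ConfigurationError("composition design needs at least 2 species")
    if any(r <= 1 for r in ratios):
        raise ConfigurationError("ratios must exceed 1")
    if len(set(ratios)) != len(ratios):
        raise ConfigurationError("duplicate ratios in design")
    if capacity <= 0:
        raise ConfigurationError("capacity must be positive")
    ids = species_ids or [f"species_{k}" for k in range(n_species)]
    compositions = [np.full(n_species, capacity / n_species)]
    labels: list[tuple[str | None, float | None]] = [(None, None)]
    for k in range(n_species):
        for r in ratios:
            rel = np.full(n_species, 1.0 / (r + n_species - 1))
            rel[k] = r / (r + n_species - 1)
            assert abs(rel.sum() - 1.0) < 1e-12
            compositions.append(rel * capacity)
            labels.append((ids[k], r))
    return CompositionDesign(compositions, labels, capacity, ids)


def sample_inflow_fluctuations(
    base_inflow: np.ndarray,
    cv: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One fluctuated inflow vector: independent normal draws per metabolite
    with mean ``base`` and standard deviation ``cv * base``.

    Negative draws are truncated to 0 (with a logged count); ``cv = 0``
    returns the base exactly.  Deterministic under a fixed seed.
    """
    if cv < 0:
        raise ConfigurationError("cv must be nonnegative")
    base = np.asarray(base_inflow, dtype=float)
    if cv == 0:
        return base.copy()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = rng.normal(loc=base, scale=cv * base)
    n_trunc = int(np.sum(draws < 0))
    if n_trunc:
        warnings.warn(f"{n_trunc} negative inflow draws truncated to 0")
    return np.maximum(draws, 0.0)


# ---------------------------------------------------------------------------
# Synthetic flux datasets with analytic ground truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticFluxSpec:
    """A multivariate-normal generator for species + environment fluxes.

    ``cov`` and ``mean`` are ordered species first, environmental inflow
    last ((n_species + 1) entries).  The covariance must be symmetric
    positive semidefinite.
    """

    n_species: int
    n_samples: int
    mean: np.ndarray
    cov: np.ndarray
    seed: int = 0
    metabolite_id: str = "synthetic_met"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.n_species + 1
        if self.mean.shape != (d,) or self.cov.shape != (d, d):
            raise ConfigurationError(
                "mean and cov must cover n_species + 1 flux sources"
            )
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ConfigurationError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.cov)
        if eigvals.min() < -1e-9 * max(eigvals.max(), 1.0):
            raise ConfigurationError("covariance must be positive semidefinite")


def _analytic_profile(spec: SyntheticFluxSpec) -> ContributionProfile:
    row_sums = spec.cov.sum(axis=1)
    c = row_sums[:-1]
    c_env = float(row_sums[-1])
    var_M = float(spec.cov.sum())
    rel = c / var_M if var_M > 0 else np.full_like(c, np.nan)
    rel_env = c_env / var_M if var_M > 0 else float("nan")
    from .contributions import classify_key_contributors

    profile = ContributionProfile(
        metabolite_id=spec.metabolite_id,
        species_ids=[f"species_{k}" for k in range(spec.n_species)],
        c=c, c_env=c_env, var_M=var_M,
        relative=rel, relative_env=rel_env, key_contributors=set(),
    )
    profile.key_contributors = classify_key_contributors(profile)
    return profile


def synthetic_flux_dataset(
    spec: SyntheticFluxSpec,
) -> tuple[FluxTable, ContributionProfile]:
    """Sample a flux table from ``spec`` and return it with the analytic
    contribution profile implied by the specified covariance.

    The concentration column is constructed as ``M = sum_i m_i + m_env``, so
    the empirical decomposition of the table converges to the analytic
    profile as the sample count grows.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.multivariate_normal(
        spec.mean, spec.cov, size=spec.n_samples, method="svd"
    )
    table = FluxTable(
        metabolite_id=spec.metabolite_id,
        species_ids=[f"species_{k}" for k in range(spec.n_species)],
        m_star=X[:, :-1],
        m_env=X[:, -1],
        M=X.sum(axis=1),
    )
    return table, _analytic_profile(spec)


def sole_producer_spec(
    n_species: int = 4,
    n_samples: int = 50,
    producer: int = 0,
    variance: float = 1.0,
    seed: int = 0,
) -> SyntheticFluxSpec:
    """One species with varying secretion; everyone else (and the inflow) is
    constant, so the producer's relative contribution is exactly 1."""
    cov = np.zeros((n_species + 1, n_species + 1))
    cov[producer, producer] = variance
    mean = np.ones(n_species + 1)
    mean[producer] = 2.0
    return SyntheticFluxSpec(n_species, n_samples, mean, cov, seed)


def compensating_pair_spec(
    n_samples: int = 200,
    rho: float = -0.9,
    var1: float = 1.0,
    var2: float = 0.5,
    n_species: int = 3,
    seed: int = 0,
) -> SyntheticFluxSpec:
    """Two anticorrelated activities: species 2 offsets species 1, earning a
    negative analytic contribution when ``rho`` is sufficiently negative."""
    cov = np.zeros((n_species + 1, n_species + 1))
    cov[0, 0] = var1
    cov[1, 1] = var2
    cov[0, 1] = cov[1, 0] = rho * np.sqrt(var1 * var2)
    mean = np.zeros(n_species + 1)
    return SyntheticFluxSpec(n_species, n_samples, mean, cov, seed)


def masked_producer_spec(
    ratio: float = 71.7,
    n_samples: int = 10_000,
    n_species: int = 2,
    seed: int = 0,
) -> SyntheticFluxSpec:
    """A producer almost fully offset by a consumer, so its positive
    contribution is ``ratio`` times the observed variance.

    With m2 = -(1 - delta) m1 + e, the producer's contribution is
    a * delta and var(M) = a delta^2 + var(e); delta and var(e) are chosen so
    c1 / var(M) equals ``ratio`` exactly.
    """
    if ratio <= 1:
        raise ConfigurationError("ratio must exceed 1")
    a = 1.0
    delta = 1.0 / (2.0 * ratio)
    s = a * delta * (1.0 / ratio - delta)  # > 0 because delta < 1/ratio
    b = 1.0 - delta
    cov = np.zeros((n_species + 1, n_species + 1))
    cov[0, 0] = a
    cov[0, 1] = cov[1, 0] = -b * a
    cov[1, 1] = b * b * a + s
    mean = np.zeros(n_species + 1)
    return SyntheticFluxSpec(n_species, n_samples, mean, cov, seed)


# ---------------------------------------------------------------------------
# End-to-end benchmark
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkConfig:
    """Everything needed to rerun a benchmark bit-identically."""

    n_species: int = 4
    n_env_metabolites: int = 8
    cross_feed_fraction: float = 0.5
    seed: int = 7
    ratios: tuple[float, ...] = (2.0, 4.5, 13.0)
    n_steps: int = 100
    dt: float = 0.25
    D: float = 0.0472
    volume: float = 0.00134
    Vmax: float = 20.0
    Km: float = 0.01
    carrying_capacity: float | None = None  # None -> estimate from simulations
    inflow_cv: float = 0.0
    alpha: float = 0.01
    alpha_kind: str = "raw"
    n_bootstrap: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_params(self, capacity: float) -> SimParams:
        return SimParams(
            dt=self.dt, n_steps=self.n_steps, D=self.D, volume=self.volume,
            Vmax=self.Vmax, Km=self.Km, carrying_capacity=capacity,
            rng_seed=self.seed,
        )


@dataclass
class BenchmarkResult:
    """All artifacts of one benchmark run."""

    config: BenchmarkConfig
    models: list[MetabolicModel]
    env: EnvironmentSpec
    design: CompositionDesign
    traces: list[SimulationTrace]
    tables: dict[str, FluxTable]
    variable_metabolites: set[str]
    profiles: dict[str, ContributionProfile]
    key_links: set[tuple[str, str]]
    abundances: pd.DataFrame
    concentrations: pd.DataFrame
    outcomes: list[PairOutcome]
    metrics: MetricsReport

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(o) for o in self.outcomes])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.design.to_frame().to_csv(directory / "design.tsv", sep="\t")
        self.abundances.to_csv(directory / "abundances.tsv", sep="\t")
        self.concentrations.to_csv(directory / "concentrations.tsv", sep="\t")
        self.outcomes_frame().to_csv(
            directory / "pair_outcomes.tsv", sep="\t", index=False
        )
        tables_dir = directory / "flux_tables"
        tables_dir.mkdir(exist_ok=True)
        for met, table in self.tables.items():
            table.save(tables_dir / f"{met}.tsv")
        profs = []
        for met, prof in self.profiles.items():
            df = prof.to_frame()
            df.insert(0, "metabolite", met)
            df.insert(1, "var_M", prof.var_M)
            profs.append(df)
        pd.concat(profs, ignore_index=True).to_csv(
            directory / "contributions.tsv", sep="\t", index=False
        )
        manifest = {
            "config": self.config.to_dict(),
            "capacity": self.design.capacity,
            "n_samples": len(self.design),
            "variable_metabolites": sorted(self.variable_metabolites),
            "metrics": {
                k: getattr(self.metrics, k)
                for k in ("TP", "FP", "FN", "TN", "sensitivity", "specificity",
                          "ppv", "accuracy", "auc")
            },
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=float) + "\n"
        )


def estimate_carrying_capacity(
    models: list[MetabolicModel],
    env: EnvironmentSpec,
    params: SimParams,
    n_compositions: int = 3,
    init_total: float = 0.01,
    seed: int = 0,
) -> float:
    """Average final total abundance over a few low-inoculum runs with varied
    compositions — the community's effective capacity in this medium."""
    rng = np.random.default_rng(seed)
    totals = []
    for _ in range(n_compositions):
        rel = rng.dirichlet(np.ones(len(models)))
        init = CommunityState(
            t=0.0, bio=rel * init_total, conc=env.initial_concentrations.copy()
        )
        trace = run_simulation(models, init, env, params)
        totals.append(float(trace.bio[-1].sum()))
    return float(np.mean(totals))


def mechanistic_capability(
    traces: list[SimulationTrace],
) -> pd.DataFrame:
    """Species x metabolite boolean frame: the species exchanged the
    metabolite (nonzero amount) at any step of any run."""
    ref = traces[0]
    any_flux = np.zeros((len(ref.species_ids), len(ref.env_metabolite_ids)), bool)
    for tr in traces:
        any_flux |= np.any(np.abs(tr.exchange) > 0, axis=0)
    return pd.DataFrame(
        any_flux, index=ref.species_ids, columns=ref.env_metabolite_ids
    )


def most_abundant_initial_species(design: CompositionDesign) -> pd.Series:
    """Subgroup label per run: the species with the highest initial abundance
    (the uniform start is its own ``uniform`` subgroup)."""
    labels = []
    for comp, (perturbed, _r) in zip(design.compositions, design.labels):
        labels.append(perturbed if perturbed is not None else "uniform")
    return pd.Series(labels, index=design.sample_ids(), name="subgroup")


def simulate_design(
    models: list[MetabolicModel],
    env: EnvironmentSpec,
    config: BenchmarkConfig,
) -> tuple[CompositionDesign, list[SimulationTrace]]:
    """Simulate one chemostat run per composition of the sweep design.

    Estimates the carrying capacity from low-inoculum runs unless the config
    fixes one; inflow fluctuations (if any) draw one child seed per sample
    from ``config.seed``.
    """
    if config.carrying_capacity is None:
        capacity = estimate_carrying_capacity(
            models, env,
            config.sim_params(capacity=1.0), seed=config.seed,
        )
    else:
        capacity = config.carrying_capacity
    params = config.sim_params(capacity)
    design = composition_design(
        n_species=len(models), ratios=config.ratios, capacity=capacity,
        species_ids=[m.species_id for m in models],
    )
    rng = np.random.default_rng(config.seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=len(design))
    traces = []
    for i, comp in enumerate(design.compositions):
        inflow = sample_inflow_fluctuations(
            env.inflow_rates, config.inflow_cv,
            np.random.default_rng(int(sample_seeds[i])),
        )
        env_i = EnvironmentSpec(
            env_metabolite_ids=list(env.env_metabolite_ids),
            inflow_rates=inflow,
            initial_concentrations=inflow * 1.0,
        )
        init = CommunityState(
            t=0.0, bio=comp.copy(), conc=env_i.initial_concentrations.copy()
        )
        traces.append(run_simulation(models, init, env_i, params))
    return design, traces


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Full pipeline: community -> simulations -> contributions -> screen.

    Deterministic for a fixed config; fluctuated-inflow runs derive one child
    seed per sample from ``config.seed``.
    """
    models, env = make_toy_community(
        config.n_species, config.n_env_metabolites,
        config.cross_feed_fraction, config.seed,
    )
    design, traces = simulate_design(models, env, config)
    tables = build_flux_tables(traces, traces[0].params)
    sample_ids = design.sample_ids()
    abundances = pd.DataFrame(
        np.array([tr.bio[-1] for tr in traces]),
        columns=[m.species_id for m in models], index=sample_ids,
    )
    concentrations = pd.DataFrame(
        np.array([tr.conc[-1] for tr in traces]),
        columns=list(env.env_metabolite_ids), index=sample_ids,
    )
    for met, table in tables.items():
        table.sample_ids = sample_ids

    variable = select_variable_metabolites(concentrations)
    profiles = {
        met: contribution_values(tables[met]) for met in sorted(variable)
    }
    key_links = {
        (sp, met)
        for met, prof in profiles.items()
        for sp in prof.key_contributors
    }
    policy = AlphaPolicy(kind=config.alpha_kind, alpha=config.alpha)
    outcomes = spearman_screen(
        abundances, concentrations[sorted(variable)], policy,
        key_links=key_links, mechanistic=mechanistic_capability(traces),
    )
    metrics = confusion_metrics(
        outcomes, n_bootstrap=config.n_bootstrap, seed=config.seed,
        alpha_policy=policy,
    )
    return BenchmarkResult(
        config=config, models=models, env=env, design=design, traces=traces,
        tables=tables, variable_metabolites=variable, profiles=profiles,
        key_links=key_links, abundances=abundances,
        concentrations=concentrations, outcomes=outcomes, metrics=metrics,
    )


def run_fluctuation_sweep(
    config: BenchmarkConfig,
    cvs: tuple[float, ...] = (0.0,) + FLUCTUATION_LEVELS,
    bin_width: float = 0.10,
) -> dict:
    """The inflow-fluctuation sweep: one benchmark dataset per fluctuation
    level (cv = 0 is the constant-inflow baseline), followed by
    environmental-contribution binning of the pooled outcomes.

    Returns ``{"datasets": {cv: BenchmarkResult}, "bins": {label:
    MetricsReport}}``.
    """
    datasets: dict[float, BenchmarkResult] = {}
    entries: list[EnvironmentBinEntry] = []
    for cv in cvs:
        cfg = dataclasses.replace(config, inflow_cv=cv)
        result = run_benchmark(cfg)
        datasets[cv] = result
        outcomes_by_met: dict[str, list[PairOutcome]] = {}
        for o in result.outcomes:
            outcomes_by_met.setdefault(o.metabolite_id, []).append(o)
        for met, prof in result.profiles.items():
            in_inflow = result.env.inflow_rates[
                result.env.index(met)
            ] > 0
            entries.append(
                EnvironmentBinEntry(
                    profile=prof,
                    outcomes=outcomes_by_met.get(met, []),
                    in_inflow=bool(in_inflow),
                    baseline=(cv == 0.0),
                )
            )
    bins = environment_bins(entries, bin_width=bin_width)
    return {"datasets": datasets, "bins": bins, "entries": entries}
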