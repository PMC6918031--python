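"""Per-species steady-state flux problems: growth maximization then pFBA.

Each call solves the classic two-stage linear program.  Stage 1 maximizes the
biomass (growth) flux subject to stoichiometric steady state ``S v = 0`` and
flux bounds, with environmental uptake limited by the supplied
:class:`UptakeBounds`.  Stage 2 (parsimonious FBA) minimizes the total
absolute flux while holding growth at (1 - eps_fix) of the stage-1 optimum,
which selects a unique, enzymatically cheap flux vector from the optimal face
and makes simulation traces reproducible.

The absolute-value objective is linearized by splitting each reaction flux
into nonnegative forward and backward parts; both stages are solved with the
deterministic single-threaded HiGHS backend of :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = ["UptakeBounds", "FluxSolution", "solve_growth", "FBANumericalError"]

#: Relative slack when pinning the stage-1 optimum for the pFBA stage.
EPS_FIX = 1e-9

#: Growth rates below this are reported as zero growth.
MU_ZERO_TOL = 1e-9


class FBANumericalError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""


@dataclass
class UptakeBounds:
    """Maximum uptake rates (nonnegative magnitudes, mmol/gDW/h) per
    environment metabolite.  Metabolites without an entry cannot be taken up.
    """

    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, rate in self.rates.items():
            if not np.isfinite(rate) or rate < 0:
                raise ValueError(f"uptake bound for {met!r} must be finite and >= 0")

    def get(self, env_metabolite: str) -> float:
        return self.rates.get(env_metabolite, 0.0)


@dataclass
class FluxSolution:
    """Result of one two-stage solve.

    ``status`` is ``"optimal"`` for positive growth, ``"zero_growth"`` when the
    optimum is (numerically) zero, and ``"infeasible"`` when the LP itself has
    no feasible point (pathological inputs; ``v`` is all zeros then).
    """

    growth_rate: float
    fluxes: np.ndarray
    status: str

    def exchange_fluxes(self, model: MetabolicModel) -> dict[str, float]:
        """Signed exchange fluxes keyed by environment metabolite id."""
        return {
            env: float(self.fluxes[idx])
            for env, idx in model.exchange_indices().items()
        }


def _effective_bounds(
    model: MetabolicModel, bounds: UptakeBounds
) -> tuple[np.ndarray, np.ndarray]:
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for rxn, env in model.exchange_map.items():
        j = model.reaction_index(rxn)
        lb[j] = max(lb[j], -bounds.get(env))
    return lb, ub


def solve_growth(model: MetabolicModel, bounds: UptakeBounds) -> FluxSolution:
    """Maximize growth, then minimize total absolute flux at that growth.

    Deterministic across repeated calls on identical input.  A model with all
    uptake shut off returns the zero flux vector with zero growth rather than
    raising.
    """
    lb, ub = _effective_bounds(model, bounds)
    n = model.n_reactions
    b_idx = model.reaction_index(model.biomass_reaction)

    c = np.zeros(n)
    c[b_idx] = -1.0
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return FluxSolution(0.0, np.zeros(n), "infeasible")
    if not res.success:
        raise FBANumericalError(f"stage-1 LP failed: {res.message}")
    mu_star = max(float(res.x[b_idx]), 0.0)

    # Stage 2: min sum(p + n) with v = p - n, growth pinned near mu_star.
    pos_lb = np.maximum(lb, 0.0)
    pos_ub = np.maximum(ub, 0.0)
    neg_lb = np.maximum(-ub, 0.0)
    neg_ub = np.maximum(-lb, 0.0)
    split_bounds = list(zip(pos_lb, pos_ub)) + list(zip(neg_lb, neg_ub))
    A_eq = np.hstack([model.S, -model.S])
    A_ub = np.zeros((1, 2 * n))
    A_ub[0, b_idx] = -1.0
    A_ub[0, n + b_idx] = 1.0
    b_ub = np.array([-(1.0 - EPS_FIX) * mu_star])
    res2 = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(model.n_metabolites),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=split_bounds,
        method="highs",
    )
    if not res2.success:
        raise FBANumericalError(f"pFBA stage LP failed: {res2.message}")
    v = res2.x[:n] - res2.x[n:]
    mu = max(float(v[b_idx]), 0.0)
    status = "optimal" if mu_star > MU_ZERO_TOL else "zero_growth"
    return FluxSolution(mu, v, status)
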