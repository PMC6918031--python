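"""Benchmarking correlation analysis against ground-truth contributions.

Treats the recovery of key contributor species as a classification task:
species-metabolite pairs are screened by Spearman correlation between species
abundance and metabolite concentration, calls are compared against the true
key-contributor links derived from flux-based contribution profiles, and the
screen's quality is summarized as a confusion table, sensitivity /
specificity / PPV / accuracy, and an ROC AUC (rank formulation on |rho|) with
a bootstrap confidence interval.

Additional diagnostics reproduce the anatomy of correlation failures:
logistic identity models with likelihood-ratio tests ask whether false
positives / false negatives track species or metabolite identity; subgroup
consistency filters links that replicate with a consistent sign across sample
subgroups; and environmental-contribution binning stratifies performance by
how much of a metabolite's variance is driven by nutrient-inflow fluctuation
rather than microbial activity.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contributions import ContributionProfile

__all__ = [
    "AlphaPolicy",
    "PairOutcome",
    "MetricsReport",
    "LRTStratumReport",
    "EnvironmentBinEntry",
    "select_variable_metabolites",
    "spearman_pair",
    "spearman_screen",
    "matched_fdr_cutoff",
    "confusion_metrics",
    "identity_misclassification_models",
    "subgroup_consistency",
    "environment_bins",
]

#: Sample sizes at or below this use the exact permutation null for Spearman p.
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class AlphaPolicy:
    """How 'significant' is decided for a family of correlation tests.

    ``kind`` is one of ``raw`` (p < alpha), ``bh`` (Benjamini-Hochberg
    adjusted p <= alpha), or ``bh-matched`` (the raw-alpha cutoff translated
    into its implied BH false-discovery threshold over the evaluated family;
    equivalent to ``raw`` on the same family but transferable to other
    families such as sample subgroups).
    """

    kind: str = "raw"
    alpha: float = 0.01
    matched_q: float | None = None  # filled in by spearman_screen

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "bh", "bh-matched"):
            raise ValueError(f"unknown alpha policy {self.kind!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PairOutcome:
    """One species-metabolite test: correlation, call, and ground truth."""

    species_id: str
    metabolite_id: str
    rho: float
    p: float
    significant: bool
    is_key_contributor: bool
    mechanistic_capable: bool = True
    undefined: bool = False


@dataclass
class MetricsReport:
    """Confusion counts and summary metrics for one set of pair outcomes."""

    TP: int
    FP: int
    FN: int
    TN: int
    sensitivity: float
    specificity: float
    ppv: float
    accuracy: float
    auc: float
    auc_ci: tuple[float, float]
    n_excluded: int
    alpha_policy: AlphaPolicy | None = None

    @property
    def n_pairs(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def select_variable_metabolites(concentrations: pd.DataFrame) -> set[str]:
    """Metabolites whose cross-sample variance strictly exceeds the 25th
    percentile of all metabolite variances.

    ``concentrations`` is samples x metabolites.  Zero-variance metabolites
    never pass (the strict inequality excludes them even when the quartile is
    zero).
    """
    if len(concentrations) < 2:
        raise ValueError("need at least 2 samples to assess variance")
    variances = concentrations.var(axis=0, ddof=1)
    cutoff = float(np.percentile(variances.to_numpy(), 25))
    return set(variances.index[variances > cutoff])


@functools.lru_cache(maxsize=4)
def _permutation_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p for one pair, ties mid-ranked.

    Exact permutation p-value (all n! orderings) for n <= 9, the t
    approximation otherwise.  Returns (nan, nan) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples for a Spearman screen")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    xc = rx - rx.mean()
    yc = ry - ry.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    rho = float(xc @ yc / denom)
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = _permutation_indices(n)
        rho_null = (yc[perms] @ xc) / denom
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum.accumulate(
        (pvals[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    return np.minimum(adjusted, 1.0)


def matched_fdr_cutoff(pvals: np.ndarray, alpha: float) -> float:
    """The BH false-discovery threshold implied by the raw cutoff ``alpha``
    over this test family (largest adjusted p among raw-significant tests)."""
    pvals = np.asarray(pvals, dtype=float)
    ok = np.isfinite(pvals)
    adjusted = _bh_adjust(pvals[ok])
    hits = adjusted[pvals[ok] < alpha]
    return float(hits.max()) if len(hits) else float(alpha)


def spearman_screen(
    abundances: pd.DataFrame,
    concentrations: pd.DataFrame,
    alpha_policy: AlphaPolicy | None = None,
    key_links: set[tuple[str, str]] | None = None,
    mechanistic: pd.DataFrame | None = None,
) -> list[PairOutcome]:
    """Correlate every species against every metabolite across samples.

    ``abundances`` (samples x species) and ``concentrations`` (samples x
    metabolites) must share their sample index.  ``key_links`` holds the true
    (species, metabolite) key-contributor pairs; ``mechanistic`` is an
    optional species x metabolite boolean frame marking pairs where the
    species ever exchanges the metabolite.  Pairs with a constant series get
    NaN statistics, are never significant, and are flagged ``undefined``
    (excluded from downstream counts, with a logged tally).
    """
    if not abundances.index.equals(concentrations.index):
        raise ValueError("abundance and concentration samples must match")
    policy = alpha_policy or AlphaPolicy()
    key_links = key_links or set()

    pairs: list[tuple[str, str, float, float]] = []
    for sp in abundances.columns:
        for met in concentrations.columns:
            rho, p = spearman_pair(
                abundances[sp].to_numpy(), concentrations[met].to_numpy()
            )
            pairs.append((sp, met, rho, p))

    pvals = np.array([p for *_, p in pairs])
    defined = np.isfinite(pvals)
    significant = np.zeros(len(pairs), dtype=bool)
    if policy.kind == "raw":
        significant[defined] = pvals[defined] < policy.alpha
    elif policy.kind == "bh":
        adj = _bh_adjust(pvals[defined])
        significant[defined] = adj <= policy.alpha
    else:  # bh-matched
        policy.matched_q = matched_fdr_cutoff(pvals, policy.alpha)
        adj = _bh_adjust(pvals[defined])
        significant[defined] = adj <= policy.matched_q

    n_undef = int(np.sum(~defined))
    if n_undef:
        warnings.warn(
            f"{n_undef} species-metabolite pairs had a constant series; "
            "reported as NA and excluded from counts"
        )
    outcomes = []
    for idx, (sp, met, rho, p) in enumerate(pairs):
        capable = True
        if mechanistic is not None:
            capable = bool(mechanistic.loc[sp, met])
        outcomes.append(
            PairOutcome(
                species_id=sp,
                metabolite_id=met,
                rho=rho,
                p=p,
                significant=bool(significant[idx]),
                is_key_contributor=(sp, met) in key_links,
                mechanistic_capable=capable,
                undefined=not defined[idx],
            )
        )
    return outcomes


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC by the Mann-Whitney rank formulation (ties mid-ranked)."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def confusion_metrics(
    outcomes: list[PairOutcome],
    n_bootstrap: int = 500,
    seed: int = 0,
    alpha_policy: AlphaPolicy | None = None,
) -> MetricsReport:
    """Confusion table and summary metrics over a set of pair outcomes.

    TP = significant and key contributor, FP = significant non-contributor,
    and so on.  The AUC uses |rho| as the score for the key-contributor label
    via the rank formulation, with a percentile bootstrap CI over pairs
    (default 500 resamples).  Pairs flagged ``undefined`` are excluded from
    all counts and reported via ``n_excluded``.
    """
    if not outcomes:
        raise ValueError("no pair outcomes supplied")
    kept = [o for o in outcomes if not o.undefined]
    n_excluded = len(outcomes) - len(kept)
    sig = np.array([o.significant for o in kept])
    key = np.array([o.is_key_contributor for o in kept])
    TP = int(np.sum(sig & key))
    FP = int(np.sum(sig & ~key))
    FN = int(np.sum(~sig & key))
    TN = int(np.sum(~sig & ~key))

    def ratio(a: int, b: int) -> float:
        return a / b if b else float("nan")

    scores = np.abs(np.array([o.rho for o in kept]))
    auc = _rank_auc(scores, key)
    ci = (float("nan"), float("nan"))
    if np.isfinite(auc) and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(kept)
        boot = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            boot.append(_rank_auc(scores[idx], key[idx]))
        boot = np.array([b for b in boot if np.isfinite(b)])
        if len(boot):
            ci = (
                float(np.percentile(boot, 2.5)),
                float(np.percentile(boot, 97.5)),
            )
    return MetricsReport(
        TP=TP, FP=FP, FN=FN, TN=TN,
        sensitivity=ratio(TP, TP + FN),
        specificity=ratio(TN, TN + FP),
        ppv=ratio(TP, TP + FP),
        accuracy=ratio(TP + TN, TP + FP + FN + TN),
        auc=auc,
        auc_ci=ci,
        n_excluded=n_excluded,
        alpha_policy=alpha_policy,
    )


@dataclass
class LRTStratumReport:
    """Likelihood-ratio tests for one stratum of the identity models.

    Compares nested logistic fits of the error outcome on species identity,
    metabolite identity, and both; ``p_species`` / ``p_metabolite`` test the
    added term set against the model containing only the other one.
    """

    stratum: str
    n_pairs: int
    n_events: int
    p_species: float
    p_metabolite: float
    df_species: int
    df_metabolite: int
    separation_detected: bool = False
    skipped: bool = False
    notice: str = ""


def _fit_logit_ll(df: pd.DataFrame, formula: str) -> tuple[float, int, bool]:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.glm(formula, data=df, family=sm.families.Binomial())
        fit = model.fit(maxiter=200)
    separated = any("separat" in str(w.message).lower() for w in caught) or bool(
        np.any(np.abs(fit.params) > 20)
    )
    return float(fit.llf), int(fit.df_model), separated


def identity_misclassification_models(
    outcomes: list[PairOutcome],
) -> list[LRTStratumReport]:
    """Do species or metabolite identities predict correlation errors?

    Two strata are analyzed separately: non-contributor pairs (event = a
    significant correlation, i.e. a false positive) and key-contributor pairs
    (event = a missed correlation, i.e. a false negative).  For each, nested
    logistic models with grouped indicator predictors are compared by
    likelihood-ratio chi-square tests.  Strata that are empty or contain a
    single species / metabolite are skipped with a notice; complete
    separation is detected and reported rather than masked.
    """
    kept = [o for o in outcomes if not o.undefined]
    strata = {
        "non_contributors": (
            [o for o in kept if not o.is_key_contributor],
            lambda o: o.significant,
        ),
        "key_contributors": (
            [o for o in kept if o.is_key_contributor],
            lambda o: not o.significant,
        ),
    }
    reports = []
    for name, (subset, event) in strata.items():
        if not subset:
            reports.append(
                LRTStratumReport(name, 0, 0, float("nan"), float("nan"), 0, 0,
                                 skipped=True, notice="empty stratum")
            )
            continue
        df = pd.DataFrame(
            {
                "outcome": [int(event(o)) for o in subset],
                "species": [o.species_id for o in subset],
                "metabolite": [o.metabolite_id for o in subset],
            }
        )
        n_sp = df["species"].nunique()
        n_met = df["metabolite"].nunique()
        if n_sp < 2 or n_met < 2:
            reports.append(
                LRTStratumReport(
                    name, len(df), int(df["outcome"].sum()),
                    float("nan"), float("nan"), 0, 0, skipped=True,
                    notice="fewer than 2 species or metabolites represented",
                )
            )
            continue
        ll_sp, df_sp, sep1 = _fit_logit_ll(df, "outcome ~ C(species)")
        ll_met, df_met, sep2 = _fit_logit_ll(df, "outcome ~ C(metabolite)")
        ll_both, df_both, sep3 = _fit_logit_ll(
            df, "outcome ~ C(species) + C(metabolite)"
        )
        d_sp = df_both - df_met
        d_met = df_both - df_sp
        p_species = float(stats.chi2.sf(2 * (ll_both - ll_met), d_sp))
        p_metabolite = float(stats.chi2.sf(2 * (ll_both - ll_sp), d_met))
        reports.append(
            LRTStratumReport(
                stratum=name,
                n_pairs=len(df),
                n_events=int(df["outcome"].sum()),
                p_species=p_species,
                p_metabolite=p_metabolite,
                df_species=d_sp,
                df_metabolite=d_met,
                separation_detected=sep1 or sep2 or sep3,
            )
        )
    return reports


def subgroup_consistency(
    abundances: pd.DataFrame,
    concentrations: pd.DataFrame,
    groups: pd.Series,
    cutoff: float,
    min_subgroup_size: int = 4,
) -> dict:
    """Links significant with a consistent sign in every sample subgroup.

    ``groups`` assigns each sample to exactly one subgroup (typically the
    most abundant initial species).  Within each subgroup of at least
    ``min_subgroup_size`` samples, pairs are re-screened and a link is
    *confirmed* if it is significant (p below ``cutoff``, usually the
    matched-FDR threshold of the pooled analysis) with the same correlation
    sign in all subgroups.  The relaxed k-of-n tally is also returned.
    """
    if not abundances.index.equals(groups.index):
        raise ValueError("groups must be indexed by the same samples")
    used, excluded = [], []
    for label, idx in groups.groupby(groups).groups.items():
        if len(idx) >= min_subgroup_size:
            used.append((label, idx))
        else:
            excluded.append(label)
    if excluded:
        warnings.warn(
            f"subgroups {excluded} have fewer than {min_subgroup_size} "
            "samples and were excluded"
        )
    per_pair: dict[tuple[str, str], list[tuple[bool, float]]] = {}
    for label, idx in used:
        ab = abundances.loc[idx]
        co = concentrations.loc[idx]
        for sp in ab.columns:
            for met in co.columns:
                rho, p = spearman_pair(ab[sp].to_numpy(), co[met].to_numpy())
                sig = np.isfinite(p) and p < cutoff
                per_pair.setdefault((sp, met), []).append((sig, rho))
    confirmed = set()
    support: dict[tuple[str, str], int] = {}
    n_groups = len(used)
    for pair, results in per_pair.items():
        sigs = [s for s, _ in results]
        rhos = [r for _, r in results]
        signs = {np.sign(r) for s, r in results if s and np.isfinite(r)}
        consistent_sign = (
            len({np.sign(r) for r in rhos if np.isfinite(r) and r != 0}) <= 1
        )
        support[pair] = sum(sigs) if consistent_sign else 0
        if all(sigs) and len(signs) == 1 and consistent_sign:
            confirmed.add(pair)
    return {
        "confirmed": confirmed,
        "support": support,
        "n_subgroups": n_groups,
        "excluded_subgroups": excluded,
    }


@dataclass
class EnvironmentBinEntry:
    """One metabolite-in-one-dataset instance for environmental binning."""

    profile: ContributionProfile
    outcomes: list[PairOutcome]
    in_inflow: bool
    baseline: bool = False  # part of the constant-inflow reference dataset


def environment_bins(
    entries: list[EnvironmentBinEntry],
    bin_width: float = 0.10,
    n_bootstrap: int = 0,
) -> dict[str, MetricsReport]:
    """Classification metrics stratified by environmental contribution share.

    The share is max(c_env, 0) over the summed positive contributions.
    Instances from the constant-inflow reference dataset form the
    ``constant`` category and inflow-absent metabolites the ``no_inflow``
    category; the rest fall into half-open share bins ((0-10%], (10-20%], ...
    by default), with share <= 0 in a ``0`` bin.
    """
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must be in (0, 1]")
    binned: dict[str, list[PairOutcome]] = {}
    for entry in entries:
        if entry.baseline:
            label = "constant"
        elif not entry.in_inflow:
            label = "no_inflow"
        else:
            prof = entry.profile
            pos_total = float(np.sum(prof.c[prof.c > 0]))
            if prof.c_env > 0:
                pos_total += prof.c_env
            share = max(prof.c_env, 0.0) / pos_total if pos_total > 0 else 0.0
            if share <= 0:
                label = "0"
            else:
                hi = min(math.ceil(share / bin_width - 1e-12), round(1 / bin_width))
                label = f"({(hi - 1) * bin_width:.0%}-{hi * bin_width:.0%}]"
        binned.setdefault(label, []).extend(entry.outcomes)
    return {
        label: confusion_metrics(outs, n_bootstrap=n_bootstrap)
        for label, outs in binned.items()
    }
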