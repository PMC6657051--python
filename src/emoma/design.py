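"""Brute-force strain-design scan ranking single-reaction interventions.

Every internal, gene-associated reaction is a candidate for knockout or
(if it carries reference flux) overexpression.  Each mutant is pushed
through the same three-stage procedure as the wild type, with the mutant
constraint

    v_target = k * v_target_ref   (overexpression, default k = 2)
    v_target = 0                  (knockout)

imposed on the FBA and pFBA stages.  For overexpression the constraint is
deliberately *not* applied to the MOMA stage: the mutant's own pFBA
solution becomes the MOMA anchor and the nutrient-limited cell may adjust
the target flux within its original bounds.  Knockouts stay fixed at zero
throughout — a deleted gene is absent in both states.

Candidates whose intervention drops the (non-limited) growth rate below
90% of the wild type are excluded: fast growth during the replete phase is
a prerequisite for high lipid productivity.  When a twofold overexpression
is infeasible or growth-inadmissible, the fold is relaxed down a 0.1-step
grid to 1.1 and the largest admissible value is used; reactions failing at
1.1 are dropped.  Orphan (no gene rule), exchange, demand and biomass
reactions cannot be engineered and never enter the pool.

Mutants are ranked by predicted lipid yield improvement: TAG demand flux
per substrate uptake in the nutrient-limited state, relative to the wild
type (a ``rank_by="rate"`` switch ranks by raw TAG flux instead, since
substrate uptake can differ between mutants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .limitation import LimitationResult, LimitationSpec, simulate_limitation
from .model import MetabolicModel
from .solvers import (
    OPTIMAL,
    ReferenceState,
    SolverSettings,
    StageError,
    solve_fba,
    solve_pfba,
)

logger = logging.getLogger("emoma")

STATUS_OK = "ok"
STATUS_EXCLUDED_GROWTH = "excluded_growth"
STATUS_EXCLUDED_ZERO_REF = "excluded_zero_ref_flux"
STATUS_INFEASIBLE = "infeasible"


@dataclass(frozen=True)
class MutationSpec:
    """A single-reaction intervention: knockout, or overexpression at fold k."""

    target_reaction_id: str
    kind: str  # "overexpression" | "knockout"
    fold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("overexpression", "knockout"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "knockout" and self.fold is not None:
            raise ValueError("knockout takes no fold")
        if self.kind == "overexpression" and self.fold is not None and self.fold < 1.0:
            raise ValueError("overexpression fold must be >= 1")


@dataclass
class ScanConfig:
    growth_threshold: float = 0.9
    fold_default: float = 2.0
    fold_min: float = 1.1
    fold_step: float = 0.1
    min_improvement_pct: float = 10.0
    substrate_exchange_id: str = "EX_glc"
    tag_demand_id: str = "DM_tag"
    rank_by: str = "yield"  # "yield" | "rate"
    oe_constraint: str = "eq"  # "eq" | "ge"

    def __post_init__(self) -> None:
        if not (0.0 < self.growth_threshold <= 1.0):
            raise ValueError("growth_threshold must be in (0, 1]")
        if self.rank_by not in ("yield", "rate"):
            raise ValueError("rank_by must be 'yield' or 'rate'")

    @property
    def fold_grid(self) -> list[float]:
        """Descending fold grid from the default down to the minimum."""
        n = int(round((self.fold_default - self.fold_min) / self.fold_step)) + 1
        return [round(self.fold_default - i * self.fold_step, 10) for i in range(n)]


@dataclass
class DesignResult:
    mutation: MutationSpec
    status: str
    mu_ratio: float = np.nan
    wt_yield: float = np.nan
    mut_yield: float = np.nan
    improvement_pct: float = np.nan
    mut_tag_flux: float = np.nan
    wt_tag_flux: float = np.nan
    above_cutoff: bool = False
    limited: object = None  # FluxVector of the mutant limited state, when solved


@dataclass
class CandidateSet:
    mutations: list[MutationSpec]
    exclusions: list[tuple[str, str, str]]  # (reaction_id, kind, reason)

    def __iter__(self):
        return iter(self.mutations)

    def __len__(self):
        return len(self.mutations)


def _engineerable(model: MetabolicModel) -> list:
    """Reactions addressable by genetic engineering: internal with a gene rule."""
    pool = []
    for rxn in model.reactions:
        if rxn.kind in ("exchange", "demand", "biomass"):
            continue
        if rxn.is_orphan:
            continue
        pool.append(rxn)
    return pool


def _mutation_overrides(
    model: MetabolicModel,
    wt_reference: ReferenceState,
    mutation: MutationSpec,
    config: ScanConfig,
) -> dict[str, tuple[float, float]]:
    rid = mutation.target_reaction_id
    if mutation.kind == "knockout":
        return {rid: (0.0, 0.0)}
    fold = mutation.fold if mutation.fold is not None else config.fold_default
    target = fold * wt_reference.v_ref[rid]
    if config.oe_constraint == "ge":
        rxn = model.reaction(rid)
        if target >= 0:
            return {rid: (target, max(rxn.upper_bound, target))}
        return {rid: (min(rxn.lower_bound, target), target)}
    return {rid: (target, target)}


def enumerate_candidates(
    model: MetabolicModel,
    wt_reference: ReferenceState,
    config: ScanConfig | None = None,
    settings: SolverSettings | None = None,
) -> CandidateSet:
    """Select the knockout and overexpression candidates for the scan.

    Knockouts must retain at least ``growth_threshold`` of wild-type growth
    under FBA with the flux fixed to zero; overexpressions additionally
    require nonzero reference flux, and the fold is the largest grid value
    keeping growth admissible.  Exclusions are recorded with reasons, never
    raised.
    """
    config = config or ScanConfig()
    settings = settings or SolverSettings()
    mu_wt = wt_reference.f_opt
    floor = config.growth_threshold * mu_wt
    mutations: list[MutationSpec] = []
    exclusions: list[tuple[str, str, str]] = []
    for rxn in model.reactions:
        if rxn.kind in ("exchange", "demand", "biomass") or rxn.is_orphan:
            reason = "orphan (no gene rule)" if rxn.is_orphan and rxn.kind not in (
                "exchange", "demand", "biomass") else f"kind={rxn.kind}"
            exclusions.append((rxn.id, "both", reason))
            continue
        # knockout screen
        ko = solve_fba(model, settings, bound_overrides={rxn.id: (0.0, 0.0)})
        if ko.status == OPTIMAL and ko.f_opt >= floor - settings.validation_tol:
            mutations.append(MutationSpec(rxn.id, "knockout"))
        else:
            exclusions.append((rxn.id, "knockout",
                               "infeasible" if ko.status != OPTIMAL
                               else f"growth {ko.f_opt:.4g} < {floor:.4g}"))
        # overexpression screen
        v_ref = wt_reference.v_ref[rxn.id]
        if abs(v_ref) <= settings.validation_tol:
            exclusions.append((rxn.id, "overexpression", "zero reference flux"))
            continue
        chosen = None
        for fold in config.fold_grid:
            spec = MutationSpec(rxn.id, "overexpression", fold)
            ov = _mutation_overrides(model, wt_reference, spec, config)
            oe = solve_fba(model, settings, bound_overrides=ov)
            if oe.status == OPTIMAL and oe.f_opt >= floor - settings.validation_tol:
                chosen = spec
                break
        if chosen is not None:
            mutations.append(chosen)
        else:
            exclusions.append((rxn.id, "overexpression",
                               f"no admissible fold in [{config.fold_min}, "
                               f"{config.fold_default}]"))
    return CandidateSet(mutations, exclusions)


def _limited_yield(
    limited, config: ScanConfig, model: MetabolicModel
) -> tuple[float, float]:
    """(tag_flux, yield) from a limited-state flux vector."""
    tag = limited[config.tag_demand_id]
    sub_rxn = model.reaction(config.substrate_exchange_id)
    uptake = sub_rxn.import_sign() * limited[config.substrate_exchange_id]
    if uptake <= 0:
        return tag, np.nan
    return tag, tag / uptake


def simulate_mutant(
    model: MetabolicModel,
    wt_reference: ReferenceState,
    mutation: MutationSpec,
    limitation: LimitationSpec,
    config: ScanConfig | None = None,
    settings: SolverSettings | None = None,
    wt_result: LimitationResult | None = None,
) -> DesignResult:
    """Run the three-stage procedure for one mutant and score it.

    The mutant constraint applies to the FBA and pFBA stages; the MOMA
    stage keeps knockouts at zero but frees an overexpressed target within
    its original bounds, anchored to the mutant's own pFBA reference.
    Infeasibility is reported in the result status, not raised.
    """
    config = config or ScanConfig()
    settings = settings or SolverSettings()
    if wt_result is None:
        wt_result = simulate_limitation(
            model, limitation, settings, reference=wt_reference
        )
    wt_tag, wt_yield = _limited_yield(wt_result.limited, config, model)

    overrides = _mutation_overrides(model, wt_reference, mutation, config)
    fba = solve_fba(model, settings, bound_overrides=overrides)
    if fba.status != OPTIMAL:
        return DesignResult(mutation, STATUS_INFEASIBLE,
                            wt_yield=wt_yield, wt_tag_flux=wt_tag)
    mu_ratio = fba.f_opt / wt_reference.f_opt if wt_reference.f_opt else np.inf
    mut_ref = solve_pfba(model, fba.f_opt, settings, bound_overrides=overrides)
    if mut_ref.status != OPTIMAL:
        return DesignResult(mutation, STATUS_INFEASIBLE, mu_ratio=mu_ratio,
                            wt_yield=wt_yield, wt_tag_flux=wt_tag)
    stage3_overrides = overrides if mutation.kind == "knockout" else {}
    try:
        mut_result = simulate_limitation(
            model, limitation, settings,
            extra_overrides=stage3_overrides, reference=mut_ref,
        )
    except StageError:
        return DesignResult(mutation, STATUS_INFEASIBLE, mu_ratio=mu_ratio,
                            wt_yield=wt_yield, wt_tag_flux=wt_tag)
    mut_tag, mut_yield = _limited_yield(mut_result.limited, config, model)
    wt_score = wt_yield if config.rank_by == "yield" else wt_tag
    mut_score = mut_yield if config.rank_by == "yield" else mut_tag
    improvement = (
        100.0 * (mut_score - wt_score) / wt_score if wt_score and wt_score > 0
        else np.nan
    )
    status = (
        STATUS_OK
        if mu_ratio >= config.growth_threshold - settings.validation_tol
        else STATUS_EXCLUDED_GROWTH
    )
    return DesignResult(
        mutation=mutation,
        status=status,
        mu_ratio=float(mu_ratio),
        wt_yield=wt_yield,
        mut_yield=mut_yield,
        improvement_pct=improvement,
        mut_tag_flux=mut_tag,
        wt_tag_flux=wt_tag,
        above_cutoff=bool(improvement >= config.min_improvement_pct)
        if np.isfinite(improvement) else False,
        limited=mut_result.limited,
    )


def design_scan(
    model: MetabolicModel,
    limitation: LimitationSpec,
    config: ScanConfig | None = None,
    settings: SolverSettings | None = None,
) -> list[DesignResult]:
    """Enumerate candidates, simulate every mutant, rank by improvement.

    Candidates are independent and scored by pure per-candidate
    computation, so any execution order yields identical results.  Results
    below the reporting cutoff are retained but flagged.
    """
    config = config or ScanConfig()
    settings = settings or SolverSettings()
    fba = solve_fba(model, settings)
    if fba.status != OPTIMAL:
        raise StageError("fba", fba.status)
    wt_reference = solve_pfba(model, fba.f_opt, settings)
    if wt_reference.status != OPTIMAL:
        raise StageError("pfba", wt_reference.status)
    wt_result = simulate_limitation(model, limitation, settings,
                                    reference=wt_reference)
    candidates = enumerate_candidates(model, wt_reference, config, settings)
    results = [
        simulate_mutant(model, wt_reference, mut, limitation, config, settings,
                        wt_result=wt_result)
        for mut in candidates
    ]
    results.sort(key=lambda r: (
        -(r.improvement_pct if np.isfinite(r.improvement_pct) else -np.inf),
        r.mutation.target_reaction_id,
    ))
    return results


def results_to_frame(results: list[DesignResult], model: MetabolicModel) -> pd.DataFrame:
    """Tabulate scan results in the shape of a published target table."""
    columns = ["reaction_id", "name", "gene_rule", "kind", "fold", "mu_ratio",
               "mut_tag_flux", "mut_yield", "improvement_pct", "status",
               "above_cutoff"]
    rows = []
    for r in results:
        rxn = model.reaction(r.mutation.target_reaction_id)
        rows.append({
            "reaction_id": rxn.id,
            "name": rxn.name,
            "gene_rule": rxn.gene_rule or "",
            "kind": r.mutation.kind,
            "fold": r.mutation.fold if r.mutation.fold is not None else "",
            "mu_ratio": r.mu_ratio,
            "mut_tag_flux": r.mut_tag_flux,
            "mut_yield": r.mut_yield,
            "improvement_pct": r.improvement_pct,
            "status": r.status,
            "above_cutoff": r.above_cutoff,
        })
    return pd.DataFrame(rows, columns=columns)
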