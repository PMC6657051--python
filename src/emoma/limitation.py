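"""Three-stage simulation of nutrient-limited metabolism, plus reporting.

The procedure predicts the flux distribution of a cell that suddenly loses
access to an essential nutrient (nitrogen or phosphate in oleaginous
yeasts) and therefore stops growing but keeps metabolising:

1. FBA on the non-limited model gives the maximum growth rate f_opt.
2. pFBA at f_opt gives a parsimonious reference flux distribution v_ref,
   the cell's established metabolic state.
3. The limiting nutrient's uptake is blocked and the MOMA QP finds the
   feasible flux vector closest to v_ref — the minimal metabolic
   readjustment to the new environment.

Growth-associated maintenance needs no special handling: it rides in the
biomass equation and vanishes with growth.  Non-growth maintenance (an ATP
hydrolysis reaction with a fixed lower bound) stays active in both states.

Reporting helpers turn the result into an exchange-flux table, a carbon
partition (what fraction of consumed carbon ends up in each secreted or
accumulated product) and a comparison against externally measured fluxes
(e.g. a 13C-MFA table), all normalised per glucose uptake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import MetabolicModel, ModelError, carbon_count
from .solvers import (
    FluxVector,
    OPTIMAL,
    ReferenceState,
    SolverSettings,
    StageError,
    emoma_distance,
    solve_emoma,
    solve_fba,
    solve_pfba,
)


@dataclass
class LimitationSpec:
    """Which exchange to block and how.

    ``block_uptake`` zeroes only the import direction of the exchange so
    secretion of the same species stays possible (nitrogen-containing
    compounds are secreted under phosphate limitation, so secretion
    channels must stay open in general); ``block_both`` fixes the flux to
    zero for sensitivity checks.
    """

    blocked_exchange_id: str
    mode: str = "block_uptake"

    def __post_init__(self) -> None:
        if self.mode not in ("block_uptake", "block_both"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class LimitationResult:
    reference: ReferenceState
    limited: FluxVector
    mu_max: float
    distance: float
    limitation: LimitationSpec


def blocked_bounds(
    model: MetabolicModel, spec: LimitationSpec
) -> dict[str, tuple[float, float]]:
    """Bound override implementing the nutrient blockage.

    The import direction of an exchange is the flux direction that moves
    the metabolite into the system; it depends on how the exchange is
    written (see :mod:`emoma.model`), so the blockage is computed from the
    stoichiometric sign rather than assuming a fixed orientation.
    """
    rxn = model.reaction(spec.blocked_exchange_id)
    if rxn.kind != "exchange":
        raise ModelError(
            f"blocked reaction {rxn.id!r} has kind {rxn.kind!r}, not exchange"
        )
    if spec.mode == "block_both":
        return {rxn.id: (0.0, 0.0)}
    if rxn.import_sign() > 0:
        return {rxn.id: (min(rxn.lower_bound, 0.0), 0.0)}
    return {rxn.id: (0.0, max(rxn.upper_bound, 0.0))}


def simulate_limitation(
    model: MetabolicModel,
    limitation: LimitationSpec,
    settings: SolverSettings | None = None,
    extra_overrides: Mapping[str, tuple[float, float]] | None = None,
    reference: ReferenceState | None = None,
) -> LimitationResult:
    """Run FBA -> pFBA -> blocked-uptake MOMA and return all three artifacts.

    ``extra_overrides`` (e.g. mutant constraints) apply to every stage; a
    precomputed ``reference`` skips stages 1-2.  Infeasibility at any stage
    raises :class:`StageError` naming the stage.
    """
    settings = settings or SolverSettings()
    extra = dict(extra_overrides or {})
    if reference is None:
        fba = solve_fba(model, settings, bound_overrides=extra or None)
        if fba.status != OPTIMAL:
            raise StageError("fba", fba.status)
        reference = solve_pfba(model, fba.f_opt, settings, bound_overrides=extra or None)
        if reference.status != OPTIMAL:
            raise StageError("pfba", reference.status)
    overrides = dict(extra)
    overrides.update(blocked_bounds(model, limitation))
    limited = solve_emoma(model, reference, settings, bound_overrides=overrides)
    if limited.status != OPTIMAL:
        raise StageError("emoma", limited.status)
    return LimitationResult(
        reference=reference,
        limited=limited,
        mu_max=reference.f_opt,
        distance=emoma_distance(limited, reference),
        limitation=limitation,
    )


def exchange_profile(
    result: LimitationResult,
    model: MetabolicModel,
    report_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Exchange/demand fluxes in the reference vs limited state.

    Rows are kept when either condition carries |flux| above the threshold
    and are ordered by |limited flux| descending (ties by reaction id).
    """
    rows = []
    for rxn in model.boundary_reactions():
        ref = result.reference.v_ref[rxn.id]
        lim = result.limited[rxn.id]
        if max(abs(ref), abs(lim)) > report_threshold:
            met, _ = rxn.boundary_metabolite()
            rows.append((rxn.id, met, ref, lim))
    frame = pd.DataFrame(
        rows, columns=["reaction_id", "metabolite_id", "reference_flux", "limited_flux"]
    )
    if len(frame):
        frame = frame.sort_values(
            by=["limited_flux", "reaction_id"],
            key=lambda s: -s.abs() if s.name == "limited_flux" else s,
        ).reset_index(drop=True)
    return frame


def carbon_partition(
    result: LimitationResult,
    model: MetabolicModel,
    flux_tol: float = 1e-6,
) -> pd.DataFrame:
    """Fraction of consumed carbon routed into each secreted/accumulated product.

    Substrates are all exchanges importing carbon in the limited state; the
    denominator is the total consumed carbon flux (mmol C/gDCW/h).  Each
    exporting exchange or demand contributes
    ``n_C(product) * |v| / total * 100`` percent.  A flux-carrying boundary
    metabolite without a parsable formula is an error (never a silent
    zero-carbon assumption).
    """
    missing: list[str] = []
    consumed = 0.0
    products: list[tuple[str, str, float]] = []
    for rxn in model.boundary_reactions():
        v = result.limited[rxn.id]
        if abs(v) <= flux_tol:
            continue
        met_id, coef = rxn.boundary_metabolite()
        met = model.metabolite(met_id)
        if met.formula is None:
            missing.append(met_id)
            continue
        n_c = carbon_count(met.formula)
        direction = coef * v  # >0: metabolite enters the system
        if direction > 0 and rxn.kind == "exchange":
            consumed += n_c * abs(v)
        elif direction < 0:
            products.append((rxn.id, met_id, n_c * abs(v)))
    if missing:
        raise ModelError(
            "metabolites with flux-carrying boundary reactions lack formulas: "
            + ", ".join(sorted(missing))
        )
    if consumed <= 0:
        raise ModelError("no carbon consumed in the limited state")
    rows = [
        (rid, met, 100.0 * cflux / consumed)
        for rid, met, cflux in products
        if cflux > 0
    ]
    frame = pd.DataFrame(rows, columns=["reaction_id", "metabolite_id", "carbon_pct"])
    return frame.sort_values("carbon_pct", ascending=False).reset_index(drop=True)


def compare_fluxes(
    predicted: FluxVector,
    measured: pd.DataFrame,
    normalization_id: str,
    mapping: pd.DataFrame | None = None,
) -> dict:
    """Compare predicted fluxes against an external measured-flux table.

    ``measured`` has columns (reaction_id, flux).  Both sets are scaled so
    the normalisation reaction (typically glucose uptake) has |flux| = 1;
    the comparison runs over the id intersection.  An optional ``mapping``
    table (predicted_id, measured_id[, sign]) aligns differing namespaces
    and sign conventions.  Returns the paired table, Pearson r and
    per-reaction residuals.
    """
    if measured.empty:
        raise ValueError("measured flux table is empty")
    meas = dict(zip(measured.iloc[:, 0], measured.iloc[:, 1].astype(float)))
    pred = predicted.as_dict()
    pairs: list[tuple[str, float, float]] = []
    if mapping is not None:
        signs = (
            mapping.iloc[:, 2].astype(float)
            if mapping.shape[1] > 2
            else pd.Series(1.0, index=mapping.index)
        )
        for (pid, mid), sign in zip(
            zip(mapping.iloc[:, 0], mapping.iloc[:, 1]), signs
        ):
            if pid in pred and mid in meas:
                pairs.append((pid, pred[pid], sign * meas[mid]))
    else:
        for rid in predicted.reaction_ids:
            if rid in meas:
                pairs.append((rid, pred[rid], meas[rid]))
    if not pairs:
        raise ValueError("no overlapping reaction ids between predicted and measured")
    p_norm = abs(pred.get(normalization_id, 0.0))
    m_norm = abs(meas.get(normalization_id, np.nan))
    if not np.isfinite(m_norm):
        # normalisation reaction may be absent from the measured table when a
        # mapping is used; fall back to its mapped pair
        for rid, p, m in pairs:
            if rid == normalization_id:
                m_norm = abs(m)
                break
    if p_norm == 0 or not np.isfinite(m_norm) or m_norm == 0:
        raise ValueError(
            f"normalisation reaction {normalization_id!r} carries zero or missing flux"
        )
    table = pd.DataFrame(pairs, columns=["reaction_id", "predicted", "measured"])
    table["predicted"] /= p_norm
    table["measured"] /= m_norm
    table["residual"] = table["predicted"] - table["measured"]
    if len(table) >= 2:
        r, pval = stats.pearsonr(table["predicted"], table["measured"])
    else:
        r, pval = np.nan, np.nan
    return {"table": table, "pearson_r": float(r), "p_value": float(pval), "n": len(table)}
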