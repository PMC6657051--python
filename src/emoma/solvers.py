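"""The three optimization kernels: FBA, pFBA and the MOMA-style QP.

Flux balance analysis (FBA) maximises an objective ``c . v`` (the biomass
flux, i.e. the specific growth rate) over the steady-state flux cone
``{v : S v = 0, a <= v <= b}``.  The optimum value f_opt is unique but the
optimal vertex generally is not.

Parsimonious FBA (pFBA) resolves that degeneracy by a second linear
program: among all flux vectors achieving ``c . v = f_opt`` it selects one
with minimal total absolute flux sum_i |v_i|, the "optimal enzyme usage"
proxy.  Implemented by splitting each flux into non-negative forward and
reverse parts and minimising their sum.  The L1-minimal vector may itself
be non-unique; deterministic solver settings (single thread, fixed variable
order) plus the reported ``l1_norm`` make alternative optima detectable.

The environmental-MOMA step is a strictly convex quadratic program: given a
reference flux distribution v_ref (from pFBA on the unperturbed model) and
a model that already carries the perturbation (a blocked nutrient uptake
and/or mutant constraints), find the unique feasible v minimising the
Euclidean distance ||v - v_ref||.  The distance runs over all reactions,
exchanges included.  Minimising the distance and its square have the same
argmin; the square is what the QP solver sees.

LP stages run on scipy's HiGHS interface; the QP runs on OSQP with
polishing enabled, followed by an independent post-solve feasibility check
(mass balance and bounds to 1e-6) that does not trust the solver report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
NUMERIC_FAILURE = "numeric_failure"


@dataclass
class SolverSettings:
    """Tolerances and backend knobs shared by all three kernels.

    feas_tol / opt_tol are handed to the solvers; post-solve validation uses
    the looser ``validation_tol`` because genome-scale stoichiometries carry
    coefficients spanning several orders of magnitude.
    """

    feas_tol: float = 1e-9
    opt_tol: float = 1e-9
    qp_tol: float = 1e-8
    validation_tol: float = 1e-6
    backend: str = "highs+osqp"
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.feas_tol <= 0 or self.opt_tol <= 0 or self.qp_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FluxVector:
    """One steady-state flux assignment, indexed by model reaction order."""

    values: np.ndarray
    reaction_ids: list[str]
    status: str

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.values[self.reaction_ids.index(reaction_id)])

    def as_dict(self) -> dict[str, float]:
        return {rid: float(v) for rid, v in zip(self.reaction_ids, self.values)}

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values, index=self.reaction_ids, name="flux")


@dataclass
class FbaResult:
    f_opt: float | None
    flux: FluxVector

    @property
    def status(self) -> str:
        return self.flux.status


@dataclass
class ReferenceState:
    """The pFBA flux vector anchoring the MOMA distance."""

    v_ref: FluxVector
    f_opt: float
    l1_norm: float

    @property
    def status(self) -> str:
        return self.v_ref.status


class StageError(RuntimeError):
    """Raised when a pipeline stage cannot produce an optimal solution."""

    def __init__(self, stage: str, status: str):
        super().__init__(f"stage {stage!r} failed with status {status!r}")
        self.stage = stage
        self.status = status


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_LP_STATUS = {0: OPTIMAL, 1: NUMERIC_FAILURE, 2: INFEASIBLE, 3: UNBOUNDED, 4: NUMERIC_FAILURE}


def _with_overrides(
    model: MetabolicModel, overrides: Mapping[str, tuple[float, float]] | None
) -> tuple[sparse.csc_matrix, np.ndarray, np.ndarray, np.ndarray]:
    """(S, a, b, c) with per-reaction bound overrides applied."""
    S = model.S
    a, b, c = model.a, model.b, model.c
    if overrides:
        for rid, (lb, ub) in overrides.items():
            j = model.reaction_index(rid)
            a[j], b[j] = lb, ub
    return S, a, b, c


def validate_flux(S: sparse.spmatrix, a, b, v, tol: float) -> None:
    """Independent post-solve check: mass balance and bounds within tol."""
    imbalance = np.abs(S @ v).max() if S.shape[0] else 0.0
    if imbalance > tol:
        raise FloatingPointError(f"mass-balance violation {imbalance:.3e} > {tol}")
    if (v < a - tol).any() or (v > b + tol).any():
        raise FloatingPointError("bound violation beyond tolerance")


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def solve_fba(
    model: MetabolicModel,
    settings: SolverSettings | None = None,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FbaResult:
    """Maximise the objective flux over the steady-state cone.

    Returns the optimum value f_opt and one optimal vertex (no uniqueness
    claim is made for the vertex).  ``bound_overrides`` maps reaction id to
    (lb, ub) and is how perturbations and mutant constraints enter.
    """
    settings = settings or SolverSettings()
    S, a, b, c = _with_overrides(model, bound_overrides)
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(a, b)),
        method="highs",
        options={"presolve": True, "primal_feasibility_tolerance": settings.feas_tol,
                 "dual_feasibility_tolerance": settings.opt_tol},
    )
    status = _LP_STATUS.get(res.status, NUMERIC_FAILURE)
    rids = model.reaction_ids
    if status != OPTIMAL:
        return FbaResult(None, FluxVector(np.full(len(rids), np.nan), rids, status))
    v = np.asarray(res.x, dtype=float)
    validate_flux(S, a, b, v, settings.validation_tol)
    return FbaResult(float(c @ v), FluxVector(v, rids, OPTIMAL))


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def solve_pfba(
    model: MetabolicModel,
    f_opt: float,
    settings: SolverSettings | None = None,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> ReferenceState:
    """Minimise sum_i |v_i| subject to S v = 0, a <= v <= b, c . v = f_opt.

    The growth constraint is imposed as an exact equality; pass the f_opt
    obtained from :func:`solve_fba` on the same (overridden) model.  A
    ``relax_fraction`` is deliberately not defaulted on; numerically fragile
    models can rescale f_opt themselves before calling.
    """
    settings = settings or SolverSettings()
    S, a, b, c = _with_overrides(model, bound_overrides)
    n = len(a)
    # Split v = p - q with p, q >= 0; bounds chosen so p - q spans exactly [a, b].
    p_lo, p_hi = np.maximum(a, 0.0), np.maximum(b, 0.0)
    q_lo, q_hi = np.maximum(-b, 0.0), np.maximum(-a, 0.0)
    A_eq = sparse.vstack([
        sparse.hstack([S, -S]),
        sparse.hstack([sparse.csr_matrix(c), sparse.csr_matrix(-c)]),
    ], format="csc")
    b_eq = np.concatenate([np.zeros(S.shape[0]), [f_opt]])
    res = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(np.concatenate([p_lo, q_lo]), np.concatenate([p_hi, q_hi]))),
        method="highs",
        options={"presolve": True, "primal_feasibility_tolerance": settings.feas_tol,
                 "dual_feasibility_tolerance": settings.opt_tol},
    )
    status = _LP_STATUS.get(res.status, NUMERIC_FAILURE)
    rids = model.reaction_ids
    if status != OPTIMAL:
        return ReferenceState(
            FluxVector(np.full(n, np.nan), rids, status), f_opt, np.nan
        )
    x = np.asarray(res.x, dtype=float)
    v = x[:n] - x[n:]
    validate_flux(S, a, b, v, settings.validation_tol)
    if abs(float(c @ v) - f_opt) > settings.validation_tol:
        return ReferenceState(FluxVector(v, rids, NUMERIC_FAILURE), f_opt, np.nan)
    return ReferenceState(
        FluxVector(v, rids, OPTIMAL), f_opt, float(np.abs(v).sum())
    )


# ---------------------------------------------------------------------------
# eMOMA QP
# ---------------------------------------------------------------------------

def solve_emoma(
    model: MetabolicModel,
    reference: ReferenceState,
    settings: SolverSettings | None = None,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    extra_equalities: Sequence[tuple[Mapping[str, float], float]] | None = None,
) -> FluxVector:
    """Minimise ||v - v_ref||^2 over the (perturbed) steady-state cone.

    The model (with ``bound_overrides``) must already carry the
    perturbation; the reference comes from pFBA on the unperturbed model.
    ``extra_equalities`` adds rows ``sum_j coef_j v_j = rhs`` — equivalent
    to bound fixing for single reactions, exposed so the equivalence can be
    exercised.  Strict convexity makes the minimiser unique, so the result
    is invariant to reaction ordering up to solver tolerance.
    """
    import osqp

    settings = settings or SolverSettings()
    S, a, b, _ = _with_overrides(model, bound_overrides)
    n = len(a)
    r = np.asarray(reference.v_ref.values, dtype=float)
    if r.shape != (n,):
        raise ValueError("reference length does not match model")
    rows = [S]
    eq_rhs = [np.zeros(S.shape[0])]
    if extra_equalities:
        extra = sparse.lil_matrix((len(extra_equalities), n))
        rhs = np.zeros(len(extra_equalities))
        for i, (coefs, val) in enumerate(extra_equalities):
            for rid, coef in coefs.items():
                extra[i, model.reaction_index(rid)] = coef
            rhs[i] = val
        rows.append(extra.tocsr())
        eq_rhs.append(rhs)
    A_eq = sparse.vstack(rows, format="csc")
    A = sparse.vstack([A_eq, sparse.identity(n)], format="csc")
    l = np.concatenate([np.concatenate(eq_rhs), a])
    u = np.concatenate([np.concatenate(eq_rhs), b])
    prob = osqp.OSQP()
    prob.setup(
        P=sparse.identity(n, format="csc") * 2.0,
        q=-2.0 * r,
        A=A, l=l, u=u,
        verbose=False,
        polishing=True,
        eps_abs=settings.qp_tol * 1e-2,
        eps_rel=settings.qp_tol * 1e-2,
        eps_prim_inf=settings.qp_tol,
        eps_dual_inf=settings.qp_tol,
        max_iter=200_000,
        scaled_termination=False,
    )
    res = prob.solve(raise_error=False)
    status = str(res.info.status).lower()
    rids = model.reaction_ids
    if "infeasible" in status:
        return FluxVector(np.full(n, np.nan), rids, INFEASIBLE)
    if "solved" not in status:
        return FluxVector(np.full(n, np.nan), rids, NUMERIC_FAILURE)
    v = np.asarray(res.x, dtype=float)
    # clip roundoff-level bound violations before independent validation
    v = np.clip(v, a - settings.validation_tol, b + settings.validation_tol)
    residual = np.abs(A_eq @ v - np.concatenate(eq_rhs))
    if (residual.size and residual.max() > settings.validation_tol) or (
        (v < a - settings.validation_tol).any()
        or (v > b + settings.validation_tol).any()
    ):
        return FluxVector(v, rids, NUMERIC_FAILURE)
    return FluxVector(v, rids, OPTIMAL)


def emoma_distance(v: FluxVector, reference: ReferenceState) -> float:
    """Euclidean distance ||v - v_ref|| between a solution and its anchor."""
    return float(np.linalg.norm(v.values - reference.v_ref.values))
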