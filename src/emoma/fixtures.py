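"""Deterministic toy metabolic networks used as closed-form oracles.

Four fixtures are provided, all desk-scale and solvable by hand or by
elementary vertex enumeration:

``TOY-A``
    Two nutrients (a carbon source and ammonium), a biomass reaction
    consuming one of each, and a TAG demand sink draining carbon.  Growth
    is capped at 10 by either uptake; under a nitrogen blockage the
    MOMA solution splits the carbon deviation evenly between reduced
    uptake and the TAG sink: (EX_glc, DM_tag) = (5, 5).

``TOY-B``
    TOY-A plus a citrate-like secretion route for carbon.  The blocked-
    nitrogen optimum spreads the deviation over two sinks:
    EX_glc = 20/3, DM_tag = EX_cit = 10/3.

``TOY-C``
    A linear pathway with a side demand, used for the overexpression
    fold-adjustment logic: a twofold flux increase through R1 exceeds the
    substrate uptake capacity (12 vs 10*k), so the largest admissible fold
    is 1.2.

``TOY-Y``
    A ~25-reaction oleaginous-yeast caricature: glycolysis, a TCA-like
    loop, a citrate node with both an export route and an ATP-citrate-lyase
    route feeding acetyl units into TAG synthesis, an NGAM-style ATP drain
    with a fixed lower bound, a biomass equation consuming carbon, nitrogen
    (as glutamate), phosphate and ATP, a glutamate synthesis/degradation
    pair forming a futile nitrogen cycle that burns ATP and NADH (its
    synthesis leg feeds biomass, so it carries reference flux), a glycogen
    storage cycle with zero reference flux, and a sterol-degradation
    reaction whose substrate is never produced — structurally blocked in
    every state, so its knockout is a strict no-op (the fate of
    lipid-degradation targets under a parsimonious reference).

Toy exchanges are written source-style (``(nothing) -> met``) so uptake
fluxes are positive, matching the hand derivations; the pipeline blocks
uptake by zeroing the import direction, which is orientation-agnostic.

Stoichiometric coefficients are fixed integers so every downstream scan
output is regression-testable; generation is deterministic given the
parameters.
"""

from __future__ import annotations

from .model import DEFAULT_BOUND, Metabolite, MetabolicModel, Reaction

FIXTURE_NAMES = ("TOY-A", "TOY-B", "TOY-C", "TOY-Y")


def _met(mid: str, formula: str | None) -> Metabolite:
    return Metabolite(id=mid, name=mid, formula=formula)


def _rxn(rid, stoich, lb=0.0, ub=DEFAULT_BOUND, kind="internal", gene=None):
    return Reaction(
        id=rid, name=rid, stoichiometry=stoich,
        lower_bound=lb, upper_bound=ub, kind=kind, gene_rule=gene,
    )


def _toy_a(uptake_cap: float = 10.0) -> MetabolicModel:
    m = MetabolicModel(id="TOY-A")
    m.metabolites = [_met("C", "C1"), _met("N", "N1"), _met("TAG", "C1")]
    m.reactions = [
        _rxn("EX_glc", {"C": 1.0}, 0.0, uptake_cap, kind="exchange"),
        _rxn("EX_nh4", {"N": 1.0}, 0.0, uptake_cap, kind="exchange"),
        _rxn("GROWTH", {"C": -1.0, "N": -1.0}, kind="biomass", gene="g_growth"),
        _rxn("DM_tag", {"C": -1.0}, kind="demand"),
    ]
    m.validate()
    return m


def _toy_b(uptake_cap: float = 10.0) -> MetabolicModel:
    m = _toy_a(uptake_cap)
    m.id = "TOY-B"
    m.reactions.append(_rxn("EX_cit", {"C": -1.0}, kind="exchange"))
    m.validate()
    return m


def _toy_c(s_cap: float = 12.0, q_cap: float = 10.0) -> MetabolicModel:
    m = MetabolicModel(id="TOY-C")
    m.metabolites = [_met("M", "C1"), _met("P", "C1"), _met("Q", "C1")]
    m.reactions = [
        _rxn("EX_s", {"M": 1.0}, 0.0, s_cap, kind="exchange"),
        _rxn("R1", {"M": -1.0, "P": 1.0}, gene="g_r1"),
        _rxn("DM_p", {"P": -1.0}, kind="demand"),
        _rxn("EX_q", {"Q": 1.0}, 0.0, q_cap, kind="exchange"),
        _rxn("GROWTH", {"P": -1.0, "Q": -1.0}, kind="biomass", gene="g_growth"),
    ]
    m.validate()
    return m


def _toy_y(glc_cap: float = 10.0, ngam: float = 1.0) -> MetabolicModel:
    """Oleaginous-like network; all internal reactions are carbon-balanced.

    ATP and NADH are treated as carbon-free currency metabolites so that
    carbon closure holds exactly by construction.
    """
    m = MetabolicModel(id="TOY-Y")
    m.metabolites = [
        _met("GLC", "C6H12O6"), _met("G6P", "C6H13O9P"), _met("PYR", "C3H4O3"),
        _met("ACCOA", "C2H3O"), _met("CIT", "C6H8O7"), _met("ICIT", "C6H8O7"),
        _met("AKG", "C5H6O5"), _met("OAA", "C4H4O5"), _met("GLU", "C5H9NO4"),
        _met("TAG", "C6H10O6"), _met("GLYCOGEN", "C6H10O5"),
        _met("STER", "C6H10O"),
        _met("NH4", "N1H4"), _met("PI", "P1"), _met("O2", "O2"),
        _met("CO2", "C1O2"), _met("ATP", None), _met("NADH", None),
    ]
    m.reactions = [
        # exchanges (source-style: positive flux = uptake for importables)
        _rxn("EX_glc", {"GLC": 1.0}, 0.0, glc_cap, kind="exchange"),
        _rxn("EX_nh4", {"NH4": 1.0}, 0.0, DEFAULT_BOUND, kind="exchange"),
        _rxn("EX_pi", {"PI": 1.0}, 0.0, DEFAULT_BOUND, kind="exchange"),
        _rxn("EX_o2", {"O2": 1.0}, 0.0, DEFAULT_BOUND, kind="exchange"),
        _rxn("EX_co2", {"CO2": -1.0}, 0.0, DEFAULT_BOUND, kind="exchange"),
        _rxn("EX_cit", {"CIT": -1.0}, 0.0, DEFAULT_BOUND, kind="exchange"),
        # amino-acid secretion channel: unused at reference, engaged under
        # phosphate limitation (nitrogen still enters, biomass cannot drain it)
        _rxn("EX_glu", {"GLU": -1.0}, 0.0, DEFAULT_BOUND, kind="exchange"),
        # NGAM: ATP hydrolysis with a fixed lower bound, active in all states
        _rxn("ATPM", {"ATP": -1.0}, ngam, DEFAULT_BOUND, kind="internal"),
        # glycolysis
        _rxn("HEX", {"GLC": -1.0, "ATP": -1.0, "G6P": 1.0}, gene="g_hex"),
        _rxn("GLYC", {"G6P": -1.0, "PYR": 2.0, "ATP": 3.0, "NADH": 2.0},
             gene="g_glyc"),
        _rxn("PDH", {"PYR": -1.0, "ACCOA": 1.0, "CO2": 1.0, "NADH": 1.0},
             gene="g_pdh"),
        _rxn("PYRCARB", {"PYR": -1.0, "CO2": -1.0, "ATP": -1.0, "OAA": 1.0},
             gene="g_pc"),
        # TCA-like loop
        _rxn("CITSYN", {"ACCOA": -1.0, "OAA": -1.0, "CIT": 1.0}, gene="g_cs"),
        _rxn("ACONT", {"CIT": -1.0, "ICIT": 1.0}, gene="g_aco"),
        _rxn("ICITDH", {"ICIT": -1.0, "AKG": 1.0, "CO2": 1.0, "NADH": 1.0},
             gene="g_idh"),
        _rxn("AKGDH", {"AKG": -1.0, "OAA": 1.0, "CO2": 1.0, "NADH": 2.0,
                       "ATP": 1.0}, gene="g_akgdh"),
        # citrate-to-lipid route (ATP-citrate lyase) and TAG synthesis
        _rxn("ACL", {"CIT": -1.0, "ATP": -1.0, "ACCOA": 1.0, "OAA": 1.0},
             gene="g_acl"),
        _rxn("TAGSYN", {"ACCOA": -3.0, "NADH": -2.0, "ATP": -1.0, "TAG": 1.0},
             gene="g_tagsyn"),
        _rxn("DM_tag", {"TAG": -1.0}, kind="demand"),
        # respiration
        _rxn("RESP", {"NADH": -1.0, "O2": -1.0, "ATP": 2.0}, gene="g_resp"),
        # futile nitrogen cycle: glutamate synthesis feeds biomass; paired
        # degradation closes a cycle that burns 1 ATP + 1 NADH per turn
        _rxn("GLUSYN", {"AKG": -1.0, "NH4": -1.0, "ATP": -1.0, "NADH": -1.0,
                        "GLU": 1.0}, gene="g_glusyn"),
        _rxn("GLUDEG", {"GLU": -1.0, "AKG": 1.0, "NH4": 1.0}, gene="g_gludeg"),
        # glycogen storage cycle, zero flux in both conditions
        _rxn("GLYCSYN", {"G6P": -1.0, "ATP": -1.0, "GLYCOGEN": 1.0},
             gene="g_glgsyn"),
        _rxn("GLYCDEG", {"GLYCOGEN": -1.0, "G6P": 1.0}, gene="g_glgdeg"),
        # storage-fat-free biomass: carbon + nitrogen + phosphate + energy
        _rxn("BIOMASS", {"GLU": -2.0, "ACCOA": -1.0, "G6P": -1.0,
                         "ATP": -12.0, "PI": -1.0}, kind="biomass",
             gene="g_bio"),
        # degradation route with an unproducible substrate: carries zero flux
        # in every state, so its knockout must be a strict no-op
        _rxn("STERDEG", {"STER": -1.0, "ACCOA": 3.0}, gene="g_sterdeg"),
        # orphan drain kept tiny and closed; exercises orphan exclusion
        _rxn("PYRLEAK", {"PYR": -1.0, "CO2": 3.0, "NADH": 1.0}, 0.0, 0.0),
    ]
    m.validate()
    return m


def make_fixture(name: str, **params) -> MetabolicModel:
    """Build one of the named toy models; deterministic given parameters."""
    key = name.upper().replace("_", "-")
    if not key.startswith("TOY-") and len(key) == 1:
        key = f"TOY-{key}"
    builders = {"TOY-A": _toy_a, "TOY-B": _toy_b, "TOY-C": _toy_c, "TOY-Y": _toy_y}
    if key not in builders:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return builders[key](**params)
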