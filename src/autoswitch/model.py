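"""The AMPK*-MTORC1-ULK1 switch model: molecule types, rewrite rules,
parameters, and variants.

The model tracks seven molecule types: FKBP1A-bound rapamycin (``rapa``),
AMPK* (AMPK carrying activating kinase-domain phosphorylation, here a fixed
``T172~P`` state site), MTOR, RPTOR, ULK1, EIF4EBP1 and AMBRA1.  Twenty-nine
rewrite rules (27 unidirectional, 2 bidirectional) encode rapamycin and RPTOR
binding to MTOR (mutually exclusive), RPTOR and AMPK binding to ULK1,
MTORC1-mediated phosphorylation of ULK1 S758 and EIF4EBP1 S65/T70,
ULK1-mediated phosphorylation of RPTOR S792 and the lumped S855/S859 site, of
AMBRA1, and of AMPK (the slow negative feedback), AMPK-mediated activation of
ULK1 at S317/S778, AMPK-mediated phosphorylation of RPTOR S792, and
first-order dephosphorylation of every site.

Inputs are the copy numbers of AMPK* and rapamycin*; they are fixed totals,
not dynamical variables.  AMBRA1 phosphorylation reports ULK1 (autophagy)
activity; EIF4EBP1 phosphorylation reports MTORC1 (translation) activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

from .graphs import Molecule, PatternGraph, SpeciesGraph


class ModelSpecError(ValueError):
    """Raised for inconsistent model specifications."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteDef:
    """One site of a molecule type: a name plus its internal states.

    ``states`` is empty for pure binding sites.  The first listed state is
    the default (unmodified) state used when seeding the network.
    """

    name: str
    states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ModelSpecError(f"duplicate states on site {self.name}")


@dataclass(frozen=True)
class MoleculeTypeDef:
    name: str
    sites: tuple[SiteDef, ...] = ()

    def __post_init__(self) -> None:
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ModelSpecError(f"duplicate site names on molecule type {self.name}")

    def site(self, name: str) -> Optional[SiteDef]:
        for s in self.sites:
            if s.name == name:
                return s
        return None

    def default_molecule(self) -> Molecule:
        """Monomer in the unmodified form: every state site in its first state."""
        return Molecule(
            self.name,
            {s.name: (s.states[0] if s.states else None) for s in self.sites},
        )


@dataclass
class RewriteRule:
    """One interaction rule.

    ``stat_factor`` is the statistical prefactor printed with the rate (2 for
    the rules written with ``2*p4`` and ``2*u0``, 1 otherwise).  Bidirectional
    rules carry a reverse rate reference and contribute reactions both ways.
    """

    id: str
    reactants: list[PatternGraph]
    products: list[PatternGraph]
    rate_ref: str
    stat_factor: float = 1.0
    bidirectional: bool = False
    reverse_rate_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stat_factor <= 0:
            raise ModelSpecError(f"rule {self.id}: stat_factor must be positive")
        if self.bidirectional and not self.reverse_rate_ref:
            raise ModelSpecError(f"rule {self.id}: bidirectional rule lacks reverse rate")


@dataclass
class ModelVariant:
    """Model variant switches.

    ``feedback_enabled=False`` forces p6 to zero, removing the flux of
    ULK1-mediated inhibitory phosphorylation of AMPK (the slow negative
    feedback).  ``p9`` overrides the strength of AMPK-mediated phosphorylation
    of RPTOR S792 (nominally zero).  ``ampk_star`` / ``rapamycin_star`` set
    the input copy numbers, and ``overrides`` may replace any parameter.
    """

    feedback_enabled: bool = True
    p9: Optional[float] = None
    ampk_star: float = 30_000.0
    rapamycin_star: float = 0.0
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ampk_star < 0 or self.rapamycin_star < 0:
            raise ModelSpecError("input copy numbers must be non-negative")
        if self.p9 is not None and self.p9 < 0:
            raise ModelSpecError("p9 must be non-negative")


@dataclass
class ParameterSet:
    """Nominal rate constants and abundances (copies/cell, s^-1 units).

    Bimolecular association constants (a1..a5) and the pseudo-second-order
    phosphorylation constants (p5, p6, p9) are in (copies/cell)^-1 s^-1; all
    other rate constants are s^-1.
    """

    # association
    a1: float = 1e-3
    a2: float = 1e-3
    a3: float = 1e-3
    a4: float = 1e-5
    a5: float = 1e-5
    # dissociation
    d1: float = 1e-2
    d2: float = 1e-1
    d3: float = 1e-1
    d3max: float = 10.0  # = 100 * d3 at nominal values
    d4: float = 1.0
    d5: float = 10.0
    # phosphorylation
    p1: float = 10.0
    p2: float = 10.0
    p3: float = 10.0
    p4: float = 10.0
    p5: float = 1e-4
    p6: float = 1e-6
    p7: float = 10.0
    p8: float = 10.0
    p9: float = 0.0
    # dephosphorylation
    u0: float = 1e-2
    u1: float = 1e-3
    u2: float = 1e-4
    # abundances (copies per cell)
    MTOR_total: float = 2e4
    RPTOR_total: float = 2e4
    ULK1_total: float = 1e4
    EIF4EBP1_total: float = 1e4
    AMBRA1_total: float = 1e4
    # inputs (copies per cell)
    ampk_star: float = 30_000.0
    rapamycin_star: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ModelSpecError(f"parameter {name} must be non-negative")


#: The 22 rate constants scanned in the sensitivity analysis (p9 excluded).
SENSITIVITY_PARAMETERS: tuple[str, ...] = (
    "a1", "a2", "a3", "a4", "a5",
    "d1", "d2", "d3", "d3max", "d4", "d5",
    "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8",
    "u0", "u1", "u2",
)


@dataclass
class Model:
    """A validated in-memory rule-based model."""

    name: str
    molecule_types: dict[str, MoleculeTypeDef]
    rules: list[RewriteRule]
    params: dict[str, float]
    seeds: list[tuple[SpeciesGraph, str]]  # (monomer, amount parameter name)
    variant: Optional[ModelVariant] = None

    def rule(self, rule_id: str) -> RewriteRule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)


# ---------------------------------------------------------------------------
# Nominal model definition
# ---------------------------------------------------------------------------

#: Molecule type declarations in BNGL dialect.  T172 on AMPK is declared as a
#: state site with the single state P: every AMPK copy in the model is AMPK*
#: (the form with activating kinase-domain phosphorylation), so rules testing
#: T172~P apply verbatim while the site can never change state.
MOLECULE_TYPE_DEFS: tuple[str, ...] = (
    "rapa(mtor)",
    "AMPK(ulk1,T172~P,ST~0~P)",
    "MTOR(HEAT,FRB)",
    "RPTOR(RNC,ulk1,WD40,S792~0~P,S855_S859~0~P~PP)",
    "ULK1(straptor,stampk,S317~0~P,S758~0~P,S778~0~P)",
    "EIF4EBP1(RCR,S65_T70~0~P)",
    "AMBRA1(ST~0~P)",
)

#: The 29 interaction rules (id, BNGL dialect).  Ids follow the customary
#: lettered numbering of the rule set; rules 1 and 2 are the two reversible
#: binding rules, everything else is unidirectional.
RULE_DEFS: tuple[tuple[str, str], ...] = (
    ("1", "rapa(mtor) + MTOR(HEAT,FRB) <-> rapa(mtor!1).MTOR(HEAT,FRB!1) a1, d1"),
    ("2", "RPTOR(WD40) + MTOR(HEAT,FRB) <-> RPTOR(WD40!1).MTOR(HEAT!1,FRB) a2, d2"),
    ("3A", "RPTOR(RNC,ulk1,S792~0,S855_S859~0) + ULK1(straptor) -> "
           "RPTOR(RNC,ulk1!1,S792~0,S855_S859~0).ULK1(straptor!1) a3"),
    ("3B", "RPTOR(ulk1!1).ULK1(straptor!1) -> RPTOR(ulk1) + ULK1(straptor) d3"),
    ("3C", "RPTOR(ulk1!1,S792~P,S855_S859~PP).ULK1(straptor!1) -> "
           "RPTOR(ulk1,S792~P,S855_S859~PP) + ULK1(straptor) d3max"),
    ("4A", "RPTOR(RNC,ulk1,S792~0,S855_S859~0) + EIF4EBP1(RCR,S65_T70~0) -> "
           "RPTOR(RNC!1,ulk1,S792~0,S855_S859~0).EIF4EBP1(RCR!1,S65_T70~0) a4"),
    ("4B", "RPTOR(RNC!1).EIF4EBP1(RCR!1) -> RPTOR(RNC) + EIF4EBP1(RCR) d4"),
    ("5A", "AMPK(ulk1,T172~P) + ULK1(stampk,S758~0) -> "
           "AMPK(ulk1!1,T172~P).ULK1(stampk!1,S758~0) a5"),
    ("5B", "AMPK(ulk1!1).ULK1(stampk!1) -> AMPK(ulk1) + ULK1(stampk) d5"),
    ("6", "MTOR(HEAT!1).RPTOR(WD40!1,ulk1!2).ULK1(straptor!2,stampk,S758~0) -> "
          "MTOR(HEAT!1).RPTOR(WD40!1,ulk1!2).ULK1(straptor!2,stampk,S758~P) p1"),
    ("7", "MTOR(HEAT!1).RPTOR(WD40!1,RNC!2).EIF4EBP1(RCR!2,S65_T70~0) -> "
          "MTOR(HEAT!1).RPTOR(WD40!1,RNC!2).EIF4EBP1(RCR!2,S65_T70~P) p2"),
    ("8A", "RPTOR(ulk1!1,S792~0).ULK1(straptor!1,S317~P,S778~P) -> "
           "RPTOR(ulk1!1,S792~P).ULK1(straptor!1,S317~P,S778~P) p3"),
    ("8B", "RPTOR(ulk1!1,S855_S859~0).ULK1(straptor!1,S317~P,S778~P) -> "
           "RPTOR(ulk1!1,S855_S859~P).ULK1(straptor!1,S317~P,S778~P) 2*p4"),
    ("8C", "RPTOR(ulk1!1,S855_S859~P).ULK1(straptor!1,S317~P,S778~P) -> "
           "RPTOR(ulk1!1,S855_S859~PP).ULK1(straptor!1,S317~P,S778~P) p4"),
    ("9", "ULK1(straptor,S317~P,S778~P) + AMBRA1(ST~0) -> "
          "ULK1(straptor,S317~P,S778~P) + AMBRA1(ST~P) p5"),
    ("10", "ULK1(straptor,S317~P,S778~P) + AMPK(ST~0) -> "
           "ULK1(straptor,S317~P,S778~P) + AMPK(ST~P) p6"),
    ("11A", "AMPK(ulk1!1,T172~P,ST~0).ULK1(stampk!1,straptor,S317~0) -> "
            "AMPK(ulk1!1,T172~P,ST~0).ULK1(stampk!1,straptor,S317~P) p7"),
    ("11B", "AMPK(ulk1!1,T172~P,ST~0).ULK1(stampk!1,S778~0) -> "
            "AMPK(ulk1!1,T172~P,ST~0).ULK1(stampk!1,S778~P) p8"),
    ("12", "AMPK(T172~P) + RPTOR(S792~0) -> AMPK(T172~P) + RPTOR(S792~P) p9"),
    ("13", "ULK1(S758~P) -> ULK1(S758~0) u0"),
    ("14", "EIF4EBP1(S65_T70~P) -> EIF4EBP1(S65_T70~0) u0"),
    ("15A", "RPTOR(S792~P) -> RPTOR(S792~0) u1"),
    ("15B", "RPTOR(S855_S859~P) -> RPTOR(S855_S859~0) u0"),
    ("15C", "RPTOR(S855_S859~PP) -> RPTOR(S855_S859~P) 2*u0"),
    ("16", "AMBRA1(ST~P) -> AMBRA1(ST~0) u0"),
    ("17", "AMPK(ST~P) -> AMPK(ST~0) u2"),
    ("18A", "ULK1(straptor,S317~P) -> ULK1(straptor,S317~0) u0"),
    ("18B", "ULK1(S778~P) -> ULK1(S778~0) u0"),
    ("19", "RPTOR(S792~P) -> RPTOR(S792~0) u0"),
)

#: Seed amounts: molecule type -> parameter carrying its total copy number.
SEED_AMOUNTS: dict[str, str] = {
    "rapa": "rapamycin_star",
    "AMPK": "ampk_star",
    "MTOR": "MTOR_total",
    "RPTOR": "RPTOR_total",
    "ULK1": "ULK1_total",
    "EIF4EBP1": "EIF4EBP1_total",
    "AMBRA1": "AMBRA1_total",
}


def build_model(variant: Optional[ModelVariant] = None) -> Model:
    """Construct the nominal model, optionally adjusted by a variant.

    The returned model carries 7 molecule types, 29 rules indexed by id, a
    parameter dictionary with Table-level nominal values adjusted by the
    variant, and the 7 monomeric seed species in their unmodified forms.
    """
    from . import bngl  # deferred: bngl imports types from this module

    variant = variant or ModelVariant()
    mol_types = {
        mt.name: mt for mt in (bngl.parse_molecule_type(s) for s in MOLECULE_TYPE_DEFS)
    }
    rules = [bngl.parse_rule(rid, text, mol_types) for rid, text in RULE_DEFS]

    params = ParameterSet().as_dict()
    params["ampk_star"] = float(variant.ampk_star)
    params["rapamycin_star"] = float(variant.rapamycin_star)
    if variant.p9 is not None:
        params["p9"] = float(variant.p9)
    if not variant.feedback_enabled:
        params["p6"] = 0.0
    for key, value in variant.overrides.items():
        if key not in params:
            raise ModelSpecError(f"unknown parameter override: {key}")
        params[key] = float(value)

    seeds = [
        (SpeciesGraph([mt.default_molecule()], {}), SEED_AMOUNTS[mt.name])
        for mt in mol_types.values()
    ]
    model = Model(
        name="ampk_mtorc1_ulk1",
        molecule_types=mol_types,
        rules=rules,
        params=params,
        seeds=seeds,
        variant=variant,
    )
    report = validate_model(model)
    if not report.ok:
        raise ModelSpecError("nominal model failed validation:\n" + str(report))
    return model


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        return "\n".join(self.findings) if self.findings else "ok"


def _check_pattern(pat: PatternGraph, mol_types: dict[str, MoleculeTypeDef],
                   where: str, findings: list[str]) -> None:
    for pm in pat.molecules:
        mt = mol_types.get(pm.type)
        if mt is None:
            findings.append(f"{where}: undeclared molecule type {pm.type}")
            continue
        for site, ps in pm.sites.items():
            sd = mt.site(site)
            if sd is None:
                findings.append(f"{where}: undeclared site {pm.type}.{site}")
                continue
            if ps.state is not None and ps.state not in sd.states:
                findings.append(
                    f"{where}: undeclared state {pm.type}.{site}~{ps.state}"
                )


def validate_model(model: Model, check_reachability: bool = False) -> ValidationReport:
    """Static consistency checks; optionally flags rules that never fire.

    The report lists undeclared molecule types/sites/states, rate references
    not bound to a parameter, and (with ``check_reachability=True``, which
    expands the network) rules generating no reaction.  The nominal model
    yields an empty report.
    """
    findings: list[str] = []
    for rule in model.rules:
        for pat in rule.reactants:
            _check_pattern(pat, model.molecule_types, f"rule {rule.id} reactants", findings)
            if not pat.is_connected():
                findings.append(f"rule {rule.id}: disconnected reactant pattern")
        for pat in rule.products:
            _check_pattern(pat, model.molecule_types, f"rule {rule.id} products", findings)
        for ref in filter(None, (rule.rate_ref, rule.reverse_rate_ref)):
            if ref not in model.params:
                findings.append(f"rule {rule.id}: unbound rate parameter {ref}")
    for species, amount_key in model.seeds:
        if amount_key not in model.params:
            findings.append(f"seed {species.label}: unbound amount parameter {amount_key}")
    if check_reachability and not findings:
        from .network import expand_network

        net = expand_network(model)
        fired = {rx.rule_id for rx in net.reactions}
        for rule in model.rules:
            if rule.id not in fired:
                findings.append(f"rule {rule.id}: matches no reachable species")
    return ValidationReport(findings)


# ---------------------------------------------------------------------------
# Rule census
# ---------------------------------------------------------------------------


def _flat_states(patterns: list[PatternGraph]) -> list[tuple[str, str, Optional[str]]]:
    out = []
    for pat in patterns:
        for pm in pat.molecules:
            for site, ps in pm.sites.items():
                out.append((pm.type, site, ps.state))
    return out


def count_rules_by_class(model: Model) -> dict[str, int]:
    """Partition the rule set into binding and (de)phosphorylation classes.

    Classification is structural: rules that add or remove bonds are
    association/dissociation rules (split into reversible and unidirectional);
    pure state-change rules are phosphorylation when the changed site moves up
    its declared state order (0 -> P -> PP) and dephosphorylation when it
    moves down.
    """
    counts = {
        "reversible_binding": 0,
        "unidirectional_binding": 0,
        "phosphorylation": 0,
        "dephosphorylation": 0,
    }
    for rule in model.rules:
        if rule.bidirectional:
            counts["reversible_binding"] += 1
            continue
        rb = sum(len(p.bonds) for p in rule.reactants)
        pb = sum(len(p.bonds) for p in rule.products)
        if rb != pb or len(rule.reactants) != len(rule.products):
            counts["unidirectional_binding"] += 1
            continue
        reac, prod = _flat_states(rule.reactants), _flat_states(rule.products)
        direction = 0
        for (mtype, site, s_r), (_, _, s_p) in zip(reac, prod):
            if s_r is None or s_p is None or s_r == s_p:
                continue
            order = model.molecule_types[mtype].site(site).states
            direction = 1 if order.index(s_p) > order.index(s_r) else -1
            break
        if direction > 0:
            counts["phosphorylation"] += 1
        elif direction < 0:
            counts["dephosphorylation"] += 1
        else:
            counts["unidirectional_binding"] += 1
    return counts
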