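"""Small closed-form rule systems for exercising the expansion engine.

Each fixture is a toy model whose complete reachable species set can be
enumerated by hand; the expected censuses recorded here are those hand
enumerations (documented rule by rule in each builder) and serve as
independent oracles for the network generator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bngl import parse_model
from .model import Model


@dataclass
class Fixture:
    name: str
    model: Model
    expected_species: int
    expected_reactions: int
    expected_species_labels: tuple[str, ...]
    description: str


def _dimer() -> Fixture:
    """Reversible dimerization.  Species: A, B, A.B (3).  Reactions: one
    association + one dissociation (2)."""
    text = """
begin parameters
  kon 1e-3
  koff 1e-2
end parameters
begin molecule types
  A(b)
  B(a)
end molecule types
begin seed species
  A(b) 100
  B(a) 100
end seed species
begin reaction rules
  bind: A(b) + B(a) <-> A(b!1).B(a!1) kon, koff
end reaction rules
"""
    return Fixture(
        "dimer", parse_model(text, "dimer"), 3, 2,
        ("A(b)", "B(a)", "A(b!1).B(a!1)"),
        "reversible heterodimer",
    )


def _phosphoforms() -> Fixture:
    """Monomer with a 2-state site x and a 3-state site y, free
    (de)phosphorylation on both.  Species: 2 x 3 = 6.  Reactions: the two
    x-rules fire in each of 3 y-contexts (6) and the four y-rules fire in
    each of 2 x-contexts (8), total 14."""
    text = """
begin parameters
  k 1.0
end parameters
begin molecule types
  M(x~0~P,y~0~P~Q)
end molecule types
begin seed species
  M(x~0,y~0) 100
end seed species
begin reaction rules
  xp: M(x~0) -> M(x~P) k
  xu: M(x~P) -> M(x~0) k
  yp1: M(y~0) -> M(y~P) k
  yp2: M(y~P) -> M(y~Q) k
  yu2: M(y~Q) -> M(y~P) k
  yu1: M(y~P) -> M(y~0) k
end reaction rules
"""
    labels = tuple(f"M(x~{x},y~{y})" for x in "0P" for y in "0PQ")
    return Fixture("phosphoforms", parse_model(text, "phosphoforms"), 6, 14,
                   labels, "2-state x 3-state monomer")


def _scaffold_chain() -> Fixture:
    """Scaffold B binding A and C independently (context-free rules).
    Species: A, B, C, A.B, B.C, A.B.C (6).  Each reversible rule fires in 2
    contexts each way: 8 reactions."""
    text = """
begin parameters
  kon 1e-3
  koff 1e-2
end parameters
begin molecule types
  A(b)
  B(a,c)
  C(b)
end molecule types
begin seed species
  A(b) 100
  B(a,c) 100
  C(b) 100
end seed species
begin reaction rules
  ab: A(b) + B(a) <-> A(b!1).B(a!1) kon, koff
  bc: B(c) + C(b) <-> B(c!1).C(b!1) kon, koff
end reaction rules
"""
    labels = ("A(b)", "B(a,c)", "C(b)", "A(b!1).B(a!1,c)", "B(a,c!1).C(b!1)",
              "A(b!1).B(a!1,c!2).C(b!2)")
    return Fixture("scaffold_chain", parse_model(text, "scaffold_chain"), 6, 8,
                   labels, "A-B-C scaffold chain")


def _competitive_binding() -> Fixture:
    """Two ligands competing for a receptor via required-unbound context (the
    binding of one requires the other's site to be free, mirroring the
    mutually exclusive binding of rapamycin* and RPTOR to MTOR).  Species:
    L, R, X, L.X, X.R (5) — the doubly bound complex is unreachable.
    Reactions: one association + one dissociation per ligand (4)."""
    text = """
begin parameters
  kon 1e-3
  koff 1e-2
end parameters
begin molecule types
  L(x)
  R(x)
  X(s,t)
end molecule types
begin seed species
  L(x) 100
  R(x) 100
  X(s,t) 100
end seed species
begin reaction rules
  bindL: L(x) + X(s,t) -> L(x!1).X(s!1,t) kon
  unbindL: L(x!1).X(s!1) -> L(x) + X(s) koff
  bindR: R(x) + X(s,t) -> R(x!1).X(s,t!1) kon
  unbindR: R(x!1).X(t!1) -> R(x) + X(t) koff
end reaction rules
"""
    labels = ("L(x)", "R(x)", "X(s,t)", "L(x!1).X(s!1,t)", "R(x!1).X(s,t!1)")
    return Fixture("competitive_binding", parse_model(text, "competitive_binding"),
                   5, 4, labels, "mutually exclusive ligands")


def _state_gated_binding() -> Fixture:
    """Binding gated by an unphosphorylated site, phosphorylation only of the
    free monomer.  Reachable species: A(s~0), A(s~P), B, A(s~0).B (4) — the
    bound-phosphorylated complex is unreachable.  Reactions: bind, unbind,
    phosphorylate (free A only), dephosphorylate (one matching species): 4."""
    text = """
begin parameters
  kon 1e-3
  koff 1e-2
  kp 1.0
  ku 0.1
end parameters
begin molecule types
  A(b,s~0~P)
  B(a)
end molecule types
begin seed species
  A(b,s~0) 100
  B(a) 100
end seed species
begin reaction rules
  bind: A(b,s~0) + B(a) -> A(b!1,s~0).B(a!1) kon
  unbind: A(b!1).B(a!1) -> A(b) + B(a) koff
  phos: A(b,s~0) -> A(b,s~P) kp
  dephos: A(s~P) -> A(s~0) ku
end reaction rules
"""
    labels = ("A(b,s~0)", "A(b,s~P)", "B(a)", "A(b!1,s~0).B(a!1)")
    return Fixture("state_gated_binding", parse_model(text, "state_gated_binding"),
                   4, 4, labels, "state-gated association")


def generate_fixtures() -> list[Fixture]:
    """The toy model suite with hand-enumerated expected networks."""
    return [
        _dimer(),
        _phosphoforms(),
        _scaffold_chain(),
        _competitive_binding(),
        _state_gated_binding(),
    ]
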