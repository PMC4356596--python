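"""Site graphs: concrete molecular species, rule patterns, subgraph matching,
and canonical labeling.

A *species graph* is a fully specified connected complex: molecule instances
whose state sites each carry exactly one internal state, plus a bond map
pairing binding sites.  A *pattern graph* is a partial specification used on
either side of a rewrite rule: each mentioned site may constrain the internal
state, require the site to be free, or tie it into a pattern bond; unmentioned
sites are unconstrained ("don't care"), following BNGL conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Iterator, Optional, Union

#: Bond condition sentinel: the site must be unbound.
FREE = "free"

# Cap on the number of candidate orderings explored by the exhaustive
# symmetry fallback in canonical labeling.  Complexes in this problem domain
# are small chains; the cap guards against pathological inputs.
_MAX_ORDERINGS = 40320  # 8!


class GraphError(ValueError):
    """Raised for malformed species or pattern graphs."""


# ---------------------------------------------------------------------------
# Concrete species
# ---------------------------------------------------------------------------


class Molecule:
    """One molecule instance: a type name plus a full site->state map.

    ``sites`` maps every declared site name to its internal state, or to
    ``None`` for pure binding sites (sites without internal states).
    """

    __slots__ = ("type", "sites")

    def __init__(self, type: str, sites: dict[str, Optional[str]]):
        self.type = type
        self.sites = sites

    def copy(self) -> "Molecule":
        return Molecule(self.type, dict(self.sites))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Molecule({self.type}, {self.sites})"


Endpoint = tuple[int, str]  # (molecule index, site name)


class SpeciesGraph:
    """A connected complex with fully specified states and bonds.

    ``bonds`` is a symmetric map: both ``(i, site_a) -> (j, site_b)`` and the
    reverse entry are present.  The canonical label is computed lazily and is
    invariant under molecule reordering and bond renumbering.
    """

    __slots__ = ("molecules", "bonds", "_label")

    def __init__(self, molecules: list[Molecule], bonds: dict[Endpoint, Endpoint]):
        self.molecules = molecules
        self.bonds = bonds
        self._label: Optional[str] = None

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_bond_list(
        cls, molecules: list[Molecule], bond_pairs: list[tuple[Endpoint, Endpoint]]
    ) -> "SpeciesGraph":
        bonds: dict[Endpoint, Endpoint] = {}
        for a, b in bond_pairs:
            if a in bonds or b in bonds:
                raise GraphError(f"site bound twice: {a} or {b}")
            bonds[a] = b
            bonds[b] = a
        return cls(molecules, bonds)

    def copy(self) -> "SpeciesGraph":
        return SpeciesGraph([m.copy() for m in self.molecules], dict(self.bonds))

    # -- basic queries -------------------------------------------------------

    def is_bound(self, i: int, site: str) -> bool:
        return (i, site) in self.bonds

    def is_connected(self) -> bool:
        n = len(self.molecules)
        if n <= 1:
            return True
        seen = {0}
        stack = [0]
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for (i, _), (j, _) in self.bonds.items():
            adj[i].add(j)
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == n

    @property
    def label(self) -> str:
        if self._label is None:
            self._label = canonical_label(self)
        return self._label

    def molecule_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.molecules:
            counts[m.type] = counts.get(m.type, 0) + 1
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesGraph):
            return NotImplemented
        return self.label == other.label

    def __hash__(self) -> int:
        return hash(self.label)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpeciesGraph({self.label})"


# ---------------------------------------------------------------------------
# Canonical labeling
# ---------------------------------------------------------------------------


def _serialize(sp: SpeciesGraph, order: list[int]) -> str:
    """Serialize a species under a given molecule ordering.

    Sites are written in sorted name order; bonds are numbered in order of
    first appearance during the scan, which makes the string independent of
    the internal bond representation.
    """
    bond_num: dict[frozenset, int] = {}
    counter = 0
    parts = []
    for old_i in order:
        mol = sp.molecules[old_i]
        toks = []
        for site in sorted(mol.sites):
            tok = site
            state = mol.sites[site]
            if state is not None:
                tok += "~" + state
            partner = sp.bonds.get((old_i, site))
            if partner is not None:
                key = frozenset(((old_i, site), partner))
                if key not in bond_num:
                    counter += 1
                    bond_num[key] = counter
                tok += "!" + str(bond_num[key])
            toks.append(tok)
        parts.append(f"{mol.type}({','.join(toks)})")
    return ".".join(parts)


def canonical_label(sp: SpeciesGraph) -> str:
    """Canonical string label for a connected species graph.

    Uses iterative neighborhood refinement (Weisfeiler-Lehman style) to
    partition molecule instances, then exhausts the remaining permutations
    within symmetric classes, returning the lexicographically smallest
    serialization.  The label is identical for isomorphic graphs and distinct
    for non-isomorphic ones (the exhaustive fallback guarantees this for the
    small complexes handled here).
    """
    n = len(sp.molecules)
    if n == 0:
        raise GraphError("empty species graph")
    if not sp.is_connected():
        raise GraphError("species graph must be connected")
    if n == 1:
        return _serialize(sp, [0])

    # Initial colors: molecule type plus full site-state fingerprint.
    colors: list = [
        (m.type, tuple(sorted((s, st or "") for s, st in m.sites.items())))
        for m in sp.molecules
    ]
    # Refine by bonded-neighbor colors (site names included on both ends).
    for _ in range(n):
        nxt = []
        for i in range(n):
            nb = []
            for site in sp.molecules[i].sites:
                partner = sp.bonds.get((i, site))
                if partner is not None:
                    j, psite = partner
                    nb.append((site, psite, colors[j]))
            nxt.append((colors[i], tuple(sorted(nb))))
        if len(set(map(repr, nxt))) == len(set(map(repr, colors))):
            colors = nxt
            break
        colors = nxt

    # Group molecules by final color; stable deterministic group order.
    keyed = sorted(range(n), key=lambda i: repr(colors[i]))
    groups: list[list[int]] = []
    for idx in keyed:
        if groups and repr(colors[groups[-1][-1]]) == repr(colors[idx]):
            groups[-1].append(idx)
        else:
            groups.append([idx])

    n_orderings = math.prod(math.factorial(len(g)) for g in groups)
    if n_orderings > _MAX_ORDERINGS:
        raise GraphError(
            f"symmetry class too large for canonical labeling ({n_orderings} orderings)"
        )
    best: Optional[str] = None
    for perm_combo in product(*(permutations(g) for g in groups)):
        order = [i for grp in perm_combo for i in grp]
        lab = _serialize(sp, order)
        if best is None or lab < best:
            best = lab
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternSite:
    """Condition on one site of a pattern molecule.

    ``state``: required internal state, or None for don't-care.
    ``bond``: ``FREE`` (site must be unbound), an integer bond id (site must
    be bonded to the pattern partner sharing the id), or None for don't-care.
    """

    state: Optional[str] = None
    bond: Union[int, str, None] = None


@dataclass
class PatternMolecule:
    type: str
    sites: dict[str, PatternSite] = field(default_factory=dict)


class PatternGraph:
    """One reactant or product pattern: molecules plus internal pattern bonds.

    Bond ids shared between two sites define pattern bonds; each id must
    appear exactly twice.  A reactant pattern must be connected so that it
    matches within a single species.
    """

    def __init__(self, molecules: list[PatternMolecule]):
        self.molecules = molecules
        by_id: dict[int, list[Endpoint]] = {}
        for i, pm in enumerate(molecules):
            for site, ps in pm.sites.items():
                if isinstance(ps.bond, int):
                    by_id.setdefault(ps.bond, []).append((i, site))
        self.bonds: list[tuple[Endpoint, Endpoint]] = []
        for bid, eps in sorted(by_id.items()):
            if len(eps) != 2:
                raise GraphError(f"bond id {bid} appears {len(eps)} time(s), expected 2")
            self.bonds.append((eps[0], eps[1]))
        self._partner: dict[Endpoint, Endpoint] = {}
        for a, b in self.bonds:
            self._partner[a] = b
            self._partner[b] = a

    def is_connected(self) -> bool:
        n = len(self.molecules)
        if n <= 1:
            return True
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for (i, _), (j, _) in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PatternGraph({unparse_pattern(self)})"


def unparse_pattern(pat: PatternGraph) -> str:
    """Render a pattern back to BNGL-style text (for messages and files)."""
    parts = []
    for pm in pat.molecules:
        toks = []
        for site, ps in pm.sites.items():
            tok = site
            if ps.state is not None:
                tok += "~" + ps.state
            if isinstance(ps.bond, int):
                tok += "!" + str(ps.bond)
            toks.append(tok)
        parts.append(f"{pm.type}({','.join(toks)})")
    return ".".join(parts)


# ---------------------------------------------------------------------------
# Embedding search
# ---------------------------------------------------------------------------


def find_embeddings(pattern: PatternGraph, species: SpeciesGraph) -> list[tuple[int, ...]]:
    """All embeddings of ``pattern`` into ``species``.

    An embedding maps each pattern molecule to a distinct species molecule of
    the same type such that every site condition holds: required states match,
    required-free sites are unbound, and pattern bonds map onto species bonds
    between the corresponding sites.  Returns tuples ``emb`` with
    ``emb[pattern_index] = species_index``.
    """
    np_, ns = len(pattern.molecules), len(species.molecules)
    if np_ == 0 or np_ > ns:
        return []

    def site_ok(pm: PatternMolecule, si: int) -> bool:
        mol = species.molecules[si]
        if mol.type != pm.type:
            return False
        for site, ps in pm.sites.items():
            if site not in mol.sites:
                return False
            if ps.state is not None and mol.sites[site] != ps.state:
                return False
            bound = (si, site) in species.bonds
            if ps.bond is FREE and bound:
                return False
            if isinstance(ps.bond, int) and not bound:
                return False
        return True

    candidates = [[si for si in range(ns) if site_ok(pm, si)] for pm in pattern.molecules]
    if any(not c for c in candidates):
        return []

    out: list[tuple[int, ...]] = []
    assign: list[int] = []
    used = [False] * ns

    def bonds_ok(pi: int, si: int) -> bool:
        # Check pattern bonds whose other endpoint is already assigned.
        for site, ps in pattern.molecules[pi].sites.items():
            if not isinstance(ps.bond, int):
                continue
            pj, psite = pattern._partner[(pi, site)]
            if pj == pi:
                if species.bonds.get((si, site)) != (si, psite):
                    return False
            elif pj < pi:
                if species.bonds.get((si, site)) != (assign[pj], psite):
                    return False
        return True

    def backtrack(pi: int) -> None:
        if pi == np_:
            out.append(tuple(assign))
            return
        for si in candidates[pi]:
            if used[si] or not bonds_ok(pi, si):
                continue
            used[si] = True
            assign.append(si)
            backtrack(pi + 1)
            assign.pop()
            used[si] = False

    backtrack(0)
    return out
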