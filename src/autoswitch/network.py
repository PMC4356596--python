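"""Reaction-network generation: iterative rule application to a fixed point.

Starting from the monomeric seed species, every rule is applied to every
species (or ordered species pair, for two-reactant rules) and novel product
complexes are added until no new species appear.  Each (rule, reactant tuple,
embedding) generates one unidirectional mass-action reaction; a bidirectional
rule contributes reactions in both directions.  Reactions that coincide in
rule, reactants and products are merged by incrementing an embedding
multiplicity; reactions that coincide only across *different* rules are kept
distinct, matching the network-generation convention of rule-based modeling
tools.  Reactions are generated for every rule regardless of the current
numeric value of its rate constant (a zero rate constant, such as nominal p9,
still shapes the network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .graphs import FREE, GraphError, PatternGraph, SpeciesGraph, find_embeddings
from .model import Model


class NetworkError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Directed rules and their graph-rewrite actions
# ---------------------------------------------------------------------------

FlatEndpoint = tuple[int, str]  # (flat molecule index across patterns, site)


@dataclass
class _DirectedRule:
    rule_id: str
    direction: str  # "fwd" | "rev"
    reactants: list[PatternGraph]
    products: list[PatternGraph]
    rate_ref: str
    stat_factor: float
    state_changes: list[tuple[int, str, str]] = field(default_factory=list)
    bond_deletions: list[tuple[FlatEndpoint, FlatEndpoint]] = field(default_factory=list)
    bond_additions: list[tuple[FlatEndpoint, FlatEndpoint]] = field(default_factory=list)

    @property
    def key(self) -> str:
        return self.rule_id if self.direction == "fwd" else f"{self.rule_id}(rev)"


def _flatten(patterns: list[PatternGraph]):
    """Flat molecule list plus (pattern, local index) -> flat index offsets."""
    mols = []
    offsets = []
    for pat in patterns:
        offsets.append(len(mols))
        mols.extend(pat.molecules)
    return mols, offsets


def _flat_bonds(patterns: list[PatternGraph]) -> set[frozenset]:
    _, offsets = _flatten(patterns)
    bonds = set()
    for pi, pat in enumerate(patterns):
        for (i, s1), (j, s2) in pat.bonds:
            bonds.add(frozenset(((offsets[pi] + i, s1), (offsets[pi] + j, s2))))
    return bonds


def _derive_actions(dr: _DirectedRule) -> None:
    """Infer the rewrite actions by index-wise molecule correspondence.

    Reactant and product patterns must list the same molecules in the same
    order (the convention of every rule handled here); the difference in
    states and bonds defines the transformation.
    """
    rmols, _ = _flatten(dr.reactants)
    pmols, _ = _flatten(dr.products)
    if len(rmols) != len(pmols) or any(a.type != b.type for a, b in zip(rmols, pmols)):
        raise NetworkError(
            f"rule {dr.key}: reactant/product molecule lists do not correspond"
        )
    for idx, (rm, pm) in enumerate(zip(rmols, pmols)):
        for site, ps in pm.sites.items():
            if ps.state is None:
                continue
            rstate = rm.sites[site].state if site in rm.sites else None
            if rstate != ps.state:
                dr.state_changes.append((idx, site, ps.state))
    rbonds, pbonds = _flat_bonds(dr.reactants), _flat_bonds(dr.products)
    dr.bond_deletions = [tuple(b) for b in sorted(rbonds - pbonds, key=sorted)]
    dr.bond_additions = [tuple(b) for b in sorted(pbonds - rbonds, key=sorted)]


def directed_rules(model: Model) -> list[_DirectedRule]:
    out = []
    for rule in model.rules:
        fwd = _DirectedRule(rule.id, "fwd", rule.reactants, rule.products,
                            rule.rate_ref, rule.stat_factor)
        _derive_actions(fwd)
        out.append(fwd)
        if rule.bidirectional:
            rev = _DirectedRule(rule.id, "rev", rule.products, rule.reactants,
                                rule.reverse_rate_ref, 1.0)
            _derive_actions(rev)
            out.append(rev)
    return out


def _apply(dr: _DirectedRule, reactant_species: list[SpeciesGraph],
           embeddings: list[tuple[int, ...]]) -> list[SpeciesGraph]:
    """Apply a directed rule to concrete reactants under given embeddings.

    Returns the product complexes (connected components after rewriting).
    """
    mols = []
    bonds = {}
    offsets = []
    for sp in reactant_species:
        off = len(mols)
        offsets.append(off)
        mols.extend(m.copy() for m in sp.molecules)
        for (i, s1), (j, s2) in sp.bonds.items():
            bonds[(off + i, s1)] = (off + j, s2)

    # flat pattern molecule index -> combined instance index
    flat_map: list[int] = []
    for pi, emb in enumerate(embeddings):
        for local in emb:
            flat_map.append(offsets[pi] + local)

    for (fi, s1), (fj, s2) in dr.bond_deletions:
        a, b = (flat_map[fi], s1), (flat_map[fj], s2)
        if bonds.get(a) != b:
            raise NetworkError(f"rule {dr.key}: bond to delete not present")
        del bonds[a]
        del bonds[b]
    for (fi, s1), (fj, s2) in dr.bond_additions:
        a, b = (flat_map[fi], s1), (flat_map[fj], s2)
        if a in bonds or b in bonds:
            raise NetworkError(f"rule {dr.key}: bond endpoint already occupied")
        bonds[a] = b
        bonds[b] = a
    for fi, site, state in dr.state_changes:
        mols[flat_map[fi]].sites[site] = state

    # split into connected components
    n = len(mols)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for (i, _), (j, _) in bonds.items():
        adj[i].add(j)
    comp = [-1] * n
    n_comp = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = n_comp
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if comp[nxt] < 0:
                    comp[nxt] = n_comp
                    stack.append(nxt)
        n_comp += 1
    products = []
    for c in range(n_comp):
        idx_map = {}
        cmols = []
        for i in range(n):
            if comp[i] == c:
                idx_map[i] = len(cmols)
                cmols.append(mols[i])
        cbonds = {}
        for (i, s1), (j, s2) in bonds.items():
            if comp[i] == c:
                cbonds[(idx_map[i], s1)] = (idx_map[j], s2)
        products.append(SpeciesGraph(cmols, cbonds))
    return products


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """One unidirectional mass-action reaction between network species.

    ``multiplicity`` counts distinct embeddings of the generating rule that
    produced identical reactant and product species; the effective rate
    constant is ``rate_constant(rate_ref) * stat_factor * multiplicity``.
    """

    rule_id: str
    direction: str
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate_ref: str
    stat_factor: float
    multiplicity: int = 1

    def rate_value(self, params: dict[str, float]) -> float:
        return params[self.rate_ref] * self.stat_factor * self.multiplicity


@dataclass
class ReactionNetwork:
    """Concrete species list, unidirectional reactions, and seed amounts."""

    species: list[SpeciesGraph]
    reactions: list[Reaction]
    seeds: list[tuple[int, Union[str, float]]]  # (species index, amount key/value)
    model_name: str = ""

    def __post_init__(self) -> None:
        self.index = {sp.label: i for i, sp in enumerate(self.species)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def rate_values(self, params: dict[str, float]) -> np.ndarray:
        return np.array([rx.rate_value(params) for rx in self.reactions])

    def initial_state(self, params: dict[str, float]) -> np.ndarray:
        y0 = np.zeros(self.n_species)
        for idx, amount in self.seeds:
            y0[idx] = params[amount] if isinstance(amount, str) else float(amount)
        return y0

    def molecule_count_matrix(self) -> tuple[list[str], np.ndarray]:
        """Molecule types and the (n_types, n_species) instance-count matrix.

        Row ``t`` dotted with a state vector gives the conserved total copy
        number of molecule type ``t``.
        """
        types = sorted({m.type for sp in self.species for m in sp.molecules})
        mat = np.zeros((len(types), self.n_species))
        for j, sp in enumerate(self.species):
            counts = sp.molecule_counts()
            for i, t in enumerate(types):
                mat[i, j] = counts.get(t, 0)
        return types, mat

    def species_total(self, molecule_type: str) -> np.ndarray:
        """Per-species instance counts of one molecule type (weight vector)."""
        return np.array(
            [sp.molecule_counts().get(molecule_type, 0) for sp in self.species],
            dtype=float,
        )


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------


def expand_network(model: Model, max_species: int = 10_000,
                   extra_seeds: Optional[list[SpeciesGraph]] = None) -> ReactionNetwork:
    """Expand the rule set into the complete reaction network.

    Fixed-point iteration: apply every rule to every species tuple, add novel
    product species, and repeat until closure.  Species are ordered by
    discovery; the procedure is deterministic, so repeated runs produce
    byte-identical network files.  Raises :class:`NetworkError` if the
    species count exceeds ``max_species`` (divergence guard).
    """
    drules = directed_rules(model)
    species: list[SpeciesGraph] = []
    index: dict[str, int] = {}
    seeds: list[tuple[int, Union[str, float]]] = []

    def get_or_add(sp: SpeciesGraph) -> int:
        lab = sp.label
        i = index.get(lab)
        if i is None:
            if len(species) >= max_species:
                raise NetworkError(
                    f"species cap exceeded ({max_species}); rule set may not close"
                )
            i = len(species)
            species.append(sp)
            index[lab] = i
            queue.append(i)
        return i

    queue: list[int] = []
    for seed_sp, amount in model.seeds:
        if not seed_sp.is_connected():
            raise NetworkError("seed species must be connected")
        seeds.append((get_or_add(seed_sp), amount))
    for sp in extra_seeds or ():
        get_or_add(sp)

    # Per directed rule: species registered as matches of each reactant slot.
    matches: list[list[list[tuple[int, list[tuple[int, ...]]]]]] = [
        [[] for _ in dr.reactants] for dr in drules
    ]
    reactions: dict[tuple, Reaction] = {}

    def record(dr: _DirectedRule, ridx: tuple[int, ...],
               embs: list[tuple[int, ...]]) -> None:
        prods = _apply(dr, [species[i] for i in ridx], list(embs))
        pidx = tuple(sorted(get_or_add(p) for p in prods))
        key = (dr.rule_id, dr.direction, tuple(sorted(ridx)), pidx)
        rx = reactions.get(key)
        if rx is None:
            reactions[key] = Reaction(dr.rule_id, dr.direction, tuple(sorted(ridx)),
                                      pidx, dr.rate_ref, dr.stat_factor)
        else:
            rx.multiplicity += 1

    head = 0
    while head < len(queue):
        s = queue[head]
        head += 1
        for di, dr in enumerate(drules):
            embs = [find_embeddings(p, species[s]) for p in dr.reactants]
            if len(dr.reactants) == 1:
                for e in embs[0]:
                    record(dr, (s,), [e])
            else:
                embs_a, embs_b = embs
                if embs_a:
                    for b_idx, b_embs in matches[di][1]:
                        for ea in embs_a:
                            for eb in b_embs:
                                record(dr, (s, b_idx), [ea, eb])
                if embs_b:
                    for a_idx, a_embs in matches[di][0]:
                        for ea in a_embs:
                            for eb in embs_b:
                                record(dr, (a_idx, s), [ea, eb])
                if embs_a and embs_b:
                    for ea in embs_a:
                        for eb in embs_b:
                            record(dr, (s, s), [ea, eb])
                if embs_a:
                    matches[di][0].append((s, embs_a))
                if embs_b:
                    matches[di][1].append((s, embs_b))

    return ReactionNetwork(species, list(reactions.values()), seeds,
                           model_name=model.name)


def verify_closure(network: ReactionNetwork, model: Model) -> bool:
    """True if re-expanding with every network species as a seed adds nothing."""
    net2 = expand_network(model, extra_seeds=network.species)
    return net2.n_species == network.n_species


# ---------------------------------------------------------------------------
# Plain-text network format
# ---------------------------------------------------------------------------


def write_network(network: ReactionNetwork) -> str:
    lines = [
        "# autoswitch reaction network v1",
        f"# model: {network.model_name}",
        f"# species: {network.n_species}  reactions: {network.n_reactions}",
        "begin species",
    ]
    seed_map = dict(network.seeds)
    for i, sp in enumerate(network.species):
        amount = seed_map.get(i, 0)
        lines.append(f"  {i + 1} {sp.label} {amount}")
    lines.append("end species")
    lines.append("begin reactions")
    for k, rx in enumerate(network.reactions):
        r = ",".join(str(i + 1) for i in rx.reactants)
        p = ",".join(str(i + 1) for i in rx.products)
        lines.append(
            f"  {k + 1} {r} {p} {rx.rate_ref} factor={rx.stat_factor:g} "
            f"mult={rx.multiplicity} rule={rx.rule_id} dir={rx.direction}"
        )
    lines.append("end reactions")
    return "\n".join(lines) + "\n"


def read_network(text: str) -> ReactionNetwork:
    """Parse the plain-text network format; inverse of :func:`write_network`."""
    from .bngl import BnglParseError, parse_species

    species: list[SpeciesGraph] = []
    seeds: list[tuple[int, Union[str, float]]] = []
    reactions: list[Reaction] = []
    model_name = ""
    block = None
    for no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("# model:"):
            model_name = line.split(":", 1)[1].strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("begin "):
            block = line[6:].strip()
            continue
        if line.startswith("end "):
            block = None
            continue
        try:
            if block == "species":
                idx_s, label, amount = line.split()
                if int(idx_s) != len(species) + 1:
                    raise ValueError("species indices must be consecutive")
                species.append(parse_species(label))
                try:
                    val = float(amount)
                    if val != 0:
                        seeds.append((len(species) - 1, val))
                except ValueError:
                    seeds.append((len(species) - 1, amount))
            elif block == "reactions":
                toks = line.split()
                _, r, p, rate_ref = toks[:4]
                extras = dict(t.split("=", 1) for t in toks[4:])
                reactions.append(Reaction(
                    rule_id=extras["rule"],
                    direction=extras.get("dir", "fwd"),
                    reactants=tuple(int(x) - 1 for x in r.split(",")),
                    products=tuple(int(x) - 1 for x in p.split(",")),
                    rate_ref=rate_ref,
                    stat_factor=float(extras.get("factor", 1.0)),
                    multiplicity=int(extras.get("mult", 1)),
                ))
            elif block is not None:
                raise ValueError(f"unknown block {block!r}")
            else:
                raise ValueError(f"content outside any block: {line!r}")
        except (ValueError, KeyError, GraphError, BnglParseError) as exc:
            raise NetworkError(f"line {no}: {exc}") from None
    return ReactionNetwork(species, reactions, seeds, model_name=model_name)
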