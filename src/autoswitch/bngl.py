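"""Reading and writing the BNGL-dialect model format.

Only the constructs used by this model family are supported: molecule type
declarations, parameters, seed species, and reaction rules for binding,
unbinding and state change with mass-action rates (optionally prefixed by an
integer statistical factor, e.g. ``2*p4``).  This is deliberately not a
general-purpose BNGL compiler.
"""

from __future__ import annotations

import re
from typing import Optional, Union

from .graphs import (
    FREE,
    Molecule,
    PatternGraph,
    PatternMolecule,
    PatternSite,
    SpeciesGraph,
    unparse_pattern,
)
from .model import (
    Model,
    ModelSpecError,
    MoleculeTypeDef,
    RewriteRule,
    SiteDef,
)


class BnglParseError(ValueError):
    def __init__(self, message: str, line_no: Optional[int] = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


#: Transcription variants of site names mapped to their canonical form.
SITE_ALIASES: dict[str, str] = {
    "S855_Ser859": "S855_S859",
    "S855-9": "S855_S859",
}

_MOL_RE = re.compile(r"([A-Za-z_]\w*)\(([^()]*)\)\Z")
_SITE_RE = re.compile(r"([A-Za-z_][\w\-]*)((?:~\w+)*)(?:!(\d+|\?|\+))?\Z")


def _split_sites(body: str) -> list[str]:
    return [tok.strip() for tok in body.split(",") if tok.strip()]


def _parse_molecule_token(text: str) -> tuple[str, list[tuple[str, tuple[str, ...], Optional[str]]]]:
    """Parse ``Name(site~s1~s2!b,...)`` -> (name, [(site, states, bond_token)])."""
    m = _MOL_RE.match(text.strip())
    if not m:
        raise BnglParseError(f"malformed molecule: {text!r}")
    name, body = m.group(1), m.group(2)
    sites = []
    for tok in _split_sites(body):
        sm = _SITE_RE.match(tok)
        if not sm:
            raise BnglParseError(f"malformed site token {tok!r} in {text!r}")
        raw_site, states_blob, bond = sm.group(1), sm.group(2), sm.group(3)
        site = SITE_ALIASES.get(raw_site, raw_site)
        states = tuple(s for s in states_blob.split("~") if s) if states_blob else ()
        sites.append((site, states, bond))
    return name, sites


def parse_molecule_type(text: str) -> MoleculeTypeDef:
    name, sites = _parse_molecule_token(text)
    defs = []
    for site, states, bond in sites:
        if bond is not None:
            raise BnglParseError(f"bond in molecule type declaration: {text!r}")
        defs.append(SiteDef(site, states))
    return MoleculeTypeDef(name, tuple(defs))


def parse_pattern(text: str) -> PatternGraph:
    """Parse one connected pattern (molecules joined by ``.``).

    BNGL pattern semantics: a mentioned site without a bond token must be
    unbound; ``!n`` ties it into pattern bond ``n``; ``!?`` leaves the binding
    status unconstrained; unmentioned sites are unconstrained.
    """
    mols = []
    for chunk in text.split("."):
        name, sites = _parse_molecule_token(chunk)
        psites: dict[str, PatternSite] = {}
        for site, states, bond in sites:
            if len(states) > 1:
                raise BnglParseError(f"multiple states in pattern site: {chunk!r}")
            state = states[0] if states else None
            if bond is None:
                bcond: Union[int, str, None] = FREE
            elif bond == "?":
                bcond = None
            elif bond == "+":
                raise BnglParseError("wildcard bond '!+' is not supported")
            else:
                bcond = int(bond)
            if site in psites:
                raise BnglParseError(f"duplicate site {site} in pattern {chunk!r}")
            psites[site] = PatternSite(state=state, bond=bcond)
        mols.append(PatternMolecule(name, psites))
    return PatternGraph(mols)


def parse_species(text: str, molecule_types: Optional[dict[str, MoleculeTypeDef]] = None
                  ) -> SpeciesGraph:
    """Parse a fully specified species string into a :class:`SpeciesGraph`.

    With ``molecule_types`` given, unmentioned sites are filled in as unbound
    with their default state and mentioned sites are checked against the
    declaration; otherwise the string must be self-contained.
    """
    mols: list[Molecule] = []
    endpoints: dict[int, list[tuple[int, str]]] = {}
    for i, chunk in enumerate(text.split(".")):
        name, sites = _parse_molecule_token(chunk)
        site_map: dict[str, Optional[str]] = {}
        for site, states, bond in sites:
            if len(states) > 1:
                raise BnglParseError(f"species site with several states: {chunk!r}")
            site_map[site] = states[0] if states else None
            if bond is not None:
                if bond in ("?", "+"):
                    raise BnglParseError(f"wildcard bond in species: {chunk!r}")
                endpoints.setdefault(int(bond), []).append((i, site))
        if molecule_types is not None:
            mt = molecule_types.get(name)
            if mt is None:
                raise BnglParseError(f"undeclared molecule type {name!r}")
            for sd in mt.sites:
                if sd.name not in site_map:
                    site_map[sd.name] = sd.states[0] if sd.states else None
                elif sd.states and site_map[sd.name] not in sd.states:
                    raise BnglParseError(
                        f"invalid state {site_map[sd.name]!r} for {name}.{sd.name}"
                    )
        mols.append(Molecule(name, site_map))
    pairs = []
    for bid, eps in endpoints.items():
        if len(eps) != 2:
            raise BnglParseError(f"bond id {bid} appears {len(eps)} time(s) in {text!r}")
        pairs.append((eps[0], eps[1]))
    return SpeciesGraph.from_bond_list(mols, pairs)


_RATE_RE = re.compile(r"(?:(\d+(?:\.\d+)?)\*)?([A-Za-z_]\w*)\Z")


def _parse_rate(text: str) -> tuple[float, str]:
    m = _RATE_RE.match(text.strip())
    if not m:
        raise BnglParseError(f"malformed rate expression {text!r}")
    factor = float(m.group(1)) if m.group(1) else 1.0
    return factor, m.group(2)


def _parse_side(text: str) -> list[PatternGraph]:
    # "+" separates reactant (product) patterns; "." joins molecules within one.
    return [parse_pattern(chunk.strip()) for chunk in text.split("+")]


def parse_rule(rule_id: str, text: str,
               molecule_types: Optional[dict[str, MoleculeTypeDef]] = None) -> RewriteRule:
    """Parse one reaction rule line (without its leading label)."""
    text = text.replace("\\", " ").strip()
    bidirectional = "<->" in text
    arrow = "<->" if bidirectional else "->"
    try:
        lhs, rhs_and_rates = text.split(arrow)
    except ValueError as exc:
        raise BnglParseError(f"rule {rule_id}: expected single {arrow!r}") from exc
    idx = rhs_and_rates.rindex(")")
    rhs = rhs_and_rates[: idx + 1]
    rate_blob = rhs_and_rates[idx + 1:].strip()
    rates = [r.strip() for r in rate_blob.split(",") if r.strip()]
    if bidirectional and len(rates) != 2:
        raise BnglParseError(f"rule {rule_id}: bidirectional rule needs two rates")
    if not bidirectional and len(rates) != 1:
        raise BnglParseError(f"rule {rule_id}: expected one rate, got {rates!r}")
    stat_factor, rate_ref = _parse_rate(rates[0])
    reverse_ref = None
    if bidirectional:
        rev_factor, reverse_ref = _parse_rate(rates[1])
        if rev_factor != 1.0:
            raise BnglParseError(f"rule {rule_id}: factor on reverse rate unsupported")
    return RewriteRule(
        id=rule_id,
        reactants=_parse_side(lhs),
        products=_parse_side(rhs),
        rate_ref=rate_ref,
        stat_factor=stat_factor,
        bidirectional=bidirectional,
        reverse_rate_ref=reverse_ref,
    )


# ---------------------------------------------------------------------------
# Whole-model files
# ---------------------------------------------------------------------------

_BLOCKS = ("parameters", "molecule types", "seed species", "reaction rules")


def parse_model(text: str, name: str = "parsed") -> Model:
    """Parse a model file (blocks: parameters, molecule types, seed species,
    reaction rules) into a :class:`Model`.  Raises :class:`BnglParseError`
    with a line number on malformed input."""
    params: dict[str, float] = {}
    mol_types: dict[str, MoleculeTypeDef] = {}
    seeds: list[tuple[SpeciesGraph, Union[str, float]]] = []
    rules: list[RewriteRule] = []
    block: Optional[str] = None
    auto_rule = 0

    # Join continuation lines first, keeping original numbering for messages.
    logical: list[tuple[int, str]] = []
    pending: Optional[tuple[int, str]] = None
    for no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if pending is not None:
            line = pending[1] + " " + line.strip()
            no = pending[0]
            pending = None
        if line.rstrip().endswith("\\"):
            pending = (no, line.rstrip()[:-1].strip())
            continue
        logical.append((no, line.strip()))
    if pending is not None:
        logical.append(pending)

    for no, line in logical:
        try:
            if line.startswith("begin "):
                blk = line[len("begin "):].strip()
                if blk not in _BLOCKS:
                    raise BnglParseError(f"unknown block {blk!r}")
                block = blk
                continue
            if line.startswith("end "):
                block = None
                continue
            if block == "parameters":
                key, _, value = line.partition(" ")
                params[key.strip()] = float(value)
            elif block == "molecule types":
                mt = parse_molecule_type(line)
                mol_types[mt.name] = mt
            elif block == "seed species":
                idx = line.rindex(")")
                species = parse_species(line[: idx + 1], mol_types or None)
                amount = line[idx + 1:].strip()
                try:
                    seeds.append((species, float(amount)))
                except ValueError:
                    seeds.append((species, amount))
            elif block == "reaction rules":
                label_match = re.match(r"([\w]+):\s*(.*)\Z", line)
                if label_match:
                    rid, body = label_match.group(1), label_match.group(2)
                else:
                    auto_rule += 1
                    rid, body = f"R{auto_rule}", line
                rules.append(parse_rule(rid, body, mol_types or None))
            else:
                raise BnglParseError(f"content outside any block: {line!r}")
        except BnglParseError as exc:
            if exc.line_no is None:
                raise BnglParseError(str(exc), no) from None
            raise
        except (ValueError, ModelSpecError) as exc:
            raise BnglParseError(str(exc), no) from None

    return Model(
        name=name,
        molecule_types=mol_types,
        rules=rules,
        params=params,
        seeds=seeds,
    )


def _molecule_type_str(mt: MoleculeTypeDef) -> str:
    toks = []
    for sd in mt.sites:
        tok = sd.name + "".join("~" + s for s in sd.states)
        toks.append(tok)
    return f"{mt.name}({','.join(toks)})"


def _rate_str(factor: float, ref: str) -> str:
    if factor == 1.0:
        return ref
    if factor == int(factor):
        return f"{int(factor)}*{ref}"
    return f"{factor}*{ref}"


def write_model(model: Model) -> str:
    """Serialize a model to the BNGL dialect; ``parse_model`` round-trips it."""
    lines = [f"# model: {model.name}", "begin parameters"]
    for key, value in model.params.items():
        lines.append(f"  {key} {value!r}")
    lines.append("end parameters")
    lines.append("begin molecule types")
    for mt in model.molecule_types.values():
        lines.append("  " + _molecule_type_str(mt))
    lines.append("end molecule types")
    lines.append("begin seed species")
    for species, amount in model.seeds:
        lines.append(f"  {species.label} {amount}")
    lines.append("end seed species")
    lines.append("begin reaction rules")
    for rule in model.rules:
        arrow = "<->" if rule.bidirectional else "->"
        lhs = " + ".join(unparse_pattern(p) for p in rule.reactants)
        rhs = " + ".join(unparse_pattern(p) for p in rule.products)
        rate = _rate_str(rule.stat_factor, rule.rate_ref)
        if rule.bidirectional:
            rate += f", {rule.reverse_rate_ref}"
        lines.append(f"  {rule.id}: {lhs} {arrow} {rhs} {rate}")
    lines.append("end reaction rules")
    return "\n".join(lines) + "\n"


def load_model(path) -> Model:
    with open(path) as fh:
        return parse_model(fh.read(), name=str(path))
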