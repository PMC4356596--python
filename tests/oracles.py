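"""Independent brute-force oracles used to cross-check the graph engine.

These deliberately avoid the library's matching and labeling code paths:
embeddings are found by exhaustive enumeration of injective molecule maps,
and label invariance is checked by explicitly permuting molecule instances.
"""

from itertools import permutations

from autoswitch.graphs import FREE, SpeciesGraph


def brute_force_embeddings(pattern, species):
    """All embeddings by exhaustive enumeration over injective molecule maps."""
    n_p, n_s = len(pattern.molecules), len(species.molecules)
    found = []
    for perm in permutations(range(n_s), n_p):
        ok = True
        for pi, pm in enumerate(pattern.molecules):
            mol = species.molecules[perm[pi]]
            if mol.type != pm.type:
                ok = False
                break
            for site, ps in pm.sites.items():
                if site not in mol.sites:
                    ok = False
                    break
                if ps.state is not None and mol.sites[site] != ps.state:
                    ok = False
                    break
                bound = (perm[pi], site) in species.bonds
                if ps.bond is FREE and bound:
                    ok = False
                    break
                if isinstance(ps.bond, int) and not bound:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        # every pattern bond must map onto a species bond
        for (i, s1), (j, s2) in pattern.bonds:
            if species.bonds.get((perm[i], s1)) != (perm[j], s2):
                ok = False
                break
        if ok:
            found.append(perm)
    return found


def permuted_copy(species, perm):
    """Rebuild a species graph with its molecule instances reordered."""
    inv = {old: new for new, old in enumerate(perm)}
    mols = [species.molecules[old].copy() for old in perm]
    bonds = {}
    for (i, s1), (j, s2) in species.bonds.items():
        bonds[(inv[i], s1)] = (inv[j], s2)
    return SpeciesGraph(mols, bonds)


def all_permutation_labels(species):
    """Canonical labels of every molecule-order permutation of a species."""
    n = len(species.molecules)
    return {
        permuted_copy(species, perm).label for perm in permutations(range(n))
    }
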