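"""Shared builders and independent oracles used across the test suite."""

from __future__ import annotations

import math

import numpy as np

from homolig.structure import (AtomRecord, BindingSite, Chain, LigandInstance,
                               PolymerResidue, StructureComplex)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def pdb_line(serial, name, resname, chain, resnum, x, y, z,
             element, het=False, occ=1.0, altloc=" ", icode=" ") -> str:
    record = "HETATM" if het else "ATOM"
    return (f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:>3} {chain}"
            f"{resnum:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
            f"{20.0:6.2f}          {element:>2}")


def make_complex(chains, ligands, structure_id="SYN") -> StructureComplex:
    """Build an in-memory complex.

    chains: {chain_id: [(resnum, one_letter, [xyz, ...]), ...]}
    ligands: [(code, [xyz, ...]), ...]  (carbon atoms)
    """
    serial = [0]

    def atom(xyz, rid, rname, polymer):
        serial[0] += 1
        return AtomRecord(serial[0], "C", tuple(float(v) for v in xyz),
                          rid, rname, polymer)

    built_chains = []
    for cid, residues in chains.items():
        recs = []
        for num, aa, coords in residues:
            res = PolymerResidue(num, "", "UNK", aa)
            res.atoms = [atom(xyz, (cid, num, ""), "UNK", True)
                         for xyz in coords]
            recs.append(res)
        built_chains.append(Chain(cid, recs))
    built_ligands = []
    for i, (code, coords) in enumerate(ligands):
        lig = LigandInstance(code, f"X:{i+1}")
        lig.atoms = [atom(xyz, ("X", i + 1, ""), code, False)
                     for xyz in coords]
        built_ligands.append(lig)
    return StructureComplex(structure_id, built_chains, built_ligands)


def random_complex(rng: np.random.Generator, max_atoms: int = 200,
                   box: float = 14.0) -> StructureComplex:
    """A random complex with one or two chains and one multi-atom ligand."""
    n_chains = int(rng.integers(1, 3))
    n_lig = int(rng.integers(5, 12))
    budget = int(rng.integers(20, max_atoms - n_lig))
    chains = {}
    for c in range(n_chains):
        cid = "AB"[c]
        n_res = max(1, budget // (n_chains * 2))
        residues = []
        for r in range(n_res):
            n_at = int(rng.integers(1, 3))
            coords = rng.uniform(0, box, size=(n_at, 3))
            residues.append((r + 1, AA20[int(rng.integers(20))], coords))
        chains[cid] = residues
    lig_coords = rng.uniform(0, box, size=(n_lig, 3))
    return make_complex(chains, [("LGX", lig_coords)])


def brute_force_contacts(cx: StructureComplex, ligand, cutoff: float):
    """All-pairs O(n^2) distance scan, independent of the KD-tree path."""
    out = {}
    for chain in cx.chains:
        counts = {}
        for res in chain.residues:
            n = 0
            for a in res.atoms:
                for b in ligand.atoms:
                    d = math.dist(a.coords, b.coords)
                    if d <= cutoff:
                        n += 1
            if n:
                counts[res.number] = n
        if counts:
            out[chain.chain_id] = counts
    return out


def make_site(rng: np.random.Generator, n_residues: int = 8,
              start: int = 1, structure_id: str = "SYN",
              chain_id: str = "A") -> BindingSite:
    """A random binding site detached from any geometry."""
    numbers = sorted(rng.choice(np.arange(start, start + 4 * n_residues),
                                size=n_residues, replace=False).tolist())
    residues = [(int(n), AA20[int(rng.integers(20))]) for n in numbers]
    counts = {n: int(rng.integers(1, 6)) for n, _ in residues}
    lig = LigandInstance("LGX", "X:1")
    lig.atoms = [AtomRecord(i + 1, "C", (0.0, 0.0, 0.0), ("X", 1, ""),
                            "LGX", False) for i in range(6)]
    return BindingSite(structure_id, chain_id, lig, residues, counts)


def split_complex(n_a_contacts, n_b_contacts, res_a, res_b):
    """Two chains around a ligand with controlled atom-pair contact counts.

    The ligand has six carbons (passes the size filters: MW ~72); only the
    first sits near the chains, so each placed chain atom contributes exactly
    one atom-pair contact.
    """
    lig = [(0.0, 0.0, 0.0)] + [(0.0, 0.0, 30.0 + 3 * i) for i in range(5)]
    chains = {"A": [], "B": []}
    for cid, n_contacts, n_res, x in (("A", n_a_contacts, res_a, 3.0),
                                      ("B", n_b_contacts, res_b, -3.0)):
        per = [n_contacts // n_res] * n_res
        for i in range(n_contacts % n_res):
            per[i] += 1
        for i, k in enumerate(per):
            coords = [(x, 0.2 * i + 0.01 * j, 0.0) for j in range(k)] \
                or [(math.copysign(60.0 + i, x), 0.0, 0.0)]
            chains[cid].append((i + 1, "A", coords))
    return make_complex(chains, [("LGX", lig)])


def identity_composed(site_pairs):
    """Composed alignment aligning each (res, aa) to itself, all equivalent."""
    from homolig.align import ComposedAlignment, ComposedPair
    pairs = [ComposedPair(n, n, aa, aa, True) for n, aa in site_pairs]
    return ComposedAlignment("A", "A", "Q", pairs)


def scipy_partitions(dist: np.ndarray, cutoffs):
    """Independent complete-linkage oracle via scipy, as frozen partitions."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    Z = linkage(squareform(dist, checks=False), method="complete")
    out = []
    for c in cutoffs:
        labels = fcluster(Z, t=c, criterion="distance")
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, []).append(i)
        out.append(sorted(sorted(g) for g in groups.values()))
    return out


def random_tie_free_distance(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric distance matrix with distinct off-diagonal values."""
    vals = rng.permutation(np.linspace(0.05, 0.95, n * (n - 1) // 2))
    d = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = vals[k]
            k += 1
    return d
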