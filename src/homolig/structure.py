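"""Structure reading and observed binding-site extraction.

A *binding site* is the set of residues on one protein chain with at least
one heavy atom within the contact cutoff (4.0 Å by default, i.e. the sum of
van der Waals radii plus ~0.5 Å tolerance) of any heavy atom of a bound
small molecule.  Sites with fewer than five residues are discarded.  When a
small molecule touches several chains, the site is assigned to a single
chain only if that chain holds at least 75 % of all atom-pair contacts;
otherwise one site per contacting chain is emitted.

Parsing conventions: heavy atoms only (hydrogens dropped on read), waters
excluded, first model of multi-model entries, alternate locations resolved
to the highest occupancy (ties: first listed).  Residues are identified by
author numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, FormatError, LigandLookupError
from .ligands import LigandPolicy, passes_size_filters

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with its residue context."""

    serial: int
    element: str
    coords: tuple[float, float, float]
    residue_id: tuple[str, int, str]   # (chain id, author number, insertion code)
    residue_name: str
    is_polymer: bool


@dataclass
class PolymerResidue:
    number: int
    icode: str
    name: str
    one_letter: str
    atoms: list[AtomRecord] = field(default_factory=list)


@dataclass
class Chain:
    chain_id: str
    residues: list[PolymerResidue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]


@dataclass
class LigandInstance:
    """A candidate small molecule: one non-polymer, non-water residue group."""

    ligand_code: str
    instance_id: str                   # "<chain>:<resnum><icode>"
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atoms)

    @property
    def molecular_weight(self) -> float:
        # Structure files carry no MW; sum standard atomic weights.
        return float(sum(gemmi.Element(a.element).weight for a in self.atoms))

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class StructureComplex:
    id: str
    chains: list[Chain]
    ligands: list[LigandInstance]

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)


@dataclass
class BindingSite:
    """Residues of one chain in contact with one small molecule."""

    structure_id: str
    chain_id: str
    ligand: LigandInstance
    residues: list[tuple[int, str]]            # (author number, one-letter), sorted
    contact_counts: dict[int, int]             # author number -> atom-pair contacts

    @property
    def total_contacts(self) -> int:
        return sum(self.contact_counts.values())

    @property
    def residue_numbers(self) -> list[int]:
        return [n for n, _ in self.residues]


def _one_letter(name: str) -> str:
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    info = gemmi.find_tabulated_residue(name)
    if info and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties first listed."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    # preserve file order
    seen = set()
    out = []
    for atom in residue:
        if atom.name not in seen and chosen[atom.name] is atom:
            out.append(atom)
            seen.add(atom.name)
        elif atom.name not in seen and chosen[atom.name] is not atom:
            out.append(chosen[atom.name])
            seen.add(atom.name)
    return out


def read_structure(path, fmt: str | None = None) -> StructureComplex:
    """Read a PDB or mmCIF file into a :class:`StructureComplex`.

    Parameters
    ----------
    path : str or Path
        Structure file.
    fmt : {"pdb", "mmcif", None}
        Force a format; ``None`` auto-detects from the content.
    """
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model")
    st.setup_entities()
    model = st[0]                      # first model only

    chains: list[Chain] = []
    ligands: list[LigandInstance] = []
    serial = 0
    for ch in model:
        polymer_residues: list[PolymerResidue] = []
        for res in ch:
            if res.is_water() or res.name in ("HOH", "DOD", "WAT"):
                continue
            atoms = []
            for atom in _resolve_altlocs(res):
                if atom.element.is_hydrogen:
                    continue
                pos = atom.pos
                if not all(np.isfinite([pos.x, pos.y, pos.z])):
                    raise FormatError(
                        f"{path}: non-finite coordinates in atom {atom.name} "
                        f"of {res.name} {ch.name}{res.seqid.num}")
                serial += 1
                atoms.append((atom, pos))
            if not atoms:
                continue
            is_polymer = res.entity_type == gemmi.EntityType.Polymer
            if res.entity_type == gemmi.EntityType.Unknown:
                # minimal files: fall back on the record type
                is_polymer = res.het_flag == "A"
            icode = res.seqid.icode.strip()
            if is_polymer:
                rec = PolymerResidue(res.seqid.num, icode, res.name, _one_letter(res.name))
                rec.atoms = [
                    AtomRecord(a.serial, a.element.name,
                               (p.x, p.y, p.z), (ch.name, res.seqid.num, icode),
                               res.name, True)
                    for a, p in atoms
                ]
                polymer_residues.append(rec)
            else:
                inst = LigandInstance(res.name, f"{ch.name}:{res.seqid.num}{icode}")
                inst.atoms = [
                    AtomRecord(a.serial, a.element.name,
                               (p.x, p.y, p.z), (ch.name, res.seqid.num, icode),
                               res.name, False)
                    for a, p in atoms
                ]
                ligands.append(inst)
        if polymer_residues:
            chains.append(Chain(ch.name, polymer_residues))
    if not chains:
        raise EmptyStructureError(f"{path}: structure has no polymer chain")
    return StructureComplex(st.name or str(path), chains, ligands)


def find_contacts(complex_: StructureComplex, ligand: LigandInstance,
                  cutoff: float = 4.0) -> dict[str, dict[int, int]]:
    """Per-chain map residue -> number of heavy-atom pairs within *cutoff*.

    The comparison is inclusive (distance <= cutoff).  A residue is reported
    iff at least one of its heavy atoms is within cutoff of a ligand heavy
    atom; the count is the number of such atom pairs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if ligand not in complex_.ligands:
        raise LigandLookupError(
            f"ligand {ligand.instance_id} not part of complex {complex_.id}")
    lig_coords = ligand.coords_array()
    tree = cKDTree(lig_coords)
    out: dict[str, dict[int, int]] = {}
    for chain in complex_.chains:
        counts: dict[int, int] = {}
        for res in chain.residues:
            if not res.atoms:
                continue
            coords = np.array([a.coords for a in res.atoms], dtype=float)
            n_pairs = int(sum(len(hits) for hits in
                              tree.query_ball_point(coords, cutoff)))
            if n_pairs > 0:
                counts[res.number] = n_pairs
        if counts:
            out[chain.chain_id] = counts
    return out


def extract_binding_sites(complex_: StructureComplex,
                          policy: LigandPolicy | None = None,
                          cutoff: float = 4.0,
                          min_residues: int = 5,
                          chain_majority: float = 0.75) -> list[BindingSite]:
    """Observed binding sites for every ligand passing the size filters.

    If a single chain holds >= *chain_majority* of all atom-pair contacts,
    one site is emitted on that chain only; otherwise one per contacting
    chain.  Sites with fewer than *min_residues* residues are dropped.
    """
    policy = policy or LigandPolicy()
    sites: list[BindingSite] = []
    for ligand in complex_.ligands:
        if not passes_size_filters(ligand, policy):
            continue
        per_chain = find_contacts(complex_, ligand, cutoff=cutoff)
        if not per_chain:
            continue
        total = sum(sum(c.values()) for c in per_chain.values())
        majority = [cid for cid, c in per_chain.items()
                    if sum(c.values()) / total >= chain_majority]
        chosen = majority[:1] if majority else sorted(per_chain)
        for cid in chosen:
            counts = per_chain[cid]
            if len(counts) < min_residues:
                continue
            chain = complex_.chain(cid)
            letters = {r.number: r.one_letter for r in chain.residues}
            residues = sorted((n, letters[n]) for n in counts)
            sites.append(BindingSite(complex_.id, cid, ligand, residues, dict(counts)))
    return sites


def write_sites_tsv(sites: Iterable[BindingSite], path) -> None:
    """Write binding sites as TSV, one row per site residue."""
    with open(path, "w") as fh:
        fh.write("structure_id\tchain\tligand_code\tligand_instance\t"
                 "residue_number\tresidue_code\tcontact_count\n")
        for site in sites:
            for num, aa in site.residues:
                fh.write(f"{site.structure_id}\t{site.chain_id}\t"
                         f"{site.ligand.ligand_code}\t{site.ligand.instance_id}\t"
                         f"{num}\t{aa}\t{site.contact_counts[num]}\n")
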