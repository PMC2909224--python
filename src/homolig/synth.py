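"""Seeded synthetic homolog families for end-to-end testing.

The generator emits everything the pipeline consumes — PDB structures,
query-neighbor alignment TSVs, a gold-annotation TSV and a JSON manifest —
with planted signal:

* a *conserved pocket* whose residues carry a probe atom placed within the
  4.0 Å contact cutoff of a shared ligand (mutation-free by default, so the
  observed sites are identical across carriers);
* a *decoy pocket* binding a second compound with heavily mutated residues;
* a *crystallization agent* (glycerol by default, on the shipped
  non-biological list) bound at its own recurring pocket;
* an identity ladder: each member's whole-chain identity to the query is
  planted by mutating non-pocket positions.

Geometry is deliberately coarse: one CA pseudo-atom per residue on an
extended trace (3.8 Å spacing), plus one side-chain probe atom per pocket
residue pointing at the ligand.  The contact rule needs only distances, so
nothing more realistic is claimed: pocket residues sit within the cutoff by
construction and every other residue is kept well outside it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import GenerationError
from .structure import ONE_TO_THREE

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CA_SPACING = 3.8          # Å between consecutive pseudo-CA atoms
LIGAND_OFFSET = 9.0       # Å from the trace to a ligand centroid
PROBE_DISTANCE = 3.0      # Å from a ligand atom to the pocket probe atom

# atom name / element templates per ligand code; GOL matches glycerol's
# heavy-atom composition so it passes the size filters like the real thing
LIGAND_TEMPLATES = {
    "LIG": [("C1", "C"), ("N1", "N"), ("O1", "O"), ("C2", "C"),
            ("N2", "N"), ("O2", "O"), ("C3", "C"), ("N3", "N"),
            ("O3", "O"), ("C4", "C"), ("N4", "N"), ("O4", "O")],
    "DCY": [("C1", "C"), ("C2", "C"), ("O1", "O"), ("N1", "N"),
            ("C3", "C"), ("O2", "O"), ("C4", "C"), ("N2", "N")],
    "GOL": [("C1", "C"), ("C2", "C"), ("C3", "C"),
            ("O1", "O"), ("O2", "O"), ("O3", "O")],
}


@dataclass(frozen=True)
class FamilySpec:
    n_members: int = 6
    seed: int = 0
    chain_length: int = 60
    query_id: str = "QUERY"
    # conserved planted pocket
    pocket_positions: tuple = (12, 15, 19, 22, 26, 29, 33, 36)
    pocket_ligand: str = "LIG"
    pocket_mutation_rate: float = 0.0
    pocket_carrier_fraction: float = 1.0
    # variable decoy pocket
    decoy_positions: tuple = (44, 47, 50, 53, 56)
    decoy_ligand: str = "DCY"
    decoy_mutation_rate: float = 0.5
    decoy_carrier_fraction: float = 0.4
    # crystallization agent at a recurring location
    agent_positions: tuple = (3, 5, 7, 9, 11)
    agent_ligand: str = "GOL"
    agent_rate: float = 0.5
    # target whole-chain identities of members to the query
    identity_ladder: tuple = (0.95, 0.85, 0.75, 0.65, 0.55, 0.45)

    def __post_init__(self):
        for rate in (self.pocket_mutation_rate, self.decoy_mutation_rate,
                     self.pocket_carrier_fraction, self.decoy_carrier_fraction,
                     self.agent_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        pockets = [set(self.pocket_positions), set(self.decoy_positions),
                   set(self.agent_positions)]
        for i in range(len(pockets)):
            for j in range(i + 1, len(pockets)):
                if pockets[i] & pockets[j]:
                    raise ValueError("pockets overlap in sequence")
        for pos in set().union(*pockets):
            if not 1 <= pos <= self.chain_length:
                raise ValueError("pocket position outside the chain")
        if len(self.identity_ladder) not in (0, self.n_members):
            raise ValueError("identity ladder length must equal n_members")


@dataclass
class FamilyBundle:
    directory: Path
    query_id: str
    member_ids: list[str]
    structure_paths: dict[str, Path]
    alignment_paths: dict[str, Path]
    gold_path: Path | None
    manifest_path: Path
    manifest: dict


def _ca_coords(length: int) -> np.ndarray:
    coords = np.zeros((length, 3))
    coords[:, 0] = CA_SPACING * np.arange(length)
    return coords


def _ligand_coords(center: np.ndarray, template, rng) -> np.ndarray:
    offsets = rng.uniform(-1.2, 1.2, size=(len(template), 3))
    return center + offsets


def _probe_coords(ca: np.ndarray, ligand_xyz: np.ndarray) -> np.ndarray:
    """Probe atom on the segment ligand-atom -> CA, PROBE_DISTANCE from the
    nearest ligand atom."""
    d = np.linalg.norm(ligand_xyz - ca, axis=1)
    nearest = ligand_xyz[int(np.argmin(d))]
    vec = ca - nearest
    norm = np.linalg.norm(vec)
    if norm < PROBE_DISTANCE:
        raise GenerationError(
            "pocket residue too close to the ligand for a probe atom")
    return nearest + vec / norm * PROBE_DISTANCE


def _pocket_geometry(positions, template, ca, rng):
    center = np.array([
        float(np.mean([ca[p - 1, 0] for p in positions])), LIGAND_OFFSET, 0.0])
    lig = _ligand_coords(center, template, rng)
    if np.min(np.linalg.norm(lig[:, None, :] - ca[None, :, :], axis=2)) <= 4.2:
        raise GenerationError("ligand atoms fall too close to the backbone trace")
    probes = {p: _probe_coords(ca[p - 1], lig) for p in positions}
    return lig, probes


def _mutate(base: list[str], spec: FamilySpec, target_identity: float,
            carried_decoy: bool, rng) -> list[str]:
    """Plant the member sequence: exactly round((1-t)*L) mutations, drawn
    first from the decoy pocket (per its rate, if carried), then the
    conserved pocket (per its rate), then random non-pocket positions."""
    length = spec.chain_length
    m_total = int(round((1.0 - target_identity) * length))
    mutate_at: list[int] = []
    if carried_decoy and spec.decoy_mutation_rate > 0:
        for p in spec.decoy_positions:
            if len(mutate_at) < m_total and rng.random() < spec.decoy_mutation_rate:
                mutate_at.append(p)
    if spec.pocket_mutation_rate > 0:
        for p in spec.pocket_positions:
            if len(mutate_at) < m_total and rng.random() < spec.pocket_mutation_rate:
                mutate_at.append(p)
    protected = (set(spec.pocket_positions) | set(spec.decoy_positions)
                 | set(spec.agent_positions))
    free = [p for p in range(1, length + 1) if p not in protected]
    n_rest = m_total - len(mutate_at)
    if n_rest > len(free):
        raise GenerationError(
            f"identity target {target_identity} needs {n_rest} free positions, "
            f"only {len(free)} outside the pockets")
    if n_rest > 0:
        mutate_at.extend(int(p) for p in
                         rng.choice(free, size=n_rest, replace=False))
    seq = list(base)
    for p in mutate_at:
        current = seq[p - 1]
        choices = [a for a in AA20 if a != current]
        seq[p - 1] = choices[int(rng.integers(len(choices)))]
    return seq


def _build_structure(name: str, sequence: list[str], ca: np.ndarray,
                     probes: dict[int, np.ndarray],
                     ligands: list[tuple[str, np.ndarray]]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for i, aa in enumerate(sequence):
        res = gemmi.Residue()
        res.name = ONE_TO_THREE[aa]
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*ca[i])
        atom.occ = 1.0
        res.add_atom(atom)
        if (i + 1) in probes:
            probe = gemmi.Atom()
            probe.name = "CB"
            probe.element = gemmi.Element("C")
            probe.pos = gemmi.Position(*probes[i + 1])
            probe.occ = 1.0
            res.add_atom(probe)
        chain.add_residue(res)
    model.add_chain(chain)
    lig_chain = gemmi.Chain("X")
    for k, (code, coords) in enumerate(ligands):
        res = gemmi.Residue()
        res.name = code
        res.seqid = gemmi.SeqId(k + 1, " ")
        res.het_flag = "H"
        for (atom_name, element), xyz in zip(LIGAND_TEMPLATES[code], coords):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
        lig_chain.add_residue(res)
    if len(lig_chain) > 0:
        model.add_chain(lig_chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _write_alignment(path: Path, query_id: str, member_id: str,
                     query_seq: list[str], member_seq: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# query: {query_id}\n# neighbor: {member_id}\n")
        fh.write("query_res\tneighbor_res\tq_aa\tn_aa\tequiv\n")
        for k, (qa, na) in enumerate(zip(query_seq, member_seq), start=1):
            fh.write(f"{k}\t{k}\t{qa}\t{na}\t1\n")


def generate_family(spec: FamilySpec, out_dir) -> FamilyBundle:
    """Generate a seeded homolog family; byte-identical for a given seed."""
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    (out_dir / "alignments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    length = spec.chain_length
    base = [AA20[int(i)] for i in rng.integers(0, 20, size=length)]
    ca = _ca_coords(length)

    pocket_lig, pocket_probes = _pocket_geometry(
        spec.pocket_positions, LIGAND_TEMPLATES[spec.pocket_ligand], ca, rng)
    decoy_lig, decoy_probes = _pocket_geometry(
        spec.decoy_positions, LIGAND_TEMPLATES[spec.decoy_ligand], ca, rng)
    agent_lig, agent_probes = _pocket_geometry(
        spec.agent_positions, LIGAND_TEMPLATES[spec.agent_ligand], ca, rng)

    ladder = spec.identity_ladder or tuple([1.0] * spec.n_members)
    n_pocket_carriers = int(round(spec.pocket_carrier_fraction * spec.n_members))
    n_decoy_carriers = int(round(spec.decoy_carrier_fraction * spec.n_members))
    n_agent_carriers = int(round(spec.agent_rate * spec.n_members))

    member_ids = [f"HOM{i+1}" for i in range(spec.n_members)]
    structures: dict[str, Path] = {}
    alignments: dict[str, Path] = {}
    members_meta = []
    for i, member in enumerate(member_ids):
        carries_pocket = i < n_pocket_carriers
        carries_decoy = i >= spec.n_members - n_decoy_carriers
        carries_agent = i < n_agent_carriers
        seq = _mutate(base, spec, ladder[i], carries_decoy, rng)
        probes: dict[int, np.ndarray] = {}
        ligands: list[tuple[str, np.ndarray]] = []
        if carries_pocket:
            probes.update(pocket_probes)
            ligands.append((spec.pocket_ligand, pocket_lig))
        if carries_decoy:
            probes.update(decoy_probes)
            ligands.append((spec.decoy_ligand, decoy_lig))
        if carries_agent:
            probes.update(agent_probes)
            ligands.append((spec.agent_ligand, agent_lig))
        st = _build_structure(member, seq, ca, probes, ligands)
        spath = out_dir / "structures" / f"{member}.pdb"
        st.write_pdb(str(spath))
        structures[member] = spath
        apath = out_dir / "alignments" / f"{spec.query_id}__{member}.aln.tsv"
        _write_alignment(apath, spec.query_id, member, base, seq)
        alignments[member] = apath
        realized = sum(b == s for b, s in zip(base, seq)) / length
        members_meta.append({
            "id": member, "target_identity": ladder[i],
            "realized_identity": realized,
            "ligands": [code for code, _ in ligands],
        })

    gold_path = out_dir / "gold.tsv"
    with open(gold_path, "w") as fh:
        for p in spec.pocket_positions:
            fh.write(f"{spec.query_id}\t{p}\tpocket\n")

    manifest = {
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
        "query_id": spec.query_id,
        "query_sequence": "".join(base),
        "members": members_meta,
        "planted": {
            "pocket": list(spec.pocket_positions),
            "decoy": list(spec.decoy_positions),
            "agent": list(spec.agent_positions),
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return FamilyBundle(out_dir, spec.query_id, member_ids, structures,
                        alignments, gold_path, manifest_path, manifest)


def generate_negative_controls(spec: FamilySpec, out_dir) -> FamilyBundle:
    """Family with no recurring pocket: each member binds the ligand at its
    own disjoint stretch of the chain, so clustering should yield singletons."""
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    (out_dir / "alignments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    length = spec.chain_length
    window = 6
    stride = window + 2
    if spec.n_members * stride + 2 > length and spec.n_members > 0:
        raise GenerationError("chain too short for disjoint member pockets")
    base = [AA20[int(i)] for i in rng.integers(0, 20, size=length)]
    ca = _ca_coords(length)
    ladder = spec.identity_ladder or tuple([1.0] * spec.n_members)

    member_ids = [f"NEG{i+1}" for i in range(spec.n_members)]
    structures: dict[str, Path] = {}
    alignments: dict[str, Path] = {}
    members_meta = []
    pockets_by_member = {}
    for i, member in enumerate(member_ids):
        positions = tuple(range(2 + i * stride, 2 + i * stride + window))
        lig, probes = _pocket_geometry(
            positions, LIGAND_TEMPLATES[spec.pocket_ligand], ca, rng)
        mut_spec = dataclasses.replace(
            spec, pocket_positions=positions, decoy_positions=(),
            agent_positions=())
        seq = _mutate(base, mut_spec, ladder[i], False, rng)
        st = _build_structure(member, seq, ca, probes,
                              [(spec.pocket_ligand, lig)])
        spath = out_dir / "structures" / f"{member}.pdb"
        st.write_pdb(str(spath))
        structures[member] = spath
        apath = out_dir / "alignments" / f"{spec.query_id}__{member}.aln.tsv"
        _write_alignment(apath, spec.query_id, member, base, seq)
        alignments[member] = apath
        pockets_by_member[member] = list(positions)
        members_meta.append({
            "id": member, "target_identity": ladder[i],
            "realized_identity": sum(b == s for b, s in zip(base, seq)) / length,
            "ligands": [spec.pocket_ligand],
        })

    manifest = {
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
        "query_id": spec.query_id,
        "query_sequence": "".join(base),
        "members": members_meta,
        "planted": {"member_pockets": pockets_by_member},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return FamilyBundle(out_dir, spec.query_id, member_ids, structures,
                        alignments, None, manifest_path, manifest)
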