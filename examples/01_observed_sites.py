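"""Extract observed binding sites from a structure complex.

Generates one synthetic homolog structure (a CA-trace chain with a bound
ligand, a decoy compound and a glycerol molecule), reads it back through
the PDB parser and lists every binding site found by the 4.0 Å heavy-atom
contact rule.  Each printed row is one site residue with the number of
atom-pair contacts it makes; a site needs at least five residues to be
reported at all.
"""

import tempfile
from pathlib import Path

from homolig import FamilySpec, extract_binding_sites, generate_family, read_structure

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_family(FamilySpec(seed=42), tmp)
    path = bundle.structure_paths["HOM1"]
    complex_ = read_structure(path)

    print(f"structure {complex_.id}: "
          f"{len(complex_.chains)} chain(s), {len(complex_.ligands)} ligand(s)")
    for site in extract_binding_sites(complex_):
        print(f"\nsite on chain {site.chain_id} for {site.ligand.ligand_code} "
              f"({site.ligand.heavy_atom_count} atoms, "
              f"{site.ligand.molecular_weight:.1f} Da), "
              f"{site.total_contacts} atom-pair contacts:")
        for num, aa in site.residues:
            print(f"  residue {num:>3} {aa}  contacts={site.contact_counts[num]}")
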