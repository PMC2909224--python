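"""Small-molecule candidacy and non-biological flagging.

Two independent decisions are made about every heteroatom group:

* *size filters* — is the group big enough (>=5 heavy atoms, 70-800 Da,
  not a lone ion) to count as a candidate small molecule at all;
* *non-biological flag* — is the compound code on the curated list of
  buffers, cryoprotectants, detergents and other crystallization additives.

Both are pure functions of (ligand, policy).  The shipped non-biological
list contains common PDB chemical-component codes and is user-replaceable;
clusters whose members all bind listed compounds are excluded from ranking
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING

from .errors import DataError

if TYPE_CHECKING:  # pragma: no cover
    from .structure import LigandInstance


def load_nonbio_codes(path=None) -> frozenset[str]:
    """Read a non-biological compound list: one code per line, '#' comments."""
    if path is None:
        text = resources.files("homolig.data").joinpath("nonbiological.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    codes = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codes.add(line.upper())
    return frozenset(codes)


@dataclass(frozen=True)
class LigandPolicy:
    min_heavy_atoms: int = 5
    mw_range: tuple[float, float] = (70.0, 800.0)
    exclude_ions: bool = True
    nonbio_codes: frozenset[str] = field(default_factory=load_nonbio_codes)

    def __post_init__(self):
        if self.mw_range[0] >= self.mw_range[1]:
            raise ValueError("mw_range low must be below high")
        if self.min_heavy_atoms < 1:
            raise ValueError("min_heavy_atoms must be >= 1")


def passes_size_filters(ligand: "LigandInstance", policy: LigandPolicy) -> bool:
    """True iff the group qualifies as a candidate small molecule.

    Boundaries are inclusive on both ends of the MW window and on the atom
    count.  A lone single atom (metal or other monoatomic species) is
    rejected as an ion when ``exclude_ions`` is set.
    """
    n = ligand.heavy_atom_count
    try:
        mw = ligand.molecular_weight
    except Exception as exc:  # element tables missing a symbol
        raise DataError(f"cannot compute molecular weight of "
                        f"{ligand.ligand_code}: {exc}") from exc
    if mw is None or mw <= 0:
        raise DataError(f"ligand {ligand.ligand_code} has no molecular weight")
    if n < policy.min_heavy_atoms:
        return False
    if not (policy.mw_range[0] <= mw <= policy.mw_range[1]):
        return False
    if policy.exclude_ions and n == 1:
        return False
    return True


def is_nonbiological(ligand_code: str, policy: LigandPolicy) -> bool:
    """Case-insensitive membership in the configured non-biological list."""
    return ligand_code.upper() in policy.nonbio_codes
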