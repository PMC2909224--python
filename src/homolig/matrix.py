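"""Substitution-matrix access.

Matrices are Biopython :class:`~Bio.Align.substitution_matrices.Array`
objects; the named default is BLOSUM62 and user files are read in the NCBI
matrix text format.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

from .errors import SubstitutionLookupError

_CACHE: dict = {}


def load_matrix(path: str | None = None):
    """Return a substitution matrix: BLOSUM62 by default, or one read from
    an NCBI-format text file at *path*."""
    if path is None:
        if "BLOSUM62" not in _CACHE:
            _CACHE["BLOSUM62"] = substitution_matrices.load("BLOSUM62")
        return _CACHE["BLOSUM62"]
    return substitution_matrices.read(str(path))


def lookup(matrix, a: str, b: str) -> float:
    """Substitution score for a residue pair.

    Unknown one-letter codes fall back to the matrix's ``X`` row when it has
    one; otherwise a :class:`SubstitutionLookupError` is raised.
    """
    alphabet = matrix.alphabet
    aa = a.upper()
    bb = b.upper()
    if aa not in alphabet:
        if "X" in alphabet:
            aa = "X"
        else:
            raise SubstitutionLookupError(f"no matrix row for residue {a!r}")
    if bb not in alphabet:
        if "X" in alphabet:
            bb = "X"
        else:
            raise SubstitutionLookupError(f"no matrix row for residue {b!r}")
    return float(matrix[aa, bb])
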