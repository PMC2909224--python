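"""Run configuration: every numeric threshold of the method in one place.

Defaults follow the method's published operating point: 4.0 Å contacts,
>=5-residue sites, 75 % chain-majority and footprint rules, 30 % identity
admission, BLOSUM62 with theta=+1 / w=-4 and the ungapped lambda/K, 90 %
redundancy collapse for singletons.  The clustering temperature and ranking
weights are calibrated values recorded here, not published constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # inputs / outputs
    query_id: str = "QUERY"
    structure_dir: str | None = None
    alignment_dir: str | None = None
    query_structure: str | None = None
    out_dir: str | None = None
    nonbio_list: str | None = None
    matrix_path: str | None = None
    # homology and transfer thresholds
    min_identity: float = 0.30
    min_footprint: float = 0.75
    footprint_mode: str = "pairs"         # pairs | residues
    jackknife_ceiling: float | None = None
    # observed-site extraction
    contact_cutoff: float = 4.0
    min_site_residues: int = 5
    chain_majority: float = 0.75
    # ligand policy
    min_heavy_atoms: int = 5
    mw_low: float = 70.0
    mw_high: float = 800.0
    exclude_ions: bool = True
    # similarity scoring
    theta: float = 1.0
    gap_penalty: float = -4.0
    lambda_: float = 0.3176
    K: float = 0.134
    span: str = "union"                   # union | intersection
    # clustering (calibrated, see docs/methods.md)
    temperature: float = 1.0
    # ranking
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    redundancy_cutoff: float = 0.90
    pssm_gap_mode: str = "column_min"     # column_min | zero
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in [0, 1]")
        if not 0.0 <= self.min_footprint <= 1.0:
            raise ValueError("min_footprint must lie in [0, 1]")
        if not 0.5 <= self.chain_majority <= 1.0:
            raise ValueError("chain_majority must lie in [0.5, 1]")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.redundancy_cutoff <= 1.0:
            raise ValueError("redundancy_cutoff must lie in [0, 1]")
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != 4:
            raise ValueError("weights must have four components")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["weights"] = list(self.weights)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "weights" in data and data["weights"] is not None:
            data["weights"] = tuple(data["weights"])
        return cls(**data)
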