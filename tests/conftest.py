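import pytest

from homolig import FamilySpec, RunConfig, generate_family, run_annotate
from homolig.synth import generate_negative_controls


@pytest.fixture(scope="session")
def family(tmp_path_factory):
    """One seeded synthetic homolog family (conserved pocket + decoy +
    crystallization agent), shared across tests."""
    out = tmp_path_factory.mktemp("family")
    spec = FamilySpec(seed=42)
    bundle = generate_family(spec, out)
    return spec, bundle


@pytest.fixture(scope="session")
def family_result(family):
    spec, bundle = family
    cfg = RunConfig(query_id=bundle.query_id,
                    structure_dir=str(bundle.directory / "structures"),
                    alignment_dir=str(bundle.directory / "alignments"))
    return spec, bundle, run_annotate(cfg)


@pytest.fixture(scope="session")
def negative_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("negative")
    spec = FamilySpec(seed=43)
    bundle = generate_negative_controls(spec, out)
    cfg = RunConfig(query_id=bundle.query_id,
                    structure_dir=str(bundle.directory / "structures"),
                    alignment_dir=str(bundle.directory / "alignments"))
    return spec, bundle, run_annotate(cfg)
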