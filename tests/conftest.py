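import numpy as np
import pytest

from stimulomics import simcom

CONDITIONS = simcom.DEFAULT_DESIGN.condition_ids


@pytest.fixture(scope="session")
def small_community():
    """Four-genome community (incl. one 2% strain) with planted truth."""
    specs = [
        simcom.GenomeSpec(
            "gA", length=80_000, gc_target=0.35, n_orfs=14, n_marker_genes=6,
            cytc_plan=(1, 3), pilin_plan=(simcom.PilinPlan(),)),
        simcom.GenomeSpec(
            "gB", length=80_000, gc_target=0.55, n_orfs=14, n_marker_genes=6,
            cytc_plan=(2,)),
        simcom.GenomeSpec("gB2", parent="gB", divergence=0.02, length=80_000),
        simcom.GenomeSpec(
            "gC", length=80_000, gc_target=0.70, n_orfs=14, n_marker_genes=6,
            pilin_plan=(simcom.PilinPlan(
                aromatic_count=4,
                essential_flags=(True,) * 4 + (False,) * 3),)),
    ]
    depths = {
        "gA": dict(zip(CONDITIONS, [40.0, 35.0, 30.0, 25.0, 20.0])),
        "gB": dict(zip(CONDITIONS, [10.0, 12.0, 30.0, 45.0, 60.0])),
        "gB2": dict(zip(CONDITIONS, [25.0, 20.0, 15.0, 25.0, 30.0])),
        "gC": dict(zip(CONDITIONS, [60.0, 50.0, 20.0, 15.0, 10.0])),
    }
    plan = {"gA_orf0001": ("AcPro", "positive", 8.0)}
    return simcom.build_community(
        specs, depths, response_plan=plan, mean_contig_len=6000, seed=7)


@pytest.fixture(scope="session")
def fixture_dir(small_community, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return simcom.emit_fixture(small_community, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
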