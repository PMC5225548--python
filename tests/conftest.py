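import pytest


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """A 200-gene synthetic dataset with planted truth, built once."""
    from riptargetkit.pipeline import make_fixture

    outdir = tmp_path_factory.mktemp("tiny_fixture")
    return make_fixture(outdir, scale="tiny", seed=7)


@pytest.fixture()
def toy_genome():
    """Deterministic 400-nt chromosome for interval-arithmetic oracles."""
    bases = "ACGT"
    seq = "".join(bases[(3 * i + 1) % 4] for i in range(400))
    return {"chr1": seq}
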