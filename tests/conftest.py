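import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def locus():
    """A deterministic multi-transcript locus shared across tests."""
    from rnaedit.synthetic import generate_locus

    return generate_locus(seed=11, n_transcripts=6, coding_fraction=0.7)


@pytest.fixture(scope="session")
def transcript_index(locus):
    from rnaedit.annotator import build_transcript_models

    return build_transcript_models(locus.gtf_records)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete simulated fixture set written to disk once per session."""
    from rnaedit.synthetic import simulate

    out = tmp_path_factory.mktemp("fixture")
    manifest, paths = simulate(seed=7, out_dir=out)
    return {"manifest": manifest, "paths": paths, "dir": out}
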