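import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

from telinc import synthetic_data as sd


@pytest.fixture(scope="session")
def desk_bundle(tmp_path_factory):
    """The default desk-scale bundle (2 x 1 Mb, ~2,000 TEs, ~300 transcripts)."""
    outdir = tmp_path_factory.mktemp("desk_bundle")
    return sd.generate(sd.default_desk_spec(seed=11), outdir)


def small_spec(seed=5):
    spec = sd.SynthSpec(
        seed=seed,
        chrom_lengths={"chr1": 150_000, "chr2": 150_000},
        te_families=sd.default_family_table(),
        n_lncrna=40,
        n_coding=20,
        n_background_dhs=30,
        n_stems=6,
    )
    return spec


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_bundle")
    return sd.generate(small_spec(), outdir)
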