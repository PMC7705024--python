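import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import androscan as asn

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic cohort: 55 samples, 5 demes, planted 24-kb region."""
    config = asn.SimConfig()
    variants, manifest = asn.simulate_genotypes(config)
    return config, variants, manifest


@pytest.fixture(scope="session")
def default_scan(default_sim):
    config, variants, manifest = default_sim
    return asn.scan(variants, manifest)


@pytest.fixture(scope="session")
def default_depth(default_sim):
    config, _, manifest = default_sim
    return asn.simulate_depth(config, manifest)


def make_variants(dosage_rows, contig="ctg1", positions=None, samples=None):
    """VariantTable from a list of per-site dosage vectors."""
    dosages = np.asarray(dosage_rows, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    if positions is None:
        positions = np.arange(n_sites) * 100 + 10
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return asn.VariantTable(
        np.full(n_sites, contig, dtype=object),
        np.asarray(positions),
        np.full(n_sites, "A", dtype=object),
        np.full(n_sites, "T", dtype=object),
        dosages,
        list(samples),
    )


def make_manifest(sexes, samples=None):
    if samples is None:
        samples = [f"s{i}" for i in range(len(sexes))]
    return asn.SexManifest(
        pd.DataFrame(
            {"sample_id": samples, "sex": list(sexes),
             "population": ["pop1"] * len(sexes)}
        )
    )


@pytest.fixture
def variants_factory():
    return make_variants


@pytest.fixture
def manifest_factory():
    return make_manifest
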