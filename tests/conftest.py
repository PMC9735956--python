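import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from thzcornea import CohortConfig, ProtocolSpec, ReferenceSpec, generate_cohort

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


#: Short protocol (periods still >= the 30 min feature window) and short
#: traces: keeps unit-test archives small and fast.
TINY_PROTOCOL = ProtocolSpec(acclimation_min=32.0, elevated_min=36.0, recovery_min=32.0)


@pytest.fixture(scope="session")
def tiny_config() -> CohortConfig:
    return CohortConfig(
        group_sizes={25.0: 3, 45.0: 3},
        protocol=TINY_PROTOCOL,
        reference=ReferenceSpec(n_samples=512),
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config, seed=3)


@pytest.fixture(scope="session")
def noiseless_tiny_cohort(tiny_config):
    return generate_cohort(dataclasses.replace(tiny_config, noise_sd=0.0), seed=3)


@pytest.fixture(scope="session")
def tiny_archive(tmp_path_factory, tiny_cohort):
    outdir = tmp_path_factory.mktemp("tiny_archive")
    archive = outdir / "archive.h5"
    labels = outdir / "labels.csv"
    tiny_cohort.write(archive, labels, meta={"config_hash": "tinycfg"})
    return {"archive": archive, "labels": labels}
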