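from dataclasses import replace

import pytest
from hypothesis import settings

import perfusionpk as pk

settings.register_profile("deterministic", derandomize=True, deadline=None, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def perfusate() -> pk.PerfusateSpec:
    return pk.PerfusateSpec(Cperf=660.0, Cstar_perf=222.0, flow_rate=10.0)


@pytest.fixture
def sample() -> pk.PerfusionSample:
    return pk.PerfusionSample(
        sample_id="S0001",
        animal_id="A0001",
        species="rat",
        region="cerebrum",
        group="control",
        treatment="none",
        tracer="SN38",
        Xtot=500.0,
        Xstar=120.0,
        T=120.0,
    )


@pytest.fixture
def noiseless_rat_scenario() -> pk.SimScenario:
    scen = pk.default_rat_scenario(seed=7)
    return replace(
        scen,
        biological_cv=0.0,
        counting=replace(scen.counting, counting_noise=False),
    )


def make_samples_csv(tmp_path, rows, header=None):
    header = header or ",".join(pk.io.SAMPLE_COLUMNS)
    path = tmp_path / "samples.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path
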