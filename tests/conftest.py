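import pytest
from hypothesis import HealthCheck, settings

from ozid.formula import get_adduct
from ozid.lipids import parse_target_name
from ozid.simulate import SimulatedLipid, SimulationSpec, simulate_run
from ozid.workflow import Target

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")


def make_target(name: str, adduct: str, rt: float) -> Target:
    return Target(name, adduct, rt, parse_target_name(name), get_adduct(adduct))


@pytest.fixture(scope="session")
def pg_standard_run():
    """Noise-free run of the triunsaturated labeled PG standard (n-6/9/12)."""
    lip = SimulatedLipid(
        "D5-PG(17:0/20:3)", "[M-H]-", rt=8.0, abundance=1e5, true_positions={1: (6, 9, 12)}
    )
    spec = SimulationSpec(lipids=(lip,), rt_start=5.0, rt_end=11.0, seed=42)
    run, truth = simulate_run(spec)
    return run, truth, make_target(lip.name, lip.adduct, lip.rt)


@pytest.fixture(scope="session")
def pc_run():
    """Noise-free monounsaturated PC run (single planted n-9 bond)."""
    lip = SimulatedLipid(
        "PC(16:0/18:1)", "[M+H]+", rt=5.0, abundance=1e5, true_positions={1: (9,)}
    )
    spec = SimulationSpec(lipids=(lip,), rt_start=2.0, rt_end=8.0, seed=7)
    run, truth = simulate_run(spec)
    return run, truth, make_target(lip.name, lip.adduct, lip.rt)
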