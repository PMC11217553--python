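import numpy as np
import pytest

import carbonflux as cf
from carbonflux.model import ForcingSeries, HetParams, ModelConfig, PhytoParams


@pytest.fixture()
def tiny_config() -> ModelConfig:
    """One phytoplankton, one heterotroph, two DOM species; fast to step."""
    return ModelConfig(
        phyto={"p1": PhytoParams(mu_max=1.0, k_light=10.0, k_din=0.5,
                                 k_po4=0.05, ke=0.02, fe=0.1, kr=0.02,
                                 fr=0.1, kd=0.1, f_dom=0.5)},
        het={"h1": HetParams(v_max=2.0, affinity={"d0": 1.0, "d1": 2.0},
                             yield_=0.3, kd=0.2, f_dom=0.6)},
        dom_ids=["d0", "d1"],
        k_dis=0.05, dt=0.05,
    )


@pytest.fixture()
def constant_forcing() -> ForcingSeries:
    n = 201
    days = np.linspace(0.0, 200.0, n)
    return ForcingSeries(days=days, temperature=np.full(n, 15.0),
                         par=np.full(n, 40.0), daylength=np.full(n, 12.0))


@pytest.fixture(scope="session")
def truth_run():
    """Ground-truth run of the default synthetic scenario (shared, ~3 s)."""
    scenario = cf.SyntheticScenario()
    traj, pairwise, blooms = cf.generate_ground_truth(scenario)
    return scenario, traj, pairwise, blooms


@pytest.fixture(scope="session")
def sampled_observations(truth_run):
    scenario, traj, _, _ = truth_run
    obs = cf.sample_observations(traj, scenario)
    return obs, cf.observations_to_carbon(obs)
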