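import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import psfsignal as ps

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_compilation():
    """60-pair compilation generated under the heavy-tailed model."""
    cfg = ps.SimulationConfig(n_pairs=60, n_species=40, n_families=8, seed=11)
    table, truth = ps.simulate_pairs(cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_pairs(small_compilation):
    table, _ = small_compilation
    return ps.assemble_pairs(ps.filter_whole_soil(table))


@pytest.fixture(scope="session")
def tiny_pairs():
    """Three pairs with 1-3 replicates each, for brute-force oracles."""
    rng = np.random.default_rng(5)
    pairs = []
    for j, (n_rep, t) in enumerate([(1, 80.0), (2, 350.0), (3, 600.0)]):
        pid = f"p{j}"
        obs = [
            ps.DissimilarityObservation(
                r=float(rng.normal(0, 0.8)),
                var_r=float(rng.uniform(0.02, 0.2)),
                pair_id=pid,
                replicate_index=i + 1,
            )
            for i in range(n_rep)
        ]
        pairs.append(
            ps.SpeciesPair(
                pair_id=pid,
                species_a_id=f"a{j}",
                species_b_id=f"b{j}",
                family_a=f"F{j % 2}",
                family_b=f"F{(j + 1) % 2}",
                t_myr=t,
                observations=obs,
            )
        )
    return pairs
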