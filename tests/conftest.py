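import numpy as np
import pytest

from repdil.synthetic import make_ground_truth, simulate


@pytest.fixture
def noiseless_halving():
    """Two groups, second with half the GOI template; E=2, no noise."""
    gt = make_ground_truth(
        {"A": {"RG": 1.0, "G": 1.0}, "B": {"RG": 1.0, "G": 0.5}},
        n_replicates=3,
    )
    return simulate(gt)


@pytest.fixture
def noisy_dataset():
    gt = make_ground_truth(
        {"ctrl": {"RG1": 1.0, "RG2": 1.0, "G": 1.0},
         "treat": {"RG1": 1.0, "RG2": 1.0, "G": 2.5}},
        n_replicates=4,
        reference_genes=["RG1", "RG2"],
        efficiencies={"RG1": 2.0, "RG2": 1.9, "G": 1.95},
        noise_sd=0.15,
        seed=7,
    )
    return simulate(gt)


def random_ground_truth(rng: np.random.Generator, noise_sd=0.2):
    """A randomized but valid dilution-replicate scenario."""
    n_rg = int(rng.integers(1, 3))
    n_goi = int(rng.integers(1, 3))
    amps = [f"RG{i}" for i in range(n_rg)] + [f"G{i}" for i in range(n_goi)]
    n_groups = int(rng.integers(2, 4))
    groups = {
        f"grp{g}": {
            a: (1.0 if a.startswith("RG") else float(rng.uniform(0.2, 5.0)))
            for a in amps
        }
        for g in range(n_groups)
    }
    return make_ground_truth(
        groups,
        n_replicates=int(rng.integers(2, 5)),
        reference_genes=amps[:n_rg],
        efficiencies={a: float(rng.uniform(1.7, 2.0)) for a in amps},
        baseline_cq={a: float(rng.uniform(18, 26)) for a in amps},
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
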