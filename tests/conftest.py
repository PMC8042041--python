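import numpy as np
import pandas as pd
import pytest

from mrkit import SimConfig, harmonize, simulate, standardize_pairs


def std_pairs_from(cfg: SimConfig):
    """Simulate one study and run it through harmonization + standardization."""
    exp, out, _, truth = simulate(cfg)
    pairs = harmonize(exp[0], out[0])
    return standardize_pairs(pairs), truth


def make_pairs(gamma, Gamma, se_gamma, se_Gamma):
    """Build a standardized-instrument frame directly from arrays."""
    gamma = np.asarray(gamma, dtype=float)
    m = len(gamma)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(m)],
            "gamma": gamma,
            "se_gamma": np.broadcast_to(np.asarray(se_gamma, float), m).copy(),
            "Gamma": np.asarray(Gamma, dtype=float),
            "se_Gamma": np.broadcast_to(np.asarray(se_Gamma, float), m).copy(),
            "maf": np.full(m, 0.3),
        }
    )


@pytest.fixture
def clean_pairs():
    """Strong instruments, no pleiotropy, known theta = 0.4."""
    return std_pairs_from(SimConfig(m=60, theta_true=0.4, sigma_gamma=0.05, seed=101))


@pytest.fixture
def sumstats_text():
    """A small well-formed canonical TSV."""
    return (
        "snp\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn\n"
        "rs1\t1\t1000\tA\tG\t0.2\t0.05\t0.01\t1e-9\t5000\n"
        "rs2\t1\t2000\tC\tT\t0.4\t-0.03\t0.012\t0.01\t5000\n"
        "rs3\t2\t3000\tG\tA\t0.15\t0.02\t0.011\t0.07\t5000\n"
        "rs4\t2\t4000\tT\tC\t0.35\t0.08\t0.02\t6e-5\t5000\n"
        "rs5\t3\t5000\tA\tC\t0.05\t-0.01\t0.015\t0.5\t5000\n"
    )
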