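import numpy as np
import pandas as pd
import pytest

from indexbias.io import PAIR_COLUMNS


def make_pairs(beta_gx, beta_gy, se_gx=None, se_gy=None, flipped=None):
    """Assemble a harmonized-pairs frame from raw vectors."""
    beta_gx = np.asarray(beta_gx, dtype=float)
    n = beta_gx.size
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n)],
            "beta_gx": beta_gx,
            "se_gx": np.full(n, 0.1) if se_gx is None else np.asarray(se_gx, float),
            "beta_gy": np.asarray(beta_gy, dtype=float),
            "se_gy": np.ones(n) if se_gy is None else np.asarray(se_gy, float),
            "flipped": np.zeros(n, dtype=bool) if flipped is None else flipped,
        }
    )[list(PAIR_COLUMNS)]


def write_tsv(path, text):
    path.write_text(text.replace(" | ", "\t"))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20230803)


@pytest.fixture
def risk_file(tmp_path):
    return write_tsv(
        tmp_path / "risk.tsv",
        "snp_id | effect_allele | other_allele | beta | se | info | n_studies\n"
        "rs1 | A | G | 0.2 | 0.05 | 1.0 | 5\n"
        "rs2 | C | T | -0.1 | 0.04 | 0.995 | 4\n"
        "rs3 | G | A | 0.3 | 0.06 | 0.99 | 3\n",
    )


@pytest.fixture
def survival_file(tmp_path):
    return write_tsv(
        tmp_path / "survival.tsv",
        "snp_id | effect_allele | other_allele | beta | se\n"
        "rs1 | A | G | -0.10 | 0.2\n"
        "rs2 | T | C | 0.05 | 0.3\n"
        "rs3 | G | A | 0.08 | 0.25\n",
    )
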