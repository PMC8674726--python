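import numpy as np
import pandas as pd
import pytest

from gwasmr.sumstats_io import CohortTable


def make_records(**overrides) -> pd.DataFrame:
    """Three well-formed canonical rows, overridable per column."""
    base = {
        "SNP": ["rs1", "rs2", "rs3"],
        "CHR": ["1", "1", "2"],
        "POS": [1000, 2000, 500],
        "EA": ["A", "C", "G"],
        "OA": ["G", "T", "A"],
        "EAF": [0.3, 0.4, 0.25],
        "BETA": [0.1, -0.05, 0.2],
        "SE": [0.05, 0.04, 0.08],
        "P": [0.0455, 0.2113, 0.0124],
        "N": [1000, 1000, 900],
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def cohort_table() -> CohortTable:
    return CohortTable("cohortA", "WBCc", make_records())


def instruments_frame(bx, by, sy, sx=None) -> pd.DataFrame:
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), bx.shape)
    sx = np.broadcast_to(np.asarray(0.01 if sx is None else sx, dtype=float), bx.shape)
    return pd.DataFrame({
        "SNP": [f"iv{i}" for i in range(len(bx))],
        "beta_x": bx, "se_x": sx, "beta_y": by, "se_y": sy,
        "proxy_of": None,
    })
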