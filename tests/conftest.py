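import numpy as np
import pandas as pd
import pytest

from shiftstate.cs_io import PRED_COLUMNS, ToleranceConfig


@pytest.fixture
def tol() -> ToleranceConfig:
    return ToleranceConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_pred_frame(rows) -> pd.DataFrame:
    """rows: iterables matching PRED_COLUMNS order."""
    return pd.DataFrame(rows, columns=PRED_COLUMNS)


@pytest.fixture
def square_pdb(tmp_path):
    """Minimal tetramer PDB: one CA per chain at the corners of a 10 Å square."""
    corners = {"A": (5.0, 5.0, 0.0), "B": (-5.0, 5.0, 0.0),
               "C": (-5.0, -5.0, 0.0), "D": (5.0, -5.0, 0.0)}
    lines = []
    serial = 1
    for chain, (x, y, z) in corners.items():
        lines.append(
            f"ATOM  {serial:5d}  CA  THR {chain} 112    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    path = tmp_path / "square.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
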