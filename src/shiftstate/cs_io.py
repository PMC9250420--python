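"""Reading and normalising chemical-shift tables.

All predicted shifts, whatever their source dialect, are normalised into one
long-format :class:`pandas.DataFrame` with the columns in :data:`PRED_COLUMNS`
(the package's canonical interchange format, written/read as TSV).
Experimental assignment tables use :data:`EXP_COLUMNS`.

Only the four backbone nuclei N, C (carbonyl), CA and CB are supported;
rows for any other atom are dropped with a logged count.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUPPORTED_ATOMS = ("N", "C", "CA", "CB")

#: canonical long-format prediction columns
PRED_COLUMNS = [
    "state",
    "method",
    "subunit",
    "frame",
    "residue_number",
    "residue_type",
    "atom",
    "shift_ppm",
]

#: canonical experimental-table columns
EXP_COLUMNS = ["residue_number", "residue_type", "atom", "condition", "shift_ppm"]

CONDITIONS = ("activated", "deactivated")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def normalize_residue_type(res: str) -> str:
    """Return the one-letter amino-acid code (3-letter codes are mapped)."""
    r = str(res).strip().upper()
    return _THREE_TO_ONE.get(r, r)


@dataclass(frozen=True, order=True)
class NucleusKey:
    """Identity of one nucleus: residue number, residue type and atom name."""

    residue_number: int
    residue_type: str
    atom: str

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if self.atom not in SUPPORTED_ATOMS:
            raise ValueError(f"unsupported atom {self.atom!r}; expected one of {SUPPORTED_ATOMS}")
        if self.atom == "CB" and normalize_residue_type(self.residue_type) == "G":
            raise ValueError("glycine has no CB nucleus")

    @property
    def label(self) -> str:
        return f"{self.residue_type}{self.residue_number}{self.atom}"


@dataclass(frozen=True)
class ToleranceConfig:
    """Per-isotope experimental tolerances and the statistical thresholds.

    ``carbon_tol`` applies to C, CA and CB (13C); ``nitrogen_tol`` to N (15N).
    """

    carbon_tol: float = 0.2
    nitrogen_tol: float = 0.5
    effect_size_threshold: float = 0.5
    ci_mass: float = 0.94

    def __post_init__(self) -> None:
        for name in ("carbon_tol", "nitrogen_tol", "effect_size_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.ci_mass < 1:
            raise ValueError("ci_mass must lie in (0, 1)")

    def for_atom(self, atom: str) -> float:
        if atom == "N":
            return self.nitrogen_tol
        if atom in ("C", "CA", "CB"):
            return self.carbon_tol
        raise ValueError(f"unsupported atom {atom!r}")


def stable_key_seed(*parts: object) -> int:
    """Deterministic 31-bit integer derived from string parts (for RNG spawning)."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def _finalize_prediction_frame(
    df: pd.DataFrame, *, source: str, drop_unsupported: bool = True
) -> pd.DataFrame:
    df = df.copy()
    df["atom"] = df["atom"].astype(str).str.upper()
    n_before = len(df)
    df = df[df["atom"].isin(SUPPORTED_ATOMS)]
    dropped = n_before - len(df)
    if dropped:
        logger.info("%s: dropped %d rows with unsupported atoms", source, dropped)
    df["residue_type"] = df["residue_type"].map(normalize_residue_type)
    gly_cb = (df["atom"] == "CB") & (df["residue_type"] == "G")
    if gly_cb.any():
        logger.warning("%s: dropped %d glycine CB rows", source, int(gly_cb.sum()))
        df = df[~gly_cb]
    df["residue_number"] = df["residue_number"].astype(int)
    df["frame"] = df["frame"].astype(int)
    df["subunit"] = df["subunit"].astype(str)
    df["shift_ppm"] = df["shift_ppm"].astype(float)
    if not np.isfinite(df["shift_ppm"]).all():
        bad = df.loc[~np.isfinite(df["shift_ppm"])].iloc[0]
        raise ValueError(f"{source}: non-finite shift for residue {bad['residue_number']}")
    return df[PRED_COLUMNS].reset_index(drop=True)


def read_prediction_table(
    path: str | Path,
    dialect: str,
    state: str | None = None,
    method: str | None = None,
    *,
    frame: int | None = None,
    subunit: str | None = None,
) -> pd.DataFrame:
    """Read a predicted-shift table in one of the supported dialects.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"sparta_plus"`` (whitespace table, columns RESID/RESNAME/ATOMNAME/SHIFT,
        optional FRAME and CHAIN), ``"shiftx2"`` (CSV, NUM/RES/ATOMNAME/SHIFT,
        optional FRAME and CHAIN) or ``"generic_long"`` (canonical TSV).
        Dialects are never sniffed: a wrong declaration should fail loudly,
        not silently misparse ppm columns.
    state, method
        Labels stamped onto every record (override file contents for
        ``generic_long``).
    frame
        Frame index for single-frame prediction files lacking a FRAME column.
    subunit
        Chain label for files lacking a CHAIN column (default ``"A"``).
    """
    path = Path(path)
    if dialect == "generic_long":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # noqa: BLE001 - re-raise as format error
            raise ValueError(f"{path}: failed to parse as generic_long TSV: {exc}") from exc
        missing = set(PRED_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: generic_long table missing columns {sorted(missing)}")
        if state is not None:
            df["state"] = state
        if method is not None:
            df["method"] = method
        return _finalize_prediction_frame(df, source=str(path))

    if dialect not in ("sparta_plus", "shiftx2"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if state is None or method is None:
        raise ValueError(f"dialect {dialect!r} requires explicit state and method labels")

    if dialect == "sparta_plus":
        colmap = {"RESID": "residue_number", "RESNAME": "residue_type",
                  "ATOMNAME": "atom", "SHIFT": "shift_ppm"}
        try:
            raw = pd.read_csv(path, sep=r"\s+", comment="#")
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"{path}: failed to parse as SPARTA+ table: {exc}") from exc
    else:
        colmap = {"NUM": "residue_number", "RES": "residue_type",
                  "ATOMNAME": "atom", "SHIFT": "shift_ppm"}
        try:
            raw = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"{path}: failed to parse as SHIFTX2 CSV: {exc}") from exc

    raw.columns = [str(c).strip().upper() for c in raw.columns]
    missing = set(colmap) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: {dialect} table missing columns {sorted(missing)}")
    df = raw.rename(columns=colmap)
    if "FRAME" in raw.columns:
        df["frame"] = raw["FRAME"]
    elif frame is not None:
        df["frame"] = frame
    else:
        raise ValueError(f"{path}: no FRAME column and no frame argument given")
    df["subunit"] = raw["CHAIN"] if "CHAIN" in raw.columns else (subunit or "A")
    df["state"] = state
    df["method"] = method
    return _finalize_prediction_frame(df, source=str(path))


def write_generic_long(df: pd.DataFrame, path: str | Path) -> None:
    """Write predictions in the canonical generic_long TSV (round-trip exact)."""
    df[PRED_COLUMNS].to_csv(path, sep="\t", index=False)


def pool_subunits(df: pd.DataFrame, pooled_label: str = "pooled") -> pd.DataFrame:
    """Concatenate the equivalent subunits of a homotetramer into one sample.

    The four chains are treated as independent realisations of the same
    nucleus, so their per-frame predictions are pooled a posteriori.  The
    subunit field collapses to ``pooled_label`` and frames are re-enumerated
    deterministically (ordered by original subunit, then frame) so that
    (state, method, subunit, frame, nucleus) stays unique.
    """
    if df.empty:
        out = df.copy()
        out["subunit"] = out["subunit"].astype(str)
        return out
    out = df.sort_values(
        ["state", "method", "residue_number", "residue_type", "atom", "subunit", "frame"],
        kind="mergesort",
    ).copy()
    group_cols = ["state", "method", "residue_number", "residue_type", "atom"]
    out["frame"] = out.groupby(group_cols, sort=False).cumcount()
    out["subunit"] = pooled_label
    return out.reset_index(drop=True)


def subsample(df: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Randomly keep at most ``n`` records per (state, method, nucleus).

    Selection is uniform without replacement and reproducible for a fixed
    seed (each group draws from its own deterministically-spawned RNG, so the
    result does not depend on row order or on which other groups exist).
    Groups with fewer than ``n`` records are kept whole with a logged warning:
    discarding data from short ensembles would bias them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if df.empty:
        return df.copy()
    parts = []
    group_cols = ["state", "method", "residue_number", "residue_type", "atom"]
    for name, group in df.groupby(group_cols, sort=True):
        if len(group) <= n:
            if len(group) < n:
                logger.warning("subsample: only %d of %d requested records for %s",
                               len(group), n, name)
            parts.append(group)
            continue
        rng = np.random.default_rng([seed, stable_key_seed(*name)])
        idx = rng.choice(len(group), size=n, replace=False)
        idx.sort()
        parts.append(group.iloc[idx])
    return pd.concat(parts, ignore_index=True)


def read_experimental_table(path: str | Path) -> pd.DataFrame:
    """Read an experimental assignment table (TSV, :data:`EXP_COLUMNS`).

    Rows with a missing shift are skipped with a log message; a duplicate
    (nucleus, condition) assignment is an error naming the nucleus.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: failed to parse experimental TSV: {exc}") from exc
    missing = set(EXP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: experimental table missing columns {sorted(missing)}")
    n_missing = int(df["shift_ppm"].isna().sum())
    if n_missing:
        logger.info("%s: skipped %d rows with missing shifts", path, n_missing)
        df = df.dropna(subset=["shift_ppm"])
    df = df.copy()
    df["atom"] = df["atom"].astype(str).str.upper()
    df = df[df["atom"].isin(SUPPORTED_ATOMS)]
    df["residue_type"] = df["residue_type"].map(normalize_residue_type)
    df["residue_number"] = df["residue_number"].astype(int)
    df["condition"] = df["condition"].astype(str).str.lower()
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        raise ValueError(f"{path}: unknown condition {df.loc[bad_cond, 'condition'].iloc[0]!r}")
    df["shift_ppm"] = df["shift_ppm"].astype(float)
    dup_cols = ["residue_number", "residue_type", "atom", "condition"]
    dups = df.duplicated(dup_cols, keep=False)
    if dups.any():
        row = df.loc[dups].iloc[0]
        raise ValueError(
            f"{path}: duplicate assignment for "
            f"{row['residue_type']}{row['residue_number']}{row['atom']} ({row['condition']})"
        )
    return df[EXP_COLUMNS].reset_index(drop=True)


def write_experimental_table(df: pd.DataFrame, path: str | Path) -> None:
    df[EXP_COLUMNS].to_csv(path, sep="\t", index=False)


def keys_of(df: pd.DataFrame) -> list[NucleusKey]:
    """Unique nuclei present in a prediction or experimental frame, sorted."""
    uniq = df[["residue_number", "residue_type", "atom"]].drop_duplicates()
    return sorted(
        NucleusKey(int(r.residue_number), str(r.residue_type), str(r.atom))
        for r in uniq.itertuples()
    )


def intersect_assigned(
    predictions: pd.DataFrame,
    experiments: pd.DataFrame,
    states: Sequence[str] | None = None,
) -> list[NucleusKey]:
    """Nuclei predicted in every simulated state and assigned in both conditions.

    Only nuclei with experimental shifts for both the activated and the
    deactivated condition, and with predictions for every state in ``states``
    (default: every state present in ``predictions``), enter the analysis.
    """
    if predictions.empty or experiments.empty:
        return []
    if states is None:
        states = sorted(predictions["state"].unique())
    key_cols = ["residue_number", "residue_type", "atom"]

    per_state = predictions.groupby(key_cols)["state"].agg(lambda s: set(s))
    pred_ok = per_state[per_state.map(lambda got: set(states) <= got)].index

    per_cond = experiments.groupby(key_cols)["condition"].agg(lambda s: set(s))
    exp_ok = per_cond[per_cond.map(lambda got: {"activated", "deactivated"} <= got)].index

    shared = set(pred_ok) & set(exp_ok)
    return sorted(NucleusKey(int(r), str(t), str(a)) for r, t, a in shared)


def shifts_for(
    df: pd.DataFrame, key: NucleusKey, state: str | None = None, method: str | None = None
) -> np.ndarray:
    """Shift values for one nucleus (optionally restricted to state/method)."""
    mask = (
        (df["residue_number"] == key.residue_number)
        & (df["residue_type"] == key.residue_type)
        & (df["atom"] == key.atom)
    )
    if state is not None:
        mask &= df["state"] == state
    if method is not None:
        mask &= df["method"] == method
    return df.loc[mask, "shift_ppm"].to_numpy()
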