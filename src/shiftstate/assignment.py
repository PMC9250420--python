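"""State assignment from difference chemical shifts.

Absolute predicted shifts carry systematic errors (referencing, lipid
environment, prediction-tool bias).  Differences relative to a common closed
reference cancel those errors, so the comparison between simulation and
experiment is made on

    dCS_sim^X = CS_sim^X - CS_sim^C        (posterior-distributed, per draw)
    dCS_exp   = CS_exp^act - CS_exp^deact  (point value)
    ddCS^X    = dCS_sim^X - dCS_exp

The state X whose |ddCS^X| credible-interval centre is smaller agrees better
with the experiment at that nucleus; if both centres sit below the
experimental tolerance no state is assigned.  Nuclei whose experimental shift
itself moves beyond tolerance between conditions are *markers*, the rest
*spectators*.  All boundary comparisons are strict (ties are conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import CredibleInterval, credible_interval
from .cs_io import NucleusKey, ToleranceConfig

logger = logging.getLogger(__name__)

UNDETERMINED = "undetermined"
MARKER = "marker"
SPECTATOR = "spectator"


@dataclass(frozen=True)
class DeltaCS:
    """Difference shifts for one nucleus/method/candidate state."""

    key: NucleusKey
    method: str
    state: str
    sim_delta_ci: CredibleInterval
    exp_delta: float
    dd_ci: CredibleInterval


@dataclass(frozen=True)
class NucleusVerdict:
    """Assigned state and marker status for one discriminating nucleus."""

    key: NucleusKey
    method: str
    verdict: str
    dd_po_center: float
    dd_fo_center: float
    marker_status: str


def delta_cs_sim(mean_draws_x, mean_draws_c, mass: float = 0.94,
                 kind: str = "hdi") -> tuple[np.ndarray, CredibleInterval]:
    """Per-draw dCS_sim^X = CS_sim^X - CS_sim^C and its credible interval."""
    x = np.asarray(mean_draws_x, dtype=float).ravel()
    c = np.asarray(mean_draws_c, dtype=float).ravel()
    n = min(x.size, c.size)
    draws = x[:n] - c[:n]
    return draws, credible_interval(draws, mass=mass, kind=kind)


def delta_cs_exp(activated_shift: float, deactivated_shift: float) -> float:
    """Experimental difference shift: activated (pH 4) minus deactivated (pH 7.5)."""
    return float(activated_shift) - float(deactivated_shift)


def delta_delta_cs(sim_delta_draws, exp_delta: float, mass: float = 0.94,
                   kind: str = "hdi") -> tuple[np.ndarray, CredibleInterval]:
    """Per-draw |ddCS^X| = |dCS_sim^X - dCS_exp| and its credible interval.

    The absolute value is taken per draw (the comparison metric is a
    magnitude); interval centres of the two candidate states are what the
    verdict compares.
    """
    draws = np.abs(np.asarray(sim_delta_draws, dtype=float).ravel() - float(exp_delta))
    return draws, credible_interval(draws, mass=mass, kind=kind)


def marker_status(exp_delta: float, key: NucleusKey, tol: ToleranceConfig) -> str:
    """Marker iff the experimental difference exceeds the isotope tolerance (strict)."""
    return MARKER if abs(exp_delta) > tol.for_atom(key.atom) else SPECTATOR


def assign_state(
    dd_po: CredibleInterval,
    dd_fo: CredibleInterval,
    key: NucleusKey,
    tol: ToleranceConfig,
    method: str = "",
    exp_delta: float | None = None,
) -> NucleusVerdict:
    """Assign PO, FO or undetermined from the two |ddCS| interval centres.

    Undetermined when both centres lie below the experimental tolerance
    (neither state is meaningfully closer than the measurement can resolve)
    or on an exact tie; otherwise the state with the smaller centre wins.
    """
    tolerance = tol.for_atom(key.atom)
    po_c, fo_c = dd_po.center, dd_fo.center
    if (po_c < tolerance and fo_c < tolerance) or po_c == fo_c:
        verdict = UNDETERMINED
    elif po_c < fo_c:
        verdict = "PO"
    else:
        verdict = "FO"
    status = (
        marker_status(exp_delta, key, tol) if exp_delta is not None else SPECTATOR
    )
    return NucleusVerdict(
        key=key, method=method, verdict=verdict,
        dd_po_center=po_c, dd_fo_center=fo_c, marker_status=status,
    )


def combine_method_verdicts(verdicts: pd.DataFrame) -> pd.DataFrame:
    """One verdict per nucleus: methods agreeing -> that state, else undetermined.

    ``verdicts`` needs columns residue_number, residue_type, atom, verdict.
    """
    key_cols = ["residue_number", "residue_type", "atom"]

    def _combine(group: pd.Series) -> str:
        states = set(group)
        return states.pop() if len(states) == 1 else UNDETERMINED

    out = verdicts.groupby(key_cols)["verdict"].agg(_combine).reset_index()
    return out


def tally_verdicts(verdicts: pd.DataFrame, level: str = "nucleus") -> dict[str, float]:
    """Percentage of PO / FO / undetermined verdicts.

    ``level="nucleus"`` counts each verdict row once.  ``level="residue"``
    first takes a majority vote over each residue's nuclei (ties and
    all-undetermined give undetermined), then counts residues.
    """
    if verdicts.empty:
        return {"PO": 0.0, "FO": 0.0, UNDETERMINED: 0.0}
    if level == "nucleus":
        counts = verdicts["verdict"].value_counts()
        total = int(counts.sum())
    elif level == "residue":
        def _majority(group: pd.Series) -> str:
            votes = group[group != UNDETERMINED].value_counts()
            if votes.empty:
                return UNDETERMINED
            top = votes[votes == votes.max()]
            return top.index[0] if len(top) == 1 else UNDETERMINED

        per_res = verdicts.groupby(["residue_number", "residue_type"])["verdict"].agg(_majority)
        counts = per_res.value_counts()
        total = int(counts.sum())
    else:
        raise ValueError(f"unknown tally level {level!r}")
    return {
        cat: float(100.0 * counts.get(cat, 0) / total)
        for cat in ("PO", "FO", UNDETERMINED)
    }


def rmse_absolute(sim_means: pd.Series | dict, exp_shifts: pd.Series | dict) -> float:
    """Root-mean-square difference of absolute shifts over shared nuclei (ppm).

    Kept as the point-measure baseline: on realistic data the RMSE gap
    between candidate states sits within experimental uncertainty, which is
    why the pipeline works with difference shifts instead.
    """
    sim = pd.Series(sim_means, dtype=float)
    exp = pd.Series(exp_shifts, dtype=float)
    shared = sim.index.intersection(exp.index)
    if len(shared) == 0:
        raise ValueError("no shared nuclei between simulation and experiment")
    diff = sim.loc[shared] - exp.loc[shared]
    return float(np.sqrt(np.mean(diff.to_numpy() ** 2)))


def recenter_bias(
    sim_minus_exp: pd.DataFrame,
    group_cols: tuple[str, ...] = ("atom",),
    min_keys: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove a per-group systematic offset by Gaussian (MLE) recentring.

    ``sim_minus_exp`` needs a ``difference_ppm`` column plus the grouping
    columns (typically atom, and optionally method/state).  For each group
    with at least ``min_keys`` rows a Gaussian is fitted and its mean
    subtracted; smaller groups are passed through with a log message.
    Returns (corrected table with ``corrected_ppm``, per-group fit table).
    """
    corrected = sim_minus_exp.copy()
    corrected["corrected_ppm"] = corrected["difference_ppm"]
    fits = []
    for name, group in sim_minus_exp.groupby(list(group_cols)):
        if len(group) < min_keys:
            logger.info("recenter_bias: group %s has %d < %d keys; skipped", name,
                        len(group), min_keys)
            continue
        center, sd = stats.norm.fit(group["difference_ppm"].to_numpy())
        corrected.loc[group.index, "corrected_ppm"] = group["difference_ppm"] - center
        row = dict(zip(group_cols, name if isinstance(name, tuple) else (name,)))
        row.update({"fitted_center_ppm": float(center), "fitted_sd_ppm": float(sd),
                    "n_keys": len(group)})
        fits.append(row)
    return corrected, pd.DataFrame(fits)
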