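"""Marker classification of assigned nuclei.

Every experimentally assigned nucleus is placed in one of five letter
classes from the three pairwise simulated distinguishabilities (booleans on
|dCS| credible-interval centres vs the isotope tolerance):

    A: no pair distinguishable
    B: FO distinct from C and from PO; PO ~ C
    C: PO distinct from C and from FO; FO ~ C
    D: PO and FO both distinct from C but not from each other
    E: all three pairs distinct

and a numeric subtype from the experimental marker status: 1 when the two
experimental conditions are indistinguishable (spectator), 2 when the shift
moves (marker).  Class A is not subdivided.  D-class nuclei can never pass
the FO-vs-PO discrimination filter (their FO-vs-PO boolean is false by
definition).

Boolean patterns that match none of the five regular rows (reachable with
noisy centres, e.g. PO distinct from C while FO is distinct from neither)
are mapped to the nearest regular pattern by Hamming distance — ties broken
by preferring candidates that agree on the FO-vs-PO boolean, then the later
letter — and flagged ``irregular`` rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cs_io import NucleusKey, ToleranceConfig

logger = logging.getLogger(__name__)

#: (PO != C, FO != C, FO != PO) -> letter
REGULAR_PATTERNS: dict[tuple[bool, bool, bool], str] = {
    (False, False, False): "A",
    (False, True, True): "B",
    (True, False, True): "C",
    (True, True, False): "D",
    (True, True, True): "E",
}
_LETTER_TO_PATTERN = {v: k for k, v in REGULAR_PATTERNS.items()}


@dataclass(frozen=True)
class MarkerClass:
    """A letter class A/B/C/D/E with subtype 1 (spectator) or 2 (marker);
    A carries no subtype."""

    letter: str
    subtype: int | None
    irregular: bool = False

    def __post_init__(self) -> None:
        if self.letter not in "ABCDE":
            raise ValueError(f"unknown class letter {self.letter!r}")
        if self.letter == "A" and self.subtype is not None:
            raise ValueError("class A has no subtype")
        if self.letter != "A" and self.subtype not in (1, 2):
            raise ValueError("subtype must be 1 or 2")

    @property
    def label(self) -> str:
        return self.letter if self.subtype is None else f"{self.letter}{self.subtype}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def classify(dpo_c: bool, dfo_c: bool, dfo_po: bool, exp_marker: bool) -> MarkerClass:
    """Classify one nucleus from the three distinguishability booleans and
    the experimental marker flag.  Pure function; total over all 16 inputs."""
    pattern = (bool(dpo_c), bool(dfo_c), bool(dfo_po))
    irregular = pattern not in REGULAR_PATTERNS
    if irregular:
        best = None
        for letter in "ABCDE":
            ref = _LETTER_TO_PATTERN[letter]
            dist = sum(p != r for p, r in zip(pattern, ref))
            fo_po_match = ref[2] == pattern[2]
            # minimise distance; prefer FO-vs-PO agreement; prefer later letter
            rank = (dist, not fo_po_match, -ord(letter))
            if best is None or rank < best[0]:
                best = (rank, letter)
        letter = best[1]
        logger.info("irregular distinguishability pattern %s mapped to class %s",
                    pattern, letter)
    else:
        letter = REGULAR_PATTERNS[pattern]
    subtype = None if letter == "A" else (2 if exp_marker else 1)
    return MarkerClass(letter=letter, subtype=subtype, irregular=irregular)


def classify_all(
    delta_table: pd.DataFrame,
    discrimination_table: pd.DataFrame,
    marker_table: pd.DataFrame,
    tol: ToleranceConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every (nucleus, method) and collect per-nucleus class sets.

    Parameters
    ----------
    delta_table
        Columns residue_number, residue_type, atom, method, state,
        sim_delta_center — the dCS_sim^X credible-interval centres for the
        two candidate states vs the closed reference.
    discrimination_table
        Columns residue_number, residue_type, atom, method, diff_center —
        the FO - PO difference-in-means CI centre.
    marker_table
        Columns residue_number, residue_type, atom, exp_delta.

    Returns (per-(nucleus, method) table, per-nucleus table whose
    ``classes`` column is the sorted union of method classes — of size 2
    when the prediction tools disagree).
    """
    key_cols = ["residue_number", "residue_type", "atom"]
    wide = delta_table.pivot_table(
        index=key_cols + ["method"], columns="state", values="sim_delta_center",
        aggfunc="first",
    ).reset_index()
    candidate_states = [c for c in wide.columns if c not in key_cols + ["method"]]
    if sorted(candidate_states) != ["FO", "PO"]:
        raise ValueError(f"expected candidate states PO and FO, got {candidate_states}")
    merged = wide.merge(discrimination_table[key_cols + ["method", "diff_center"]],
                        on=key_cols + ["method"], how="inner")
    merged = merged.merge(marker_table[key_cols + ["exp_delta"]], on=key_cols, how="inner")
    n_skipped = len(wide) - len(merged)
    if n_skipped:
        logger.info("classify_all: skipped %d (nucleus, method) rows with missing inputs",
                    n_skipped)

    rows = []
    for r in merged.itertuples():
        key = NucleusKey(int(r.residue_number), str(r.residue_type), str(r.atom))
        tolerance = tol.for_atom(key.atom)
        dpo_c = abs(r.PO) > tolerance
        dfo_c = abs(r.FO) > tolerance
        dfo_po = abs(r.diff_center) > tolerance
        exp_marker = abs(r.exp_delta) > tolerance
        cls = classify(dpo_c, dfo_c, dfo_po, exp_marker)
        rows.append({
            "residue_number": key.residue_number,
            "residue_type": key.residue_type,
            "atom": key.atom,
            "method": r.method,
            "class": cls.label,
            "dpo_c": dpo_c,
            "dfo_c": dfo_c,
            "dfo_po": dfo_po,
            "exp_marker": exp_marker,
            "irregular": cls.irregular,
        })
    per_method = pd.DataFrame(rows)
    if per_method.empty:
        return per_method, pd.DataFrame(columns=key_cols + ["classes"])
    per_nucleus = (
        per_method.groupby(key_cols)["class"]
        .agg(lambda s: ",".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"class": "classes"})
    )
    return per_method, per_nucleus
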