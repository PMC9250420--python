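"""Structural and trajectory-curation utilities.

The analysis consumes only curated ensembles: frames after a water molecule
enters the selectivity filter are discarded (a symptom of inactivation), and
so are initial segments where the inner gate has not yet stabilised.  The
degree of gate opening is quantified by the cross-bundle distance — the
Cα–Cα distance between the gate residue (T112 in KcsA) of opposing subunits
of the tetramer.  Detection of water-entry events and per-site selectivity
filter occupancies from raw trajectories is out of scope; this module
consumes precomputed event frames and site-state series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import gemmi
import numpy as np

OCCUPANCY_SYMBOLS = ("W", "K", "0")
N_FILTER_SITES = 6  # S0..S4 plus the cavity site


@dataclass(frozen=True)
class FrameWindow:
    """Half-open frame interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def intersect(self, other: "FrameWindow") -> "FrameWindow":
        return FrameWindow(max(self.start, other.start), min(self.end, other.end))

    def contains(self, frame: int) -> bool:
        return self.start <= frame < self.end


@dataclass(frozen=True)
class GateSeries:
    """Inner-gate distance time series (ns, Å) for the two diagonal pairs."""

    time: np.ndarray
    distance: np.ndarray
    pair_labels: tuple[str, str] = ("A-C", "B-D")

    def __post_init__(self) -> None:
        if len(self.time) != len(self.distance):
            raise ValueError("time and distance must have equal length")
        if np.any(np.asarray(self.distance) <= 0):
            raise ValueError("distances must be positive")


@dataclass(frozen=True)
class GateDistance:
    """Cross-bundle opening: mean of the two diagonal Cα–Cα distances."""

    mean: float
    diagonals: tuple[float, float]
    pairs: tuple[tuple[str, str], tuple[str, str]]


def _atom_positions(
    structure: gemmi.Structure, residue_number: int, atom_name: str
) -> dict[str, np.ndarray]:
    positions: dict[str, np.ndarray] = {}
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.seqid.num != residue_number:
                continue
            atom = residue.find_atom(atom_name, "*")
            if atom is not None:
                positions[chain.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    return positions


def gate_distance(
    structure: gemmi.Structure | str | Path,
    residue_number: int,
    atom_name: str = "CA",
) -> GateDistance:
    """Cross-bundle distance at a gate residue of a homotetramer.

    The two opposing (diagonal) chain pairs are identified geometrically, as
    the pairing of the four chains that maximises the summed pair distances
    (chain naming conventions vary between PDB entries, so chain IDs are not
    trusted).  Both diagonals are returned — they can differ when the gate
    asymmetrises — along with their mean.
    """
    if not isinstance(structure, gemmi.Structure):
        structure = gemmi.read_structure(str(structure))
    positions = _atom_positions(structure, residue_number, atom_name)
    if len(positions) < 4:
        raise ValueError(
            f"need atom {atom_name} at residue {residue_number} in 4 chains; "
            f"found only in {sorted(positions) or 'none'}"
        )
    if len(positions) > 4:
        raise ValueError(
            f"atom {atom_name} at residue {residue_number} found in "
            f"{len(positions)} chains {sorted(positions)}; expected a tetramer"
        )
    names = sorted(positions)
    # the 3 perfect matchings of 4 chains into 2 pairs
    a = names[0]
    matchings = []
    for partner in names[1:]:
        rest = [n for n in names[1:] if n != partner]
        matchings.append(((a, partner), (rest[0], rest[1])))

    def pair_dist(p):
        return float(np.linalg.norm(positions[p[0]] - positions[p[1]]))

    best = max(matchings, key=lambda m: pair_dist(m[0]) + pair_dist(m[1]))
    d1, d2 = pair_dist(best[0]), pair_dist(best[1])
    return GateDistance(mean=0.5 * (d1 + d2), diagonals=(d1, d2), pairs=best)


def exclude_after_water_entry(water_entry_frame: int | None, n_frames: int) -> FrameWindow:
    """Usable window before the first water molecule enters the selectivity filter.

    Returns [0, entry) when an entry event exists, else the full trajectory.
    An entry at frame 0 leaves no usable data and is an error; an entry frame
    beyond the trajectory keeps the full window with a warning.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if water_entry_frame is None:
        return FrameWindow(0, n_frames)
    if water_entry_frame == 0:
        raise ValueError("water entered the selectivity filter at frame 0: no usable data")
    if water_entry_frame >= n_frames:
        warnings.warn(
            f"water entry frame {water_entry_frame} beyond trajectory ({n_frames} frames); "
            "keeping the full window",
            stacklevel=2,
        )
        return FrameWindow(0, n_frames)
    return FrameWindow(0, int(water_entry_frame))


def stable_gate_window(
    series: GateSeries,
    explicit_window_ns: tuple[float, float] | None = None,
    rolling_frames: int = 20,
    max_drift: float = 1.0,
    min_frames: int | None = None,
) -> FrameWindow:
    """Frames over which the inner-gate distance is considered stable.

    An explicit (start_ns, end_ns) window passes through verbatim (converted
    to frame indices).  In heuristic mode the longest suffix [s, N) is
    returned whose rolling mean (window ``rolling_frames``) varies by at most
    ``max_drift`` Å — i.e. the earliest start after which the gate no longer
    drifts.  The stable stretch must span at least ``min_frames`` frames
    (default twice the rolling window), so a trailing sliver never counts
    as stable.
    """
    t = np.asarray(series.time, dtype=float)
    d = np.asarray(series.distance, dtype=float)
    n = len(d)
    if n == 0:
        raise ValueError("empty gate series")
    if explicit_window_ns is not None:
        t0, t1 = explicit_window_ns
        idx = np.nonzero((t >= t0) & (t < t1))[0]
        if idx.size == 0:
            raise ValueError(f"no frames inside explicit window [{t0}, {t1}) ns")
        return FrameWindow(int(idx[0]), int(idx[-1]) + 1)

    w = min(rolling_frames, n)
    if min_frames is None:
        min_frames = 2 * w
    kernel = np.ones(w) / w
    rolling = np.convolve(d, kernel, mode="valid")  # rolling[i] = mean of d[i:i+w]
    # suffix min/max of the rolling means
    suf_min = np.minimum.accumulate(rolling[::-1])[::-1]
    suf_max = np.maximum.accumulate(rolling[::-1])[::-1]
    ok = np.nonzero(suf_max - suf_min <= max_drift)[0]
    ok = ok[ok <= n - min_frames]
    if ok.size == 0:
        raise ValueError("no suffix window satisfies the drift criterion")
    return FrameWindow(int(ok[0]), n)


def occupancy_string(site_states, n_sites: int = N_FILTER_SITES) -> str:
    """Selectivity-filter occupancy code, e.g. ``WKK0KW``.

    One symbol per site from the extracellular side inward: W = water,
    K = potassium ion, 0 = empty.
    """
    states = [str(s) for s in site_states]
    if len(states) != n_sites:
        raise ValueError(f"expected {n_sites} site states, got {len(states)}")
    for s in states:
        if s not in OCCUPANCY_SYMBOLS:
            raise ValueError(f"unknown occupancy symbol {s!r}")
    return "".join(states)


def parse_occupancy_string(text: str, n_sites: int = N_FILTER_SITES) -> list[str]:
    """Inverse of :func:`occupancy_string`."""
    return list(occupancy_string(list(text), n_sites=n_sites))
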