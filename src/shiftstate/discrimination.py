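"""Statistical filtering: which nuclei distinguish the two open states.

A nucleus (per prediction method) has *discrimination power* when both

* the centre of the 94% credible interval of the difference in means
  (FO - PO) exceeds the experimental tolerance in absolute value
  (0.2 ppm for C/CA/CB, 0.5 ppm for N), and
* the centre of the effect-size credible interval exceeds 0.5 in absolute
  value, where the effect size is the difference in means scaled by the
  pooled standard deviation sqrt((var_FO + var_PO) / 2).

Both criteria act on interval *centres*, never on the bounds.  Draws from
the two independent posteriors are paired by index; because the posteriors
are independent the pairing is arbitrary and introduces no bias, while
keeping results reproducible for fixed seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bayes import CredibleInterval, credible_interval
from .cs_io import NucleusKey, ToleranceConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscriminationResult:
    """Filter outcome for one nucleus and one prediction method."""

    key: NucleusKey
    method: str
    diff_ci: CredibleInterval
    effect_ci: CredibleInterval
    passes_diff: bool
    passes_effect: bool
    passes: bool


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        logger.warning("draw arrays differ in length (%d vs %d); trimming", a.size, b.size)
        n = min(a.size, b.size)
        a, b = a[:n], b[:n]
    return a, b


def difference_in_means(mean_draws_fo, mean_draws_po, mass: float = 0.94,
                        kind: str = "hdi") -> CredibleInterval:
    """Credible interval of the FO - PO difference of distribution means (ppm)."""
    fo, po = _paired(mean_draws_fo, mean_draws_po)
    return credible_interval(fo - po, mass=mass, kind=kind)


def effect_size_draws(mean_draws_fo, mean_draws_po, var_draws_fo, var_draws_po) -> np.ndarray:
    """Per-draw effect size (FO - PO) / sqrt((var_FO + var_PO)/2)."""
    fo, po = _paired(mean_draws_fo, mean_draws_po)
    vfo, vpo = _paired(var_draws_fo, var_draws_po)
    if np.any(vfo <= 0) or np.any(vpo <= 0):
        raise ValueError("variance draws must be strictly positive")
    std_pool = np.sqrt(0.5 * (vfo + vpo))
    return (fo - po) / std_pool


def effect_size(mean_draws_fo, mean_draws_po, var_draws_fo, var_draws_po,
                mass: float = 0.94, kind: str = "hdi") -> CredibleInterval:
    """Credible interval of the effect size (dimensionless)."""
    return credible_interval(
        effect_size_draws(mean_draws_fo, mean_draws_po, var_draws_fo, var_draws_po),
        mass=mass, kind=kind,
    )


def has_discrimination_power(
    diff_ci: CredibleInterval,
    effect_ci: CredibleInterval,
    key: NucleusKey,
    tol: ToleranceConfig,
    method: str = "",
) -> DiscriminationResult:
    """Apply both filter criteria (strict inequalities on CI centres)."""
    tolerance = tol.for_atom(key.atom)
    passes_diff = abs(diff_ci.center) > tolerance
    passes_effect = abs(effect_ci.center) > tol.effect_size_threshold
    return DiscriminationResult(
        key=key,
        method=method,
        diff_ci=diff_ci,
        effect_ci=effect_ci,
        passes_diff=passes_diff,
        passes_effect=passes_effect,
        passes=passes_diff and passes_effect,
    )
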