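"""Ground-truth-labelled synthetic inputs for the full pipeline.

The generator emulates the statistical structure the analysis assumes:
per-nucleus, per-state, per-method skew-normal ensembles of predicted
shifts, four exchangeable subunits, optional two-component contamination
(bimodal ensembles), and experimental assignment tables produced from a
designated *true* state — the activated-condition shift is the population
mean of the true state plus small measurement noise, the deactivated shift
comes from the closed reference state.  Every scenario verifies analytically
that its planted marker classes are achievable by its own parameters before
any data are drawn.

Ensembles are parameterised by target population mean / sd / skewness
(:func:`skewnorm_from_moments` converts to location/scale), so the planted
ground truth is read directly off the scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayes import SkewNormalParams, skewnorm_mean, skewnorm_variance
from .classify import classify
from .cs_io import (
    EXP_COLUMNS,
    PRED_COLUMNS,
    NucleusKey,
    ToleranceConfig,
    stable_key_seed,
)

logger = logging.getLogger(__name__)

#: plausible backbone ppm ranges per nucleus type (centre values)
ATOM_BASE_PPM = {"CA": 55.0, "CB": 32.0, "C": 175.0, "N": 119.0}

SUBUNITS = ("A", "B", "C", "D")


def skewnorm_from_moments(mean: float, sd: float, alpha: float) -> SkewNormalParams:
    """Skew-normal with the requested *population* mean and sd at skewness alpha."""
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    var_factor = 1.0 - 2.0 * delta * delta / np.pi
    sigma = sd / np.sqrt(var_factor)
    mu = mean - sigma * np.sqrt(2.0 / np.pi) * delta
    return SkewNormalParams(mu=float(mu), sigma=float(sigma), alpha=float(alpha))


@dataclass(frozen=True)
class MixtureParams:
    """Two-component skew-normal mixture (bimodal contamination)."""

    components: tuple[SkewNormalParams, SkewNormalParams]
    weight: float  # weight of the first component

    def __post_init__(self) -> None:
        if not 0 < self.weight < 1:
            raise ValueError("mixture weight must lie in (0, 1)")

    @property
    def mean(self) -> float:
        w = self.weight
        return w * self.components[0].mean + (1 - w) * self.components[1].mean

    @property
    def variance(self) -> float:
        w = self.weight
        m = self.mean
        return sum(
            wi * (c.variance + (c.mean - m) ** 2)
            for wi, c in zip((w, 1 - w), self.components)
        )

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        pick = rng.uniform(size=size) < self.weight
        out = np.empty(size)
        n0 = int(pick.sum())
        if n0:
            out[pick] = self.components[0].rvs(n0, rng)
        if size - n0:
            out[~pick] = self.components[1].rvs(size - n0, rng)
        return out


Dist = SkewNormalParams | MixtureParams


@dataclass(frozen=True)
class NucleusSpec:
    """Planted truth for one nucleus: a distribution per (state, method)."""

    key: NucleusKey
    params: dict[str, dict[str, Dist]]  # state -> method -> distribution
    planted_class: str | None = None
    subunit_overrides: dict[str, dict[str, dict[str, Dist]]] = field(default_factory=dict)

    def dist(self, state: str, method: str, subunit: str | None = None) -> Dist:
        if subunit is not None and subunit in self.subunit_overrides:
            override = self.subunit_overrides[subunit]
            if state in override and method in override[state]:
                return override[state][method]
        return self.params[state][method]


@dataclass(frozen=True)
class SyntheticScenario:
    """A complete ground-truth parameter set for one end-to-end run."""

    name: str
    nuclei: tuple[NucleusSpec, ...]
    states: tuple[str, ...] = ("C", "PO", "FO")
    methods: tuple[str, ...] = ("SPARTA+",)
    n_frames: int = 250
    n_subunits: int = 4
    true_state: str = "PO"
    reference_state: str = "C"
    experimental_noise_sd: float = 0.05
    seed: int = 0
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)

    def __post_init__(self) -> None:
        if self.experimental_noise_sd < 0:
            raise ValueError("experimental noise sd must be >= 0")
        if self.true_state not in self.states or self.reference_state not in self.states:
            raise ValueError("true_state and reference_state must be among states")
        if not 1 <= self.n_subunits <= len(SUBUNITS):
            raise ValueError(f"n_subunits must be in 1..{len(SUBUNITS)}")
        self.verify_planted_classes()

    # -- analytic ground truth -------------------------------------------------

    def population_mean(self, spec: NucleusSpec, state: str) -> float:
        """Method-averaged population mean for a state (the experimental truth)."""
        return float(np.mean([spec.dist(state, m).mean for m in self.methods]))

    def expected_class(self, spec: NucleusSpec) -> str:
        """Marker class implied analytically by the planted parameters."""
        tol = self.tolerances.for_atom(spec.key.atom)
        means = {s: self.population_mean(spec, s) for s in ("C", "PO", "FO")}
        dpo_c = abs(means["PO"] - means["C"]) > tol
        dfo_c = abs(means["FO"] - means["C"]) > tol
        dfo_po = abs(means["FO"] - means["PO"]) > tol
        exp_delta = self.population_mean(spec, self.true_state) - self.population_mean(
            spec, self.reference_state
        )
        return classify(dpo_c, dfo_c, dfo_po, abs(exp_delta) > tol).label

    def verify_planted_classes(self) -> None:
        for spec in self.nuclei:
            if spec.planted_class is None:
                continue
            implied = self.expected_class(spec)
            if implied != spec.planted_class:
                raise ValueError(
                    f"scenario {self.name!r}: nucleus {spec.key.label} plants class "
                    f"{spec.planted_class} but its parameters imply {implied}"
                )

    # -- data generation -------------------------------------------------------

    def sample_ensemble(self, spec: NucleusSpec, state: str, method: str) -> pd.DataFrame:
        """n_subunits x n_frames shift records for one nucleus/state/method."""
        rows = []
        # the RNG stream is keyed by the state's *position* in the scenario,
        # not its label, so relabelling states permutes outputs exactly
        state_idx = self.states.index(state)
        method_idx = self.methods.index(method)
        for subunit in SUBUNITS[: self.n_subunits]:
            rng = np.random.default_rng(
                [self.seed, stable_key_seed(spec.key.label, state_idx, method_idx, subunit)]
            )
            dist = spec.dist(state, method, subunit)
            shifts = dist.rvs(self.n_frames, rng)
            for frame, shift in enumerate(shifts):
                rows.append(
                    (state, method, subunit, frame, spec.key.residue_number,
                     spec.key.residue_type, spec.key.atom, float(shift))
                )
        return pd.DataFrame(rows, columns=PRED_COLUMNS)

    def prediction_table(self) -> pd.DataFrame:
        """All ensembles of the scenario in the canonical long format."""
        parts = [
            self.sample_ensemble(spec, state, method)
            for spec in self.nuclei
            for state in self.states
            for method in self.methods
        ]
        return pd.concat(parts, ignore_index=True)

    def make_experimental_tables(self) -> pd.DataFrame:
        """Experimental assignments for both conditions from the planted truth.

        activated = population mean of the true state (+ noise);
        deactivated = population mean of the reference state (+ noise).
        """
        rows = []
        for spec in self.nuclei:
            rng = np.random.default_rng(
                [self.seed, stable_key_seed("experiment", spec.key.label)]
            )
            for condition, state in (
                ("activated", self.true_state),
                ("deactivated", self.reference_state),
            ):
                shift = self.population_mean(spec, state)
                if self.experimental_noise_sd > 0:
                    shift += rng.normal(scale=self.experimental_noise_sd)
                rows.append(
                    (spec.key.residue_number, spec.key.residue_type, spec.key.atom,
                     condition, float(shift))
                )
        return pd.DataFrame(rows, columns=EXP_COLUMNS)

    def relabel_states(self, mapping: dict[str, str]) -> "SyntheticScenario":
        """Scenario with state labels swapped (used for label-symmetry checks)."""
        new_nuclei = tuple(
            replace(
                spec,
                params={mapping.get(s, s): dict(per_m) for s, per_m in spec.params.items()},
                subunit_overrides={
                    su: {mapping.get(s, s): dict(per_m) for s, per_m in per_s.items()}
                    for su, per_s in spec.subunit_overrides.items()
                },
            )
            for spec in self.nuclei
        )
        return replace(
            self,
            nuclei=new_nuclei,
            states=tuple(mapping.get(s, s) for s in self.states),
            true_state=mapping.get(self.true_state, self.true_state),
            reference_state=mapping.get(self.reference_state, self.reference_state),
        )


# ---------------------------------------------------------------------------
# preset scenarios


_RESIDUE_CYCLE = "AVLIMFSTYQ"  # no glycine: every nucleus may carry a CB
_ATOM_CYCLE = ("CA", "CB", "C", "N")


def _nucleus_keys(n: int, start_residue: int = 30) -> list[NucleusKey]:
    keys = []
    for i in range(n):
        keys.append(
            NucleusKey(start_residue + i, _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)],
                       _ATOM_CYCLE[i % len(_ATOM_CYCLE)])
        )
    return keys


def _base_ppm(key: NucleusKey, rng: np.random.Generator) -> float:
    return ATOM_BASE_PPM[key.atom] + rng.uniform(-3.0, 3.0)


def _broadcast(states_to_mean: dict[str, float], sd: float, alpha: float,
               methods: tuple[str, ...]) -> dict[str, dict[str, Dist]]:
    return {
        state: {m: skewnorm_from_moments(mean, sd, alpha) for m in methods}
        for state, mean in states_to_mean.items()
    }


def preset_scenario(
    name: str,
    seed: int = 0,
    methods: tuple[str, ...] = ("SPARTA+",),
    n_frames: int = 250,
) -> SyntheticScenario:
    """Build one of the named preset scenarios.

    ``spectator_only``
        All states share one distribution per nucleus: every nucleus is a
        class-A spectator and nothing passes the discrimination filter.
    ``b1_panel``
        FO displaced from C = PO by 4x the isotope tolerance; experiment
        unchanged between conditions (true state PO): all class B1.
    ``e2_panel``
        C, PO, FO mutually separated by >= 3x tolerance with effect sizes
        >= 2 and the experiment following the PO state: all class E2, and
        the pipeline should assign PO at (nearly) every nucleus.
    ``fo_truth``
        The e2 geometry with the experiment following the FO state instead.
    ``bimodal_stress``
        Spectator panel whose ensembles are two-component mixtures with a
        3-sd gap, stressing the posterior-predictive envelope.
    ``tie_stress``
        Gaps placed exactly at the tolerance: with strict inequalities these
        nuclei are planted as non-distinguishing (class A boundary cases).
    """
    tol = ToleranceConfig()
    rng = np.random.default_rng([seed, stable_key_seed("preset", name)])
    alpha = 2.0  # mild skew everywhere: the model's own regime

    def panel(n, mean_fn, planted, sd_fn):
        nuclei = []
        for key in _nucleus_keys(n):
            base = _base_ppm(key, rng)
            t = tol.for_atom(key.atom)
            nuclei.append(
                NucleusSpec(
                    key=key,
                    params=_broadcast(mean_fn(base, t), sd_fn(t), alpha, methods),
                    planted_class=planted,
                )
            )
        return nuclei

    if name == "spectator_only":
        nuclei = panel(10, lambda b, t: {"C": b, "PO": b, "FO": b}, "A", lambda t: 2 * t)
        return SyntheticScenario(name=name, nuclei=tuple(nuclei), methods=methods,
                                 n_frames=n_frames, true_state="PO", seed=seed)
    if name == "b1_panel":
        nuclei = panel(12, lambda b, t: {"C": b, "PO": b, "FO": b + 4 * t}, "B1",
                       lambda t: t)
        return SyntheticScenario(name=name, nuclei=tuple(nuclei), methods=methods,
                                 n_frames=n_frames, true_state="PO", seed=seed)
    if name in ("e2_panel", "fo_truth"):
        nuclei = panel(20, lambda b, t: {"C": b, "PO": b + 4 * t, "FO": b - 4 * t}, "E2",
                       lambda t: 2 * t)
        return SyntheticScenario(
            name=name, nuclei=tuple(nuclei), methods=methods, n_frames=n_frames,
            true_state=("FO" if name == "fo_truth" else "PO"), seed=seed,
        )
    if name == "bimodal_stress":
        nuclei = []
        for key in _nucleus_keys(8):
            base = _base_ppm(key, rng)
            t = tol.for_atom(key.atom)
            sd = 2 * t
            mix = MixtureParams(
                components=(
                    skewnorm_from_moments(base - 1.5 * sd, sd, 0.0),
                    skewnorm_from_moments(base + 1.5 * sd, sd, 0.0),
                ),
                weight=0.5,
            )
            nuclei.append(NucleusSpec(
                key=key,
                params={s: {m: mix for m in methods} for s in ("C", "PO", "FO")},
                planted_class="A",
            ))
        return SyntheticScenario(name=name, nuclei=tuple(nuclei), methods=methods,
                                 n_frames=n_frames, true_state="PO", seed=seed)
    if name == "tie_stress":
        # population gaps sit exactly on the tolerance: with strict
        # comparisons the outcome hinges on the last floating-point ulp, so
        # no class is planted (that boundary ambiguity is the stress)
        nuclei = panel(8, lambda b, t: {"C": b, "PO": b, "FO": b + t}, None, lambda t: 2 * t)
        return SyntheticScenario(name=name, nuclei=tuple(nuclei), methods=methods,
                                 n_frames=n_frames, true_state="PO", seed=seed)
    raise ValueError(f"unknown preset scenario {name!r}")


PRESET_NAMES = (
    "spectator_only", "b1_panel", "e2_panel", "fo_truth", "bimodal_stress", "tie_stress",
)


def preset_scenarios(seed: int = 0, **kwargs) -> dict[str, SyntheticScenario]:
    """Catalog of all named preset scenarios."""
    return {name: preset_scenario(name, seed=seed, **kwargs) for name in PRESET_NAMES}
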