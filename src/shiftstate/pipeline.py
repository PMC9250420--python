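"""End-to-end orchestration: ingest -> QC -> subsample -> fit -> discriminate
-> assign -> classify -> report.

:func:`analyze` is the in-memory engine operating on canonical DataFrames;
:func:`run_pipeline` wraps it with file input declarations, per-stage
artifacts on disk and a posterior cache, driven by a :class:`RunConfig`
(optionally loaded from YAML).  Every per-(nucleus, state, method) fit gets
its own deterministic seed derived from the run seed, so two clean runs of
the same configuration produce identical verdict tables.
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cs_io
from .bayes import (
    PosteriorDraws,
    SamplerConfig,
    credible_interval,
    fit_posterior,
    mean_draws,
    variance_draws,
)
from .cs_io import NucleusKey, ToleranceConfig, stable_key_seed
from .discrimination import difference_in_means, effect_size, has_discrimination_power
from .assignment import (
    UNDETERMINED,
    assign_state,
    combine_method_verdicts,
    delta_cs_exp,
    delta_cs_sim,
    delta_delta_cs,
    marker_status,
    tally_verdicts,
)
from .classify import classify_all
from .structure import FrameWindow

logger = logging.getLogger(__name__)

KEY_COLS = ["residue_number", "residue_type", "atom"]


@dataclass
class InputDecl:
    """One prediction input: a file, its dialect, and its state/method labels."""

    path: str
    dialect: str
    state: str
    method: str
    frame: int | None = None


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    predictions: list[InputDecl]
    experimental_table: str
    output_dir: str
    reference_state: str = "C"
    candidate_states: tuple[str, str] = ("PO", "FO")
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    subsample_n: int = 2000
    seed: int = 0
    qc_windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    combine_methods: str = "any"  # how a nucleus counts as discriminating

    def validate(self) -> None:
        states = {d.state for d in self.predictions}
        if self.reference_state not in states:
            raise ValueError(f"no prediction input for reference state {self.reference_state!r}")
        if len(self.candidate_states) < 2:
            raise ValueError("need at least two candidate states")
        for cand in self.candidate_states:
            if cand not in states:
                raise ValueError(f"no prediction input for candidate state {cand!r}")
        for decl in self.predictions:
            if not Path(decl.path).exists():
                raise FileNotFoundError(decl.path)
        if not Path(self.experimental_table).exists():
            raise FileNotFoundError(self.experimental_table)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            predictions=[InputDecl(**d) for d in raw["predictions"]],
            experimental_table=raw["experimental_table"],
            output_dir=raw["output_dir"],
            reference_state=raw.get("reference_state", "C"),
            candidate_states=tuple(raw.get("candidate_states", ("PO", "FO"))),
            tolerances=ToleranceConfig(**raw.get("tolerances", {})),
            sampler=SamplerConfig(**raw.get("sampler", {})),
            subsample_n=raw.get("subsample_n", 2000),
            seed=raw.get("seed", 0),
            qc_windows={k: tuple(v) for k, v in raw.get("qc_windows", {}).items()},
            combine_methods=raw.get("combine_methods", "any"),
        )


@dataclass
class RunResult:
    """All per-stage output tables plus the aggregate report."""

    posterior_summary: pd.DataFrame
    discrimination: pd.DataFrame
    delta_table: pd.DataFrame
    verdicts: pd.DataFrame
    combined_verdicts: pd.DataFrame
    classes_per_method: pd.DataFrame
    classes_per_nucleus: pd.DataFrame
    report: dict


def _fit_seed(run_seed: int, key: NucleusKey, state: str, method: str) -> int:
    return (run_seed * 1_000_003 + stable_key_seed(key.label, state, method)) % (2**31)


def fit_all_posteriors(
    pred: pd.DataFrame,
    keys: Sequence[NucleusKey],
    states: Sequence[str],
    methods: Sequence[str],
    sampler: SamplerConfig,
    run_seed: int,
) -> dict[tuple[NucleusKey, str, str], PosteriorDraws]:
    """Independent skew-normal fits for every (nucleus, state, method)."""
    posteriors = {}
    for key in keys:
        for state in states:
            for method in methods:
                data = cs_io.shifts_for(pred, key, state=state, method=method)
                cfg = SamplerConfig(
                    n_chains=sampler.n_chains, draws=sampler.draws,
                    warmup=sampler.warmup, seed=_fit_seed(run_seed, key, state, method),
                    target_accept=sampler.target_accept,
                )
                posteriors[(key, state, method)] = fit_posterior(
                    data, config=cfg, key=key, state=state, method=method
                )
    return posteriors


def analyze(
    predictions: pd.DataFrame,
    experimental: pd.DataFrame,
    *,
    reference_state: str = "C",
    candidate_states: tuple[str, str] = ("PO", "FO"),
    tolerances: ToleranceConfig | None = None,
    sampler: SamplerConfig | None = None,
    subsample_n: int = 2000,
    seed: int = 0,
    qc_windows: dict[str, tuple[int, int]] | None = None,
    posteriors: dict | None = None,
) -> RunResult:
    """Run the statistical pipeline on in-memory canonical tables.

    ``candidate_states`` is ordered (first, second); the discrimination
    difference is second - first, i.e. FO - PO with the default order.
    Pre-computed ``posteriors`` (e.g. from a cache) may be passed to skip
    the sampling stage.
    """
    tol = tolerances or ToleranceConfig()
    sampler = sampler or SamplerConfig()
    if set(candidate_states) != {"PO", "FO"}:
        raise ValueError("candidate states must be PO and FO (in either order)")
    first, second = candidate_states[0], candidate_states[1]
    states = [reference_state, *candidate_states]
    mass = tol.ci_mass

    # --- QC windows, pooling, subsampling ------------------------------------
    pred = predictions
    if qc_windows:
        parts = []
        for state, group in pred.groupby("state"):
            if state in qc_windows:
                win = FrameWindow(*qc_windows[state])
                kept = group[(group["frame"] >= win.start) & (group["frame"] < win.end)]
                logger.info("qc: state %s kept %d/%d records in window [%d, %d)",
                            state, len(kept), len(group), win.start, win.end)
                parts.append(kept)
            else:
                parts.append(group)
        pred = pd.concat(parts, ignore_index=True)
    pred = cs_io.pool_subunits(pred)
    pred = cs_io.subsample(pred, subsample_n, seed)

    methods = sorted(pred["method"].unique())
    keys = cs_io.intersect_assigned(pred, experimental, states=states)
    logger.info("analyze: %d nuclei assigned in both conditions and predicted in all states",
                len(keys))

    # --- fits -----------------------------------------------------------------
    if posteriors is None:
        posteriors = fit_all_posteriors(pred, keys, states, methods, sampler, seed)

    summary_rows = []
    mean_cache: dict[tuple, np.ndarray] = {}
    var_cache: dict[tuple, np.ndarray] = {}
    for (key, state, method), post in posteriors.items():
        m = mean_draws(post)
        v = variance_draws(post)
        mean_cache[(key, state, method)] = m
        var_cache[(key, state, method)] = v
        ci = credible_interval(m, mass)
        summary_rows.append({
            "residue_number": key.residue_number, "residue_type": key.residue_type,
            "atom": key.atom, "state": state, "method": method,
            "cs_mean_center": ci.center, "cs_mean_low": ci.lower, "cs_mean_high": ci.upper,
            "rhat_max": max(post.diagnostics.get(f"rhat_{p}", np.nan)
                            for p in ("mu", "sigma", "alpha")),
            "ess_min": min(post.diagnostics.get(f"ess_{p}", np.nan)
                           for p in ("mu", "sigma", "alpha")),
            "n_warnings": len(post.warnings),
        })
    posterior_summary = pd.DataFrame(summary_rows)

    # --- experimental difference shifts --------------------------------------
    exp_wide = experimental.pivot_table(
        index=KEY_COLS, columns="condition", values="shift_ppm", aggfunc="first"
    )
    exp_delta_by_key = {}
    for key in keys:
        row = exp_wide.loc[(key.residue_number, key.residue_type, key.atom)]
        exp_delta_by_key[key] = delta_cs_exp(row["activated"], row["deactivated"])

    # --- discrimination filter -------------------------------------------------
    discr_rows = []
    for key in keys:
        for method in methods:
            diff_ci = difference_in_means(
                mean_cache[(key, second, method)], mean_cache[(key, first, method)], mass
            )
            eff_ci = effect_size(
                mean_cache[(key, second, method)], mean_cache[(key, first, method)],
                var_cache[(key, second, method)], var_cache[(key, first, method)], mass,
            )
            res = has_discrimination_power(diff_ci, eff_ci, key, tol, method)
            discr_rows.append({
                "residue_number": key.residue_number, "residue_type": key.residue_type,
                "atom": key.atom, "method": method,
                "diff_center": diff_ci.center, "diff_low": diff_ci.lower,
                "diff_high": diff_ci.upper,
                "effect_center": eff_ci.center, "effect_low": eff_ci.lower,
                "effect_high": eff_ci.upper,
                "passes_diff": res.passes_diff, "passes_effect": res.passes_effect,
                "passes": res.passes,
            })
    discrimination = pd.DataFrame(discr_rows)

    # --- difference shifts and verdicts ---------------------------------------
    delta_rows = []
    verdict_rows = []
    for key in keys:
        exp_d = exp_delta_by_key[key]
        for method in methods:
            dd_ci = {}
            for cand in (first, second):
                sim_draws, sim_ci = delta_cs_sim(
                    mean_cache[(key, cand, method)],
                    mean_cache[(key, reference_state, method)], mass,
                )
                _, dd = delta_delta_cs(sim_draws, exp_d, mass)
                dd_ci[cand] = dd
                delta_rows.append({
                    "residue_number": key.residue_number, "residue_type": key.residue_type,
                    "atom": key.atom, "method": method, "state": cand,
                    "sim_delta_center": sim_ci.center, "sim_delta_low": sim_ci.lower,
                    "sim_delta_high": sim_ci.upper, "exp_delta": exp_d,
                    "dd_center": dd.center, "dd_low": dd.lower, "dd_high": dd.upper,
                })
            passes = discrimination[
                (discrimination["residue_number"] == key.residue_number)
                & (discrimination["residue_type"] == key.residue_type)
                & (discrimination["atom"] == key.atom)
                & (discrimination["method"] == method)
            ]["passes"].iloc[0]
            if not passes:
                continue  # verdicts are defined only for discriminating nuclei
            verdict = assign_state(dd_ci["PO"], dd_ci["FO"], key, tol, method, exp_d)
            verdict_rows.append({
                "residue_number": key.residue_number, "residue_type": key.residue_type,
                "atom": key.atom, "method": method, "verdict": verdict.verdict,
                "dd_po_center": verdict.dd_po_center, "dd_fo_center": verdict.dd_fo_center,
                "marker_status": verdict.marker_status, "exp_delta": exp_d,
            })
    delta_table = pd.DataFrame(delta_rows)
    verdicts = pd.DataFrame(
        verdict_rows,
        columns=KEY_COLS + ["method", "verdict", "dd_po_center", "dd_fo_center",
                            "marker_status", "exp_delta"],
    )

    combined = (
        combine_method_verdicts(verdicts)
        if not verdicts.empty
        else pd.DataFrame(columns=KEY_COLS + ["verdict"])
    )

    # --- classification ---------------------------------------------------------
    marker_table = pd.DataFrame(
        [
            {"residue_number": k.residue_number, "residue_type": k.residue_type,
             "atom": k.atom, "exp_delta": exp_delta_by_key[k]}
            for k in keys
        ],
        columns=KEY_COLS + ["exp_delta"],
    )
    if delta_table.empty:
        classes_pm = pd.DataFrame()
        classes_pn = pd.DataFrame()
    else:
        classes_pm, classes_pn = classify_all(delta_table, discrimination, marker_table, tol)

    # --- report -----------------------------------------------------------------
    n_discr_any = (
        int(discrimination.groupby(KEY_COLS)["passes"].any().sum())
        if not discrimination.empty else 0
    )
    n_discr_all = (
        int(discrimination.groupby(KEY_COLS)["passes"].all().sum())
        if not discrimination.empty else 0
    )
    report = {
        "n_nuclei_considered": len(keys),
        "n_discriminating_any_method": n_discr_any,
        "n_discriminating_all_methods": n_discr_all,
        "n_verdicts": len(verdicts),
        "tally_nucleus": tally_verdicts(verdicts, "nucleus"),
        "tally_residue": tally_verdicts(combined, "residue") if not combined.empty
        else tally_verdicts(combined),
        "class_counts": (classes_pm["class"].value_counts().to_dict()
                         if not classes_pm.empty else {}),
        "n_markers": int((marker_table["exp_delta"].abs()
                          > marker_table["atom"].map(tol.for_atom)).sum())
        if not marker_table.empty else 0,
        "seed": seed,
        "sampler": asdict(sampler),
        "n_fit_warnings": int(posterior_summary["n_warnings"].sum())
        if not posterior_summary.empty else 0,
    }
    return RunResult(
        posterior_summary=posterior_summary,
        discrimination=discrimination,
        delta_table=delta_table,
        verdicts=verdicts,
        combined_verdicts=combined,
        classes_per_method=classes_pm,
        classes_per_nucleus=classes_pn,
        report=report,
    )


# ---------------------------------------------------------------------------
# file-based runner with cached posteriors


def _config_fingerprint(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "predictions": [asdict(d) for d in config.predictions],
            "experimental": config.experimental_table,
            "reference": config.reference_state,
            "candidates": list(config.candidate_states),
            "tol": asdict(config.tolerances),
            "sampler": asdict(config.sampler),
            "subsample_n": config.subsample_n,
            "seed": config.seed,
            "qc": {k: list(v) for k, v in config.qc_windows.items()},
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute a configured run, writing per-stage artifacts under output_dir.

    Posterior draws are cached (``posteriors_<fingerprint>.npz``); re-running
    an unchanged configuration reuses them, so the MCMC stage is never
    recomputed on downstream changes.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    pred = pd.concat(
        [
            cs_io.read_prediction_table(d.path, d.dialect, d.state, d.method, frame=d.frame)
            for d in config.predictions
        ],
        ignore_index=True,
    )
    exp = cs_io.read_experimental_table(config.experimental_table)
    cs_io.write_generic_long(pred, outdir / "predictions_normalized.tsv")

    fingerprint = _config_fingerprint(config)
    cache_path = outdir / f"posteriors_{fingerprint}.npz"
    if cache_path.exists():
        posteriors = _load_posterior_cache(cache_path, config.sampler)
        logger.info("run_pipeline: reused %d cached posteriors", len(posteriors))
    else:
        states = [config.reference_state, *config.candidate_states]
        pred_qc = pred
        if config.qc_windows:
            parts = []
            for state, group in pred.groupby("state"):
                if state in config.qc_windows:
                    win = FrameWindow(*config.qc_windows[state])
                    parts.append(group[(group["frame"] >= win.start)
                                       & (group["frame"] < win.end)])
                else:
                    parts.append(group)
            pred_qc = pd.concat(parts, ignore_index=True)
        pred2 = cs_io.subsample(cs_io.pool_subunits(pred_qc), config.subsample_n, config.seed)
        keys = cs_io.intersect_assigned(pred2, exp, states=states)
        methods = sorted(pred2["method"].unique())
        posteriors = fit_all_posteriors(pred2, keys, states, methods,
                                        config.sampler, config.seed)
        _save_posterior_cache(cache_path, posteriors)

    result = analyze(
        pred, exp,
        reference_state=config.reference_state,
        candidate_states=config.candidate_states,
        tolerances=config.tolerances,
        sampler=config.sampler,
        subsample_n=config.subsample_n,
        seed=config.seed,
        qc_windows=config.qc_windows,
        posteriors=posteriors,
    )

    result.posterior_summary.to_csv(outdir / "posterior_summary.tsv", sep="\t", index=False)
    result.discrimination.to_csv(outdir / "discrimination.tsv", sep="\t", index=False)
    result.delta_table.to_csv(outdir / "delta_shifts.tsv", sep="\t", index=False)
    result.verdicts.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
    result.combined_verdicts.to_csv(outdir / "verdicts_combined.tsv", sep="\t", index=False)
    if not result.classes_per_method.empty:
        result.classes_per_method.to_csv(outdir / "classes.tsv", sep="\t", index=False)
        result.classes_per_nucleus.to_csv(outdir / "classes_per_nucleus.tsv", sep="\t",
                                          index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    return result


def _save_posterior_cache(path: Path, posteriors: dict) -> None:
    arrays = {}
    for (key, state, method), post in posteriors.items():
        tag = f"{key.residue_number}|{key.residue_type}|{key.atom}|{state}|{method}"
        arrays[f"{tag}|mu"] = post.mu
        arrays[f"{tag}|sigma"] = post.sigma
        arrays[f"{tag}|alpha"] = post.alpha
    np.savez_compressed(path, **arrays)


def _load_posterior_cache(path: Path, sampler: SamplerConfig) -> dict:
    data = np.load(path)
    grouped: dict[tuple, dict] = {}
    for name in data.files:
        rn, rt, atom, state, method, param = name.split("|")
        grouped.setdefault((NucleusKey(int(rn), rt, atom), state, method), {})[param] = data[name]
    return {
        k: PosteriorDraws(mu=v["mu"], sigma=v["sigma"], alpha=v["alpha"],
                          seed=sampler.seed, config=sampler,
                          key=k[0], state=k[1], method=k[2])
        for k, v in grouped.items()
    }


# ---------------------------------------------------------------------------
# figure data


def make_figures(result: RunResult, outdir: str | Path, render: bool = True) -> dict[str, Path]:
    """Emit plot-ready tables (and rendered PNGs) for the two summary figures.

    ``filtering_panel.tsv`` holds per-nucleus difference-in-means and
    effect-size credible intervals with the tolerance band (dot-and-bar
    panels); ``dd_panel.tsv`` holds the paired |ddCS| bars per candidate
    state, omitting (nucleus, method) rows that failed discrimination.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    filt = result.discrimination.copy()
    tol = ToleranceConfig()
    if not filt.empty:
        filt["tolerance"] = filt["atom"].map(tol.for_atom)
        filt["effect_threshold"] = tol.effect_size_threshold
    path = outdir / "filtering_panel.tsv"
    filt.to_csv(path, sep="\t", index=False)
    written["filtering_panel"] = path

    if result.delta_table.empty:
        dd = result.delta_table.copy()
    else:
        passing = result.verdicts[KEY_COLS + ["method"]]
        dd = result.delta_table.merge(passing, on=KEY_COLS + ["method"], how="inner")
        if not dd.empty:
            dd["tolerance"] = dd["atom"].map(tol.for_atom)
    path = outdir / "dd_panel.tsv"
    dd.to_csv(path, sep="\t", index=False)
    written["dd_panel"] = path

    if render and not filt.empty:
        written.update(_render_figures(filt, dd, outdir))
    return written


def _render_figures(filt: pd.DataFrame, dd: pd.DataFrame, outdir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    labels = filt["residue_type"] + filt["residue_number"].astype(str) + filt["atom"]
    y = np.arange(len(filt))
    fig, axes = plt.subplots(1, 2, figsize=(9, 0.25 * len(filt) + 2), sharey=True)
    for ax, stem, band in (
        (axes[0], "diff", filt["tolerance"] if "tolerance" in filt else None),
        (axes[1], "effect", filt["effect_threshold"] if "effect_threshold" in filt else None),
    ):
        center = filt[f"{stem}_center"]
        ax.hlines(y, filt[f"{stem}_low"], filt[f"{stem}_high"], color="0.5", lw=1)
        ax.plot(center, y, "o", ms=3, color="C0")
        if band is not None:
            lim = band.to_numpy()
            ax.fill_betweenx(y, -lim, lim, color="green", alpha=0.15, lw=0)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("difference in means (ppm)" if stem == "diff" else "effect size")
    axes[0].set_yticks(y, labels)
    fig.tight_layout()
    p = outdir / "filtering_panel.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["filtering_panel_png"] = p

    if not dd.empty:
        piv = dd.pivot_table(index=KEY_COLS + ["method"], columns="state",
                             values="dd_center", aggfunc="first").reset_index()
        lab = piv["residue_type"] + piv["residue_number"].astype(str) + piv["atom"] \
            + "/" + piv["method"]
        x = np.arange(len(piv))
        fig, ax = plt.subplots(figsize=(0.4 * len(piv) + 2, 4))
        ax.bar(x - 0.2, piv.get("PO", np.nan), width=0.4, label="PO", color="C0")
        ax.bar(x + 0.2, piv.get("FO", np.nan), width=0.4, label="FO", color="C1")
        ax.set_xticks(x, lab, rotation=90, fontsize=7)
        ax.set_ylabel("|ddCS| CI centre (ppm)")
        ax.legend()
        fig.tight_layout()
        p = outdir / "dd_panel.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["dd_panel_png"] = p
    return written
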