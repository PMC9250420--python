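# shiftstate

Bayesian comparison of simulated NMR chemical-shift ensembles for
conformational-state assignment.

## The problem

Membrane-protein states that resist crystallography — such as the
short-lived *activated* (open, conductive) state of the KcsA potassium
channel — can be probed by solid-state NMR under near-native conditions,
but the spectra alone do not say which candidate structure the sample
adopts. If molecular-dynamics ensembles are seeded from the candidate
crystal structures (here: Partially Open **PO**, Fully Open **FO**, and a
Closed reference **C**) and converted to predicted chemical shifts per
snapshot, the question becomes statistical: *which simulated ensemble best
explains the measured shifts?* `shiftstate` is a pipeline for answering
that question, for structural-NMR and MD practitioners.

## The method

For each nucleus (N, C′, Cα, Cβ), state and prediction method, the ensemble
of predicted shifts *d* is modelled with a skew-normal likelihood

    L(d | μ, σ, α) = (2/σ) φ((d−μ)/σ) Φ(α(d−μ)/σ)

with priors μ ~ N(d̄, 10 ppm), σ ~ HalfCauchy(10 ppm), α ~ N(0, 10), sampled
by seeded MCMC (4 chains). The NMR peak position is identified with the
distribution mean μ + σ√(2/π)·α/√(1+α²), a posterior quantity summarised by
its 94% highest-density interval. The pipeline then:

1. **filters** — a nucleus discriminates PO from FO when the
   difference-in-means CI centre exceeds the experimental tolerance
   (0.2 ppm ¹³C / 0.5 ppm ¹⁵N) *and* the effect-size CI centre exceeds 0.5,
   where effect = (mean_FO − mean_PO)/√((var_FO+var_PO)/2);
2. **assigns** — compares ΔCS_sim^X = CS_sim^X − CS_sim^C against
   ΔCS_exp = CS_exp^act − CS_exp^deact via ΔΔCS^X = |ΔCS_sim^X − ΔCS_exp|:
   the state with the smaller CI centre wins (both under tolerance →
   undetermined). Differencing against the closed reference cancels
   referencing and other systematic errors;
3. **classifies** — every nucleus gets a marker class (A, B1/B2, C1/C2,
   D1/D2, E1/E2) from the three pairwise distinguishabilities plus the
   experimental marker/spectator status, and verdicts are tallied at
   nucleus and residue (majority-vote) level.

A fully parameterised synthetic-data generator (known ground truth, planted
marker classes, four exchangeable subunits, optional bimodal contamination)
makes every stage testable end to end. Small structural utilities compute
the inner-gate cross-bundle Cα–Cα distance from a PDB tetramer, frame
windows for trajectory curation, and selectivity-filter occupancy strings.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Generate a panel of 20 synthetic nuclei whose three states are mutually
separated by 4× the experimental tolerance, with the experiment generated
from the PO state, and run the full pipeline:

```python
from shiftstate import SamplerConfig, analyze, preset_scenario

scenario = preset_scenario("e2_panel", seed=7, n_frames=100)
result = analyze(
    scenario.prediction_table(),
    scenario.make_experimental_tables(),
    sampler=SamplerConfig(draws=400, warmup=400),
    subsample_n=400,
    seed=7,
)
r = result.report
print(f"nuclei considered:        {r['n_nuclei_considered']}")
print(f"discriminating (any):     {r['n_discriminating_any_method']}")
print(f"nucleus-level tally (%):  {r['tally_nucleus']}")
print(f"marker classes:           {r['class_counts']}")
print(result.verdicts.head(3).to_string(index=False))
```

prints

```
nuclei considered:        20
discriminating (any):     20
nucleus-level tally (%):  {'PO': 100.0, 'FO': 0.0, 'undetermined': 0.0}
marker classes:           {'E2': 20}
 residue_number residue_type atom  method verdict  dd_po_center  dd_fo_center marker_status  exp_delta
             30            A   CA SPARTA+      PO      0.054000      1.599041        marker   0.779870
             31            V   CB SPARTA+      PO      0.052233      1.512993        marker   0.774849
             32            L    C SPARTA+      PO      0.028173      1.580264        marker   0.796301
```

Every nucleus passes the discrimination filter, the |ΔΔCS| centre is an
order of magnitude smaller for PO than for FO (e.g. 0.05 vs 1.60 ppm at
A30 Cα), all verdicts recover the planted PO truth, and all 20 nuclei land
in class E2 (all three states distinct, experimental shift observed) — the
class with the strongest diagnostic power.

File-based runs work the same way through the CLI:

```bash
shiftstate simulate e2_panel --seed 7 --outdir data/
shiftstate run --config run.yaml          # ingest -> fit -> ... -> report
shiftstate gate-distance structure.pdb --residue 112
```

`run` writes per-stage TSV artifacts, cached posterior draws, figure tables
and a JSON report under the configured output directory.

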