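# il4redox

Mass-action modeling of redox regulation in IL-4/JAK/STAT6 signaling.

Cytokine receptors transiently produce reactive oxygen species (ROS,
chiefly H2O2) on ligation, and ROS reversibly oxidize the active-site
cysteine of protein tyrosine phosphatases (PTPs), among other targets.
Which of several candidate redox mechanisms — PTP inactivation,
receptor/JAK-kinase inactivation, redox-driven relocation of a nuclear
phosphatase — actually shapes IL-4 signaling is not directly
measurable. This package implements a computational strategy for that
question, aimed at systems biologists working with phospho-flow time
courses: exploit the characteristic *two-peaked* shape of the total
pSTAT6 response over two hours to discriminate network topologies, and
then embed the winning mechanisms in a quantitative, predictive model.

It provides:

- **`network_library`** — a combinatorial library of 16 reduced IL-4
  network topologies (all combinations of four regulatory mechanisms
  over a fixed core), each compiled to an elementary mass-action ODE
  system `dx/dt = N v(x)`, with `v_r = k_r Π x_i` over reactant
  multisets.
- **`mc_screen`** — Monte-Carlo topology selection: rate constants are
  sampled log-uniformly over one decade around a center vector
  (50,000 draws per topology at full scale), each draw is integrated
  over 0–120 min, and topologies are ranked by the fraction of traces
  whose total pSTAT6 shows two distinct local maxima (strict 0.1%
  pass threshold), plus a quantitative match of peak-shape feature
  densities against a measured curve.
- **`ros_input`** — ROS input inference from cumulative
  dye-oxidation (DCFDA) time courses: Hill-curve fits, closed-form
  derivatives, and input profiles `u(t) = a + b·dHill/dt` with
  optional exponentially decaying H2O2 boluses.
- **`systems_model`** — the detailed IL-4 model: receptor activation,
  two-step enzyme kinetics, two reversibly oxidized phosphatases (P1
  acting on pSTAT6, P2 on the active receptor), saturating SOCS
  feedback, STAT6 turnover, phospho-dependent nuclear cycling, and
  pharmacological condition switches (DPI, exogenous H2O2, CHX,
  MG132).
- **`fitting`** — a (μ+λ) evolutionary strategy with hyper-mutation
  minimizing `Σ ((y−e)/(e·σ))²` in log-parameter space, with
  per-species affine observation scalings profiled out by weighted
  least squares.
- **`synthetic_data`** — a generator of flow-cytometry-style
  normalized-MFI datasets (mean ± SEM, 3 replicates, 5% CV) and dye
  curves from a vetted truth parameterization, so the whole pipeline
  runs and is tested without any external data.

See `docs/methods.md` for the model assumptions, parameter defaults
and calibration choices.

## Worked example

Simulate the fitted systems model under IL-4 and under DPI
pretreatment, and classify the pSTAT6 trace:

```python
from il4redox import Il4SystemsModel, STANDARD_CONDITIONS, extract_features

model = Il4SystemsModel()
il4 = model.simulate_condition(STANDARD_CONDITIONS["IL4"])
dpi = model.simulate_condition(STANDARD_CONDITIONS["IL4+DPI"])
f = extract_features(il4["pSTAT6"].to_numpy(), il4["time_min"].to_numpy())
print(f"pSTAT6 peaks: {f.n_peaks} (t1={f.t1:.0f} min, t2={f.t2:.0f} min, "
      f"h2/h1={f.ratio_heights:.2f})")
print(f"DPI peak / IL-4 peak: {dpi['pSTAT6'].max() / il4['pSTAT6'].max():.3f}")
```

prints

```
pSTAT6 peaks: 2 (t1=10 min, t2=40 min, h2/h1=0.72)
DPI peak / IL-4 peak: 0.109
```

i.e. the model produces the two-peaked response (first maximum at
10 min, second at 40 min at 72% of the first), and suppressing ROS
production caps STAT6 phosphorylation at ~11% of the control peak.

A small topology screen (2,000 draws here; 50,000 at full scale):

```python
from il4redox import enumerate_topologies, run_mc_screen

res = run_mc_screen([t for t in enumerate_topologies()
                     if t.label in ("P+D", "P", "core")],
                    n_samples=2000, seed=0)
print(res.summary()[["topology", "two_peak_count", "fraction", "passes"]]
      .to_string(index=False))
```

prints

```
topology  two_peak_count  fraction  passes
    core               0    0.0000   False
       P               0    0.0000   False
     P+D             293    0.1465    True
```

PTP oxidation combined with phospho-dependent STAT6 cycling (`P+D`)
produces two-peaked dynamics in ~15% of parameter draws; the same
mechanism with phosphorylation-independent cycling (`P`), or the core
network alone, essentially never does.

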