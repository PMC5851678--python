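# conformo

Single-molecule FRET analysis of conformational dynamics in diffusing
proteins — with the binding thermodynamics and structure-based dye
modelling that accompany such a study.

## The problem

G-domain proteins such as the translation elongation factor EF-Tu switch
between a compact, GTP-associated *closed* conformation and a loose,
GDP-associated *open* conformation.  Single-pair FRET on freely
diffusing molecules can watch this cycle one molecule at a time: a donor
and an acceptor dye attached to two domains report the inter-dye
distance through the transfer efficiency `E = 1/(1 + (R/R0)^6)`, and the
millisecond kinetics of opening and closing leave a characteristic
signature in the photon statistics.  `conformo` implements the full
computational chain for such an experiment:

- **`conformo.simulate`** — photon-level simulation of labelled
  molecules diffusing through a Gaussian confocal volume with alternating
  two-color excitation, exact Markov interconversion between
  Gaussian-distance conformational states, dye-linker dynamics,
  fluorescence lifetimes, anisotropy and background.  Photon-HDF5
  compatible IO.
- **`conformo.bursts`** — all-photon sliding-window burst search
  (500 µs / 5 / 50 defaults), the ALEX-2CDE kernel-density filter,
  corrected FRET efficiency and stoichiometry, burst-wise
  maximum-likelihood lifetimes, anisotropy with Perrin analysis, and
  static/dynamic FRET lines.
- **`conformo.pda`** — static and *dynamic* photon distribution
  analysis: shot-noise-exact proximity-ratio histograms for Gaussian
  states, the exact occupancy-time law of a two-state Markov chain
  inside each time bin (0.2 / 0.5 / 0.75 / 1 ms), global multi-histogram
  simplex fitting with parameter linking, profile-likelihood confidence
  intervals, dwell times and equilibrium distance distributions.
- **`conformo.thermo`** — one-site ITC isotherm simulation and fitting,
  the Gibbs relations `dG = -RT ln(1/Kd)` and `dG = dH - T dS`,
  Kirchhoff dissection (`dCp` from `dH(T)`), the Murphy–Freire
  surface-area parameterization, and stopped-flow `kon`/`koff`/`Kd`.
- **`conformo.structmap`** — per-residue solvent accessibility
  (Shrake–Rupley) with exposure classification, buried surface between
  conformations, and accessible-volume dye clouds with FRET-averaged
  inter-dye distances `<R_DA>_E`.

Dynamic PDA is the scientific core: the acceptor count of a bin with
`F` photons is binomial with an apparent probability set by the
occupancy-weighted average of the two exchanging states, so fitting the
proximity-ratio histograms of several bin durations *simultaneously*
separates true conformational heterogeneity from shot noise and yields
the opening/closing rate constants — including the regime where states
are not resolved as separate peaks.

## Worked example

Simulate a two-state system (closed 41 Å / open 62 Å, symmetric exchange
at 1/ms, `R0 = 53 Å`), run the burst pipeline and fit dynamic PDA:

```python
from conformo.simulate import (SimulationConfig, StateModel,
                               FretCalibration, simulate_photon_stream)
from conformo.bursts import analyze_bursts, CorrectionSet
from conformo.pda import rebin_bursts, PdaModel, global_fit, dwell_and_pdf

states = StateModel(states=[(41.0, 3.3), (62.0, 5.0)],
                    rate_matrix=[[0.0, 1.0], [1.0, 0.0]])   # 1/ms
config = SimulationConfig(mode="event", n_bursts=600, seed=1,
                          peak_brightness=1.5e5, gamma=0.69, crosstalk=0.01)
stream = simulate_photon_stream(config, states, FretCalibration())

table, summary = analyze_bursts(stream, CorrectionSet(beta=0.01, gamma=0.69),
                                lifetimes=False, anisotropies=False)
dataset = rebin_bursts(table, gamma=0.69, beta=0.01, label="demo")

model0 = PdaModel(R1=45.0, R2=58.0, width_fraction=0.06, linker_width=5.0,
                  kind="dynamic", k12=[0.5], k21=[2.0], A3=[0.0])
fit = global_fit([dataset], model0, n_restarts=3, seed=0)
m = fit.model
print(f"chi2_red = {fit.chi2_red:.2f}")
print(f"R_closed = {m.R1:.1f} A, R_open = {m.R2:.1f} A")
print(f"k_opening = {m.k12[0]:.2f} /ms, k_closing = {m.k21[0]:.2f} /ms")
d = dwell_and_pdf(fit)["datasets"][0]
print(f"closed dwell = {d['dwells']['state1_ms']:.2f} ms, "
      f"open dwell = {d['dwells']['state2_ms']:.2f} ms")
```

Output:

```
chi2_red = 1.23
R_closed = 40.2 A, R_open = 62.3 A
k_opening = 1.40 /ms, k_closing = 1.09 /ms
closed dwell = 0.72 ms, open dwell = 0.91 ms
```

The fit recovers the generating distances to within an Ångström and the
1/ms exchange rates to within the statistical precision of this small
run (600 molecule transits); `chi2_red < 3` with trend-free residuals is
the documented goodness criterion.  At full scale (2000 transits, at
least 3000 bins per bin duration) the 95% profile confidence intervals
of both rates are below 25% relative width — see the acceptance script.

A command-line layer wraps the same functionality:

```
conformo simulate --config sim.toml --out run.h5 --mode event --seed 1
conformo bursts run.h5 --corrections corr.toml --out bursts.csv
conformo pda-fit run.h5 --model dynamic --gamma 0.69 --beta 0.01 --ci --out fit.json
conformo itc fit titration.csv --cell-conc 1e-5 --syringe-conc 2e-4 --out thermo.json
conformo sasa structure.pdb --sites 61,158,382 --out exposure.csv
conformo av structure.pdb --donor-site 82 --acceptor-site 222 --out av.json
```

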