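# atdfret

Single-molecule FRET (smFRET) analysis of a receptor domain that separates in
two discrete, ligand-driven steps — simulation, trace processing, histogram
analysis, idealization, and dwell-time kinetic modeling in one tested package.

## The problem

NMDA-receptor amino-terminal domains (ATDs) report receptor activation as a
change in inter-dimer distance. smFRET traces of single receptors at 100-ms
frames show three conformational states — FRET ≈ 0.52 (resting, R),
≈ 0.40 (one glutamate site occupied, RA), ≈ 0.28 (both occupied, RAA) — whose
occupancies and transition rates depend on glutamate concentration. For two
identical, independent binding sites with per-site association rate constant
k_on (µM⁻¹s⁻¹) and dissociation rate constant k_off (s⁻¹), the chain is

    R  ⇌  RA  ⇌  RAA        forward: 2·k_on·c,  k_on·c
                             backward: k_off,  2·k_off

with per-site dissociation constant K_d = k_off/k_on and equilibrium
occupancy Binomial(2, θ), θ = c/(c + K_d). The package recovers k_on, k_off,
and K_d from noisy donor/acceptor traces by the standard single-molecule
workflow:

1. **simulate** — Gillespie realizations of the chain rendered into
   donor/acceptor intensities with 10.5 % donor→acceptor crosstalk, γ = 1.1
   detection asymmetry, Gaussian channel noise, and single-step donor and
   acceptor photobleaching, grouped into movies (`atdfret.synthetic`);
2. **process** — corrected FRET E = (I_A − 0.105·I_D)/(I_D + I_A) with the
   donor pre-scaled by γ; change-point photobleach detection; selection of
   traces with single-donor and single-acceptor bleaching, stable total
   intensity, and ≥ 20 s of usable FRET; per-movie normalized histograms with
   across-movie SEM (`atdfret.traces`);
3. **histogram analysis** — per-movie and global (shared-mean) Gaussian fits,
   activated-state occupancy, three-parameter logistic dose–response
   (EC50, Hill), and Student t tests (`atdfret.histograms`);
4. **idealize** — segmental k-means (SKM: iterated Viterbi segmentation with
   re-estimation), zero-FRET-state removal, transition-density plots, and
   dwell extraction with 200-ms dead-time merging (`atdfret.idealize`);
5. **kinetics** — maximum-likelihood fitting (MIL) of dead-time-conditioned
   dwell sequences: truncated-exponential dwell densities with branching
   probabilities, constrained (independent-sites) or free rates, Kd with
   delta-method errors, and alternative-scheme comparison
   (`atdfret.kinetics`).

## Worked example

Simulate an experiment at 300 nM glutamate from the default scheme
(k_on = 1.0 µM⁻¹s⁻¹, k_off = 0.46 s⁻¹, so K_d = 0.46 µM), then run the full
chain back to the rate constants:

```python
import atdfret as af

kp = af.KineticParams(kon=1.0, koff=0.46, conc=0.3)       # Kd = 0.46 uM
ts = af.simulate_experiment(kp, n_movies=15, traces_per_movie=120,
                            duration=60.0, seed=7)
fts, reasons = af.select_traces(ts)
print(f"selected {len(fts)} of {len(ts)} traces")

ens = af.skm_idealize_ensemble(fts, n_states=3, seed=0)
print("SKM state means:", ens.state_means.round(3))

dwells = [af.extract_dwells(it, dead_time=0.2) for it in ens.traces]
dwells = [d for d in dwells if d.dwells]
fit = af.fit_rates(dwells, af.SchemeSpec("linear", "independent_sites", conc=0.3))
print(f"kon  = {fit.rates['kon']:.2f} /uM/s")
print(f"koff = {fit.rates['koff']:.2f} /s")
print(f"Kd   = {fit.kd:.2f} +/- {fit.kd_se:.2f} uM")
```

which prints

```
selected 62 of 1800 traces
SKM state means: [0.522 0.401 0.278]
kon  = 0.75 /uM/s
koff = 0.36 /s
Kd   = 0.48 +/- 0.03 uM
```

Only ~3–5 % of traces survive the photobleaching-based selection (both dyes
must bleach, in order, inside the 60-s observation window with ≥ 20 s of
usable FRET first) — that is the point of the filter: it authenticates single
molecules. The three SKM state means land on the configured emission levels,
and the constrained dwell-time fit returns K_d within its standard error of
the generator's 0.46 µM.

A configuration-driven command line drives the same chain stage by stage
(`simulate → process → histfit → doseresponse → idealize → kinetics`), with
TSV/JSON artifacts on disk and a deterministic JSON run report:

```sh
atdfret all --config config.yaml --outdir out/ --seed 7
atdfret simulate --outdir out/ --seed 7      # or stage by stage
```

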