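# gpcuq

Polynomial-chaos surrogate models for global sensitivity analysis and
Bayesian parameter estimation of expensive biological models, demonstrated
end-to-end on two models of the budding-yeast mating response:

- **Model 1** — the heterotrimeric G-protein cycle (4 ODE species, 8 rate
  constants), whose output is the free-Gβγ fraction Gbg/Gt on a
  time-course / dose-response observation grid;
- **Model 2** — a mechanistic reaction–diffusion model of
  pheromone-induced Cdc42 polarization on a circular membrane (11 membrane
  fields + 2 conserved cytoplasmic pools, 35 parameters), whose output is
  the polarization factor (PF) of active Cdc42 at steady state.

The package is for modellers who need parameter analysis of simulators too
expensive to call inside a sampling loop. The idea: map the parameters to
the cube [−1, 1]ⁿ with a uniform prior, fit a total-degree Legendre
expansion

    z(y) ≈ Σ_{|α| ≤ d} c_α Π_k P_{α_k}(y_k)

to a modest number of simulator runs — by least squares when oversampled,
or by compressed sensing (min ‖c‖₁ s.t. ‖Ac − b‖₂ ≤ ε) when the basis is
larger than the sample budget — and then do everything else on the
surrogate. Global derivative-based sensitivities come out analytically
(S_j = E[∂z/∂y_j] is a signed sum of coefficients), parameters below a
sensitivity threshold can be screened out, and Metropolis–Hastings MCMC
with a Gaussian likelihood costs one polynomial evaluation per step
instead of one simulation, which makes 10⁶–10⁷-step chains routine.
Simulated annealing on the surrogate refines point estimates.

## Worked example

The two-parameter G-protein study, end to end (also available through the
CLI, see below):

```python
import numpy as np
from gpcuq import gprotein as gp, bundled_space, fit_surrogates
from gpcuq.surrogate import SampleSet
from gpcuq.sensitivity import sensitivity_report
from gpcuq.synth import GProteinDatasetSpec, generate_gprotein_dataset
from gpcuq.inference import GaussianLikelihood, MCMCConfig, mh_chain, posterior_summary

space = bundled_space("gprotein2")          # kGa, kGd on log scales
Y = space.sample_uniform(1000, seed=0)      # cube samples
Z = np.array([gp.response_vector(
        gp.BASELINE.with_values(**space.natural_dict(space.from_cube(y))))
      for y in Y])
surrogates = fit_surrogates(SampleSet(Y=Y, Z=Z, seed=0), degree=10, space=space)

rep = sensitivity_report(surrogates)
print("mean sensitivities:",
      {n: round(s, 3) for n, s in zip(rep.names, rep.mean_over_responses)})

data = generate_gprotein_dataset(GProteinDatasetSpec(
    params=gp.BASELINE.with_values(kGa=1e-5, kGd=0.11), seed=1))
chain = mh_chain(
    MCMCConfig(chain_length=1_000_000, burn_in=100_000, proposal_sd=0.12, seed=2),
    GaussianLikelihood(surrogates, data), space)
summ = posterior_summary(chain, space)
print("posterior mode:", {n: f"{v:.2e}" for n, v in zip(summ.names, summ.mode)})
print("kGa-kGd correlation:", round(summ.correlation[0, 1], 3))
```

Output (~2 minutes, one CPU):

```
mean sensitivities: {'kGa': np.float64(0.431), 'kGd': np.float64(-0.322)}
posterior mode: {'kGa': '1.15e-05', 'kGd': '1.51e-01'}
kGa-kGd correlation: 0.999
```

Reading: averaged over the 15 observation responses, raising the
G-protein activation rate kGa raises free Gβγ (sensitivity +0.43 per unit
of the log-mapped cube coordinate) and raising the deactivation rate kGd
lowers it (−0.32) — these two dominate all other rates. The posterior
over (kGa, kGd) given the synthetic dataset (generated at
kGa = 10⁻⁵, kGd = 0.11) peaks near the generating values and is almost
perfectly correlated along the diagonal: the data constrain the
activation/deactivation *ratio* far more tightly than either rate alone.

The spatial model is driven the same way:

```python
from gpcuq import polarization as pol
res = pol.simulate_to_steady(pol.BASELINE, pol.Geometry(), t_end=1000.0, dt=0.05)
c42a = res.state.field("C42a")
pf = pol.polarization_factor(c42a, res.geometry)       # 0.680 at baseline
z  = pol.cutoff_response(pf, c42a.max(), pol.BASELINE, res.geometry)
```

A shallow ligand gradient (10 ± 0.2 nM across the cell) is amplified by
the Bem1–Cdc24–Cdc42 positive feedback into a sharp cap of active Cdc42
at the up-gradient pole; PF = 0 would be an unpolarized cell, PF → 1 an
infinitely sharp cap.

## Command-line pipeline

Each stage reads its predecessor's files, writes plain CSV/JSON, and
records a manifest (seed + config hash) next to every artifact:

```bash
gpcuq synth --kind gprotein --seed 5 --out data.csv
gpcuq sample --model gprotein --space gprotein2 --count 1000 --seed 3 --out samples.csv
gpcuq fit --samples samples.csv --degree 10 --space gprotein2 --out-prefix sur
gpcuq cv --samples samples.csv --degree 10 --folds 12
gpcuq sensitivity sur_*.json --threshold 0.01 --out sens.csv
gpcuq screen sur_*.json --space gprotein2 --threshold 0.01 --out reduced.json
gpcuq mcmc sur_*.json --data data.csv --space gprotein2 --steps 1000000 --out chain.csv
gpcuq converge chain1.csv chain2.csv --space gprotein2
gpcuq summarize --chain chain.csv --space gprotein2
gpcuq anneal --surrogate sur_z.json --target 0.87 --start "[0.0, 0.0]"
```

`gpcuq sample --model polarization` supports `--checkpoint` for
restartable (and partitionable) PDE sampling campaigns.

## Layout

| module | contents |
| --- | --- |
| `gpcuq.spaces` | parameter specs, cube bijection, bundled spaces |
| `gpcuq.gprotein` | Model 1 ODE, response vector, MSE, observation CSV I/O |
| `gpcuq.polarization` | Model 2 PDE, Crank–Nicolson stepper, PF, cutoff response |
| `gpcuq.surrogate` | multi-index bases, design matrices, LS and ℓ1 fits, CV |
| `gpcuq.sensitivity` | analytic S_j, mean-|S| estimates, threshold screening |
| `gpcuq.inference` | Gaussian likelihood, MH-MCMC, convergence check, summaries, annealing |
| `gpcuq.synth` | synthetic datasets, von-Mises profiles, PDE sample campaigns |
| `gpcuq.cli` | the `gpcuq` console pipeline |

`docs/methods.md` documents the models, numerics and design decisions in
detail.
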