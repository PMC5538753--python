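# stressim

Deterministic population genetics of **stress-induced mutagenesis (SIM)**:
when can an allele that raises mutation rates *only under stress* persist in
a population purely through second-order selection?

Many bacteria switch on error-prone repair pathways under stress (SOS
response, stress-induced competence), effectively becoming transient
mutators. A SIM allele confers no direct fitness benefit; it can spread only
by hitchhiking with the beneficial (e.g. antibiotic-resistance) mutations it
generates while stress lasts, and it steadily decays by loss-of-function
mutation the rest of the time. `stressim` implements the minimal model of
this trade-off and the treatment-scheduling questions it raises: does
cycling several drugs maintain a mutator more readily than repeating one, and
does combining drugs suppress it?

## Model

An effectively infinite haploid population carries a SIM locus (`M`/`m`) and
one resistance locus (`R`/`r`) per stress, all completely linked
(no recombination). Genotype frequencies `p` follow replicator–mutator
dynamics

```
dp/dt = p (w − w̄) + M p
```

with, per unit time:

| symbol  | meaning                                              | benchmark |
|---------|------------------------------------------------------|-----------|
| `s`     | selective advantage of resistance during its stress  | 1         |
| `σ`     | mutation-rate amplification by an active SIM allele  | 100       |
| `μ_M`   | loss rate of the SIM allele (no back-mutation)       | 10⁻³      |
| `μ_R`   | loss rate of a resistance allele                     | 10⁻²      |
| `ν_R`   | gain rate of a resistance allele                     | 10⁻⁴      |

Under no stress all genotypes have fitness 1 and only mutation acts (a linear
flow, solved exactly by a matrix exponential). Under stress, resistant
genotypes gain `+s` per active stress (additively for simultaneous stresses),
and a genotype that carries `M` *and* is susceptible to a current stress has
all its outgoing mutation rates multiplied by `σ`. The environment alternates
stress phases (`τ_S`) with no-stress phases (`τ_NS`); the cycle length is
`τ = τ_S + τ_NS`.

Sampling the SIM frequency once per cycle collapses the dynamics to a
one-dimensional recursion whose fixed points have closed forms, governed by

```
Γ = (s/σ + μ_M + ν_R) / μ_R
```

- **Non-recurrent regime** (every stress novel):
  `p̂_M = max{0, e^(−μ_M τ) − Γ(1 − e^(−μ_M τ))}`, positive exactly for
  `τ < τ_c = (1/μ_M) ln(1 + 1/Γ)`.
- **Recurrent regime** (one stress, repeated): the `Γ` term is multiplied by
  a carry-over factor ≥ 1, so repeating one stress never maintains the SIM
  allele better than novel stresses — for the benchmark parameters it never
  maintains it at all.
- **χ distinct stresses in rotation** interpolate between the two, simulated
  exactly on the `2^(χ+1)`-genotype hypercube.

## Worked example

```bash
stressim fixtures --out-dir configs
stressim analytic --config configs/single_stress.yaml
```

```
gamma = 1.11
lambda = 0.900901
tau_c = 642.328
p_hat_nr = 0.799207
p_hat_r = 0
```

With the benchmark rates, `Γ = (1/100 + 10⁻³ + 10⁻⁴)/10⁻² = 1.11`: the SIM
allele survives novel stresses arriving faster than once per
`τ_c ≈ 642` time units, and at `τ = 100` it is predicted at 80% frequency —
while the recurrent regime loses it (`p_hat_r = 0`). The full ODE simulation
agrees:

```python
>>> from stressim import REFERENCE_PARAMS, run_cycles
>>> run_cycles(None, REFERENCE_PARAMS, "NR").p_hat_M   # tau_S=10, tau_NS=90
0.7927959427569449
>>> run_cycles(None, REFERENCE_PARAMS, "R").converged
'extinct'
```

and a single repeated stress drives the allele extinct:

```bash
stressim simulate --config configs/single_stress.yaml --regime R --tau 100
```

```
regime = R
p_hat_M = 0
converged = extinct
n_cycles = 262
```

Sweeps over the cycle length, randomized stress orders, and the
combined/paired/sequential four-drug comparison are available as
`stressim sweep`, `stressim random-sweep`, and `stressim treatment`; each
writes a CSV table plus a JSON manifest of the resolved configuration. The
same functionality is importable from `stressim.experiments`.

## Layout

- `src/stressim/model_core.py` — four-genotype ODE flows, phase integration,
  the novel-stress resistance reset, cycle iteration.
- `src/stressim/analytic.py` — `Γ`, hitchhiking factor, recursion, closed-form
  equilibria, `τ_c`, multi-stress heuristic.
- `src/stressim/multistress.py` — hypercube genotype engine and stress
  schedules (cyclic, randomized, combined, paired, sequential).
- `src/stressim/experiments.py` — sweep/comparison tables with analytic
  overlays.
- `src/stressim/cli.py`, `src/stressim/config.py` — command line, YAML
  configs, fixture generation.

See `docs/methods.md` for modelling assumptions, numerical choices, and
limitations.
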