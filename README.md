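# nmrdyn

Multi-timescale analysis of protein backbone dynamics from solution-NMR
observables, built as a reusable, fully tested pipeline.

Solution NMR probes protein motion in three complementary windows, and this
package implements the complete analysis chain for each:

* **Nanoseconds — ¹⁵N relaxation.** Single-exponential fitting of R₁/R₂
  intensity decays, heteronuclear NOE ratios, R₂/R₁-based flagging of
  conformational-exchange residues, rotational-correlation-time estimation,
  and Lipari–Szabo model-free fitting of (R₁, R₂, NOE) triples at a single
  field, yielding per-residue order parameters S² with AIC model selection
  among {S²}, {S², τₑ}, {S², R_ex}, {S², τₑ, R_ex}.
* **Microseconds — residual dipolar couplings (RDCs).** Back-calculation
  `D = D_max·vᵀS v` from bond vectors and the Saupe alignment tensor,
  SVD tensor fitting, Cornilescu Q factors, a steric (shape-based) tensor
  predictor, and **replica-averaged RDC-restrained simulated annealing**:
  the pseudo-energy `E_RDC = α Σᵢ (D_calc,i − D_exp,i)²`, with `D_calc`
  averaged over M simultaneously simulated replicas, is added to a force
  field and sampled by Metropolis Monte Carlo over a desk-scale toy
  potential. Replica averaging lets heterogeneous data be satisfied by an
  ensemble populating several conformational basins at once — which no
  single structure can do.
* **Milliseconds and beyond — hydrogen/deuterium exchange.** EX2 kinetics
  (`k_obs = k_op·k_int/(k_cl + k_int)`), single-exponential HX decay fits,
  CLEANEX initial-slope rates for fast exchangers, intrinsic random-coil
  rates from the poly-DL-alanine reference formalism, and protection factors
  `logP = log₁₀(k_int/k_obs)`.

Ensembles are analysed by projection onto reaction coordinates (radius of
gyration, catalytic side-chain distance), Boltzmann inversion
`G = −k_B T ln(n/n_max)` into 2-D free-energy surfaces with basin analysis,
and per-residue RMSF about the iteratively superposed ensemble mean.

Because experimental datasets of this kind are rarely deposited, the
`nmrdyn.synth` module generates seeded synthetic inputs with stored ground
truth for every stage, so the whole pipeline is validated by parameter
recovery — the test suite inverts each forward model and checks the truth
comes back at a stated tolerance.

## Worked example

Generate a 20-residue synthetic relaxation dataset (700 MHz, 3% noise,
true mean S² = 0.824, τ_m = 5 ns) and run the model-free analysis:

```bash
$ nmrdyn --seed 7 simulate relaxation --out relax.tsv --truth truth.json --n 20
wrote relaxation data -> relax.tsv (truth -> truth.json)

$ nmrdyn modelfree --relaxation relax.tsv --out modelfree.tsv
tau_m = 4.96 ns; mean S2 = 0.807 +- 0.064 (20 residues) -> modelfree.tsv
```

The fitted tumbling time (4.96 ns) recovers the generating 5 ns within 1%,
and the fitted mean order parameter (0.807) recovers the generating 0.824
within the 0.02 tolerance the recovery tests enforce. The output table holds
per-residue S², its fit error, the selected model, τₑ and R_ex:

```
# residue  aa  model  S2      S2_err  tau_e   R_ex  tau_m  chi2  flagged
1          A   2      0.8305  0.0185  31.96   0     4.955  2.38  0
2          A   2      0.8240  0.0179  33.69   0     4.955  1.54  0
```

Intrinsic exchange rates for an arbitrary sequence at pD 6.5 and 353 K
(about 80 °C, where random-coil amides exchange in milliseconds):

```bash
$ nmrdyn hx-intrinsic --sequence AKLVGAEFT --pd 6.5 --temperature 353 --out kint.tsv
8 intrinsic rates -> kint.tsv
```

Other subcommands: `relax-fit`, `rdc-fit`, `rdc-qfactor`, `refine`,
`hx-fit`, `hx-cleanex`, `fes`, and `simulate relaxation|ensemble|rdc|hx`;
all accept a global `--seed`, `--config` (YAML mirroring the flags) and
`--log-level`.

## Layout

```
src/nmrdyn/
  io.py          TSV + multi-model-PDB readers/writers, config, logging
  relaxation.py  exponential fits, hetNOE, R2/R1 analysis, model-free
  rdc.py         tensors, SVD fits, Q factors, replica-averaged restraint
  refine.py      annealing schedule, toy potentials, MC refinement driver
  hx.py          EX2 kinetics, decay/CLEANEX fits, intrinsic rates, logP
  fes.py         reaction coordinates, free-energy surfaces, RMSF
  synth.py       seeded ground-truth generators for every stage
  cli.py         the `nmrdyn` executable
docs/methods.md  models, assumptions, parameter choices, limitations
```
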