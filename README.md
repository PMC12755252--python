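# grnswitch

Stochastic simulation and analysis of **bistable genetic regulatory
networks with distributed transcriptional delay**.

Producing a functional regulator protein takes time — transcription,
translation, folding, oligomerization — and that time is random.  For
bistable gene circuits this *distributed* delay is not a nuisance term: at
fixed mean delay, increasing the delay's coefficient of variation
`cv[tau] = sd[tau]/E[tau]` can dramatically *stabilize* the circuit's
metastable states, lengthening the mean residence time `E[R]` between
stochastic switches before eventually destabilizing them again (a
unimodal response).  This package provides the tools to simulate, measure
and explain that phenomenon:

* an exact **delay stochastic simulation algorithm** (dSSA; a delay
  variant of the Gillespie direct method, numba-compiled to ~5e6 events/s)
  for networks mixing instantaneous and delayed reactions;
* builders for three bistable circuits: the **co-repressive toggle
  switch**, a **single-gene positive feedback loop**, and the reduced
  **lambda-phage** lysis/lysogeny switch, with delay-free fixed-point
  location and bistability certification;
* **residence-time analysis** by the thresholding clock
  `G_n = inf{t > G_{n-1}: X(t) in U_i}`, CV sweeps with normalization by
  the fixed-delay baseline, and **transition-attempt statistics** over a
  three-region H/I/L coding;
* a **delay-switching ("unfolded") hybrid simulator**: a background
  two-state Markov chain at switching rate `r` chooses which fixed delay
  `mu -+ sigma` each initiating reaction uses.  The Bernoulli-delay model
  is its fast-switching limit; slow switching *destabilizes* while fast
  switching *stabilizes*, and sweeping `r` interpolates between the two;
* closed-form analytics for the **three-states reduced model** with
  memory-dependent rates `lambda^i_{j->k}`: attempt failure probability
  `f_H(tau) = (1-Z_H)p^H_{I->H} + Z_H p^I_{I->H}`, two-branch loop-time
  densities, geometric failed-attempt counts, the residence estimate
  `E[R_H] ~ (f_H/(1-f_H))(E[F_H] + 1/lambda^H_{H->I}) + E[S_H] +
  1/lambda^H_{H->I}`, and its delay-switching extension whose averaged
  failure ratio is provably decreasing in `sigma` (Jensen), all validated
  against brute-force discretized-chain oracles.

It is written for computational/systems biologists studying metastability
in gene circuits and for synthetic-biology modelers who want delay
distributions, not just delay means, as a design axis.

## Worked example

Measure how gamma-distributed delay noise stabilizes the positive
feedback loop at fixed mean delay 3 (time unit = protein half-life):

```python
import grnswitch as gs

pfl = gs.make_pfl()                        # 1 species, bistable
print(gs.find_steady_states(pfl))          # [array([7.215...]), array([36.019...])]

regions = gs.make_regions(pfl)             # thresholded neighborhoods
df = gs.cv_sweep(pfl, family="gamma", mean=3.0, cv_grid=[0.0, 0.3, 1.0],
                 min_residences=28, seeds=(41, 42), regions=regions,
                 per_state=True)
print(df[["cv", "state", "n_residences", "mean_residence", "norm_mean"]])
```

```
    cv state  n_residences  mean_residence  norm_mean
0  0.0     H            16    63937.073827   1.000000
1  0.0     L            14    24752.534557   1.000000
2  0.3     H            16   104117.825652   1.628442
3  0.3     L            14    39148.352066   1.581590
4  1.0     H            16    30461.814747   0.476434
5  1.0     L            14     8454.418744   0.341558
```

Reading the table: at CV 0.3 the mean residence time of the high state is
~1.6x its fixed-delay baseline and the low state ~1.6x as well — delay
noise has *stabilized* both metastable states.  By CV 1.0 the response
has passed its peak and both states switch faster than with fixed delay.
(`H`/`L` are the high/low-protein states; `mean_residence` is in units of
the protein half-life; `norm_mean` divides by the CV = 0 row; at this
reduced replication, per-cell means carry sampling errors of order 25%.)

The same analysis from the shell:

```bash
grnswitch steady-states --model pfl
grnswitch sweep-cv --model toggle --config examples/toggle_sweep.yaml
grnswitch heatmap --model toggle --attempts   # (r, cv) unfolding sweep
grnswitch rm-report --seed 3                  # reduced-model closed forms vs oracle
```

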