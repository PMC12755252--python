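# Methods

This note records the models, algorithms, numerical choices and known
limitations of `grnswitch`.

## The stochastic model and the dSSA

A network is a list of species with integer counts `X(t)` and reactions,
each carrying a propensity `a_r(x)` and a state-change vector.  A reaction
is either *instantaneous* (its state change applies when it fires) or
*delayed*: at firing a delay `tau` is drawn from the reaction's kernel and
the state change is applied at `t + tau`.  Delayed reactions here are
**non-consuming** — nothing changes at initiation.  This is the correct
convention for the shipped circuits, whose delayed reactions are all
catalytic production reactions (`0 -> Q`, `O -> O + A`): the delay models
the time to transcribe, translate and fold a functional protein, during
which the template is not sequestered.  A delayed reaction with a negative
state-change entry is rejected at run time.

The simulator is the direct-method delay SSA with interruption, exact for
the delayed chemical master process:

1. with total propensity `a0`, draw the putative next firing at
   `t + Exp(a0)`;
2. if a queued completion (or a background mode switch, below) comes
   first, advance to it, apply it, and redraw the exponential clock —
   valid by memorylessness (after completions the clock must be redrawn
   anyway because propensities changed; after mode switches propensities
   are unchanged and the clock is kept);
3. at a firing, pick reaction `r` with probability `a_r/a0`; delayed
   reactions enqueue `(t + tau, r)`, instantaneous ones apply their state
   change.

Ties between a putative firing and a queued completion go to the
completion (completions are pre-committed events).  The pending queue is a
binary min-heap keyed on `(time, insertion sequence)`, so exactly-equal
completion times pop FIFO.  Enqueued delays are never revised.  The loop
is compiled with numba; all randomness flows through one per-run PRNG
seeded once, so a whole run (including kernel draws and mode switches)
replays from a single integer seed.  A plain-Python heapq implementation
in the test suite serves as an independent statistical oracle.

## Delay kernels

Kernels are parameterized by mean and coefficient of variation so the mean
can be held fixed while the noise level sweeps:

| family      | construction                          | constraint |
|-------------|---------------------------------------|------------|
| `fixed`     | point mass at `mean`                  | `cv = 0`   |
| `gamma`     | shape `cv^-2`, scale `mean*cv^2`      | `cv >= 0`  |
| `bernoulli` | `(1/2)d_{mu-sigma} + (1/2)d_{mu+sigma}`, `sigma = cv*mean` | `cv < 1` |

`cv = 0` collapses every family to the point mass.  Draws of exactly zero
(possible for gamma by underflow at very small shape) are rejected and
redrawn: completions must strictly follow initiations.

## The three circuits

All parameters are in units of the protein half-life (`gamma = log 2`).

* **Toggle switch** (2 species): production `beta*kappa/(kappa + Q_other^2)`
  (delayed), dilution `gamma*Q`.  The delay-free rate equations are
  bistable iff `beta/gamma > 2*sqrt(kappa)` (pitchfork criterion
  `q*^2 > kappa` at the symmetric fixed point; derived from
  `|F'(q*)| = 2q*^2/(kappa+q*^2)`).
* **Positive feedback loop** (1 species): production
  `alpha + beta*Q^b/(c^b + Q^b)` (delayed), dilution `gamma*Q`; defaults
  `alpha=5, beta=20, b=10, c=19` give stable states at `Q ~ 7.2` and
  `Q ~ 36.0` with a saddle at `Q ~ 18.1`.
* **Lambda-phage switch** (7 species, 14 reactions): the reduced
  Warren–ten Wolde lysis/lysogeny model.  Two factors A, B are expressed
  (with delay) from the free operator or from their own bound-operator
  complex, dimerize reversibly, and the dimers compete to occupy the
  single operator (`O + OA2 + OB2` conserved).  Defaults
  `kb=kf=kon=5, kA=kB=koff=1, muA=muB=0.3`.  Bistability lives in the
  projection `A_T = A + 2A2 + 2OA2`, `B_T = B + 2B2 + 2OB2`.

Fixed points of the delay-free rate equations locate the metastable states
for *every* delay kernel (delay enters only through history arguments).
They are found by multi-start root finding (`scipy.optimize.root`) with
Jacobian eigenvalue classification; the PFL uses dense scalar bracketing,
and the phage system is first reduced by the operator conservation law and
relaxed along the ODE flow (`solve_ivp`) from A- and B-dominant starts
before polishing, because its attractors sit near the boundary of the
clamped mass-action form (`x(x-1)/2` is cut off below `x = 1`).

### Toggle parameter disambiguation

The source table for the toggle prints `beta` and `kappa` with corrupted
typography (inline-collapsed superscripts/fractions).  The builder ships
candidate readings and requires the chosen reading to certify bistability
of the delay-free ODE; among certifying candidates, the shipped default
`beta = 31.6404*log(2)`, `kappa = 1000/21.6404 ~ 46.21` (the kappa cell
read as a collapsed fraction) is the one whose simulated fixed-delay
baselines reproduce the reported mean residence times (`~1.9e4` at delay
2, `~6.7e4` at delay 3).  The resolved reading is recorded in the network
metadata and in every experiment's `metadata.json`.  Quantitative
toggle results inherit the residual uncertainty of this reading.

## Residence-time measurement

Residence times use the thresholding clock: with neighborhoods U0 (= H)
and U1 (= L) fixed, transition times are
`G_n = inf{t > G_{n-1}: X(t) in U_i}` with the target alternating, and
residences are the gaps `G_{n+1} - G_n`.  Exits and re-entries of the
current neighborhood do not stop the clock — only first entry into the
other neighborhood does.

All shipped circuits admit a scalar reaction coordinate
`d = Q1 - Q2` (toggle), `A_T - B_T` (phage), `Q - q_saddle` (PFL); regions
are half-planes `H = {d >= theta_pos}`, `L = {d <= -theta_neg}` and the
band `I = {-w_neg <= d <= w_pos}` around the separatrix.  Defaults place
the thresholds at **85%** of the distance from the separatrix to each
fixed point (`radius_frac = 0.85`) with I-band half-width half the
threshold (`iband_frac = 0.5`).  The tight thresholds are deliberate:
switching transients of delayed circuits *ring* — production initiated
before a switch keeps completing after it — and with thresholds halfway
to the separatrix a single physical transition is scored as several
back-and-forth transitions a few delay-times long, collapsing the
low-state mean of the PFL from `~1.8e4` to `~1.4e3`.  In the 0.8–0.9
range the measured means plateau (<2% change between 0.85 and 0.9) and the
fixed-delay baselines of the PFL match the reported values without further
adjustment.  Both fractions are config-exposed.

One measured quantity deserves a health warning.  At longer delays the
PFL's high state exhibits rare, violent relaxation crashes: a fluctuation
below the activation threshold shuts production off, the count dilutes
toward zero within a few half-lives, and the ~`tau * rate` pending
completions then slam the count back up.  A crash that touches the low
neighborhood scores as a genuine (few-time-unit) low residence under the
thresholding clock.  At delay mean 5 the low-state residence distribution
is therefore a mixture of ~92% crash entries (median ~3) and ~8% long
genuine sojourns (~1e5), and its mean — which *falls* as the delay grows,
opposite to the high state — is controlled by the Poisson count of long
sojourns: at 50–100 low residences it carries a relative sampling error
of 40–50% and is the most threshold-sensitive number this package
produces.  Conclusions should rest on the robust statistics (the toggle
and phage baselines, the PFL delay-3 baselines, normalized CV responses),
not on this one.

Measurement conventions: runs start at a stable fixed point; the first
residence (initial-condition burn-in) is discarded; symmetric models
(toggle, phage) pool the two states, the asymmetric PFL reports low/high
separately; standard errors are batch means over independent seeds
(two or more per cell); sweep cells run until a target number of pooled
residences accrues, with an event budget that flags incomplete cells.

### Transition attempts

The H/I/L coding refines residences into attempts: an excursion H -> I
fails if the trajectory next returns to H and succeeds if it reaches L.
Per attempt we record the *wait* (sojourn in the metastable neighborhood
before entering I) and the *excursion* (sojourn in I), giving the
decomposition `E[R_H] ~ E[N](E[wait] + E[I->H]) + (E[wait] + E[I->L])`.
Because attempts exactly partition each residency, the decomposition
evaluated on one dataset reproduces the directly measured mean by
construction; the test suite uses this as a parser-correctness identity
and the scientific content lies in how the attempt counts and waits vary
with delay CV and switching rate.  Attempt-time histograms default to
Freedman–Diaconis binning (numpy `bins="fd"`), config-overridable.

## The delay-switching (unfolded) model

A background two-state Markov chain with symmetric switching rate `r`
selects the delay used by *initiating* delayed reactions: `mu - sigma` in
mode 0, `mu + sigma` in mode 1; the mode at completion is irrelevant, and
reactions never feed back on the chain.  Mode switches are first-class
events in the event loop (exact, not thinned).  The Bernoulli-kernel model
is the fast-switching limit of this family; `r = 0` freezes a mode
(reproducing the fixed-delay model at `mu -+ sigma` event-for-event with
the same seed), and `sigma = 0` makes the modes indistinguishable.  The
initial mode defaults to a fair coin derived from the run seed; burn-in
removal also discards initial-mode bias.  Heatmap sweeps share one CV = 0
baseline across switching rates, since at `sigma = 0` the law does not
depend on `r`.

## Three-states reduced model

The symbolic model has states {H, I, L} with rates `lambda^i_{j->k}`
depending on the state `i` occupied `tau` time units ago; direct H <-> L
jumps are forbidden.  Under the standing assumptions (delay short against
residences; fast exits from I; memory bias `p^H_{I->H} > p^I_{I->H}`) the
failure probability of a transition attempt is the convex combination
`f_H = (1 - Z_H)p^H_{I->H} + Z_H p^I_{I->H}` with survival factor
`Z_H(tau) = exp(-(lambda^H_{I->H}+lambda^H_{I->L})tau)`; the loop- and
sequence-time densities are two-branch exponentials switching at the delay
horizon; the failed-attempt count is geometric with mean `f_H/(1-f_H)`.
The expected H->I->L sequence time `E[S_H]` is implemented from the same
two-branch integral with the I->L numerator rates and normalization
`1 - f_H` (validated against the simulation oracle and by quadrature
identities; the printed source of the loop-time expectation contains an
evident subscript typo in its survival factor, which the quadrature
identity resolves in favor of `Z_H`).

The extension redraws the delay after each attempt from
`{mu - sigma, mu + sigma}` with a fair coin, giving expected failures
`m/(1-m)` with `m = (f_H(mu-sigma)+f_H(mu+sigma))/2`.  Convexity of `Z_H`
(Jensen) makes `m`, and hence the failure ratio and the residence
estimate, strictly decreasing in `sigma` under the memory-bias assumption:
the analytic counterpart of slow-switching destabilization.

Oracles: the delay is discretized as `tau = K*Delta` (default `K = 2^7`)
and the attempt chain is simulated with the memory vector re-initialized
to all-H before each attempt, mirroring the analytic conditioning; once an
attempt starts the symbol stays in I until completion, so the look-back
state is H for the first K steps and I afterwards.  The discretization is
rejected when any per-step jump probability reaches 1, and the discrete
chain's completion times carry an O(Delta) whole-step bias that the
comparisons account for.  No published numeric rate values exist for this
model; test rates are chosen with a x50–x100 scale separation and clear
memory-bias margins, and delays are taken on the scale of the I-exit time
(`tau ~ 1.5/Lambda_I`) so the memory weight `Z_H(tau)` is well inside
(0, 1) — for much larger delays `Z_H` underflows and finite-difference
monotonicity checks lose meaning.

## Problem sizes and reproducibility

The test suite and the acceptance script run everything at reduced
replication, chosen as the smallest scales at which the qualitative
signatures are stable across seeds: 40–60 pooled residences for
fixed-delay baselines, 18–45 residences per sweep cell, Monte Carlo
oracles at 2–3e5 episodes, and 100 random rate sets for the monotonicity
scan.  Every cell derives its seeds deterministically from a base seed,
and rerunning any cell with its recorded seed reproduces it bit-for-bit.

## What the simulations do and do not show

The circuits are idealized: no explicit mRNA step, no cell division or
partitioning noise, one operator copy, and delay distributions restricted
to the three families above.  Passing tests demonstrate the computational
claims — exactness of the event loop, the delay-noise stabilization
signatures of these three circuits at the stated parameters, the
switching-rate transition of the unfolded model, and the reduced-model
algebra — not that real gene circuits realize the same magnitudes.
Absolute residence times also inherit the (config-exposed) neighborhood
geometry and, for the toggle, the typographic parameter reading described
above.
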