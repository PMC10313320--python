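# Methods

This note records the model equations as implemented, the numerical
conventions, the choices made where the design was genuinely open, and what
the synthetic data generators do and do not emulate.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The circuit model

Each choice option *i* is represented by three rate units: an excitatory
unit R_i receiving the value input V_i, an inhibitory gain-control unit G_i
(biologically SST/PV interneurons), and a disinhibitory unit D_i
(biologically VIP interneurons) that inhibits the local G_i:

    tau_R dR_i/dt = -R_i + (V_i + alpha R_i + B_R) / (1 + G_i)
    tau_G dG_i/dt = -G_i + sum_j omega_ij R_j + B_G - D_i
    tau_D dD_i/dt = -D_i + beta R_i

with self-excitation alpha, baseline inputs B_R and B_G, gain-control
coupling omega (local weight w on the diagonal, lateral weight v
off-diagonal), and the disinhibition weight beta.  beta is treated as a
top-down gate: zero during value representation, switched to its configured
value when selection is cued.  With the gate off the equilibrium is the
divisive-normalization solution

    R_i* = (V_i + B_R) / (1 + B_G - alpha + sum_j omega_ij R_j*),

so the circuit reproduces the dynamic normalization model (DNM) up to the
constant B_G - alpha; with the gate on, disinhibition breaks the symmetry
between the option subcircuits and produces winner-take-all (WTA)
competition.  The DNM (alpha = beta = B_G = 0, no D units), the reduced
two-variable recurrent network model (RNM), the leaky competing accumulator
(LCA) and a generalized motif family (optional cross-inhibition and lateral
gain-boost loops, 2^4 on/off combinations) are implemented alongside as
comparison models.

## Phase-plane analysis and regime taxonomy

For two options the fixed points reduce to intersections of two scalar
nullclines,

    v R_2 = (V_1 + B_R)/R_1 - (w - beta) R_1 - (1 + B_G - alpha),

and symmetrically.  `find_equilibria` scans R_1 on a 2000-point log grid,
maps it through the first nullcline and polishes sign changes of the second
nullcline's residual with Brent's method; each root is certified by the
residuals of the full system (< 1e-8) and classified by the eigenvalues of
the analytic 3N x 3N Jacobian.  Jacobian rows are scaled by their 1/tau
factors (the true linearization); the scaling cannot change the sign of any
eigenvalue real part, so stability conclusions are unaffected by it.
Stability threshold: real parts below -1e-6 are stable, above +1e-6
unstable, otherwise marginal (the line-attractor case, which linearization
cannot decide and which the trajectory probe `attractor_type` resolves).
Equilibria on the clamping boundary (any unit at 0) are excluded; the
analysis lives in the positive quadrant.

Under equal inputs, the (alpha, beta) plane partitions into five
territories by the diagnostic tuple (number of equilibria, stable,
unstable): dark green (1,1,0) and green (3,1,2) implement normalized value
coding; blue (3,2,1), yellow (1,0,1) and red (0,0,0) implement WTA.  The
green territory is a sliver: for B_G = 0 and inputs of 250 it requires
alpha < 1 and beta within about 1.6% above 1 (from the discriminant
condition (alpha-1-B_G)^2 > 4 (beta-1)^2 (V+B_R)/beta), which is why grid
maps only show it under deliberate refinement near beta = 1, alpha < 1.
The default search box is [1e-3, 300] Hz; regime scans use [1e-3, 1e4]
because the symmetric root diverges as beta approaches the red boundary.

With inputs withdrawn (V = 0) the fixed-point structure is analytic
(`persistent_equilibria`): no elevated activity when alpha <= 1 + B_G; a
line attractor with conserved sum (alpha-1-B_G)/w when v = w and beta = 0;
a point attractor at (alpha-1-B_G)/(w+v) when v < w; and WTA corners, with
winner level (alpha-1-B_G)/(w-beta) for 0 < beta < w and unbounded growth
for beta >= w.

## Numerical integration and noise

Deterministic dynamics are advanced by classical RK4 at dt = 1 ms (0.1 ms
available for convergence checks); all activities are clamped at zero after
each full step — not inside RK4 sub-stages — which is the simplest contract
consistent with non-negative rates.  Each unit carries an independent
Ornstein-Uhlenbeck noise term n with time constant tau_noise = 2 ms,
entering its rate equation additively (tau_X dX/dt = f + n); a switch moves
the noise onto the inputs instead (default off).  The OU update is

    n <- n (1 - dt/tau_noise) + sigma sqrt(dt/tau_noise) N(0,1),

the Euler discretization of tau dn/dt = -n + sqrt(tau sigma^2) xi(t) with
xi white noise; its stationary SD is sigma/sqrt(2) (exactly
sigma/sqrt(2 - dt/tau) for the discrete chain, so convergence checks use
dt = 0.1 ms).  Published parameter values fitted under a different, unknown
noise discretization keep their qualitative meaning here (the ordering and
monotonicity of predictions) but not the literal calibration of sigma; all
fitting and recovery in this package use the one convention end-to-end, so
fitted sigmas are internally consistent.

Trials of the reaction-time task start at R = 32 Hz, G = D = 0 (G and D
initial values are not constrained by the trial design; starting them at
zero gives the fastest stimulus-onset transient and is configurable),
include a 90 ms gap at stimulus onset carrying zero input with the gate off,
and threshold at 70 Hz on the first grid step at-or-above (no
interpolation), plus 30 ms motor delay.  Trials that have not crossed by
the 5 s cutoff are censored: they are reported, and the quantile likelihood
assigns them the censored-mass probability so that per-coherence
probabilities always sum to one.

The Monte-Carlo RT kernels (numba) re-implement the identical scheme per
trial with early exit at threshold; normal variates come from a 128-layer
Marsaglia-Tsang ziggurat driven by xorshift64* (seeded through splitmix64),
whose output distribution is verified against scipy in the test suite.  The
numpy integrator remains the reference path; the two are cross-checked.

## Quantile maximum likelihood (QMLE)

Observed RTs are summarized per (coherence x correctness) cell by nine
empirical quantiles (0.1 ... 0.9, type-7 interpolation), giving ten bins;
cells with fewer than ten trials collapse to a single bin so that sparse
error cells at high coherence remain usable.  Predicted bin probabilities
come from Monte-Carlo simulation (default 1024 repetitions per coherence at
desk scale; the full-scale 10,240 remains available), are normalized
jointly per coherence over correct bins, error bins and the censored mass
(choice accuracy is therefore estimated implicitly), floored at
eps = 1/(10 n_reps) and renormalized.  nLL = -sum n_obs log p; AIC = 2k +
2 nLL.

Fitting minimizes this objective with multi-start bounded Nelder-Mead
(adaptive simplex) on a unit-cube reparameterization (log scale for sigma,
S and the time constants), after a Latin-hypercube screen evaluated at a
reduced Monte-Carlo size picks the most promising starts, and finishes
with simplex restarts around the incumbent at decreasing scales.  The
LDDM likelihood has long, nearly flat valleys along which the recurrence
alpha trades off against beta, sigma and S, and the input scale S against
tau_R (the same kind of collinearity the model shows between alpha and
B_G); optional profile-likelihood scans over these coordinate groups are
available in the fitter.  Every evaluation within a fit reuses one fixed
simulation seed (common random numbers), making the stochastic objective
quasi-deterministic and the whole fit reproducible from its seed.  The free parameters follow the published
reductions: LDDM 7 (alpha, beta, sigma, S, three taus; omega = 1, B_R = 0,
and B_G = 0 because alpha and B_G are collinear), RNM 8, LCA 4 (tau fixed
at 100 ms, non-decision time fixed at 120 ms).  The LDDM/RNM trial
timeline shares the 90 + 30 ms non-decision structure; the RNM thresholds
at 15 Hz on the population rate, the value used by the original reduced
model (the 70 Hz threshold is specific to the LDDM's parietal calibration).

## Equilibrium firing-rate fits

The trinary value-representation design (rewards from {0, 50, 100, 200,
250} microliters, omitted targets coded 0, 28 condition means) is fitted at
the model equilibria with the gate off.  The trinary fixed point is closed
form: s = sum_j R_j solves s^2 + c0 s - Rmax sum_j (V_j + B_R) = 0 with
c0 = 1 (DNM) or 1 + B_G - alpha (LDDM), and R_1 = Rmax (V_1 + B_R)/(c0+s);
Rmax multiplies inside the value term.  Free parameters: DNM (B_R, Rmax),
LDDM (B_R, Rmax, B_G - alpha — only the difference is identifiable, which
the tests assert directly), trinary RNM (JN_same, JN_diff, I0, rate scale).
The exact 28-condition table of the original experiment is not public; the
package ships a reader for arbitrary condition lists and a default design
crossing each direct value with seven contextual pairs.  For the RNM the
reward values are normalized by the largest reward (250 ul) and injected as
stimulus current through the standard external gain (5.2e-4 nA/Hz x 30 Hz);
this mapping is a package choice — only comparative statements (divisive
models fit divisively normalized data better than the subtractive RNM) are
asserted, not absolute RNM numbers.

## Inhibitory potentiation

A GABAergic-agonist manipulation is modelled as potentiating both
GABAergic synapse classes of the circuit — the G -> R gain-control synapse
and the D -> G disinhibitory synapse — by a common factor f.  By the change
of variables G' = f G, D' = f^2 D this is exactly the parameter map
(omega -> f omega, B_G -> f B_G, beta -> f^2 beta), which is how it is
implemented.  Two coarser readings were rejected on behavioral grounds:
scaling omega alone abolishes WTA entirely at the sweep preset (beta falls
below omega and every trial censors), and scaling the G -> R synapse alone
preserves the inhibition/disinhibition balance and only slows the circuit
down.  Potentiating both classes deepens divisive suppression during
representation while strengthening disinhibition relatively faster,
accelerating the WTA bifurcation: reaction times shorten and accuracy
falls, the speed-accuracy tradeoff the manipulation is meant to probe.  In
the RNM the manipulated weight is the cross-population coupling JN_diff.

## Synthetic data generators

`generate_rt_dataset` simulates trial tables (coherences 0 ... 0.512, the
canonical six levels) from a known parameterization through the same trial
machinery used for fitting, and writes a truth record sufficient to rerun
it bit-identically.  The default generating truth (alpha = 8, beta = 1.35,
sigma = 20, S = 1500, taus 0.08/0.12/0.15 s) lies in the WTA regime with
every recovered parameter nonzero — the published best-fit has alpha = 0,
where relative recovery error is undefined — and produces realistic RT
ranges (roughly 0.3-1.3 s mean across coherences).  `generate_rates_dataset`
draws condition means from the LDDM equilibrium at the published
normalization fit values (B_R = 71.53, B_G - alpha = 3.82) with Rmax = 30
(a realistic 0-60 Hz response range) plus i.i.d. Gaussian measurement noise
(default SD 2 Hz; negative draws clamp at zero and are counted).

Recovery experiments refit such synthetic datasets from scratch.  The
default recovery design uses 4096 trials per coherence: with fewer trials
the likelihood contrast along the collinear (alpha, beta, sigma, S) ridge
falls below what desk-scale Monte-Carlo resolution (1024 repetitions per
evaluation) can exploit, and the recovered alpha is then set by the
sub-basin the optimizer happens to enter rather than by the data.

What the generators do not emulate: session structure, neuron-to-neuron
heterogeneity, trial-history effects, lapses, and any mismatch between the
fitted model family and the true data-generating process.  Passing
recovery tests therefore demonstrate internal consistency of the estimation
machinery, not that real data are identified this well.

## Problem sizes and defaults

Desk-scale defaults: 1024 Monte-Carlo repetitions per coherence and 8
optimizer starts for behavioral fits (the published analysis used 10,240
repetitions and 160 starts on a GPU cluster; both remain configurable),
2000-point nullcline scans, and 2000-trial symmetric-input checks.  The
acceptance script's critical-disinhibition sweep uses the 0.01 beta grid on
[0, 3] stated with the analysis.

## Known limitations

- The exact OU discretization behind the published sigma is not
  reconstructable from the text; sigma values are convention-bound.
- Full behavioral parameter recovery is optimization-limited at desk
  scale.  With 4096 trials per coherence the quantile likelihood's global
  optimum sits at the generating parameters (verified by local search
  seeded at the truth, which stays there with every parameter inside a
  20%/30% band), but the common-random-numbers objective at 1024
  repetitions is rugged at the ~100 log-likelihood scale and its collinear
  ridges hold many shallow sub-basins.  Multi-start Nelder-Mead, simplex
  restarts, compass/pattern search, profile scans and the DIRECT global
  optimizer all terminate in sub-basins with the recurrence alpha (and
  often S and tau_R) tens of percent off, at likelihoods 70-250 above the
  truth basin.  The original analysis solved the same problem with a
  model-based mesh-adaptive search (BADS) across 160 GPU-hosted starts;
  within this package's desk-scale budget, beta and sigma are recovered
  reliably and the remaining parameters should be read as
  valley-constrained rather than point-identified.
- Accuracy saturates at 1.0 at the highest coherences under the best-fit
  parameterization and this package's noise convention, so rank statistics
  on accuracy have ties there.
- The general-N equilibrium solver covers the symmetric-input cases used by
  the analyses; exhaustive root finding in high dimensions is out of scope.
- Boundary (clamped) equilibria are deliberately excluded from counts; the
  WTA corner states reached by simulation are therefore described by the
  persistent-activity analysis, not by the nullcline intersection counts.
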