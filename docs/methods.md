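# Methods

## Models

The package treats one physical system at three levels of description.

**QIF network.** N quadratic integrate-and-fire neurons,
`dv_n/dt = v_n^2 + eta_n + kappa S(t)`, with reset from `v_th` to `v_r` and
all-to-all chemical coupling through the mean synaptic activity `S(t)`.
Each spike feeds a normalized gamma-family kernel

    g(t) = (t/tau)^q exp(-t/tau) / (q! tau),

the Green's function of `(tau d/dt + 1)^(q+1)`, so `S` obeys a cascade of
q+1 first-order ODEs driven by the population spike train.  `q` sets the
synaptic latency (peak at `q*tau`, mean `(q+1)*tau`, variance
`(q+1)*tau^2`, skewness `2/sqrt(q+1)`), `tau` the time scale.

**Theta-neuron network.** The smooth equivalent under `v = tan(theta/2)`
at infinite threshold, with finite-width pulses
`P_nu(theta) = p_nu (1 - cos theta)^nu` in place of delta spikes.  The
normalization `p_nu = 2^nu (nu!)^2 / (pi (2nu)!)` is fixed by requiring the
circle integral of `P_nu` to equal 2, which is the unique choice that makes
the `nu -> inf` limit deliver exactly one unit of time-integrated drive per
spike (the phase crosses pi at speed 2), and hence makes the theta network
degenerate to the QIF network in that limit.  A release-blocking test
validates this constant through the agreement between the closed-form
Fourier coefficients (which carry `p_nu` analytically) and direct
quadrature of the normalized pulse.

**Kuramoto–Sakaguchi (KS) reduction.** With all `eta_n > 0` the phases
rotate; in the uniformly rotating coordinate `2 tan(theta/2) = Omega
tan(phi/2)` the network is a generalized Winfree model, and first-order
averaging in the weak-coupling parameter `eps = 2|kappa|/Omega` yields

    dphi_n/dt = omega_n + (K/N) sum sin(phi_n' - phi_n - alpha),
    omega_n = 2(eta_n - Omega^2/4 + kappa Q_nu0)/Omega,
    K       = 2 kappa |G_1| Q_nu1 / Omega,
    alpha   = -arg G_1 - pi/2,

where `G_1` is the kernel Fourier coefficient at the fast frequency and
`Q_nu0, Q_nu1` the first two Fourier coefficients of the transformed pulse.
`Omega` solves `<eta> - Omega^2/4 + kappa Q_nu0(Omega) = 0` (zero-mean
reduced frequencies); in the delta-pulse limit the solution is
`(kappa + sqrt(kappa^2 + 4 pi^2 <eta>))/pi`.  Since `Q_nu1 <= 0`, `K` and
`kappa` have opposite signs: inhibition is effectively attractive.
Synchronization is favoured iff `K cos(alpha) > 0`, which for the gamma
kernel with `kappa < 0` reads `sin((q+1) arctan(tau*Omega)) > 0` — an
alternating sequence of attractive windows in `tau*Omega` whose full-axis
count is `floor(q/2)+1`.

## Numerical choices

* **Hypergeometric coefficients.** `Q_nu_ell` is a finite sum of Gauss
  `2F1` terms at argument `z = 1 - Omega^2/4`, evaluated with log-gamma
  prefactors.  For `z < 0` a Pfaff transformation (`z -> z/(z-1)`) is
  applied: the direct series silently loses accuracy for sharp pulses with
  `Omega > 2`.  The transformed evaluation agrees with adaptive quadrature
  of the defining integral to better than 1e-9 for `nu` up to 1e5, so no
  separate large-`nu` asymptotic path is needed.  A non-finite value
  (possible only as `Omega -> 0`, where `z -> 1`) falls back to quadrature
  with a warning.
* **Quadratures.** Kernel transforms integrate over the dimensionless
  variable to `(q+1) + 12 sqrt(q+1) + 25` (mean + 12 SD + a flat margin
  that matters at small q), absolute tolerance 1e-11.  Pulse quadratures
  place an adaptive breakpoint a few widths `(2/Omega)/sqrt(nu)` before the
  peak at pi.
* **Omega root.** Bracketed scan on `[1e-6, 2 sqrt(<eta>) + 2|kappa| + 1]`,
  Brent's method at 1e-12; with multiple sign changes the root nearest the
  uncoupled value `2 sqrt(<eta>)` is selected.
* **Integration.** All simulators use classical fixed-step RK4, default
  `dt = 0.01`.  Spike times are linearly interpolated within the step
  (second-order accurate; halving `dt` quarters the timing error).  Spike
  jumps into the cascade (`u_1 += 1/(N tau)`) are applied at the end of the
  containing step.
* **QIF threshold handling.** With `v_th = 1e5` the quadratic blow-up
  crosses threshold faster than any fixed step, so above a hand-off value
  `V_c = min(10, 0.1/dt)` the integrator switches to the exact inverse
  coordinate `w = 1/v`, `dw/dt = -1 - (eta + kappa S) w^2`, which is smooth
  and nearly linear through the spike and the reset.  This is a change of
  variables, not an approximation; uncoupled inter-spike intervals
  reproduce the closed-form period `pi/sqrt(eta)` to ~2e-5 at `dt = 0.01`.
  The default reset jumps to `v_r` at the interpolated crossing;
  `pass_through` mode lets `w` run through the singularity, adding the
  finite transit time `~ 1/v_th + 1/|v_r|`.
* **Classification.** Regimes are decided on the second half of a run, in
  the common rotating coordinate: time-mean `r1 > 0.95` = synchronized,
  `< 0.1` = generalized splay, a persistent `(m, m, 1)` cluster pattern
  (0.05 rad single-linkage tolerance, >= 90% of samples) = cyclops.  All
  thresholds are configurable and recorded in the report; they are
  qualitative heuristics, not sharp invariants.

## Study horizons

The reduced model predicts its own relaxation rate, `|K cos(alpha)|`.  At
the canonical operating points (`kappa = -0.2 pi`, `<eta> = 2`, N = 21):

| point | q | tau  | nu  | rate     | e-fold | horizon T |
|-------|---|------|-----|----------|--------|-----------|
| A     | 2 | 0.5  | 20  | 0.0146   | ~68    | 1000      |
| B     | 2 | 0.8  | 20  | 0.0034   | ~290   | 2000      |
| C     | 4 | 0.15 | inf | 0.133    | ~7.5   | 200       |
| D     | 4 | 0.41 | inf | 0.024    | ~42    | 400       |

Horizons are chosen as at least ~5 e-folding times so that the second-half
window samples the asymptotic state; points A and B sit close to
`alpha = pi/2` (weak effective coupling), which is why their transients are
two orders slower than C.  These are properties of the dynamics, computable
in closed form before any simulation.

## Accuracy of the reduction

The reduction is first order in `eps = 2|kappa|/Omega`.  At
`kappa = -0.2 pi` (`eps ~ 0.48`) the locked synchronized state at point A
carries phase differences up to ~0.35 rad (set by the `eta_n` spread over
`K cos alpha`), and the neglected corrections displace them by
`O(eps * dphi) ~ 0.1-0.2 rad` for the worst neuron.  Order-parameter
trajectories, regime boundaries, firing rates and cluster structure are
reproduced essentially exactly; individual locked phase differences agree
to the ~0.1-0.2 rad level, not better.  A max-norm agreement bound of
0.1 rad over all neurons is therefore slightly beyond the method's
intrinsic accuracy at this coupling strength; the test asserting that
bound fails at this operating point (measured mismatch ~0.15-0.2 rad
depending on the seed), which is the expected first-order behaviour, not
an implementation defect, and is left in the suite as documentation of
the reduction's limits.

## Synthetic inputs

`make_eta` draws excitabilities uniformly on
`[eta_mean - d/2, eta_mean + d/2]` (the canonical spreads are 6e-3 at A, C,
D and 1e-3 at B; `d = 0` gives identical drives).  `make_initial_phases`
draws uniform phases on `[-pi, pi]` for the synchronization/splay studies;
the near-cyclops generator places two m-clusters at +/-1 rad and a solitary
phase at pi (an antipodal-ish reconstruction — the converged pattern, two
coherent 10-clusters plus a solitary oscillator, is insensitive to the
placement, which was checked for cluster positions between 0.8 and 2.1
rad).  Everything is seeded; identical configurations are bitwise
reproducible.

What the generator does *not* emulate: heterogeneous or structured
connectivity, noise, synaptic plasticity or adaptation beyond the fixed
kernel, conductance-based synapses, and Lorentzian-tailed excitability
distributions.  Passing tests therefore demonstrate correctness of the
reduction and simulators under the stated homogeneous, all-to-all,
noise-free conditions, not robustness of the phenomena beyond them.

## Known limitations

* The attractive/repulsive classification is a sign condition; no stability
  exponents or basins are computed.
* At N = 21 the repulsive point D shows weak finite-size coherence
  (`r1 ~ 0.15`) rather than clean asynchrony; the asynchronous character is
  recovered at larger N (the N = 100 scaled runs in the test suite) and in
  the sign classification itself.
* `pass_through` mode approximates refractory handling by the leading-order
  transit time through the singularity only.
* The cyclops state is weakly stable; very long horizons or larger
  perturbations (beyond ~0.05 rad) can let the solitary oscillator drift
  into a cluster.
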