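# qifks

Kuramoto–Sakaguchi reduction of finite-size networks of quadratic
integrate-and-fire (QIF) neurons with general synaptic kernels — for
computational neuroscientists studying how synaptic activation rates and
latencies control critical transitions between synchronized and partially
synchronized firing.

## The problem and the method

A globally coupled network of N Type I neurons,

    dv_n/dt = v_n² + η_n + ϰ S(t),       v_n ← v_r  when  v_n ≥ v_th,

interacts through the mean synaptic activity S(t), obtained by filtering
the population spike train with a normalized gamma-family kernel
G(t) = (t/τ)^q e^{−t/τ}/(q! τ) — the shape order q sets the synaptic
latency, τ the time scale.  Equivalently (at infinite threshold) the
network is a theta-neuron population with finite-width pulses
P_ν(θ) = p_ν (1 − cos θ)^ν.

For weak coupling and oscillatory drives (η_n > 0) this package reduces the
network analytically to the Kuramoto–Sakaguchi phase model

    dϕ_n/dt = ω_n + (K/N) Σ_{n'} sin(ϕ_{n'} − ϕ_n − α),

with parameters in closed form:

    ω_n = 2(η_n − Ω²/4 + ϰ Q_ν0)/Ω,   K = 2ϰ|G₁|Q_ν1/Ω,   α = −arg G₁ − π/2,

where G₁ = 1/(1 + iΩτ)^{q+1} is the kernel's Fourier coefficient at the
self-consistent fast frequency Ω, and Q_ν0, Q_ν1 are hypergeometric
Fourier coefficients of the transformed pulse.  Because Q_ν1 ≤ 0, K and ϰ
have opposite signs: *inhibitory* pulse coupling is effectively attractive.
The coupling is synchronizing iff K cos α > 0, i.e. (for ϰ < 0)

    sin((q+1)·arctan(τΩ)) > 0,

an alternating sequence of attractive/repulsive windows in τΩ.  The
package also integrates all model levels directly (QIF, theta,
Winfree-form, KS) and classifies the resulting regimes — synchronization,
generalized splay states, and three-cluster "cyclops" states (two equal
coherent clusters plus one solitary oscillator).

## Worked example

```python
import numpy as np
from qifks import NetworkParams, SynapticKernel, reduce_to_ks

params = NetworkParams(
    N=21, eta=np.full(21, 2.0), kappa=-0.2 * np.pi, nu=20,
    kernel=SynapticKernel(q=2, tau=0.5),
)
print(reduce_to_ks(params).to_dict())
```

prints

```
{'Omega': 2.638615697075573, 'K': 0.040017941026976485,
 'alpha': 1.1958392671510403, 'omega_mean': 4.2e-17, 'omega_std': 6.2e-33,
 'attractive': True}
```

The fast frequency Ω ≈ 2.639 solves ⟨η⟩ − Ω²/4 + ϰQ_ν0(Ω) = 0; the reduced
coupling K ≈ 0.040 is positive (opposite in sign to the inhibitory ϰ) and
the Sakaguchi lag α ≈ 1.196 < π/2, so coupling is attractive and the
network synchronizes.  Raising the synaptic time constant to τ = 0.8 flips
the sign of K cos α (τΩ crosses √3) and the same network settles into a
non-stationary generalized splay state instead — run both dynamically with

```
qifks scenario run A --out out_A      # theta + KS, synchronizes
qifks scenario run B --out out_B      # theta + KS, generalized splay
qifks scenario run cyclops            # KS cyclops state, clusters [10, 10, 1]
```

The same CLI exposes `reduce`, `regions` (attractive/repulsive maps over a
(τ, η) grid), `simulate` and `compare`; see `qifks --help`.

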