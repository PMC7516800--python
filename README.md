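# isingphi

Integrated information at the critical point of the generalized Ising model.

Small excitatory brain-network motifs can be modelled as Ising spin systems
whose couplings `J_ij` come from a weighted connectivity matrix (for real
data, tractography fiber counts; here, a random ensemble).  As the
temperature of the heat bath is swept, such systems pass through an
order–disorder transition.  This package implements the full analysis
pipeline that asks whether **integrated information Φ** — the IIT 3.0
measure of how irreducible a system's cause–effect structure is — behaves
as an *order parameter* of that transition: whether the generalized
susceptibility of Φ peaks at the same critical temperature as the magnetic
susceptibility.

The pipeline, per network and temperature:

1. **Dynamics.**  Metropolis Monte-Carlo on the energy
   `H(s) = −Σ_{i<j} J_ij s_i s_j` (spins `s_i = ±1`, no external field,
   `k_B = 1`): a spin flip is accepted with probability `exp(−ΔE/T)` when it
   raises the energy and always otherwise.  Sequential (single-site) updates
   satisfy detailed balance and sample the Boltzmann distribution;
   synchronous (all-site) updates define the Markov kernel analysed by IIT.
2. **Kernel.**  The synchronous dynamics factorizes over nodes, giving the
   `2^n × n` *state-by-node* transition probability matrix: entry `(s, i)`
   is the probability node `i` is up next step given the current
   configuration `s`.
3. **Integrated information.**  For each visited state, Φ is the
   concept-space distance between the system's cause–effect structure and
   that of the least-destructive unidirectional system cut (minimum
   information partition), computed per the IIT 3.0 reference algorithm with
   exact earth-mover distances (Hamming ground metric) and cached per
   (TPM, state).
4. **Observables.**  `M = |Σ s_i|/N`, `E = H`,
   `χ = (⟨M²⟩−⟨M⟩²)/T`, `C_v = (⟨E²⟩−⟨E⟩²)/T²`, and the generalized
   susceptibility `χ_Φ = ⟨Φ²⟩−⟨Φ⟩²`; ensemble means, standard deviations
   and across-network variances `σ_J²`.
5. **Criticality.**  `T_c` is the temperature of the (smoothed) peak of the
   ensemble-mean susceptibility curve.  For random normalized fully
   connected 5-node networks the peak sits near `T_c ≈ 1.8`, and the `χ_Φ`
   peak coincides with it.

## Worked example

```python
import numpy as np
from isingphi import (
    generate_random_network, temperature_grid, build_state_by_node_tpm,
    big_phi,
)
from isingphi.criticality import sweep_network

net = generate_random_network(5, seed=42)

# Phi of one state at one temperature
tpm = build_state_by_node_tpm(net, temperature=1.8)
res = big_phi(tpm, state=0b11111)
print(f"Phi = {res.phi:.6f}  (system MIP: {res.system_mip})")

# a small sweep (chi only)
grid = temperature_grid(25, 0.1, 4.0)
sweep = sweep_network(net, grid, seed=1)
print(f"chi peaks at T = {sweep.tc_chi:.3f}")
```

Output:

```
Phi = 3.898679  (system MIP: ((0, 1, 3, 4), (2,)))
chi peaks at T = 2.163
```

`Phi = 3.9` says the 5-node system's cause–effect structure at the all-up
state loses about 3.9 units of integrated conceptual information under its
least destructive cut (severing the inputs from nodes {0, 1, 3, 4} into
node 2) — the system is strongly irreducible at this near-critical
temperature.  The susceptibility peak near `T ≈ 2.2` is one network's
noisy estimate of the critical temperature from a single 2000-iteration
trace; averaging the curves of ≥ 20 networks tightens it toward
`T_c ≈ 1.8` (that ensemble average is exactly what
`scripts/acceptance.py` computes).

A command-line interface covers the same pipeline end to end
(`isingphi generate | sweep | report | validate`); see `isingphi --help`.

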