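# neuroperc

Percolation analysis of functional-connectivity formation on directed
connectomes.

A connectome fixes where signals *can* travel: a directed graph of neurons
whose edges are directionally adjacent relations (DAs) weighted by synapse
counts α_ij. Which of those channels actually carry coactivations depends
on the excitation–inhibition balance **λ** — the fraction of excitatory
synapses among all synapses. `neuroperc` implements the full chain from
anatomy to function:

1. **E/I assignment** — greedy single-flip search labels each neuron
   excitatory/inhibitory so the synapse-weighted excitatory fraction λ̂
   matches a target λ.
2. **Static strengths** — every edge gets
   S_ij = (α_ij/⟨α⟩)(X_i Y_ij + (1−X_i) Z_ij), Y ~ U(0,1], Z ~ U[−1,0].
3. **Coactivation probabilities** — P_ij is the fraction of m = 100
   leaky integrate-and-fire trials (V_rest = −70 mV, V̂ = −50 mV,
   τ_m = 10 ms, 50 ms horizon) in which continuously driving neuron i plus
   ≥ 20 % of j's presynaptic pool makes j spike.
4. **Functional graphs** — each static edge is kept with probability P_ij
   (Bernoulli), giving one realization of functional connectivity, always
   a subgraph of the anatomy.
5. **Percolation theory** — from the joint in/out-degree distribution
   P(u,v) and its generating function G(x,y) = Σ P(u,v)x^u y^v, the solver
   finds the probabilities P̂_in, P̂_out that an edge leads to / comes
   from the giant strongly connected component (GSCC), predicts the
   membership probability
   φ = 1 − G(1−P̂_out, 1) − G(1, 1−P̂_in) + G(1−P̂_out, 1−P̂_in),
   and the site-dilution threshold ρ_c = ⟨k⟩/⟨uv⟩.
6. **Metric suite** — characteristic path length and global efficiency
   (unreachable pairs at distance n+1), degree assortativity, rich-club
   curve φ(k) = E_{>k}/(N_{>k}(N_{>k}−1)), directed clustering and
   transitivity (Fagiolo convention), SCC/WCC cluster statistics, and
   physical Rentian scaling log e = α log n + β over a cubic partition of
   the embedding volume.

A synthetic-connectome generator (heavy-tailed, in/out-symmetric degrees;
geometric synapse multiplicities; 3-D positions at 10-nm resolution)
provides study-condition inputs so the whole pipeline runs without any
download.

## Worked example

```python
from neuroperc import (
    ConnectomeSpec, LIFConfig, SweepConfig,
    make_synthetic_connectome, run_sweep, report_transition,
)

conn = make_synthetic_connectome(ConnectomeSpec(n_neurons=2000, seed=7))
cfg = SweepConfig(lambda_grid=tuple(round(0.1 * k, 1) for k in range(1, 10)),
                  replicates=3, master_seed=11)
res = run_sweep(cfg, connectome=conn)
print(res.rows.groupby("lambda")[["phi", "phi_experimental",
                                  "global_efficiency"]].mean().round(4))
print("phi_static =", round(res.phi_static, 4))
print(report_transition(res))
```

prints (≈ 80 s on one CPU):

```
           phi  phi_experimental  global_efficiency
lambda
0.1     0.0000            0.0007             0.0006
0.2     0.0006            0.0027             0.0011
0.3     0.0666            0.0748             0.0099
0.4     0.2189            0.2268             0.0399
0.5     0.3611            0.3625             0.0867
0.6     0.4689            0.4688             0.1160
0.7     0.5475            0.5507             0.1509
0.8     0.6230            0.6275             0.1773
0.9     0.6944            0.6888             0.2022
phi_static = 1.0
TransitionReport(lambda_threshold=0.1, lambda_saturation=None, no_transition=False)
```

Reading: below λ ≈ 0.3 the functional graph is fragmentized (the GSCC
contains a vanishing fraction of neurons and the predicted φ is the
trivial root or nearly so); around λ = 0.3 a percolation transition sets
in, after which the theoretical prediction φ tracks the observed GSCC
fraction to within ~0.02 while global efficiency rises with it. Everything stays below the
static-anatomy ceiling `phi_static`. The same sweep also emits ρ_c per
realization: below the transition ρ_c > 1 (no retention probability can
sustain a giant cluster — the threshold is meaningless), above it ρ_c
drops steeply, i.e. the network tolerates increasingly heavy neuron loss.

The command-line surface mirrors the stages:

```bash
neuroperc synth --n-neurons 2000 --seed 7 --out conn/
neuroperc sweep --nodes conn/nodes.csv --edges conn/edges.csv \
    --seed 11 --replicates 3 --grid 0.1,0.2,0.3,0.4,0.5,0.6,0.7,0.8,0.9 \
    --out sweep/
neuroperc report --sweep-dir sweep/
```

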