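# Methods

## Model overview

`neuroperc` treats the formation of functional connectivity as a
percolation process on a fixed anatomical substrate. The substrate is a
directed simple graph of neurons; each ordered pair with at least one
synaptic cleft is a single edge carrying the cleft count α_ij. Function is
introduced through a single global control parameter, the
excitation–inhibition balance λ ∈ (0, 1): the fraction of excitatory
synapses among all synapses. For each λ the pipeline produces coactivation
probabilities per edge, samples functional graphs, and compares the
observed giant strongly connected component (GSCC) with the prediction of
directed-graph percolation theory.

## E/I assignment

Neuron identities X_i ∈ {0, 1} are binary; a neuron's synapses inherit its
identity, so the achieved balance is
λ̂ = Σ_{i: X_i=1} (outgoing synapses of i) / (all synapses). Labels are
initialized Bernoulli(λ) and refined by a greedy single-flip random
search: a uniformly chosen neuron is flipped and the flip kept only if it
strictly reduces |λ̂ − λ|, until |λ̂ − λ| ≤ tol (default 1e−3) or an
iteration cap (500 n flips) is hit, in which case the best assignment is
returned with a non-convergence flag. Because the smallest achievable step
in λ̂ is (min out-synapse count)/(total synapses), the default tolerance is
reachable on any connectome whose total synapse count exceeds a few
thousand; on the default 2,000-neuron synthetic connectome the worst-case
error across the 0.05…0.95 grid is below 1e−3.

## Static strengths and the LIF trial

Edge strengths are S_ij = (α_ij/⟨α⟩)(X_i Y_ij + (1 − X_i) Z_ij) with
Y_ij ~ U(0, 1] and Z_ij ~ U[−1, 0] drawn independently per edge and per λ
condition; ⟨α⟩ is the arithmetic mean cleft count over all edges, so an
average edge has |S| ≤ 1.

Coactivation of an edge (i, j) is probed with a discrete-time leaky
integrate-and-fire simulation of j's presynaptic neighborhood (the target
plus all of its presynaptic neighbors, with every static edge internal to
that set). Parameters: resting potential −70 mV, spiking threshold
V̂ = −50 mV, membrane time constant 10 ms, horizon 50 ms, explicit Euler
with dt = 1 ms. Per trial, a driven set — neuron i plus enough uniformly
sampled presynaptic neighbors of j to reach ⌈0.2 · indegree(j)⌉ — spikes
at every time step. Each step applies the leak and then all arriving
impulses simultaneously against the same pre-impulse potential:

    V ← V (1 − dt/τ_m) + E_leak dt/τ_m
    V ← V (1 − Σ_h S_hj − Σ_pend S) + (V̂ Σ_h S_hj + Σ_pend S · V_spike)

where the first sum runs over currently spiking driven neighbors (their
spike-instant potential is V̂) and the second over endogenous spikes
registered at the previous step (delivered with one-step delay at their
pre-reset potential, which can exceed V̂). A free neuron reaching V̂
registers a spike and resets to rest; there is no refractory period.
P_ij is the fraction of m = 100 trials in which the target crossed
threshold, so P_ij is always a multiple of 1/m.

The simultaneous-impulse rule is load-bearing: a single impulse
S (V̂ − V) with S ≤ 1 can only approach threshold asymptotically, whereas
simultaneous impulses with Σ S > 1 overshoot it. Firing therefore requires
either one strong edge (S ≥ 1, i.e. a high-multiplicity synapse bundle) or
the cooperation of several driven excitatory inputs — which is exactly the
mechanism through which λ controls coactivation.

Two further conventions were genuinely open and are fixed as follows. The
leak's reversal potential is configurable and defaults to the resting
potential (a literal reading of the update equation would leak toward the
spiking threshold, making every neuron fire eventually; initializing at
rest and leaking back to rest is the physiologically standard choice, and
the literal behavior remains available via `LIFConfig.leak_reversal`).
Driven neurons are forced spikers with spike-instant potential V̂ and do
not integrate input.

### Numerics and determinism

The production path runs a numba kernel, trial-by-trial, with two exact
early exits: a trial stops once the target has fired, and a spikeless
("quiet") trial stops once no free node can ever cross threshold — the
quiet dynamics of each node are a fixed affine map V ← A V + B, so a node
is provably subthreshold forever when (0 < A < 1 and max(V, V*) < V̂), or
(−1 < A ≤ 0 and V* + |V − V*| < V̂), or (A > 1 and V < V*), or
(A = 1 and B ≤ 0), with V* = B/(1 − A). These exits change nothing about
the returned indicator; they only skip provably-decided work. A scalar
reference implementation (`run_lif_trial`) spells out one trial in plain
loops and is held equal to the kernel in the test suite.

Randomness is plumbed as: master seed → per-(λ) streams for labels and
strength draws → per-edge substreams (seeded by (seed, pre, post)) whose
t-th draw fixes trial t's driven set. Whole-graph evaluation therefore
agrees bit-exactly with independent per-edge evaluation and is independent
of edge order.

## Functional graphs and percolation theory

A functional graph keeps each static edge with one Bernoulli(P_ij) draw
(seeded per replicate). All neurons of the static connectome remain in the
node set, so the experimental GSCC fraction is measured against the full
brain, not only non-isolated neurons.

The theory consumes only the joint in/out-degree distribution P(u, v) of
the realization under study (recomputed per realization). With
G(x, y) = Σ P(u,v) x^u y^v and ⟨k⟩ the common mean of the two marginals,
the edge probabilities solve

    P_in  = 1 − (1/⟨k⟩) ∂G/∂x |_(1, 1−P_in)
    P_out = 1 − (1/⟨k⟩) ∂G/∂y |_(1−P_out, 1)

by damped fixed-point iteration started from 1 (the map is monotone, so
iteration converges to the largest, physical root; default tolerance
1e−10, 1e5 iterations). A converged root below 10·tol is declared trivial
and φ = 0. Otherwise

    φ = 1 − G(1−P̂_out, 1) − G(1, 1−P̂_in) + G(1−P̂_out, 1−P̂_in),

the inclusion–exclusion of "reaches the GSCC" and "is reached by it". For
independent Poisson(c) degrees this reduces to the scalar fixed point
s = 1 − e^{−cs} with φ = s², which the test suite checks to 1e−8 against
bisection. The site-dilution threshold is the exact moment ratio
ρ_c = ⟨k⟩/⟨uv⟩; it is meaningful only in [0, 1], and 1 − ρ_c is the
maximum tolerable random-attack intensity. The upper bound φ_static is
obtained by running the same theory on the full static graph.

## Metric conventions

* Path metrics run over all ordered pairs; unreachable pairs enter both
  the characteristic path length and the global efficiency at distance
  n + 1, keeping the sample size constant across λ.
* Assortativity is the Pearson correlation over edges of source
  out-degree vs target in-degree, with an undefined flag (NaN) when either
  sequence is constant.
* The rich-club curve uses total degree from the original graph and the
  directed normalization N_{>k}(N_{>k} − 1); entries with fewer than two
  survivors are omitted.
* Clustering and transitivity follow the directed binary (Fagiolo)
  convention: per-node triangles diag((A+Aᵀ)³)/2 normalized by
  d_tot(d_tot − 1) − 2 d_bidirectional; the mean skips nodes with zero
  denominator, the transitivity is the global ratio of the two sums.
* Rentian scaling tiles the bounding box with cubes of side
  (V_bbox/m)^{1/3} anchored at the box corner and regresses log e on
  log n over cubes with n ≥ 1 and e ≥ 1 (e counts edges with exactly one
  endpoint inside). A uniform lattice tiled by an anchored grid can give
  every cube identical occupancy (zero regressor variance), so the fitter
  optionally pools additional randomly offset grids (`n_offsets`, seeded);
  the default remains the single deterministic grid. On the k = 8 lattice
  fixture the sensible partition scale is cubes much larger than the
  lattice spacing and much smaller than the lattice (m = 8 with offsets),
  the regime where the surface-to-volume argument e ∝ n^{2/3} applies;
  finer partitions inflate the exponent through boundary-clipped cubes.

## Power-law and symmetry analysis

The tail fitter histograms the data into 150 linearly spaced bins,
considers every bin edge as a cutoff candidate, fits the continuous
power-law exponent by maximum likelihood on the binned tail counts (last
bin open-ended), and keeps the cutoff minimizing the Kolmogorov–Smirnov
distance between fitted and empirical tail CDFs; candidates with fewer
than `min_tail` (default 50) samples are skipped. The estimate is
scale-invariant and approaches the closed-form unbinned MLE
α̂ = 1 + n/Σ ln(x/x_min) as bins refine. "Scale-free" means exponent in
the open interval (2, 3) with KS < 0.05 (both strict). Symmetry between
paired in/out variables reports the Pearson correlation with two-sided
p-value and the average change fraction mean |x_i − y_i|/y_i (pairs with
zero reference excluded and counted); the written-out form of the fraction
is not fully determined by its printed shorthand, and the per-entity
absolute mean is the implemented reading. Levels: *strictly strong* iff
(r > 0.9 and p < 1e−3) and fraction < 1; *less strong* iff exactly one
criterion holds; *relatively weak* otherwise.

## Synthetic data: what it emulates, and what it does not

`ConnectomeSpec` defaults define the study conditions at desk scale:
2,000 neurons in a (2.5e5 nm)³ volume at 10-nm coordinate resolution,
eight spatial-block regions, truncated-Pareto degrees (exponent 2.5 on
[4, 300]) giving a mean total adjacency degree ≈ 21 (the full fly central
brain has ≈ 27.6 DAs per neuron), shifted-geometric synapse multiplicities
with mean 7.8 clefts per DA (matching the global cleft/DA ratio), and an
in/out symmetry knob of 0.95. The lower degree cutoff of 4 matters: with a
tail starting at 1 the 20 %-of-indegree drive protocol pins most targets
to a single driven neuron and the functional graph stays subcritical at
every λ, which is not the regime under study.

The in/out coupling is a comonotone mixture: with probability equal to the
knob the two degree ranks coincide, otherwise they are independent. This
maps the knob directly onto the Pearson correlation of the degree pair for
any marginal (a Gaussian copula with latent r = 0.95 realizes only ~0.85
on this heavy-tailed marginal). Degrees are materialized with an erased
directed configuration model: stub totals are balanced by unit increments
on randomly chosen nodes, stubs matched uniformly, and multi-edges and
self-loops discarded.

What the generator does not emulate: spatial wiring-length bias (edges are
placed independently of distance, so Rentian exponents of synthetic
connectomes are near the random-placement regime), neuron morphology,
region-specific connectivity motifs, and correlations between synapse
multiplicity and degree. Passing tests on synthetic data therefore
validate the machinery and the theory–experiment consistency, not any
claim about a real connectome's particular numbers.

## Problem sizes

The default verification conditions are: 2,000-neuron sweeps with a
0.1-step λ grid and 3 replicates (~80 s on one CPU), configuration-model
checks at n = 10⁴ with 10 replicates per mean degree, and estimator
recoveries at 10⁵ samples. These sizes put every stochastic check at least
3σ away from its pass boundary while keeping the full suite in a few
minutes.

## Known limitations

* The threshold/saturation report is grid-resolution-limited by design; no
  interpolation between λ grid points.
* The greedy E/I search optimizes only λ̂; it does not randomize over the
  set of label assignments achieving a given λ̂ uniformly.
* The LIF neighborhood is one synaptic hop (the target's presynaptic
  pool); polysynaptic recruitment beyond that pool is outside the drive
  protocol.
* Near the percolation transition, single realizations at desk scale
  fluctuate by a few percent in GSCC fraction; comparisons there are made
  on replicate averages.
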