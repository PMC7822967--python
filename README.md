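# stpfit

Short-term depression modeling and quantal analysis of GABAergic IPSC trains.

`stpfit` is a pipeline for characterizing short-term depression (STD) at
GABAergic synapses from trains of inhibitory postsynaptic currents
(IPSCs), of the kind recorded with optogenetic stimulation of parvalbumin
(PV) afferents — either the septohippocampal projection from the medial
septum/diagonal band (the "SH" model) or local hippocampal PV
interneurons ("HC").  It is aimed at synaptic physiologists who want to
go from amplitude tables (or raw traces) to quantal parameters, train
metrics, and fitted kinetic models without any external data: a
stochastic generator reproduces the experimental design end to end.

## The model

Between stimuli the synapse is described by two presynaptic variables:
residual calcium `c` (in units of the per-stimulus increment, Δ = 1) and
the available fraction `R` of the readily-releasable pool,

    dc/dt = -c / τ_Ca
    dR/dt = k(c) · (1 - R)

with saturating release-probability and recovery-rate functions

    P(c) = P_max · c / (c + K)
    k(c) = k_min + Δk · c / (c + K_r).

At each pulse calcium jumps by Δ, the observable release probability
`p_n = P(c) · R` is recorded (this is what "IPSC amplitude divided by
N·q" estimates), and the pool is depleted by the released fraction.  The
calcium dependence of `k` implements calcium-dependent recovery (CDR):
during high-frequency trains accumulated calcium accelerates
replenishment, which is what lets the SH synapse resist depression in the
gamma band.  Both inter-pulse updates have closed forms, so train
simulation is exact.

Quantal analysis uses the variance–mean parabola across 20-pulse trains
at 5/10/20/50 Hz (7 repeats),

    σ² = (1 + CV²)·q·I − I²/N_VM ,      p_max = p_x / (N_VM·q) ,

with the intrasite quantal CV fixed at 0.3.  Model fitting minimizes the
mean squared error between predicted and observed release probabilities
over 4 × 20 train values plus P1/P2 at six recovery intervals (92 points),
then samples the posterior of the five free kinetic parameters
{τ_Ca, K, k_min, Δk, K_r} with an adaptive Metropolis sampler
(delayed-rejection fallback, Gibbs-sampled error variance).

## Worked example

```python
import stpfit as sp

sh = sp.builtin_params("SH")            # septohippocampal PV synapse model
hc = sp.builtin_params("HC")            # local hippocampal PV synapse model

# forward-simulate a paired-pulse protocol at 20 Hz (50 ms interval)
print(sp.simulate_train(sp.StimulusProtocol.paired(50.0), sh).ppr)  # 0.7026
print(sp.simulate_train(sp.StimulusProtocol.paired(50.0), hc).ppr)  # 0.6443

# generate a synthetic cell and run variance-mean analysis
gt = sp.QuantalGroundTruth(n_sites=10, q_pa=22.7)
ds = sp.generate_experiment(sh, gt, seed=1, p_scale=0.87 / 0.44379)
fit = sp.variance_mean_fit(ds.tables)
print(round(fit.q_pa, 1), round(fit.n_vm, 1), round(fit.p_max_hat, 2))
# 23.4 9.3 0.96
```

The two PPR numbers say the SH model loses ~30% of its response on the
second pulse at 20 Hz while the HC model loses ~36% — the weaker
paired-pulse depression of the septohippocampal synapse.  The last line
shows the variance–mean fit recovering the generating quantal amplitude
(22.7 pA), number of release sites (10) and peak release probability
(0.87) from one noisy 7-repeat session.

The same stages are available as a CLI
(`stpfit simulate | generate | vm-fit | fit | mcmc | report`); every
output embeds the seed and a config hash, and identical seeds reproduce
files bit for bit.

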