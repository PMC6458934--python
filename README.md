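# gesnn

Grammatical-evolution design of partially connected spiking neural networks
(SNNs) for supervised classification.

`gesnn` evolves complete three-layer feedforward SNNs — the number of hidden
neurons, which input features each one connects to, and every synaptic weight
and delay — in a single evolutionary search. There is no separate training
phase: the search space *is* the space of fully configured networks. Because
hidden neurons connect to only a subset of the inputs, the designs perform
implicit feature selection and stay small.

It is aimed at researchers in neuroevolution and spiking computation who want
a reproducible, scriptable implementation of grammar-guided SNN design for
tabular classification benchmarks.

## The model

Neurons follow the single-spike Spike Response Model. The membrane potential
of neuron *j* is a weighted, delayed sum of postsynaptic potentials,

```
x_j(t) = Σ_{i ∈ Γ_j} w_ji · ε(t − t_i − d_ji),
ε(t)   = (t/τ) · e^(1 − t/τ)   for t > 0, else 0,
```

and the neuron fires when `x_j(t) ≥ θ` (defaults: τ = 9 ms, θ = 1 mV). Each
scalar feature `f` becomes an input spike time through the linear map
`Y(f) = ((b−a)/r)·f + (a·M − b·m)/r` onto the window [a, b] = [0.01, 9] ms,
with `m`, `M` the per-feature minimum/maximum of the design subset and
`r = M − m`.

Class k of a K-class problem is assigned the target output firing time
`12 + 3k` ms; a pattern is classified by the target nearest to the output
neuron's first spike (time-to-first-spike decoding). The simulation ends 2 ms
after the last target, and output spikes are read from 10 ms onward.

Candidate networks are words of a BNF grammar: `{` separates hidden-neuron
blocks, `(` separates synapse configurations `id@weight@delay`, and the last
configuration of each block is the hidden neuron's synapse onto the output
neuron. A fixed-length genotype of 500 integer codons in [0, 255] is mapped
to a word by the standard depth-first grammatical-evolution derivation
(codon mod number-of-alternatives at each choice point; exhausting the
codons makes the individual invalid). Two search engines minimise either the
squared error `E_s = Σ_p (t_actual(p) − t_desired(p))²` or the accuracy
error `E_a = 1 − C/T` over the design subset: a generational GA over 4000-bit
genomes (5-tournament, 10% elitism, one-point crossover, 5% bit negation)
and DE/Rand/1 with binomial crossover (CR = 0.1) over real vectors in
[0, 255]^500.

## Worked example

Design a network for a synthetic, well-separated two-class problem (40
samples, 2 features) with DE and the accuracy-error fitness, at desk scale
(population 20, 4000 fitness evaluations):

```python
from gesnn import ExperimentConfig, run_single

cfg = ExperimentConfig(
    dataset={"n_samples": 40, "n_features": 2, "n_classes": 2, "separation": 8.0},
    engine="de", fitness="accuracy", population=20, budget=4000,
)
result = run_single(cfg, seed=1)
print(f"design accuracy: {result.design_accuracy:.4f}")
print(f"test accuracy:   {result.test_accuracy:.4f}")
print(f"hidden units: {result.stats.hidden_units}, "
      f"features employed: {result.stats.features_employed}, "
      f"synapses: {result.stats.synapses}")
```

prints

```
design accuracy: 1.0000
test accuracy:   0.9500
hidden units: 6, features employed: 2, synapses: 14
```

The design half (20 samples) is classified perfectly and the held-out half at
95%; the evolved network uses 6 hidden neurons and 14 synapses, touching both
input features. `result.best_word` holds the full grammar word, e.g. the
first hidden block `47@2.90@02.55(0@-9.81@6.48{` reads: one input synapse
from input `47 mod 2 = 1` with weight 2.90 and delay 2.55 ms, then the output
synapse with weight −9.81 and delay 6.48 ms.

The same run from the shell:

```
gesnn generate --n-samples 40 --separation 8 --seed 1 --out blobs.csv
gesnn design blobs.csv --engine de --population 20 --budget 4000 --seed 1 --out-dir run/
gesnn stats run/best_word.txt --n-features 2
```

Further subcommands: `split`, `encode`, `evaluate`, and `experiment` (full
multi-repetition protocol from a YAML config).

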