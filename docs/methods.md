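# Methods

## Neuron model and simulation

Networks are three-layer feedforward SNNs of reduced Spike Response Model
neurons. The membrane potential is a weighted, delayed, linear sum of PSP
kernels `ε(t) = (t/τ)·e^(1−t/τ)` (zero for `t ≤ 0`), and a neuron fires at
its first threshold crossing. The variant deliberately has no reset or
refractory kernel: time-to-first-spike decoding only ever reads the first
spike, so every neuron fires at most once per pattern.

Potentials are evaluated on a fixed grid with step `dt = 0.01` ms — the same
resolution at which synaptic delays are expressed — and a spike time is the
first grid point at or above threshold. No event-driven root finding is
attempted; at τ = 9 ms the potential varies slowly relative to the grid, and
the grid solver agrees with a 10×-finer brute-force search within one `dt`
on randomized neurons (this is a test). Grid evaluation makes every
simulation bit-reproducible.

The output neuron's spike is searched from `decision_start = 10` ms; hidden
neurons are simulated from `t = 0`. The stated simulation window
"[10 ms, last target + 2]" is read as constraining the *output decision*
only: input spikes land in [0.01, 9] ms, so hidden spikes must be allowed
before 10 ms or nothing could ever reach the output layer. A hidden neuron
that never fires contributes no PSP to the output, silently.

Defaults (all exposed): τ = 9 ms, θ = 1 mV, weights in [−999.99, 999.99]
(unitless; `w·ε` is compared directly to θ), delays in [0.01, 19.99] ms.

## Temporal encoding

Feature `f` maps to spike time `Y(f) = ((b−a)/r)·f + (a·M − b·m)/r` on
[a, b] = [0.01, 9] ms, with per-feature `m`, `M` computed **on the design
subset only** — the held-out half never influences the encoding (leakage is
excluded by construction and asserted by a test that perturbs the test half
and checks the designed network is unchanged). Two edge rules: values
outside [m, M] are clamped before encoding, keeping all spike times inside
the window; a feature constant on the design subset (`r = 0`) maps every
value to the midpoint `(a+b)/2` with a warning, which preserves
dimensionality without a division by zero. The map's endpoint identities
`Y(m) = a`, `Y(M) = b` degrade numerically as `r → 0` (cancellation error
grows like `1/r`), which is why the degenerate case is handled by rule
rather than by the formula.

## Grammar and genotype mapping

The shipped BNF grammar generates hidden-neuron blocks terminated by `{`;
each block holds one or more `(`-terminated input-synapse configurations
`id@weight@delay` followed by an output-synapse configuration. Recursion is
right-branching with two alternatives per recursive rule, so under uniform
random codons the hidden-neuron count and the synapses-per-neuron count are
geometrically distributed with mean 2 — architecture size is genotype-driven,
not fixed. Weight literals carry an optional sign, 1–3 integer digits and
exactly 2 decimals (hence |w| ≤ 999.99 by construction); delay literals carry
1–2 integer digits and 2 decimals and are clamped into [0.01, 19.99] at parse
time; neuron identifiers are reduced modulo the input count. Duplicate
synapses between the same pair of neurons are legal (parallel multi-delay
paths). The exact literal sub-grammar is this package's own reconstruction of
the dialect, so topology-size statistics are not expected to match any
particular external tabulation.

Mapping is the standard depth-first grammatical-evolution derivation: always
rewrite the left-most nonterminal; at a choice point with k > 1 alternatives
consume one codon `c` and take alternative `c mod k`; single-alternative
rules consume nothing. There is no genotype wrapping — running out of codons
with nonterminals pending makes the individual invalid, and invalidity is a
value (a sentinel fitness), not an exception. With 500 codons, random
genotypes map to valid words ≈99% of the time.

## Fitness and decoding

Class k's target output time is `12 + 3k` ms; `t_end` is the last target
plus 2 ms. Prediction is nearest-target with ties toward the smaller class
id; a silent output neuron is a rejection and always counts as incorrect.
The nearest-target rule is the natural reading of per-class target times;
no other decision rule is implied by the setup.

* Squared error: `E_s = Σ_p (t_actual − t_target-of-true-class)²` over the
  single output neuron. A non-firing output substitutes `t_actual = t_end`
  (maximally late), giving a finite, direction-consistent penalty rather
  than an infinite or arbitrary one.
* Accuracy error: `E_a = 1 − C/T`, the design-subset misclassification rate.

Invalid individuals receive sentinel fitnesses (10⁹ for `E_s`, 2.0 for
`E_a`), strictly worse than any attainable valid value (`E_a ≤ 1`;
`E_s ≤ P·t_end²` at this tool's problem sizes).

## Search engines

Both engines stop on a hard budget of fitness evaluations; each newly
created individual costs exactly one evaluation and cached fitnesses (GA
elites, DE survivors) are never re-evaluated.

GA (binary): 8-bit codons, 4000-bit genomes (500 codons, MSB-first),
population 100, 5-tournament selection (minimum of 5 uniform draws),
elitism ⌈10%⌉ copied unchanged, one-point crossover, independent per-bit
negation with probability 0.05. Generational; a budget-truncated final
generation is topped up with the best survivors so population size is
conserved.

DE (real): DE/Rand/1/bin on [0, 255]^500, population 100, CR = 0.1, one
guaranteed crossover component, components clamped into the domain, floor
to integer codons at evaluation time. The differential weight F is not part
of the protocol's stated parameters; the conventional F = 0.5 is the
default and is exposed. Selection is greedy with ties moving to the trial —
under the accuracy-error fitness the landscape is piecewise constant, and
tie-acceptance lets the population drift across plateaus instead of
freezing.

Each search owns one seeded generator (initialisation first, then
per-generation operators in population order), so identical seeds reproduce
runs bit for bit.

On a separable toy objective (sum of codons), DE with default operators
reaches below 5% of the random-initialisation mean within 10,000 evaluations
at 50 codons (asserted over seeds in the suite). The GA does not reach that
bar at any tested dimension: its 5% per-bit mutation maintains a high
mutation–selection equilibrium, so the suite instead asserts strict,
substantial improvement over initialisation for the GA. This is a property
of the prescribed operator rates, not a defect of the implementation.

## Experiment protocol

One run: stratified halving into design/test (odd per-class counts send the
extra sample to the design half; CSV class labels are remapped to contiguous
ids in first-appearance order) → fit encoding on the design half → encode
both halves → search on the design half → remap the best genotype → report
design and test accuracy plus topology statistics (distinct input features
used, hidden-unit count, total synapse count including the output synapses).
Repetition i uses seed `base_seed + i`. Named presets pair the engines with
the two fitness functions: `beta1`/`beta2` = GA with squared/accuracy error,
`gamma1`/`gamma2` = DE with squared/accuracy error.

## Synthetic fixture

`make_synthetic` draws Gaussian blobs with unit noise: class centroids sit
on scaled coordinate axes so that (for K ≤ d) every pair of centroids is
exactly `separation` apart; labels are balanced and rows shuffled,
deterministically per seed. At `separation = 8` the classes are ~8σ apart —
trivially separable by a nearest-centroid rule — which isolates the question
"can the search find a network that expresses the boundary?" from the
question of statistical difficulty. What passing at desk scale shows: the
full pipeline (encoding → grammar → simulation → fitness → search) can
discover accurate, partially connected designs within a few thousand
evaluations on an easy geometry. What it does not show: performance on
overlapping classes, correlated or irrelevant features, class imbalance, or
the large-budget regime (10⁶ evaluations) used for real benchmark tables —
the fixture has none of those traits.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: populations
10–20, budgets 150–10,000 evaluations, 16–40-sample fixtures; the full
protocol (population 100, 10⁶ evaluations, 33 repetitions) remains available
through the same configuration surface. Ties in tournament selection resolve
by draw order (first minimum); `argmin` tie-breaks in decoding take the
smaller class id; weights and delays are rendered and parsed at exactly 2
decimals, so word↔topology round trips are exact for 2-decimal topologies.

## Known limitations

* Single output neuron; per-class output neurons and multi-objective or
  complexity-penalised fitnesses are out of scope.
* No categorical features, missing-value handling, or population/receptive-
  field encodings; the one-dimensional linear encoding only.
* The grid solver can in principle miss a threshold excursion narrower than
  `dt`; at τ = 9 ms and 2-decimal delays this was never observed against the
  fine-grid oracle, but pathological weight combinations could construct one.
* Full-scale benchmark accuracies depend on external datasets and ~10⁶
  evaluations per run; nothing at desk scale certifies them.
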