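# Methods

## The model

`logicmap` evolves populations of deterministic logic circuits that
classify amino-acid pairs as in-contact / not-in-contact from binarized
feature vectors.  A circuit ("Markov network" with 0/1 probability
tables) is encoded as a byte-string genome: each gene starts with the
two-byte codon `42 213` and then specifies, in a fixed 26-byte body
(one-byte addressing), a gate's input/output arity (1–4 each), the state
nodes it reads and writes, and its full truth table.  The state vector
is `[inputs | hidden | 4 outputs]`; the four outputs are
negative-primary, negative-veto, positive-primary, positive-veto.  A
class is asserted iff its primary output is 1 and its veto output is 0 —
the simplest consistent reading of a second "veto" output whose job is
to suppress over-eager yes answers.  When several gates write one node
in a step, the node takes the OR of the written values.

Execution runs a configurable number of synchronous update steps
(default 1).  At a single step, hidden nodes — which start at zero and
are write-only dead ends — cannot influence the outputs, so the
evaluator only simulates gates wired into the output block; this is an
exact optimization, not an approximation, and the batch evaluator is
property-tested against the per-example reference path.

### Addressing

Gate addresses are one byte by default, resolved modulo the state size
(inputs) or modulo `n_hidden + 4` with an offset past the input block
(outputs), so gates can never overwrite the clamped input sensors.  One
byte reaches only the first 256 state nodes; for wide encodings (the
full 688-feature layouts are 1,376–11,008 bits) an `address_bytes=2`
mode extends the reach.  The default stays at one byte because the
fixed-width 28-byte gene makes duplication/deletion spans trivial and
keeps hand-decoding easy.  The consequences of the 256-node ceiling for
wide inputs are deliberate and documented below.

## Encoding

Continuous features are split into 4, 10 or 16 equal-width bins fitted
on the *training* range of each feature; out-of-range test values clamp
to the extreme bins.  Uncompressed encodings spend `split` bits per
feature and write bin k as a thermometer pattern (first k bits set);
compressed encodings write the bin index in base 2, most significant bit
first (bin 0 = all zeros).  Binary features always emit all-ones /
all-zeros across the full per-feature width so every feature occupies
the same number of input bits.  Ties at bin edges go to the upper bin,
matching the half-open interval convention; the last bin is closed.

## Fitness and evolution

Fitness is `f = sqrt((acc_pos + out_pos)^2 + (acc_neg + out_neg)^2)`
with class-conditional accuracies and an output reward `out_c` = the
fraction of class-c examples on which the network asserted any class
(maximum `sqrt(8)`).  An example of class c counts as correct iff
channel c is asserted and the opposite channel is not; asserting both or
neither is incorrect.  This blocks the degenerate always-assert-both
strategy, at the cost of a strong local optimum discussed below.

Each update is one generation: tournament selection (size 2) with one
elite, offspring mutated with per-byte point mutations (rate 0.001) and
per-offspring gene duplication/deletion (rate 0.05 each; a duplication
that would exceed the 40,000-byte cap is skipped rather than truncated).
Training examples rotate through disjoint chunks on a fixed schedule,
and all cached fitnesses are invalidated at each rotation.  Every run is
driven by a single seeded generator and is reproducible bit-for-bit.

Committees collect the best genome of each independent run; per example
the positive and negative vote sums are compared and ties are broken
uniformly at random.  A member asserting both channels contributes one
vote to each sum.  The positive vote count doubles as a confidence proxy
for top-L and top-L/k selection.  Fixed-quota (CASP-style) selection
ranks *all* predictions by positive votes, since the quota must be
filled even when majority-positive predictions are scarce; top-L
selection ranks majority-positive predictions only.

`Fmax = spec * sens / (spec + sens)` with specificity = precision on the
positive class; 0/0 is defined as 0.  The label-blind random baseline
uses expected specificity = positive prevalence and expected sensitivity
= guess rate.

## Profiles and problem sizes

Two named profiles ship with the CLI.  The `paper` profile carries the
full-scale reference parameterization (60 runs x 100,000 updates, population
500, 100 starting gates, 50,000-example chunks rotated every 25,000
updates).  The `desk` profile — 5 runs x 500 updates, population 50, 20
starting gates, 16 hidden nodes, 2,000-example chunks rotated every 250
updates — is what the test suite and the reference studies run; a full
desk study (data synthesis, 5 runs, committee evaluation, salience
analysis) takes about half a minute per seed on one CPU.

## The synthetic reference study

`logicmap.study` freezes one fully specified experiment used by the
validation suite:

* 5,000 training pairs at the reference training prevalence (35.155%
  positive) and 2,000 held-out test pairs at the reference testing
  prevalence (2.78%), 50 and 20 proteins respectively;
* 100 features, 15 binary; 10 planted informative features: eight
  binary near-deterministic markers (P(1|contact)=1, P(1|no contact)=0)
  and two continuous features with a +5 SD class shift.  The binary
  markers are the synthetic analog of the sequence-separation indicator
  bins of the real feature set — near-deterministic class markers that
  are exactly the features the full-scale committees recognize most;
* the `split16` encoding (1,600 input bits) and the desk profile.

Success is measured two ways: the committee's held-out Fmax against
3x the random baseline at guess rate 0.5, and the mean recognition count
of planted versus null features.

### Why these conditions (desk-scale evolvability)

The fitness landscape has a deep local optimum at `f = sqrt(5)`: assert
one class on every example.  Escaping it requires a coordinated change —
a gate driving the opposite primary output (or a veto) from an
informative bit, with a compatible truth table — and intermediate states
are strictly worse unless the informative bit is a near-perfect marker,
in which case the intermediate is fitness-neutral and can drift.  A desk
run produces ~25,000 offspring versus ~50,000,000 in a full-scale run,
so weakly informative plants (e.g. +2 SD shifts) are not recoverable at
desk scale: in exploratory runs every population locked at `sqrt(5)`,
and none of 20,000 single-mutation offspring of a locked champion
improved on it.  The frozen study therefore plants strong markers and
uses the widest encoding: binary features replicate across all 16 bits
of their block, and with one-byte addressing those marker bits make up
roughly half of the gate-addressable input space, so marker-reading
wirings are dense in genotype space.  Under these conditions roughly
half to three quarters of individual runs escape the degenerate corner,
and the five-run committee almost always recovers the signal (members
still locked in the corner split between the always-positive and
always-negative corners and largely cancel in the vote).

What passing these tests shows: the full pipeline — synthesis, binning,
genome decoding, evolution, committee voting, salience readout — can
find and exploit planted, strongly informative structure at desk scale,
and the recognition counts separate planted from null features.  What it
does not show: performance on real contact data (no feature
correlations, no per-protein structure in the features, no label noise,
far smaller scale) or recoverability of weak signals, which demonstrably
requires the full-scale compute budget.

## Feature salience and reduction

A member recognizes a feature when any of that feature's bits appears
among its gate inputs (raw connectivity; an output-reachability-pruned
variant is available).  Recognition counts across the committee rank
features; thresholding them builds a reduced dataset.  The desk analog
of the full-scale reduction (which kept features recognized by >=6 of 60
networks) keeps features recognized by >=3 of the 5 desk members;
re-evolving on the reduced set reproduces the full-feature committee
Fmax with no measured loss on the reference seeds.

## Numerical and degenerate-input conventions

* Constant (degenerate) features encode as all-zero bits and always map
  to bin 0.
* Fitness requires both classes present in the evaluation chunk.
* `Fmax` 0/0 -> 0; random baseline requires both classes and a positive
  guess rate.
* Tie-breaking (committee votes, selection cutoffs, tournament ties)
  always draws from the caller's seeded generator.
* Median of an even-sized recognition count set is the midpoint.
* Unparseable genome tails are ignored; a genome with zero genes is a
  legal circuit that never asserts.

## Known limitations

* The gene layout (start codon, fixed-width body) is this package's own
  documented design; the original system's exact byte layout is not
  public.
* One-byte addressing cannot read input bits past node 255; wide
  encodings need `address_bytes=2`, which changes genome geometry.
* Hidden state is inert at the default single update step; multi-step
  execution is implemented but unexplored here.
* The evolutionary "update" is interpreted generationally; steady-state
  interpretations would change the meaning of the update budget.
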