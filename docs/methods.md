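# Methods

## Boolean dynamics and attractors

Networks are synchronous: every gene applies its logic function to the
current state simultaneously, `s_{t+1} = D(s_t)`. Gene 0 is the
least-significant bit of the integer state code, and a node's inputs are
listed most-significant bit first, so for inputs `(j1, j0)` the truth
table row consulted is `2*s[j1] + s[j0]`. Both conventions are arbitrary;
they are fixed once here and stated on every I/O surface (network JSON,
rule text, reports).

Attractor enumeration is exhaustive. The deterministic map over all `2^n`
states is built as a lookup table; composing it with itself `n+1` times
(pointer doubling, `O(n 2^n)`) maps every state onto its attractor cycle,
after which cycles are decomposed by following `D` and basins read off
directly. Attractors are ordered by their smallest member state, so all
downstream tables are reproducible. The exhaustive cap defaults to
`n = 20` (an explicit opt-in raises it); the noisy-chain analysis below
is the practical limit anyway.

## Noise model and MFPT

Noise is an independent flip of each gene with probability `p_e` per
step. A step is a mixture: with probability `(1-p_e)^n` no gene flips and
the deterministic update runs; otherwise the state jumps directly to the
flipped state. This yields

    p(x->y) = p_e^h (1-p_e)^(n-h)  [y != x]  +  (1-p_e)^n [y = D(x)]

whose rows sum to 1 exactly (the flip kernel over `y != x` contributes
`1 - (1-p_e)^n`). The construction is validated in the tests against a
brute-force enumeration of all `2^n` flip patterns. An alternative
reading — flip first, then update — exists; the jump reading is used
because it makes the displayed flip term the literal transition
probability and normalises without correction terms. For `0 < p_e < 1`
the flip kernel is strictly positive, so the chain is irreducible, every
MFPT is finite, and there is no sparsity to exploit: dense linear algebra
is used throughout, with a default cap of `n = 14` (8 GiB-scale memory at
the cap).

MFPTs are computed three ways, and the triangle is a standing test:

1. **Linear solve** (production): hitting times of a target set `T` solve
   `m = 1 + Q m` with `Q` the transition matrix restricted to non-target
   states. One solve serves every source state, so the all-pairs
   attractor matrix costs one factorisation per attractor.
2. **Truncated series** (oracle): `Σ k F_k` iterated until the
   unaccounted first-passage tail mass drops below a tolerance
   (default 1e-9; the tests use 1e-12), warning if the iteration cap is
   hit first.
3. **Monte-Carlo simulation** (oracle): lock-step vectorised walkers of
   the mixture process, reporting mean and standard error.

Attractor-to-attractor MFPT starts from a uniform mixture over the source
attractor's cycle states and targets the whole destination cycle; the
cycle states of a noisy attractor are visited approximately uniformly at
small `p_e`, and the choice only matters for cyclic attractors. The
default noise is `p_e = 0.01`: small enough that attractor identity is
meaningful between flips, large enough that an 8–10-node chain mixes in
computable time. It is a free parameter everywhere and is recorded in all
outputs (see "Sensitivity to p_e" below).

## Critical network generation

Fixed in-degree `q` (default 2), inputs drawn without replacement
(self-inputs permitted — the switch motifs themselves use feedback),
truth-table entries i.i.d. Bernoulli(`p_N`). The average sensitivity
`s = 2 q p_N (1-p_N)` is the expected one-step spread of a single-bit
perturbation; `s = 1` defines criticality. `critical_bias(q)` returns the
lower root of `2 q p(1-p) = 1` (sparse expression; the upper root is a
flag away). For `q = 1` the equation has no real solution (`s <= 1/2`),
which the function reports as a domain error; `q = 2` gives exactly
`p_N = 1/2`. An empirical Derrida-style estimator (sampled one-bit
perturbations propagated one step) validates generated ensembles at
`1.0 +- 0.1`.

Ensemble node counts are drawn uniformly from {8, 9, 10}: large enough
for rich multi-attractor landscapes, small enough that the `2^n` Markov
analysis of thousands of networks stays in minutes on one CPU.

## Switch motifs and embedding

Per-node truth tables over rows `[00, 01, 10, 11]`: `[1,1,0,1]` for BS
(`!u | v` with `u` the most-significant input) and `[0,1,0,0]` for
MI00/MI0+/MI++ (`!u & v`). In both tables the most-significant input is
the negated one, so the mutual-inhibition cross-coupling is wired to that
slot (each motif node's most-significant input is its partner), and the
least-significant slot carries the motif's positive self-feedback where
it has one (MI0+: first node of the pair; MI++: both) or an external
signal otherwise. This slot assignment is forced by the motifs' defining
dynamics: it is the unique wiring under which the isolated BS is bistable
and the isolated MI++ is the tristable switch (three point attractors:
both-off and the two polarized states — verified by enumeration in the
tests). Isolated motif networks clamp dangling external slots to a
constant (default 0, folded into a reduced table); note MI00 collapses to
the all-off state under a low clamp and needs a high external drive to
show its toggle behaviour.

Embedding replaces the truth tables of two randomly chosen distinct nodes
and rewires only their inputs (partner on the negated slot; self-loop or
a retained original source on the other); all other nodes are untouched
and the node count never changes. Nodes whose in-degree differs from 2
are truncated/extended to the motif's 2-input arity, recorded in the
embedding record. Two copies use four distinct nodes.

## Landscape statistics

For each unordered attractor pair the smaller MFPT is *forward* (ties
keep the original orientation and are flagged). A pair is **separate**
when the forward MFPT reaches `sep_threshold` (default `10^3` — the
pruning threshold conventionally applied to MFPT graphs), else
**directional** when reverse/forward reaches `dir_ratio_threshold`
(default 10), else **neither**. Both thresholds are free parameters and
are echoed into every output. Density grids are 40x40 histograms over
(log10 forward, log10 reverse) on a fixed window (default 0–8 decades);
out-of-window values are clipped into the edge bins so mass is always
conserved, which keeps grid differences exactly zero-sum.

The ensemble protocol per network type: draw a critical RBN, embed 0/1/2
motif copies, enumerate attractors, reject the network if it has fewer
than `min_attractors` (default 5; acceptance rates for bare critical RBNs
are around 10%, so rejection dominates generation cost), then classify
all pairs. Each attempt's RNG stream is keyed by
`(master_seed, type_index, attempt_index)` via `SeedSequence` spawn keys,
so every accepted network is independently regenerable and the rejection
decisions cannot bias accepted streams. Region-fraction contrasts between
types come with percentile-bootstrap CIs resampling networks (the pairs
within a network are dependent).

## Barrier-measure comparisons

The transitory bit-flip measure `P(i, j)` enumerates every single-bit
flip of every state of attractor `i` (`cycle_length * n` flips) and
relaxes it noise-free; flips returning to `i` stay in the denominator (so
rows sum to 1 — excluding them is the obvious alternative and would only
rescale rows). Attractor Hamming distance averages the bitwise distance
over all cross pairs of cycle states (a min-distance variant is behind a
flag); the forward/reverse-averaged MFPT is its natural dynamic partner.
Comparisons use pooled Pearson correlation and ordinary least squares.

## Sensitivity to p_e (known limitation)

The separation statistic couples `p_e` to `sep_threshold`: any barrier
crossable by a *single* flip has MFPT of order `1/p_e`, so with
`p_e = 0.01` such pairs (MFPT ~ 100) always fall below the default
threshold of 1000. This matters for embedded MI0+/MI++ pairs, which are
closed 2-node subsystems whose both-off attractor exchanges with the
polarized states through single flips while multiplying the attractor
count roughly 3-fold per copy: at `p_e = 0.01` the resulting flood of
sub-threshold pairs *lowers* the separate fraction for MI++ even though
the switch adds deep polarized barriers, whereas at `p_e = 0.003` the
expected ordering (two copies > one copy > none) holds for every motif
kind. Conclusions about the separate fraction should therefore always be
read jointly with (`p_e`, `sep_threshold`); the defaults are kept at
(0.01, 10^3) and both are exposed on the CLI and config.

## What the synthetic ensembles do and do not show

Generated ensembles emulate critical, fixed-in-degree random logic with
unbiased (q=2) tables — not curated biological networks: no scale-free
topology, no canalizing-function enrichment, no transcription-factor
modularity, and node counts (8–10) far below real GRNs. Passing ensemble
tests demonstrates the machinery and the direction of motif effects in
this model class; it does not calibrate absolute MFPT scales or fractions
for real differentiation networks. Numerical edge cases are handled
explicitly: degenerate (single-attractor) networks are rejected or
reported, infinite/failed MFPTs raise rather than silently dropping, and
all tie-breaks (pair orientation, attractor ordering) are deterministic.
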