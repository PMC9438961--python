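# Methods notes

## Model

qqfilter treats an RNA-seq experiment as a bag of canonical (w,k)-minimizer
occurrence counts and defines a transcript's expression in that experiment
as the median of its minimizers' counts. The index discretizes each
experiment's count distribution into q levels (one interleaved Bloom filter
per level) and reconstructs the median at query time by linear interpolation
between the two thresholds bracketing the half-coverage point. The method is
deliberately a *prefilter*: it trades the accuracy of alignment-based
quantifiers for an index that answers a transcript-vs-all-experiments query
in q bit-vector passes.

Assumptions worth keeping in mind:

- minimizer counts are a usable proxy for read coverage (reasonable when k
  is large enough, 16–32, that random hits are rare);
- the median is taken over the *run-compressed minimizer multiset* of the
  query (duplicated values from distinct runs each contribute), so repeats
  inside a transcript weight its repeated sequence accordingly;
- Bloom false positives are independent across levels and corrected on
  expectation only, via n_tp = (n_o − m·fpr)/(1 − fpr), clamped to
  [0, n_o].

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| k | 21 | k-mer size (nt); 16–32 keeps random collisions rare, 21 is the conventional RNA-seq choice |
| w | 25 | minimizer window (nt); w>k shrinks the sketch ~(w−k+2)/2-fold at some sensitivity cost; w=k gives plain canonical k-mers |
| order_seed | 0x9E3779B97F4A7C15 | XOR mask randomizing the minimizer order; any fixed 64-bit constant works, this one is documented and pinned for reproducibility |
| q | 8 | number of count levels; expression resolution is ~log₂ of the count range, and q ≤ 15 suffices in practice |
| p (target FPR) | 0.05 | per-level Bloom false-positive target, sized on the mean per-experiment load |
| h | 3 | hash functions per Bloom filter |
| cutoff t₁ | auto | noise floor; "auto" applies the gzipped-file-size rule (1/3/10/20/50) |

Per-level bins never shrink below 64 bits, so an empty level cannot collapse
into an all-collision filter.

## Numerical and interpretive choices

- **Median convention.** The recursive automatic thresholds use the *lower*
  median (index ⌊(s−1)/2⌋ of the sorted multiset), so every threshold is an
  attained integer count. The recursion domain is inclusive
  (counts ≥ t_{i−1}), matching the inclusive level brackets
  t_i ≤ c < t_{i+1}, and the last level is inclusive at t_q.
- **Level lookup.** `level_of` is `bisect_right` over the threshold list:
  with tied thresholds the intermediate tied levels are simply empty, and
  assignment stays a partition.
- **Interpolation.** The median approximation is computed with threshold
  *values* (not level indices) and the half-count m/2:
  μ = T_y − (T_y − T_x)·((m/2 − b)/a). An index-valued reading would produce
  numbers in [1, q] that cannot approximate a count median; the
  threshold-valued form reproduces the intended worked-example behavior and
  has count units. μ is clamped into [T_x, T_y] because the false-positive
  correction can push the interpoland slightly outside the bracket.
- **Half comparisons** are evaluated as 2(a+b) ≥ m and 2b < m, avoiding a
  floor/ceil choice for odd m; corrected counts stay fractional throughout.
- **Top-down scan.** Levels are scanned from q downward so the result does
  not depend on the cutoff-dependent first level; the crossing level is
  unique because the cumulative corrected count is monotone along the scan.
- **"Not expressed"** is emitted as 0 and is distinct from an estimate at
  the cutoff threshold (which is ≥ t₁ ≥ 1).
- **Hashing.** splitmix64 finalizer of (value XOR seed), reduced to [0, n)
  by multiply-shift fastrange; the h seeds are the 64-bit fractional parts
  of √2, √3, √5, … (pinned constants). The reduction is exact for
  n < 2³², far beyond any per-level size this package targets.
- **Ambiguous bases.** Any window containing a non-ACGT character yields no
  minimizer; reads shorter than w contribute nothing. Both situations are
  unspecified in the field's tool descriptions; skipping is the conservative
  choice and is exercised in the tests.
- **Actual vs target FPR.** Levels are sized for the mean per-experiment
  load, so experiments with above-average load exceed the target rate; the
  realized per-experiment, per-level rates are stored in the index and are
  the ones used in the query-time correction.

## Synthetic data

The generator emulates a differential-expression study: uniform-random
transcripts (the ground-truth table, not biology, is the oracle),
uniform-start 75-bp paired-end reads at
round(coverage·length/150) pairs per transcript, a configurable
differentially expressed fraction (default 10%) with fold changes 1/4, 1/2,
2, 4 at equal probability, and several coverage levels from one expression
profile. It does **not** model sequencing errors (an optional uniform
substitution rate exists), fragment-length distributions, positional or GC
bias, isoform structure, or shared sequence between transcripts — so
passing tests demonstrate the correctness of the sketch/index/estimate
machinery under its stated model, not robustness to real library artifacts.
Read counts are deterministically rounded rather than drawn from a negative
binomial; expectations in tests are therefore exact where a simulator with
count noise would need tolerances.

Test problem sizes were chosen to keep the whole suite in seconds on one
core while leaving every code path exercised: the "tiny" fixture is 5
transcripts × 2 experiments at coverage 10; fold-change recovery uses 20
transcripts of 500 nt at coverages 8 vs 16 (a true fold change of 2 for
non-DE transcripts), with the acceptance band [1.5, 2.7] on the median
estimated ratio reflecting the one-bucket resolution of the discretized
median.

## Known limitations

- Estimates are bucketed: resolution is the local threshold spacing, so two
  expressions inside one bucket are indistinguishable.
- Shared minimizers between transcripts inflate both (no EM-style
  disambiguation; explicitly out of scope for a prefilter).
- Normalization by t₂ requires automatic thresholds and assumes the
  experiment's count distribution scales with coverage.
- The compressed/sparse bit-vector variant is not implemented (the
  serialization format reserves a flag byte for it); the index is held
  uncompressed in memory during build and query.
- Bit-compatibility with other implementations of the same data structure
  is not attempted: hash seeds and the ordering constant are this package's
  own pinned choices.
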