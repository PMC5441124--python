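# Methods

## The model

Base-scale entropy treats a beat-interval series as a symbolic
dynamical system. Each overlapping vector of m consecutive intervals
is quantized into a word over {0,1,2,3} relative to its *own* mean and
its *own* base scale (the RMS of successive differences), and the
Shannon entropy of the word distribution over a sliding window of N_w
beats measures how varied the local beat patterns are. Low entropy
means few distinct patterns (rigid, overly regular rhythm); high
entropy means many patterns with comparable frequency.

The underlying assumptions are modest: the series is a sequence of
strictly positive intervals; complexity is meaningfully captured by
patterns of m consecutive beats; and the per-vector normalization
(mean and base scale) is the right way to make patterns comparable
across slow drifts in rate. Nothing is assumed about stationarity
beyond the window length, and no distributional model is fitted.

### The incremental update

When the window slides by one beat, the mode histogram changes in
exactly two bins: the word of the departing oldest vector (address h)
loses a count, the word of the new trailing vector (address k) gains
one. The entropy correction splits into cases by whether n(h) hits
zero and whether n(k) was zero:

1. both modes persist — the generic two-term correction;
2. h = k — histogram unchanged, entropy unchanged;
3. the departing mode disappears (n(h) → 0);
4. the arriving mode appears for the first time (n(k): 0 → 1);
5. a singleton swap: one mode disappears while another appears — the
   count multiset is unchanged, so the entropy is unchanged.

All five branches are implemented and instrumented (`case_counts`).
Numerically, however, the entropy is not carried by adding the
correction terms to a running value: that recurrence accumulates
rounding error linearly in the number of pushes. Instead the state
maintains the accumulator A = Σ_{n(j)>0} n(j) log₂ n(j), updated with
the two touched terms per push, and reports

    BSE = log₂ D − A / D,    D = N_w − m + 1.

This is an algebraic identity with the entropy definition (expand
p = n/D inside −Σ p log₂ p). Each accumulator update uses log₂ of a
small integer, so A is a short sum of exactly-computed terms and the
observed deviation from batch recomputation stays at the 1e-14 level
over tens of thousands of pushes (the suite asserts 1e-9). In branches
2 and 5 the accumulator is untouched (the moved terms are 1·log₂ 1 =
0), so "entropy unchanged" holds bit for bit, as the case analysis
demands. A `recompute()` hook rebuilds A from the histogram exactly;
it exists for defense in depth and is never needed in normal use.

During the fill phase (fewer than N_w beats buffered) each arriving
beat completes at most one new trailing vector and probabilities are
taken over the current vector count, so the entropy grows as patterns
accumulate. The batch analyzer, which has no state, reports 0 until a
full window exists; profiles from the two methods are aligned on the
full-window region (that is also the region over which trace MSE is
computed).

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| m | vector length (beats per pattern) | 3 | short-term configuration; 4^m = 64 modes resolve well within a 300-beat window |
| α | threshold multiplier on the base scale | 0.5 | centers the four bands on the typical beat-to-beat step size |
| N_w | window width in beats | 300 | ~4–5 min of resting pulse at 60–75 bpm, the standard short-term HRV horizon |

An alternative preset m=4, α=0.2, N_w=500 is common for ~5-minute
records when finer pattern resolution is wanted. m is capped at 10
(the histogram needs 4^m counters; 4^10 ≈ 1M). α has no universally
agreed selection rule; it is a plain parameter here. Intervals may be
in any time unit — the analysis is exactly invariant under positive
rescaling and additive shifts, because thresholds are per-vector.

Quantizer comparisons are exact IEEE comparisons with no epsilon: the
four bands partition the real line, and any tolerance would break the
partition and the shift/scale invariances. The flip side is that data
lying exactly on a threshold are sensitive to rounding in a transformed
copy of the series; the property tests therefore sample data away from
the (measure-zero) thresholds.

Degenerate vectors (base scale 0, i.e. all m values equal) map every
datum to symbol 3 by the case order of the quantizer; this is the
documented behavior, not a special case.

## Preprocessing

Two deletion rules for singular intervals, applied to short-term
series: the first interval is deleted iff it is more than 1.5 standard
deviations from the whole-series mean (applied once, not re-applied to
the new first datum); any later interval is deleted iff it is more
than 30% above or below the previous retained interval. Population
(divide-by-N) standard deviation is used; with short-term series the
sample/population distinction is immaterial to the rule's intent, and
the convention is a named constant. Referencing the previous
*retained* datum stops one ectopic beat from cascading deletions.
Deleted positions are reported 1-based, matching the PP(i) convention.

The naive beat detector (`detect_beats_naive`) is convenience plumbing
for synthetic waveforms: local maxima above a rolling-median + 3·MAD
threshold with a 0.3 s refractory period. It is not a validated pulse
fiducial-point calibrator and real recordings deserve a proper one.

## Synthetic data

The generators produce interval series with the gross statistics of
resting human pulse (800–1000 ms scale, tens of ms beat-to-beat
fluctuation), at graded complexity: constant, short periodic patterns,
mean-reverting AR(1) (mean 850 ms, φ=0.9, σ=20 ms), and a bounded
random walk (step σ=20 ms reflected into [600, 1200] ms) whose slow
wandering drives beat modes in and out of a sliding window — the
fixture that exercises every incremental-update branch. Stochastic
series are clipped at a 200 ms floor to guarantee positivity. All
randomness uses numpy's default PCG64 generator under explicit seeds,
so outputs are bit-reproducible across platforms.

These are statistical stand-ins, not cardiovascular models: no
respiratory modulation, no 1/f structure, no ectopy. Passing tests on
them demonstrates the *algorithmic* claims (batch–stream equivalence,
exactness of the entropy bookkeeping, invariances), not physiological
validity on real recordings.

### The maximum-entropy fixture and the reachability bound

The entropy formula's ceiling is log₂ 4^m = 2m bits, attained only if
all 4^m modes are equiprobable. That ceiling is unattainable on data:
symbols 0 and 1 both require a datum strictly above its vector's own
mean, so no vector realizes a word drawn wholly from {0,1}; dually,
all-{2,3} words other than the all-3 word would need every datum at or
below the mean without all being equal, which is impossible. At most
4^m − 2^(m+1) + 1 modes are reachable (9 of 16 at m=2, 49 of 64 at
m=3), and in practice the quantizer's geometry concentrates random
data onto far fewer (around 18 at m=3). The `uniform_modes` generator
therefore equidistributes over a constructible set of P modes — a
seeded local search finds a period-P pattern whose P cyclic windows
symbolize to P distinct words, tiled so each occurs equally often —
yielding an exact, verifiable entropy of log₂ P bits (exactly
representable when P is a power of two). The suite keeps one check of
the theoretical 2m ceiling against this fixture; it fails by design
and documents the bound.

## Resource model

The memory/operation accounting is a unit-cost model, exactly one
"byte" per stored scalar (interval, base scale, symbol, count, or the
real-valued entropy itself) and one unit per elementary operation —
deliberately not real machine sizing, but the right model for
comparing the two algorithms' footprints on a small device. Batch:
window + (N_w−m+1) base scales + (N_w−m+1)·m symbols + 4^m counts + 1.
Streaming: window + 2 base scales + 2m symbols + 4^m counts + 1. The
streaming entropy update is at most 9 multiplications, 3 logarithms
and 6 additions regardless of N_w (cases 2 and 5 skip it entirely).

## Test-fixture and problem-size choices

The equivalence grid runs four fixtures of 5000 beats across
m ∈ {2,3,4}, α ∈ {0.2,0.5}, N_w ∈ {100,300,500} — 72 combinations,
each checked at trace-MSE ≤ 1e-12 and per-beat ≤ 1e-9. The
case-coverage check uses the random walk at m=4: with 256 modes and
~297 vectors the histogram is sparse enough that singleton modes
appear and disappear regularly, so all five branches (including the
rare singleton swap) fire robustly for any seed; at m=3 the 64-bin
histogram almost never holds singletons and the swap branch would
make the check a knife-edge. Histogram-conservation is asserted over
10,000 steady-state pushes.

## Known limitations

* No physiological realism in the generators (see above); no claims
  about group differences on real cohorts are tested here.
* The beat detector is naive; use a real calibrator for waveforms.
* The entropy ceiling 2m is unreachable on data (reachability bound
  above); comparisons across m should use the empirical range, not
  the nominal one.
* Beat timestamps, multichannel streams and resampling are out of
  scope; input is an interval series (or beat sample indices plus a
  sampling rate).
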