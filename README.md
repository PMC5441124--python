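# bsentropy

Base-scale entropy analysis of pulse-rate-variability (PRV) and
heart-rate-variability (HRV) beat-interval series, with a
sliding-window **incremental** analyzer that updates the entropy in
O(1) work per beat — producing the same numbers as full recomputation
at a fraction of the memory and arithmetic, which is what makes
beat-by-beat entropy monitoring feasible on wearable and portable
devices.

## Who this is for

Researchers and engineers analyzing beat-to-beat (PP or RR) interval
series — from continuous blood-pressure, photoplethysmography or ECG
recordings — who want a symbolic-dynamics complexity measure that can
run in real time on a stream of beats, plus the batch reference
implementation to validate against.

## The method

Given intervals PP(1..N) and parameters (m, α, N_w):

1. **Vectors.** Every window position yields overlapping vectors
   X(i) = (PP(i), …, PP(i+m−1)), i = 1 … N−m+1.
2. **Base scale.** Each vector's adaptive quantization width is the
   RMS of its successive differences:
   BS(i) = √( Σ_j (PP(i+j) − PP(i+j−1))² / (m−1) ).
3. **Symbolization.** Each datum maps to one of four symbols by its
   position relative to the vector mean μ̄ ± α·BS:
   `0`: μ̄ < x ≤ μ̄+α·BS `1`: x > μ̄+α·BS `2`: μ̄−α·BS < x ≤ μ̄
   `3`: x ≤ μ̄−α·BS. The symbol word is a *beat mode*, one of 4^m,
   stored at its base-4 address.
4. **Entropy.** Over a window of N_w beats, with mode probabilities
   p(π) = n(π)/(N_w−m+1):

   BSE(m) = −Σ_π p(π) log₂ p(π),  0 ≤ BSE(m) ≤ 2m bits.

The **batch analyzer** re-runs all four steps per window position. The
**incremental analyzer** observes that when one beat arrives and the
oldest departs, only two vectors change: it decrements the count of
the departing mode *h*, increments the arriving mode *k*, and corrects
the entropy by a closed-form O(1) update with four cases (both modes
persist; a mode disappears; a mode appears; a singleton swap — plus
the h = k case where nothing changes at all). Internally the entropy
is carried through the accumulator A = Σ n(j)·log₂ n(j), so
BSE = log₂ D − A/D with D = N_w−m+1, which is algebraically identical
but immune to additive rounding drift over arbitrarily long streams.

Because the thresholds are relative to each vector's own mean and
spread, the entropy is invariant under additive shifts and positive
rescaling of the input — milliseconds or seconds, it does not matter.

A unit-cost resource model quantifies the device budget: at
N_w = 1024, m = 5 the batch method needs 8169 storage cells and ~20k
comparison operations per beat; the incremental method needs 2061
cells and 40 comparisons.

## Worked example

The six-beat series `[800, 820, 810, 800, 820, 810]` at m=3, α=0.5
contains four vectors. The first, `(800, 820, 810)`, has mean 810 and
base scale √250 ≈ 15.81, so the bands sit at 810 ± 7.91:

```python
>>> import bsentropy as b
>>> b.symbolize([800, 820, 810], alpha=0.5)
SymbolVector(symbols=(3, 1, 2), address=54)
```

800 falls below the lower band (symbol 3), 820 above the upper band
(symbol 1), 810 between the lower band and the mean (symbol 2); the
word (3,1,2) lives at base-4 address 3·16 + 1·4 + 2 = 54. The four
vectors land on modes {54: 2, 27: 1, 45: 1}, giving

```python
>>> b.bse_window([800, 820, 810, 800, 820, 810], b.BseParams(3, 0.5, 300))
1.5
```

−(½·log₂ ½ + ¼·log₂ ¼ + ¼·log₂ ¼) = 1.5 bits.

From the shell, generate a synthetic AR(1) pulse series and check that
the two analyzers agree beat for beat:

```sh
$ bsentropy simulate iv.csv --kind ar1 --length 2000 --seed 7
$ bsentropy compare iv.csv -m 3 -a 0.5 -w 300
{
  "n_intervals": 2000,
  "n_emissions": 1701,
  "params": { "m": 3, "alpha": 0.5, "window": 300 },
  "mse": 4.887563736364698e-29,
  "max_abs_diff": 1.199040866595169e-14,
  "within_tolerance": true
}
```

The mean squared error between the 1701 aligned entropy emissions is
zero to floating-point rounding: the incremental analyzer is exact,
not approximate. Other subcommands: `analyze` (entropy trace to CSV),
`preprocess` (singularity removal), `beats2prv` (beat locations to
intervals), `resources` (the device budget above).

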