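# Methods

This note records the models implemented in `nucperiod`, the numerical and
design choices that were genuinely open, what the synthetic data emulate,
and the known limitations.

## Numerical representation

DNA fragments are mapped to binary indicator sequences: `x[n] = 1` iff a
member of the k-mer set of interest starts at position `n`. The default set
{AA, TT, TA} (k = 2) is reverse-complement closed, so scanning the forward
strand covers both strands; for general sets `SymbolSet.with_reverse_complement()`
restores that property. Overlapping occurrences each count; ambiguity
symbols (N etc.) never match. The trailing `k − 1` positions of a fragment
carry 0 — a k-mer cannot start there — and the indicator keeps the full
fragment length `N` so that every estimator formula uses one consistent
`N`. Coordinates are 0-based half-open (BED convention) throughout.

Perfect *p*-periodicity is the impulse train `x[n] = 1` iff
`n ≡ n0 (mod p)`, with `n0` the phase of the first occurrence.

## Exploratory estimators

All four profiles are computed by direct summation rather than FFT: with
`p_max = 20` the direct evaluation is cheap, and the IPDFT is not on the
DFT frequency grid anyway.

* **DFT**: evaluated at integer frequency indices `k` with `N/k` inside the
  period range. DFT periods depend on `N`; the profile keeps the raw
  fractional period `N/k` and bins the dominant period by rounding. This
  surfaces, rather than hides, the DFT's grid mismatch at integer periods.
* **IPDFT**: `X_IP[p] = Σ x[n] e^{−2πin/p}` at every integer period in
  range. Its components are not mutually orthogonal; this is why the SNR
  estimate below uses the DFT instead.
* **Autocorrelation**: the finite-window sample form
  `r_xx[p] = Σ_{n≤N−1−p} x[n]x[n+p]`, unnormalized. Its decay with `p`
  (fewer summands at longer lags) is deliberate: the Hybrid relies on it to
  damp long-period aliases. Lag 0 is excluded; `p_min = 2`, since period 1
  is meaningless for dinucleotide periodicity.
* **Hybrid**: the per-period product `r_xx[p]·|X_IP[p]|`. The exact factor
  scaling is a free choice (any per-period rescaling leaves both the argmax
  within each factor's peaks and all bootstrap p-values unchanged); the
  plain product is used.

**Dominant period and ties.** The dominant period is the argmax of the
profile; an all-zero profile returns "no periodicity" (`None`). Exact ties
are structural, not incidental: a perfect period-10 train has *identical*
Fourier magnitude at periods 10, 5 and 2 (harmonics of the impulse train).
Ties — detected with relative tolerance 1e-9, since analytically equal
magnitudes agree only to float rounding — are broken toward the **largest**
tied period, which recovers the fundamental from its harmonic divisors.
(Breaking toward the smallest period would systematically return period 2
for perfectly periodic input.)

**Period range.** Defaults `p_min = 2`, `p_max = 20` for fragment work.
Fourier methods cannot resolve adjacent integer periods beyond roughly
`√N` (~12 at N = 150), so long-period values are indicative only.

## Confirmatory measures

* **Fisher g**: `g = max S[p] / Σ S[p]` over the profile; p-value from the
  exact alternating-sign series
  `P(g > g_obs) = Σ_{j=1}^{⌊1/g⌋} (−1)^{j−1} C(n,j)(1 − j·g_obs)^{n−1}`
  with `n` the component count. The exact distribution holds for
  periodogram ordinates of Gaussian white noise (verified by Monte-Carlo
  in the test suite); applied to autocorrelation or Hybrid profiles the
  ratio form is kept but the p-value is approximate.
* **Chi-squared deviation**: perfect periodicity as the model — every
  occurrence should be followed by an occurrence `p` later. For each
  occurrence at `n` with `n + p ≤ N − k`, record match/mismatch at
  `n + p`; the k-mer set is lumped as one "symbol". The model's expected
  mismatch count is 0, which leaves the raw Pearson statistic undefined,
  so the zero cell's denominator is floored at `ε = 1/(2·n_obs)`
  (continuity-style). The floor is applied to the denominator only, so the
  deviation is exactly 0 — and `P_CS = 1` — iff the empirical p-spaced pmf
  equals the perfect model. The p-value is the χ²(1 df) upper tail.
* **SNR and Cramér–Rao bound**: the SNR of the period-`p` component is the
  DFT energy in the harmonic bins (integer `k` nearest each multiple of
  `N/p`, DC excluded, deduplicated) over the remaining non-DC energy;
  perfectly periodic input gives an `inf` sentinel. The CRB,
  `var(p̂) ≥ 3p⁴/(π²·SNR·N(N²−1))`, follows from the classical
  sinusoid-frequency bound `var(ω̂) ≥ 12/(SNR·N(N²−1))` via
  `ω = 2π/p`: the p⁴ factor is the period-resolution effect. It is a
  strength measure, not a test; `SNR = inf` maps to bound 0.
* **Blockwise bootstrap**: `⌈N/L⌉` blocks of length `L` (default: the
  tested period) copied from uniformly random starts of the original
  sequence with replacement, truncated to length `N` (the last block may
  be partial). `P_BWB = N_G/R` with `N_G` counting resamples whose
  embedded-metric value at the tested period is ≥ the observed value — no
  pseudocount; a zero prints as `< 1/R`. Resample values are compared
  with a 1e-9 relative tolerance so that bit-identical resamples (e.g. a
  constant sequence) compare equal despite BLAS summation-order noise.
  Real sequences are resampled at the symbol level (indicator recomputed
  per resample, junction k-mers accepted); numeric studies that synthesize
  the indicator directly are resampled at the indicator level.
  `R = 1000` is the fragment-study default, `R = 250` the genome-scan
  default, `R = 200` the desk-scale evaluation default.

**Dominant-period gating.** `confirm_period` runs the BWB only when the
embedded estimator's dominant period equals the tested period — the same
restriction the genome scanner applies. This gate is what makes
confirmatory analysis robust to factor/multiple-period confounders: the
*ungated* test at period 2 or 5 on perfect period-10 input is genuinely
significant, because the period-10 impulse train carries exact
harmonic-magnitude components at its divisor periods while block
resampling scrambles their phase. Callers who want the ungated test at an
a-priori period still have `bwb_pvalue`.

## Synthetic data

The generators emulate the standard study conditions: fragments of
`N = 150` (the approximate length of nucleosome-associated DNA) with true
period 10 and uniformly random phase.

* **Erosion** (substitution model): flip exactly `round(f·N)` distinct
  indicator positions, `f` swept up to 50%. Note that beyond ~20% the
  spurious occurrences (~0.9 per flipped zero) greatly outnumber the
  surviving periodic ones, so all estimators approach the noise floor.
* **Approximate periodicity** (indel model): inter-occurrence gaps drawn
  from `Normal(10, σ)`, rounded to integers, redrawn below 1; first event
  at a uniform integer phase in `[0, 10)`. `σ = 0` is exactly perfect
  periodicity.
* **Permutation**: uniform position permutation; composition exactly
  preserved. ROC negatives are permutations of the corresponding
  positives.
* **Panels**: fresh base sequences are drawn for every (level, replicate)
  cell, each from a counter-derived child seed, so panels are
  bit-reproducible and independent of panel shape. ROC panels sweep
  erosion 1–50% and σ ∈ [0.2, 4] uniformly across instances (1000 at full
  scale; any size keeps the same level span).
* **Planted demo genome**: period-10 blocks of TA dinucleotides on a C/G
  background, separated by C/G-only spacers. The spacers deliberately
  contain no NPS dinucleotide: the fixture isolates the scanner's wiring
  (windowing, gating, merging, coverage, BED) so its expected discovery
  set is exactly the planted blocks. With realistic A/T-containing
  spacers (available via `at_fraction`), ~5% of windows are
  dominant-period-10 by chance and a nominal-α fraction of those are
  significant — real scans produce background calls by construction, and
  interpreting them needs multiplicity control that is out of scope here.

What passing these tests does **not** show about real data: synthetic
indicators have an unstructured background, whereas genomic sequence has
correlated composition (the very reason for blockwise rather than
positionwise resampling); absolute power figures and method orderings
within a few percent should not be extrapolated to genomes.

## Evaluation harnesses and problem sizes

Accuracy curves report the fraction of replicates whose dominant period is
exactly 10. Significance curves report the per-level mean of the measure's
output. ROC curves sweep all observed scores (probability measures scored
as `1 − p`, CRB and deviation negated so larger = more positive); AUC by
the trapezoid rule. Default desk-scale sizes — 100 replicates per level,
200+200 ROC panels with `R = 200`, and a ~50 kb demo genome at step 5 with
`R = 100` — keep the full evaluation suite under a minute while leaving
Monte-Carlo standard errors of a few percent; full-scale settings
(1000+1000, `R = 1000`, step 1) are plain configuration.

## Known limitations

* The Hybrid's factor scaling and the relative power of embedded IPDFT vs
  embedded Hybrid are implementation-sensitive where the two are nearly
  matched: on eroded panels their rejection rates and AUCs differ by less
  than Monte-Carlo noise at desk scale (AUC gap ~0.02), so orderings
  between these two on eroded data should not be over-interpreted. Their
  joint superiority over embedded autocorrelation (roughly tenfold in
  rejection rate) and the Hybrid's advantage on approximate periodicity
  are robust.
* The g-statistic's exact null assumes independent exponential ordinates;
  IPDFT components are correlated (non-orthogonal), so its p-values on
  real profiles are approximate.
* The blockwise bootstrap slightly underweights the first/last `L − 1`
  positions (block starts cannot overhang), so composition is preserved
  in expectation only up to an `O(L/N)` edge effect.
* Genome-scan significance is per-window at nominal α with no
  multiple-testing correction; the dominant-period gate also induces
  selection bias in `P_BWB` (the tested statistic is the profile maximum).
  Segment calls should be treated as candidate regions.
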