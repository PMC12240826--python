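# Methods

## Background and model

An entrapment experiment evaluates whether a tandem-MS analysis tool
actually delivers the false discovery rate (FDR) it reports.  The
tool's input database of original target sequences is augmented with
entrapment sequences known to be absent from the sample; the
original/entrapment labels are hidden from the tool and revealed only
to the evaluator.  At an FDR threshold `t`, let `N_T` and `N_E` be the
numbers of original-target and entrapment discoveries and `r` the
effective entrapment-to-original database-size ratio.  entrapkit
implements four estimators of the false discovery proportion (FDP):

| estimator | formula | nature |
|---|---|---|
| lower bound | `N_E / (N_T + N_E)` | lower bound on the FDP of the combined list |
| combined | `N_E (1 + 1/r) / (N_T + N_E)` | upper bound on average |
| sample | `(N_E / r) / N_T` | neither bound; estimates the original-only FDP |
| paired | `(N_E + N_{E>=s>T} + 2 N_{E>T>=s}) / (N_T + N_E)` | tighter upper bound on average, needs pairing, `r = 1` |

For the paired estimator, `s` is the score cutoff of the discovery
list; `N_{E>=s>T}` counts discovered entrapments whose paired original
scored below the cutoff and `N_{E>T>=s}` those whose paired original
was discovered but scored strictly lower.  A peptide absent from the
report carries an explicit sentinel-lowest score that any real score
beats.  The upper-bound nature of the combined and paired estimators
holds on average under an equal-chance assumption — an incorrect
discovery is as likely to arise from the entrapment part of the
database as from the (absent) original part — which is the analogue of
the assumption underlying target-decoy competition itself.

### The k-matched generalization

When each original peptide is associated with `k > 1` entrapment
partners (`r = k`), the paired estimator generalizes as follows.  Every
discovered entrapment is false and contributes 1.  The number of false
*original* discoveries is estimated by two terms: (a) `1/k` times the
number of pair groups whose best discovered entrapment strictly beats
the group's original — under score exchangeability each of the `k`
partners of a false original is exactly as likely as the original
itself to top its group, so this count divided by `k` estimates the
number of false originals that topped their group and were discovered;
plus (b) the directly observed number of discovered originals strictly
beaten by one of their discovered partners (counting true originals
here only adds conservatism, preserving the upper-bound property).
The estimate is

```
( N_E + (1/k) * #{groups: best discovered entrapment > original}
      + #{discovered originals beaten by a discovered partner} )
/ (N_T + N_E)
```

At `k = 1` this reduces term-by-term — including the handling of ties,
where "beats" is strict — to the paired formula above, and it always
dominates the lower bound.  Tie policy throughout: an entrapment must
*strictly* outscore the original to count as beating it; discovery
cutoffs are closed (`score >= s`, `q <= t`).

### Thresholding and clipping

Curves are evaluated against the tool's *reported* q-values: the
discovery set at threshold `t` is every record with `q <= t`, matching
how tools are evaluated at a nominal 1% FDR.  For the paired terms,
"discovered" means membership in that same set, and score comparisons
use the score column; when only q-values are reported, `-q` serves as a
monotone score surrogate (with a warning).  Raw estimates can exceed 1
on adversarial inputs (the paired numerator counts some records twice),
so reported curves are clipped to [0, 1] while the raw values are kept
for diagnostics.  95% coverage bands across `n` replicate databases are
`±1.96 σ_n/√n` with `σ_n` the sample standard deviation of the per-
replicate estimates.

## Database generation

**Digestion** is tryptic without proline suppression (cleave C-terminal
to every K/R, even before P); a proline-suppressed variant exists
behind the `enzyme` flag but is never the default.  N-terminal
methionine is not clipped.  Peptide databases use one missed cleavage
and lengths 7–35 by default; protein-level entrapment construction
digests with zero missed cleavages and no length filter so that the
fragments concatenate back to the protein.

**Shuffled entrapment (peptide level).**  Each original peptide is
shuffled uniformly with its C-terminal residue fixed (optionally also
the N-terminal one).  A candidate is accepted only if distinct from all
original peptides and all previously accepted entrapments; up to
`20 + k` draws are spent per original, and originals that fail are
dropped from the database (and recorded).  The ratio is exactly
`r = k`.

**Shuffled entrapment (protein level).**  Each distinct digested
peptide receives `k` replacements, distinct from the original and from
each other when possible within the retry budget; with `0 < n < k`
distinct shuffles the remainder is drawn with replacement from the `n`,
and with none the replacement equals the original — so no protein is
ever dropped, intentionally unlike the peptide level.  A peptide shared
between proteins or positions is swapped consistently everywhere, and
entrapment protein `j` concatenates the `j`-th replacements in original
order, preserving protein length and K/R cleavage positions.

**Foreign entrapment** samples whole proteins (protein level) or
digested peptides after removing any that match an original peptide
(peptide level), to reach `⌊r × n_originals⌋`.  No pairing exists, so
only the lower/combined/sample estimators apply.  Requesting more than
the pool allows is an error that reports the achievable maximum `r`.

Generation is deterministic given a seed: each original draws from a
sub-stream keyed by `(seed, index)`, so edits to one input do not
perturb the shuffles of others, and identical inputs and seed produce
byte-identical FASTA output.

## Reference FDR-control procedures

Target-decoy competition (TDC) consumes winner/label pairs sorted by
decreasing score (ties broken uniformly at random from the module RNG)
and reports the targets among the top
`K = max{k : (D_k + 1)/max(T_k, 1) <= alpha}`.  The q-value of a target
is the running minimum of that ratio from the bottom of the list, so
the q-thresholded set coincides exactly with the K-rule set; q-values
above 1 are left uncapped to preserve that equivalence (callers cap for
presentation).  Peptide-level control uses the PSM-and-peptide double
competition: best PSM per spectrum, peptide score = max over its PSMs
(sentinel-lowest if none), and within each target–decoy pair only the
higher scorer survives.  Pairs where neither side has any PSM are
dropped; they carry no information and would only append coin-flip
labels at the sentinel score.

The non-competition route computes empirical p-values (share of decoy
peptides scoring at least as high; an optional add-one correction is
off by default, so p = 0 is possible) followed by Benjamini–Hochberg
(delegated to statsmodels) or Storey q-values.  Storey's null
proportion π̂₀ is estimated on the λ grid 0.05, 0.10, …, 0.95 with a
cubic least-squares smoother evaluated at λ = 0.95 (a bootstrap
variant is available behind a flag); q = π̂₀ × BH, so fixing π̂₀ = 1
reproduces BH exactly.  Degenerate inputs clamp π̂₀ with a warning.

## The simulation harness

The simulator stands in for a search engine so that every bound
property can be tested against a known truth.  Per replicate,
`n_native` original peptides are present in the sample and draw scores
from a right-shifted Gumbel (`loc = 3`, `scale = 1` by default);
`n_absent` originals, the `k` entrapments per original, and one decoy
per database peptide draw i.i.d. from a configurable Gaussian null
(standard normal by default; `null_scale = 0` gives the degenerate
separation limit).  The equal-chance assumption therefore holds by
construction.  Honest tools get q-values from the package's own TDC
sweep; miscalibrated tools multiply them by a bias factor
(anticonservative < 1, conservative > 1).  Default study conditions are
300 native among 1000 original peptides, `k = 1`, 200 replicates, and
thresholds {0.5%, 1%, 2%, 5%, 10%} — large enough that the FDP
concentrates near the FDR yet small enough that the whole suite runs in
seconds.  Monte-Carlo tolerances are always expressed in standard
errors of the replicate mean, never absolute constants.

The double-entrapment mode mixes the native peptides with a
foreign-absent pool (`foreign_fraction` of the original database, e.g.
1:20 native:foreign) plus shuffled entrapments at `r = 1`; since
foreign and entrapment discoveries are false by construction, the
direct estimate (their share of all discoveries) anchors the
entrapment estimators to the truth.  It shares one code path with the
plain experiment, so the `foreign_fraction → 0` limit is exact.

What the simulation does *not* emulate: spectrum-level noise, retention
time, fragmentation, score correlations between neighboring peptides
(homologs), or any specific engine's score distribution.  Passing
bound properties here shows the estimators behave as proven *under the
equal-chance assumption*; it cannot certify a real engine whose errors
violate that assumption.

### Numerical and edge-case conventions

- Empty discovery lists give estimate 0 by convention; the sample
  estimator with `N_T = 0 < N_E` is reported as 1.0 with a warning.
- An entrapment discovery whose paired original has no record at all is
  compared against the sentinel-lowest score and flagged with
  `MissingPairWarning` (routine in simulations, where competition
  losers are simply unreported).
- In the exact separation limit the +1-corrected TDC sweep still admits
  the first few nulls ranked directly behind the last native (their
  ratio `1/(T+j)` keeps falling), so the discovery list equals the
  native set only up to a handful of false entries of vanishing
  proportion — the harness tests assert exactly that.
- Detection of a miscalibrated tool by the lower bound is a large-list
  property: with bias 0.5 and an entrapment share `ρ` of false
  discoveries, the expected lower bound at reported threshold `t` is
  about `ρ(2t − 1/N)` for a list of size `N`, which only exceeds `t`
  once `N ≫ ρ/(2ρ−1) / t`.  The harness verifies detection at the 1%
  threshold with lists of ~5000 database peptides.

## Known limitations

- Peptide identity is exact string equality; I and L are distinct
  letters.  An I/L-collapsed mode is deliberately not offered.
- Foreign entrapment supports only the unpaired estimators.
- Protein grouping is consumed (via the any-original-member rule), not
  computed.
- The Storey smoother is a cubic polynomial fit rather than a smoothing
  spline; under the null its π̂₀ is unbiased to within the grid noise
  but can differ from spline-based implementations in the second
  decimal.
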