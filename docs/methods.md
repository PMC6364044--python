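# Methods

## Scope and data model

All coordinates are 0-based half-open, internally and in every text
output; base positions appear 1-based only on plot axes. A restriction
digestion tiles each chromosome exactly: fragment *k* ends where *k+1*
starts, the first starts at 0 and the last ends at the chromosome length.
Every fragment contributes two fragment ends (FENDs); each FEND carries
the three bias features used for correction: fragment length, GC
fraction, and mappability. Contact matrices are square, symmetric and
per-chromosome; inter-chromosomal pairs are retained in the valid-pairs
table but never binned (only intra-chromosomal maps are computed).

## Digestion and FEND annotation

Recognition sites are scanned on the top strand only, case-insensitively;
this is exhaustive because non-palindromic sites are rejected at enzyme
construction. Cut positions are `site_start + cut_offset`. Ambiguity
codes are not supported — the four standard Hi-C cutters need none.

Feature windows are measured interior to the fragment from the FEND
coordinate, truncated at the opposite fragment boundary:

* **GC** — fraction of G/C among non-N bases of a 200 bp window; a window
  of only Ns gets the sentinel −1 and such FENDs are excluded from
  correction learning entirely (every feature, not just GC).
* **Mappability** — fraction of k-mers (k = 50) starting in a 500 bp
  window that occur exactly once in the genome counting both strands;
  k-mers containing N, palindromic k-mers, and any k-mer shared between
  chromosomes are non-unique.

The window sizes and the exact-uniqueness algorithm are package defaults
(config-overridable): they follow the convention of fragment-level
explicit-factor correction inputs, where the features summarize the
sequence context immediately interior to the cut site.

## Pre-truncation

The ligation junction is the fill-in-then-blunt-ligate chimera
`site[:L−o] + site[o:]` (length `2(L−o)`). A read containing the junction
at first position *p* keeps its first `p + (L − o)` bases — the part
derived from its own fragment through that fragment's half-site — making
the operation idempotent. Both sequence and quality are truncated (a
FASTQ record must stay consistent). Reads truncated below 20 bp are kept
and counted; discarding short reads is delegated to the aligner/MAPQ
stage, since truncation runs before mapping. Mate files are processed
independently, mirroring independent alignment of the two mates.

## Pair filtering

The taxonomy of non-informative products, applied after MAPQ ≥ 30
filtering, re-pairing by read id, and 5′-coordinate deduplication:

| same fragment | strands | category |
|---|---|---|
| yes | convergent (+ at or before −) | dangling end |
| yes | divergent or equal | self-circle |
| adjacent fragments | any | re-ligation |
| otherwise | any | valid |

The 5′ position (leftmost base for +, rightmost for −) defines fragment
assignment because it is the ligation-proximal end; the FEND a mate
"faces" is the downstream end of its fragment for + reads and the
upstream end for − reads. Duplicates are detected on the canonical
ordering of the two (chrom, 5′ pos, strand) triples, so mate swapping
between files does not hide a duplicate. Categories partition the paired
input; re-ligation removal can be disabled.

## Distance decay and the expectation model

The bin-level profile is the mean of O[i,j] over all bin pairs at each
distance, pooled across chromosomes. Restriction sites are unevenly
spaced, so the *number of observable FEND pairs per bin pair* fluctuates
with distance and the bin-level profile is not monotone in expectation;
monotonicity holds for the per-FEND-pair contact rate. The expectation
model therefore converts the profile to counts per observable FEND pair,
applies isotonic (non-increasing beyond distance 1) regression there, and
imputes empty distances from the nearest positive neighbor. "Observable"
excludes FEND pairs on the same or adjacent fragments: the filter removes
those products categorically, so they can contribute no counts and must
contribute no expectation.

## Correction learning

Explicit-factor model: each feature is quantile-binned (default 20
groups; ties fall in the left-closed right-open group; degenerate
features collapse with a warning) and a symmetric per-feature table
C_f is learned so that a FEND pair's weight is
`rate(d) · ∏_f C_f[g_f(p), g_f(q)]`. Learning is cyclic multiplicative
moment matching (iterative proportional fitting): for each feature and
group pair, multiply by observed count / expected sum over *all*
observable FEND pairs in that combination, using only pairs separated by
more than `min_distance` (default 500 kb — this exclusion is also the
entire treatment of TSS/CTCF-driven "biological biases"; no annotation
files are consumed). After each sweep the tables are renormalized to
mean-zero log over occupied group pairs, with a global scale factor
absorbing the overall observed/expected ratio so the updates are
idempotent in scale. Convergence: max relative table change < 1e-4 or
100 sweeps. This optimizer is a deliberate reimplementation choice — the
model class (explicit factors over length/GC/mappability with the 500 kb
exclusion) is fixed, the fitting machinery is not — and it is validated
by planted-bias recovery, not by numeric identity with any particular
implementation.

On small test genomes `min_distance` is scaled to 20 kb (the default
500 kb would exclude every pair of a 200 kb chromosome); the learner
raises a clear error suggesting this when no pairs survive the exclusion.

## E, N and observed/expected

Two expectations serve two purposes:

* **E (correction matrix)** — the **mean** per-pair correction
  `∏_f C_f` over the observed read pairs of each bin pair (zero exactly
  where O is zero; a pair involving an excluded FEND contributes 1).
  N = O/E then equals O exactly under an identity model and otherwise
  rescales each bin pair by the average bias of the pairs that produced
  it, preserving contact structure. The count-weighted **sum** variant is
  available (`statistic="sum"`); note that dividing O by the summed
  corrections would cancel the counts themselves and flatten the map,
  which is why the mean is the default.
* **Full expectation (O/E)** — the sum over *all* observable FEND pairs
  of each bin pair of `scale · rate(d) · ∏_f C_f`, i.e. decay and
  corrections together. The O/E map stores `log2(O/expected)` with two
  sentinels: `na_expected` where the expectation is zero (no usable FEND
  pairs) and `na_observed` where contacts were expected but none seen.
  On unbiased decay-only simulations the mean of O/expected per distance
  is calibrated to 1 (zero-observed entries counted as ratio 0; dropping
  them would bias sparse distances upward).

## DI, HMM and TAD coordinates

DI uses a 2-Mb window (w bins on each side, clipped at chromosome ends):
`A` and `B` are the contact sums to the upstream and downstream windows,
`E = (A+B)/2`, `DI = sign(B−A)·[(A−E)²/E + (B−E)²/E]`, 0 when A = B,
masked (NaN) when A + B = 0. Masked bins are excluded from HMM fitting
and break TAD runs.

The three-state HMM (downstream / no bias / upstream) has univariate
Gaussian emissions and is fitted by Baum–Welch (scaled forward–backward,
variance floor 1e-8, best of 5 seeded restarts by log-likelihood, states
relabeled by descending emission mean). Decoding is Viterbi — a single
coherent path, which is what "state shifts" semantics require — applied
per contiguous unmasked segment. Emissions are modeled on the **signed
square root** of DI by default: the DI statistic is chi-square-like with
heavy tails, and on the raw scale EM reliably finds a degenerate
huge-variance state that absorbs strong boundaries of both signs,
breaking decoding on a substantial fraction of seeds; the
variance-stabilizing transform removes the failure mode entirely (the
raw scale remains available via `emission_scale="identity"`). The model
is fitted per chromosome by default.

TAD rule: a domain opens at the first bin of a downstream (+1) run and
closes at the end of the next upstream (−1) run; if another +1 run (or a
masked gap, or the track end) arrives first, the open domain closes just
before it. No-bias (0) bins between an opening and its closing run are
inside the domain; 0-runs outside any open domain are TAD-free gaps.
This gap treatment and the per-chromosome HMM fit are documented
decisions where the procedure is genuinely underdetermined.

## Storage format

Upper triangle, row-major, one token per line; each maximal run of *k*
zeros becomes `-k`; observed matrices are written as integers, float
matrices at 6 significant digits (configurable), formatted so that a
float can never be confused with a run token; O/E sentinels are the
reserved tokens above. A one-line header
`#hicforge triangular n=<n> bin=<bp> chrom=<name> role=<role>` makes
files self-describing; `headerless=True` writes the bare stream. Streams
decode only if their expanded length is triangular, and two consecutive
run tokens are rejected. Gzip is transparent on read and write.

## Synthetic data: what it emulates, and what it does not

The generators emulate: multi-chromosome genomes with restriction sites
planted at recorded positions and guaranteed absent elsewhere; read pairs
drawn from `(1+d)^(−α) · enrichment^[same block] · bias(p)·bias(q)` over
observable FEND pairs; ligation junctions planted in an exact fraction of
mate-1 reads at recorded offsets; and SAM mates with planted duplicates,
low-MAPQ mates, self-circles, dangling ends and re-ligations, each with
exact truth accounting. They do **not** emulate sequencing errors,
quality-score structure, chimeric alignments, copy-number variation, or
inter-chromosomal contacts — so passing tests demonstrate correctness of
the pipeline's logic and estimators under the stated generative model,
not robustness to every artifact of real libraries.

Default study conditions at desk scale: 2–4 chromosomes of 100–200 kb,
5-kb bins (so that a 40-bin chromosome plays the role a 40-kb-binned
chromosome arm plays at full scale), 10⁴–2·10⁵ pairs, junction rate 0.15
(matching the mid-teens truncation percentages typical of HindIII
libraries), artifact rates of a few percent each, and planted TAD blocks
of 10–30 bins with 5× enrichment over a 1/d background at depth 100
(near-diagonal bin pairs of order 10² counts, typical of deeply
sequenced 40-kb maps). TAD-recovery simulations use 150 bins at 40-kb
bin size directly.

## Numerical choices and degenerate inputs

* Symmetry is checked at 1e-9 relative tolerance before encoding.
* N[i,j] = 0 where O = E = 0 by convention; E = 0 with O > 0 is an error
  (it violates the construction of E).
* Quantile-edge ties: left-closed right-open groups.
* HMM variances floored at 1e-8; empty transition rows fall back to
  uniform.
* An all-zero observed matrix is a hard error for decay estimation; a
  window smaller than one bin is a hard error for DI.
* All randomness flows through explicit integer seeds; per-chromosome
  computations are pure functions of their inputs, so threaded and
  serial runs are byte-identical.

## Known limitations

* The optimizer is moment matching, not a likelihood method; with very
  sparse group pairs (no observed counts) the corresponding table entries
  simply stay at their current value rather than shrinking to a prior.
* E as a per-bin-pair mean makes N insensitive to within-bin-pair count
  weighting; at realistic depths the difference from a count-weighted
  estimator is negligible, at extreme sparsity N inherits O's noise.
* Matrix balancing (ICE/Knight–Ruiz), inter-chromosomal expectations,
  nested TADs, loop and compartment calling are out of scope.
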