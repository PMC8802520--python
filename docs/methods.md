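# Methods

## Genome models

The base at position *i* of a reference sequence is `x_i`. Two families of
conditional models are implemented over the alphabet {A,C,G,T}; positions
whose context window contains N or crosses a record boundary are skipped
entirely (no prediction, excluded from every numerator and denominator).

**Central model.** The context of half-width *k* is the 2*k* flanking bases
`s_i(k) = x_(i-k)…x_(i-1), x_(i+1)…x_(i+k)`. The conditional distribution
is estimated from genome-wide counts on both strands,

    P(b | s_i) = (n(b|s_i) − δ_(b,x_i)) / (N(s_i) − 1),   N(s) = Σ_b n(b|s),

where the Kronecker δ implements leave-one-out estimation: the query site's
own occurrence never contributes to its own probability.

**Markov model.** The same machinery with the context redefined as the *k*
preceding bases. Because counting runs over both strands, a 5' model is
identical to the complement of a 3' model, so all Markov models are 5'.
The *bidirectional* probability at a site averages the forward prediction
with the same model's prediction of the complementary base on the reverse
strand: `½·[P(b | left flank) + P(comp(b) | revcomp(right flank))]`. It is
invariant under reverse complementation of the whole genome (tested).

**Interpolation.** Counts of order *k* are regularized by pseudo-counts
from the order-(k−1) distribution,

    r(b|s(k)) = γ · P(b|s(k−1)),
    P(b|s(k)) = (n − δ + r) / (N − 1 + γ),

applied recursively down to an unregularized base order `k_min`. Defaults
mirror the intended genome-scale use: central k=7 from k_min=4, Markov k=14
from k_min=8, γ=100; desk-scale analyses in the tests use smaller orders.
With γ>0, a context with zero counts falls back exactly to the lower-order
estimate; if even the base order has zero counts the model falls back to
the uniform distribution (this happens only when a query context never
occurs in the training records, e.g. under record-held-out
cross-validation). With γ=0 a zero denominator raises an explicit error
naming the context.

**Leave-one-out and strand symmetry.** Counting both strands makes
n(b|s) = n(comp b | revcomp s) by construction. A query site contributes to
its own count row once through its forward reading, and a second time
through its reverse-strand reading exactly when that reading falls in the
same row — for the central model, when the context is its own reverse
complement; for the Markov model, when the reverse complement of the right
flank equals the left flank. Leave-one-out subtracts every such self
contribution (denominator reduced by 1 or 2). With this rule the averaging
identity holds exactly: for γ=0, the average of the leave-one-out
P(b|s) over all occurrences of a context equals n(b|s)/N(s), which the
test-suite verifies to 1e-12 on random genomes.

**Counting backends.** The table backend counts each order once per
training pass (sparse sorted-code tables, so memory scales with observed
contexts, not 4^2k). The FM-index backend stores the Burrows-Wheeler
transform of all records plus reverse complements, with terminators sorting
before all bases and N after T, and answers k-mer counts by backward
search; rank queries use coarse int64 checkpoints (stride 65536 by
default) plus fine uint16 relative checkpoints (stride 256) and a short
scan. Both strides are configurable; suffix sorting uses numpy prefix
doubling, which is ample at desk scale. The two backends return bit-equal
probabilities (tested), so the FM-index — whose advantage is answering any
order from one structure — is exercised without being on the hot path of
large simulations.

**Prediction and accuracy.** The predicted base is the argmax of the
per-site distribution, with ties broken uniformly at random from a seeded
generator (deterministic alternatives would bias accuracy on
low-complexity sequence). Accuracy is the fraction of evaluable sites whose
argmax equals the reference base, reported overall, per record, and per
region label (a site counts toward every label overlapping it, matching
bedtools-intersect semantics). Chromosome cross-validation refits the model
with each record excluded and scores that record without leave-one-out.
Auxiliary summaries: Pearson correlation of per-record GC fraction
(G+C over A+C+G+T, N excluded) with per-record accuracy; equal-width
histograms of the reference probability over [0,1] (default 100 bins);
splice-site profiles as the mean reference probability per offset in a
window (default 500 nt intron side, 100 nt exon side), oriented 5'→3' on
the coding strand, with minus-strand windows mirrored so offsets are
transcript-relative.

## Substitution model

The *simple model* estimates mutability directly from variants in a small
symmetric context ŝ of half-width k̂:

    P_simple(a→b | ŝ) = n(a→b|ŝ) / n(a|ŝ),

with n(a|ŝ) counted over the whole genome on both strands and every variant
also counted as comp(a)→comp(b) in the reverse-complement context.

The factorized model assumes the mutability is proportional to the genome
model's probability of the target base,

    μ_(ab|s) = α_(ab|ŝ) · P(b|s)   (a ≠ b),

in the spirit of general time-reversible rate models but without requiring
reversibility or a symmetric α. Summing the defining relation over all
large contexts containing ŝ gives the estimator

    α_(ab|ŝ) = P_simple(a→b|ŝ) / Z_(ab|ŝ),
    Z_(ab|ŝ) = mean of P(b|s_i) over sites i with reference a and context ŝ,

where Z is accumulated over both strand readings of every site the genome
model can score. When ŝ = s and the genome model is the corresponding
central conditional, the factor P(b|s)/Z is identically 1 and the model
reduces to the simple model at machine precision (tested). The total
mutability of a site is `1 − exp(−Σ_(b≠a) μ_(ab|s))`, the first-order rate
approximation with the exponential diagonal correction; diagonal α entries
and full rate-matrix exponentials are deliberately out of scope.

Numerical conventions: α entries with no usable estimate (unobserved
context/base pair, or Z absent) are stored as absent and scored as μ=0 with
a logged warning — rare contexts must not poison whole-track scoring. The
n(a|ŝ) denominator is whole-genome while Z averages only model-scorable
sites; the discrepancy is the handful of record-edge/N sites, a relative
bias of order k divided by the record length, far below the sampling noise
at every scale used here.

Calibration: sites are binned by total mutability (default width 1e-4) and
the fraction of sites in each bin carrying an observed variant (any-alt
semantics) is compared with the bin center; spline smoothing is available
but off by default and purely cosmetic. Cumulative distributions of total
mutability are reported on a fixed grid, optionally restricted to variant
sites.

## Synthetic data

Genomes are sampled left-to-right from an explicit conditional table
(i.i.d. or Markov of any order). The first `order` bases are drawn i.i.d.
uniform unless an initial context is given — a boundary effect of order/L
that is irrelevant at the lengths used. Variants are drawn per scored site
as one multinomial event over {no change} ∪ {three alternatives} with
probabilities {1 − Σμ, μ_(ab)}: the continuous-time picture is collapsed to
a single generation with time set to 1, so a μ sum above 1 (α outside the
first-order regime) is an error. The generator never emits N; N-handling
is covered by hand-edited fixtures.

What the generator does *not* emulate: repeat structure, isochores,
selection, sampling bias of variant discovery, or linkage. Recovery tests
on synthetic data therefore demonstrate estimator correctness — that the
implemented formulas invert the generating process — not performance on
real genomes, where those ignored features dominate (repeats, in
particular, drive genome predictability upward).

## Study conditions used by the automated checks

- Random-sequence baseline: central k=3 (the 7-mer baseline capacity,
  3·4^6 = 12288 free parameters), leave-one-out, on 1 Mb i.i.d. uniform
  sequence; accuracy must equal the 25% chance level within 0.2 percentage
  points. Because all sites sharing a 6-mer context row are predicted from
  the same counts, the per-genome accuracy fluctuates with a standard
  deviation of ~0.14 p.p. — about 3× the binomial standard error of 10^6
  independent sites. The acceptance script therefore averages ten
  independent seeded replicates, which restores the binomial error scale
  (~0.045 p.p.) that the 0.2 p.p. band presumes; averaging sharpens, not
  loosens, the check (a genuinely biased estimator fails it more reliably).
- Estimator recovery: conditional tables of an order-2 generator recovered
  within 0.01 from 1 Mb; a k̂=0 alpha matrix with entries in [0.02, 0.12]
  recovered within 5% relative error from ~50k sampled variants (binomial
  relative error ≈ 2/√n per entry); model-sampled variants fall on the
  slope-1 calibration diagonal within 4σ binomial bands per occupied bin.
- FM-index correctness: ≥1000 random genome/pattern pairs against the
  sliding-window oracle, plus rank-vs-scan, inverse-transform, strand
  symmetry and monotonicity properties.
- Exact identities (leave-one-out averaging, backend equality, α-model
  reduction at ŝ=s, toy-fixture counts) are verified to 1e-12 or bit-exact.

## Known limitations

- Suffix sorting is in-memory numpy prefix doubling: fine to tens of
  megabases, not engineered for 3 Gb genomes (no external-memory or
  compressed construction, and the index keeps plain arrays rather than
  wavelet trees).
- Interpolated orders are bounded by int64 k-mer packing (context width
  ≤ 20 bases per side of the recursion), far beyond any order estimable at
  desk scale anyway.
- The VCF reader keeps structurally bi-allelic SNV lines; multi-allelic
  sites split across several VCF lines are treated independently rather
  than re-merged and excluded.
- Mutability is a per-generation probability with time set to 1, not a
  calibrated mutation rate; no equilibrium or reversibility constraint is
  imposed on α.
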