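# Methods

This note records the models behind each stage, the conventions and numerical
choices the implementation commits to, what the synthetic data does and does
not emulate, and the limitations a user should know about.

## Sliding-window divergence

Windows slide over a codon-aware alignment (frame anchored at column 0) at
starts 0, s, 2s, … with the last start at L − W, giving ⌊(L − W)/s⌋ + 1
windows; W = 90 nt and s = 3 nt by default, and both must be multiples of 3
so every window opens on a codon boundary (non-multiples are rejected rather
than silently re-framed). Stop-containing codon columns are removed as whole
triplets across all taxa beforehand, keeping the matrix rectangular and in
frame; removed indices are returned so coordinates can be mapped back.

**π by codon position.** For each unordered taxon pair and codon position
k ∈ {1,2,3}, π_k is the proportion of differing sites among position-k sites
where both bases are plain A/C/G/T; gap/N pair-sites are treated as missing
data (excluded from numerator and denominator), not as differences. The
window value is the mean over pairs; pairs with no comparable site are
flagged, and windows report NaN when no pair is defined.

**dN/dS by counting.** The estimator is Nei–Gojobori (1986) with equal-path
weighting. Per codon, each position contributes (synonymous one-step
changes)/3 and (nonsynonymous)/3 to the site totals S and N, with changes
into stop codons excluded from both; pairwise sites average the two codons.
Differences in multi-hit codons are averaged over all orderings of the
minimal mutation path, excluding orderings that pass through a stop (if all
do, all orderings are used so the pair is never dropped). Proportions
p = Sd/S, Nd/N get the Jukes–Cantor correction −¾ ln(1 − 4p/3) when
p < 0.75; otherwise the raw proportion is reported with an `out_of_domain`
flag. Per window, dN and dS are means over non-degenerate pairs and the
ratio is mean(dN)/mean(dS); degenerate windows (no valid pair, dS = 0) are
emitted with flags rather than dropped, so window indices always align with
coordinates. The 95% interval is a percentile bootstrap over the window's
codon columns (the codon, not the nucleotide, is the resampling unit, to
preserve within-codon dependence); `n_boot=0` disables it.

This counting estimator deliberately replaces a phylogenetic MG94 likelihood
fit: it is exactly specifiable, fast, and checkable against brute-force
enumeration, at the cost of ignoring the tree (pairwise distances double-count
shared branches) and of the path-averaging bias noted below. The package's
windowed means and intervals are therefore comparable in shape, not in exact
value, to likelihood-based window scans.

**A property worth knowing:** under a model with ω = 0 every codon stays
amino-acid identical, yet NG86 can still report small positive Nd, because a
codon hit twice by synonymous events (e.g. CTT→CTA→TTA, all leucine) has
minimal paths that detour through another amino acid. The estimator is
consistent for contrasts like "below 1 vs above 1" but not unbiased at the
extremes.

## Substitution rates

For each internal node ("internode", identified by its sorted descendant
leaf set) of a rooted single-gene phylogram, the branch lengths from every
descendant tip up to that node are summed. The internode's own stem branch
is not included — the paths start at the internode, matching the plain
reading of "tip-to-root" distances within a subtree. Relative rate = gene
sum / reference-phylogram sum; absolute rate = gene sum /
reference-chronogram sum (units: substitutions/site/Myr, since chronogram
branches are in Myr).

Conventions and filters:

* Both references are pruned to the gene's taxon set before any comparison,
  which makes "the corresponding sum" well defined when genes differ in
  coverage; pruning sums the lengths of suppressed unifurcations so the
  path-length metric among survivors is untouched.
* An internode is used only if its leaf set is monophyletic in **both**
  restricted references; otherwise the row is emitted with
  `included=False` and reason `not_monophyletic_in_reference`. This keeps
  the root placement of numerator and denominator consistent.
* Internodes need ≥ 2 tips; a zero reference sum excludes the row
  (`zero_reference_sum`).
* Tips with frameshift counts > 0 (pseudogene-like copies) can be dropped
  before estimation; labels are harmonized by whitespace→underscore
  normalization, and any unmatched label is a hard error, never a silent
  drop.
* Gene trees are used as rooted exactly as provided; no re-rooting is
  attempted, so rooting fidelity is the caller's responsibility.

Per-gene summaries are five-number boxplot statistics over all included
internodes pooled within the gene (median, quartiles by linear interpolation
— numpy's default, R type 7 — whiskers at 1.5×IQR, outliers beyond).
Pooling internodes per gene is one of two defensible aggregation levels; the
per-internode rows are always emitted so callers can re-aggregate.

## RNA editing

A pileup row carries the DNA base and RNA read counts at one site. The
candidate edit base is the non-reference base with the highest count; exact
ties emit every tied base as its own row, flagged for review, since ambiguous
sites deserve eyes rather than an arbitrary winner. A site passes when
coverage ≥ 10, edited reads ≥ 3 and edited fraction ≥ 10% — all three
inclusive (the 10% boundary is treated as ≥, consistent with the other two
thresholds) and all three configurable. Efficiency = edited reads / coverage
is reported for all candidates. Types are C-to-U (ref C, edit T) and U-to-C
(ref T, edit C); other mismatches are reported but excluded from summaries by
default. Effect annotation places the site in its codon
(position (offset−1) mod 3 + 1), applies the edit, and translates both codons
with the standard code; offsets inside the ±100 nt extracted flanks are
`noncoding`. Raising any threshold can only shrink the passed set
(monotonicity), which the tests assert.

Out of algorithmic scope: the manual inspection of low-coverage regions and
of cross-mapping artifacts from paralogous copies that a careful analyst
performs on real data — the caller sees only the pileup.

## Codon usage

RSCU_ij = x_ij /(X_i / n_i) for codon j in amino-acid family i with n_i
synonymous codons and family total X_i, so every observed family sums to its
size (mean 1). Methionine and tryptophan are excluded (single-codon families
carry no usage information) along with stops, leaving 18 families and 59
codons. Counting skips codons containing N or gaps and drops a terminal stop.
Genes must be **strictly longer than** 500 nt (a deliberate `>`; the ORF
scanner's floor is a separate `≥ 500` and the two are easy to conflate — a
flag relaxes the boundary). The PCA runs on the centered, unscaled gene × 59
matrix (RSCU is already dimensionless and family-normalized; unit-variance
scaling is available behind a flag), with unobserved families imputed at 1 —
the no-information expectation, which pulls genes nowhere — and a
deterministic sign convention (the largest-magnitude loading of each
component is made positive), so results are invariant to input order.

## The synthetic-data generator

The generator reproduces the statistical structure the analyses assume, with
defaults fixed to the package's reference conditions:

* **Trees** — a pure-birth (Yule) topology; because the simulator stops at
  the n-th speciation event, which would leave a zero-length terminal cherry,
  every tip branch is extended by one exponential holding time at rate n·λ
  (the process's own waiting time to the next event) before the tree is
  scaled to the crown age. Default 12 taxa and 136 Myr — a fern-family crown
  minimum, with 231.11 Myr kept as the maximum-calibration metadata. The
  phylogram multiplies each branch by the base rate (default 5 × 10⁻⁴
  substitutions/site/Myr, typical of plastid CDS) and, optionally, lognormal
  per-branch noise (σ = 0 by default: strict clock).
* **Codon alignments** — a Muse–Gaut-flavored model: instantaneous rate to a
  single-nucleotide-neighbor codon ∝ target-codon frequency × κ (transitions)
  × ω (nonsynonymous), zero to stops and multi-hit changes; the generator is
  normalized so a branch length t yields t expected substitutions per
  nucleotide site; transition matrices come from the matrix exponential and
  are cached per branch length. Defaults ω = 0.2, κ = 2. Frequency vectors
  with disconnected support are rejected. Gene panels plant a canonical class
  (rate ×1) against a mobile class (×12.5 — the middle of the elevation range
  the toolkit is designed to detect) of 20 and 5 genes × 300 codons, and emit
  branch-length-true gene trees so rate estimation can be scored independent
  of tree inference.
* **Pileups** — coverage ~ Poisson(mean 100) per site (so the coverage
  threshold is exercised stochastically), planted edits draw
  Binomial(coverage, efficiency) edited reads, and the remainder mismatch at
  a 10⁻³ error rate spread uniformly over the three non-reference bases.
* **Codon-usage classes** — genes as i.i.d. codon draws from class frequency
  vectors; the defaults tilt frequencies by exp(±0.8 × GC-count), giving an
  AT-rich organellar-like and a GC-rich nuclear-like profile with
  total-variation distance > 0.3, and lengths (300 codons) that pass the
  strict 500 nt filter.

Everything is deterministic under the seed (byte-identical Newick/FASTA/TSV),
and every dataset ships a truth object (class labels, multipliers, planted
edits, generating trees) sufficient to score recovery exactly.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: indels and alignment error (alignments are gap-free),
among-site rate heterogeneity, base-composition drift across lineages,
cross-mapping reads from paralogs, coverage autocorrelation along a
transcript, and tree-inference error in gene phylograms (the
branch-length-true trees isolate the rate estimator; an optional noise flag
exists for robustness checks but inference itself is out of scope).

## Problem sizes and tolerances

The default verification runs are desk-scale by design: 900-codon, 10-taxon
alignments for window scans; 25-gene panels on 12 taxa for rates; 40 planted
edits at coverage ~100 for editing recall; 15–25 genes per class for
RSCU/PCA. Identities (RSCU family sums, NG86 vs brute-force enumeration,
self-normalization of rates) are asserted at 10⁻⁹–10⁻¹²; stochastic
recoveries use fixed seeds with slack appropriate to their sampling noise
(ω within 0.15 at 1000 codons; rate-contrast ratio within 20%; editing
recall ≥ 98%; silhouette thresholds 0.3). Ultrametricity of chronograms is
enforced exactly at generation and checked at 10⁻⁶ relative tolerance on
read.

## Known limitations

* Pairwise NG86 ignores phylogeny; windowed dN/dS values are correlated
  across overlapping windows and between pairs sharing branches, so the
  bootstrap interval understates between-gene uncertainty.
* The JC correction saturates at p = 0.75; highly diverged windows surface
  flagged raw proportions instead of distances.
* Relative/absolute rates inherit whatever bias the input gene phylogram's
  branch lengths carry; the package never re-estimates branch lengths.
* The editing caller has no model of strand bias, mapping quality or paralog
  cross-mapping; its thresholds are the classical hard cutoffs.
* RSCU-based ordination reflects composition, not selection directly; short
  genes are excluded precisely because drift dominates their usage vectors.
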