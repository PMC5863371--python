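# Methods

`metatriage` implements the computational core of an "unconstrained"
root-metatranscriptome analysis: every assembled contig is annotated
without prior assumptions about its organism of origin, tested for
differential expression between two conditions, partitioned by taxonomy,
and — for polycistronic bacterial transcripts — decoded into ordered
operon chains. This note records the models, the parameters that matter,
and the design choices made where the procedure was genuinely open.

## Annotation triage by percent of maximum potential bitscore

A contig's candidate annotations come from tiered homology searches
(precomputed BLAST-tabular tables; running the searches is out of
scope). Hits are ranked by **PMPB**, the hit bitscore as a percentage of
the query's *maximum potential bitscore* — the bitscore the query would
achieve against itself. PMPB normalizes away query length, so hits to a
short contig and a long contig are comparable.

The self-score is taken from a provided table when available; otherwise
it is computed as the ungapped self-alignment score under a scoring
scheme, converted to bits with the Karlin–Altschul form

    bits = (λ · S_raw − ln K) / ln 2,

where `S_raw` is the sum of diagonal substitution scores over the
sequence. The bundled schemes are BLOSUM62 with the published ungapped
constants (λ = 0.3176, K = 0.134; diagonal restricted to the 20 standard
residues — ambiguity codes have non-positive self-scores and no defined
maximum potential) and a blastn-like nucleotide scheme (match +1,
λ = 1.28, K = 0.46). Hits whose reported bitscore marginally exceeds the
self-score (third-party rounding) are capped at PMPB 100 with a warning.

Selection rules, per contig and tier:

* hits at or above the tier's e-value cutoff are discarded
  (defaults: protein tiers 1e-4, nucleotide tier 1e-6);
* the **primary** annotation is the maximum-PMPB hit; ties break by
  lower e-value, then lower tier, then lexicographic subject id (the
  chain is a deterministic stand-in — the original method does not
  specify one);
* all other hits within the **secondary window** (default 10 PMPB
  *percentage points*, the literal reading of "within 10%";
  configurable) are retained as secondary annotations, one best hit per
  subject.

The cascade runs tiers in order; a contig resolves at the first
applicable tier that yields a hit, even if a later tier would score
higher — fallback tiers exist for contigs the earlier databases missed,
not to outvote them. Tiers can be scoped to all contigs or to
differentially expressed ones only (the canonical cascade uses a
DE-only protein fallback and a DE-only nucleotide tier).

Primaries whose description contains a stoplist term (`hypothetical`,
`predicted`, `putative`, `uncharacterized/-ised`, `unknown`;
case-insensitive substring match) are demoted when an in-window
secondary carries an informative description: the best such secondary
becomes primary and the swap is flagged. The taxon of record follows the
swap — the two hits were statistically equivalent, and the informative
one is the better witness. Resolved taxa roll up into a Krona-style tree
whose nodes carry distinct-contig counts and summed mean TPM; contigs
with no hit anywhere sit under a reserved top-level `Unknown` node, and
unresolvable taxon keys under `unclassified`.

## Counts, filtering and normalization

* **Low-count filter**: per-contig totals across all samples; threshold
  either absolute (default 29) or the
  nearest-rank percentile of the total distribution (sorted totals,
  index ⌈p/100·n⌉); rows with total ≥ threshold are kept, so ties
  survive. The filter is order-agnostic with respect to any prior
  length filtering.
* **TPM**: `tpm_i = (c_i/ℓ_i) / Σ_j (c_j/ℓ_j) × 1e6` from provided
  effective lengths; each non-zero sample column sums to 1e6 exactly,
  all-zero columns stay zero.
* **Median-of-ratios size factors** (used by the DE model):
  `s_j = median_i c_ij / geomean(c_i·)` over contigs positive in every
  sample. The median is taken over the ratios directly; the reference R
  implementation medians the logs, which differs only in the even-count
  tie average (cross-checked in the test suite).
* **TMM factors** (for MA-plot CPM): weighted trimmed mean of M-values
  against a reference sample (closest upper quartile to the mean by
  default), trimming 30% from each tail of M and 5% from each tail of
  A, inverse asymptotic variance weights, factors rescaled to product 1.
  Checked against both a literal sort-trim-average oracle and edgeR.
* **log2 CPM**: `log2((c + p)/(N·s + 2p) × 1e6)` with prior count
  p = 0.5 by default (finite at zero counts, scale-invariant as p → 0).

## Empirical-Bayes differential expression

Counts follow a negative binomial: `X_gj ~ NB(r_g·s_j, q_g)` with a
conjugate `Beta(α, β)` prior on `q_g` shared across contigs. Integrating
`q` out gives, for a sample set `S`,

    f(x_S) = [Π_{j∈S} C(x_gj + r_gj − 1, x_gj)]
             · B(α + Σ_S r_gj, β + Σ_S x_gj) / B(α, β),

computed entirely in log space. Equivalent expression (EE) treats all
samples as one set; differential expression (DE) multiplies the two
per-condition marginals. The posterior probability of differential
expression is

    PPDE_g = π f_DE,g / ((1−π) f_EE,g + π f_DE,g),

and contigs with PPDE ≥ 0.95 (default) are called DE. The reported
"soft FDR" is the posterior estimate mean(1 − PPDE) over called contigs;
no additional multiple-testing correction is applied, matching the
empirical-Bayes paradigm of a target FDR controlled through the
posterior. Isoform-group stratification of the original framework is
omitted — one hyperparameter set serves all contigs, which keeps the
model fully testable without isoform annotations.

`r_g` comes from method of moments on size-factor-scaled counts,
`r = m̂²/(v̂ − m̂)`, with the **variance pooled within conditions**
(overall mean, within-group variance). Pooling across all samples would
fold a real group difference into the dispersion and let the EE model
absorb it; the within-condition estimate keeps the null calibrated
(≈0.1% of truly-EE contigs called at 0.95 in simulation) while reaching
≈98% recall at a 4-fold change with dispersion 0.1 and 6+6 replicates.
Poisson-like contigs (v̂ ≤ m̂) are clamped to r = 1e8 to keep the
marginals finite. EM alternates the PPDE E-step with π ← mean(PPDE) and
a Nelder-Mead maximization of the PPDE-weighted log marginal over
(log α, log β); defaults are 5 rounds with tolerance 1e-3 on π, and a
non-converged fit is returned with a warning rather than an error. The
fit is deterministic given its inputs.

**Infinity genes.** A contig with nonzero counts in only one condition
has an infinite raw fold change; an epsilon is substituted for the zero
condition mean so the value stays finite and plottable. The default
epsilon is half the smallest nonzero condition-mean in the dataset,
which keeps every exclusive contig's |log2 FC| above any finite one at
comparable abundance; a constant override is accepted. Presence classes
(`both`, `treatment_only`, `control_only`) use the sum > 0 rule, which
is deliberately permissive — a single read in one replicate counts as
present; the rule is configurable at the reporting layer. Both the raw
TPM-ratio fold change and the posterior (shrunken) fold change are
emitted because they answer different questions and can disagree at low
counts. Swapping condition labels negates every log2 FC exactly and
leaves PPDE unchanged (tested).

## Polycistron decoding

Six-frame ORF extraction: within each frame the codon string is
segmented at stop codons; each segment yields at most one ORF, from its
first ATG (or from the contig edge for the frame's first segment,
flagged 5'-partial) to the closing stop (included in the span) or the
contig edge (3'-partial). Codons containing N never match start or stop.
Minimum length 100 aa by default (the conventional coding-region
threshold for this kind of decoding), all rules configurable. Coordinates are 0-based half-open on the forward
axis everywhere in memory; GFF3 output converts to 1-based inclusive.
The implementation is equivalence-tested against an independent
brute-force enumerator on random sequences.

Labeled ORFs (gene symbols from per-ORF annotation through the same
triage selector) are ordered along the direction of transcription
(ascending start on +, descending on −) and joined into a chain that is
matched against the reference operon table: `exact`, a
`contiguous_subset` of a reference row, or `novel`. Contigs with
comparable labeled ORF counts on both strands produce one chain per
strand flagged mixed-strand rather than a merged chain — operons are
single-strand transcriptional units. Near-duplicate variants (identical
chain, concatenated amino-acid identity ≥ 0.98 by global edit distance)
are grouped transitively with the longest member as representative.
Overlapping unannotated ORFs are never silently dropped; they are
counted per chain so a curator can inspect them.

The optional hexamer Markov coding score is
`Σ log(P_coding(h)/P_background(h))` over sliding hexamers, trained on
≥ 10 kb of coding sequence with the background from a seeded nucleotide
shuffle of the same set. Draws from the coding model score clearly
positive; uniform-random sequences score near zero with a small
*negative* bias, because the structured coding distribution is the more
concentrated of the two — the score separates, it does not center
exactly. It is off by default: the default filtering path is minimum
length plus annotation, because a confident homology hit is stronger
evidence of coding potential than any composition score.

## The synthetic scenario

The generator emulates the study's community structure so every stage is
testable against ground truth: a stable plant clade (800 contigs), a
fungal clade uniformly down 4-fold in treatment (500), a small
control-exclusive fungal clade (15), a second fungal lineage that is
mostly treatment-exclusive (300 exclusive + 150 up), and a bacterial
family uniformly up in treatment (250 + 8 polycistronic contigs with
planted, reference-ordered gene cassettes) — 2023 contigs over 6+6
replicates. 34% of contigs receive no homology hit. Counts are negative
binomial (dispersion 0.1 by default) around lognormal per-contig means
(σ = 0.5) scaled by lognormal per-sample depth factors (σ = 0.1);
condition-exclusive contigs are hard zeros in the excluded condition,
exercising the epsilon path. Annotated contigs get a primary hit at PMPB
uniform on 60–100 plus, for half of them, two decoys inside the
10-point window (gap U(0.5, 9.5)) and two outside (gap U(11, 30)); 5% of
DE contigs resolve only at the fallback tier. Polycistronic cassettes
are ATG + non-stop codons + TAA blocks separated by short spacers that
end in an in-frame stop, so recovered coordinates are exact by
construction; some contigs are reverse-complemented to exercise the
minus strand and one chain per reference row wraps into a truncated
(contiguous-subset) variant.

What the generator does **not** emulate: sequence-level homology (hits
and self-scores are planted directly, so PMPB structure is exact and
controllable), read-level noise and mapping, assembly artifacts
(chimeras, fragmentation), isoform structure, GC/length biases, and
between-replicate batch effects. Passing tests therefore demonstrate
correctness of the selection, inference and decoding rules under the
declared noise model — not robustness to upstream artifacts of real
assemblies.

Everything is a deterministic function of the seed: two runs with the
same configuration are byte-identical on disk, and the full pipeline
rerun on the same inputs reproduces every artifact byte for byte.

## Numerical and degenerate-input choices

* Marginal likelihoods, betaln/gammaln in log space; finite for counts
  up to 1e6 (tested).
* PPDE odds are clamped at exp(±700) before exponentiation; π is kept
  in [1e-6, 1−1e-6].
* All-zero count rows are rejected by the DE fit (the filter removes
  them); an all-zero sample column is rejected by normalization.
* A filter that removes every contig warns and returns an empty matrix
  rather than raising.
* Nearest-rank percentile with keep-if-≥ makes the filter deterministic
  under ties.
* Report fractions with empty denominators are NaN, never fabricated
  zeros.

## Problem sizes used by the test suite and acceptance script

The default scenario (2023 contigs, 12 samples) drives annotation
recovery, infinity-gene, operon and end-to-end checks; DE calibration
uses 2000-contig single-clade scenarios, 10 seeds for the null and 10
for the power study. Selector and ORF-finder oracle equivalence run on
500 random hit tables and 100 random sequences respectively. The whole
suite completes in well under a minute on one CPU; the acceptance script
in about 15 seconds.

## Known limitations

* The secondary window is interpreted in percentage points; a relative
  (10% of primary) reading would retain slightly different sets — the
  window is configurable precisely because the convention is a choice.
* Single-stratum hyperparameters can under-shrink heterogeneous data
  (e.g. mixed isoform classes).
* The presence rule (sum > 0) does not model sampling depth; at very low
  depth an "exclusive" label can be a sampling artifact. The epsilon
  substitution makes exclusive fold changes finite but their magnitude
  is a reporting convention, not an estimate.
* Operon matching is symbol-exact: paralog renaming or annotation
  synonyms break an `exact` match to `novel`.
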