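# Methods

## Scope and coordinate conventions

The package analyzes adapter-trimmed small-RNA inserts (15–50 nt) against a
small reference space: mature tRNAs (with the 3′ CCA), precursor-tRNA 3′
trailers, mature miRNAs, and spike-in controls. All coordinates are 1-based
and inclusive on the mature tRNA *including* CCA; sequences are stored in
the DNA alphabet (U→T), matching sequencing output. "Position 58" is a
property of specific annotated tRNAs — tRNAs of non-canonical length keep
their own length L, and the T-loop m¹A site of a generated tRNA is placed
at L−18, which is fragment position 4 of its 22-nt 3′ fragment for every L.

## The RT misincorporation model

A reverse transcriptase encountering m¹A on a molecule either stalls
(probability `p_stall`) or reads through and misincorporates (probability
`p_mis`, substituted base drawn from a spectrum over C/G/T, uniform by
default since only the aggregate A→C/G/T rate is constrained by data).
Stalling removes the molecule entirely — no truncated reads — modeling a
ligation-first protocol in which a truncated cDNA lacks the 5′ adaptor
complement and is never amplified. This single choice reproduces the
under-representation of modified molecules by high-stall enzymes without
modeling truncation products. Background error is an independent per-base
substitution `eps_bg` (uniform over the three non-reference bases), applied
to every position that did not already receive the m¹A misincorporation.

Expected mismatch fraction at a site of stoichiometry p, among emitted
reads:

    f(p) = φ(m + (1−m)ε) + (1−φ)ε,  φ = p(1−s)/(1−ps)

(`expected_site_mismatch_rate`). The RT presets — TGIRT (m=0.85, s=0.05,
ε=0.002), ProtoScriptII (m=0.05, s=0.90, ε=0.005), RT-1306 (m=0.70, s=0.10,
ε=0.005) — are qualitative configuration defaults: a read-through enzyme
with ~0.2% background, a stalling enzyme, and an intermediate. They shape
simulated behavior (dynamic range of the mismatch index, relative cloning
frequency) but no quantitative conclusion depends on their exact values,
and all are overridable.

## Synthetic data: what it emulates and what it does not

`simulate.build_reference` generates random tRNAs (72–90 nt, CCA-terminal,
m¹A annotated at L−18; mitochondrial tRNAs additionally at position 9),
per-tRNA trailers (poly-U-ending), miRNAs (21–23 nt), QC spike-ins and m¹A
control oligos. Spike-ins are regenerated until no 15-nt window matches any
tRNA/miRNA reference within 1 mismatch, so spike-in reads can never be
absorbed by the biological reference space. `simulate_fragment_pool` draws
molecule counts multinomially over a class profile (tRF-3b/-3a exact 22/18
suffixes, tRF-5 prefixes, tRF-1 trailer prefixes, halves, miRNAs,
spike-ins) and assigns per-molecule modification status Bernoulli(p) at
each annotated site. `simulate_rip` multiplies a molecule's sampling weight
by the antibody enrichment factor iff it carries ≥1 modified site; the IgG
arm captures nonspecifically. Expression tables plant per-site-type log2FC
shifts (targets ~ Normal(δ_t, σ), non-targets ~ Normal(0, σ)); 3′ UTRs are
uniform random sequence with site motifs written at known offsets.

Deliberately not modeled: adapters and UMIs, PCR duplication, quality-score
profiles, biological overdispersion between replicates, antibody
cross-reactivity (e.g. with m⁷G caps), sequence-context-dependent RT error,
and real tRNA secondary structure or isodecoder families beyond what random
sequence produces. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted effects under
Poisson-like sampling — not robustness to the full noise structure of real
libraries (in particular, the binomial enrichment test would be
anti-conservative on overdispersed biological replicates; see below).

Default study conditions: pools of 40k molecules at stoichiometry 0.8
(high-stoichiometry T-loop m¹A), RIP enrichment factor 8 at 40k reads per
arm, calibration gradients at 0/20/40/60/80/100% with 10⁴ reads per level,
expression tables of ~1000 genes with shifts −0.5/−0.3/−0.3/−0.1 at
σ = 0.4. These sizes resolve every planted effect with wide margins while
keeping a full end-to-end run in seconds.

## Mapping policy and tRF taxonomy

Reads are collapsed to unique sequences and searched against categories in
priority order — miRNA, then tRNA space (mature + trailers), then
spike-ins; a read with any hit in an earlier category is never searched in
later ones. miRNA mapping allows ≤2 non-templated 3′ bases (soft-clipped,
minimal sufficient clip, excluded from mismatch counting) plus 1 internal
mismatch; tRNA-space and spike-in mapping allow 1 mismatch, no indels, no
free terminal mismatches. Hits are *all* placements within budget
(pigeonhole candidate generation over an exact k-mer index, verified by
Hamming distance; an exhaustive-scan oracle checks equivalence in tests),
and a multi-mapping read contributes equal fractional weight to each hit,
so fractional counts sum exactly to mapped reads.

Taxonomy from placement alone: alignment ending at the mature 3′ terminus →
tRF-3 (22 nt → isoform 3b, 18 nt → 3a); starting at position 1 → tRF-5;
trailer prefix → tRF-1; fragments ≥30 nt anchored at either terminus are
halves (the boundary is placed so that "30-nucleotide" names the first half
length). tRF-3 status requires the full CCA: CC-ended reads classify as
`other`, keeping the A₄ coordinate frame unambiguous. Internal fragments
are `other`.

## Mismatch statistics

Pileups carry fractional weights and exclude clipped tail bases. The
mismatch index is 100 × substitutions/coverage at a position, **undefined**
(never zero) at coverage ≤ 50 reads, and undefinedness propagates through
every downstream comparison. Cross-condition comparison reports the
percentage-point difference and log2((m_A+ψ)/(m_B+ψ)) with ψ = 0.1
percentage points (a pseudocount of our choosing; no published convention
exists). The normalized mismatch index is mismatch%/(100−mismatch%),
infinite at 100%. The A-share statistic (fraction of all mismatches at
reference-A positions) is accumulated per mismatch event, so pooled
profiles across parents remain correct.

## Calibration

Zero-intercept least squares: slope = Σxy/Σx², R² = 1 − SS_res/Σy² on the
*uncentered* total sum of squares — stated explicitly because centered R²
is misleading when the intercept is suppressed. Background (observed
mismatch at 0% stoichiometry) is not subtracted inside the fit; it enters
only the inversion p̂ = clamp((observed − background)/slope, 0, 1). The
inversion is semi-quantitative: stalling makes f(p) slightly convex, so the
linear estimand deviates from the planted p by up to ~0.01 under TGIRT
defaults (bounded by 0.05 across the 0.2–1.0 grid in tests). The percentile
bootstrap CI resamples the observed mismatch count binomially and — when
the calibration depth is supplied — refits the curve on resampled
calibration points per replicate, so the interval reflects both counting
noise and calibration uncertainty; its coverage target is the linear
estimand, which is what the procedure estimates.

## Enrichment and the m¹A candidate call

Enrichment is tested at the (parent, class) group level ("clustered on
parental gene level"), not per unique read. The test is a two-sided
binomial test of the RIP count against the combined RIP+input count with
null proportion set by library sizes, BH-adjusted; groups under 10 combined
reads are excluded. This deliberately replaces a negative-binomial GLM
(DESeq2): the simulator's counts are Poisson-like with no biological
dispersion, where the binomial test is near-nominal (verified in tests).
Its p-values are not comparable to published DESeq2 values on real data.
Thresholds: padj < 0.1 for candidate calls, padj < 10⁻⁵ for strict
volcano-style coloring, both configurable. log2 fold enrichment uses RPM
(or spike-in-normalized frequency when QC spike-ins are present) with a
0.5-RPM pseudocount. Class-level comparisons against the miRNA class use
the two-sided Mann-Whitney U (exact for small untied samples, tie-corrected
normal approximation otherwise).

A group is an **m¹A candidate** only if enriched (padj < cut, log2FE > 0)
in *every* antibody arm, not enriched in the IgG arm, and supported by a
defined mismatch index > 10% at ≥1 annotated site. The 10% evidence
threshold is this package's operationalization of qualitative judgment;
groups failing individual prongs are reported as antibody-only /
mismatch-only / negative rather than silently dropped.

## Seed targets and repression

The seed is guide positions 2–8 (7 nt). Seed families cluster
alignment-corrected guide sequences — the reference sequence under each
hit, not the raw read — because the m¹A misincorporation falls at guide
position 4, inside the seed, and clustering raw reads would fragment
families by RT error. (Clustering by positions 1–8 instead of 2–8 is a
defensible alternative; position 1 is buried in Argonaute and does not
pair, so the 2–8 convention is used and families are keyed accordingly.)
The coverage report returns the minimal number of seeds whose cumulative
Ago-bound share *meets* the threshold (default 0.90, inclusive).

Site taxonomy on the mRNA (5′→3′), with core7 = revcomp(guide 2–8) and
core6 = revcomp(guide 2–7): 8mer-A1 = core7 + A; 7mer-m8 = core7 not
followed by A; 7mer-A1 = core6 + A not part of a core7 match; 6mer = core6
alone. The A is the adenosine opposite guide position 1; N never matches.
Each occurrence resolves to its single highest type, and a gene is labeled
by the highest-rank type over occurrences. Genes without a UTR or with
baseMean ≤ 100 (strictly greater required) are excluded entirely — neither
target nor non-target.

Repression: all log2FC values are centered by the non-target median; each
class with ≥10 genes is compared to non-targets by a one-sided two-sample
K-S test with the alternative direction (repressed/de-repressed) given
explicitly by the caller, never inferred. No multiple-testing correction is
applied across the ≤4 class tests (per-class p-values are reported as
such, noted in output metadata).

## Numerical and engineering choices

Every stochastic operation takes an explicit integer seed or numpy
Generator; fixed seeds give byte-identical FASTQ/FASTA/TSV outputs. The
alignment index is an exact k-mer table (k=6) with pigeonhole candidate
generation — appropriate for a reference space of a few kb, where a genome
aligner would add opacity without speed. Output tables carry the
configuration hash in a leading comment line. Ties in the mismatch-peak
report resolve to the smallest position. Degenerate inputs (empty pools,
zero spike-in counts, all-zero calibration x, coverage below threshold)
raise named errors or propagate explicit undefined values rather than
silent zeros.

## Known limitations

- The binomial enrichment test cannot reproduce DESeq2 adjusted p-values
  from real replicated data; it is calibrated only for the simulator's
  sampling model.
- Stoichiometry inversion is semi-quantitative (linear inversion of a
  mildly nonlinear response); per-sequence-context calibration curves are
  out of scope.
- The scanner ignores conservation and context scores (no TargetScan
  context++), and UTRs are treated as plain sequence.
- Non-templated miRNA tails are assumed pure non-templated; possible
  overlap with genomic continuation is not modeled.
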