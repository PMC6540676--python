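# Methods

This note documents the models, conventions and numerical choices behind
`aflpcap`, in the order the workflow runs.

## In-silico digestion and selective amplification

**Cut model.** A restriction enzyme is an exact recognition site plus a
0-based cut offset on the top strand (MluI = `A^CGCGT`, offset 1; SbfI =
`CCTGCA^GG`, offset 6). A cut is the single coordinate site start + offset;
sticky-end overhangs are not modeled, because only fragment identity — not
end chemistry — matters for bait capture. Both default sites are
palindromic, so one top-strand scan finds every site; a non-palindromic
enzyme is additionally scanned as its reverse complement with the mirrored
offset. Overlapping occurrences are resolved left to right, two enzymes
cutting the same coordinate collapse to one cut, and a site window
containing N never matches (matching is exact).

A consequence of the single-strand cut model worth knowing: digesting the
reverse complement reproduces the same recognition sites, but each cut
coordinate reflects with a shift of len(site) − 2·offset (±4 bp for both
defaults — the overhang width). Fragment boundaries therefore differ by up
to 8 bp between orientations while cut sites, fragment counts and end-label
multisets are exactly orientation-invariant; the tests assert the latter.

**Amplifiability.** Y-adapters suppress exponential amplification of
fragments with two same-enzyme ends, so `adapter_compatible` keeps exactly
the fragments with one MluI and one SbfI end; terminal (chromosome-end)
fragments never amplify.

**Size selection** is inclusive on both edges (500 and 2,000 bp pass at the
defaults); the protocol states the window without edge handling, and
inclusivity is the least surprising reading.

**Selective bases.** Fragments are normalised so the MluI end is leftmost
(reverse-complementing as needed). The forward selective base is compared to
the sense-strand base immediately 3′ of the 5-bp MluI remnant (`CGCGT`); the
reverse base to the antisense-strand base immediately 3′ of the 6-bp SbfI
remnant (`TGCAGG`) — the primer-extension direction on each strand. This
convention reproduces the expected retention under uniform composition:
1/16 for one combination, 1/4 for the four pooled combinations {A,T}×{C,G},
and the sixteen single-base combinations partition the N-free compatible
fragments. A fragment shorter than both remnants plus two bases (13 bp at
the defaults) cannot be tested and is tallied separately. N at a tested
position never matches. The fraction is computed over adapter-compatible
fragments (the denominator the amplification chemistry acts on); the run
report also carries the total-fragment denominator.

## Local similarity and e-values

The built-in aligner seeds on shared 11-mers and then computes the exact
affine-gap Smith–Waterman optimum (match +2, mismatch −3, gap of length k
costs 5 + 2k — megablast-like) via `Bio.Align.PairwiseAligner`. One shared
11-mer is required at oracle scale (≤ 500 bp); kilobase-scale pairs must
share two distinct 11-mers, since one chance 11-mer between unrelated
kilobase sequences is common (expected count ≈ mn/4^11) while genuine
homologs share many. Both subject strands are searched; a minus-strand hit
is encoded `send < sstart` exactly as in the 12-column tabular dialect, so
imported and built-in tables are interchangeable.

E-values follow the Karlin–Altschul form E = mn·2^(−S′) with bitscore
S′ = (λS − ln K)/ln 2. λ solves Σ pᵢpⱼe^(λsᵢⱼ) = 1 for uniform base
frequencies (λ ≈ 0.624 for +2/−3); K is fixed at 0.28, a typical nucleotide
value. Absolute e-values are therefore approximate, but the pipeline only
uses them relative to the 1e−10 ceiling, which planted homologs pass by
dozens of orders of magnitude and chance alignments fail.

`best_hit` ranks by bitscore, then lower e-value, longer alignment, and
lexicographically smallest subject id — a pure function of table contents,
invariant to row order.

## Contig QC, redundancy, orthology

Both QC thresholds are inclusive (length ≥ 200 bp AND mean depth ≥ 5×);
a contig lacking depth information is an error whenever a positive depth
threshold is in force. Depths come from a two-column TSV or from
assembler-style `cov_<float>` tokens in FASTA ids. QC runs before redundancy
reduction (the source protocol does not fix the order; a flag reverses it in
the pipeline by skipping either step).

Redundancy reduction is greedy and longest-first: a contig joins an existing
representative when best-local-hit identities divided by the shorter
sequence's length reach the cutoff (default 0.95), else it founds a new
cluster. The identity denominator follows the short-sequence convention so a
contained duplicate of a long representative is recognised as redundant.

Orthology is mutual best hit: member c of sample s joins the group of
reference r iff c's best hit among reference contigs is r and r's best hit
among s's contigs is c, both directions searched at the e-value ceiling.
Every reference contig anchors at most one group and contributes itself as
the trivial reference member; a member belongs to at most one group by
construction (it has one best hit). Samples with no mutual pair for a
reference are simply absent from that group.

## Projection, trimming, alignment, supermatrix

**Projection** treats the linking hit as ungapped: a single offset
(sstart − 1) − (qstart − 1) places the whole member on the reference, so a
member's span is [offset, offset + member length). Minus-strand members are
reverse-complemented first (flipping their query coordinates), then
projected as plus strand. This mirrors a position-only use of the search
results; small indels inside the hit shift the span by at most the net
indel length, which the subsequent multiple alignment absorbs.

**Optimal aligning region.** With cov(p) the number of spans containing
reference column p and k = ⌈threshold·n⌉, the window is
[min F, max F + 1) for F = {p : cov(p) ≥ k}. Both boundary columns meet the
coverage demand by construction, and no strictly wider window can (window
maximality is property-tested against a brute-force column scan). Interior
dips below k are allowed — only the boundaries are constrained. An empty F
rejects the group with a distinct status. Members are cropped to
span ∩ window in their own coordinates; members missing the window entirely
are dropped, and a group needs ≥ 2 survivors to proceed.

**Multiple alignment.** The built-in backend is center-star: the row with
the highest mean k-mer similarity to the rest is the center, every other row
is globally aligned to it (same scoring as the local aligner; end gaps
charged), and pairwise gaps merge under once-a-gap-always-a-gap. End gaps
are deliberately penalised: with free ends, an unrelated row can slide into
near-disjoint placement and evade the shared-column similarity measure.
Center-star is a deliberately simple stand-in for a progressive aligner and
is exact for the no-indel sequences the default generator produces; any
external aligner can be substituted via a command template
(`"mafft --quiet {in}"`).

**Row filter.** Pairwise similarity is identical columns over columns where
both rows are non-gap (0 if none). Rows whose mean similarity to all others
is strictly below 0.30 are removed in one pass against the full alignment,
and survivors are realigned exactly once — no iteration. A row at exactly
the cutoff stays. Note that a gapped aligner places even random DNA rows at
~30–60% identity over shared columns (match-seeking DP inflates identity),
so the 30% rule is a backstop against egregious misassignments rather than
a contamination filter; contamination control comes from the MBH e-value
ceiling upstream.

**Supermatrix.** Loci with fewer than `min_taxa` rows are dropped; the
threshold is inclusive ("at least", default 6) with the strict reading
available by passing `min_taxa + 1`, since the source protocol uses both
phrasings. Surviving alignments concatenate in sorted locus-id order,
absent species are gap-filled with `-`, partitions are 1-based inclusive
and tile the matrix exactly. Completeness by locus and species is filled
cells over n_species × n_loci; completeness by characters is non-gap
characters over total matrix characters.

## SNP matrix

The quality rule is strict QUAL > threshold (default 30), matching the
protocol's "higher than" wording; per-sample GQ can be selected instead
(`quality_field="GQ"`, every called sample strictly above). Filters apply
in order quality → biallelic → missing, with a removal tally per criterion
that sums to input − output. Multi-allelic sites and indels are dropped, not
split — the matrix needs one column per site and dropping is conservative.
Heterozygotes collapse to IUPAC two-base codes (A/G→R, C/T→Y, G/C→S, A/T→W,
G/T→K, A/C→M); phased and unphased separators are treated identically;
missing calls become `?` by default. Writers (NEXUS, relaxed PHYLIP, FASTA)
are byte-stable for fixed input.

## Synthetic data: what it does and does not emulate

The generator draws i.i.d. genomes at a configurable GC fraction, evolves
each locus ancestor to n species along a star tree under Jukes–Cantor at
branch length d (a site differs from the ancestor with probability
(3/4)(1 − e^(−4d/3)); p-distances are tested against this closed form),
wraps loci into contigs with independent uniform flanks up to a maximum (the
staggered extents the boundary search exists to handle), draws log-normal
per-contig depths, applies independent per-species locus dropout, and emits
toy VCFs with exact per-class site counts (QUAL straddling 30,
multi-allelics, planted missing calls).

Defaults model a small capture panel: 8 species, 30 loci of 400–1,200 bp,
divergence 0.05 substitutions/site per species, flanks ≤ 300 bp, 10%
dropout, depths centred near 30× (log-mean 3.4, log-sd 0.5). All randomness
flows from integer seeds through per-stage `numpy` generator streams, so
outputs are bit-reproducible.

Not emulated: indels (a JC-only model; alignment-level gaps are still
exercised through trimming offsets and the aligner), sequencing error,
read-level artefacts, assembly chimeras, paralogy, PCR bias, base-composition
heterogeneity along the genome. Passing tests on this generator demonstrate
the pipeline's bookkeeping and decision rules under known truth; they do not
certify recovery rates on real capture data, where orthology confusion comes
mostly from paralogy and assembly error rather than substitution distance.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problems chosen to exercise every
rule: 100,000 fragments for the amplification fractions (3 binomial-SE
tolerance), 100 span groups for the boundary guarantee, 50 alignment
fixtures for the row filter, 8–12 locus panels with 4–6 species for
orthology recovery and the divergence sweep {0.05, 0.10, 0.20, 0.30}
(recovery non-increasing by majority vote over 5 seeds). Fixed seeds make
every reported number reproducible; thresholds and tolerances are stated
where each quantity is computed.
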