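# aflpcap

In-silico AFLP bait design and an AFLP sequence-capture data pipeline for
phylogenomics.

AFLP Capture is a reduced-representation strategy for non-model organisms:
genomic DNA is double-digested with a rare cutter (SbfI, `CCTGCA^GG`) and a
frequent cutter (MluI, `A^CGCGT`), Y-shaped adapters are ligated so that only
fragments carrying one adapter of each kind amplify exponentially, fragments
are size-selected (500–2,000 bp) and selectively amplified with primers
bearing one extra 3′ selective nucleotide, and the pooled products become
hybridization baits. Captured libraries from many species are sequenced,
assembled, and turned into phylogenomic matrices. `aflpcap` models every
computational step of that workflow:

- **`insilico_aflp`** — predict the bait set a wet-lab run would produce from
  any genome: exact-site digestion, adapter-compatibility (one MluI end + one
  SbfI end), inclusive size selection, selective amplification, pooling. A
  single selective-base pair retains ~1/16 of the compatible fragments; the
  four pooled combinations {A,T}×{C,G} retain ~1/4.
- **`similarity`** — built-in local aligner (k-mer seeding + affine-gap
  Smith–Waterman, Karlin–Altschul e-values) plus reader/writer for 12-column
  tabular (outfmt-6) hit files, so external search results can be dropped in.
- **`orthology`** — contig QC (length ≥ 200 bp, mean depth ≥ 5×), greedy
  redundancy reduction (95% identity, longest-first), and 1:1 orthology
  groups by the mutual best-hit (MBH) criterion at e-value ≤ 1e−10 against a
  reference contig set.
- **`trim_align`** — projection of each member onto reference coordinates
  via its linking hit, the optimal aligning-region search (the widest window
  whose two boundary columns are each covered by ≥ 50% of members),
  multiple alignment (built-in center-star or any external command, e.g.
  MAFFT), removal of rows with mean pairwise similarity < 30%, and
  supermatrix assembly with partition map and completeness statistics.
- **`snp_matrix`** — VCF → shared SNP matrix: strict QUAL > 30, biallelic
  SNPs only, zero missing data, IUPAC coding of heterozygotes, NEXUS /
  relaxed PHYLIP / FASTA output.
- **`synthdata`** — seeded generators (random genomes, Jukes–Cantor ortholog
  families, flanked contigs with depths and dropout, toy VCFs) with known
  truth, so every stage is testable at desk scale.

The package emits matrices and partition files for downstream tree inference
(RAxML, SNAPP, …); it does not infer trees, and it does not model wet-lab
chemistry, read processing, assembly, mapping or variant calling.

## Model summary

Let cut positions be the union over enzymes of (site start + cut offset) for
every exact top-strand site occurrence; fragments are the intervals between
consecutive cuts. A fragment amplifies iff its end labels are {MluI, SbfI}.
With the fragment oriented MluI-end left, the forward selective base is
compared to the first insert base 3′ of the MluI remnant on the sense strand
and the reverse base to the first insert base 3′ of the SbfI remnant on the
antisense strand; under uniform base composition each test passes with
probability 1/4, giving the 1/16 and (for four pooled disjoint combinations)
1/4 expectations.

For a group of members projected to reference spans, with cov(p) the number
of spans containing column p and k = ⌈t·n⌉ at threshold t (default 0.5), the
optimal aligning region is [min F, max F + 1) where F = {p : cov(p) ≥ k} —
the widest window whose two boundary columns both meet the coverage demand.
Supermatrix completeness is reported two ways: by locus and species
(filled cells / (n_species × n_loci)) and by characters (non-gap characters
/ matrix size).

## Worked example

Design baits for a simulated 50 Mb genome (45% GC):

```bash
aflpcap digest --fasta genome.fa --enzymes MluI,SbfI \
    --size 500:2000 --combos A:C,A:G,T:C,T:G -o baits
```

```
10225 fragments -> 938 adapter-compatible -> 250 size-selected -> 61 pooled baits
```

10,225 restriction fragments arise from the double digest; 938 carry one
MluI and one SbfI end and can amplify; 250 fall in the 500–2,000 bp window;
the four pooled selective products keep 61 of them (61/250 ≈ 1/4, as
expected). A warning notes when the bait count falls outside the 500–5,000
window recommended for efficient capture. `baits.fa` headers carry 0-based
half-open source coordinates (`>chr1:737461-739224|left=MluI|right=SbfI`);
`baits.json` records summary statistics (here length range 532–1,996 bp,
mean 1,120 bp, GC 0.452).

Process synthetic capture data end to end (first species as reference):

```bash
aflpcap simulate --preset family --seed 7 -o synth
aflpcap matrix --reference synth/sp01.fa \
    --samples synth/sp02.fa ... --samples synth/sp08.fa \
    --min-taxa 6 -o sm
```

```
supermatrix: 8 species x 46747 bp, 28 loci, 92.0% complete by locus, 58.1% by characters
```

which writes `sm.fa`, `sm.phy`, a RAxML-style `sm.partitions`
(`DNA, og0001 = 1-1886` …) and a completeness report `sm.json`.

Convert a VCF to a shared SNP matrix (QUAL > 30, biallelic, zero missing):

```bash
aflpcap snps --vcf vcfdemo/sim.vcf -o matrix.nex
```

```
{"input": 20, "removed_low_qual": 5, "removed_not_biallelic_snp": 3, "removed_missing": 2, "retained": 10}
```

The library API mirrors the CLI one-to-one (`aflpcap.digest_sequence`,
`aflpcap.mutual_best_hit_groups`, `aflpcap.run_capture_pipeline`, …); see the
module docstrings.

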