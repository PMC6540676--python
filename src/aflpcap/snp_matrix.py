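"""VCF → shared SNP matrix conversion.

Variant sites from an external caller are filtered (strict QUAL threshold,
biallelic-SNP-only, zero-missing-data), diploid genotypes are collapsed to
single IUPAC characters (heterozygote → two-base ambiguity code), and the
resulting samples × sites matrix is written as NEXUS, relaxed PHYLIP or
FASTA for downstream phylogenetic/coalescent tools.

The quality filter reads the site-level VCF QUAL column by default
("quality score" in the source protocol); per-sample GQ can be selected
instead where callers emit it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "VariantSite",
    "SNPMatrix",
    "read_vcf",
    "filter_sites",
    "encode_genotype",
    "build_snp_matrix",
    "write_matrix",
    "read_matrix",
    "IUPAC_HET",
]

MISSING_ALLELE = None

# unordered base pair -> IUPAC ambiguity character
IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


@dataclass
class VariantSite:
    """One VCF record: position, alleles, QUAL, per-sample diploid calls.

    ``genotypes`` maps sample -> (allele, allele) as nucleotide strings, or
    None for a missing call. ``gq`` optionally maps sample -> genotype
    quality.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple
    qual: float
    genotypes: dict
    gq: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele or any(not a for a in self.alt_alleles):
            raise ValueError("alleles must be non-empty")

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alt_alleles) == 1
            and len(self.ref_allele) == 1
            and len(self.alt_alleles[0]) == 1
        )

    @property
    def has_missing(self) -> bool:
        return any(gt is None for gt in self.genotypes.values())


@dataclass
class SNPMatrix:
    """Samples × variant sites with single-character IUPAC genotype codes."""

    samples: list
    sites: list          # ordered (chrom, pos)
    codes: dict          # sample -> string of len(sites)
    missing_symbol: str = "?"

    def __post_init__(self) -> None:
        for sample in self.samples:
            if len(self.codes[sample]) != len(self.sites):
                raise ValueError(f"code row length mismatch for {sample!r}")


def read_vcf(path) -> tuple[list[str], list[VariantSite]]:
    """Parse a VCF (plain or bgzipped) into VariantSite records via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites = []
    for rec in vcf:
        genotypes = {}
        gq = {}
        for i, sample in enumerate(samples):
            a1, a2 = rec.genotypes[i][0], rec.genotypes[i][1]
            if a1 < 0 or a2 < 0:
                genotypes[sample] = None
            else:
                alleles = [rec.REF] + list(rec.ALT)
                genotypes[sample] = (alleles[a1], alleles[a2])
        try:
            gqs = rec.format("GQ")
        except KeyError:
            gqs = None
        if gqs is not None:
            for i, sample in enumerate(samples):
                gq[sample] = float(gqs[i][0])
        sites.append(
            VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_alleles=tuple(rec.ALT),
                qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                genotypes=genotypes,
                gq=gq,
            )
        )
    return samples, sites


def filter_sites(
    sites: Sequence[VariantSite],
    min_qual: float = 30.0,
    biallelic_only: bool = True,
    zero_missing: bool = True,
    quality_field: str = "QUAL",
) -> tuple[list[VariantSite], dict]:
    """Apply the hard site filters in order qual → biallelic → missing.

    The quality rule is strict (``qual > min_qual``). With
    ``quality_field="GQ"`` a site passes when every called sample's GQ is
    strictly above the threshold. Returns the surviving sites plus a tally of
    removals per criterion; tallies sum to input − output.
    """
    kept: list[VariantSite] = []
    tally = {
        "input": len(sites),
        "removed_low_qual": 0,
        "removed_not_biallelic_snp": 0,
        "removed_missing": 0,
        "retained": 0,
    }
    for site in sites:
        if quality_field == "QUAL":
            qual_ok = site.qual > min_qual
        elif quality_field == "GQ":
            called = [s for s, gt in site.genotypes.items() if gt is not None]
            qual_ok = bool(called) and all(
                site.gq.get(s, 0.0) > min_qual for s in called
            )
        else:
            raise ValueError(f"unknown quality_field {quality_field!r}")
        if not qual_ok:
            tally["removed_low_qual"] += 1
            continue
        if biallelic_only and not site.is_biallelic_snp:
            tally["removed_not_biallelic_snp"] += 1
            continue
        if zero_missing and site.has_missing:
            tally["removed_missing"] += 1
            continue
        kept.append(site)
    tally["retained"] = len(kept)
    return kept, tally


def encode_genotype(call: Optional[tuple], missing_symbol: str = "?") -> str:
    """Collapse one diploid call to a single IUPAC character.

    Homozygote → its base; heterozygote → the two-base ambiguity code
    (A/G→R, C/T→Y, G/C→S, A/T→W, G/T→K, A/C→M); missing → the missing
    symbol. Phasing is irrelevant (unordered pair).
    """
    if call is None:
        return missing_symbol
    a, b = (allele.upper() for allele in call)
    for allele in (a, b):
        if allele not in "ACGT" or len(allele) != 1:
            raise ValueError(f"non-SNP allele {allele!r} cannot be IUPAC-coded")
    if a == b:
        return a
    return IUPAC_HET[frozenset((a, b))]


def build_snp_matrix(
    samples: Sequence[str],
    sites: Sequence[VariantSite],
    missing_symbol: str = "?",
) -> SNPMatrix:
    """Assemble the samples × sites IUPAC matrix (sites in input order)."""
    codes = {
        sample: "".join(
            encode_genotype(site.genotypes.get(sample), missing_symbol)
            for site in sites
        )
        for sample in samples
    }
    return SNPMatrix(
        samples=list(samples),
        sites=[(s.chrom, s.pos) for s in sites],
        codes=codes,
        missing_symbol=missing_symbol,
    )


def write_matrix(matrix: SNPMatrix, path, format: str = "nexus") -> None:
    """Write the SNP matrix as ``nexus``, ``phylip`` (relaxed) or ``fasta``.

    Output is byte-stable for a fixed matrix.
    """
    if not matrix.samples or not matrix.sites:
        raise ValueError("cannot write an empty SNP matrix")
    ntax, nchar = len(matrix.samples), len(matrix.sites)
    with open(path, "w") as fh:
        if format == "nexus":
            fh.write("#NEXUS\n")
            fh.write("begin data;\n")
            fh.write(f"\tdimensions ntax={ntax} nchar={nchar};\n")
            fh.write(
                f"\tformat datatype=dna missing={matrix.missing_symbol} gap=-;\n"
            )
            fh.write("\tmatrix\n")
            width = max(len(s) for s in matrix.samples) + 2
            for sample in matrix.samples:
                fh.write(f"\t{sample.ljust(width)}{matrix.codes[sample]}\n")
            fh.write("\t;\nend;\n")
        elif format == "phylip":
            fh.write(f"{ntax} {nchar}\n")
            for sample in matrix.samples:
                fh.write(f"{sample}  {matrix.codes[sample]}\n")
        elif format == "fasta":
            for sample in matrix.samples:
                fh.write(f">{sample}\n{matrix.codes[sample]}\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def read_matrix(path, format: str = "nexus") -> SNPMatrix:
    """Parse a matrix previously produced by :func:`write_matrix`."""
    with open(path) as fh:
        text = fh.read()
    codes: dict[str, str] = {}
    missing = "?"
    if format == "nexus":
        in_matrix = False
        for line in text.splitlines():
            stripped = line.strip()
            if stripped.startswith("format"):
                for token in stripped.rstrip(";").split():
                    if token.startswith("missing="):
                        missing = token.split("=", 1)[1]
            if stripped == "matrix":
                in_matrix = True
                continue
            if in_matrix:
                if stripped in (";", "end;"):
                    break
                if stripped:
                    name, row = stripped.split(None, 1)
                    codes[name] = row.strip()
    elif format == "phylip":
        lines = text.splitlines()
        for line in lines[1:]:
            if line.strip():
                name, row = line.split(None, 1)
                codes[name] = row.strip()
    elif format == "fasta":
        name = None
        for line in text.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                codes[name] = ""
            elif name:
                codes[name] += line.strip()
    else:
        raise ValueError(f"unknown format {format!r}")
    samples = list(codes)
    nchar = len(next(iter(codes.values())))
    return SNPMatrix(
        samples=samples,
        sites=[("unknown", i + 1) for i in range(nchar)],
        codes=codes,
        missing_symbol=missing,
    )
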