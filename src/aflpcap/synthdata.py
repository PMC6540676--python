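"""Seeded synthetic data with known truth for every pipeline stage.

Generates (i) random genomes with controllable base composition, (ii)
ortholog families evolved under the Jukes–Cantor substitution process at a
stated per-species divergence, (iii) per-sample contigs with staggered
flanking extents, missing taxa and simulated depths — the regime the
boundary-search trimmer exists to handle — and (iv) toy VCFs with QUAL
values straddling the hard-filter threshold, heterozygotes and missing
genotypes.

All randomness flows from integer seeds through per-stage
``numpy.random.default_rng`` streams, so outputs are reproducible across
platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "TruthTable",
    "simulate_genome",
    "evolve_family",
    "simulate_families",
    "simulate_contigs",
    "simulate_vcf",
    "jc69_expected_p_distance",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def jc69_expected_p_distance(d: float) -> float:
    """Expected proportion of differing sites after branch length ``d``."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


@dataclass
class SimulationConfig:
    """Study-condition defaults for one synthetic capture experiment.

    Defaults emulate a small multi-species capture panel: 8 species, 30
    captured loci of 400–1,200 bp, moderate nuclear-locus divergence 0.05
    substitutions/site per species, flanks up to 300 bp (captured contigs
    often extend beyond the bait region), 10% locus dropout per species, and
    log-normal per-contig depths centred near 30x.
    """

    seed: int = 0
    genome_length: int = 100_000
    gc: float = 0.5
    n_species: int = 8
    divergence: float = 0.05
    locus_count: int = 30
    locus_length: tuple = (400, 1200)
    flank_length: int = 300
    dropout: float = 0.10
    depth_log_mean: float = 3.4
    depth_log_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name, p in (("gc", self.gc), ("dropout", self.dropout)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.genome_length < 1 or self.locus_count < 1:
            raise ValueError("lengths and counts must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Where one emitted contig truly belongs."""

    family: str
    species: str
    contig_id: str
    locus_offset: int       # 0-based offset of the locus within the contig
    locus_length: int


@dataclass
class TruthTable:
    """Ground truth for simulated contigs, keyed by true family."""

    records: list = field(default_factory=list)

    def by_family(self) -> dict:
        out: dict[str, list[TruthRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.family, []).append(rec)
        return out

    def family_of(self, contig_id: str) -> str:
        for rec in self.records:
            if rec.contig_id == contig_id:
                return rec.family
        raise KeyError(contig_id)


def simulate_genome(length: int, gc: float = 0.5, seed: int | np.random.Generator = 0) -> str:
    """I.i.d. random nucleotide string with P(G) + P(C) = ``gc``."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=probs)
    return _BASES[idx].tobytes().decode()


def evolve_family(
    ancestor: str,
    n_species: int,
    divergence: float,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Evolve one ortholog family: a star tree with ``n_species`` tips.

    Each tip sequence evolves independently from the ancestor under the
    Jukes–Cantor process at branch length ``divergence`` (expected
    substitutions per site): a site differs from the ancestor with
    probability (3/4)(1 − e^(−4d/3)), and a changed site takes each of the
    three other bases with equal probability. Species are named sp01..spNN.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = np.random.default_rng(seed)
    anc = np.frombuffer(ancestor.encode(), dtype="S1")
    lookup = {b: i for i, b in enumerate(_BASES)}
    anc_idx = np.array([lookup[b] for b in anc], dtype=np.int8)
    p_change = jc69_expected_p_distance(divergence)
    out = {}
    for i in range(1, n_species + 1):
        changed = rng.random(len(anc)) < p_change
        shift = rng.integers(1, 4, size=len(anc))
        tip = anc_idx.copy()
        tip[changed] = (tip[changed] + shift[changed]) % 4
        out[f"sp{i:02d}"] = _BASES[tip].tobytes().decode()
    return out


def simulate_families(config: SimulationConfig) -> tuple[dict, dict]:
    """Draw locus ancestors and evolve them into per-species ortholog sets.

    Returns ``(ancestors, families)`` where ancestors maps family id ->
    ancestral locus sequence and families maps family id -> {species: seq}.
    """
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.locus_length
    ancestors = {}
    families = {}
    for j in range(1, config.locus_count + 1):
        fam = f"fam{j:03d}"
        length = int(rng.integers(lo, hi + 1))
        ancestors[fam] = simulate_genome(length, config.gc, rng)
        families[fam] = evolve_family(
            ancestors[fam], config.n_species, config.divergence, rng
        )
    return ancestors, families


def simulate_contigs(
    families: Mapping[str, Mapping[str, str]],
    flank_length: int = 300,
    dropout: float = 0.10,
    depth_log_mean: float = 3.4,
    depth_log_sigma: float = 0.5,
    gc: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[dict, dict, TruthTable]:
    """Wrap evolved loci into per-species assembled contigs with known truth.

    Each retained species × family pair yields one contig: the species' locus
    sequence padded with independently drawn random flanks (uniform length in
    [0, flank_length] per end) and a log-normal mean-depth draw. Dropout
    removes species × family pairs independently.

    Returns ``(contigs, depths, truth)`` where contigs maps species ->
    {contig_id: sequence} and depths maps species -> {contig_id: depth}.
    """
    if not families:
        raise ValueError("families must be non-empty")
    rng = np.random.default_rng(seed)
    contigs: dict[str, dict[str, str]] = {}
    depths: dict[str, dict[str, float]] = {}
    truth = TruthTable()
    for fam in sorted(families):
        for species in sorted(families[fam]):
            if rng.random() < dropout:
                continue
            locus = families[fam][species]
            left = int(rng.integers(0, flank_length + 1))
            right = int(rng.integers(0, flank_length + 1))
            flank_l = simulate_genome(left, gc, rng) if left else ""
            flank_r = simulate_genome(right, gc, rng) if right else ""
            cid = f"{species}_{fam}"
            contigs.setdefault(species, {})[cid] = flank_l + locus + flank_r
            depths.setdefault(species, {})[cid] = float(
                rng.lognormal(depth_log_mean, depth_log_sigma)
            )
            truth.records.append(
                TruthRecord(fam, species, cid, left, len(locus))
            )
    if not truth.records:
        warnings.warn("dropout removed every simulated contig", stacklevel=2)
    return contigs, depths, truth


def simulate_vcf(
    n_samples: int,
    site_classes: Mapping[str, int],
    seed: int | np.random.Generator = 0,
    chrom: str = "contig1",
    path: Optional[str] = None,
) -> tuple[str, dict]:
    """Emit a toy VCF with planted per-class site counts.

    ``site_classes`` gives counts for {"pass", "low_qual", "multi_allelic",
    "with_missing"}: pass sites are biallelic SNPs with QUAL > 30 and a call
    in every sample; low-qual sites have QUAL <= 30; multi-allelic sites
    carry two ALT alleles; with-missing sites have at least one ./. call.
    Sites are emitted in shuffled position order. Returns
    ``(vcf_text, truth_counts)``; the text is also written to ``path`` when
    given.
    """
    classes = {"pass": 0, "low_qual": 0, "multi_allelic": 0, "with_missing": 0}
    classes.update(site_classes)
    if any(v < 0 for v in classes.values()):
        raise ValueError("site class counts must be >= 0")
    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1}" for i in range(n_samples)]

    labels = (
        ["pass"] * classes["pass"]
        + ["low_qual"] * classes["low_qual"]
        + ["multi_allelic"] * classes["multi_allelic"]
        + ["with_missing"] * classes["with_missing"]
    )
    rng.shuffle(labels)

    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={10 * (len(labels) + 1)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    bases = "ACGT"
    for i, label in enumerate(labels):
        pos = 10 * (i + 1)
        ref = bases[int(rng.integers(4))]
        others = [b for b in bases if b != ref]
        alt = [others[int(rng.integers(3))]]
        if label == "multi_allelic":
            alt.append([b for b in others if b != alt[0]][int(rng.integers(2))])
        qual = (
            float(rng.uniform(5.0, 30.0))
            if label == "low_qual"
            else float(rng.uniform(30.5, 900.0))
        )
        gts = []
        for _ in samples:
            a1 = int(rng.integers(0, len(alt) + 1))
            a2 = int(rng.integers(0, len(alt) + 1))
            gts.append(f"{a1}/{a2}")
        if label == "with_missing":
            n_miss = 1 + int(rng.integers(0, max(1, n_samples)))
            for j in rng.choice(n_samples, size=min(n_miss, n_samples), replace=False):
                gts[int(j)] = "./."
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alt)}\t{qual:.2f}\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text, dict(classes)
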