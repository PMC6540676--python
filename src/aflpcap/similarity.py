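"""Local-similarity search between nucleotide sequence sets.

Provides the hit currency used for redundancy reduction, mutual-best-hit
orthology and member-to-reference projection: a built-in local aligner
(k-mer pre-seeding + affine-gap Smith–Waterman via Bio.Align) and an
importer/exporter for the 12-column tabular hit dialect
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore), so externally produced hit tables can be dropped in.

Hit coordinates are 1-based inclusive; a minus-strand hit is encoded by
``send < sstart``, exactly as in the tabular dialect. E-values follow the
Karlin–Altschul form E = m*n*2^(-bitscore) with lambda solved for the
score system under uniform base composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional

from Bio import Align

from .insilico_aflp import revcomp

__all__ = [
    "ScoringScheme",
    "HitRecord",
    "HitTable",
    "local_align",
    "search_all",
    "read_hits_tabular",
    "write_hits_tabular",
    "best_hit",
    "DEFAULT_EVALUE_MAX",
]

DEFAULT_EVALUE_MAX = 1e-10


@dataclass(frozen=True)
class ScoringScheme:
    """Megablast-like nucleotide scoring (gap of length k costs open + k*extend)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    seed_k: int = 11
    # Karlin-Altschul K for nucleotide searches; lambda is derived per scheme.
    ka_k: float = 0.28

    def karlin_lambda(self) -> float:
        """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for uniform base frequencies."""
        p_match, p_mis = 0.25, 0.75

        def f(lam: float) -> float:
            return p_match * math.exp(lam * self.match) + p_mis * math.exp(lam * self.mismatch) - 1.0

        lo, hi = 1e-6, 5.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def bitscore(self, raw_score: float) -> float:
        lam = self.karlin_lambda()
        return (lam * raw_score - math.log(self.ka_k)) / math.log(2.0)

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bitscore(raw_score))


_DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class HitRecord:
    """One local-similarity hit in the tabular (outfmt-6) dialect."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.qstart > self.qend:
            raise ValueError("qstart must be <= qend")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def is_minus(self) -> bool:
        return self.send < self.sstart

    def to_tabular(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.pct_identity:.3f}",
                str(self.aln_len),
                str(self.mismatch),
                str(self.gapopen),
                str(self.qstart),
                str(self.qend),
                str(self.sstart),
                str(self.send),
                f"{self.evalue:.3g}",
                f"{self.bitscore:.1f}",
            ]
        )


@dataclass
class HitTable:
    """Ordered collection of hits plus provenance (built-in vs imported)."""

    records: list[HitRecord]
    provenance: str = "built-in"

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def for_query(self, query_id: str) -> list[HitRecord]:
        return [r for r in self.records if r.query_id == query_id]


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of two sequences (0-based half-open coordinates)."""

    qstart: int
    qend: int
    sstart: int
    send: int
    score: float
    identities: int
    mismatches: int
    gapopens: int
    aln_len: int


@lru_cache(maxsize=512)
def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _seeded(a: str, b: str, k: int) -> bool:
    """Seed requirement before running the full DP.

    One shared k-mer suffices at oracle scale (<= 500 bp); larger pairs must
    share two distinct k-mers, since a single chance k-mer between unrelated
    kilobase sequences is common while genuine homologs share many.
    """
    if len(a) < k or len(b) < k:
        return a in b or b in a if min(len(a), len(b)) > 0 else False
    shared = _kmer_set(a, k) & _kmer_set(b, k)
    required = 1 if min(len(a), len(b)) <= 500 else 2
    return len(shared) >= required


def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Bio.Align charges open_gap_score for the first gap column, so a gap of
    # length k costs open + (k-1)*extend there; fold our open cost in.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def local_align(
    a: str, b: str, scoring: ScoringScheme = _DEFAULT_SCORING
) -> Optional[LocalAlignment]:
    """Best local alignment of ``a`` vs ``b``, or None.

    A shared k-mer (default k=11) is required as a seed before the full
    affine-gap Smith–Waterman optimum is computed; without a seed the pair is
    reported as having no alignment. On seeded pairs the returned score is
    the exact Smith–Waterman optimum for the scoring scheme.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if not _seeded(a, b, scoring.seed_k):
        return None
    aligner = _make_aligner(scoring)
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    (qblocks, sblocks) = aln.aligned
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    sstart, send = int(sblocks[0][0]), int(sblocks[-1][1])
    identities = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        aligned_cols += qe - qs
        identities += sum(1 for x, y in zip(a[qs:qe], b[ss:se]) if x == y)
    gapopens = len(qblocks) - 1
    gap_cols = (qend - qstart) + (send - sstart) - 2 * aligned_cols
    aln_len = aligned_cols + gap_cols
    return LocalAlignment(
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        score=float(alignments.score),
        identities=identities,
        mismatches=aligned_cols - identities,
        gapopens=gapopens,
        aln_len=aln_len,
    )


def _hit_from_alignment(
    query_id: str,
    subject_id: str,
    aln: LocalAlignment,
    scoring: ScoringScheme,
    m: int,
    n_total: int,
    minus: bool,
    subject_len: int,
) -> HitRecord:
    if minus:
        # alignment was computed on revcomp(subject); map back, s coords descend
        sstart = subject_len - aln.sstart
        send = subject_len - aln.send + 1
    else:
        sstart = aln.sstart + 1
        send = aln.send
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=100.0 * aln.identities / aln.aln_len,
        aln_len=aln.aln_len,
        mismatch=aln.mismatches,
        gapopen=aln.gapopens,
        qstart=aln.qstart + 1,
        qend=aln.qend,
        sstart=sstart,
        send=send,
        evalue=scoring.evalue(aln.score, m, n_total),
        bitscore=round(scoring.bitscore(aln.score), 1),
    )


def search_all(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    scoring: ScoringScheme = _DEFAULT_SCORING,
    both_strands: bool = True,
) -> HitTable:
    """All query x subject local hits with e-value <= ``evalue_max``.

    Self-hits (identical ids) are excluded, so a set may be searched against
    itself. Sequence sets are mappings id -> sequence or iterables of
    (id, sequence) pairs; duplicate ids are an input error. Each
    query/subject pair contributes at most its best-strand hit. Ordering is
    deterministic: by query id, then descending bitscore with the best-hit
    tie-break order.
    """
    queries = _as_unique_mapping(queries, "query")
    subjects = _as_unique_mapping(subjects, "subject")
    n_total = sum(len(s) for s in subjects.values())
    records: list[HitRecord] = []
    for qid in queries:
        qseq = queries[qid].upper()
        for sid in subjects:
            if sid == qid:
                continue
            sseq = subjects[sid].upper()
            candidates = []
            aln = local_align(qseq, sseq, scoring)
            if aln is not None:
                candidates.append((aln, False))
            if both_strands:
                aln_rc = local_align(qseq, revcomp(sseq), scoring)
                if aln_rc is not None:
                    candidates.append((aln_rc, True))
            if not candidates:
                continue
            best, minus = max(candidates, key=lambda c: c[0].score)
            hit = _hit_from_alignment(
                qid, sid, best, scoring, len(qseq), n_total, minus, len(sseq)
            )
            if hit.evalue <= evalue_max:
                records.append(hit)
    records.sort(key=lambda r: (r.query_id, *_hit_rank(r)))
    return HitTable(records, provenance="built-in")


def _as_unique_mapping(seqs, role: str) -> dict:
    if isinstance(seqs, Mapping):
        return dict(seqs)
    pairs = list(seqs)
    out = dict(pairs)
    if len(out) != len(pairs):
        raise ValueError(f"duplicate {role} ids")
    return out


def _hit_rank(r: HitRecord) -> tuple:
    """Sort key implementing the deterministic best-hit preference order."""
    return (-r.bitscore, r.evalue, -r.aln_len, r.subject_id)


def best_hit(table: HitTable, query_id: str) -> Optional[HitRecord]:
    """The query's maximal-bitscore hit.

    Ties broken by lower e-value, then longer alignment, then
    lexicographically smallest subject id — a pure function of the table
    contents, invariant to row order.
    """
    hits = table.for_query(query_id)
    if not hits:
        return None
    return min(hits, key=_hit_rank)


def read_hits_tabular(path) -> HitTable:
    """Parse a 12-column tabular hit file (outfmt-6 dialect)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            records.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return HitTable(records, provenance="imported")


def write_hits_tabular(table: HitTable, path) -> None:
    with open(path, "w") as fh:
        for record in table.records:
            fh.write(record.to_tabular() + "\n")


def filter_evalue(table: HitTable, evalue_max: float) -> HitTable:
    """Apply the e-value ceiling to an imported table."""
    return HitTable(
        [r for r in table.records if r.evalue <= evalue_max], table.provenance
    )
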