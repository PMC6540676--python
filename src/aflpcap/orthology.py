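"""Contig QC and 1:1 orthology-group construction.

Assembled contigs from each captured sample are filtered on length and mean
sequencing depth, reduced for redundancy by greedy longest-first clustering,
and assigned to orthology groups by the mutual best-hit (MBH) criterion
against a designated reference contig set: a sample contig joins the group
of reference contig r iff each is the other's best hit in the bidirectional
search at the configured e-value ceiling.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from . import similarity
from .similarity import HitRecord, HitTable, best_hit, search_all

__all__ = [
    "Contig",
    "OrthologyGroup",
    "read_contigs_fasta",
    "read_depth_tsv",
    "qc_filter_contigs",
    "reduce_redundancy",
    "mutual_best_hit_groups",
]

_COV_HEADER = re.compile(r"cov_([0-9]+(?:\.[0-9]+)?)")


@dataclass(frozen=True)
class Contig:
    """One assembled contig; ``mean_depth`` is fold-coverage (optional)."""

    id: str
    sample: str
    sequence: str
    mean_depth: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrthologyGroup:
    """A reference contig with its mutually-best-hitting member contigs.

    ``members`` maps sample name -> (member contig id, linking HitRecord with
    the member as query and the reference as subject). At most one member per
    sample; the reference sample's own contig is the trivial anchor member.
    """

    og_id: str
    reference_id: str
    members: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def read_contigs_fasta(path, sample: str, depths: Optional[Mapping[str, float]] = None) -> list[Contig]:
    """Load per-sample contigs from FASTA.

    Depth is taken from ``depths`` when given, else parsed from assembler-style
    ``cov_<float>`` tokens in the record id, else left unset.
    """
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        depth = None
        if depths is not None and rec.id in depths:
            depth = depths[rec.id]
        else:
            m = _COV_HEADER.search(rec.id)
            if m:
                depth = float(m.group(1))
        contigs.append(Contig(rec.id, sample, str(rec.seq).upper(), depth))
    return contigs


def read_depth_tsv(path) -> dict[str, float]:
    """Two-column TSV: contig id, mean depth."""
    depths = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, depth = line.split("\t")[:2]
            depths[cid] = float(depth)
    return depths


def qc_filter_contigs(
    contigs: Iterable[Contig],
    min_len: int = 200,
    min_depth: float = 5.0,
) -> tuple[list[Contig], dict]:
    """Keep contigs with length >= ``min_len`` AND mean depth >= ``min_depth``.

    Both thresholds are inclusive. Returns the retained contigs plus a report
    counting removals per criterion (a contig failing both counts once,
    under the length criterion, applied first).
    """
    kept: list[Contig] = []
    report = {"input": 0, "removed_short": 0, "removed_low_depth": 0, "retained": 0}
    for contig in contigs:
        report["input"] += 1
        if len(contig) < min_len:
            report["removed_short"] += 1
            continue
        if min_depth > 0:
            if contig.mean_depth is None:
                raise ValueError(
                    f"contig {contig.id!r} has no depth but min_depth={min_depth} > 0"
                )
            if contig.mean_depth < min_depth:
                report["removed_low_depth"] += 1
                continue
        kept.append(contig)
    report["retained"] = len(kept)
    return kept, report


def reduce_redundancy(
    contigs: Sequence[Contig],
    identity_cutoff: float = 0.95,
    scoring: similarity.ScoringScheme = similarity.ScoringScheme(),
) -> list[Contig]:
    """Greedy longest-first redundancy reduction within one sample.

    Contigs are visited longest first (ties by id). A contig joins an
    existing cluster when its best local hit against a representative has
    identities / length(shorter sequence) >= ``identity_cutoff``; otherwise it
    founds a new cluster. Only representatives are returned, in visit order.
    """
    ordered = sorted(contigs, key=lambda c: (-len(c), c.id))
    representatives: list[Contig] = []
    for contig in ordered:
        redundant = False
        for rep in representatives:
            aln = similarity.local_align(contig.sequence, rep.sequence, scoring)
            if aln is None:
                continue
            shorter = min(len(contig), len(rep))
            if aln.identities / shorter >= identity_cutoff:
                redundant = True
                break
        if not redundant:
            representatives.append(contig)
    return representatives


def mutual_best_hit_groups(
    reference: Sequence[Contig],
    samples: Mapping[str, Sequence[Contig]],
    evalue_max: float = similarity.DEFAULT_EVALUE_MAX,
    reference_sample: str = "reference",
    hit_tables: Optional[Mapping[str, tuple[HitTable, HitTable]]] = None,
) -> list[OrthologyGroup]:
    """Build 1:1 orthology groups by the mutual best-hit criterion.

    For each sample the bidirectional search (sample -> reference and
    reference -> sample) is run with the built-in aligner, or taken from
    ``hit_tables`` (sample -> (sample_to_ref, ref_to_sample)) when externally
    produced tables are supplied. Member c of sample s joins the group
    anchored at reference contig r iff best_hit(s->ref, c) = r and
    best_hit(ref->s, r) = c. Groups are keyed og0001.. in sorted reference-id
    order; samples without a mutual pair for a reference are simply absent
    from that group.
    """
    if reference_sample in samples:
        raise ValueError(
            f"sample name {reference_sample!r} collides with the reference set"
        )
    ref_seqs = {c.id: c.sequence for c in reference}
    if len(ref_seqs) != len(reference):
        raise ValueError("duplicate reference contig ids")

    assignments: dict[str, dict[str, tuple[str, HitRecord]]] = {
        c.id: {} for c in reference
    }
    for sample_name in sorted(samples):
        sample_contigs = samples[sample_name]
        sample_seqs = {c.id: c.sequence for c in sample_contigs}
        if hit_tables is not None and sample_name in hit_tables:
            to_ref, from_ref = hit_tables[sample_name]
            to_ref = similarity.filter_evalue(to_ref, evalue_max)
            from_ref = similarity.filter_evalue(from_ref, evalue_max)
        else:
            to_ref = search_all(sample_seqs, ref_seqs, evalue_max)
            from_ref = search_all(ref_seqs, sample_seqs, evalue_max)
        for contig in sample_contigs:
            fwd = best_hit(to_ref, contig.id)
            if fwd is None:
                continue
            back = best_hit(from_ref, fwd.subject_id)
            if back is None or back.subject_id != contig.id:
                continue
            assignments[fwd.subject_id][sample_name] = (contig.id, fwd)

    groups: list[OrthologyGroup] = []
    for i, ref_id in enumerate(sorted(assignments), 1):
        members = assignments[ref_id]
        og = OrthologyGroup(og_id=f"og{i:04d}", reference_id=ref_id)
        # the reference contributes its own contig as the trivial anchor member
        anchor = HitRecord(
            query_id=ref_id,
            subject_id=ref_id,
            pct_identity=100.0,
            aln_len=len(ref_seqs[ref_id]),
            mismatch=0,
            gapopen=0,
            qstart=1,
            qend=len(ref_seqs[ref_id]),
            sstart=1,
            send=len(ref_seqs[ref_id]),
            evalue=0.0,
            bitscore=float(2 * len(ref_seqs[ref_id])),
        )
        og.members[reference_sample] = (ref_id, anchor)
        for sample_name, (cid, hit) in sorted(members.items()):
            og.members[sample_name] = (cid, hit)
        groups.append(og)
    return groups


def write_groups_tsv(groups: Sequence[OrthologyGroup], path) -> None:
    """og_id, reference_id, sample, member_id, bitscore, evalue — one row per member."""
    with open(path, "w") as fh:
        fh.write("og_id\treference_id\tsample\tmember_id\tbitscore\tevalue\n")
        for og in groups:
            for sample_name, (cid, hit) in og.members.items():
                fh.write(
                    f"{og.og_id}\t{og.reference_id}\t{sample_name}\t{cid}"
                    f"\t{hit.bitscore:.1f}\t{hit.evalue:.3g}\n"
                )


def write_qc_report(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(report), fh, indent=2)
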