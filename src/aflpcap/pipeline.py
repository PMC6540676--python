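"""End-to-end capture-data pipeline: contigs in, supermatrix out.

Thin orchestration over the stage modules — QC filter, mutual-best-hit
orthology against the reference contig set, projection, optimal-window
trimming, alignment, low-similarity row removal, supermatrix assembly —
with per-group status reporting. Exists so the CLI, the tests and the
synthetic-truth comparisons all run the exact same path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import orthology as orth
from . import trim_align as ta
from .insilico_aflp import revcomp
from .orthology import Contig, OrthologyGroup
from .similarity import DEFAULT_EVALUE_MAX
from .trim_align import MultipleAlignment, Supermatrix

__all__ = ["PipelineResult", "group_to_alignment", "run_capture_pipeline"]

REFERENCE_SAMPLE = "reference"


@dataclass
class PipelineResult:
    groups: list
    alignments: dict            # og_id -> MultipleAlignment (post-filter)
    supermatrix: Optional[Supermatrix]
    group_status: dict          # og_id -> "ok" | rejection reason
    qc_reports: dict = field(default_factory=dict)


def group_to_alignment(
    group: OrthologyGroup,
    sequences_by_id: Mapping[str, str],
    reference_length: int,
    threshold: float = 0.5,
    min_mean_similarity: float = 0.30,
    backend: str = "builtin",
) -> MultipleAlignment:
    """Project, trim, align and similarity-filter one orthology group.

    ``sequences_by_id`` must contain every member contig (plus orientation
    as assembled; minus-strand members are reverse-complemented here using
    the linking hit's strand). Raises the trim/alignment rejection
    exceptions for infeasible groups.
    """
    member_lengths = {
        cid: len(sequences_by_id[cid]) for _, (cid, _) in group.members.items()
    }
    spans = ta.project_members(
        group, member_lengths, reference_length, reference_sample=REFERENCE_SAMPLE
    )
    oriented = {}
    for span in spans:
        seq = sequences_by_id[span.member_id]
        oriented[span.member_id] = revcomp(seq) if span.strand == "-" else seq
    window = ta.find_trim_window(spans, threshold=threshold)
    trimmed_by_id = ta.trim_group(oriented, spans, window)
    # rekey by sample for alignment rows
    id_to_sample = {cid: sample for sample, (cid, _) in group.members.items()}
    trimmed = {id_to_sample[cid]: seq for cid, seq in trimmed_by_id.items()}
    aln = ta.align_group(trimmed, backend=backend)
    return ta.filter_low_similarity(
        aln, min_mean_similarity=min_mean_similarity, backend=backend
    )


def run_capture_pipeline(
    reference: Sequence[Contig],
    samples: Mapping[str, Sequence[Contig]],
    min_len: int = 200,
    min_depth: float = 5.0,
    redundancy_cutoff: Optional[float] = 0.95,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    threshold: float = 0.5,
    min_mean_similarity: float = 0.30,
    min_taxa: int = 6,
    backend: str = "builtin",
) -> PipelineResult:
    """Run QC → orthology → trim → align → filter → supermatrix.

    ``min_depth=0`` skips the depth requirement (contigs without depths
    allowed); ``redundancy_cutoff=None`` skips redundancy reduction. The
    supermatrix is None when no group satisfies ``min_taxa``.
    """
    qc_reports = {}
    filtered_samples = {}
    for name in sorted(samples):
        kept, report = orth.qc_filter_contigs(samples[name], min_len, min_depth)
        if redundancy_cutoff is not None:
            kept = orth.reduce_redundancy(kept, redundancy_cutoff)
        qc_reports[name] = report
        filtered_samples[name] = kept

    groups = orth.mutual_best_hit_groups(
        reference, filtered_samples, evalue_max, reference_sample=REFERENCE_SAMPLE
    )
    sequences_by_id = {c.id: c.sequence for c in reference}
    for contigs in filtered_samples.values():
        sequences_by_id.update({c.id: c.sequence for c in contigs})
    ref_lengths = {c.id: len(c.sequence) for c in reference}

    alignments = {}
    status = {}
    for group in groups:
        if len(group.members) < 2:
            status[group.og_id] = "single member"
            continue
        try:
            alignments[group.og_id] = group_to_alignment(
                group,
                sequences_by_id,
                ref_lengths[group.reference_id],
                threshold=threshold,
                min_mean_similarity=min_mean_similarity,
                backend=backend,
            )
            status[group.og_id] = "ok"
        except ta.NoFeasibleWindow:
            status[group.og_id] = "no feasible window"
        except ta.GroupRejected as exc:
            status[group.og_id] = str(exc)

    supermatrix = None
    eligible = {og: a for og, a in alignments.items() if len(a) >= min_taxa}
    if eligible:
        supermatrix = ta.build_supermatrix(alignments, min_taxa=min_taxa)
    return PipelineResult(groups, alignments, supermatrix, status, qc_reports)
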