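"""Optimal aligning-region search, alignment filters and supermatrix assembly.

Contigs within an orthology group differ in extent (captured loci often carry
flanking sequence), which frustrates direct alignment. Each member is first
projected onto reference coordinates using its linking hit, then the group is
trimmed to the widest window whose two boundary columns are each covered by
at least a threshold fraction of members (interior coverage dips are
permitted — only the boundaries are constrained). Trimmed groups are
multiple-aligned, rows of low average similarity are discarded and the
survivors realigned once, and the retained alignments are concatenated into
a partitioned supermatrix with occupancy/completeness statistics.
"""

from __future__ import annotations

import json
import math
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align

from .orthology import OrthologyGroup

__all__ = [
    "ProjectedSpan",
    "TrimWindow",
    "MultipleAlignment",
    "Supermatrix",
    "NoFeasibleWindow",
    "GroupRejected",
    "project_members",
    "find_trim_window",
    "trim_group",
    "align_group",
    "pairwise_similarity",
    "filter_low_similarity",
    "build_supermatrix",
    "write_supermatrix_fasta",
    "write_supermatrix_phylip",
    "write_partitions_raxml",
]

GAP = "-"


class NoFeasibleWindow(Exception):
    """No reference column reaches the boundary-coverage threshold."""


class GroupRejected(Exception):
    """Group cannot proceed (fewer than two usable members)."""


@dataclass(frozen=True)
class ProjectedSpan:
    """A member's extent in reference coordinates (0-based half-open).

    Minus-strand members are reverse-complemented before projection; the
    original orientation is recorded in ``strand``.
    """

    sample: str
    member_id: str
    ref_start: int
    ref_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"degenerate span [{self.ref_start}, {self.ref_end}) for {self.member_id!r}"
            )

    def __len__(self) -> int:
        return self.ref_end - self.ref_start

    def covers(self, column: int) -> bool:
        return self.ref_start <= column < self.ref_end


@dataclass(frozen=True)
class TrimWindow:
    """The optimal aligning region in reference coordinates."""

    ref_start: int
    ref_end: int
    boundary_coverage_up: int
    boundary_coverage_down: int


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over {A,C,G,T,N,-}, keyed by sample."""

    rows: dict
    # rows: map sample -> gapped sequence

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Supermatrix:
    """Concatenated alignments with a partition map and occupancy matrix."""

    rows: dict            # species -> concatenated sequence
    partitions: list      # ordered (og_id, start, end), 1-based inclusive
    occupancy: dict       # species -> {og_id: bool}
    completeness_by_locus: float
    completeness_by_characters: float

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


# ---------------------------------------------------------------------------
# projection


def project_members(
    group: OrthologyGroup,
    member_lengths: Mapping[str, int],
    reference_length: int,
    reference_sample: str = "reference",
) -> list[ProjectedSpan]:
    """Project each member onto reference coordinates via its linking hit.

    The hit is treated as ungapped for offset purposes: a single offset
    ``(sstart-1) - (qstart-1)`` places the whole member (hit query) on the
    reference (hit subject). A minus-strand hit (send < sstart) is handled by
    reverse-complementing the member first, which flips its query coordinates,
    then projecting as plus strand. The reference projects to [0, L).
    """
    spans = []
    for sample, (member_id, hit) in group.members.items():
        length = member_lengths[member_id]
        if sample == reference_sample and member_id == group.reference_id:
            spans.append(ProjectedSpan(sample, member_id, 0, reference_length, "+"))
            continue
        if hit.qend > length:
            raise ValueError(
                f"hit coordinates exceed member length for {member_id!r} "
                f"(qend={hit.qend} > {length})"
            )
        if max(hit.sstart, hit.send) > reference_length:
            raise ValueError(
                f"hit coordinates exceed reference length for {member_id!r}"
            )
        if hit.is_minus:
            # after reverse-complementing the member, the hit's query interval
            # [qstart, qend] becomes [L-qend+1, L-qstart+1] and the subject
            # interval reads forward
            qstart = length - hit.qend + 1
            sstart = hit.send
            strand = "-"
        else:
            qstart = hit.qstart
            sstart = hit.sstart
            strand = "+"
        offset = (sstart - 1) - (qstart - 1)
        spans.append(ProjectedSpan(sample, member_id, offset, offset + length, strand))
    return spans


# ---------------------------------------------------------------------------
# trim window


def find_trim_window(
    spans: Sequence[ProjectedSpan],
    threshold: float = 0.5,
    ref_len: Optional[int] = None,
) -> TrimWindow:
    """Widest window whose boundary columns each reach threshold coverage.

    With cov(p) = number of spans containing column p and
    k = ceil(threshold * n_spans), the feasible set is
    F = {p : cov(p) >= k} and the window is [min F, max F + 1). Both boundary
    columns then satisfy the coverage demand by construction; interior
    columns may dip below it. Raises :class:`NoFeasibleWindow` when F is
    empty.
    """
    if len(spans) < 2:
        raise GroupRejected("need at least two projected spans")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    k = math.ceil(threshold * len(spans))
    lo = min(s.ref_start for s in spans)
    hi = max(s.ref_end for s in spans)
    cov = np.zeros(hi - lo, dtype=np.int32)
    for s in spans:
        cov[s.ref_start - lo : s.ref_end - lo] += 1
    feasible = np.nonzero(cov >= k)[0]
    if feasible.size == 0:
        raise NoFeasibleWindow(
            f"no column reaches coverage {k} of {len(spans)} spans"
        )
    start = int(feasible[0]) + lo
    end = int(feasible[-1]) + lo + 1
    return TrimWindow(
        ref_start=start,
        ref_end=end,
        boundary_coverage_up=int(cov[feasible[0]]),
        boundary_coverage_down=int(cov[feasible[-1]]),
    )


def trim_group(
    sequences: Mapping[str, str],
    spans: Sequence[ProjectedSpan],
    window: TrimWindow,
) -> dict[str, str]:
    """Crop each member to (span ∩ window), in member-local coordinates.

    ``sequences`` maps member id to its plus-orientation sequence (minus
    members already reverse-complemented). Members whose span misses the
    window entirely are dropped.
    """
    trimmed: dict[str, str] = {}
    for s in spans:
        lo = max(s.ref_start, window.ref_start)
        hi = min(s.ref_end, window.ref_end)
        if lo >= hi:
            continue
        seq = sequences[s.member_id]
        local_lo = lo - s.ref_start
        local_hi = hi - s.ref_start
        trimmed[s.member_id] = seq[local_lo:local_hi]
    return trimmed


# ---------------------------------------------------------------------------
# multiple alignment


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    # end gaps are charged: trimmed members mostly tile the same window, and
    # penalised ends stop unrelated rows from sliding into disjoint placement
    # (which would empty the shared-column set the similarity filter uses)
    return aligner


def _pairwise_global(a: str, b: str) -> tuple[str, str]:
    """Gapped (a, b) rows of one optimal global alignment."""
    aln = _global_aligner().align(a, b)[0]
    rows = str(aln).splitlines()
    # Alignment.__str__ wraps; rebuild from aligned coordinate blocks instead
    ga, gb = [], []
    pa = pb = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        if qs > pa:
            ga.append(a[pa:qs])
            gb.append(GAP * (qs - pa))
        if ss > pb:
            ga.append(GAP * (ss - pb))
            gb.append(b[pb:ss])
        ga.append(a[qs:qe])
        gb.append(b[ss:se])
        pa, pb = qe, se
    if pa < len(a):
        ga.append(a[pa:])
        gb.append(GAP * (len(a) - pa))
    if pb < len(b):
        ga.append(GAP * (len(b) - pb))
        gb.append(b[pb:])
    return "".join(ga), "".join(gb)


def _kmer_similarity(a: str, b: str, k: int = 6) -> float:
    ka = {a[i : i + k] for i in range(max(0, len(a) - k + 1))}
    kb = {b[i : i + k] for i in range(max(0, len(b) - k + 1))}
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))


def _align_star(sequences: Mapping[str, str]) -> MultipleAlignment:
    """Center-star multiple alignment.

    The center is the row with the highest mean k-mer similarity to the
    others (the similarity-ordered guide); every other row is aligned to the
    center by global DP and merged under the once-a-gap-always-a-gap rule.
    """
    names = sorted(sequences)
    if len(names) == 1:
        return MultipleAlignment({names[0]: sequences[names[0]]})
    sims = {
        n: sum(_kmer_similarity(sequences[n], sequences[m]) for m in names if m != n)
        for n in names
    }
    center = max(names, key=lambda n: (sims[n], -len(sequences[n]), n))
    center_seq = sequences[center]

    # master gap pattern for the center: counts of gap columns inserted
    # before each center position (index L means after the last base)
    others = [n for n in names if n != center]
    pair_rows: dict[str, tuple[str, str]] = {}
    master = np.zeros(len(center_seq) + 1, dtype=np.int64)
    for name in others:
        gc, go = _pairwise_global(center_seq, sequences[name])
        pair_rows[name] = (gc, go)
        gaps_before = np.zeros(len(center_seq) + 1, dtype=np.int64)
        pos = 0
        run = 0
        for ch in gc:
            if ch == GAP:
                run += 1
            else:
                gaps_before[pos] = run
                pos += 1
                run = 0
        gaps_before[len(center_seq)] = run
        master = np.maximum(master, gaps_before)

    def expand(gapped_center: str, row: str) -> str:
        """Re-space ``row`` onto the master center gap pattern."""
        out = []
        pos = 0
        pending: list[str] = []
        for cc, rc in zip(gapped_center, row):
            if cc == GAP:
                pending.append(rc)
            else:
                need = int(master[pos])
                out.append(GAP * (need - len(pending)))
                out.extend(pending)
                pending = []
                out.append(rc)
                pos += 1
        need = int(master[len(gapped_center.replace(GAP, ""))])
        out.append(GAP * (need - len(pending)))
        out.extend(pending)
        return "".join(out)

    rows = {center: expand(center_seq, center_seq)}
    for name in others:
        gc, go = pair_rows[name]
        rows[name] = expand(gc, go)
    return MultipleAlignment(rows)


def align_group(
    sequences: Mapping[str, str],
    backend: str = "builtin",
) -> MultipleAlignment:
    """Multiple-align one trimmed group.

    ``backend`` is either ``"builtin"`` (center-star, global DP) or an
    external aligner command template containing ``{in}`` and ``{out}``
    placeholders (e.g. ``"mafft --quiet {in} > {out}"`` is expressed as
    ``"mafft --quiet {in}"`` with stdout capture when ``{out}`` is absent).
    """
    if len(sequences) < 2:
        raise GroupRejected("alignment needs at least two sequences")
    if backend == "builtin":
        return _align_star(sequences)
    return _align_external(sequences, backend)


def _align_external(sequences: Mapping[str, str], command: str) -> MultipleAlignment:
    with tempfile.TemporaryDirectory() as tmp:
        fa_in = Path(tmp) / "in.fa"
        fa_out = Path(tmp) / "out.fa"
        with open(fa_in, "w") as fh:
            for name in sorted(sequences):
                fh.write(f">{name}\n{sequences[name]}\n")
        cmd = command.replace("{in}", str(fa_in)).replace("{out}", str(fa_out))
        use_stdout = "{out}" not in command
        try:
            proc = subprocess.run(
                shlex.split(cmd), capture_output=True, text=True, check=True
            )
        except subprocess.CalledProcessError as exc:
            raise RuntimeError(
                f"external aligner failed ({exc.returncode}): {exc.stderr}"
            ) from exc
        text = proc.stdout if use_stdout else fa_out.read_text()
        rows = {}
        name = None
        for line in text.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                rows[name] = []
            elif name is not None:
                rows[name].append(line.strip())
        rows = {n: "".join(parts).upper() for n, parts in rows.items()}
        if set(rows) != set(sequences):
            raise RuntimeError("external aligner did not preserve the row set")
        return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# similarity filter


def pairwise_similarity(row_a: str, row_b: str) -> float:
    """Identical columns over columns where both rows are non-gap (0 if none)."""
    shared = ident = 0
    for x, y in zip(row_a, row_b):
        if x != GAP and y != GAP:
            shared += 1
            if x == y:
                ident += 1
    return ident / shared if shared else 0.0


def filter_low_similarity(
    aln: MultipleAlignment,
    min_mean_similarity: float = 0.30,
    backend: str = "builtin",
    realign: bool = True,
) -> MultipleAlignment:
    """Discard rows whose mean similarity to all other rows is below cutoff.

    Removal is a single pass against the full alignment (a row at exactly the
    cutoff is kept — the rule is strictly-below); the survivors are realigned
    once. Raises :class:`GroupRejected` when fewer than two rows survive.
    """
    names = sorted(aln.rows)
    if len(names) < 2:
        raise GroupRejected("similarity filter needs at least two rows")
    keep = []
    for name in names:
        sims = [
            pairwise_similarity(aln.rows[name], aln.rows[other])
            for other in names
            if other != name
        ]
        if sum(sims) / len(sims) >= min_mean_similarity:
            keep.append(name)
    if len(keep) < 2:
        raise GroupRejected("fewer than two rows survive the similarity filter")
    if len(keep) == len(names):
        return aln
    survivors = {n: aln.rows[n].replace(GAP, "") for n in keep}
    if not realign:
        return MultipleAlignment({n: aln.rows[n] for n in keep})
    return align_group(survivors, backend=backend)


# ---------------------------------------------------------------------------
# supermatrix


def build_supermatrix(
    alignments: Mapping[str, MultipleAlignment],
    min_taxa: int = 6,
) -> Supermatrix:
    """Concatenate per-locus alignments into one species × characters matrix.

    Loci with fewer than ``min_taxa`` rows are dropped (inclusive threshold);
    the rest are concatenated in sorted locus-id order with absent species
    gap-filled. Completeness by locus = filled species×locus cells over all
    cells; completeness by characters = non-gap characters over matrix size.
    """
    surviving = {
        og_id: aln for og_id, aln in alignments.items() if len(aln) >= min_taxa
    }
    if not surviving:
        raise ValueError(f"no alignment has at least {min_taxa} taxa")
    species = sorted({sp for aln in surviving.values() for sp in aln.rows})
    og_ids = sorted(surviving)

    parts: dict[str, list[str]] = {sp: [] for sp in species}
    partitions: list[tuple[str, int, int]] = []
    occupancy: dict[str, dict[str, bool]] = {sp: {} for sp in species}
    pos = 0
    for og_id in og_ids:
        aln = surviving[og_id]
        partitions.append((og_id, pos + 1, pos + aln.length))
        for sp in species:
            present = sp in aln.rows
            occupancy[sp][og_id] = present
            parts[sp].append(aln.rows[sp] if present else GAP * aln.length)
        pos += aln.length

    rows = {sp: "".join(parts[sp]) for sp in species}
    n_cells = len(species) * len(og_ids)
    filled = sum(1 for sp in species for og in og_ids if occupancy[sp][og])
    total_chars = len(species) * pos
    nongap = sum(len(r) - r.count(GAP) for r in rows.values())
    return Supermatrix(
        rows=rows,
        partitions=partitions,
        occupancy=occupancy,
        completeness_by_locus=filled / n_cells,
        completeness_by_characters=nongap / total_chars,
    )


def write_supermatrix_fasta(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for sp in sorted(sm.rows):
            fh.write(f">{sp}\n{sm.rows[sp]}\n")


def write_supermatrix_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name, whitespace, full sequence on one line."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.rows)} {sm.length}\n")
        for sp in sorted(sm.rows):
            fh.write(f"{sp}  {sm.rows[sp]}\n")


def write_partitions_raxml(sm: Supermatrix, path) -> None:
    """RAxML-style partition file: ``DNA, og0001 = 1-1378``."""
    with open(path, "w") as fh:
        for og_id, start, end in sm.partitions:
            fh.write(f"DNA, {og_id} = {start}-{end}\n")


def write_completeness_report(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_species": len(sm.rows),
                "n_loci": len(sm.partitions),
                "total_length": sm.length,
                "completeness_by_locus": sm.completeness_by_locus,
                "completeness_by_characters": sm.completeness_by_characters,
            },
            fh,
            indent=2,
        )
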