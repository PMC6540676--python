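"""In-silico AFLP bait design.

Simulates the wet-lab bait-generation protocol on arbitrary input sequence:
double restriction digest, Y-adapter amplifiability (only fragments carrying
one adapter of each kind amplify exponentially), size selection, selective
amplification with single 3' selective nucleotides, and pooling of several
selective-primer combinations into one bait set.

Coordinates are 0-based half-open on the source top strand throughout.
Overhangs are not modeled: a cut is a single top-strand position
(site start + cut offset), because only fragment identity matters for
bait capture, not sticky-end chemistry.
"""

from __future__ import annotations

import json
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "RestrictionEnzyme",
    "Fragment",
    "SelectiveCombination",
    "BaitSet",
    "MLUI",
    "SBFI",
    "TERMINAL",
    "digest_sequence",
    "adapter_compatible",
    "size_select",
    "selective_amplify",
    "pool_baits",
    "revcomp",
    "BAIT_COUNT_RECOMMENDED",
]

TERMINAL = "terminal"

# Recommended bait-set complexity window for efficient capture.
BAIT_COUNT_RECOMMENDED = (500, 5000)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InputError(ValueError):
    """Invalid input sequence or record."""


class ConfigError(ValueError):
    """Invalid configuration parameter."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme with an exact recognition site.

    ``cut_offset`` is the 0-based offset of the top-strand cut within the
    recognition site: MluI = A^CGCGT has offset 1, SbfI = CCTGCA^GG offset 6.
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site or set(site) - set("ACGT"):
            raise ConfigError(
                f"recognition site for {self.name!r} must be non-empty A/C/G/T, "
                f"got {self.recognition_site!r}"
            )
        if not 0 <= self.cut_offset <= len(site):
            raise ConfigError(
                f"cut_offset {self.cut_offset} outside recognition site "
                f"of length {len(site)} for {self.name!r}"
            )
        object.__setattr__(self, "recognition_site", site)

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition_site) == self.recognition_site

    def cut_positions(self, seq: str) -> list[int]:
        """Top-strand cut coordinates for every exact site occurrence.

        Overlapping occurrences are found left-to-right; a site window that
        contains N (or any non-ACGT base) never matches, because matching is
        exact. Non-palindromic enzymes are additionally scanned on the
        bottom strand (reverse-complement site on the top strand).
        """
        positions = []
        for site, offset in self._scan_patterns():
            start = seq.find(site)
            while start != -1:
                positions.append(start + offset)
                start = seq.find(site, start + 1)
        return positions

    def _scan_patterns(self) -> list[tuple[str, int]]:
        patterns = [(self.recognition_site, self.cut_offset)]
        if not self.is_palindromic:
            # bottom-strand occurrence seen on the top strand: the bottom
            # strand cut maps to len(site) - cut_offset from the match start
            patterns.append(
                (revcomp(self.recognition_site), len(self.recognition_site) - self.cut_offset)
            )
        return patterns


MLUI = RestrictionEnzyme("MluI", "ACGCGT", 1)
SBFI = RestrictionEnzyme("SbfI", "CCTGCAGG", 6)


@dataclass(frozen=True)
class Fragment:
    """One digestion product, the bait candidate unit.

    ``left_end`` / ``right_end`` name the enzyme whose cut produced that end,
    or ``"terminal"`` at the extremities of the source sequence.
    """

    source_id: str
    start: int
    end: int
    left_end: str
    right_end: str
    sequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InputError(f"bad fragment interval [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise InputError("fragment sequence length disagrees with coordinates")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.source_id, self.start, self.end)


@dataclass(frozen=True)
class SelectiveCombination:
    """One selective-primer pair: a single 3' selective base per side.

    ``None`` means no selection on that side (preamplification behaviour).
    """

    forward_base: Optional[str] = None
    reverse_base: Optional[str] = None

    def __post_init__(self) -> None:
        for base in (self.forward_base, self.reverse_base):
            if base is not None and base not in "ACGT":
                raise ConfigError(f"selective base must be A/C/G/T or None, got {base!r}")

    def __str__(self) -> str:
        return f"F{self.forward_base or '-'}/R{self.reverse_base or '-'}"


@dataclass
class BaitSet:
    """Pooled selective-amplification products plus summary statistics."""

    fragments: list[Fragment]
    combinations: list[SelectiveCombination]
    summary: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def to_json(self) -> str:
        return json.dumps(
            {"combinations": [str(c) for c in self.combinations], **self.summary},
            indent=2,
        )


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise InputError("empty input sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise InputError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq


def digest_sequence(
    seq: str,
    enzymes: Sequence[RestrictionEnzyme] = (MLUI, SBFI),
    source_id: str = "seq",
) -> list[Fragment]:
    """Digest ``seq`` with all ``enzymes`` simultaneously (complete digestion).

    Cut positions are the union over enzymes of (site start + cut offset) for
    every exact top-strand occurrence. Returns fragments left to right; the
    concatenation of fragment sequences equals the input. A sequence with no
    sites yields one fragment with both ends ``"terminal"``.
    """
    seq = _validate_sequence(seq)
    cuts: list[tuple[int, str]] = []
    for enz in enzymes:
        cuts.extend((pos, enz.name) for pos in enz.cut_positions(seq))
    # two enzymes cutting the same position: keep the first left-to-right
    cuts.sort(key=lambda c: c[0])
    dedup: list[tuple[int, str]] = []
    for pos, name in cuts:
        if not dedup or dedup[-1][0] != pos:
            dedup.append((pos, name))
    # drop degenerate cuts at the extremities (would make empty fragments)
    dedup = [(p, n) for p, n in dedup if 0 < p < len(seq)]

    fragments = []
    prev_pos, prev_label = 0, TERMINAL
    for pos, name in dedup:
        fragments.append(
            Fragment(source_id, prev_pos, pos, prev_label, name, seq[prev_pos:pos])
        )
        prev_pos, prev_label = pos, name
    fragments.append(
        Fragment(source_id, prev_pos, len(seq), prev_label, TERMINAL, seq[prev_pos:])
    )
    return fragments


def adapter_compatible(
    fragments: Iterable[Fragment],
    enzyme_a: str = "MluI",
    enzyme_b: str = "SbfI",
) -> list[Fragment]:
    """Keep the fragments that would amplify after Y-adapter ligation.

    Only fragments carrying one ``enzyme_a`` end and one ``enzyme_b`` end (in
    either orientation) amplify exponentially; same-enzyme and terminal-ended
    fragments are removed.
    """
    wanted = {enzyme_a, enzyme_b}
    return [f for f in fragments if {f.left_end, f.right_end} == wanted]


def size_select(
    fragments: Iterable[Fragment], min_len: int = 500, max_len: int = 2000
) -> list[Fragment]:
    """Keep fragments with ``min_len <= length <= max_len`` (both inclusive)."""
    if not 0 < min_len <= max_len:
        raise ConfigError(f"bad size window [{min_len}, {max_len}]")
    return [f for f in fragments if min_len <= len(f) <= max_len]


def _orient_mlui_left(frag: Fragment, mlui_name: str) -> Fragment:
    """Normalise fragment orientation so the MluI-cut end is leftmost."""
    if frag.left_end == mlui_name:
        return frag
    return Fragment(
        frag.source_id, frag.start, frag.end,
        frag.right_end, frag.left_end, revcomp(frag.sequence),
    )


def selective_amplify(
    fragments: Iterable[Fragment],
    combo: SelectiveCombination,
    mlui: RestrictionEnzyme = MLUI,
    sbfi: RestrictionEnzyme = SBFI,
) -> tuple[list[Fragment], int]:
    """Apply one selective-primer combination to adapter-compatible fragments.

    The forward selective base is tested on the sense strand immediately 3' of
    the MluI site remnant (the fragment is oriented MluI-end left); the
    reverse base on the antisense strand immediately 3' of the SbfI remnant —
    the primer-extension direction on each strand. ``None`` on a side means no
    selection. N at a tested position never matches.

    Returns ``(retained fragments, too_short_count)`` where the tally counts
    fragments too short to expose both tested positions.
    """
    left_remnant = len(mlui.recognition_site) - mlui.cut_offset
    right_remnant = sbfi.cut_offset
    min_testable = left_remnant + right_remnant + 2

    retained: list[Fragment] = []
    too_short = 0
    for frag in fragments:
        frag = _orient_mlui_left(frag, mlui.name)
        if len(frag) < min_testable:
            too_short += 1
            continue
        if combo.forward_base is not None:
            sense_base = frag.sequence[left_remnant]
            if sense_base != combo.forward_base:
                continue
        if combo.reverse_base is not None:
            antisense_base = revcomp(frag.sequence)[right_remnant]
            if antisense_base != combo.reverse_base:
                continue
        retained.append(frag)
    return retained, too_short


def pool_baits(
    fragments: Iterable[Fragment],
    combos: Sequence[SelectiveCombination],
    mlui: RestrictionEnzyme = MLUI,
    sbfi: RestrictionEnzyme = SBFI,
) -> BaitSet:
    """Pool the selective-amplification products of several combinations.

    The bait set is the union over combinations, deduplicated by source
    coordinates. A warning is emitted when the pooled bait count falls
    outside the recommended complexity window for efficient capture.
    """
    if not combos:
        raise ConfigError("at least one selective combination is required")
    fragments = list(fragments)
    seen: dict[tuple[str, int, int], Fragment] = {}
    total_too_short = 0
    for combo in combos:
        kept, too_short = selective_amplify(fragments, combo, mlui, sbfi)
        total_too_short = max(total_too_short, too_short)
        for frag in kept:
            seen.setdefault(frag.key, frag)
    pooled = sorted(seen.values(), key=lambda f: f.key)

    lengths = [len(f) for f in pooled]
    gc = (
        sum(f.sequence.count("G") + f.sequence.count("C") for f in pooled)
        / max(1, sum(lengths))
    )
    summary = {
        "n_baits": len(pooled),
        "n_input_fragments": len(fragments),
        "n_too_short_to_test": total_too_short,
        "length_min": min(lengths) if lengths else 0,
        "length_mean": statistics.fmean(lengths) if lengths else 0.0,
        "length_max": max(lengths) if lengths else 0,
        "gc_fraction": gc,
    }
    lo, hi = BAIT_COUNT_RECOMMENDED
    if not lo <= len(pooled) <= hi:
        warnings.warn(
            f"bait count {len(pooled)} outside the recommended window "
            f"[{lo}, {hi}] for efficient capture",
            stacklevel=2,
        )
    return BaitSet(pooled, list(combos), summary)


def bait_fasta_records(baits: BaitSet) -> Iterable[tuple[str, str]]:
    """(header, sequence) pairs for bait FASTA output.

    Headers encode 0-based half-open source coordinates and end labels:
    ``srcID:start-end|left=MluI|right=SbfI``.
    """
    for f in baits.fragments:
        yield (
            f"{f.source_id}:{f.start}-{f.end}|left={f.left_end}|right={f.right_end}",
            f.sequence,
        )
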