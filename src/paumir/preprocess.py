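"""Raw small-RNA read cleaning and unique-tag collapsing.

Sequenced small-RNA inserts arrive with a 3' sequencing adapter, a tail of
technical contaminants (adapter dimers, poly(A) carry-over, low-quality
calls) and a broad length range; the biologically meaningful unit downstream
is the 18-30 nt *unique tag* with its read count.  This module reproduces the
standard cleaning cascade — quality filter, 3' adapter trim, contaminant
rejection, length window — and collapses the survivors into a
:class:`TagLibrary` whose ``clean_total`` (the total number of clean reads,
not the number of unique tags) is the denominator used later for
reads-per-million normalisation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "RawRead",
    "CleaningParams",
    "TagLibrary",
    "filter_raw_reads",
    "collapse_tags",
    "length_distribution",
]

#: rejection reasons, in the order the rules are applied
REJECT_REASONS = (
    "low_quality",
    "adapter_contaminated",
    "n_bases",
    "poly_a",
    "oversize",
    "undersize",
)


@dataclass(frozen=True)
class RawRead:
    """One sequencer read: identifier, base calls and optional Phred scores."""

    identifier: str
    sequence: str
    quality: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.identifier!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.identifier!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class CleaningParams:
    """Thresholds of the cleaning cascade.

    The length window [18, 30] nt is the gel-selected insert range; the other
    defaults (mean Phred >= 20, any N rejected, >= 80% A counted as poly(A),
    adapter matched with minimum 6 nt overlap and at most 1 mismatch) are
    conventional Illumina-era choices and are all configurable.
    """

    adapter_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_5p: str = ""
    min_mean_quality: float = 20.0
    polya_fraction: float = 0.8
    min_length: int = 18
    max_length: int = 30
    adapter_min_overlap: int = 6
    adapter_max_mismatches: int = 1
    trim_adapter: bool = True

    def __post_init__(self) -> None:
        if self.trim_adapter and not self.adapter_3p:
            raise ValueError("adapter trimming requested but adapter_3p is empty")


@dataclass
class TagLibrary:
    """Collapsed unique tags of one library plus its clean-read total.

    ``clean_total`` is recorded independently of the tag map: it counts every
    clean read of the library, including reads later annotated away, because
    it is the normalisation denominator.
    """

    name: str
    tags: dict[str, int] = field(default_factory=dict)
    clean_total: int = 0

    def __post_init__(self) -> None:
        for seq, count in self.tags.items():
            if not (18 <= len(seq) <= 30):
                raise ValueError(f"tag {seq!r} outside the 18-30 nt window")
            if count < 1:
                raise ValueError(f"tag {seq!r} has non-positive count {count}")
        if self.tags and self.clean_total <= 0:
            raise ValueError("clean_total must be positive for a non-empty library")


def _find_adapter(seq: str, adapter: str, min_overlap: int, max_mm: int) -> int:
    """Return the leftmost start of a 3' adapter occurrence, or -1.

    The adapter may occur in full inside the read, or as a prefix of the
    adapter matching the read's suffix; both are searched with at most
    ``max_mm`` mismatches and at least ``min_overlap`` matched bases.
    """
    n, m = len(seq), len(adapter)
    for start in range(0, n - min_overlap + 1):
        k = min(m, n - start)
        if k < min_overlap:
            break
        mm = 0
        ok = True
        for j in range(k):
            if seq[start + j] != adapter[j]:
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            return start
    return -1


def trim_adapter_3p(seq: str, params: CleaningParams) -> str:
    """Trim the 3' adapter from a read; returns '' for adapter-only reads."""
    pos = _find_adapter(seq, params.adapter_3p, params.adapter_min_overlap,
                        params.adapter_max_mismatches)
    return seq if pos < 0 else seq[:pos]


def filter_raw_reads(
    reads: Iterable[RawRead], params: CleaningParams = CleaningParams()
) -> tuple[list[RawRead], Counter]:
    """Apply the cleaning cascade; return surviving reads and a rejection tally.

    Rules are applied per read in a fixed order, and the first failing rule
    claims the read, so the tally plus the retained count always partitions
    the input:

    1. low_quality          — mean Phred below threshold (FASTA input skips this)
    2. adapter trimming     — 3' adapter removed before any length test
    3. adapter_contaminated — nothing left after trimming, or 5' adapter present
    4. n_bases              — any ambiguous base in the trimmed insert
    5. poly_a               — >= ``polya_fraction`` of the trimmed insert is A
    6. oversize / undersize — trimmed length outside [min_length, max_length]
    """
    kept: list[RawRead] = []
    tally: Counter = Counter({k: 0 for k in REJECT_REASONS})
    for read in reads:
        if read.quality is not None:
            mean_q = sum(read.quality) / len(read.quality)
            if mean_q < params.min_mean_quality:
                tally["low_quality"] += 1
                continue
        seq = read.sequence
        if params.trim_adapter:
            seq = trim_adapter_3p(seq, params)
        if not seq or (
            params.adapter_5p
            and _find_adapter(seq, params.adapter_5p, params.adapter_min_overlap,
                              params.adapter_max_mismatches) == 0
        ):
            tally["adapter_contaminated"] += 1
            continue
        if any(b not in "ACGT" for b in seq):
            tally["n_bases"] += 1
            continue
        if seq.count("A") / len(seq) >= params.polya_fraction:
            tally["poly_a"] += 1
            continue
        if len(seq) > params.max_length:
            tally["oversize"] += 1
            continue
        if len(seq) < params.min_length:
            tally["undersize"] += 1
            continue
        qual = None
        if read.quality is not None:
            qual = tuple(read.quality[: len(seq)])
        kept.append(RawRead(read.identifier, seq, qual))
    return kept, tally


def collapse_tags(clean_reads: Iterable[RawRead], name: str) -> TagLibrary:
    """Collapse length-filtered clean reads into unique tags with counts.

    ``clean_total`` is set to the number of input reads, so collapsing the
    full clean library records the normalisation denominator as a side effect.
    """
    tags: Counter = Counter()
    total = 0
    for read in clean_reads:
        tags[read.sequence] += 1
        total += 1
    return TagLibrary(name=name, tags=dict(tags), clean_total=total)


def length_distribution(lib: TagLibrary) -> dict[int, tuple[int, int]]:
    """Per-length (total reads, unique tags) summary of a tag library."""
    out: dict[int, tuple[int, int]] = {}
    for seq, count in lib.tags.items():
        total, unique = out.get(len(seq), (0, 0))
        out[len(seq)] = (total + count, unique + 1)
    return dict(sorted(out.items()))
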