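"""Tag annotation cascade: transcript mapping, structural ncRNA removal,
conserved miRNA matching, family aggregation.

Each unique tag receives exactly one class.  Structural ncRNAs (rRNA, tRNA,
snRNA, snoRNA, other ncRNA — what an Rfam/GenBank screen would remove) take
precedence over the mature-miRNA reference match; tags matching a reference
mature miRNA end-to-end with at most two mismatches are ``conserved_miRNA``;
everything else is ``unannotated`` and feeds hairpin discovery.  Transcript
mapping is annotational only (it records where a tag sits on the unigene
set) and does not affect the class.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .preprocess import TagLibrary

__all__ = [
    "NCRNA_CLASSES",
    "ReferenceSet",
    "AnnotatedTag",
    "revcomp",
    "map_tags_to_transcripts",
    "classify_ncrna",
    "match_conserved_mirna",
    "annotate_library",
    "assign_families",
    "family_name",
]

logger = logging.getLogger(__name__)

#: structural ncRNA classes in precedence order
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "other_ncRNA")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReferenceSet:
    """A named reference sequence collection (U normalised to T)."""

    name: str
    entries: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for ident, seq in self.entries.items():
            if not seq:
                raise ValueError(f"reference {ident!r} in set {self.name!r} is empty")
            clean[ident] = seq.upper().replace("U", "T")
        self.entries = clean


@dataclass
class AnnotatedTag:
    sequence: str
    counts: dict[str, int]
    annotation_class: str = "unannotated"
    best_match: Optional[tuple[str, int]] = None
    transcript_hits: list[tuple[str, int, str]] = field(default_factory=list)


def map_tags_to_transcripts(
    lib: TagLibrary | Iterable[str], transcripts: Mapping[str, str]
) -> dict[str, list[tuple[str, int, str]]]:
    """Exact full-length matches of each tag on either strand of each transcript.

    Coordinates are 1-based; ``start`` is always the leftmost matched
    position on the transcript's forward strand, with strand '+' or '-'.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    tags = lib.tags.keys() if isinstance(lib, TagLibrary) else lib
    hits: dict[str, list[tuple[str, int, str]]] = {}
    for tag in tags:
        found: list[tuple[str, int, str]] = []
        rc = revcomp(tag)
        for tid, tseq in transcripts.items():
            for query, strand in ((tag, "+"), (rc, "-")):
                start = tseq.find(query)
                while start >= 0:
                    found.append((tid, start + 1, strand))
                    start = tseq.find(query, start + 1)
        hits[tag] = found
    return hits


def classify_ncrna(tag: str, reference_sets: Iterable[ReferenceSet]) -> str:
    """Assign a structural ncRNA class by substring match, or 'unannotated'.

    A tag counts as a fragment of a reference entry if it (or its reverse
    complement) is an exact substring.  Sets are consulted in the fixed
    precedence order rRNA > tRNA > snRNA > snoRNA > other_ncRNA regardless of
    the order given.
    """
    by_name = {rs.name: rs for rs in reference_sets}
    rc = revcomp(tag)
    for cls in NCRNA_CLASSES:
        rs = by_name.get(cls)
        if rs is None:
            continue
        for seq in rs.entries.values():
            if tag in seq or rc in seq:
                return cls
    return "unannotated"


def _hamming_le(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings, or limit+1 once exceeded."""
    mm = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            mm += 1
            if mm > limit:
                return mm
    return mm


def match_conserved_mirna(
    tag: str, mature_ref: ReferenceSet, max_mismatches: int = 2
) -> Optional[tuple[str, int]]:
    """Best reference mature miRNA within the mismatch allowance, if any.

    The comparison is ungapped and end-to-end: references of the tag's
    length are compared directly; references longer by up to two nucleotides
    are slid over the tag (no indels are modelled).  The minimum-mismatch hit
    wins, ties broken by lexicographically smallest reference identifier.
    """
    best: Optional[tuple[int, str]] = None
    L = len(tag)
    for ident in sorted(mature_ref.entries):
        ref = mature_ref.entries[ident]
        if len(ref) == L:
            candidates = (ref,)
        elif L < len(ref) <= L + 2:
            candidates = tuple(ref[i : i + L] for i in range(len(ref) - L + 1))
        else:
            continue
        for window in candidates:
            mm = _hamming_le(tag, window, max_mismatches)
            if mm <= max_mismatches and (best is None or mm < best[0]):
                best = (mm, ident)
    if best is None:
        return None
    return best[1], best[0]


def annotate_library(
    libs: Mapping[str, TagLibrary],
    reference_sets: Iterable[ReferenceSet],
    mature_ref: Optional[ReferenceSet] = None,
    transcripts: Optional[Mapping[str, str]] = None,
    max_mismatches: int = 2,
) -> list[AnnotatedTag]:
    """Run the full cascade over the union of tags of one or more libraries."""
    reference_sets = list(reference_sets)
    all_tags: dict[str, dict[str, int]] = {}
    for lib_name, lib in libs.items():
        for seq, count in lib.tags.items():
            all_tags.setdefault(seq, {})[lib_name] = count
    hit_map = (
        map_tags_to_transcripts(all_tags.keys(), transcripts) if transcripts else {}
    )
    annotated: list[AnnotatedTag] = []
    for seq, counts in sorted(all_tags.items()):
        tag = AnnotatedTag(seq, counts, transcript_hits=hit_map.get(seq, []))
        cls = classify_ncrna(seq, reference_sets)
        if cls != "unannotated":
            tag.annotation_class = cls
        elif mature_ref is not None:
            match = match_conserved_mirna(seq, mature_ref, max_mismatches)
            if match is not None:
                tag.annotation_class = "conserved_miRNA"
                tag.best_match = match
        annotated.append(tag)
    return annotated


_FAMILY_RE = re.compile(r"mir[-]?0*(\d+)", re.IGNORECASE)


def family_name(mirna_id: str) -> str:
    """Extract the miRNA family (e.g. 'pas-miR166a-3p' -> 'MIR166')."""
    m = _FAMILY_RE.search(mirna_id)
    if m is None:
        logger.warning("cannot parse a miRNA family from %r", mirna_id)
        return "UNKNOWN"
    return f"MIR{m.group(1)}"


def assign_families(
    hits: Mapping[str, Mapping[str, int]],
    families: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Aggregate per-miRNA counts into a family table.

    ``hits`` maps miRNA identifier -> {library: count}; ``families`` may
    override the family parsed from each identifier.  Returns a tidy frame
    with one row per (family, miRNA) plus per-library family totals and the
    family's share of all counts, in percent.
    """
    if not hits:
        return pd.DataFrame(
            columns=["family", "mirna", "library", "count", "family_total", "share_pct"]
        )
    rows = []
    for mirna in sorted(hits):
        fam = families[mirna] if families else family_name(mirna)
        for lib_name, count in sorted(hits[mirna].items()):
            rows.append({"family": fam, "mirna": mirna, "library": lib_name, "count": count})
    df = pd.DataFrame(rows)
    totals = df.groupby(["family", "library"])["count"].transform("sum")
    grand = df.groupby("library")["count"].transform("sum")
    df["family_total"] = totals
    df["share_pct"] = 100.0 * totals / grand
    return df
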