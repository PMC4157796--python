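"""Degradome-guided miRNA target calling with t-plot categorisation.

Degradome (PARE) tags are the 5' ends of uncapped mRNA fragments; a
miRNA-sliced transcript leaves an abundant tag whose 5' end sits exactly at
the cleavage position, between the target bases paired to miRNA positions
10 and 11.  Targets are called by scanning each transcript for windows
complementary to a miRNA under the plant scoring convention (Watson-Crick
pair 0, G:U wobble 0.5, mismatch 1, gap 2; total score <= 4; strict
Watson-Crick pairing required opposite miRNA positions 10 and 11), then
requiring degradome signal at the predicted slice position.  Events are
categorised from the transcript's signature profile: the slice abundance
equal to the transcript maximum is category I, above the median of observed
signatures but below the maximum is II, at or below the median is III.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .annotation import revcomp

__all__ = [
    "ScoringParams",
    "SignatureProfile",
    "TargetAlignment",
    "CleavageEvent",
    "map_degradome_tags",
    "score_site",
    "scan_sites",
    "predict_slice_position",
    "categorize_event",
    "call_targets",
    "t_plot_series",
    "alignment_text",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
#: penalty[mirna_base, site_base] on the transcript sense strand: the miRNA
#: base pairs the site base when the site base is its reverse complement.
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # rG:rU wobble, written in DNA alphabet


@dataclass(frozen=True)
class ScoringParams:
    """Complementarity penalties and thresholds of the plant target screen."""

    gu_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    gap_penalty: float = 2.0
    max_score: float = 4.0
    slice_positions: tuple[int, int] = (10, 11)  # 1-based from the miRNA 5' end
    min_slice_reads: int = 1


@dataclass
class SignatureProfile:
    """Per-transcript degradome signature: 5'-end read counts by position."""

    transcript_id: str
    abundance: dict[int, int] = field(default_factory=dict)
    multimapped: set[int] = field(default_factory=set)

    def maximum(self) -> int:
        return max(self.abundance.values())

    def median(self) -> float:
        """Median over positions carrying at least one signature read."""
        return statistics.median(self.abundance.values())


@dataclass(frozen=True)
class TargetAlignment:
    """A scored miRNA:site duplex.

    ``pairing`` has one column per alignment position, 5'->3' along the
    miRNA (i.e. 3'->5' along the site): '|' Watson-Crick, 'o' G:U wobble,
    'x' mismatch, '-' gap.  For gapped alignments ``mirna_aln``/``site_aln``
    carry the '-'-padded strings (site written 3'->5' so columns line up).
    """

    mirna_id: str
    mirna_seq: str  # 5'->3', ungapped
    transcript_id: str
    site_start: int  # 1-based inclusive, transcript sense strand
    site_end: int
    score: float
    pairing: str
    site_seq: str = ""  # transcript sense strand, 5'->3'
    mirna_aln: str = ""  # only for gapped alignments
    site_aln: str = ""


@dataclass(frozen=True)
class CleavageEvent:
    alignment: TargetAlignment
    slice_position: int
    slice_abundance: int
    category: str  # "I" | "II" | "III"
    multimapped: bool = False


def _pair_class(mirna_base: str, site_base: str) -> str:
    if (mirna_base, site_base) in _WC:
        return "|"
    if (mirna_base, site_base) in _GU:
        return "o"
    return "x"


def map_degradome_tags(
    tags: Mapping[str, int], transcripts: Mapping[str, str]
) -> dict[str, SignatureProfile]:
    """Map degradome tags sense-strand, perfect-match, to 5'-end profiles.

    A tag's count is added at the transcript position of its 5'-most aligned
    base; tags matching more than one locus contribute to every locus and
    those positions are flagged ``multimapped``.
    """
    lengths = sorted({len(t) for t in tags})
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, tseq in transcripts.items():
        for L in lengths:
            for pos in range(0, len(tseq) - L + 1):
                index.setdefault(tseq[pos : pos + L], []).append((tid, pos + 1))
    profiles: dict[str, SignatureProfile] = {}
    for tag, count in tags.items():
        loci = index.get(tag, [])
        for tid, pos in loci:
            prof = profiles.setdefault(tid, SignatureProfile(tid))
            prof.abundance[pos] = prof.abundance.get(pos, 0) + count
            if len(loci) > 1:
                prof.multimapped.add(pos)
    return profiles


def score_site(
    mirna: str, site: str, params: ScoringParams = ScoringParams()
) -> Optional[tuple[float, str]]:
    """Score an ungapped miRNA:site duplex; None when the site is rejected.

    ``site`` is the transcript sense sequence, same length as the miRNA;
    miRNA position i (1-based, 5'->3') is evaluated against site base
    ``site[L-i]`` (the site read 3'->5').  Rejection: total score above
    ``max_score`` or non-Watson-Crick pairing opposite miRNA positions
    10/11 (G:U does not count as a pair at the cleavage site).
    """
    mirna = mirna.upper().replace("U", "T")
    site = site.upper().replace("U", "T")
    if any(b not in "ACGT" for b in mirna + site):
        raise ValueError("sequences must be over A/C/G/U/T")
    if len(mirna) != len(site):
        raise ValueError("ungapped scoring requires equal lengths")
    L = len(mirna)
    pairing = []
    score = 0.0
    for i in range(L):
        cls = _pair_class(mirna[i], site[L - 1 - i])
        pairing.append(cls)
        if cls == "o":
            score += params.gu_penalty
        elif cls == "x":
            score += params.mismatch_penalty
    for p in params.slice_positions:
        if pairing[p - 1] != "|":
            return None
    if score > params.max_score:
        return None
    return score, "".join(pairing)


def score_gapped_alignment(
    mirna_gapped: str, site_gapped: str, params: ScoringParams = ScoringParams()
) -> Optional[tuple[float, str]]:
    """Score an explicit gapped alignment ('-' for gaps, site given 3'->5'
    relative to the miRNA, i.e. both strings aligned column by column).

    Each gapped column costs ``gap_penalty``; a gap or non-WC column opposite
    miRNA positions 10/11 rejects the alignment.
    """
    if len(mirna_gapped) != len(site_gapped):
        raise ValueError("aligned strings must have equal length")
    score = 0.0
    pairing = []
    mpos = 0
    slice_cols = set(params.slice_positions)
    for mb, sb in zip(mirna_gapped.upper(), site_gapped.upper()):
        if mb == "-" or sb == "-":
            score += params.gap_penalty
            cls = "-"
        else:
            cls = _pair_class(mb.replace("U", "T"), sb.replace("U", "T"))
            score += {"|": 0.0, "o": params.gu_penalty, "x": params.mismatch_penalty}[cls]
        if mb != "-":
            mpos += 1
            if mpos in slice_cols and cls != "|":
                return None
        pairing.append(cls)
    if score > params.max_score:
        return None
    return score, "".join(pairing)


def scan_sites(
    mirna: str,
    transcript: str,
    params: ScoringParams = ScoringParams(),
) -> list[tuple[int, float, str]]:
    """All accepted ungapped sites of a miRNA on one transcript (vectorised).

    Returns (site_start 1-based, score, pairing string) triples.
    """
    mirna = mirna.upper().replace("U", "T")
    L = len(mirna)
    n = len(transcript)
    if n < L:
        return []
    t = np.frombuffer(transcript.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)  # (n-L+1, L)
    # column j of the window faces miRNA position L-j (1-based L-j ... ugh):
    # miRNA position i (0-based) pairs site base at window column L-1-i
    m = np.array([_ENC.get(b, -1) for b in mirna], dtype=np.int8)
    penalty = np.full((4, 256), params.mismatch_penalty)
    # site bases by ASCII code
    codes = {b: ord(b) for b in "ACGT"}
    for (mb, sb) in _WC:
        penalty[_ENC[mb], codes[sb]] = 0.0
    for (mb, sb) in _GU:
        penalty[_ENC[mb], codes[sb]] = params.gu_penalty
    site_cols = windows[:, ::-1]  # column i now faces miRNA position i
    pen = penalty[m[None, :], site_cols]  # (n_windows, L)
    scores = pen.sum(axis=1)
    wc_ok = np.ones(len(windows), dtype=bool)
    for p in params.slice_positions:
        wc_ok &= pen[:, p - 1] == 0.0
    accept = np.flatnonzero((scores <= params.max_score) & wc_ok)
    out = []
    for idx in accept:
        site = transcript[idx : idx + L]
        scored = score_site(mirna, site, params)
        if scored is not None:  # re-derive the pairing string exactly
            out.append((int(idx) + 1, scored[0], scored[1]))
    return out


def predict_slice_position(alignment: TargetAlignment, slice_pos: int = 10) -> int:
    """Transcript coordinate of the base paired to miRNA position 10.

    For an ungapped site [s, s+L-1] this is s + (L - 10).  Gapped alignments
    are resolved by walking the aligned columns from the miRNA 5' end (the
    site's 3' end): the walk tracks how many site bases have been consumed
    when the miRNA's 10th base is reached.
    """
    if "-" not in alignment.pairing:
        L = len(alignment.mirna_seq)
        return alignment.site_start + (L - slice_pos)
    if not (alignment.mirna_aln and alignment.site_aln):
        raise ValueError("gapped alignment requires mirna_aln/site_aln strings")
    mpos = 0
    site_consumed = 0
    for mb, sb in zip(alignment.mirna_aln, alignment.site_aln):
        if mb != "-":
            mpos += 1
        if mpos == slice_pos and mb != "-":
            if sb == "-":
                raise ValueError("gap opposite the cleavage position")
            return alignment.site_end - site_consumed
        if sb != "-":
            site_consumed += 1
    raise ValueError("alignment shorter than the slice position")


def categorize_event(
    slice_position: int,
    profile: SignatureProfile,
) -> Optional[str]:
    """Three-way t-plot category of a slice position, or None without signal.

    Category I: abundance equals the transcript maximum (ties allowed);
    II: above the median of positions with >= 1 read but below the maximum;
    III: at or below that median.
    """
    reads = profile.abundance.get(slice_position, 0)
    if reads < 1:
        return None
    if reads == profile.maximum():
        return "I"
    if reads > profile.median():
        return "II"
    return "III"


def call_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    profiles: Mapping[str, SignatureProfile],
    params: ScoringParams = ScoringParams(),
    exclude_regions: Optional[Mapping[str, Iterable[tuple[int, int]]]] = None,
) -> list[CleavageEvent]:
    """Scan, require degradome signal at the slice site, and categorise.

    ``exclude_regions`` maps transcript id to 1-based spans whose sites are
    suppressed — conventionally the miRNA-generating hairpin loci, whose
    star arms are trivially self-complementary and would otherwise surface
    as targets.  At most one event is emitted per (miRNA, transcript, slice
    position); alternative alignments there resolve to the lowest score,
    then the leftmost site.  Events are sorted by (category, descending
    slice abundance).
    """
    events: dict[tuple[str, str, int], tuple[float, int, CleavageEvent]] = {}
    excludes = {
        tid: list(spans) for tid, spans in (exclude_regions or {}).items()
    }
    for mid in sorted(mirnas):
        mseq = mirnas[mid].upper().replace("U", "T")
        for tid in sorted(transcripts):
            profile = profiles.get(tid)
            if profile is None:
                continue
            for start, score, pairing in scan_sites(mseq, transcripts[tid], params):
                end = start + len(mseq) - 1
                if any(not (end < s or start > e) for s, e in excludes.get(tid, ())):
                    continue
                aln = TargetAlignment(
                    mid, mseq, tid, start, start + len(mseq) - 1, score, pairing,
                    site_seq=transcripts[tid][start - 1 : start - 1 + len(mseq)],
                )
                slice_pos = predict_slice_position(aln, params.slice_positions[0])
                reads = profile.abundance.get(slice_pos, 0)
                if reads < params.min_slice_reads:
                    continue
                category = categorize_event(slice_pos, profile)
                if category is None:
                    continue
                event = CleavageEvent(
                    aln, slice_pos, reads, category,
                    multimapped=slice_pos in profile.multimapped,
                )
                key = (mid, tid, slice_pos)
                rank = (score, start)
                if key not in events or rank < events[key][:2]:
                    events[key] = (score, start, event)
    order = {"I": 0, "II": 1, "III": 2}
    out = [e for _, _, e in events.values()]
    out.sort(key=lambda e: (order[e.category], -e.slice_abundance,
                            e.alignment.mirna_id, e.alignment.transcript_id))
    return out


def t_plot_series(
    profile: SignatureProfile, slice_positions: Iterable[int] = ()
) -> pd.DataFrame:
    """Signature abundance by position with the slice position(s) flagged."""
    slices = set(slice_positions)
    rows = [
        {"position": pos, "abundance": profile.abundance[pos], "is_slice": pos in slices}
        for pos in sorted(profile.abundance)
    ]
    return pd.DataFrame(rows, columns=["position", "abundance", "is_slice"])


def render_tplot(profile: SignatureProfile, slice_positions: Iterable[int], path) -> None:
    """Optional graphical t-plot (abundance vs position, slice site marked)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = t_plot_series(profile, slice_positions)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.vlines(df["position"], 0, df["abundance"], color="grey", lw=1)
    hit = df[df["is_slice"]]
    ax.plot(hit["position"], hit["abundance"], "rv", label="slice site")
    ax.set_xlabel("transcript position (nt)")
    ax.set_ylabel("degradome reads")
    ax.set_title(profile.transcript_id)
    if len(hit):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def alignment_text(event: CleavageEvent) -> str:
    """Readable miRNA:site alignment block (| WC, o G:U, x mismatch).

    The target site is printed 5'->3' on top, the miRNA 3'->5' underneath,
    with the slice position marked by an asterisk.
    """
    aln = event.alignment
    site = aln.site_seq or revcomp(aln.mirna_seq)
    offset = event.slice_position - aln.site_start
    lines = [
        f"{aln.transcript_id}:{aln.site_start}-{aln.site_end}",
        " " * (3 + offset) + "*",
        "5' " + site + " 3'   (target)",
        "   " + aln.pairing[::-1],
        "3' " + aln.mirna_seq[::-1] + " 5'   ({})".format(aln.mirna_id),
        f"score {aln.score:g}, slice at {event.slice_position}, "
        f"{event.slice_abundance} reads, category {event.category}",
    ]
    return "\n".join(lines)
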