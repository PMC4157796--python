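"""Novel miRNA discovery from unannotated transcript-mapped tags.

A candidate miRNA must sit in one arm of a single stem-loop whose predicted
minimum-free-energy structure satisfies the community hairpin criteria
(mature length 20-23 nt, duplex mismatches <= 4, bulged nucleotides <= 2,
MFE <= -18 kcal/mol, precursor 60-300 nt, one terminal loop).  Around every
transcript position carrying an unannotated tag two precursor windows are
excised (tag at the 5' end with a downstream flank, and at the 3' end with
an upstream flank), folded, and screened; detection of the star strand (the
duplex partner offset by the canonical 2-nt 3' overhangs) in the sequenced
libraries is recorded as additional evidence.

Folding is a pluggable contract.  The default engine is the ViennaRNA
thermodynamic nearest-neighbour implementation (``import RNA``); a
deterministic base-pair-maximisation fallback with a crude per-pair energy
model (GC -3, AU -2, GU -1 kcal/mol, minimum loop 3) keeps the module
self-contained, at documented lower fidelity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional

from .annotation import revcomp
from .preprocess import TagLibrary

__all__ = [
    "FoldResult",
    "MeyersCriteria",
    "HairpinCandidate",
    "fold_rna",
    "pair_table",
    "excise_precursor_windows",
    "evaluate_candidate",
    "detect_star",
    "discover_mirnas",
    "summarize_candidates",
]


@dataclass(frozen=True)
class FoldResult:
    """A sequence with its MFE dot-bracket structure (kcal/mol, <= 0)."""

    sequence: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure/sequence length mismatch")
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")
        if self.mfe > 0:
            raise ValueError("MFE must be <= 0")


@dataclass(frozen=True)
class MeyersCriteria:
    """Numeric hairpin acceptance thresholds (all configurable)."""

    mature_length: tuple[int, int] = (20, 23)
    max_duplex_mismatches: int = 4
    max_bulges: int = 2
    max_mfe: float = -18.0
    precursor_length: tuple[int, int] = (60, 300)
    overhang: int = 2


@dataclass
class HairpinCandidate:
    transcript_id: str
    start: int  # 1-based, inclusive, transcript forward strand
    end: int
    strand: str
    fold: FoldResult
    mature: str
    mature_arm: str  # "5p" | "3p"
    mature_counts: dict[str, int]
    star: Optional[str] = None
    star_counts: dict[str, int] = field(default_factory=dict)
    duplex_mismatches: int = 0
    bulged_nucleotides: int = 0
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.flags) and all(self.flags.values())

    @property
    def precursor(self) -> str:
        return self.fold.sequence


# ---------------------------------------------------------------------------
# folding engines

def _vienna_fold(seq: str) -> tuple[str, float]:
    import RNA

    structure, mfe = RNA.fold(seq.replace("T", "U"))
    return structure, float(mfe)


_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}


def _nussinov_fold(seq: str, min_loop: int = 3) -> tuple[str, float]:
    """Deterministic energy-weighted base-pair maximisation (fallback engine).

    Dynamic programme over pair energies only (no stacking or loop terms),
    ties broken toward the unpaired/leftmost solution so the traceback is
    unique.  Lower fidelity than a thermodynamic engine; suitable for the
    idealised stems the simulator plants and as an engine-free default.
    """
    n = len(seq)
    E = [[0.0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1][j]  # i unpaired
            pair = _PAIR_ENERGY.get((seq[i], seq[j]))
            if pair is not None:
                inner = E[i + 1][j - 1] if i + 1 <= j - 1 else 0.0
                best = min(best, pair + inner)
            for k in range(i + min_loop + 1, j):
                pk = _PAIR_ENERGY.get((seq[i], seq[k]))
                if pk is not None:
                    left = E[i + 1][k - 1] if i + 1 <= k - 1 else 0.0
                    right = E[k + 1][j] if k + 1 <= j else 0.0
                    best = min(best, pk + left + right)
            E[i][j] = best
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if E[i][j] == (E[i + 1][j] if i + 1 <= j else 0.0):
                i += 1
                continue
            pair = _PAIR_ENERGY.get((seq[i], seq[j]))
            if pair is not None:
                inner = E[i + 1][j - 1] if i + 1 <= j - 1 else 0.0
                if abs(E[i][j] - (pair + inner)) < 1e-9:
                    structure[i], structure[j] = "(", ")"
                    i, j = i + 1, j - 1
                    continue
            for k in range(i + min_loop + 1, j):
                pk = _PAIR_ENERGY.get((seq[i], seq[k]))
                if pk is None:
                    continue
                left = E[i + 1][k - 1] if i + 1 <= k - 1 else 0.0
                right = E[k + 1][j] if k + 1 <= j else 0.0
                if abs(E[i][j] - (pk + left + right)) < 1e-9:
                    structure[i], structure[k] = "(", ")"
                    traceback(i + 1, k - 1)
                    i = k + 1
                    break
            else:  # pragma: no cover - defensive
                i += 1

    traceback(0, n - 1)
    return "".join(structure), E[0][n - 1]


@lru_cache(maxsize=1)
def _have_vienna() -> bool:
    try:
        import RNA  # noqa: F401
        return True
    except ImportError:
        return False


def fold_rna(sequence: str, engine: str = "auto") -> FoldResult:
    """Predict the MFE secondary structure of an RNA sequence.

    ``engine`` is "vienna", "fallback", or "auto" (vienna when importable).
    """
    seq = sequence.upper().replace("U", "T")
    if not seq or any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must be non-empty over A/C/G/U/T")
    if engine == "auto":
        engine = "vienna" if _have_vienna() else "fallback"
    if engine == "vienna":
        structure, mfe = _vienna_fold(seq)
    elif engine == "fallback":
        structure, mfe = _nussinov_fold(seq)
    else:
        raise ValueError(f"unknown folding engine {engine!r}")
    return FoldResult(seq, structure, min(mfe, 0.0))


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position, -1 where unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced structure")
    return pt


# ---------------------------------------------------------------------------
# precursor excision and evaluation

def excise_precursor_windows(
    hit: tuple[str, int, str],
    tag_length: int,
    transcripts: Mapping[str, str],
    flank: int = 150,
) -> list[tuple[str, int, int]]:
    """Candidate precursor windows around a mapped tag.

    Two windows per hit — the tag at the window's 5' end with a downstream
    flank, and at the 3' end with an upstream flank — clipped to transcript
    bounds and deduplicated.  Coordinates are 1-based inclusive.
    """
    tid, start, _strand = hit
    tseq = transcripts.get(tid)
    if tseq is None:
        raise ValueError(f"unknown transcript {tid!r}")
    end = start + tag_length - 1
    if start < 1 or end > len(tseq):
        raise ValueError(f"tag at {start}-{end} outside transcript {tid!r}")
    windows = [
        (tid, start, min(len(tseq), end + flank)),
        (tid, max(1, start - flank), end),
    ]
    out: list[tuple[str, int, int]] = []
    for w in windows:
        if w not in out:
            out.append(w)
    return out


def _duplex_stats(pt: list[int], m0: int, m1: int, overhang: int) -> tuple[int, int, bool]:
    """(mismatches, bulged nucleotides, on_single_arm) for mature at [m0, m1]."""
    paired = [i for i in range(m0, m1 + 1) if pt[i] != -1]
    if not paired:
        return m1 - m0 + 1, 0, False
    partners = [pt[i] for i in paired]
    if any(m0 <= p <= m1 for p in partners):
        return m1 - m0 + 1, 0, False  # pairs within the mature itself
    one_arm = all(p > m1 for p in partners) or all(p < m0 for p in partners)
    # unpaired overhangs: the 2-nt 3' overhang of the duplex is not a defect
    mism = (paired[0] - m0) + max(0, (m1 - paired[-1]) - overhang)
    bulges = 0
    for (i, j) in zip(paired, paired[1:]):
        a = j - i - 1
        b = abs(pt[i] - pt[j]) - 1
        mism += min(a, b)
        bulges += abs(a - b)
    return mism, bulges, one_arm


def _loop_count(structure: str, region: Optional[tuple[int, int]] = None) -> int:
    """Number of terminal (hairpin) loops, optionally within a sub-region.

    The one-terminal-loop criterion is judged over the stem-loop that hosts
    the miRNA duplex; accidental micro-hairpins folded by flanking sequence
    outside that stem-loop do not disqualify a candidate.
    """
    if region is not None:
        structure = structure[region[0] : region[1] + 1]
    return len(re.findall(r"\(\.*\)", structure))


def evaluate_candidate(
    fold: FoldResult,
    mature: str,
    mature_counts: Mapping[str, int],
    coords: tuple[str, int, int, str] = ("window", 1, 0, "+"),
    criteria: MeyersCriteria = MeyersCriteria(),
) -> HairpinCandidate:
    """Score one precursor window against the hairpin acceptance criteria.

    Returns a candidate with one boolean flag per criterion; the candidate
    passes iff all flags are true.
    """
    m0 = fold.sequence.find(mature)
    if m0 < 0:
        raise ValueError("mature sequence not found in the precursor window")
    m1 = m0 + len(mature) - 1
    pt = pair_table(fold.structure)
    mism, bulges, one_arm = _duplex_stats(pt, m0, m1, criteria.overhang)
    partners = [pt[i] for i in range(m0, m1 + 1) if pt[i] != -1]
    arm = "5p" if partners and partners[0] > m1 else "3p"
    if partners:
        stemloop = (min(m0, min(partners)), max(m1, max(partners)))
        loops = _loop_count(fold.structure, stemloop)
    else:
        loops = 0
    lo, hi = criteria.mature_length
    plo, phi = criteria.precursor_length
    flags = {
        "mature_length": lo <= len(mature) <= hi,
        "precursor_length": plo <= len(fold.sequence) <= phi,
        "single_arm": one_arm,
        "duplex_mismatches": mism <= criteria.max_duplex_mismatches,
        "bulged_nucleotides": bulges <= criteria.max_bulges,
        "mfe": fold.mfe <= criteria.max_mfe,
        "single_loop": loops == 1,
    }
    tid, start, end, strand = coords
    if end < start:
        end = start + len(fold.sequence) - 1
    return HairpinCandidate(
        transcript_id=tid, start=start, end=end, strand=strand,
        fold=fold, mature=mature, mature_arm=arm,
        mature_counts=dict(mature_counts),
        duplex_mismatches=mism, bulged_nucleotides=bulges, flags=flags,
    )


def detect_star(
    candidate: HairpinCandidate,
    libraries: Mapping[str, TagLibrary],
    overhang: int = 2,
) -> Optional[tuple[str, dict[str, int]]]:
    """Locate the star strand and read its per-library counts (0 allowed).

    The star is the duplex partner of the mature shifted by the canonical
    2-nt 3' overhang on each strand: its 3' end lies ``overhang`` positions
    past the partner of the mature's 5'-most paired base.  Returns None when
    no valid duplex position exists (e.g. the star would leave the
    precursor).
    """
    fold = candidate.fold
    pt = pair_table(fold.structure)
    m0 = fold.sequence.find(candidate.mature)
    m1 = m0 + len(candidate.mature) - 1
    partners = [pt[i] for i in range(m0, m1 + 1) if pt[i] != -1]
    if not partners:
        return None
    star_right = max(partners) + overhang
    star_left = star_right - len(candidate.mature) + 1
    if star_left < 0 or star_right >= len(fold.sequence):
        return None
    star_seq = fold.sequence[star_left : star_right + 1]
    counts = {name: lib.tags.get(star_seq, 0) for name, lib in libraries.items()}
    return star_seq, counts


def _refine_precursor(fold: FoldResult, mature: str, pad: int) -> Optional[tuple[int, int]]:
    """Trim a folded excision window to the stem-loop around the mature tag.

    Returns the (0-based, inclusive) sub-window spanning the mature and all
    its pairing partners, extended by ``pad`` nt each side — the flank of an
    excision window folds independently of the hairpin and would otherwise
    fail the single-stem-loop criterion.  None when the mature is entirely
    unpaired.
    """
    m0 = fold.sequence.find(mature)
    if m0 < 0:
        return None
    m1 = m0 + len(mature) - 1
    pt = pair_table(fold.structure)
    partners = [pt[i] for i in range(m0, m1 + 1) if pt[i] != -1]
    if not partners:
        return None
    lo = max(0, min(m0, min(partners)) - pad)
    hi = min(len(fold.sequence) - 1, max(m1, max(partners)) + pad)
    return lo, hi


# ---------------------------------------------------------------------------
# discovery driver

def discover_mirnas(
    tags: Iterable[tuple[str, dict[str, int], list[tuple[str, int, str]]]],
    transcripts: Mapping[str, str],
    libraries: Mapping[str, TagLibrary],
    criteria: MeyersCriteria = MeyersCriteria(),
    flank: int = 150,
    min_total_count: int = 3,
    engine: str = "auto",
    max_hits_per_tag: int = 10,
) -> list[HairpinCandidate]:
    """Full hairpin screen over unannotated tags with transcript hits.

    ``tags`` yields (sequence, per-library counts, transcript hits).  For
    each hit both precursor windows are folded and evaluated; when both
    pass, the window with the larger |MFE| per nucleotide is kept.
    Candidates whose precursors overlap on the same transcript are
    deduplicated in favour of the higher-count mature.
    """
    candidates: list[HairpinCandidate] = []
    for seq, counts, hits in tags:
        if sum(counts.values()) < min_total_count:
            continue
        for hit in hits[:max_hits_per_tag]:
            tid, start, strand = hit
            best: Optional[HairpinCandidate] = None
            for wtid, ws, we in excise_precursor_windows(hit, len(seq), transcripts, flank):
                window = transcripts[wtid][ws - 1 : we]
                mature = seq
                if strand == "-":
                    window = revcomp(window)
                if mature not in window:
                    continue
                wfold = fold_rna(window, engine=engine)
                span = _refine_precursor(wfold, mature, pad=15)
                if span is None:
                    continue
                sub = window[span[0] : span[1] + 1]
                lo, hi = criteria.precursor_length
                if not (lo <= len(sub) <= hi) or mature not in sub:
                    continue
                fold = fold_rna(sub, engine=engine)
                # precursor coordinates on the transcript forward strand
                if strand == "+":
                    ps, pe = ws + span[0], ws + span[1]
                else:
                    pe = we - span[0]
                    ps = we - span[1]
                cand = evaluate_candidate(
                    fold, mature, counts, coords=(wtid, ps, pe, strand), criteria=criteria
                )
                if not cand.passed:
                    continue
                if best is None or (
                    abs(fold.mfe) / len(sub)
                    > abs(best.fold.mfe) / len(best.precursor)
                ):
                    best = cand
            if best is not None:
                star = detect_star(best, libraries, criteria.overhang)
                if star is not None:
                    best.star, best.star_counts = star
                candidates.append(best)
    # deduplicate overlapping precursors on the same transcript
    candidates.sort(key=lambda c: (-sum(c.mature_counts.values()), c.transcript_id, c.start))
    kept: list[HairpinCandidate] = []
    for cand in candidates:
        clash = any(
            k.transcript_id == cand.transcript_id
            and not (cand.end < k.start or cand.start > k.end)
            for k in kept
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.transcript_id, c.start))
    return kept


def summarize_candidates(candidates: Iterable[HairpinCandidate]) -> dict[str, float]:
    """Report summary: candidate count, mean precursor length, mean MFE."""
    cands = list(candidates)
    if not cands:
        return {"n_candidates": 0, "mean_precursor_length": float("nan"),
                "mean_mfe": float("nan"), "n_with_star_reads": 0}
    return {
        "n_candidates": len(cands),
        "mean_precursor_length": sum(len(c.precursor) for c in cands) / len(cands),
        "mean_mfe": sum(c.fold.mfe for c in cands) / len(cands),
        "n_with_star_reads": sum(
            1 for c in cands if c.star_counts and sum(c.star_counts.values()) > 0
        ),
    }
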