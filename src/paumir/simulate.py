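"""Synthetic study generator: transcriptome, planted hairpins, two-condition
tag libraries, degradome tags, and contaminated raw reads, with a
machine-readable truth table.

The generator emulates the statistical shape of a two-genotype plant
small-RNA/degradome study: a unigene-style transcript set; miRNA precursors
planted as fold-verified stem-loops; per-miRNA read counts drawn with
Poisson sampling noise around configured RPM levels and log2 fold-changes
(one library per condition, so no overdispersion is identifiable);
degradome 5'-end tags concentrated at planted slice sites over a uniform
low-level background; and, for the cleaning filters, raw reads wrapped with
a 3' adapter plus counted contaminant classes.

Planted expression levels are bimodal by design — a low tier (a few RPM to
a few tens of RPM, like novel miRNA candidates) and a high tier (thousands
of RPM, like the dominant conserved families) — mirroring the dynamic range
such libraries actually show.  Large planted fold-changes ride on the high
tier, where a single-library Poisson design can actually resolve them.
All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import revcomp
from .preprocess import RawRead, TagLibrary
from .hairpin import MeyersCriteria, evaluate_candidate, fold_rna

__all__ = [
    "DuplexSpec",
    "PlantedHairpin",
    "PlantedCleavage",
    "TruthTable",
    "generate_transcriptome",
    "plant_hairpins",
    "plant_cleavage_sites",
    "simulate_libraries",
    "simulate_degradome",
    "simulate_raw_reads",
    "DEFAULT_RPM_TIERS",
    "DEFAULT_FC_CYCLE",
]

_BASES = np.array(list("ACGT"))

#: default per-miRNA expression levels (RPM), low tier then high tier
DEFAULT_RPM_TIERS = (
    (3.0, 5.0, 8.0, 10.0, 15.0, 20.0, 25.0, 30.0, 30.0, 40.0),
    (1000.0, 1500.0, 2000.0, 3000.0, 5000.0, 8000.0, 10000.0, 20000.0, 30000.0, 50000.0),
)
#: default true log2 fold-changes; strong effects are cycled on the high tier
DEFAULT_FC_CYCLE = ((0.0, 0.5, -0.5, 1.0, -1.0), (0.0, 1.0, -1.0, 2.0, -2.0, 3.0, -3.0))


@dataclass(frozen=True)
class DuplexSpec:
    """Geometry of planted miRNA/miRNA* duplexes."""

    mature_length: int = 21
    mismatches: int = 0
    bulges: int = 0
    overhang: int = 2
    stem_pad: int = 14  # extra fully-paired stem below the duplex, per side
    loop: str = "CAAGAAGAAC"

    def __post_init__(self) -> None:
        limits = MeyersCriteria()
        if not (limits.mature_length[0] <= self.mature_length <= limits.mature_length[1]):
            raise ValueError("mature length outside the 20-23 nt window")
        if self.mismatches > limits.max_duplex_mismatches:
            raise ValueError("requested duplex mismatches exceed the acceptance limit")
        if self.bulges > limits.max_bulges:
            raise ValueError("requested bulges exceed the acceptance limit")


@dataclass
class PlantedHairpin:
    name: str
    transcript_id: str
    start: int  # 1-based precursor span on the transcript
    end: int
    mature: str
    star: str
    arm: str


@dataclass
class PlantedCleavage:
    mirna: str
    transcript_id: str
    site_start: int
    slice_position: int
    peak_height: int


@dataclass
class TruthTable:
    seed: int
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    expression: dict[str, dict] = field(default_factory=dict)  # name -> levels/counts
    cleavage_sites: list[PlantedCleavage] = field(default_factory=list)
    contamination: dict[str, int] = field(default_factory=dict)

    def mature_sequences(self) -> dict[str, str]:
        return {h.name: h.mature for h in self.hairpins}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            seed=raw["seed"],
            hairpins=[PlantedHairpin(**h) for h in raw["hairpins"]],
            expression=raw["expression"],
            cleavage_sites=[PlantedCleavage(**c) for c in raw["cleavage_sites"]],
            contamination=raw["contamination"],
        )


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def generate_transcriptome(
    n_transcripts: int,
    mean_length: int = 1000,
    gc_content: float = 0.5,
    seed: int = 0,
    length_sd: int = 0,
) -> dict[str, str]:
    """Random uppercase-ACGT transcripts, reproducible given the seed."""
    if n_transcripts < 0 or mean_length <= 0:
        raise ValueError("transcript count and length must be positive")
    rng = np.random.default_rng([seed, 0x7478])  # domain-tagged stream
    out: dict[str, str] = {}
    for i in range(n_transcripts):
        length = mean_length
        if length_sd:
            length = max(200, int(rng.normal(mean_length, length_sd)))
        out[f"Unigene{i + 1}"] = _random_seq(rng, length, gc_content)
    return out


_NON_PAIRING = {"A": "C", "C": "A", "G": "A", "T": "C"}


def _build_precursor(
    rng: np.random.Generator, spec: DuplexSpec
) -> tuple[str, str, str, str]:
    """Construct one hairpin precursor; returns (precursor, mature, star, arm).

    The precursor is a perfect stem (mature-bearing arm + loop + reverse
    complement) optionally perturbed on the star-side arm: each requested
    duplex mismatch becomes a 1x1 internal loop (substitution opposite a
    mature base), each requested bulge a single-nucleotide insertion.  The
    star span follows the 2-nt 3' overhang duplex convention.
    """
    L = spec.mature_length
    p = spec.stem_pad
    mature = _random_seq(rng, L, gc=0.55)
    pad5 = _random_seq(rng, p, gc=0.6)
    pad3 = _random_seq(rng, p, gc=0.6)
    arm = "5p" if rng.random() < 0.5 else "3p"
    embed = mature if arm == "5p" else revcomp(mature)
    stem5 = pad5 + embed + pad3
    S = len(stem5)
    # the arm carrying the star (opposite the mature) receives the edits
    star_arm = list(revcomp(stem5)) if arm == "5p" else list(stem5)

    def star_local(k: int) -> int:
        """Star-arm index pairing mature base k (perfect-stem geometry)."""
        return (S - 1 - (p + k)) if arm == "5p" else (p + (L - 1 - k))

    n_edits = spec.mismatches + spec.bulges
    ks = (
        [int(k) for k in rng.choice(np.arange(3, L - 5), size=n_edits, replace=False)]
        if n_edits
        else []
    )
    for k in ks[: spec.mismatches]:
        star_arm[star_local(k)] = _NON_PAIRING[mature[k]]
    for t in sorted((star_local(k) for k in ks[spec.mismatches :]), reverse=True):
        star_arm.insert(t, str(rng.choice(_BASES)))
    ins_positions = sorted(star_local(k) for k in ks[spec.mismatches :])
    # star span on the star arm, in perfect-stem local coordinates
    if arm == "5p":
        sr = (S - 1 - p) + spec.overhang  # partner of mature 5' start + overhang
    else:
        sr = (p + L - 1) + spec.overhang
    sl = sr - L + 1
    for t in ins_positions:  # shift for the inserted bulged nucleotides
        if t < sl:
            sl += 1
            sr += 1
        elif t <= sr:
            sr += 1
    star = "".join(star_arm[sl : sr + 1])
    if arm == "5p":
        precursor = stem5 + spec.loop + "".join(star_arm)
    else:
        precursor = "".join(star_arm) + spec.loop + revcomp(stem5)
    return precursor, mature, star, arm


def plant_hairpins(
    transcripts: Mapping[str, str],
    n_hairpins: int,
    duplex_spec: DuplexSpec = DuplexSpec(),
    seed: int = 0,
    criteria: MeyersCriteria = MeyersCriteria(),
    engine: str = "auto",
    max_attempts: int = 20,
) -> tuple[dict[str, str], TruthTable]:
    """Insert fold-verified precursors; returns (updated transcriptome, truth).

    Each precursor is folded with the module's engine and re-checked against
    the acceptance criteria before insertion; a draw that fails (rare) is
    re-attempted with fresh sequence.  Transcripts too short to host a
    precursor are skipped with a warning entry in the truth contamination
    tally.
    """
    rng = np.random.default_rng([seed, 0x6870])  # domain-tagged stream
    truth = TruthTable(seed=seed)
    updated = dict(transcripts)
    tids = sorted(updated)
    if not tids:
        raise ValueError("cannot plant hairpins into an empty transcriptome")
    for i in range(n_hairpins):
        tid = tids[i % len(tids)]
        planted = None
        for _ in range(max_attempts):
            precursor, mature, star, arm = _build_precursor(rng, duplex_spec)
            fold = fold_rna(precursor, engine=engine)
            if mature not in fold.sequence:
                continue
            cand = evaluate_candidate(fold, mature, {}, criteria=criteria)
            if cand.passed:
                planted = (precursor, mature, star, arm)
                break
        if planted is None:  # pragma: no cover - construction is near-certain
            raise RuntimeError("could not construct a passing hairpin")
        precursor, mature, star, arm = planted
        tseq = updated[tid]
        if len(tseq) < len(precursor) + 40:
            truth.contamination["hairpin_skipped_short_transcript"] = (
                truth.contamination.get("hairpin_skipped_short_transcript", 0) + 1
            )
            continue
        pos = int(rng.integers(20, len(tseq) - len(precursor) - 20))
        updated[tid] = tseq[:pos] + precursor + tseq[pos + len(precursor):]
        truth.hairpins.append(
            PlantedHairpin(
                name=f"syn-mir{i + 1}",
                transcript_id=tid,
                start=pos + 1,
                end=pos + len(precursor),
                mature=mature,
                star=star,
                arm=arm,
            )
        )
    return updated, truth


def plant_cleavage_sites(
    transcripts: Mapping[str, str],
    mirnas: Mapping[str, str],
    truth: TruthTable,
    n_sites: int = 20,
    seed: int = 1,
) -> dict[str, str]:
    """Write perfect-complement target sites into transcripts and record the
    slice position (the base paired to miRNA position 10) in the truth table.

    Sites avoid planted precursor spans and transcript edges.
    """
    rng = np.random.default_rng([seed, 0x636c])  # domain-tagged stream
    updated = dict(transcripts)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for h in truth.hairpins:
        occupied.setdefault(h.transcript_id, []).append((h.start, h.end))
    tids = sorted(updated)
    names = sorted(mirnas)
    for i in range(n_sites):
        mid = names[i % len(names)]
        site = revcomp(mirnas[mid].upper().replace("U", "T"))
        L = len(site)
        for _ in range(200):
            tid = tids[int(rng.integers(len(tids)))]
            tseq = updated[tid]
            if len(tseq) < L + 80:
                continue
            start = int(rng.integers(30, len(tseq) - L - 30))  # 0-based
            span = (start + 1, start + L)
            if any(not (span[1] < s or span[0] > e) for s, e in occupied.get(tid, [])):
                continue
            updated[tid] = tseq[:start] + site + tseq[start + L:]
            occupied.setdefault(tid, []).append(span)
            truth.cleavage_sites.append(
                PlantedCleavage(
                    mirna=mid,
                    transcript_id=tid,
                    site_start=start + 1,
                    slice_position=start + 1 + (L - 10),
                    peak_height=0,  # filled by simulate_degradome
                )
            )
            break
        else:  # pragma: no cover - ample space in practice
            raise RuntimeError("could not place a cleavage site")
    return updated


def _assign_levels(
    truth: TruthTable,
    rpm_tiers: Sequence[Sequence[float]] = DEFAULT_RPM_TIERS,
    fc_cycle: Sequence[Sequence[float]] = DEFAULT_FC_CYCLE,
    fc_map: Optional[Mapping[str, float]] = None,
) -> None:
    """Attach per-miRNA condition-1 RPM and true log2 fold-change to truth."""
    low, high = rpm_tiers
    fc_low, fc_high = fc_cycle
    n = len(truth.hairpins)
    for i, h in enumerate(truth.hairpins):
        high_tier = i >= n // 2
        tier, fcs = (high, fc_high) if high_tier else (low, fc_low)
        j = i - n // 2 if high_tier else i
        rpm1 = tier[j % len(tier)]
        fc = fcs[j % len(fcs)]
        if fc_map is not None and h.name in fc_map:
            fc = fc_map[h.name]
        truth.expression[h.name] = {
            "rpm1": rpm1,
            "rpm2": rpm1 * 2.0 ** fc,
            "log2fc": fc,
        }


def simulate_libraries(
    truth: TruthTable,
    depth: int = 1_000_000,
    fc_map: Optional[Mapping[str, float]] = None,
    seed: int = 2,
    names: tuple[str, str] = ("cond1", "cond2"),
    star_fraction: float = 0.1,
    n_background: int = 200,
    background_length_weights: Optional[Mapping[int, float]] = None,
    overdispersion: Optional[float] = None,
    rpm_tiers: Sequence[Sequence[float]] = DEFAULT_RPM_TIERS,
    fc_cycle: Sequence[Sequence[float]] = DEFAULT_FC_CYCLE,
) -> tuple[TagLibrary, TagLibrary]:
    """Draw two condition libraries around the planted expression levels.

    Counts are Poisson with mean RPM x depth / 1e6 per condition (negative
    binomial with ``overdispersion`` (size parameter) when requested); star
    tags ride at ``star_fraction`` of the mature level; background tags are
    random sequences rejection-sampled to stay >= 3 mismatches from every
    planted mature so truth labels stay unambiguous.  Realized counts are
    written back into the truth table.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng([seed, 0x6c6962])  # domain-tagged stream
    if not truth.expression or fc_map:
        _assign_levels(truth, rpm_tiers=rpm_tiers, fc_cycle=fc_cycle, fc_map=fc_map)

    def draw(mean: float) -> int:
        if mean <= 0:
            return 0
        if overdispersion:
            p = overdispersion / (overdispersion + mean)
            return int(rng.negative_binomial(overdispersion, p))
        return int(rng.poisson(mean))

    tags1: dict[str, int] = {}
    tags2: dict[str, int] = {}
    matures = {h.name: h.mature for h in truth.hairpins}
    for h in truth.hairpins:
        levels = truth.expression[h.name]
        c1 = draw(levels["rpm1"] * depth / 1e6)
        c2 = draw(levels["rpm2"] * depth / 1e6)
        s1 = draw(star_fraction * levels["rpm1"] * depth / 1e6)
        s2 = draw(star_fraction * levels["rpm2"] * depth / 1e6)
        if c1:
            tags1[h.mature] = tags1.get(h.mature, 0) + c1
        if c2:
            tags2[h.mature] = tags2.get(h.mature, 0) + c2
        if s1:
            tags1[h.star] = tags1.get(h.star, 0) + s1
        if s2:
            tags2[h.star] = tags2.get(h.star, 0) + s2
        levels.update({"count1": c1, "count2": c2, "star1": s1, "star2": s2})
    # unannotated background tags
    n_bg = n_background if depth > 0 else 0
    weights = dict(background_length_weights or {21: 0.35, 22: 0.1, 23: 0.1, 24: 0.45})
    lengths = sorted(weights)
    p = np.array([weights[l] for l in lengths], dtype=float)
    p /= p.sum()
    made = 0
    while made < n_bg:
        L = int(rng.choice(lengths, p=p))
        seq = _random_seq(rng, L)
        if any(
            len(m) == L and sum(a != b for a, b in zip(seq, m)) <= 2
            for m in matures.values()
        ):
            continue
        c1 = draw(2.0)
        c2 = draw(2.0)
        if c1:
            tags1[seq] = c1
        if c2:
            tags2[seq] = c2
        made += 1
    total = depth if depth > 0 else 1
    return (
        TagLibrary(names[0], tags1, clean_total=total),
        TagLibrary(names[1], tags2, clean_total=total),
    )


def simulate_degradome(
    truth: TruthTable,
    transcripts: Mapping[str, str],
    peak_height: int = 50,
    background_rate: float = 0.1,
    seed: int = 3,
    tag_length: int = 20,
) -> dict[str, int]:
    """Degradome 5'-end tags: planted slice peaks over uniform background.

    Each planted cleavage site contributes a tag starting exactly at its
    slice position with count ``peak_height``; every other transcript
    position receives Poisson(background_rate x peak_height) reads.
    """
    rng = np.random.default_rng([seed, 0x646567])  # domain-tagged stream
    tags: dict[str, int] = {}
    planted_pos = {(c.transcript_id, c.slice_position) for c in truth.cleavage_sites}
    for c in truth.cleavage_sites:
        c.peak_height = peak_height
        if peak_height > 0:
            tseq = transcripts[c.transcript_id]
            tag = tseq[c.slice_position - 1 : c.slice_position - 1 + tag_length]
            if len(tag) == tag_length:
                tags[tag] = tags.get(tag, 0) + peak_height
    lam = background_rate * peak_height
    if lam > 0:
        for tid in sorted(transcripts):
            tseq = transcripts[tid]
            npos = len(tseq) - tag_length + 1
            if npos <= 0:
                continue
            counts = rng.poisson(lam, size=npos)
            for pos in np.flatnonzero(counts):
                if (tid, int(pos) + 1) in planted_pos:
                    continue
                tag = tseq[pos : pos + tag_length]
                tags[tag] = tags.get(tag, 0) + int(counts[pos])
    return tags


def simulate_raw_reads(
    tags: Mapping[str, int],
    seed: int = 4,
    adapter_3p: str = "TGGAATTCTCGGGTGCCAAGG",
    contaminants: Optional[Mapping[str, int]] = None,
    read_length: int = 50,
) -> tuple[list[RawRead], dict[str, int]]:
    """Wrap clean tags with the 3' adapter and inject counted contaminants.

    Contaminant classes (counts configurable): ``adapter_only``,
    ``undersize`` (<18 nt inserts), ``poly_a``, ``low_quality``, ``n_bases``,
    ``oversize`` (>30 nt inserts).  Returns reads in a deterministic shuffled
    order plus the contamination tally.
    """
    rng = np.random.default_rng([seed, 0x726177])  # domain-tagged stream
    counts = {"adapter_only": 20, "undersize": 30, "poly_a": 25,
              "low_quality": 15, "n_bases": 10, "oversize": 20}
    if contaminants:
        counts.update(contaminants)
    reads: list[RawRead] = []

    def pad(insert: str) -> str:
        full = insert + adapter_3p
        if len(full) < read_length:
            full = full + _random_seq(rng, read_length - len(full))
        return full[:read_length]

    good_q = tuple([36] * read_length)
    i = 0
    for seq, count in sorted(tags.items()):
        for _ in range(count):
            i += 1
            reads.append(RawRead(f"read{i}", pad(seq), good_q))
    for _ in range(counts["adapter_only"]):
        i += 1
        reads.append(RawRead(f"read{i}", pad(""), good_q))
    for _ in range(counts["undersize"]):
        i += 1
        reads.append(RawRead(f"read{i}", pad(_random_seq(rng, int(rng.integers(8, 18)))), good_q))
    for _ in range(counts["poly_a"]):
        i += 1
        reads.append(RawRead(f"read{i}", pad("A" * int(rng.integers(20, 28))), good_q))
    for _ in range(counts["low_quality"]):
        i += 1
        reads.append(RawRead(f"read{i}", pad(_random_seq(rng, 21)), tuple([8] * read_length)))
    for _ in range(counts["n_bases"]):
        i += 1
        seq = list(_random_seq(rng, 21))
        for j in rng.choice(len(seq), size=5, replace=False):
            seq[j] = "N"
        reads.append(RawRead(f"read{i}", pad("".join(seq)), good_q))
    for _ in range(counts["oversize"]):
        i += 1
        reads.append(RawRead(f"read{i}", pad(_random_seq(rng, int(rng.integers(31, 41)))), good_q))
    order = rng.permutation(len(reads))
    return [reads[k] for k in order], dict(counts)
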