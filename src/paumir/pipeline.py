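"""End-to-end orchestration: one configuration, all stages, one manifest.

``run_pipeline`` executes the stages in analysis order — cleaning,
annotation, hairpin discovery, differential expression, degradome target
calling — writes every report into the output directory, and returns a
manifest with a content checksum per file plus the stage summary
statistics.  Reruns with the same configuration and inputs are
byte-identical.

Inputs come either from files (collapsed tag TSVs, transcript FASTA,
reference FASTAs, degradome tag TSV) or, by default, from the synthetic
study generator, which writes its inputs and truth table into the output
directory first, so the whole pipeline is testable offline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as pio
from .annotation import ReferenceSet, annotate_library, assign_families
from .degradome import ScoringParams, call_targets, map_degradome_tags, t_plot_series
from .diffexpr import CountPair, expression_result, de_summary, round_half_up
from .hairpin import MeyersCriteria, discover_mirnas, summarize_candidates
from .preprocess import CleaningParams, TagLibrary, collapse_tags, filter_raw_reads
from .simulate import (
    generate_transcriptome,
    plant_cleavage_sites,
    plant_hairpins,
    simulate_degradome,
    simulate_libraries,
    simulate_raw_reads,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Every tunable of every stage, plus input paths and the seed.

    With ``synthetic=True`` (the default) the generator produces the input
    bundle; otherwise the ``*_path`` fields must point at existing files.
    """

    outdir: str = "paumir_out"
    seed: int = 42
    synthetic: bool = True

    # file inputs (used when synthetic=False)
    library1_path: Optional[str] = None  # collapsed TSV
    library2_path: Optional[str] = None
    library1_total: Optional[int] = None
    library2_total: Optional[int] = None
    transcripts_path: Optional[str] = None
    mature_ref_path: Optional[str] = None
    ncrna_ref_paths: dict = field(default_factory=dict)  # class -> FASTA path
    degradome_path: Optional[str] = None  # collapsed TSV

    # synthetic-study shape
    n_transcripts: int = 40
    transcript_length: int = 800
    gc_content: float = 0.5
    n_hairpins: int = 20
    n_cleavage_sites: int = 20
    depth: int = 1_000_000
    peak_height: int = 50
    background_rate: float = 0.1

    # stage thresholds
    conserved_max_mismatches: int = 2
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    rpm_floor: float = 0.01
    flank: int = 150
    min_candidate_count: int = 3
    fold_engine: str = "auto"
    # hairpin criteria
    max_duplex_mismatches: int = 4
    max_bulges: int = 2
    max_mfe: float = -18.0
    # degradome scoring
    max_target_score: float = 4.0
    gu_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    gap_penalty: float = 2.0
    min_slice_reads: int = 1

    def criteria(self) -> MeyersCriteria:
        return MeyersCriteria(
            max_duplex_mismatches=self.max_duplex_mismatches,
            max_bulges=self.max_bulges,
            max_mfe=self.max_mfe,
        )

    def scoring(self) -> ScoringParams:
        return ScoringParams(
            gu_penalty=self.gu_penalty,
            mismatch_penalty=self.mismatch_penalty,
            gap_penalty=self.gap_penalty,
            max_score=self.max_target_score,
            min_slice_reads=self.min_slice_reads,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise PipelineError(f"missing input: {what}")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"missing input file for {what}: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "files": {}}
    t_start = time.time()

    def emit(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name: str):
        logger.info("stage %s ...", name)
        manifest["stages"][name] = {"started_s": round(time.time() - t_start, 3)}
        return name

    # ---- inputs (synthetic bundle or files) --------------------------------
    current = stage("inputs")
    try:
        if config.synthetic:
            transcripts = generate_transcriptome(
                config.n_transcripts, config.transcript_length,
                config.gc_content, seed=config.seed,
            )
            transcripts, truth = plant_hairpins(
                transcripts, config.n_hairpins, seed=config.seed,
                engine=config.fold_engine,
            )
            transcripts = plant_cleavage_sites(
                transcripts, truth.mature_sequences(), truth,
                n_sites=config.n_cleavage_sites, seed=config.seed,
            )
            lib1, lib2 = simulate_libraries(truth, depth=config.depth, seed=config.seed)
            degradome_tags = simulate_degradome(
                truth, transcripts, peak_height=config.peak_height,
                background_rate=config.background_rate, seed=config.seed,
            )
            pio.write_fasta(sorted(transcripts.items()), out / "transcripts.fa")
            truth.to_json(out / "truth.json")
            emit("transcripts", out / "transcripts.fa")
            emit("truth", out / "truth.json")
            mature_ref = None
            ncrna_refs: list[ReferenceSet] = []
        else:
            lib1 = TagLibrary(
                "lib1",
                pio.read_collapsed_tsv(_require(config.library1_path, "library 1 tags")),
                clean_total=config.library1_total or 0,
            )
            lib2 = TagLibrary(
                "lib2",
                pio.read_collapsed_tsv(_require(config.library2_path, "library 2 tags")),
                clean_total=config.library2_total or 0,
            )
            transcripts = pio.read_fasta(_require(config.transcripts_path, "transcripts"))
            mature_ref = None
            if config.mature_ref_path:
                mature_ref = ReferenceSet(
                    "mature_miRNA",
                    pio.read_fasta(_require(config.mature_ref_path, "mature reference")),
                )
            ncrna_refs = [
                ReferenceSet(cls, pio.read_fasta(_require(p, f"{cls} reference")))
                for cls, p in sorted(config.ncrna_ref_paths.items())
            ]
            degradome_tags = (
                pio.read_collapsed_tsv(_require(config.degradome_path, "degradome tags"))
                if config.degradome_path
                else {}
            )
            truth = None
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage {current} failed: {err}") from err

    libs = {lib1.name: lib1, lib2.name: lib2}

    # ---- preprocessing (cleaning report) -----------------------------------
    current = stage("preprocess")
    try:
        if config.synthetic:
            # exercise the cleaning cascade on a capped raw-read bundle
            sample_tags = {
                seq: min(count, 5)
                for seq, count in sorted(lib1.tags.items())[:200]
            }
            raw_reads, _ = simulate_raw_reads(sample_tags, seed=config.seed)
            clean, tally = filter_raw_reads(raw_reads, CleaningParams())
            recovered = collapse_tags(clean, "cleaning_check")
        else:
            clean, tally = [], {}
            recovered = None
        pio.write_tally_tsv(dict(tally), out / "cleaning_report.tsv")
        emit("cleaning_report", out / "cleaning_report.tsv")
        for name, lib in libs.items():
            pio.write_collapsed_tsv(lib.tags, out / f"{name}_tags.tsv")
            emit(f"{name}_tags", out / f"{name}_tags.tsv")
        manifest["stages"]["preprocess"]["clean_reads"] = len(clean)
        if recovered is not None:
            manifest["stages"]["preprocess"]["unique_tags_checked"] = len(recovered.tags)
    except Exception as err:
        raise PipelineError(f"stage {current} failed: {err}") from err

    # ---- annotation --------------------------------------------------------
    current = stage("annotate")
    try:
        annotated = annotate_library(
            libs, ncrna_refs, mature_ref, transcripts,
            max_mismatches=config.conserved_max_mismatches,
        )
        with open(out / "annotation.tsv", "w") as fh:
            fh.write("tag\tclass\tbest_match\tmismatches\t"
                     + "\t".join(sorted(libs)) + "\tn_hits\n")
            for tag in annotated:
                match = tag.best_match or ("", "")
                counts = "\t".join(str(tag.counts.get(n, 0)) for n in sorted(libs))
                fh.write(f"{tag.sequence}\t{tag.annotation_class}\t{match[0]}\t"
                         f"{match[1]}\t{counts}\t{len(tag.transcript_hits)}\n")
        emit("annotation", out / "annotation.tsv")
        manifest["stages"]["annotate"]["n_tags"] = len(annotated)
        manifest["stages"]["annotate"]["n_conserved"] = sum(
            1 for t in annotated if t.annotation_class == "conserved_miRNA"
        )
    except Exception as err:
        raise PipelineError(f"stage {current} failed: {err}") from err

    # ---- hairpin discovery -------------------------------------------------
    current = stage("discover")
    try:
        unannotated = [
            (t.sequence, t.counts, t.transcript_hits)
            for t in annotated
            if t.annotation_class == "unannotated" and t.transcript_hits
        ]
        candidates = discover_mirnas(
            unannotated, transcripts, libs,
            criteria=config.criteria(), flank=config.flank,
            min_total_count=config.min_candidate_count, engine=config.fold_engine,
        )
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("id\ttranscript\tstart\tend\tstrand\tarm\tmfe\tstructure\t"
                     "mature\tstar\tmismatches\tbulges\t"
                     + "\t".join(f"mature_{n}" for n in sorted(libs)) + "\t"
                     + "\t".join(f"star_{n}" for n in sorted(libs)) + "\n")
            for i, c in enumerate(candidates, start=1):
                mc = "\t".join(str(c.mature_counts.get(n, 0)) for n in sorted(libs))
                sc = "\t".join(str(c.star_counts.get(n, 0)) for n in sorted(libs))
                fh.write(f"cand-mir{i}\t{c.transcript_id}\t{c.start}\t{c.end}\t"
                         f"{c.strand}\t{c.mature_arm}\t{c.fold.mfe:.1f}\t"
                         f"{c.fold.structure}\t{c.mature}\t{c.star or ''}\t"
                         f"{c.duplex_mismatches}\t{c.bulged_nucleotides}\t{mc}\t{sc}\n")
        pio.write_fasta(
            ((f"cand-mir{i}", c.precursor) for i, c in enumerate(candidates, start=1)),
            out / "precursors.fa",
        )
        emit("candidates", out / "candidates.tsv")
        emit("precursors", out / "precursors.fa")
        manifest["stages"]["discover"].update(summarize_candidates(candidates))
    except Exception as err:
        raise PipelineError(f"stage {current} failed: {err}") from err

    # ---- differential expression -------------------------------------------
    current = stage("diffexp")
    try:
        n1 = max(lib1.clean_total, 1)
        n2 = max(lib2.clean_total, 1)
        de_rows = []
        for t in annotated:
            if t.annotation_class == "conserved_miRNA":
                de_rows.append(("conserved", t.best_match[0], t.sequence, t.counts))
        for i, c in enumerate(candidates, start=1):
            de_rows.append(("novel", f"cand-mir{i}", c.mature, c.mature_counts))
        results = []
        lib_names = sorted(libs)
        with open(out / "diffexp.tsv", "w") as fh:
            fh.write("name\tgroup\tsequence\tcount1\tcount2\trpm1\trpm2\t"
                     "log2fc\tpvalue\tstatus\n")
            for group, name, seq, counts in de_rows:
                x = counts.get(lib_names[0], 0)
                y = counts.get(lib_names[1], 0)
                res = expression_result(
                    CountPair(x, y, n1, n2), floor=config.rpm_floor,
                    fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
                )
                results.append((group, res))
                fh.write(f"{name}\t{group}\t{seq}\t{x}\t{y}\t{res.rpm1:.4f}\t"
                         f"{res.rpm2:.4f}\t{round_half_up(res.log2fc, 2):.2f}\t"
                         f"{res.pvalue:.3e}\t{res.status.value}\n")
        emit("diffexp", out / "diffexp.tsv")
        manifest["stages"]["diffexp"].update(de_summary(results))
    except Exception as err:
        raise PipelineError(f"stage {current} failed: {err}") from err

    # ---- degradome targets -------------------------------------------------
    current = stage("degradome")
    try:
        mirna_seqs: dict[str, str] = {}
        for t in annotated:
            if t.annotation_class == "conserved_miRNA":
                mirna_seqs.setdefault(t.best_match[0], t.sequence)
        for i, c in enumerate(candidates, start=1):
            mirna_seqs[f"cand-mir{i}"] = c.mature
        profiles = map_degradome_tags(degradome_tags, transcripts)
        exclude: dict[str, list[tuple[int, int]]] = {}
        for c in candidates:
            exclude.setdefault(c.transcript_id, []).append((c.start, c.end))
        events = call_targets(
            mirna_seqs, transcripts, profiles,
            params=config.scoring(), exclude_regions=exclude,
        )
        with open(out / "cleavage_events.tsv", "w") as fh:
            fh.write("mirna\ttranscript\tsite_start\tsite_end\tscore\tpairing\t"
                     "slice_position\tslice_abundance\tcategory\tmultimapped\n")
            for e in events:
                a = e.alignment
                fh.write(f"{a.mirna_id}\t{a.transcript_id}\t{a.site_start}\t"
                         f"{a.site_end}\t{a.score:g}\t{a.pairing}\t"
                         f"{e.slice_position}\t{e.slice_abundance}\t{e.category}\t"
                         f"{int(e.multimapped)}\n")
        emit("cleavage_events", out / "cleavage_events.tsv")
        slice_by_tid: dict[str, list[int]] = {}
        for e in events:
            slice_by_tid.setdefault(e.alignment.transcript_id, []).append(e.slice_position)
        with open(out / "tplots.tsv", "w") as fh:
            fh.write("transcript\tposition\tabundance\tis_slice\n")
            for tid in sorted(slice_by_tid):
                series = t_plot_series(profiles[tid], slice_by_tid[tid])
                for r in series.itertuples(index=False):
                    fh.write(f"{tid}\t{r.position}\t{r.abundance}\t{int(r.is_slice)}\n")
        emit("tplots", out / "tplots.tsv")
        manifest["stages"]["degradome"]["n_events"] = len(events)
        for cat in ("I", "II", "III"):
            manifest["stages"]["degradome"][f"category_{cat}"] = sum(
                1 for e in events if e.category == cat
            )
    except Exception as err:
        raise PipelineError(f"stage {current} failed: {err}") from err

    # ---- family aggregation over conserved hits ----------------------------
    current = stage("families")
    try:
        hits = {
            t.best_match[0]: t.counts
            for t in annotated
            if t.annotation_class == "conserved_miRNA"
        }
        fam = assign_families(hits)
        fam.to_csv(out / "families.tsv", sep="\t", index=False)
        emit("families", out / "families.tsv")
        manifest["stages"]["families"]["n_families"] = (
            int(fam["family"].nunique()) if len(fam) else 0
        )
    except Exception as err:
        raise PipelineError(f"stage {current} failed: {err}") from err

    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
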