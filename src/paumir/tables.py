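"""Published count-table fixtures and their statistical reproduction.

The package ships the printed per-miRNA read counts of the two-genotype
study it models — 45 conserved and 31 novel miRNAs with their counts in the
diploid (PA2) and autotetraploid (PA4) libraries, the printed fold-changes
and p-values, and the star-strand counts — together with both libraries'
clean-read totals.  ``table_reproduction`` recomputes every statistic from
the raw counts and compares against the printed values at printed
precision; it is both a regression surface for the statistics module and a
worked audit of the published analysis (including the rows whose printed
p-values are inconsistent with the stated significance filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .annotation import assign_families
from .diffexpr import (
    CountPair,
    DEStatus,
    audic_claverie_pvalue,
    classify_de,
    log2_fold_change,
    normalize_rpm,
    round_half_up,
)

__all__ = [
    "CLEAN_TOTAL_PA2",
    "CLEAN_TOTAL_PA4",
    "load_printed_tables",
    "table_reproduction",
    "TableReport",
]

#: clean-read totals of the two libraries (normalisation denominators)
CLEAN_TOTAL_PA2 = 10_691_271
CLEAN_TOTAL_PA4 = 10_712_733


def load_printed_tables() -> pd.DataFrame:
    """The packaged transcription of the published count tables.

    One row per miRNA with columns: group (conserved/novel), family (conserved
    only), mirna, pa2/pa4 counts, printed_fc, printed_p (as printed, string),
    star_pa2/star_pa4.
    """
    frames = []
    for fname, group in (("table1_conserved.tsv", "conserved"), ("table2_novel.tsv", "novel")):
        with resources.files("paumir.data").joinpath(fname).open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype={"printed_p": str})
        df["group"] = group
        if "family" not in df.columns:
            df["family"] = ""
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["group", "family", "mirna", "pa2", "pa4",
                "printed_fc", "printed_p", "star_pa2", "star_pa4"]]


def _decimals(printed: float) -> int:
    """Number of decimals the table printed for a fold-change (2, or 1)."""
    text = f"{printed}"
    return len(text.split(".")[1]) if "." in text else 0


@dataclass
class TableReport:
    """Outcome of recomputing the published per-miRNA statistics."""

    rows: pd.DataFrame
    n_rows: int
    n_fc_match: int
    up: int = 0
    up_conserved: int = 0
    up_novel: int = 0
    down: int = 0
    down_conserved: int = 0
    down_novel: int = 0
    family_aggregates: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: rows that the published down-regulated tally includes although their
    #: printed p-values fail the stated p <= 0.05 filter
    discrepant_rows: list[str] = field(default_factory=list)

    @property
    def all_fold_changes_match(self) -> bool:
        return self.n_fc_match == self.n_rows


def table_reproduction(
    table: pd.DataFrame | None = None,
    n1: int = CLEAN_TOTAL_PA2,
    n2: int = CLEAN_TOTAL_PA4,
    floor: float = 0.01,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> TableReport:
    """Recompute fold-changes, p-values and the DE filter for every row.

    Each row's log2 fold-change (zero-RPM floor applied) is compared with
    the printed value at the printed precision; the DE tally applies the
    stated |fc| >= 1, p <= 0.05 filter to the recomputed statistics.  Rows
    whose |printed fc| passes but whose *printed* p-value fails the filter
    are listed in ``discrepant_rows`` — the published down-regulated count
    includes them, the stated filter excludes them.
    """
    if table is None:
        table = load_printed_tables()
    required = {"group", "mirna", "pa2", "pa4", "printed_fc", "printed_p"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table is missing columns: {sorted(missing)}")
    recs = []
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        try:
            x, y = int(row.pa2), int(row.pa4)
            printed_fc = float(row.printed_fc)
        except (TypeError, ValueError) as err:
            raise ValueError(f"malformed count table at row {idx}: {err}") from None
        rpm1 = normalize_rpm(x, n1)
        rpm2 = normalize_rpm(y, n2)
        fc = log2_fold_change(rpm1, rpm2, floor=floor)
        p = audic_claverie_pvalue(CountPair(x, y, n1, n2))
        nd = _decimals(printed_fc)
        fc_rounded = round_half_up(fc, nd)
        status = classify_de(fc, p, fc_threshold, p_threshold)
        printed_p = float(row.printed_p)
        printed_pass_p = printed_p <= p_threshold
        recs.append({
            "group": row.group, "family": row.family, "mirna": row.mirna,
            "pa2": x, "pa4": y, "rpm_pa2": rpm1, "rpm_pa4": rpm2,
            "log2fc": fc, "log2fc_rounded": fc_rounded,
            "printed_fc": printed_fc, "fc_match": fc_rounded == printed_fc,
            "pvalue": p, "printed_p": printed_p, "status": status.value,
            "printed_p_fails_filter": (abs(printed_fc) >= fc_threshold
                                       and not printed_pass_p),
        })
    rows = pd.DataFrame(recs)
    report = TableReport(rows=rows, n_rows=len(rows), n_fc_match=int(rows["fc_match"].sum()))
    for status, key in ((DEStatus.UP, "up"), (DEStatus.DOWN, "down")):
        sub = rows[rows["status"] == status.value]
        setattr(report, key, len(sub))
        setattr(report, f"{key}_conserved", int((sub["group"] == "conserved").sum()))
        setattr(report, f"{key}_novel", int((sub["group"] == "novel").sum()))
    conserved = rows[rows["group"] == "conserved"]
    hits = {
        r.mirna: {"PA2": r.pa2, "PA4": r.pa4}
        for r in conserved.itertuples(index=False)
    }
    families = {r.mirna: r.family for r in conserved.itertuples(index=False)}
    report.family_aggregates = assign_families(hits, families)
    report.discrepant_rows = sorted(rows.loc[rows["printed_p_fails_filter"], "mirna"])
    return report
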