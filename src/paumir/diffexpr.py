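"""Two-library differential expression for tag counts.

The study design is one sequencing library per condition, so the only
identifiable noise model is the sampling noise of the counts themselves.
Expression is normalised to reads per million (RPM),

    RPM = count / clean_total * 1e6,

fold-change is ``log2(RPM2 / RPM1)`` with zero RPM floored at a small
pseudo-value so the ratio stays finite, and significance comes from the
exact two-library tag-count test (Audic & Claverie): conditional on the
count ``x`` observed in library 1, the count ``Y`` in library 2 follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

a negative-binomial-form distribution in the library-size ratio.  The
two-sided p-value is ``min(1, 2*min(P(Y<=y), P(Y>=y)))``, computed in log
space by direct tail summation with a geometric truncation bound so that
counts up to millions neither overflow nor lose the small tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "CountPair",
    "DEStatus",
    "ExpressionResult",
    "normalize_rpm",
    "log2_fold_change",
    "audic_claverie_pvalue",
    "classify_de",
    "expression_result",
    "de_summary",
    "bh_adjust",
    "round_half_up",
]


@dataclass(frozen=True)
class CountPair:
    """Counts of one tag in two libraries plus both clean-read totals."""

    x: int
    y: int
    N1: int
    N2: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("library totals must be positive")


class DEStatus(str, Enum):
    UP = "up"
    DOWN = "down"
    NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class ExpressionResult:
    rpm1: float
    rpm2: float
    log2fc: float
    pvalue: float
    status: DEStatus


def normalize_rpm(count: int, clean_total: int) -> float:
    """Reads-per-million normalisation: count / clean_total * 1e6."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    return count / clean_total * 1_000_000


def log2_fold_change(rpm1: float, rpm2: float, floor: float = 0.01) -> float:
    """log2(rpm2 / rpm1) with zero RPM values floored at ``floor``.

    The 0.01 RPM floor is what makes fold-changes of library-specific tags
    finite; it is uniquely consistent with the reported values for
    zero-count rows (244 vs 0 reads at ~10.7M totals gives -11.16).
    """
    if rpm1 < 0 or rpm2 < 0:
        raise ValueError("RPM values must be non-negative")
    a = rpm1 if rpm1 > 0 else floor
    b = rpm2 if rpm2 > 0 else floor
    return math.log2(b / a)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _log_pmf(y: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log p(y | x) of the conditional tag-count distribution (r = N2/N1)."""
    y = np.asarray(y, dtype=float)
    return (
        gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        + y * log_r
        - (x + y + 1) * np.log1p(math.exp(log_r))
    )


def _log_upper_tail(y0: int, x: int, log_r: float, chunk: int = 8192) -> float:
    """log P(Y >= y0), summed upward from y0 until the geometric bound on the
    remainder is negligible relative to the partial sum.

    Past the conditional mode the term ratio p(y+1)/p(y) = q*(x+y+1)/(y+1)
    (q = r/(1+r) < 1) decreases monotonically, so the tail beyond the last
    summed term is bounded by a geometric series with that ratio.
    """
    log_q = log_r - math.log1p(math.exp(log_r))
    total = -math.inf
    y = y0
    while True:
        ys = np.arange(y, y + chunk)
        total = np.logaddexp(total, logsumexp(_log_pmf(ys, x, log_r)))
        last = y + chunk - 1
        log_ratio = log_q + math.log(x + last + 1) - math.log(last + 1)
        if log_ratio < 0:
            log_last = float(_log_pmf(np.array([last]), x, log_r)[0])
            log_rem_bound = log_last + log_ratio - math.log1p(-math.exp(log_ratio))
            if log_rem_bound < total + math.log(1e-15) or log_rem_bound < -746:
                return float(total)
        y += chunk


def audic_claverie_pvalue(pair: CountPair, convention: str = "split") -> float:
    """Exact two-sided tag-count p-value for one tag across two libraries.

    The default "split" convention doubles the smaller of the two CDF
    halves, ``min(1, 2 * min(P(Y <= y), P(Y > y)))``, computed by direct
    log-space summation of the decaying side (downward to zero, or upward
    with a geometric truncation bound) and exact complement for the other.
    This is the convention that reproduces published two-library test
    values, and it is exactly invariant under swapping the libraries: the
    conditional pmf satisfies p(y | x; N1, N2) = p(x | y; N2, N1)
    pointwise, so the swapped lower tail equals one minus the unswapped
    lower tail.  For equal counts and equal totals the lower tail is
    exactly one half (an incomplete-beta identity), giving p = 1.

    ``convention="inclusive"`` instead includes the full point mass at the
    observed count in both tails before taking the minimum — the more
    conservative textbook doubling.  The two conventions differ by at most
    the point mass itself.
    """
    if convention not in ("split", "inclusive"):
        raise ValueError(f"unknown tail convention {convention!r}")
    x, y = pair.x, pair.y
    log_r = math.log(pair.N2) - math.log(pair.N1)
    point = math.exp(float(_log_pmf(np.array([y]), x, log_r)[0]))
    # sum the shorter/decaying side directly; the other tail by complement
    mean = (x + 1) * math.exp(log_r)
    if y <= mean:
        lower = math.exp(min(0.0, float(logsumexp(_log_pmf(np.arange(0, y + 1), x, log_r)))))
        upper_strict = 1.0 - lower
        upper_incl = min(1.0, upper_strict + point)
    else:
        upper_incl = math.exp(min(0.0, _log_upper_tail(y, x, log_r)))
        upper_strict = max(0.0, upper_incl - point)
        lower = min(1.0, 1.0 - upper_incl + point)
    if convention == "inclusive":
        small = min(lower, upper_incl)
        if small >= 0.5 - 1e-12:  # both tails cover the median: exactly 1
            return 1.0
        return min(1.0, 2.0 * small)
    small = min(lower, upper_strict)
    if small >= 0.5 - 1e-12:
        return 1.0
    return min(1.0, 2.0 * small)


def classify_de(
    result_or_fc,
    pvalue: Optional[float] = None,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> DEStatus:
    """Apply the significance filter |log2fc| >= fc_threshold and p <= p_threshold.

    Accepts either an :class:`ExpressionResult` or an (un-rounded) fold-change
    plus p-value.  Both thresholds are inclusive.
    """
    if isinstance(result_or_fc, ExpressionResult):
        fc, p = result_or_fc.log2fc, result_or_fc.pvalue
    else:
        fc, p = float(result_or_fc), float(pvalue)
    if p <= p_threshold:
        if fc >= fc_threshold:
            return DEStatus.UP
        if fc <= -fc_threshold:
            return DEStatus.DOWN
    return DEStatus.NOT_SIGNIFICANT


def expression_result(
    pair: CountPair,
    floor: float = 0.01,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> ExpressionResult:
    """Full per-tag statistics: RPM pair, fold-change, p-value, DE status."""
    rpm1 = normalize_rpm(pair.x, pair.N1)
    rpm2 = normalize_rpm(pair.y, pair.N2)
    fc = log2_fold_change(rpm1, rpm2, floor=floor)
    p = audic_claverie_pvalue(pair)
    return ExpressionResult(rpm1, rpm2, fc, p, classify_de(fc, p, fc_threshold, p_threshold))


def de_summary(
    results: Iterable[tuple[str, ExpressionResult]]
) -> dict[str, int]:
    """Tally up/down counts, split by the conserved/novel label of each row.

    ``results`` yields (label, result) pairs where label is "conserved" or
    "novel".
    """
    out = {
        "up": 0, "down": 0,
        "up_conserved": 0, "up_novel": 0,
        "down_conserved": 0, "down_novel": 0,
    }
    for label, res in results:
        if label not in ("conserved", "novel"):
            raise ValueError(f"row label must be conserved or novel, got {label!r}")
        if res.status is DEStatus.UP:
            out["up"] += 1
            out[f"up_{label}"] += 1
        elif res.status is DEStatus.DOWN:
            out["down"] += 1
            out[f"down_{label}"] += 1
    return out


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Optional Benjamini-Hochberg adjustment (not applied by default)."""
    from statsmodels.stats.multitest import multipletests

    if len(pvalues) == 0:
        return []
    return list(multipletests(pvalues, method="fdr_bh")[1])
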