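"""Single-agent miRNA viability screen with MAD-based hit calling.

For each cell line, every miRNA's quadruplicate MTS wells are summarized as
the ratio of their mean signal to the *global median* of all
miRNA-transfected wells of that line. A miRNA is called a hit when its
ratio falls outside ``median(ratios) +/- k * MAD``, where MAD is the raw
median absolute deviation of the per-miRNA ratio distribution (no
1.4826 normal-consistency factor) and k defaults to 2. Ratios above the
upper bound are proliferative hits, ratios below the lower bound
anti-proliferative. Candidate miRNAs are those hit, in a consistent or any
direction, in at least ``min_cell_lines`` cell lines.

With the same wells defining both the ratios and the global median, the
ratio distribution is centered near 1, so the rule is self-consistent on
the ratio scale. When the MAD degenerates to 0 (e.g. near-constant
ratios), any ratio strictly different from the median is flagged as a hit
and the table carries a degenerate-dispersion flag.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .plate_data import NEG_CONTROL, Assay, ViabilityRecord

__all__ = [
    "HitCall",
    "MirnaRatio",
    "ScreenHitTable",
    "summarize_ratios",
    "call_hits",
    "select_candidates",
]


class HitCall(str, Enum):
    PROLIFERATIVE = "proliferative"
    ANTI_PROLIFERATIVE = "anti_proliferative"
    NONE = "none"


@dataclass(frozen=True, slots=True)
class MirnaRatio:
    """Mean replicate signal of one miRNA, normalized to the line's global median."""

    cell_line: str
    mirna: str
    mean_signal: float
    ratio: float


@dataclass(frozen=True)
class ScreenHitTable:
    """Per-cell-line MAD hit calls.

    ``global_median`` is the center of the threshold rule: the median of
    the per-miRNA ratio distribution (≈ 1 by construction). ``mad`` is the
    raw median absolute deviation of the ratios. ``degenerate`` flags a
    zero MAD, in which case any ratio strictly off the median is a hit.
    """

    cell_line: str
    global_median: float
    mad: float
    k: float
    ratios: dict[str, float]
    calls: dict[str, HitCall]
    degenerate: bool = False

    @property
    def lower_bound(self) -> float:
        return self.global_median - self.k * self.mad

    @property
    def upper_bound(self) -> float:
        return self.global_median + self.k * self.mad

    def hit_mirnas(self, direction: HitCall | None = None) -> list[str]:
        """miRNAs with a non-NONE call (optionally of one direction), sorted."""
        return sorted(
            m
            for m, c in self.calls.items()
            if c is not HitCall.NONE and (direction is None or c is direction)
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format result table (one row per miRNA)."""
        rows = [
            {
                "cell_line": self.cell_line,
                "mirna": m,
                "ratio": self.ratios[m],
                "global_median": self.global_median,
                "mad": self.mad,
                "lower_bound": self.lower_bound,
                "upper_bound": self.upper_bound,
                "call": self.calls[m].value,
                "degenerate_flag": self.degenerate,
            }
            for m in sorted(self.ratios)
        ]
        return pd.DataFrame(rows)


def summarize_ratios(
    records: Sequence[ViabilityRecord], cell_line: str
) -> list[MirnaRatio]:
    """Per-miRNA mean MTS signal over the line's global transfection median.

    Only miRNA-transfected, drug-free MTS wells enter: untransfected wells
    and negative controls are excluded from both the per-miRNA means and
    the global median ("all transfections" = all miRNA wells).
    """
    wells: dict[str, list[float]] = {}
    for r in records:
        if (
            r.cell_line == cell_line
            and r.assay is Assay.MTS
            and r.mirna not in (None, NEG_CONTROL)
            and r.drug is None
        ):
            wells.setdefault(r.mirna, []).append(r.signal)
    if not wells:
        raise ValidationError(
            f"no miRNA-transfected MTS wells for cell line {cell_line!r}"
        )
    all_signals = [s for sig in wells.values() for s in sig]
    global_median = statistics.median(all_signals)
    if global_median <= 0:
        raise ValidationError("global median of signals is not positive")
    return [
        MirnaRatio(
            cell_line=cell_line,
            mirna=m,
            mean_signal=statistics.fmean(sig),
            ratio=statistics.fmean(sig) / global_median,
        )
        for m, sig in sorted(wells.items())
    ]


def call_hits(ratios: Iterable[MirnaRatio], k: float = 2.0) -> ScreenHitTable:
    """Call proliferative/anti-proliferative hits at ``median +/- k*MAD``.

    The MAD is the median over miRNAs of the absolute deviation of each
    ratio from the median ratio, without a consistency factor. Strict
    inequalities; a zero MAD triggers the degenerate fallback (any ratio
    strictly different from the median is a hit).
    """
    ratios = list(ratios)
    if len({r.mirna for r in ratios}) < 2:
        raise InsufficientDataError("hit calling needs at least 2 distinct miRNAs")
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    cell_line = ratios[0].cell_line
    values = {r.mirna: r.ratio for r in ratios}
    center = statistics.median(values.values())
    mad = statistics.median(abs(v - center) for v in values.values())
    degenerate = mad == 0.0
    calls: dict[str, HitCall] = {}
    for m, v in values.items():
        if degenerate:
            hi, lo = v > center, v < center
        else:
            hi, lo = v > center + k * mad, v < center - k * mad
        calls[m] = (
            HitCall.PROLIFERATIVE
            if hi
            else HitCall.ANTI_PROLIFERATIVE
            if lo
            else HitCall.NONE
        )
    return ScreenHitTable(
        cell_line=cell_line,
        global_median=center,
        mad=mad,
        k=k,
        ratios=values,
        calls=calls,
        degenerate=degenerate,
    )


def select_candidates(
    tables: Iterable[ScreenHitTable],
    min_cell_lines: int = 2,
    direction: HitCall | str | None = None,
) -> list[str]:
    """miRNAs hit in at least ``min_cell_lines`` cell lines.

    ``direction`` restricts the count to one call direction
    (:class:`HitCall` member or its string value); ``None``/"any" counts
    hits of either direction. Result is sorted by the number of supporting
    cell lines (descending), then by identifier.
    """
    tables = list(tables)
    if min_cell_lines < 1:
        raise ValidationError("min_cell_lines must be >= 1")
    if len({t.cell_line for t in tables}) < min_cell_lines:
        raise InsufficientDataError(
            f"need tables from >= {min_cell_lines} cell lines, got {len(tables)}"
        )
    want: HitCall | None
    if direction is None or (isinstance(direction, str) and direction.lower() == "any"):
        want = None
    else:
        want = HitCall(direction)
    support: dict[str, int] = {}
    for t in tables:
        for m, c in t.calls.items():
            if c is HitCall.NONE:
                continue
            if want is not None and c is not want:
                continue
            support[m] = support.get(m, 0) + 1
    hits = [m for m, n in support.items() if n >= min_cell_lines]
    return sorted(hits, key=lambda m: (-support[m], m))
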