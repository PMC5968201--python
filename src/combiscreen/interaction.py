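"""Rank-sum testing of miRNA/drug combination experiments.

The decision procedure for a "true interaction" between a miRNA mimic and
a drug in one cell line is a conjunction of three two-sided Mann-Whitney
rank-sum comparisons against the combination arm:

    miRNA-only  vs combination
    drug-only   vs combination
    untreated   vs combination

Each family of interaction calls shares a Bonferroni-corrected alpha,
``0.05 / n_comparisons`` (n = the number of drugs tested in that cell
line's experiment; single-agent miRNA effects use n = the number of
miRNAs). A pair is a true interaction only when all three p-values fall
below the corrected alpha *and* the combination's median viability lies
strictly below the medians of all other arms (the direction check, which
keeps antagonism from being labeled an interaction).

p-values are exact whenever the group sizes allow it: the permutation
distribution of the rank sum over all C(n+m, n) group labelings of the
pooled mid-ranks (ties need no correction on this path). Above the
enumeration cutoff the tie-corrected, continuity-corrected normal
approximation is used. At the study's group size (6 vs 6, 924 labelings)
the smallest attainable two-sided p is 2/924 ≈ 0.00216.
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .errors import MissingArmError, ValidationError
from .plate_data import Assay, ExperimentDesign, ViabilityRecord, group_arms

__all__ = [
    "ArmSet",
    "InteractionCall",
    "FamilyResult",
    "rank_sum_p",
    "bonferroni_alpha",
    "call_interaction",
    "call_single_mirna_effect",
    "run_interaction_family",
]

#: Exact enumeration is used when C(n+m, n) does not exceed this.
EXACT_ENUMERATION_LIMIT = 50_000

Alternative = Literal["two_sided", "less", "greater"]


@dataclass(frozen=True)
class ArmSet:
    """The four arms of one (cell line, miRNA, drug) combination experiment."""

    cell_line: str
    mirna: str
    drug: str
    untreated: tuple[float, ...]
    mirna_only: tuple[float, ...]
    drug_only: tuple[float, ...]
    combination: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("untreated", "mirna_only", "drug_only", "combination"):
            arm = getattr(self, name)
            if len(arm) < 2:
                raise ValidationError(f"arm {name!r} needs >= 2 wells, got {len(arm)}")
            if any(s < 0 for s in arm):
                raise ValidationError(f"arm {name!r} contains a negative signal")


@dataclass(frozen=True, slots=True)
class InteractionCall:
    """Verdict for one miRNA/drug pair.

    ``is_true_interaction`` is the conjunction of the three p-values being
    below ``alpha`` and the direction check.
    """

    cell_line: str
    mirna: str
    drug: str
    p_mirna_vs_comb: float
    p_drug_vs_comb: float
    p_untreated_vs_comb: float
    alpha: float
    direction_ok: bool
    is_true_interaction: bool


@dataclass(frozen=True)
class FamilyResult:
    """All interaction and single-agent calls of one cell line's experiment."""

    design: ExperimentDesign
    alpha_interaction: float
    alpha_single: float
    interactions: pd.DataFrame
    single_effects: pd.DataFrame


@lru_cache(maxsize=64)
def _combo_matrix(n_total: int, n_x: int) -> np.ndarray:
    """All C(n_total, n_x) index subsets, one per row."""
    return np.array(list(itertools.combinations(range(n_total), n_x)), dtype=np.intp)


def rank_sum_p(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two_sided",
) -> float:
    """Mann-Whitney rank-sum p-value, exact for small groups.

    The exact path enumerates every assignment of the pooled mid-ranks to
    the two groups and counts rank sums at least as extreme as the
    observed one; it is used when C(n+m, n) <= 50,000 (all study-scale
    groups). Larger problems fall back to the tie- and
    continuity-corrected normal approximation. The two-sided p is
    ``min(1, 2 * min(one-sided p's))``.

    ``alternative="less"`` tests whether ``x`` tends below ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    n, m = int(x.size), int(y.size)
    total = math.comb(n + m, n)
    if total <= EXACT_ENUMERATION_LIMIT:
        ranks = rankdata(np.concatenate([x, y]))
        observed = float(ranks[:n].sum())
        sums = ranks[_combo_matrix(n + m, n)].sum(axis=1)
        eps = 1e-9
        p_less = float(np.count_nonzero(sums <= observed + eps)) / total
        p_greater = float(np.count_nonzero(sums >= observed - eps)) / total
    else:
        p_less = float(mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue)
        p_greater = float(mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    if alternative == "two_sided":
        return min(1.0, 2.0 * min(p_less, p_greater))
    raise ValidationError(f"unknown alternative {alternative!r}")


def bonferroni_alpha(n_comparisons: int, family_alpha: float = 0.05) -> float:
    """Family-wise threshold ``family_alpha / n_comparisons`` (full precision).

    Reporting layers may round to 3 decimals (0.05/7 prints as 0.007), but
    verdicts always compare against the unrounded value.
    """
    if n_comparisons < 1:
        raise ValidationError(f"n_comparisons must be >= 1, got {n_comparisons}")
    if not 0 < family_alpha <= 1:
        raise ValidationError(f"family_alpha must be in (0, 1], got {family_alpha}")
    return family_alpha / n_comparisons


def call_interaction(
    arms: ArmSet, alpha: float, one_sided: bool = False
) -> InteractionCall:
    """Test one miRNA/drug pair for a true interaction.

    Three rank-sum tests of each non-combination arm against the
    combination (two-sided by default; ``one_sided`` uses the
    greater-than-combination alternative). The direction check requires
    the combination median to be strictly below every other arm's median.
    """
    alt: Alternative = "greater" if one_sided else "two_sided"
    p_mirna = rank_sum_p(arms.mirna_only, arms.combination, alt)
    p_drug = rank_sum_p(arms.drug_only, arms.combination, alt)
    p_untr = rank_sum_p(arms.untreated, arms.combination, alt)
    med_comb = statistics.median(arms.combination)
    direction_ok = med_comb < min(
        statistics.median(arms.mirna_only),
        statistics.median(arms.drug_only),
        statistics.median(arms.untreated),
    )
    return InteractionCall(
        cell_line=arms.cell_line,
        mirna=arms.mirna,
        drug=arms.drug,
        p_mirna_vs_comb=p_mirna,
        p_drug_vs_comb=p_drug,
        p_untreated_vs_comb=p_untr,
        alpha=alpha,
        direction_ok=direction_ok,
        is_true_interaction=bool(
            p_mirna < alpha and p_drug < alpha and p_untr < alpha and direction_ok
        ),
    )


def call_single_mirna_effect(
    untreated: Sequence[float], mirna_only: Sequence[float], alpha: float
) -> tuple[float, bool]:
    """Two-sided rank-sum test of a miRNA-only arm against untreated wells."""
    p = rank_sum_p(untreated, mirna_only, "two_sided")
    return p, p < alpha


def _arm(
    arms: dict, mirna: str | None, drug: str | None, design: ExperimentDesign
) -> tuple[float, ...]:
    sig = arms.get((mirna, drug))
    if not sig:
        raise MissingArmError(
            f"missing arm (cell_line={design.cell_line!r}, mirna={mirna!r}, drug={drug!r})"
        )
    return tuple(sig)


def run_interaction_family(
    records: Sequence[ViabilityRecord],
    design: ExperimentDesign,
    family_alpha: float = 0.05,
    assay: Assay | None = Assay.ALAMAR,
) -> FamilyResult:
    """Run every (miRNA, drug) interaction call of one cell line's design.

    The interaction alpha is ``family_alpha / n_drugs``; single-agent
    miRNA effects are tested against untreated wells at
    ``family_alpha / n_mirnas``. A missing arm raises
    :class:`~combiscreen.errors.MissingArmError` naming the triple.
    """
    arms = group_arms(records, design.cell_line, assay=assay)
    alpha_int = bonferroni_alpha(design.n_drug_comparisons, family_alpha)
    alpha_single = bonferroni_alpha(design.n_mirna_comparisons, family_alpha)
    untreated = _arm(arms, None, None, design)

    calls = []
    for mirna in design.mirnas:
        mirna_only = _arm(arms, mirna, None, design)
        for drug in design.drugs:
            arm_set = ArmSet(
                cell_line=design.cell_line,
                mirna=mirna,
                drug=drug,
                untreated=untreated,
                mirna_only=mirna_only,
                drug_only=_arm(arms, None, drug, design),
                combination=_arm(arms, mirna, drug, design),
            )
            calls.append(call_interaction(arm_set, alpha_int))
    interactions = pd.DataFrame(
        {
            "cell_line": [c.cell_line for c in calls],
            "mirna": [c.mirna for c in calls],
            "drug": [c.drug for c in calls],
            "p_mirna_vs_comb": [c.p_mirna_vs_comb for c in calls],
            "p_drug_vs_comb": [c.p_drug_vs_comb for c in calls],
            "p_untreated_vs_comb": [c.p_untreated_vs_comb for c in calls],
            "alpha": [c.alpha for c in calls],
            "direction_ok": [c.direction_ok for c in calls],
            "is_true_interaction": [c.is_true_interaction for c in calls],
        }
    )

    singles = []
    for mirna in design.mirnas:
        p, sig = call_single_mirna_effect(
            untreated, _arm(arms, mirna, None, design), alpha_single
        )
        singles.append(
            {
                "cell_line": design.cell_line,
                "mirna": mirna,
                "p": p,
                "alpha": alpha_single,
                "significant": sig,
            }
        )
    return FamilyResult(
        design=design,
        alpha_interaction=alpha_int,
        alpha_single=alpha_single,
        interactions=interactions,
        single_effects=pd.DataFrame(singles),
    )
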