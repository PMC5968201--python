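"""Expression-association stage: linking a miRNA to genome-wide mRNA levels.

Given a genes x samples expression matrix and a per-sample driver vector
(the miRNA's expression in the same cohort), the stage

1. removes low-variation genes — a gene is kept only when at least a
   fraction ``min_frac`` (default 20%) of its samples deviate from the
   gene's median by at least ``fold`` (default 1.5x) in either direction;
2. screens the surviving genes by Spearman correlation against the driver
   with a Bonferroni-corrected pass threshold (corrected p < 0.05, with
   the requested correlation sign);
3. optionally filters the passing genes by concordance with a 3-level
   perturbation experiment (over-expression = 1, control = 0,
   knock-down = -1): kept genes must decrease with the coded level;
4. intersects candidate target lists (e.g. sequence-predicted targets
   with a curated cancer-gene list) by case-insensitive set intersection.

Spearman p-values come from the t-distribution approximation for cohort-
sized n and from exact permutation enumeration for n <= 9 samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .errors import ValidationError

__all__ = [
    "ExpressionCohort",
    "AssociationResult",
    "filter_variable_genes",
    "spearman_screen",
    "lentiviral_concordance",
    "intersect_candidate_targets",
    "results_frame",
]

#: Exact permutation p-values are used at or below this sample count.
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class ExpressionCohort:
    """Genes x samples expression matrix plus a per-sample driver vector.

    ``values`` rows are genes, columns samples; ``driver`` is indexed by
    the same samples (a miRNA's expression, or coded perturbation
    levels). ``planted_genes`` records simulated ground truth and is empty
    for real data.
    """

    values: pd.DataFrame
    driver: pd.Series
    planted_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValidationError("expression matrix is empty")
        if list(self.values.columns) != list(self.driver.index):
            raise ValidationError("driver samples do not match matrix columns")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, driver_path: str | Path) -> "ExpressionCohort":
        """Load a TSV matrix (first column = gene id) and a 2-column driver TSV."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        driver_df = pd.read_csv(driver_path, sep="\t", index_col=0)
        driver = driver_df.iloc[:, 0].reindex(values.columns)
        if driver.isna().any():
            missing = list(driver.index[driver.isna()])[:5]
            raise ValidationError(f"driver file lacks samples {missing}")
        return cls(values=values, driver=driver)

    def to_tsv(self, matrix_path: str | Path, driver_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene")
        self.driver.rename("value").to_csv(driver_path, sep="\t", index_label="sample")


@dataclass(frozen=True, slots=True)
class AssociationResult:
    """One gene's Spearman association with the driver.

    ``p_adjusted`` is the Bonferroni-corrected p (capped at 1); ``passes``
    requires corrected p < alpha and the requested correlation sign.
    ``degenerate`` marks constant genes, whose rho is undefined (NaN) and
    whose p is reported as 1.
    """

    gene: str
    rho: float
    p: float
    p_adjusted: float
    passes: bool
    degenerate: bool = False


def filter_variable_genes(
    cohort: ExpressionCohort, fold: float = 1.5, min_frac: float = 0.2
) -> ExpressionCohort:
    """Keep genes with enough fold-change variation around their median.

    A sample "deviates" when its value is >= fold * median or
    <= median / fold (boundaries inclusive); a gene is kept when the
    deviating fraction is >= min_frac. Zero-median genes are evaluated
    after adding the smallest positive value of the matrix as a
    pseudocount, which keeps the ratio rule total on count-like data.
    """
    if fold <= 1:
        raise ValidationError(f"fold must exceed 1, got {fold}")
    if not 0 < min_frac <= 1:
        raise ValidationError(f"min_frac must be in (0, 1], got {min_frac}")
    mat = cohort.values.to_numpy(dtype=float)
    medians = np.median(mat, axis=1)
    positive = mat[mat > 0]
    pseudo = float(positive.min()) if positive.size else 1.0
    zero_med = medians == 0
    if zero_med.any():
        mat = mat.copy()
        mat[zero_med] += pseudo
        medians = np.median(mat, axis=1)
    med = medians[:, None]
    deviates = (mat >= fold * med) | (mat <= med / fold)
    keep = deviates.mean(axis=1) >= min_frac
    return ExpressionCohort(
        values=cohort.values.loc[keep],
        driver=cohort.driver,
        planted_genes=cohort.planted_genes,
    )


def _spearman_exact_p(gene_ranks: np.ndarray, driver_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for one gene at toy sample counts."""
    n = gene_ranks.size
    g = gene_ranks - gene_ranks.mean()
    perms = np.array(list(itertools.permutations(driver_ranks)), dtype=float)
    perms -= driver_ranks.mean()
    denom = np.sqrt((g @ g) * (perms[0] @ perms[0]))
    rhos = perms @ g / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_screen(
    cohort: ExpressionCohort,
    sign: str = "negative",
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Per-gene Spearman correlation with the driver, Bonferroni-corrected.

    ``sign`` selects which correlations may pass: "negative", "positive"
    or "any". The Bonferroni multiplier is the number of genes tested
    (i.e. the genes present in the cohort, normally after
    :func:`filter_variable_genes`). Mid-ranks handle ties. Constant genes
    get an undefined rho, p = 1 and a degenerate flag.
    """
    if sign not in {"negative", "positive", "any"}:
        raise ValidationError(f"sign must be negative/positive/any, got {sign!r}")
    mat = cohort.values.to_numpy(dtype=float)
    driver = cohort.driver.to_numpy(dtype=float)
    n = driver.size
    if n < 4:
        raise ValidationError("need at least 4 samples")
    if np.ptp(driver) == 0:
        raise ValidationError("driver is constant; correlation undefined")

    d_ranks = rankdata(driver)
    g_ranks = rankdata(mat, axis=1)
    dc = d_ranks - d_ranks.mean()
    gc = g_ranks - g_ranks.mean(axis=1, keepdims=True)
    g_ss = (gc**2).sum(axis=1)
    d_ss = float(dc @ dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = gc @ dc / np.sqrt(g_ss * d_ss)
    degenerate = g_ss == 0

    n_tested = mat.shape[0]
    exact = n <= EXACT_PERMUTATION_MAX_N
    results: list[AssociationResult] = []
    for i, gene in enumerate(cohort.genes):
        if degenerate[i]:
            results.append(AssociationResult(gene, float("nan"), 1.0, 1.0, False, True))
            continue
        r = float(np.clip(rho[i], -1.0, 1.0))
        if exact:
            p = _spearman_exact_p(g_ranks[i], d_ranks, r)
        elif abs(r) == 1.0:
            p = 0.0
        else:
            stat = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * t_dist.sf(abs(stat), df=n - 2))
        p_adj = min(1.0, p * n_tested)
        sign_ok = sign == "any" or (r < 0 if sign == "negative" else r > 0)
        results.append(
            AssociationResult(gene, r, p, p_adj, bool(p_adj < alpha and sign_ok), False)
        )
    return results


def results_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results (one row per gene)."""
    rows = list(results)
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "rho": [r.rho for r in rows],
            "p": [r.p for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
            "passes": [r.passes for r in rows],
        }
    )


def lentiviral_concordance(
    expression_by_condition: Mapping[int, Mapping[str, float] | pd.Series],
    cohort_results: Iterable[AssociationResult],
) -> list[str]:
    """Genes down-modulated by the perturbation *and* passing the cohort screen.

    ``expression_by_condition`` maps the coded levels {1: over-expression,
    0: control, -1: knock-down} to per-gene expression values. A gene is
    concordant when its expression is negatively rank-correlated with the
    level across the three conditions (for single values per condition
    this means strictly decreasing: level 1 < level 0 < level -1 in
    expression... i.e. expression falls as the level rises). With only
    three coded conditions this is a filter, not an inference.
    """
    levels = set(expression_by_condition)
    if levels != {1, 0, -1}:
        raise ValidationError(f"need exactly the levels 1, 0, -1; got {sorted(levels)}")
    frames = {lvl: pd.Series(vals, dtype=float) for lvl, vals in expression_by_condition.items()}
    common = set(frames[1].index) & set(frames[0].index) & set(frames[-1].index)
    passing = {r.gene for r in cohort_results if r.passes}

    concordant = []
    for gene in common:
        lvls = np.array([1.0, 0.0, -1.0])
        expr = np.array([frames[1][gene], frames[0][gene], frames[-1][gene]], dtype=float)
        if np.ptp(expr) == 0:
            continue
        lr = rankdata(lvls)
        er = rankdata(expr)
        lc, ec = lr - lr.mean(), er - er.mean()
        rho = float(lc @ ec / np.sqrt((lc @ lc) * (ec @ ec)))
        if rho < 0 and gene in passing:
            concordant.append(gene)
    return sorted(concordant)


def intersect_candidate_targets(
    predicted_targets: Iterable[str], cancer_genes: Iterable[str]
) -> list[str]:
    """Case-normalized set intersection of two gene lists, sorted."""
    a = {str(g).strip().upper() for g in predicted_targets if str(g).strip()}
    b = {str(g).strip().upper() for g in cancer_genes if str(g).strip()}
    return sorted(a & b)
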