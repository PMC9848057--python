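"""Three-category tissue-specificity classification of TPM expression and
the fold-change / adjusted-P differential screen between two skin types.

Classification rules (evaluated in order, first match wins):

1. ``not_detected``  — TPM below the detection threshold in every tissue.
2. ``tissue_enriched`` — highest tissue at least ``fold_threshold`` times the
   second-highest tissue.
3. ``group_enriched`` — the set of tissues with per-gene Z-score at or above
   ``z_threshold`` (size 2..group_max) has mean TPM at least
   ``fold_threshold`` times the mean of all remaining tissues.
4. ``other`` — everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import ExpressionMatrix

CATEGORIES = ("not_detected", "tissue_enriched", "group_enriched", "other")


@dataclass(frozen=True)
class ExpressionClass:
    gene_id: str
    category: str
    focus_tissues: frozenset[str]
    fold: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    passes_screen: bool


def _zscores(values: np.ndarray, log_space: bool) -> np.ndarray:
    x = np.log2(values + 1.0) if log_space else values
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def classify_genes(
    matrix: ExpressionMatrix,
    fold_threshold: float = 5.0,
    detect_threshold: float = 1.0,
    z_threshold: float = 1.0,
    group_max: int = 7,
    z_log_space: bool = False,
) -> list[ExpressionClass]:
    """Assign each gene exactly one of the four expression categories.

    Z-scores are computed per gene across tissue TPMs (raw scale by
    default). A second-highest tissue of exactly zero with a positive
    maximum counts as infinite enrichment.
    """
    tissues = matrix.tissue_ids
    if len(tissues) < 3:
        raise ValidationError("classification needs at least 3 tissues")
    if group_max < 2:
        raise ValidationError("group_max must be at least 2")
    out: list[ExpressionClass] = []
    values = matrix.values.to_numpy(dtype=float)
    for gene_id, row in zip(matrix.gene_ids, values):
        if (row < detect_threshold).all():
            out.append(ExpressionClass(gene_id, "not_detected", frozenset(), 0.0))
            continue
        order = np.argsort(row)[::-1]
        top, second = row[order[0]], row[order[1]]
        if second == 0.0 and top > 0.0:
            out.append(
                ExpressionClass(
                    gene_id, "tissue_enriched",
                    frozenset({tissues[order[0]]}), math.inf,
                )
            )
            continue
        if second > 0.0 and top / second >= fold_threshold:
            out.append(
                ExpressionClass(
                    gene_id, "tissue_enriched",
                    frozenset({tissues[order[0]]}), top / second,
                )
            )
            continue
        z = _zscores(row, z_log_space)
        group = z >= z_threshold
        n_group = int(group.sum())
        if 2 <= n_group <= group_max and n_group < len(tissues):
            group_mean = row[group].mean()
            rest_mean = row[~group].mean()
            if rest_mean == 0.0 and group_mean > 0.0:
                fold = math.inf
            elif rest_mean > 0.0:
                fold = group_mean / rest_mean
            else:
                fold = 0.0
            if fold >= fold_threshold:
                out.append(
                    ExpressionClass(
                        gene_id, "group_enriched",
                        frozenset(t for t, g in zip(tissues, group) if g), fold,
                    )
                )
                continue
        out.append(ExpressionClass(gene_id, "other", frozenset(), 0.0))
    return out


def skin_related_set(
    classes: list[ExpressionClass], anchor_tissue: str
) -> tuple[set[str], dict[str, int]]:
    """Genes enriched in (or group-enriched with) the anchor tissue, plus a
    tally of co-expression partner tissues among group-enriched members."""
    known = {t for c in classes for t in c.focus_tissues}
    related: set[str] = set()
    partner_counts: dict[str, int] = {}
    for cls in classes:
        if cls.category == "tissue_enriched" and cls.focus_tissues == {anchor_tissue}:
            related.add(cls.gene_id)
        elif cls.category == "group_enriched" and anchor_tissue in cls.focus_tissues:
            related.add(cls.gene_id)
            for partner in cls.focus_tissues - {anchor_tissue}:
                partner_counts[partner] = partner_counts.get(partner, 0) + 1
    if not related and known and anchor_tissue not in known:
        # distinguish "no skin genes" from a typo'd tissue name
        raise ValidationError(f"tissue {anchor_tissue!r} not seen in any class")
    return related, partner_counts


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running_min = 1.0
    for rank_index in range(m - 1, -1, -1):
        idx = order[rank_index]
        value = p[idx] * m / (rank_index + 1)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def differential_screen(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    classes: list[ExpressionClass],
    anchor_tissue: str = "skin",
    fold_cut: float = 2.0,
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Per-gene Welch's t-test on log2(TPM+1) between two replicate groups,
    BH-adjusted, combined with the fold-change and enrichment-class filter.

    ``matrix_a``/``matrix_b`` are genes x replicate-column frames sharing a
    gene index. ``passes_screen`` requires |fold| > fold_cut, adjusted
    P < alpha, and membership in the anchor tissue's related gene set.
    """
    if matrix_a.shape[1] < 2 or matrix_b.shape[1] < 2:
        raise ValidationError("each side needs at least 2 replicates")
    if not matrix_a.index.equals(matrix_b.index):
        raise ValidationError("replicate matrices must share a gene index")
    related, _ = skin_related_set(classes, anchor_tissue) if classes else (set(), {})

    a = np.log2(matrix_a.to_numpy(dtype=float) + 1.0)
    b = np.log2(matrix_b.to_numpy(dtype=float) + 1.0)
    mean_a = matrix_a.to_numpy(dtype=float).mean(axis=1) + 1.0
    mean_b = matrix_b.to_numpy(dtype=float).mean(axis=1) + 1.0
    log2_fc = np.log2(mean_a / mean_b)

    p_values = np.ones(len(matrix_a), dtype=float)
    for i in range(len(matrix_a)):
        if a[i].std(ddof=1) == 0.0 and b[i].std(ddof=1) == 0.0:
            p_values[i] = 1.0  # no within-group evidence
            continue
        p_values[i] = stats.ttest_ind(a[i], b[i], equal_var=False).pvalue
    adjusted = benjamini_hochberg(p_values)

    results = []
    for gene_id, fc, p, ap in zip(matrix_a.index, log2_fc, p_values, adjusted):
        passes = (
            abs(fc) > math.log2(fold_cut)
            and ap < alpha
            and gene_id in related
        )
        results.append(DifferentialResult(gene_id, float(fc), float(p), float(ap), passes))
    return results


def classes_to_frame(classes: list[ExpressionClass]) -> pd.DataFrame:
    """Stable-column TSV-ready view of a classification."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in classes],
            "category": [c.category for c in classes],
            "focus_tissues": [",".join(sorted(c.focus_tissues)) for c in classes],
            "fold": [c.fold for c in classes],
        }
    )


def classes_from_frame(frame: pd.DataFrame) -> list[ExpressionClass]:
    out = []
    for row in frame.itertuples(index=False):
        focus = frozenset(t for t in str(row.focus_tissues).split(",") if t and t != "nan")
        out.append(ExpressionClass(row.gene_id, row.category, focus, float(row.fold)))
    return out
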