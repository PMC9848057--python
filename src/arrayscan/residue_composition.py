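"""Amino-acid / nucleotide composition statistics, the tyrosine x
skin-enrichment candidate screen, and per-group composition summaries with
one-way ANOVA."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .expression_atlas import ExpressionClass, skin_related_set
from .io_formats import CodingRecord

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CompositionProfile:
    """Residue proportions over the 20 standard amino acids (X excluded from
    numerator and denominator) and CDS GC content over unambiguous bases."""

    gene_id: str
    proportions: Mapping[str, float]
    gly: float
    tyr: float
    gly_tyr: float
    gc: float
    gc3: float


def composition(record: CodingRecord) -> CompositionProfile:
    counts = Counter(record.protein)
    counts.pop("X", None)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError(f"{record.gene_id}: empty protein after X exclusion")
    proportions = {aa: counts.get(aa, 0) / total for aa in STANDARD_RESIDUES}
    nt = Counter(record.cds)
    unambiguous = sum(nt[b] for b in "ACGT")
    gc = (nt["G"] + nt["C"]) / unambiguous if unambiguous else 0.0
    third = record.cds[2::3]
    nt3 = Counter(third)
    unamb3 = sum(nt3[b] for b in "ACGT")
    gc3 = (nt3["G"] + nt3["C"]) / unamb3 if unamb3 else 0.0
    return CompositionProfile(
        gene_id=record.gene_id,
        proportions=proportions,
        gly=proportions["G"],
        tyr=proportions["Y"],
        gly_tyr=proportions["G"] + proportions["Y"],
        gc=gc,
        gc3=gc3,
    )


def tyrosine_screen(
    profiles: Sequence[CompositionProfile],
    classes: Sequence[ExpressionClass],
    tyr_cutoff: float = 0.05,
    anchor_tissue: str = "skin",
    family_labels: Mapping[str, str] | None = None,
) -> tuple[set[str], dict[str, int]]:
    """Genes with tyrosine proportion >= cutoff AND anchor-tissue-related
    expression. Returns the gene set and a per-family breakdown when family
    labels are supplied."""
    class_ids = {c.gene_id for c in classes}
    missing = [p.gene_id for p in profiles if p.gene_id not in class_ids]
    if missing:
        raise ValidationError(f"profiles without expression classes: {missing}")
    related, _ = skin_related_set(list(classes), anchor_tissue)
    selected = {
        p.gene_id for p in profiles if p.tyr >= tyr_cutoff and p.gene_id in related
    }
    breakdown: dict[str, int] = {}
    if family_labels:
        for gene_id in selected:
            family = family_labels.get(gene_id, "unlabeled")
            breakdown[family] = breakdown.get(family, 0) + 1
    return selected, breakdown


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """F statistic, (df_between, df_within), and p-value."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValidationError(f"ANOVA group {i} has fewer than 2 members")
    result = stats.f_oneway(*groups)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    f = float(result.statistic)
    p = float(result.pvalue)
    if f != f:  # all values identical across all groups -> 0/0
        f, p = 0.0, 1.0
    return f, (df_between, df_within), p


def group_composition_summary(
    grouped_profiles: Mapping[str, Sequence[CompositionProfile]],
    anova: bool = True,
) -> pd.DataFrame:
    """Per-group means of gly/tyr/gly_tyr/gc with an omnibus one-way ANOVA
    per metric (attached in ``DataFrame.attrs['anova']``)."""
    if not grouped_profiles:
        raise ValidationError("no groups supplied")
    metrics = ("gly", "tyr", "gly_tyr", "gc")
    rows = {
        group: {m: sum(getattr(p, m) for p in ps) / len(ps) for m in metrics}
        for group, ps in grouped_profiles.items()
        if ps or _raise_empty(group)
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(metrics)]
    frame.index.name = "group"
    if anova:
        if len(grouped_profiles) < 2:
            raise ValidationError("ANOVA requested with a single group")
        frame.attrs["anova"] = {
            m: one_way_anova(
                [[getattr(p, m) for p in ps] for ps in grouped_profiles.values()]
            )
            for m in metrics
        }
    return frame


def _raise_empty(group: str) -> bool:
    raise ValidationError(f"group {group!r} is empty")
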