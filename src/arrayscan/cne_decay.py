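"""Conserved-noncoding-element (CNE) decay scoring.

Coverage of each CNE is the union of identity-filtered hit intervals on the
CNE axis divided by CNE length; status uses strict cuts (decayed below the
lower cut, intact above the upper cut, intermediate in between).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .errors import ValidationError
from .io_formats import HitRecord


@dataclass(frozen=True)
class CoverageReport:
    cne_id: str
    cne_length: int
    merged_covered: int
    coverage: float
    status: str


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def classify_coverage(coverage: float, decay_cut: float, intact_cut: float) -> str:
    if coverage < decay_cut:
        return "decayed"
    if coverage > intact_cut:
        return "intact"
    return "intermediate"


def coverage_from_hits(
    cne_lengths: Mapping[str, int],
    hits: Sequence[HitRecord],
    min_identity: float = 0.6,
    decay_cut: float = 0.5,
    intact_cut: float = 0.9,
) -> list[CoverageReport]:
    """Merged-interval coverage and decay status per CNE.

    Hits below ``min_identity`` are discarded; CNEs with no surviving hit get
    coverage 0 and status decayed.
    """
    if not 0 <= decay_cut <= intact_cut <= 1:
        raise ValidationError("require 0 <= decay_cut <= intact_cut <= 1")
    by_cne: dict[str, list[tuple[int, int]]] = {c: [] for c in cne_lengths}
    for hit in hits:
        if hit.query_id not in cne_lengths:
            raise ValidationError(f"hit for unknown CNE {hit.query_id!r}")
        if hit.query_end > cne_lengths[hit.query_id]:
            raise ValidationError(
                f"{hit.query_id}: hit end {hit.query_end} exceeds declared "
                f"length {cne_lengths[hit.query_id]}"
            )
        if hit.percent_identity >= min_identity:
            by_cne[hit.query_id].append((hit.query_start, hit.query_end))
    reports = []
    for cne_id, length in cne_lengths.items():
        covered = sum(e - s for s, e in merge_intervals(by_cne[cne_id]))
        coverage = covered / length
        reports.append(
            CoverageReport(
                cne_id=cne_id,
                cne_length=length,
                merged_covered=covered,
                coverage=coverage,
                status=classify_coverage(coverage, decay_cut, intact_cut),
            )
        )
    return reports


def _make_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = -abs(mismatch)
    aligner.open_gap_score = -abs(gap)
    aligner.extend_gap_score = -abs(gap)
    return aligner


def _best_local_hit(
    aligner: PairwiseAligner, query: str, target: str
) -> tuple[float, int, int, float] | None:
    """(score, query_start, query_end, identity) of the best local alignment,
    or None when nothing aligns."""
    if not query or not target:
        return None
    alignments = aligner.align(query, target)
    try:
        best = alignments[0]
    except (IndexError, ValueError):
        return None
    counts = best.counts()
    aligned_cols = counts.identities + counts.mismatches
    if aligned_cols == 0:
        return None
    identity = counts.identities / aligned_cols
    qblocks = best.aligned[0]
    return float(best.score), int(qblocks[0][0]), int(qblocks[-1][1]), identity


def local_align_coverage(
    cne_seqs: Sequence[tuple[str, str]],
    target_seqs: Sequence[tuple[str, str]],
    match: float = 1.0,
    mismatch: float = 1.0,
    gap: float = 2.0,
    min_score: float = 20.0,
) -> list[HitRecord]:
    """Desk-scale Smith-Waterman substitute for genome alignment.

    Every CNE is locally aligned against every target on both strands;
    alignments at or above ``min_score`` become HitRecords. After each hit
    the covered query segment is masked and the flanks are re-searched, so a
    CNE split by a deletion in the target yields multiple hits.
    """
    if min_score <= 0:
        raise ValidationError("min_score must be positive")
    if not cne_seqs or not target_seqs:
        raise ValidationError("empty input sequences")
    aligner = _make_aligner(match, mismatch, gap)
    hits: list[HitRecord] = []

    def search(cne_id: str, query: str, offset: int, target_id: str, target: str) -> None:
        if len(query) * match < min_score:
            return
        fwd = _best_local_hit(aligner, query, target)
        rc = _best_local_hit(aligner, str(Seq(query).reverse_complement()), target)
        candidates = []
        if fwd is not None:
            candidates.append(("+", fwd))
        if rc is not None:
            score, s, e, ident = rc
            candidates.append(("-", (score, len(query) - e, len(query) - s, ident)))
        if not candidates:
            return
        strand, (score, qs, qe, identity) = max(candidates, key=lambda c: c[1][0])
        if score < min_score or qe <= qs:
            return
        hits.append(
            HitRecord(
                query_id=cne_id,
                query_start=offset + qs,
                query_end=offset + qe,
                target_id=target_id,
                percent_identity=identity,
                score=score,
                strand=strand,
            )
        )
        search(cne_id, query[:qs], offset, target_id, target)
        search(cne_id, query[qe:], offset + qe, target_id, target)

    for cne_id, cne_seq in cne_seqs:
        if not cne_seq:
            raise ValidationError(f"empty CNE sequence {cne_id!r}")
        for target_id, target_seq in target_seqs:
            if not target_seq:
                raise ValidationError(f"empty target sequence {target_id!r}")
            search(cne_id, cne_seq, 0, target_id, target_seq)
    return hits


def decay_contrast(
    reports_by_species: Mapping[str, Sequence[CoverageReport]],
    focal_species: str,
    region_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-CNE table flagging focal-decayed & all-others-intact elements,
    with optional per-region decayed fractions in ``attrs['region_decay']``
    (decay fractions are computed from the focal species' statuses)."""
    if focal_species not in reports_by_species:
        raise ValidationError(f"no reports for focal species {focal_species!r}")
    per_species = {
        sp: {r.cne_id: r for r in reports} for sp, reports in reports_by_species.items()
    }
    cne_ids = sorted(per_species[focal_species])
    for sp, reports in per_species.items():
        if sorted(reports) != cne_ids:
            raise ValidationError(f"species {sp!r} missing CNE ids")
    others = [sp for sp in per_species if sp != focal_species]
    rows = []
    for cne_id in cne_ids:
        focal = per_species[focal_species][cne_id]
        flagged = focal.status == "decayed" and all(
            per_species[sp][cne_id].status == "intact" for sp in others
        )
        row = {
            "cne_id": cne_id,
            "focal_coverage": focal.coverage,
            "focal_status": focal.status,
            "flagged": flagged,
        }
        for sp in others:
            row[f"coverage_{sp}"] = per_species[sp][cne_id].coverage
        rows.append(row)
    frame = pd.DataFrame(rows)
    if region_labels is not None:
        missing = set(cne_ids) - set(region_labels)
        if missing:
            raise ValidationError(f"CNEs without region label: {sorted(missing)}")
        region_decay: dict[str, float] = {}
        regions: dict[str, list[str]] = {}
        for cne_id in cne_ids:
            regions.setdefault(region_labels[cne_id], []).append(cne_id)
        for region, members in regions.items():
            decayed = sum(
                per_species[focal_species][c].status == "decayed" for c in members
            )
            region_decay[region] = decayed / len(members)
        frame.attrs["region_decay"] = region_decay
    return frame
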