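"""Homogenization statistics for tandem gene arrays.

Contains the global protein aligner (affine-gap Needleman-Wunsch/Gotoh with
deterministic traceback), p-distance/identity, neighbor-identity array
reports with identical-CDS clade detection and orientation, an NG86-style
synonymous-substitution (Ks) estimator with Jukes-Cantor correction, and
molecular-clock dating T = Ks / (2 * mu).

Gap cost convention: a gap of length k costs gap_open + (k - 1) * gap_extend
(penalties given as positive numbers).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .errors import ValidationError
from .io_formats import CodingRecord, GeneLocus
from .residue_composition import one_way_anova

DEFAULT_MU = 2e-9  # substitutions per site per year

_BASES = "ACGT"
_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned strings differ in length")

    @property
    def p_distance(self) -> float:
        """Mismatch fraction over columns where neither side has a gap."""
        pairs = [
            (x, y)
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        ]
        if not pairs:
            return 0.0
        return sum(x != y for x, y in pairs) / len(pairs)

    @property
    def identity(self) -> float:
        return 1.0 - self.p_distance


def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except (FileNotFoundError, ValueError) as exc:
        raise ValidationError(f"unknown substitution matrix {name!r}") from exc


def align_proteins(
    a: str,
    b: str,
    id_a: str = "a",
    id_b: str = "b",
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment (Gotoh affine-gap DP).

    Tie-breaking during traceback is deterministic: match/mismatch is
    preferred over a gap in ``a``, which is preferred over a gap in ``b``.
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    sub = _load_matrix(matrix)
    alphabet = str(sub.alphabet)
    try:
        idx_a = np.array([alphabet.index(c) for c in a])
        idx_b = np.array([alphabet.index(c) for c in b])
    except ValueError as exc:
        raise ValidationError(f"residue outside {matrix} alphabet: {exc}") from exc
    smat = np.asarray(sub)[np.ix_(idx_a, idx_b)]
    n, m = len(a), len(b)
    neg = -math.inf
    # M: both consumed; GA: gap in a (column consumes b); GB: gap in b.
    M = np.full((n + 1, m + 1), neg)
    GA = np.full((n + 1, m + 1), neg)
    GB = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    GA[0, 1:] = -(gap_open + np.arange(m) * gap_extend)
    col_ext = np.arange(m + 1) * gap_extend
    for i in range(1, n + 1):
        M[i, 1:] = smat[i - 1] + np.maximum(
            np.maximum(M[i - 1, :-1], GA[i - 1, :-1]), GB[i - 1, :-1]
        )
        GB[i, 0] = -(gap_open + (i - 1) * gap_extend)
        GB[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], GA[i - 1, 1:]) - gap_open,
            GB[i - 1, 1:] - gap_extend,
        )
        # GA[i, j] = max_{k <= j-1} (max(M[i,k], GB[i,k]) - gap_open
        #                            - (j-1-k) * gap_extend), via a prefix max
        shifted = np.maximum(M[i], GB[i]) - gap_open + col_ext
        GA[i, 1:] = np.maximum.accumulate(shifted[:-1]) - col_ext[:-1]
    # traceback, preferring M > GA > GB at every tie
    i, j = n, m
    finals = (M[n, m], GA[n, m], GB[n, m])
    score = max(finals)
    state = finals.index(score)  # 0=M, 1=GA, 2=GB
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            s = sub[a[i - 1], b[j - 1]]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            candidates = (M[i, j], GA[i, j], GB[i, j])
        elif state == 1:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = GA[i, j]
            j -= 1
            candidates = (
                M[i, j] - gap_open,
                GA[i, j] - gap_extend,
                GB[i, j] - gap_open,
            )
        else:
            out_a.append(a[i - 1])
            out_b.append("-")
            target = GB[i, j]
            i -= 1
            candidates = (
                M[i, j] - gap_open,
                GA[i, j] - gap_open,
                GB[i, j] - gap_extend,
            )
        if i == 0 and j == 0:
            break
        state = next(
            k for k, c in enumerate(candidates) if math.isclose(c, target, abs_tol=1e-9)
        )
    return PairwiseAlignment(
        id_a, id_b, "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)
    )


# ---------------------------------------------------------------------------
# Array report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrayReport:
    contig: str
    ordered_genes: tuple[str, ...]
    neighbor_identities: tuple[float, ...]
    mean_neighbor_identity: float
    tail_to_head: bool
    clades: tuple[tuple[str, ...], ...]

    @property
    def clade_sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.clades)


def neighbor_identity_profile(
    records: Sequence[CodingRecord],
    loci: Sequence[GeneLocus],
    family_filter: set[str] | None = None,
) -> ArrayReport:
    """Order genes along their contig, align adjacent protein pairs, and
    summarize identity, orientation, and identical-CDS clades."""
    by_id = {r.gene_id: r for r in records}
    kept = [
        l
        for l in loci
        if (family_filter is None or l.gene_id in family_filter)
    ]
    if family_filter is not None:
        missing = family_filter - {l.gene_id for l in loci}
        if missing:
            raise ValidationError(f"genes without loci: {sorted(missing)}")
    contigs = {l.contig for l in kept}
    if len(contigs) != 1:
        raise ValidationError(
            f"one contig per report required, got {sorted(contigs)}"
        )
    for locus in kept:
        if locus.gene_id not in by_id:
            raise ValidationError(f"locus {locus.gene_id!r} without coding record")
    starts = [l.start for l in kept]
    if len(set(starts)) != len(starts):
        raise ValidationError("tied start coordinates among distinct genes")
    ordered = sorted(kept, key=lambda l: l.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            warnings.warn(
                f"overlapping loci {prev.gene_id}/{cur.gene_id}; order kept by start"
            )
    gene_order = tuple(l.gene_id for l in ordered)
    identities = tuple(
        align_proteins(
            by_id[x].protein, by_id[y].protein, id_a=x, id_b=y
        ).identity
        for x, y in zip(gene_order, gene_order[1:])
    )
    mean_identity = float(np.mean(identities)) if identities else 1.0
    tail_to_head = len({l.strand for l in ordered}) <= 1
    clade_map: dict[str, list[str]] = {}
    for gene_id in gene_order:
        clade_map.setdefault(by_id[gene_id].cds, []).append(gene_id)
    clades = tuple(tuple(v) for v in clade_map.values())
    return ArrayReport(
        contig=next(iter(contigs)),
        ordered_genes=gene_order,
        neighbor_identities=identities,
        mean_neighbor_identity=mean_identity,
        tail_to_head=tail_to_head,
        clades=clades,
    )


def compare_arrays(*reports: ArrayReport) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA over the neighbor-identity samples of >= 2 arrays."""
    if len(reports) < 2:
        raise ValidationError("need at least 2 arrays to compare")
    groups = [list(r.neighbor_identities) for r in reports]
    return one_way_anova(groups)


# ---------------------------------------------------------------------------
# NG86 Ks and molecular-clock dating
# ---------------------------------------------------------------------------


def _synonymous_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of the 3 possible nucleotide changes that are
    synonymous (changes producing a stop count as nonsynonymous)."""
    aa = _CODON_TABLE[codon]
    fractions = []
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[mutant] == aa:
                syn += 1
        fractions.append(syn / 3.0)
    return tuple(fractions)


_SYN_FRACTIONS = {
    c: _synonymous_fractions(c) for c in _CODON_TABLE if _CODON_TABLE[c] != "*"
}


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Synonymous/nonsynonymous difference counts between two sense codons,
    averaged over all minimal substitution pathways that avoid stop codons.
    Returns None when every pathway crosses a stop codon."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                ok = False
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_total / n_paths, nonsyn_total / n_paths


@dataclass(frozen=True)
class KsEstimate:
    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    mu: float
    T: float
    n_codons: int
    n_excluded: int
    saturated: bool

    @property
    def t_mya(self) -> float:
        return self.T / 1e6


def jukes_cantor(p: float) -> float:
    """JC-corrected substitution rate; NaN past the 3/4 saturation bound."""
    if p < 0:
        raise ValidationError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def divergence_time(ks: float, mu: float = DEFAULT_MU) -> float:
    """Molecular-clock dating in years: T = Ks / (2 * mu)."""
    if mu <= 0:
        raise ValidationError("mu must be positive")
    return ks / (2.0 * mu)


def codon_align(a: CodingRecord, b: CodingRecord) -> tuple[str, str]:
    """Protein-guided codon alignment: align proteins, thread gaps back onto
    the CDS, and drop codon columns where either side is gapped."""
    alignment = align_proteins(a.protein, b.protein, id_a=a.gene_id, id_b=b.gene_id)
    codons_a = a.codons()
    codons_b = b.codons()
    ia = ib = 0
    kept_a: list[str] = []
    kept_b: list[str] = []
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x != "-" and y != "-":
            kept_a.append(codons_a[ia])
            kept_b.append(codons_b[ib])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(kept_a), "".join(kept_b)


def ng86_ks(a: CodingRecord, b: CodingRecord, mu: float = DEFAULT_MU) -> KsEstimate:
    """NG86-style Ks/Ka with Jukes-Cantor correction and clock dating.

    Codons containing N or a stop in either sequence are excluded pairwise;
    codon pairs whose every minimal pathway crosses a stop are excluded and
    counted in ``n_excluded``. S and N are averaged over the two sequences;
    multi-position differences are averaged over minimal pathways.
    """
    cds_a, cds_b = codon_align(a, b)
    if len(cds_a) != len(cds_b):
        raise ValidationError("codon alignment produced unequal lengths")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    n_excluded = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if "N" in ca or "N" in cb:
            n_excluded += 1
            continue
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            n_excluded += 1
            continue
        counts = _pathway_counts(ca, cb)
        if counts is None:
            n_excluded += 1
            continue
        sa = _SYN_FRACTIONS[ca]
        sb = _SYN_FRACTIONS[cb]
        S += (sum(sa) + sum(sb)) / 2.0
        N += 3.0 - (sum(sa) + sum(sb)) / 2.0
        Sd += counts[0]
        Nd += counts[1]
        n_codons += 1
    if n_codons == 0:
        raise ValidationError(f"{a.gene_id}/{b.gene_id}: no comparable codons")
    if S == 0:
        raise ValidationError(f"{a.gene_id}/{b.gene_id}: zero synonymous sites")
    pS = Sd / S
    pN = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    saturated = math.isnan(ks)
    t = math.nan if saturated else divergence_time(ks, mu)
    return KsEstimate(
        id_a=a.gene_id,
        id_b=b.gene_id,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=ks,
        Ka=ka,
        mu=mu,
        T=t,
        n_codons=n_codons,
        n_excluded=n_excluded,
        saturated=saturated,
    )


@dataclass(frozen=True)
class KsGroupSummary:
    mean_ks: float
    mean_t: float
    n_pairs: int
    n_saturated: int


@dataclass(frozen=True)
class CladeKsSummary:
    within_a: KsGroupSummary | None
    within_b: KsGroupSummary | None
    between: KsGroupSummary


def _summarize_pairs(
    records: dict[str, CodingRecord],
    pairs: Iterable[tuple[str, str]],
    mu: float,
) -> KsGroupSummary:
    ks_values: list[float] = []
    n_saturated = 0
    for x, y in pairs:
        est = ng86_ks(records[x], records[y], mu=mu)
        if est.saturated:
            n_saturated += 1
        else:
            ks_values.append(est.Ks)
    mean_ks = float(np.mean(ks_values)) if ks_values else math.nan
    mean_t = divergence_time(mean_ks, mu) if ks_values else math.nan
    return KsGroupSummary(mean_ks, mean_t, len(ks_values), n_saturated)


def clade_ks_summary(
    records: Sequence[CodingRecord],
    clade_a: set[str],
    clade_b: set[str],
    mu: float = DEFAULT_MU,
) -> CladeKsSummary:
    """Within-clade and between-clade mean pairwise Ks and clock dates.

    Saturated pairs are excluded from means but counted. Singleton clades get
    no within-group summary; the between-group summary is still computed.
    """
    if clade_a & clade_b:
        raise ValidationError("clades must be disjoint")
    by_id = {r.gene_id: r for r in records}
    missing = (clade_a | clade_b) - set(by_id)
    if missing:
        raise ValidationError(f"clade genes without records: {sorted(missing)}")
    a_sorted, b_sorted = sorted(clade_a), sorted(clade_b)
    within_a = (
        _summarize_pairs(by_id, itertools.combinations(a_sorted, 2), mu)
        if len(a_sorted) >= 2
        else None
    )
    within_b = (
        _summarize_pairs(by_id, itertools.combinations(b_sorted, 2), mu)
        if len(b_sorted) >= 2
        else None
    )
    between = _summarize_pairs(by_id, itertools.product(a_sorted, b_sorted), mu)
    return CladeKsSummary(within_a=within_a, within_b=within_b, between=between)
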