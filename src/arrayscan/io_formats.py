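"""Readers/writers for the external formats the pipeline touches and
validated construction of the core domain records.

Internal coordinate convention is 0-based half-open everywhere; conversion
to/from 1-based inclusive dialects (GFF3, BLAST outfmt 6) happens only at
the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def translate_cds(cds: str) -> str:
    """Translate a CDS under the standard genetic code (N-containing codons
    become X unless the ambiguity is resolvable)."""
    if len(cds) % 3 != 0:
        raise FormatError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate())


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingRecord:
    """A gene's CDS paired with its translated protein.

    Invariants enforced at construction: CDS length divisible by 3, no
    internal stop codons, translation consistent with ``protein``.
    """

    gene_id: str
    cds: str
    protein: str

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        object.__setattr__(self, "protein", self.protein.upper())
        if not cds:
            raise FormatError(f"{self.gene_id}: empty CDS")
        bad = set(cds) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FormatError(f"{self.gene_id}: illegal CDS characters {sorted(bad)}")
        if len(cds) % 3 != 0:
            raise FormatError(
                f"{self.gene_id}: CDS length {len(cds)} not divisible by 3"
            )
        translated = translate_cds(cds)
        if "*" in translated:
            raise FormatError(f"{self.gene_id}: internal stop codon in CDS")
        bad = set(self.protein) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"{self.gene_id}: illegal protein characters {sorted(bad)}"
            )
        if translated != self.protein:
            raise FormatError(
                f"{self.gene_id}: protein does not match CDS translation "
                f"({self.protein!r} vs {translated!r})"
            )

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]


@dataclass(frozen=True)
class GeneLocus:
    """Placement of a gene on a contig; 0-based half-open interval."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"{self.gene_id}: negative start {self.start}")
        if self.start >= self.end:
            raise FormatError(
                f"{self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class HitRecord:
    """One local-alignment hit on a query sequence (0-based half-open)."""

    query_id: str
    query_start: int
    query_end: int
    target_id: str
    percent_identity: float
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.query_start < 0 or self.query_start >= self.query_end:
            raise FormatError(
                f"{self.query_id}: bad query interval "
                f"[{self.query_start}, {self.query_end})"
            )
        if not 0.0 <= self.percent_identity <= 1.0:
            raise FormatError(
                f"{self.query_id}: identity {self.percent_identity} outside [0, 1]"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.query_id}: unknown strand {self.strand!r}")


class ExpressionMatrix:
    """Genes x tissues TPM matrix after replicate aggregation."""

    def __init__(
        self,
        values: pd.DataFrame,
        replicate_map: Mapping[str, str] | None = None,
    ) -> None:
        if values.index.has_duplicates:
            raise FormatError("duplicate gene ids in expression matrix")
        if values.columns.has_duplicates:
            raise FormatError("duplicate tissue ids in expression matrix")
        if values.shape[1] < 2:
            raise FormatError("expression matrix needs at least 2 tissues")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise FormatError("expression values must be finite and non-negative")
        self.values = values.astype(float)
        self.replicate_map = dict(replicate_map or {})

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and (
            self.replicate_map == other.replicate_map
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered (id, sequence) list.

    Sequences are uppercased; duplicate ids, empty sequences and characters
    outside the *kind* alphabet are rejected.
    """
    if kind not in {"nucleotide", "protein"}:
        raise ValidationError(f"unknown FASTA kind {kind!r}")
    alphabet = NUCLEOTIDE_ALPHABET if kind == "nucleotide" else PROTEIN_ALPHABET
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        bad = set(seq) - alphabet - ({"*"} if kind == "protein" else set())
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has illegal characters {sorted(bad)}"
            )
        seen.add(rec.id)
        out.append((rec.id, seq))
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Coding records
# ---------------------------------------------------------------------------


def _trim_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def build_coding_records(
    cds: Sequence[tuple[str, str]],
    proteins: Sequence[tuple[str, str]] | None = None,
) -> list[CodingRecord]:
    """Pair CDS with proteins (translating when proteins are omitted).

    Terminal stop codons are trimmed before translation; internal stops and
    translation mismatches are hard errors.
    """
    prot_map = dict(proteins) if proteins is not None else None
    if prot_map is not None and len(prot_map) != len(proteins):
        raise FormatError("duplicate ids in protein collection")
    records: list[CodingRecord] = []
    seen: set[str] = set()
    for gene_id, seq in cds:
        if gene_id in seen:
            raise FormatError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        trimmed = _trim_terminal_stop(seq.upper())
        translated = translate_cds(trimmed)
        if "*" in translated:
            raise FormatError(f"{gene_id}: internal stop codon in CDS")
        if prot_map is not None:
            if gene_id not in prot_map:
                raise FormatError(f"{gene_id}: CDS without matching protein")
            provided = prot_map[gene_id].upper().rstrip("*")
            if provided != translated:
                raise FormatError(
                    f"{gene_id}: provided protein disagrees with translation"
                )
        records.append(CodingRecord(gene_id, trimmed, translated))
    return records


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    replicate_map: Mapping[str, str],
    aggregator: str = "mean",
) -> ExpressionMatrix:
    """Read a genes x samples TPM TSV and aggregate replicates per tissue."""
    if aggregator != "mean":
        raise ValidationError(f"unsupported aggregator {aggregator!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    unmapped = [s for s in df.columns if s not in replicate_map]
    if unmapped:
        raise FormatError(f"{path}: unmapped sample columns {unmapped}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative TPM value")
    tissues = pd.Series({s: replicate_map[s] for s in df.columns})
    aggregated = df.T.groupby(tissues, sort=False).mean().T
    return ExpressionMatrix(aggregated, replicate_map=dict(replicate_map))


def write_expression(path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Loci (GFF3 / BED)
# ---------------------------------------------------------------------------


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_loci(path: str | Path, dialect: str | None = None) -> list[GeneLocus]:
    """Read gene loci from GFF3 (1-based inclusive) or BED (0-based
    half-open), normalizing to the internal 0-based half-open convention.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        if suffix in {".gff", ".gff3"}:
            dialect = "gff3"
        elif suffix == ".bed":
            dialect = "bed"
        else:
            raise ValidationError(
                f"cannot infer loci dialect from {path.name!r}; pass dialect="
            )
    if dialect not in {"gff3", "bed"}:
        raise ValidationError(f"unknown loci dialect {dialect!r}")
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                contig, _source, ftype, start, end, _score, strand, _frame, attrs = (
                    fields
                )
                if ftype != "gene":
                    continue
                gene_id = _parse_gff3_attributes(attrs).get("ID")
                if gene_id is None:
                    raise FormatError(f"{path}:{lineno}: gene line without ID=")
                start0, end0 = int(start) - 1, int(end)
            else:
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: expected >= 6 BED columns")
                contig, start, end, gene_id, _score, strand = fields[:6]
                start0, end0 = int(start), int(end)
            if strand == ".":
                raise FormatError(
                    f"{path}:{lineno}: strand required for orientation analysis"
                )
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            loci.append(GeneLocus(gene_id, contig, start0, end0, strand))
    if not loci:
        raise FormatError(f"{path}: no gene loci found")
    return loci


def write_loci(path: str | Path, loci: Iterable[GeneLocus], dialect: str = "gff3") -> None:
    if dialect not in {"gff3", "bed"}:
        raise ValidationError(f"unknown loci dialect {dialect!r}")
    with open(path, "w") as handle:
        if dialect == "gff3":
            handle.write("##gff-version 3\n")
            for locus in loci:
                handle.write(
                    f"{locus.contig}\tarrayscan\tgene\t{locus.start + 1}\t"
                    f"{locus.end}\t.\t{locus.strand}\t.\tID={locus.gene_id}\n"
                )
        else:
            for locus in loci:
                handle.write(
                    f"{locus.contig}\t{locus.start}\t{locus.end}\t"
                    f"{locus.gene_id}\t0\t{locus.strand}\n"
                )


# ---------------------------------------------------------------------------
# Hit tables (BLAST outfmt 6 / minimal PAF)
# ---------------------------------------------------------------------------


def read_hits(path: str | Path, dialect: str = "outfmt6") -> list[HitRecord]:
    """Read alignment hits from a 12-column outfmt-6-like table (1-based
    inclusive query coordinates, pident in percent) or minimal PAF (0-based
    half-open)."""
    if dialect not in {"outfmt6", "paf"}:
        raise ValidationError(f"unknown hit dialect {dialect!r}")
    hits: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "outfmt6":
                if len(fields) < 12:
                    raise FormatError(f"{path}:{lineno}: expected 12 columns")
                qseqid, sseqid, pident, _length, _mm, _go, qstart, qend = fields[:8]
                bitscore = fields[11]
                hits.append(
                    HitRecord(
                        query_id=qseqid,
                        query_start=int(qstart) - 1,
                        query_end=int(qend),
                        target_id=sseqid,
                        percent_identity=float(pident) / 100.0,
                        score=float(bitscore),
                    )
                )
            else:
                if len(fields) < 12:
                    raise FormatError(f"{path}:{lineno}: expected >= 12 PAF columns")
                qname, _qlen, qstart, qend, strand, tname = fields[:6]
                nmatch, alnlen = int(fields[9]), int(fields[10])
                if alnlen <= 0:
                    raise FormatError(f"{path}:{lineno}: non-positive alignment length")
                hits.append(
                    HitRecord(
                        query_id=qname,
                        query_start=int(qstart),
                        query_end=int(qend),
                        target_id=tname,
                        percent_identity=nmatch / alnlen,
                        score=float(nmatch),
                        strand=strand,
                    )
                )
    return hits


def write_hits_paf(
    path: str | Path, hits: Iterable[HitRecord], query_lengths: Mapping[str, int]
) -> None:
    """Write hits as minimal PAF rows (coverage analysis only uses the
    query-side interval; target coordinates are emitted as the interval
    span)."""
    with open(path, "w") as handle:
        for hit in hits:
            span = hit.query_end - hit.query_start
            nmatch = int(round(hit.percent_identity * span))
            handle.write(
                f"{hit.query_id}\t{query_lengths[hit.query_id]}\t{hit.query_start}\t"
                f"{hit.query_end}\t{hit.strand}\t{hit.target_id}\t{span}\t0\t{span}\t"
                f"{nmatch}\t{span}\t255\n"
            )
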