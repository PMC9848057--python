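"""End-to-end pipeline wiring: config validation, stage ordering, and a
versioned output bundle with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cne_decay import coverage_from_hits
from .errors import ArrayscanError, ValidationError
from .expression_atlas import (
    classes_to_frame,
    classify_genes,
    differential_screen,
)
from .io_formats import (
    build_coding_records,
    read_expression,
    read_fasta,
    read_hits,
    read_loci,
)
from .residue_composition import composition, tyrosine_screen
from .tandem_array import DEFAULT_MU, neighbor_identity_profile, ng86_ks

logger = logging.getLogger("arrayscan")


class PipelineError(ArrayscanError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    expression_tsv: str
    replicate_map_tsv: str
    cds_fasta: str
    loci_path: str
    cne_fasta: str | None = None
    cne_hits: str | None = None
    cne_hits_dialect: str = "paf"
    protein_fasta: str | None = None
    family_list: str | None = None
    anchor_tissue: str = "skin"
    side_a: str | None = None
    side_b: str | None = None
    fold_threshold: float = 5.0
    detect_threshold: float = 1.0
    z_threshold: float = 1.0
    group_max: int = 7
    tyr_cutoff: float = 0.05
    decay_cut: float = 0.5
    intact_cut: float = 0.9
    min_identity: float = 0.6
    fold_cut: float = 2.0
    alpha: float = 0.05
    mu: float = DEFAULT_MU
    seed: int = 0
    out_dir: str = "arrayscan_out"

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha {self.alpha} outside (0, 1]")
        if self.fold_threshold < 1 or self.fold_cut < 1:
            raise ValidationError("fold thresholds must be >= 1")
        if not 0 <= self.decay_cut <= self.intact_cut <= 1:
            raise ValidationError("require 0 <= decay_cut <= intact_cut <= 1")
        if not 0 <= self.tyr_cutoff <= 1 or not 0 <= self.min_identity <= 1:
            raise ValidationError("tyr_cutoff and min_identity must lie in [0, 1]")
        if self.mu <= 0:
            raise ValidationError("mu must be positive")
        if self.group_max < 2:
            raise ValidationError("group_max must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def read_replicate_map(path: str | Path) -> dict[str, str]:
    """Two-column headerless TSV: sample id, tissue id."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            sample, tissue = parts
            if sample in mapping:
                raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
            mapping[sample] = tissue
    if not mapping:
        raise ValidationError(f"{path}: empty replicate map")
    return mapping


def _stage(name: str):
    def wrap(func):
        def inner(*args, **kwargs):
            logger.info("[%s] starting", name)
            try:
                result = func(*args, **kwargs)
            except ArrayscanError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("[%s] done", name)
            return result

        return inner

    return wrap


def run_full(config: PipelineConfig) -> dict[str, str]:
    """Run expression -> composition -> array stats -> Ks -> CNE, then write
    the bundle atomically (all artifacts only after every stage succeeded).

    Returns the manifest's artifact map (name -> path).
    """
    config.validate()
    replicate_map = read_replicate_map(config.replicate_map_tsv)

    @_stage("expression")
    def stage_expression():
        matrix = read_expression(config.expression_tsv, replicate_map)
        classes = classify_genes(
            matrix,
            fold_threshold=config.fold_threshold,
            detect_threshold=config.detect_threshold,
            z_threshold=config.z_threshold,
            group_max=config.group_max,
        )
        de_frame = None
        if config.side_a and config.side_b:
            samples = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
            cols_a = [s for s in samples.columns if replicate_map.get(s) == config.side_a]
            cols_b = [s for s in samples.columns if replicate_map.get(s) == config.side_b]
            results = differential_screen(
                samples[cols_a],
                samples[cols_b],
                classes,
                anchor_tissue=config.anchor_tissue,
                fold_cut=config.fold_cut,
                alpha=config.alpha,
            )
            de_frame = pd.DataFrame(
                {
                    "gene_id": [r.gene_id for r in results],
                    "log2_fold_change": [r.log2_fold_change for r in results],
                    "p_value": [r.p_value for r in results],
                    "adjusted_p": [r.adjusted_p for r in results],
                    "passes_screen": [r.passes_screen for r in results],
                }
            )
        return matrix, classes, de_frame

    matrix, classes, de_frame = stage_expression()

    @_stage("composition")
    def stage_composition():
        cds = read_fasta(config.cds_fasta, kind="nucleotide")
        proteins = (
            read_fasta(config.protein_fasta, kind="protein")
            if config.protein_fasta
            else None
        )
        records = build_coding_records(cds, proteins)
        profiles = [composition(r) for r in records]
        in_classes = {c.gene_id for c in classes}
        screened, _ = tyrosine_screen(
            [p for p in profiles if p.gene_id in in_classes],
            classes,
            tyr_cutoff=config.tyr_cutoff,
            anchor_tissue=config.anchor_tissue,
        )
        frame = pd.DataFrame(
            {
                "gene_id": [p.gene_id for p in profiles],
                "gly": [p.gly for p in profiles],
                "tyr": [p.tyr for p in profiles],
                "gly_tyr": [p.gly_tyr for p in profiles],
                "gc": [p.gc for p in profiles],
                "gc3": [p.gc3 for p in profiles],
                "tyrosine_screen": [p.gene_id in screened for p in profiles],
            }
        )
        return records, frame

    records, comp_frame = stage_composition()

    @_stage("array")
    def stage_array():
        loci = read_loci(config.loci_path)
        family = None
        if config.family_list:
            family = {
                line.strip()
                for line in open(config.family_list)
                if line.strip() and not line.startswith("#")
            }
        contigs: dict[str, list] = {}
        for locus in loci:
            if family is not None and locus.gene_id not in family:
                continue
            contigs.setdefault(locus.contig, []).append(locus)
        reports = {}
        for contig, contig_loci in sorted(contigs.items()):
            if len(contig_loci) < 2:
                continue
            report = neighbor_identity_profile(records, contig_loci)
            reports[contig] = {
                "contig": report.contig,
                "ordered_genes": list(report.ordered_genes),
                "neighbor_identities": list(report.neighbor_identities),
                "mean_neighbor_identity": report.mean_neighbor_identity,
                "tail_to_head": report.tail_to_head,
                "clades": [list(c) for c in report.clades],
            }
        return {"schema_version": 1, "arrays": reports}

    array_report = stage_array()

    @_stage("ks")
    def stage_ks():
        by_id = {r.gene_id: r for r in records}
        rows = []
        for contig_data in array_report["arrays"].values():
            genes = contig_data["ordered_genes"]
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    est = ng86_ks(by_id[genes[i]], by_id[genes[j]], mu=config.mu)
                    rows.append(
                        {
                            "id_a": est.id_a,
                            "id_b": est.id_b,
                            "S": est.S,
                            "N": est.N,
                            "Sd": est.Sd,
                            "Nd": est.Nd,
                            "Ks": est.Ks,
                            "Ka": est.Ka,
                            "T_years": est.T,
                            "saturated": est.saturated,
                        }
                    )
        return pd.DataFrame(rows)

    ks_frame = stage_ks()

    @_stage("cne")
    def stage_cne():
        if not (config.cne_fasta and config.cne_hits):
            return None
        cnes = read_fasta(config.cne_fasta, kind="nucleotide")
        lengths = {name: len(seq) for name, seq in cnes}
        hits = read_hits(config.cne_hits, dialect=config.cne_hits_dialect)
        reports = coverage_from_hits(
            lengths,
            hits,
            min_identity=config.min_identity,
            decay_cut=config.decay_cut,
            intact_cut=config.intact_cut,
        )
        return pd.DataFrame(
            {
                "cne_id": [r.cne_id for r in reports],
                "length": [r.cne_length for r in reports],
                "covered": [r.merged_covered for r in reports],
                "coverage": [r.coverage for r in reports],
                "status": [r.status for r in reports],
            }
        )

    cne_frame = stage_cne()

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit_tsv(name: str, frame: pd.DataFrame | None) -> None:
        if frame is None:
            return
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        artifacts[name] = str(path)

    emit_tsv("classes.tsv", classes_to_frame(classes))
    emit_tsv("de.tsv", de_frame)
    emit_tsv("composition.tsv", comp_frame)
    emit_tsv("ks.tsv", ks_frame)
    emit_tsv("cne.tsv", cne_frame)
    array_path = out_dir / "array_report.json"
    with open(array_path, "w") as handle:
        json.dump(array_report, handle, indent=2, sort_keys=True)
    artifacts["array_report.json"] = str(array_path)

    manifest = {
        "version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    artifacts["manifest.json"] = str(out_dir / "manifest.json")
    return artifacts
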