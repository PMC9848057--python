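"""Synthetic inputs with known ground truth for every pipeline stage:
tandem CDS arrays evolved forward in time under duplication, Jukes-Cantor
point mutation and optional nonallelic gene conversion across a two-species
split; planted-structure expression matrices; and CNE decay scenarios.

Selection is not modeled: only the conversion component of the
conversion-plus-selection homogenization mechanism is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import CodingRecord, ExpressionMatrix, GeneLocus, translate_cds

SPECIES = ("A", "B")
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class ArraySimParams:
    n_genes: int = 4
    codons: int = 100
    mu: float = 2e-9
    t_split: float = 7.5e6
    conversion_rate: float = 0.0
    tract_len: float = 100.0
    duplication_mode: str = "ancestral"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if self.codons < 50:
            raise ValidationError("codons must be >= 50")
        if self.mu < 0 or self.t_split < 0 or self.conversion_rate < 0:
            raise ValidationError("rates and times must be non-negative")
        if self.tract_len < 3:
            raise ValidationError("tract_len must be >= 3")
        if self.duplication_mode not in {"ancestral", "post_split"}:
            raise ValidationError(
                f"unknown duplication_mode {self.duplication_mode!r}"
            )


@dataclass
class SimTruth:
    true_t_split: float = 0.0
    true_mu: float = 0.0
    event_log: list[dict] = field(default_factory=list)
    planted_classes: dict[str, str] = field(default_factory=dict)


def _has_internal_stop(cds: str) -> bool:
    return any(cds[i : i + 3] in _STOPS for i in range(0, len(cds), 3))


def _draw_cds(rng: np.random.Generator, codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _mutate(rng: np.random.Generator, cds: str) -> tuple[str, int | None]:
    """Attempt one point mutation; stop-creating attempts are discarded.

    Discarding (rather than redrawing) keeps the attempted per-site rate at
    exactly mu and leaves the synonymous substitution process unbiased:
    synonymous changes can never create a stop, so thinning only removes a
    small fraction of nonsynonymous attempts.
    """
    pos = int(rng.integers(0, len(cds)))
    current = cds[pos]
    base = _BASES[int(rng.integers(0, 3))]
    if base == current:  # map the 3-way draw onto the other three bases
        base = _BASES[3]
    codon_start = 3 * (pos // 3)
    offset = pos - codon_start
    codon = cds[codon_start : codon_start + 3]
    mutant_codon = codon[:offset] + base + codon[offset + 1 :]
    if mutant_codon in _STOPS:
        return cds, None
    return cds[:pos] + base + cds[pos + 1 :], pos


def _convert_tract(
    rng: np.random.Generator, acceptor: str, donor: str, mean_tract: float
) -> tuple[str, tuple[int, int]] | None:
    """Copy a geometric-length tract from donor into acceptor; None when no
    stop-free placement is found."""
    length = len(acceptor)
    for _ in range(20):
        tract = int(rng.geometric(1.0 / mean_tract))
        tract = max(3, min(tract, length))
        start = int(rng.integers(0, length - tract + 1))
        candidate = acceptor[:start] + donor[start : start + tract] + acceptor[start + tract :]
        if not _has_internal_stop(candidate):
            return candidate, (start, start + tract)
    return None


def _evolve_species(
    rng: np.random.Generator,
    species: str,
    genes: list[str],
    params: ArraySimParams,
    event_log: list[dict],
) -> list[str]:
    """Gillespie forward simulation of one species' array for t_split years."""
    n = len(genes)
    site_count = 3 * params.codons
    mutation_rate = n * params.mu * site_count
    conversion_rate = n * params.conversion_rate
    total = mutation_rate + conversion_rate
    if total == 0 or params.t_split == 0:
        return genes
    t = 0.0
    while True:
        t += rng.exponential(1.0 / total)
        if t > params.t_split:
            break
        if rng.random() < mutation_rate / total:
            idx = int(rng.integers(0, n))
            genes[idx], pos = _mutate(rng, genes[idx])
            if pos is not None:
                event_log.append(
                    {"time": t, "species": species, "kind": "mutation",
                     "gene": idx, "position": pos}
                )
        else:
            acceptor = int(rng.integers(0, n))
            donor = int(rng.integers(0, n - 1))
            if donor >= acceptor:
                donor += 1
            result = _convert_tract(rng, genes[acceptor], genes[donor], params.tract_len)
            if result is None:
                continue
            genes[acceptor], tract = result
            event_log.append(
                {"time": t, "species": species, "kind": "conversion",
                 "acceptor": acceptor, "donor": donor, "tract": tract}
            )
    return genes


def simulate_array(
    params: ArraySimParams,
) -> tuple[dict[str, list[CodingRecord]], dict[str, list[GeneLocus]], SimTruth]:
    """Evolve a tandem CDS array across a two-species split.

    ``ancestral`` duplication copies the ancestral gene to ``n_genes`` before
    the split, so paralogs diverge for the full ``t_split`` in each species;
    ``post_split`` evolves a single lineage per species and duplicates it at
    the present (the very-recent-duplication regime). Loci are emitted in
    tandem tail-to-head (all ``+`` strand) order. Fully reproducible from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    truth = SimTruth(true_t_split=params.t_split, true_mu=params.mu)
    ancestral = _draw_cds(rng, params.codons)
    records: dict[str, list[CodingRecord]] = {}
    loci: dict[str, list[GeneLocus]] = {}
    for species in SPECIES:
        if params.duplication_mode == "ancestral":
            genes = [ancestral] * params.n_genes
            truth.event_log.append(
                {"time": 0.0, "species": species, "kind": "duplication",
                 "copies": params.n_genes}
            )
            genes = _evolve_species(rng, species, genes, params, truth.event_log)
        else:
            lineage = _evolve_species(
                rng, species, [ancestral], params, truth.event_log
            )
            genes = [lineage[0]] * params.n_genes
            truth.event_log.append(
                {"time": params.t_split, "species": species, "kind": "duplication",
                 "copies": params.n_genes}
            )
        gene_len = 3 * params.codons
        spacer = 200
        records[species] = [
            CodingRecord(f"{species}_g{i + 1}", cds, translate_cds(cds))
            for i, cds in enumerate(genes)
        ]
        loci[species] = [
            GeneLocus(
                gene_id=f"{species}_g{i + 1}",
                contig=f"{species}_ctg1",
                start=i * (gene_len + spacer),
                end=i * (gene_len + spacer) + gene_len,
                strand="+",
            )
            for i in range(params.n_genes)
        ]
    truth.event_log.sort(key=lambda e: e["time"])
    return records, loci, truth


# ---------------------------------------------------------------------------
# Expression matrices with planted structure
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSim:
    """Replicate-level synthetic expression with its ground truth."""

    samples: pd.DataFrame  # genes x sample columns
    replicate_map: dict[str, str]
    truth: SimTruth

    def aggregate(self) -> ExpressionMatrix:
        tissues = pd.Series(self.replicate_map)
        aggregated = self.samples.T.groupby(
            tissues[self.samples.columns], sort=False
        ).mean().T
        return ExpressionMatrix(aggregated, replicate_map=self.replicate_map)


def simulate_expression(
    n_genes: int,
    tissues: Sequence[str],
    planted: Mapping[str, tuple[str, Sequence[str], float]],
    noise_sigma: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> ExpressionSim:
    """Planted-structure TPM matrix with replicate columns.

    ``planted`` maps gene id (of ``g1..g<n>``) to (category, focus tissues,
    fold); unplanted genes are flat-profile ``other``. Baselines are
    log-normal (floored at 2 TPM, so every non-planted gene is detected);
    ``not_detected`` genes get sub-detection baselines. Replicate noise is
    multiplicative log-normal(0, noise_sigma).
    """
    if len(tissues) < 3:
        raise ValidationError("need at least 3 tissues")
    if len(set(tissues)) != len(tissues):
        raise ValidationError("duplicate tissue ids")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    unknown = set(planted) - set(gene_ids)
    if unknown:
        raise ValidationError(f"planted spec for unknown genes: {sorted(unknown)}")
    tissue_set = set(tissues)
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    base_profiles = np.empty((n_genes, len(tissues)))
    for i, gene_id in enumerate(gene_ids):
        category, focus, fold = planted.get(gene_id, ("other", (), 1.0))
        focus = tuple(focus)
        if set(focus) - tissue_set:
            raise ValidationError(f"{gene_id}: planted tissues not in panel")
        if fold < 1.0:
            raise ValidationError(f"{gene_id}: planted fold must be >= 1")
        if category == "not_detected":
            base_profiles[i, :] = rng.uniform(0.05, 0.5)
        elif category in {"tissue_enriched", "group_enriched"}:
            if category == "tissue_enriched" and len(focus) != 1:
                raise ValidationError(f"{gene_id}: tissue_enriched needs one tissue")
            if category == "group_enriched" and len(focus) < 2:
                raise ValidationError(f"{gene_id}: group_enriched needs >= 2 tissues")
            baseline = max(2.0, float(rng.lognormal(mean=3.0, sigma=0.5)))
            base_profiles[i, :] = baseline
            for t in focus:
                base_profiles[i, tissues.index(t)] = baseline * fold
        elif category == "other":
            base_profiles[i, :] = max(2.0, float(rng.lognormal(mean=3.0, sigma=0.5)))
        else:
            raise ValidationError(f"{gene_id}: unknown planted category {category!r}")
        truth.planted_classes[gene_id] = category
    columns: dict[str, np.ndarray] = {}
    replicate_map: dict[str, str] = {}
    for j, tissue in enumerate(tissues):
        for r in range(replicates):
            sample = f"{tissue}_r{r + 1}"
            noise = (
                np.exp(rng.normal(0.0, noise_sigma, size=n_genes))
                if noise_sigma > 0
                else np.ones(n_genes)
            )
            columns[sample] = base_profiles[:, j] * noise
            replicate_map[sample] = tissue
    samples = pd.DataFrame(columns, index=gene_ids)
    return ExpressionSim(samples=samples, replicate_map=replicate_map, truth=truth)


# ---------------------------------------------------------------------------
# CNE decay scenarios
# ---------------------------------------------------------------------------


def simulate_cne_decay(
    cne: str,
    decay_fraction: float,
    point_rate: float = 0.0,
    seed: int = 0,
    flank: int = 200,
) -> tuple[str, tuple[float, float]]:
    """Derive a target sequence from a CNE by deleting a contiguous fraction
    and applying point substitutions, embedded in random flanks.

    Returns (target sequence, (low, high) expected-coverage band implied by
    the deletion).
    """
    if not 0 <= decay_fraction <= 1 or not 0 <= point_rate <= 1:
        raise ValidationError("fractions must lie in [0, 1]")
    if not cne:
        raise ValidationError("empty CNE sequence")
    rng = np.random.default_rng(seed)
    length = len(cne)
    deleted = int(round(decay_fraction * length))
    if deleted > 0:
        start = int(rng.integers(0, length - deleted + 1))
        remnant = cne[:start] + cne[start + deleted :]
    else:
        remnant = cne
    remnant_list = list(remnant)
    for i in range(len(remnant_list)):
        if rng.random() < point_rate:
            options = [b for b in _BASES if b != remnant_list[i]]
            remnant_list[i] = options[int(rng.integers(0, 3))]
    left = "".join(_BASES[i] for i in rng.integers(0, 4, size=flank))
    right = "".join(_BASES[i] for i in rng.integers(0, 4, size=flank))
    target = left + "".join(remnant_list) + right
    retained = 1.0 - deleted / length
    band = (max(0.0, retained - 0.05 - 2.0 * point_rate), min(1.0, retained + 0.02))
    return target, band
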