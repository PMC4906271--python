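"""Seeded two-species synthetic data with known ground truth.

The generator emulates the processed shapes of a cross-species Hox ChIP
study: two "species" genomes (uniform base composition) with gene models,
two replicate ChIP peak sets per species planted unambiguously near known
target genes, an ortholog table onto a shared reference gene space with a
controlled fraction of shared targets, motif instances injected at
configured foreground/background densities, functional-category annotation
with controlled fold over-representation in the shared targets, and a
two-condition expression table with a controlled fraction of >= 2-fold
genes.

Design guarantees (what "controlled" means here)
------------------------------------------------
* Each planted peak lies within 2 kb of its target gene body with no nearer
  gene, so nearest-gene assignment recovers the truth exactly.
* Exactly ``round(shared_target_fraction * n_peaks)`` targets of each
  species map to shared reference ids; every target gene has an ortholog
  entry (``ortholog_coverage`` thins non-target genes only), so Venn region
  counts are exactly the configured values.
* Category annotation is planted with exact counts per stratum
  (``round(rate * n)`` genes drawn without replacement), so the realised
  fold over-representation equals the configured fold up to rounding.
* DE genes are separated by construction: non-DE ratios stay below 1.8 and
  DE ratios at or above 2.25 with baseline values >= 10, so a 2-fold filter
  (pseudocount 0 or 1) recovers exactly the planted set.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .compare import OrthologMap
from .enrich import AnnotationTable, ExpressionTable
from .io import (
    IUPAC_BASES,
    GeneModel,
    GenomicInterval,
    MotifModel,
    Peak,
    SequenceRecord,
    write_bed,
    write_fasta,
    write_gff3,
    write_motif_library,
)
from .motifs import builtin_library

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SpeciesData",
    "SyntheticDataset",
    "generate",
    "generate_expression",
    "generate_target_structure",
]

SPECIES_TAGS = ("apis", "bombyx")
REFERENCE_TAG = "dmel"

CATEGORY_LABELS = {
    "GO-35220": "wing development",
    "GO-06350": "transcription",
    "GO-45449": "regulation of transcription",
    "GO-07049": "cell cycle",
    "GO-51726": "regulation of cell cycle",
    "GO-40007": "growth",
    "GO-40008": "regulation of growth",
    "GO-12501": "programmed cell death",
    "GO-07155": "cell adhesion",
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are desk-scale renditions of
    the real study's structure (two species, two replicates, a minority of
    shared targets, a 4-fold wing-development over-representation in shared
    targets, a small minority of >=2-fold DE genes)."""

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length_bp: int = 600_000
    n_genes: int = 300
    gene_length_bp_range: tuple[int, int] = (500, 1500)
    n_peaks: int = 60
    peak_length_bp_range: tuple[int, int] = (150, 400)
    shared_target_fraction: float = 0.2
    ortholog_coverage: float = 0.85
    #: (motif_id, foreground density per kb, background density per kb)
    planted_motifs: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("MAD1", 3.0, 1.0)]
    )
    #: (category_id, base rate, fold over-representation in shared targets)
    categories: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("GO-35220", 0.05, 4.0),
            ("GO-06350", 0.20, 1.0),
            ("GO-07049", 0.10, 1.0),
        ]
    )
    de_fraction_2fold: float = 0.02
    # placement geometry (spacers guarantee unambiguous nearest genes)
    min_intergenic_bp: int = 3000
    intergenic_jitter_bp: int = 2000
    peak_gene_gap_bp_range: tuple[int, int] = (100, 800)

    def validate(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length_bp < 1:
            raise ValueError("need at least one scaffold of positive length")
        if not (0 <= self.shared_target_fraction <= 1):
            raise ValueError("shared_target_fraction must be in [0, 1]")
        if not (0 <= self.ortholog_coverage <= 1):
            raise ValueError("ortholog_coverage must be in [0, 1]")
        if not (0 <= self.de_fraction_2fold <= 1):
            raise ValueError("de_fraction_2fold must be in [0, 1]")
        if self.n_peaks > self.n_genes:
            raise ValueError("n_peaks cannot exceed n_genes")
        for _, fg, bg in self.planted_motifs:
            if fg < 0 or bg < 0:
                raise ValueError("motif densities must be >= 0")
        for _, rate, fold in self.categories:
            if rate < 0 or fold < 0:
                raise ValueError("category rates and folds must be >= 0")
        gmin, gmax = self.gene_length_bp_range
        pmin, pmax = self.peak_length_bp_range
        if not (0 < gmin <= gmax) or not (0 < pmin <= pmax):
            raise ValueError("invalid length ranges")
        gap_min, gap_max = self.peak_gene_gap_bp_range
        if not (0 < gap_min <= gap_max):
            raise ValueError("invalid peak-gene gap range")
        if gap_max + pmax > self.min_intergenic_bp - 1000:
            raise ValueError(
                "min_intergenic_bp too small to keep planted peaks unambiguous "
                f"(need > gap_max + peak_max + 1000 = {gap_max + pmax + 1000})"
            )
        per_scaffold = math.ceil(self.n_genes / self.n_scaffolds)
        footprint = per_scaffold * (
            self.min_intergenic_bp + self.intergenic_jitter_bp + gmax
        ) + 2000
        if footprint > self.scaffold_length_bp:
            raise ValueError(
                f"infeasible placement: {per_scaffold} genes/scaffold need up to "
                f"{footprint} bp but scaffolds are {self.scaffold_length_bp} bp"
            )


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a dataset."""

    peak_to_gene: dict[str, dict[str, str]]
    ortholog_map: OrthologMap
    shared_target_ids: frozenset[str]
    species_specific_ids: dict[str, frozenset[str]]
    planted_motif_densities: dict[str, tuple[float, float]]
    category_assignments: AnnotationTable
    de_gene_ids: frozenset[str]
    target_gene_ids: dict[str, frozenset[str]]

    def to_json(self, path) -> None:
        payload = {
            "peak_to_gene": self.peak_to_gene,
            "shared_target_ids": sorted(self.shared_target_ids),
            "species_specific_ids": {
                tag: sorted(ids) for tag, ids in self.species_specific_ids.items()
            },
            "planted_motif_densities": {
                m: list(d) for m, d in self.planted_motif_densities.items()
            },
            "de_gene_ids": sorted(self.de_gene_ids),
            "target_gene_ids": {
                tag: sorted(ids) for tag, ids in self.target_gene_ids.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SpeciesData:
    tag: str
    genome: list[SequenceRecord]
    genes: list[GeneModel]
    peak_replicates: list[list[Peak]]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    species: dict[str, SpeciesData]
    ortholog_map: OrthologMap
    annotation: AnnotationTable
    expression: ExpressionTable
    motif_library: list[MotifModel]
    truth: SyntheticTruth

    def write(self, out_dir) -> dict[str, str]:
        """Write every standard-format file; returns name -> path.

        Output is byte-identical for identical configs (no timestamps,
        deterministic ordering).
        """
        os.makedirs(out_dir, exist_ok=True)
        paths: dict[str, str] = {}

        def _p(name):
            paths[name] = os.path.join(out_dir, name)
            return paths[name]

        for tag, data in self.species.items():
            write_fasta(data.genome, _p(f"{tag}_genome.fa"))
            write_gff3(data.genes, _p(f"{tag}_genes.gff3"))
            for r, peaks in enumerate(data.peak_replicates, start=1):
                write_bed(peaks, _p(f"{tag}_peaks_rep{r}.bed"), name_prefix=f"{tag}_p")
        self.ortholog_map.to_tsv(_p("orthologs.tsv"))
        self.annotation.to_tsv(_p("annotation.tsv"))
        self.expression.to_tsv(_p("expression.tsv"))
        write_motif_library(self.motif_library, _p("motifs.json"))
        self.truth.to_json(_p("truth.json"))
        return paths


# ---------------------------------------------------------------------------
# target / ortholog / annotation structure (no sequences)
# ---------------------------------------------------------------------------

def generate_target_structure(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict:
    """Gene ids, target choices, ortholog map and category annotation.

    The set-level skeleton of a dataset; :func:`generate` builds genomes and
    peaks on top of it.  Exposed separately so set-statistics can be studied
    over many replicates without synthesising sequence.
    """
    config.validate()
    n_shared = round(config.shared_target_fraction * config.n_peaks)
    ref_counter = 0

    def new_ref():
        nonlocal ref_counter
        ref_counter += 1
        return f"{REFERENCE_TAG}_g{ref_counter:05d}"

    shared_refs = [new_ref() for _ in range(n_shared)]
    gene_ids: dict[str, list[str]] = {}
    target_idx: dict[str, np.ndarray] = {}
    pairs: dict[str, set[str]] = {}
    specific_refs: dict[str, list[str]] = {}
    other_refs: list[str] = []

    for tag in SPECIES_TAGS:
        ids = [f"{tag}_g{i:04d}" for i in range(config.n_genes)]
        gene_ids[tag] = ids
        perm = rng.permutation(config.n_genes)[: config.n_peaks]
        target_idx[tag] = perm
        specific_refs[tag] = []
        for j, gidx in enumerate(perm):
            if j < n_shared:
                ref = shared_refs[j]
            else:
                ref = new_ref()
                specific_refs[tag].append(ref)
            pairs[ids[gidx]] = {ref}
        target_set = set(perm.tolist())
        for i, gene_id in enumerate(ids):
            if i in target_set:
                continue
            if rng.random() < config.ortholog_coverage:
                ref = new_ref()
                pairs[gene_id] = {ref}
                other_refs.append(ref)

    # exact-count category planting per stratum
    assignments: dict[str, set[str]] = {}
    strata = [
        (shared_refs, True),
        (specific_refs[SPECIES_TAGS[0]], False),
        (specific_refs[SPECIES_TAGS[1]], False),
        (other_refs, False),
    ]
    for cat_id, base_rate, fold in config.categories:
        for refs, is_shared in strata:
            rate = min(base_rate * fold, 1.0) if is_shared else min(base_rate, 1.0)
            k = min(round(rate * len(refs)), len(refs))
            if k == 0:
                continue
            for i in rng.choice(len(refs), size=k, replace=False):
                assignments.setdefault(refs[int(i)], set()).add(cat_id)

    return {
        "gene_ids": gene_ids,
        "target_idx": target_idx,
        "shared_refs": shared_refs,
        "specific_refs": specific_refs,
        "other_refs": other_refs,
        "ortholog_map": OrthologMap(pairs),
        "annotation": AnnotationTable(assignments, CATEGORY_LABELS),
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[ExpressionTable, frozenset[str]]:
    """Two-condition expression table with a controlled >=2-fold minority.

    Non-DE genes get ratios in [1, 1.8]; DE genes ratios in [2.25, 8] on
    baselines >= 10, so the 2-fold filter separates them exactly for any
    pseudocount in [0, 1].  Returns the table and the planted DE gene set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if gene_ids is None:
        gene_ids = [f"{SPECIES_TAGS[1]}_g{i:04d}" for i in range(config.n_genes)]
    n = len(gene_ids)
    n_de = round(config.de_fraction_2fold * n)
    de_ids = frozenset(
        gene_ids[int(i)] for i in rng.choice(n, size=n_de, replace=False)
    )
    rows: dict[str, tuple[float, float]] = {}
    for gene_id in gene_ids:
        lo = float(rng.uniform(10, 200))
        if gene_id in de_ids:
            ratio = float(rng.uniform(2.25, 8.0))
        else:
            ratio = float(rng.uniform(1.0, 1.8))
        hi = lo * ratio
        if rng.random() < 0.5:
            rows[gene_id] = (hi, lo)
        else:
            rows[gene_id] = (lo, hi)
    return (
        ExpressionTable(rows, condition_names=("forewing", "hindwing")),
        de_ids,
    )


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def _motif_instance(motif: MotifModel, rng: np.random.Generator) -> str:
    """A concrete sequence realising the motif (degenerate codes resolved
    uniformly; matrix motifs use the per-position modal base)."""
    if motif.is_consensus:
        return "".join(
            str(rng.choice(sorted(IUPAC_BASES[c]))) for c in motif.iupac
        )
    return "".join("ACGT"[i] for i in motif.matrix.argmax(axis=1))


_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = {b: i for i, b in enumerate("ACGT")}


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full paired-species dataset plus ground truth.

    Fully deterministic under ``config.seed``.  Raises ``ValueError`` with a
    diagnostic when genes and peaks cannot fit the scaffolds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    structure = generate_target_structure(config, rng)
    library = builtin_library()
    by_id = {m.motif_id: m for m in library}
    for motif_id, _, _ in config.planted_motifs:
        if motif_id not in by_id:
            raise ValueError(f"planted motif {motif_id!r} not in the motif library")

    gmin, gmax = config.gene_length_bp_range
    pmin, pmax = config.peak_length_bp_range
    gap_min, gap_max = config.peak_gene_gap_bp_range

    species: dict[str, SpeciesData] = {}
    peak_to_gene: dict[str, dict[str, str]] = {}
    for tag in SPECIES_TAGS:
        ids = structure["gene_ids"][tag]
        scaffold_names = [f"{tag}_scf{s + 1}" for s in range(config.n_scaffolds)]
        codes = [
            rng.integers(0, 4, size=config.scaffold_length_bp, dtype=np.uint8)
            for _ in scaffold_names
        ]
        # genes round-robin across scaffolds, sequential placement
        genes: list[GeneModel] = []
        cursors = [1000] * config.n_scaffolds
        for i, gene_id in enumerate(ids):
            s = i % config.n_scaffolds
            spacer = config.min_intergenic_bp + int(
                rng.integers(0, config.intergenic_jitter_bp + 1)
            )
            glen = int(rng.integers(gmin, gmax + 1))
            start = cursors[s] + spacer
            end = start + glen
            if end + 2000 > config.scaffold_length_bp:
                raise ValueError(
                    f"infeasible placement on {scaffold_names[s]}: gene {gene_id} "
                    f"would end at {end} of {config.scaffold_length_bp} bp"
                )
            genes.append(GeneModel(gene_id, GenomicInterval(scaffold_names[s], start, end)))
            cursors[s] = end

        # peaks adjacent to target genes; spacers guarantee no nearer gene
        rep1: list[Peak] = []
        rep2: list[Peak] = []
        mapping: dict[str, str] = {}
        for j, gidx in enumerate(structure["target_idx"][tag]):
            gene = genes[int(gidx)]
            gap = int(rng.integers(gap_min, gap_max + 1))
            plen = int(rng.integers(pmin, pmax + 1))
            start = gene.interval.end + gap
            iv1 = GenomicInterval(gene.interval.scaffold, start, start + plen)
            shift = int(rng.integers(-(plen // 20), plen // 20 + 1))
            iv2 = GenomicInterval(
                gene.interval.scaffold, start + shift, start + shift + plen
            )
            rep1.append(Peak(iv1, score=float(rng.uniform(5, 50)),
                             replicate_ids=frozenset({f"{tag}_rep1"})))
            rep2.append(Peak(iv2, score=float(rng.uniform(5, 50)),
                             replicate_ids=frozenset({f"{tag}_rep2"})))
            mapping[f"{tag}_p{j}"] = gene.gene_id
        peak_to_gene[tag] = mapping

        _plant_motifs(config, rng, by_id, scaffold_names, codes, genes, rep1, rep2)

        genome = [
            SequenceRecord(name, _LETTERS[c].tobytes().decode("ascii"))
            for name, c in zip(scaffold_names, codes)
        ]
        species[tag] = SpeciesData(tag, genome, genes, [rep1, rep2])

    expression, de_ids = generate_expression(
        config, rng=rng, gene_ids=structure["gene_ids"][SPECIES_TAGS[1]]
    )

    n_shared = len(structure["shared_refs"])
    truth = SyntheticTruth(
        peak_to_gene=peak_to_gene,
        ortholog_map=structure["ortholog_map"],
        shared_target_ids=frozenset(structure["shared_refs"]),
        species_specific_ids={
            tag: frozenset(structure["specific_refs"][tag]) for tag in SPECIES_TAGS
        },
        planted_motif_densities={
            motif_id: (fg, bg) for motif_id, fg, bg in config.planted_motifs
        },
        category_assignments=structure["annotation"],
        de_gene_ids=de_ids,
        target_gene_ids={
            tag: frozenset(
                structure["gene_ids"][tag][int(i)]
                for i in structure["target_idx"][tag]
            )
            for tag in SPECIES_TAGS
        },
    )
    assert len(truth.shared_target_ids) == n_shared
    return SyntheticDataset(
        config=config,
        species=species,
        ortholog_map=structure["ortholog_map"],
        annotation=structure["annotation"],
        expression=expression,
        motif_library=library,
        truth=truth,
    )


def _plant_motifs(config, rng, by_id, scaffold_names, codes, genes, rep1, rep2):
    """Inject motif instances: foreground into replicate-intersection peak
    regions, background into gene-free, peak-free genome."""
    if not config.planted_motifs:
        return
    name_to_idx = {name: i for i, name in enumerate(scaffold_names)}

    fg_regions = []
    for p1, p2 in zip(rep1, rep2):
        iv = p1.interval.intersection(p2.interval)
        if iv is not None:
            fg_regions.append(iv)

    # background space: whole scaffolds minus gene bodies and peak envelopes
    blocked: dict[str, list[tuple[int, int]]] = {name: [] for name in scaffold_names}
    for g in genes:
        blocked[g.interval.scaffold].append((g.interval.start, g.interval.end))
    for p in list(rep1) + list(rep2):
        blocked[p.interval.scaffold].append((p.interval.start, p.interval.end))
    bg_regions: list[GenomicInterval] = []
    for name in scaffold_names:
        spans = sorted(blocked[name])
        cursor = 0
        for start, end in spans:
            if start > cursor:
                bg_regions.append(GenomicInterval(name, cursor, start))
            cursor = max(cursor, end)
        if cursor < config.scaffold_length_bp:
            bg_regions.append(GenomicInterval(name, cursor, config.scaffold_length_bp))

    # avoid planting instances on top of each other: an overwritten instance
    # would silently lower the realised density below the configured one
    planted: dict[str, list[tuple[int, int]]] = {}

    def _write(instance: str, region: GenomicInterval) -> None:
        L = len(instance)
        if len(region) < L:
            return
        occupied = planted.setdefault(region.scaffold, [])
        for _ in range(20):
            pos = int(rng.integers(region.start, region.end - L + 1))
            if all(pos + L <= s or pos >= e for s, e in occupied):
                break
        else:
            return  # region saturated; drop this instance
        occupied.append((pos, pos + L))
        arr = codes[name_to_idx[region.scaffold]]
        arr[pos : pos + L] = [_ENC[b] for b in instance]

    for motif_id, fg_density, bg_density in config.planted_motifs:
        motif = by_id[motif_id]
        for region in fg_regions:
            count = rng.poisson(fg_density * len(region) / 1000.0)
            for _ in range(count):
                _write(_motif_instance(motif, rng), region)
        if bg_density > 0 and bg_regions:
            sizes = np.array([len(r) for r in bg_regions], dtype=float)
            total_kb = sizes.sum() / 1000.0
            count = rng.poisson(bg_density * total_kb)
            picks = rng.choice(len(bg_regions), size=count, p=sizes / sizes.sum())
            for r in picks:
                _write(_motif_instance(motif, rng), bg_regions[int(r)])
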