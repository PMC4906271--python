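"""Orchestrate the full cross-species comparison from one config file.

Stages run in a fixed order (annotate -> map -> partition -> enrich ->
defilter -> motif-enrich -> array-diff); every stage persists its TSV
outputs, a MANIFEST records completeness, and a consolidated report is
written as JSON and human-readable text.  One global seed is split into
per-stage substreams so each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import compare as _compare
from . import enrich as _enrich
from . import motifs as _motifs
from .io import read_bed, read_fasta, read_gff3, read_motif_library

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SpeciesInput", "ComparisonReport", "StageError", "ConfigError", "run"]


class ConfigError(ValueError):
    """Configuration invalid (missing file, bad parameter) - nothing was run."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SpeciesInput:
    tag: str
    genome: str
    genes: str
    peaks: list[str]  # one BED per replicate


@dataclass
class RunConfig:
    species: list[SpeciesInput]
    orthologs: str
    annotation: str
    motifs: str
    out_dir: str
    expression: str | None = None
    expression_species: str | None = None  # defaults to the last species tag
    max_distance_bp: int = 10_000
    replicate_mode: str = "intersect"
    min_overlap_bp: int = 1
    universe: int | None = None  # default: reference genes with an ortholog entry
    categories: list[str] | None = None  # default: every annotated category
    window_bp: int = 500
    n_draws: int = 200
    min_fold: float = 2.0
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        try:
            species = [SpeciesInput(**s) for s in raw.pop("species")]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid species block: {exc}") from exc
        try:
            config = cls(species=species, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        config.validate()
        return config

    def validate(self) -> None:
        if len(self.species) < 2:
            raise ConfigError("need at least two species to compare")
        if self.replicate_mode not in ("intersect", "union"):
            raise ConfigError(f"unknown replicate_mode {self.replicate_mode!r}")
        missing = []
        for sp in self.species:
            for path in [sp.genome, sp.genes, *sp.peaks]:
                if not os.path.exists(path):
                    missing.append(path)
        for path in [self.orthologs, self.annotation, self.motifs, self.expression]:
            if path is not None and not os.path.exists(path):
                missing.append(path)
        if missing:
            raise ConfigError(f"missing input file(s): {missing}")


@dataclass
class ComparisonReport:
    """Consolidated numbers; every count is re-derivable from the stage TSVs
    shipped alongside it."""

    seed: int
    species_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    venn_regions: dict[str, int] = field(default_factory=dict)
    overlap_test: dict | None = None
    category_folds: list[dict] = field(default_factory=list)
    enrichment: list[dict] = field(default_factory=list)
    de: dict | None = None
    motif_folds: dict[str, list[dict]] = field(default_factory=dict)
    array_comparison: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_round_sig(dataclasses.asdict(self)), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = [f"cistarget-compare run (seed={self.seed})", ""]
        for tag, counts in self.species_counts.items():
            lines.append(
                f"[{tag}] peaks reconciled: {counts['n_peaks_reconciled']}  "
                f"target genes: {counts['n_target_genes']}  "
                f"ortholog-mapped: {counts['n_mapped']} "
                f"(unmapped {counts['n_unmapped']})"
            )
        lines.append("")
        lines.append("Venn regions (reference gene space):")
        for region, count in self.venn_regions.items():
            lines.append(f"  {region}: {count}")
        if self.overlap_test:
            t = self.overlap_test
            lines.append(
                f"overlap test: k={t['overlap']} |A|={t['size_a']} |B|={t['size_b']} "
                f"U={t['universe']} fold={t['fold']:.3g} p={t['p_value']:.3g}"
            )
        if self.category_folds:
            lines.append("")
            lines.append("category fold over-representation (shared vs specific):")
            for row in self.category_folds:
                fold = row["fold"]
                fold_s = "inf" if fold is None else f"{fold:.3g}"
                lines.append(
                    f"  {row['comparison']} {row['category_id']}: fold={fold_s} "
                    f"p={row['p_value']:.3g}"
                )
        if self.de:
            lines.append("")
            lines.append(
                f"DE genes (>= {self.de['min_fold']}-fold): {self.de['n_de']}; "
                f"overlap with {self.de['species']} targets: {self.de['overlap_count']} "
                f"({100 * self.de['proportion_of_targets']:.1f}% of targets)"
            )
        for tag, rows in self.motif_folds.items():
            lines.append("")
            lines.append(f"motif fold enrichment [{tag}] (ChIP vs non-coding background):")
            for row in rows:
                fold = row["fold"]
                fold_s = "inf" if fold is None else f"{fold:.3g}"
                lines.append(
                    f"  {row['motif_id']}: fold={fold_s} p={row['empirical_p']:.3g}"
                )
        if self.array_comparison:
            c = self.array_comparison
            lines.append("")
            lines.append(
                f"binding-site array {c['a_tag']} vs {c['b_tag']}: "
                f"shared TFs {sorted(c['shared_tfs'])}, "
                f"{c['a_tag']}-only {sorted(c['a_only_tfs'])}, "
                f"{c['b_tag']}-only {sorted(c['b_only_tfs'])}"
            )
        return "\n".join(lines) + "\n"


def _round_sig(obj, digits: int = 4):
    if isinstance(obj, float):
        if math.isinf(obj) or math.isnan(obj):
            return None
        return float(f"{obj:.{digits}g}")
    if isinstance(obj, dict):
        return {k: _round_sig(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_sig(v, digits) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return obj


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def run(config: RunConfig) -> ComparisonReport:
    """Execute all stages; see module docstring.

    Any stage failure raises :class:`StageError` after writing a MANIFEST
    marking the run incomplete.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: list[str] = []
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.species) + 1)
    report = ComparisonReport(seed=config.seed)

    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cistarget_compare")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("run: seed=%d out_dir=%s", config.seed, config.out_dir)

    stage = "load"
    try:
        genomes, genes, replicate_peaks = {}, {}, {}
        for sp in config.species:
            genomes[sp.tag] = read_fasta(sp.genome)
            genes[sp.tag] = read_gff3(sp.genes)
            replicate_peaks[sp.tag] = [
                read_bed(path, replicate_id=f"{sp.tag}_rep{i + 1}")
                for i, path in enumerate(sp.peaks)
            ]
        ortho = _compare.OrthologMap.from_tsv(config.orthologs)
        annotation = _enrich.AnnotationTable.from_tsv(config.annotation)
        library = read_motif_library(config.motifs)
        categories = list(config.categories or annotation.categories)

        stage = "annotate"
        target_sets, mapped_sets = {}, {}
        reconciled = {}
        for sp in config.species:
            peaks = _annotate.reconcile_replicates(
                replicate_peaks[sp.tag], config.min_overlap_bp, config.replicate_mode
            )
            reconciled[sp.tag] = peaks
            assignments = _annotate.nearest_gene(
                peaks, genes[sp.tag], config.max_distance_bp
            )
            _write_assignments(
                assignments, os.path.join(config.out_dir, f"{sp.tag}_targets.tsv"),
                config.seed,
            )
            manifest.append(f"{sp.tag}_targets.tsv")
            tset = _annotate.target_gene_set(assignments, sp.tag)
            target_sets[sp.tag] = tset
            logger.info(
                "annotate[%s]: %d reconciled peaks, %d assignments, %d target genes",
                sp.tag, len(peaks), len(assignments), len(tset),
            )

        stage = "map"
        for sp in config.species:
            mapped, unmapped = _compare.map_to_reference(target_sets[sp.tag], ortho)
            mapped_sets[sp.tag] = mapped
            path = f"{sp.tag}_targets_reference.tsv"
            mapped.to_tsv(os.path.join(config.out_dir, path))
            manifest.append(path)
            report.species_counts[sp.tag] = {
                "n_peaks_reconciled": len(reconciled[sp.tag]),
                "n_target_genes": len(target_sets[sp.tag]),
                "n_mapped": len(mapped),
                "n_unmapped": unmapped,
            }
            logger.info("map[%s]: %d mapped, %d unmapped", sp.tag, len(mapped), unmapped)

        stage = "partition"
        venn = _compare.venn_partition(list(mapped_sets.values()))
        venn_rows = []
        for sig, count in venn.region_counts.items():
            venn_rows.append(
                {"region": "&".join(sig), "count": count,
                 "members": ",".join(venn.region_members[sig])}
            )
            report.venn_regions["&".join(sig)] = count
        pd.DataFrame(venn_rows).to_csv(
            os.path.join(config.out_dir, "venn_regions.tsv"), sep="\t", index=False
        )
        manifest.append("venn_regions.tsv")

        universe = config.universe or len(ortho.reference_ids)
        a_tag, b_tag = config.species[0].tag, config.species[1].tag
        test = _compare.overlap_significance(
            mapped_sets[a_tag], mapped_sets[b_tag], universe
        )
        report.overlap_test = dataclasses.asdict(test)

        stage = "enrich"
        tags = tuple(mapped_sets)
        shared_ids = frozenset.intersection(*(s.ids for s in mapped_sets.values()))
        shared_set = _compare.GeneSet("shared", shared_ids, namespace="reference")
        fold_rows = []
        for tag in tags:
            specific_ids = mapped_sets[tag].ids - shared_ids
            if not shared_ids or not specific_ids:
                continue
            specific = _compare.GeneSet(f"{tag}_specific", specific_ids, "reference")
            for cat in categories:
                res = _enrich.fold_overrepresentation(
                    shared_set, specific, annotation, cat
                )
                fold_rows.append(
                    {"comparison": f"shared_vs_{tag}_specific", "category_id": cat,
                     "fold": None if res.fold_undefined else res.fold,
                     "p_value": res.p_value,
                     "count_shared": res.count_set, "size_shared": res.size_set,
                     "count_specific": res.count_ref, "size_specific": res.size_ref}
                )
        report.category_folds = fold_rows
        pd.DataFrame(fold_rows).to_csv(
            os.path.join(config.out_dir, "category_folds.tsv"), sep="\t", index=False
        )
        manifest.append("category_folds.tsv")

        universe_set = _compare.GeneSet("universe", ortho.reference_ids, "reference")
        if shared_ids and shared_ids <= universe_set.ids:
            enr = _enrich.enrichment_vs_universe(
                shared_set, annotation, universe_set, categories
            )
            report.enrichment = [dataclasses.asdict(e) for e in enr]
            pd.DataFrame(report.enrichment).to_csv(
                os.path.join(config.out_dir, "enrichment.tsv"), sep="\t", index=False
            )
            manifest.append("enrichment.tsv")

        stage = "defilter"
        if config.expression:
            expr = _enrich.ExpressionTable.from_tsv(config.expression)
            de_tag = config.expression_species or config.species[-1].tag
            de_set = _enrich.fold_change_filter(
                expr, config.min_fold, config.pseudocount, species_tag=de_tag
            )
            de_set.to_tsv(os.path.join(config.out_dir, "de_genes.tsv"))
            manifest.append("de_genes.tsv")
            count, prop = _enrich.de_overlap(target_sets[de_tag], de_set)
            report.de = {
                "species": de_tag, "min_fold": config.min_fold,
                "n_de": len(de_set), "overlap_count": count,
                "proportion_of_targets": prop,
            }
            logger.info("defilter[%s]: %d DE genes, %d overlap targets",
                        de_tag, len(de_set), count)

        stage = "motif-enrich"
        for i, sp in enumerate(config.species):
            seq_by_id = {rec.id: rec.residues for rec in genomes[sp.tag]}
            fg = [
                seq_by_id[p.interval.scaffold][p.interval.start : p.interval.end]
                for p in reconciled[sp.tag]
            ]
            rows = []
            rng = np.random.default_rng(seeds[i])
            for motif in library:
                fe = _motifs.fold_enrichment(
                    fg, motif, genomes[sp.tag], genes[sp.tag],
                    n_draws=config.n_draws, rng=rng,
                )
                rows.append(
                    {"motif_id": fe.motif_id, "tf": motif.tf_name,
                     "fg_density": fe.fg_density,
                     "bg_mean_density": fe.bg_mean_density, "bg_sd": fe.bg_sd,
                     "fold": None if fe.fold_undefined else fe.fold,
                     "empirical_p": fe.empirical_p,
                     "n_draws": fe.n_background_draws}
                )
                logger.info("motif-enrich[%s] %s: %d draws", sp.tag,
                            motif.motif_id, config.n_draws)
            report.motif_folds[sp.tag] = rows
            pd.DataFrame(rows).to_csv(
                os.path.join(config.out_dir, f"{sp.tag}_motif_enrichment.tsv"),
                sep="\t", index=False,
            )
            manifest.append(f"{sp.tag}_motif_enrichment.tsv")

        stage = "array-diff"
        arrays = {}
        for sp in config.species:
            arr = _best_anchor_array(
                reconciled[sp.tag], genomes[sp.tag], library, config.window_bp
            )
            if arr is not None:
                arrays[sp.tag] = arr
        if len(arrays) >= 2:
            (a_tag, arr_a), (b_tag, arr_b) = list(arrays.items())[:2]
            comp = _motifs.compare_arrays(arr_a, arr_b)
            report.array_comparison = {
                "a_tag": a_tag, "b_tag": b_tag,
                "shared_tfs": sorted(comp.shared_tfs),
                "a_only_tfs": sorted(comp.a_only_tfs),
                "b_only_tfs": sorted(comp.b_only_tfs),
                "per_tf_offset_pairs": {
                    tf: [list(p) for p in pairs]
                    for tf, pairs in comp.per_tf_offset_pairs.items()
                },
            }
            with open(os.path.join(config.out_dir, "array_comparison.json"), "w") as fh:
                json.dump(report.array_comparison, fh, indent=1, sort_keys=True)
                fh.write("\n")
            manifest.append("array_comparison.json")

        stage = "report"
        report.to_json(os.path.join(config.out_dir, "report.json"))
        with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
            fh.write(report.to_text())
        manifest += ["report.json", "report.txt", "run.log"]
        _write_manifest(config.out_dir, manifest, complete=True)
        return report
    except Exception as exc:
        _write_manifest(config.out_dir, manifest, complete=False, stage=stage)
        raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _best_anchor_array(peaks, genome, library, window_bp):
    """Array around the summit of the highest-scoring reconciled peak."""
    if not peaks:
        return None
    peak = max(peaks, key=lambda p: (p.score, -p.interval.start))
    seq_by_id = {rec.id: rec.residues for rec in genome}
    seq = seq_by_id[peak.interval.scaffold]
    lo = max(0, peak.summit - window_bp - 50)
    hi = min(len(seq), peak.summit + window_bp + 50)
    return _motifs.anchor_array(
        seq[lo:hi], peak.summit - lo, library, window_bp, anchor=peak.interval
    )


def _write_assignments(assignments, path, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write("scaffold\tstart\tend\tgene_id\tdistance_bp\trelation\ttie\n")
        for a in assignments:
            iv = a.peak.interval
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{a.gene_id}\t"
                f"{a.distance_bp}\t{a.relation}\t{int(a.tie)}\n"
            )


def _write_manifest(out_dir, files, complete: bool, stage: str | None = None) -> None:
    with open(os.path.join(out_dir, "MANIFEST"), "w") as fh:
        fh.write("status: complete\n" if complete
                 else f"status: INCOMPLETE (failed at stage {stage})\n")
        for name in files:
            fh.write(name + "\n")
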