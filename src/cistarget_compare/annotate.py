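"""Nearest-gene assignment of ChIP peaks and replicate reconciliation.

Putative targets are the genes nearest to each peak, measured as the
edge-to-edge gap between the peak interval and the gene body (0 when they
overlap).  Strand is ignored for assignment; the reported relation describes
where the peak lies relative to the gene in genome + orientation
('downstream' = peak after the gene body).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GeneModel, GenomicInterval, Peak
from .compare import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "TargetAssignment",
    "reconcile_replicates",
    "nearest_gene",
    "target_gene_set",
]

RELATIONS = ("overlapping", "upstream", "downstream")


@dataclass(frozen=True)
class TargetAssignment:
    """A peak -> nearest-gene link.

    ``distance_bp`` is the edge-to-edge gap (0 iff ``relation`` is
    'overlapping').  ``tie`` marks peaks equidistant from several genes; each
    tied gene gets its own assignment.
    """

    peak: Peak
    gene_id: str
    distance_bp: int
    relation: str
    tie: bool = False

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if (self.distance_bp == 0) != (self.relation == "overlapping"):
            raise ValueError("distance 0 iff relation 'overlapping'")


# ---------------------------------------------------------------------------
# replicate reconciliation
# ---------------------------------------------------------------------------

def reconcile_replicates(
    peak_lists: list[list[Peak]],
    min_overlap_bp: int = 1,
    mode: str = "intersect",
) -> list[Peak]:
    """Merge replicate peak calls into one consolidated peak list.

    ``intersect`` (default, conservative) keeps only peaks present in every
    replicate, where presence means an overlap of at least ``min_overlap_bp``
    with a peak of each other replicate; the merged peak is the intersection
    interval, its score the mean of the contributing scores and its
    ``replicate_ids`` their union.  ``union`` merges any peaks overlapping by
    at least ``min_overlap_bp`` across all replicates into their union
    interval.
    """
    if not peak_lists:
        raise ValueError("at least one replicate peak list is required")
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if mode not in ("intersect", "union"):
        raise ValueError(f"unknown replicate mode {mode!r}")
    if mode == "union":
        return _union_merge(peak_lists, min_overlap_bp)

    # accumulator: (interval, scores, replicate ids)
    current = [
        (p.interval, [p.score], set(p.replicate_ids)) for p in peak_lists[0]
    ]
    for rep in peak_lists[1:]:
        nxt = []
        for iv, scores, reps in current:
            best = None
            best_ovl = 0
            for q in rep:
                ovl = iv.overlap_len(q.interval)
                if ovl >= min_overlap_bp and ovl > best_ovl:
                    best, best_ovl = q, ovl
            if best is None:
                continue
            merged = iv.intersection(best.interval)
            nxt.append((merged, scores + [best.score], reps | set(best.replicate_ids)))
        current = nxt
    return [
        Peak(iv, score=float(np.mean(scores)), replicate_ids=frozenset(reps))
        for iv, scores, reps in current
    ]


def _union_merge(peak_lists, min_overlap_bp):
    pool = sorted(
        (p for rep in peak_lists for p in rep),
        key=lambda p: (p.interval.scaffold, p.interval.start, p.interval.end),
    )
    merged: list[Peak] = []
    acc = None  # (scaffold, start, end, scores, reps)
    for p in pool:
        iv = p.interval
        if acc is not None and iv.scaffold == acc[0] and min(acc[2], iv.end) - max(acc[1], iv.start) >= min_overlap_bp:
            acc = (acc[0], min(acc[1], iv.start), max(acc[2], iv.end),
                   acc[3] + [p.score], acc[4] | set(p.replicate_ids))
        else:
            if acc is not None:
                merged.append(_acc_to_peak(acc))
            acc = (iv.scaffold, iv.start, iv.end, [p.score], set(p.replicate_ids))
    if acc is not None:
        merged.append(_acc_to_peak(acc))
    return merged


def _acc_to_peak(acc):
    scaffold, start, end, scores, reps = acc
    return Peak(
        GenomicInterval(scaffold, start, end),
        score=float(np.mean(scores)),
        replicate_ids=frozenset(reps),
    )


# ---------------------------------------------------------------------------
# nearest-gene assignment
# ---------------------------------------------------------------------------

def nearest_gene(
    peaks: list[Peak],
    genes: list[GeneModel],
    max_distance_bp: int = 10_000,
) -> list[TargetAssignment]:
    """Assign each peak to its nearest gene(s) on the same scaffold.

    Distance is the edge-to-edge gap between peak and gene body.  Peaks
    farther than ``max_distance_bp`` from every gene yield no assignment
    (counted and logged).  Exact ties produce one assignment per tied gene,
    ``tie=True``, ordered lexicographically by gene_id.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if max_distance_bp < 0:
        raise ValueError("max_distance_bp must be >= 0")

    by_scaffold: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
    for scaffold in {g.interval.scaffold for g in genes}:
        sub = sorted(
            (g for g in genes if g.interval.scaffold == scaffold),
            key=lambda g: (g.interval.start, g.interval.end, g.gene_id),
        )
        by_scaffold[scaffold] = (
            np.array([g.interval.start for g in sub]),
            np.array([g.interval.end for g in sub]),
            sub,
        )

    assignments: list[TargetAssignment] = []
    unassigned = 0
    for peak in peaks:
        entry = by_scaffold.get(peak.interval.scaffold)
        if entry is None:
            unassigned += 1
            continue
        starts, ends, sub = entry
        gaps = np.maximum(starts - peak.interval.end, 0) + np.maximum(
            peak.interval.start - ends, 0
        )
        dmin = int(gaps.min())
        if dmin > max_distance_bp:
            unassigned += 1
            continue
        tied = [sub[i] for i in np.nonzero(gaps == dmin)[0]]
        tied.sort(key=lambda g: g.gene_id)
        is_tie = len(tied) > 1
        for g in tied:
            if dmin == 0:
                relation = "overlapping"
            elif g.interval.end <= peak.interval.start:
                relation = "downstream"  # peak lies downstream of the gene
            else:
                relation = "upstream"
            assignments.append(
                TargetAssignment(peak, g.gene_id, dmin, relation, tie=is_tie)
            )
    if unassigned:
        logger.info(
            "nearest_gene: %d peak(s) unassigned (no gene within %d bp)",
            unassigned,
            max_distance_bp,
        )
    return assignments


def target_gene_set(assignments: list[TargetAssignment], species_tag: str) -> GeneSet:
    """Deduplicated set of target gene ids from a list of assignments."""
    return GeneSet(species_tag, frozenset(a.gene_id for a in assignments))
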