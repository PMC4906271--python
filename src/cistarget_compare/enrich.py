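"""Functional-category profiles, fold over-representation and enrichment.

The central comparison is the fold over-representation of a category between
two target subsets (e.g. targets shared with the reference species versus
reference-specific targets): ``fold = proportion_a / proportion_b``.  A
two-sided Fisher exact test on the 2x2 table (annotated / not x set A / set
B) accompanies the fold, and enrichment of one set against a gene universe
uses the hypergeometric upper tail with Benjamini-Hochberg correction across
the tested categories.

A differential-expression filter keeps genes whose between-condition ratio
(pseudocounted, either direction) reaches a minimum fold, mirroring the
common ">= 2-fold difference" criterion for calling a gene differentially
expressed between two tissues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from .compare import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "CategoryEnrichment",
    "ExpressionTable",
    "category_proportions",
    "fold_overrepresentation",
    "enrichment_vs_universe",
    "bh_adjust",
    "fold_change_filter",
    "de_overlap",
]


class AnnotationTable:
    """gene_id -> set of functional category ids, with category labels.

    Any category referenced by an assignment gets a label entry (the id
    itself when no human-readable label was supplied).
    """

    def __init__(
        self,
        assignments: dict[str, set[str]],
        category_labels: dict[str, str] | None = None,
    ) -> None:
        self.assignments = {g: frozenset(cats) for g, cats in assignments.items()}
        labels = dict(category_labels or {})
        for cats in self.assignments.values():
            for cat in cats:
                labels.setdefault(cat, cat)
        self.category_labels = labels

    def categories_of(self, gene_id: str) -> frozenset[str]:
        return self.assignments.get(gene_id, frozenset())

    def genes_in(self, category_id: str) -> frozenset[str]:
        return frozenset(
            g for g, cats in self.assignments.items() if category_id in cats
        )

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.category_labels))

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        """Read ``gene_id <tab> category_id [<tab> label]`` rows."""
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            names=["gene_id", "category_id", "label"],
        )
        assignments: dict[str, set[str]] = {}
        labels: dict[str, str] = {}
        for _, row in df.iterrows():
            assignments.setdefault(row["gene_id"], set()).add(row["category_id"])
            if isinstance(row["label"], str) and row["label"]:
                labels[row["category_id"]] = row["label"]
        return cls(assignments, labels)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for gene_id in sorted(self.assignments):
                for cat in sorted(self.assignments[gene_id]):
                    fh.write(f"{gene_id}\t{cat}\t{self.category_labels[cat]}\n")


@dataclass
class CategoryEnrichment:
    """Per-category comparison between a gene set and a reference set."""

    category_id: str
    count_set: int
    size_set: int
    count_ref: int
    size_ref: int
    proportion_set: float
    proportion_ref: float
    fold: float           # math.inf / math.nan when flagged undefined
    fold_undefined: bool
    p_value: float
    q_value: float | None = None


class ExpressionTable:
    """gene_id -> (value in condition 1, value in condition 2)."""

    def __init__(self, rows: dict[str, tuple[float, float]],
                 condition_names: tuple[str, str] = ("cond1", "cond2")) -> None:
        for gene_id, (v1, v2) in rows.items():
            if not (math.isfinite(v1) and math.isfinite(v2)):
                raise ValueError(f"non-finite expression value for {gene_id!r}")
            if v1 < 0 or v2 < 0:
                raise ValueError(f"negative expression value for {gene_id!r}")
        self.rows = dict(rows)
        self.condition_names = condition_names

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if df.shape[1] < 3:
            raise ValueError("expression table needs gene_id + two value columns")
        gene_col, c1, c2 = df.columns[:3]
        rows = {
            str(g): (float(a), float(b))
            for g, a, b in zip(df[gene_col], df[c1], df[c2])
        }
        return cls(rows, condition_names=(str(c1), str(c2)))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"gene_id\t{self.condition_names[0]}\t{self.condition_names[1]}\n")
            for gene_id in sorted(self.rows):
                v1, v2 = self.rows[gene_id]
                fh.write(f"{gene_id}\t{v1:g}\t{v2:g}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def category_proportions(
    gene_set: GeneSet,
    annotation: AnnotationTable,
    categories: list[str],
) -> dict[str, tuple[int, float]]:
    """Count and proportion of set members annotated with each category.

    Genes lacking any annotation still count in the denominator.
    """
    if not categories:
        raise ValueError("categories must be non-empty")
    if len(gene_set) == 0:
        raise ValueError("gene_set must be non-empty")
    n = len(gene_set)
    out = {}
    for cat in categories:
        count = sum(1 for g in gene_set.ids if cat in annotation.categories_of(g))
        out[cat] = (count, count / n)
    return out


def fold_overrepresentation(
    set_a: GeneSet,
    set_b: GeneSet,
    annotation: AnnotationTable,
    category: str,
) -> CategoryEnrichment:
    """Fold over-representation of a category in set A relative to set B.

    ``fold = proportion_a / proportion_b``; when B's proportion is 0 the fold
    is flagged undefined (``inf`` if A has members annotated, ``nan`` if
    neither set does).  The p-value is a two-sided Fisher exact test on the
    annotated/not x A/B table.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both gene sets must be non-empty")
    ka = sum(1 for g in set_a.ids if category in annotation.categories_of(g))
    kb = sum(1 for g in set_b.ids if category in annotation.categories_of(g))
    na, nb = len(set_a), len(set_b)
    pa, pb = ka / na, kb / nb
    if pb > 0:
        fold, undefined = pa / pb, False
    elif pa > 0:
        fold, undefined = math.inf, True
    else:
        fold, undefined = math.nan, True
    _, p = fisher_exact([[ka, na - ka], [kb, nb - kb]], alternative="two-sided")
    return CategoryEnrichment(
        category_id=category,
        count_set=ka, size_set=na,
        count_ref=kb, size_ref=nb,
        proportion_set=pa, proportion_ref=pb,
        fold=fold, fold_undefined=undefined,
        p_value=float(p),
    )


def bh_adjust(p_values: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (same order as input)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrichment_vs_universe(
    gene_set: GeneSet,
    annotation: AnnotationTable,
    universe_set: GeneSet,
    categories: list[str],
) -> list[CategoryEnrichment]:
    """Hypergeometric enrichment of each category in a set versus a universe.

    ``gene_set`` must be a subset of ``universe_set``.  Returns one
    :class:`CategoryEnrichment` per category with BH q-values, sorted by
    ascending q (then p, then category id).
    """
    if not categories:
        raise ValueError("categories must be non-empty")
    if not gene_set.ids <= universe_set.ids:
        missing = sorted(gene_set.ids - universe_set.ids)[:3]
        raise ValueError(f"gene_set is not a subset of the universe (e.g. {missing})")
    n, U = len(gene_set), len(universe_set)
    results = []
    for cat in categories:
        k = sum(1 for g in gene_set.ids if cat in annotation.categories_of(g))
        K = sum(1 for g in universe_set.ids if cat in annotation.categories_of(g))
        p = float(hypergeom.sf(k - 1, U, K, n)) if n > 0 else 1.0
        pa = k / n if n else 0.0
        pu = K / U if U else 0.0
        if pu > 0:
            fold, undefined = pa / pu, False
        elif pa > 0:
            fold, undefined = math.inf, True
        else:
            fold, undefined = math.nan, True
        results.append(
            CategoryEnrichment(
                category_id=cat,
                count_set=k, size_set=n,
                count_ref=K, size_ref=U,
                proportion_set=pa, proportion_ref=pu,
                fold=fold, fold_undefined=undefined,
                p_value=min(p, 1.0),
            )
        )
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.category_id))
    return results


def fold_change_filter(
    expr: ExpressionTable,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    species_tag: str = "de",
) -> GeneSet:
    """Genes whose between-condition ratio reaches ``min_fold`` (inclusive).

    The ratio is unsigned: ``max((v1+ps)/(v2+ps), (v2+ps)/(v1+ps))``.  Rows
    with both values 0 and pseudocount 0 are skipped (counted in the log).
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    kept: set[str] = set()
    skipped = 0
    for gene_id, (v1, v2) in expr.rows.items():
        a, b = v1 + pseudocount, v2 + pseudocount
        if a == 0 and b == 0:
            skipped += 1
            continue
        if b == 0 or a == 0:          # one-sided zero without pseudocount
            kept.add(gene_id)
            continue
        if max(a / b, b / a) >= min_fold:
            kept.add(gene_id)
    if skipped:
        logger.warning("fold_change_filter: %d gene(s) skipped (0/0 ratio)", skipped)
    return GeneSet(species_tag, frozenset(kept))


def de_overlap(target_set: GeneSet, de_set: GeneSet) -> tuple[int, float]:
    """Overlap of a target set with a differential-expression set.

    Returns ``(count, proportion_of_targets)``.
    """
    if len(target_set) == 0:
        raise ValueError("target_set must be non-empty")
    count = len(target_set.ids & de_set.ids)
    return count, count / len(target_set)
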