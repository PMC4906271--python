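"""Ortholog-anchored comparison of target gene sets across species.

Species target sets are projected into a common reference gene space (the
*Drosophila* orthologs of each species gene), then compared by exhaustive
Venn partition and, where a significance statement is wanted, by a
hypergeometric overlap test: with a universe of ``U`` genes, set sizes
``|A|``, ``|B|`` and overlap ``k``, the upper-tail probability
``P(X >= k)`` for ``X ~ Hypergeom(U, |A|, |B|)`` and the fold
``k·U / (|A|·|B|)`` over the expected overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSet",
    "OrthologMap",
    "VennPartition",
    "OverlapTest",
    "map_to_reference",
    "venn_partition",
    "overlap_significance",
]


@dataclass(frozen=True)
class GeneSet:
    """A species-tagged set of gene ids.

    ``namespace`` declares the id space the members live in (e.g. the
    species' own annotation, or the shared reference space after ortholog
    mapping); Venn partitions refuse to mix namespaces unless forced.
    """

    species_tag: str
    ids: frozenset[str]
    namespace: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(self.ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.ids

    @classmethod
    def from_tsv(cls, path, species_tag: str | None = None) -> "GeneSet":
        """Read a one-column gene-id TSV; '#' lines may carry
        ``species_tag=`` / ``namespace=`` declarations."""
        tag, namespace, ids = species_tag, None, set()
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for token in line[1:].split():
                        if token.startswith("species_tag=") and tag is None:
                            tag = token.split("=", 1)[1]
                        elif token.startswith("namespace="):
                            namespace = token.split("=", 1)[1]
                    continue
                ids.add(line.split("\t")[0])
        return cls(tag or "set", frozenset(ids), namespace=namespace)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# species_tag={self.species_tag}")
            if self.namespace:
                fh.write(f" namespace={self.namespace}")
            fh.write("\n")
            for gene_id in sorted(self.ids):
                fh.write(gene_id + "\n")


class OrthologMap:
    """Mapping species gene id -> set of reference gene ids.

    Empty reference sets are rejected; many-to-many relations are allowed and
    collapse to the union of reference ids on mapping.
    """

    def __init__(self, pairs: dict[str, set[str]]) -> None:
        self.pairs: dict[str, frozenset[str]] = {}
        for gene_id, refs in pairs.items():
            refs = frozenset(refs)
            if not refs:
                raise ValueError(f"gene {gene_id!r} maps to an empty reference set")
            self.pairs[gene_id] = refs

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.pairs

    def __getitem__(self, gene_id: str) -> frozenset[str]:
        return self.pairs[gene_id]

    @property
    def reference_ids(self) -> frozenset[str]:
        """All reference genes with at least one ortholog entry (the default
        significance universe)."""
        out: set[str] = set()
        for refs in self.pairs.values():
            out |= refs
        return frozenset(out)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["gene_id", "ref_id"], dtype=str,
        )
        pairs: dict[str, set[str]] = {}
        for gene_id, ref_id in zip(df["gene_id"], df["ref_id"]):
            pairs.setdefault(gene_id, set()).add(ref_id)
        return cls(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for gene_id in sorted(self.pairs):
                for ref in sorted(self.pairs[gene_id]):
                    fh.write(f"{gene_id}\t{ref}\n")


@dataclass
class VennPartition:
    """Exhaustive overlap partition of 2-4 gene sets.

    Regions are keyed by the tuple of input species_tags containing the gene,
    in input order; all ``2^k - 1`` regions are present, empty ones with
    count 0.
    """

    set_tags: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    region_members: dict[tuple[str, ...], tuple[str, ...]]

    def count(self, *tags: str) -> int:
        return self.region_counts[tuple(tags)]

    @property
    def common_count(self) -> int:
        """Size of the region shared by all input sets."""
        return self.region_counts[self.set_tags]

    def total(self) -> int:
        return sum(self.region_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sig), "count": self.region_counts[sig]}
            for sig in self.region_counts
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric overlap test between two gene sets."""

    overlap: int
    size_a: int
    size_b: int
    universe: int
    p_value: float
    fold: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def map_to_reference(
    gene_set: GeneSet,
    ortholog_map: OrthologMap,
    namespace: str = "reference",
) -> tuple[GeneSet, int]:
    """Project a species gene set into the reference gene space.

    Returns the mapped set (union of reference ids of all mappable members;
    many-to-one relations collapse silently) and the count of members with no
    ortholog entry.
    """
    mapped: set[str] = set()
    unmapped = 0
    for gene_id in gene_set.ids:
        refs = ortholog_map.pairs.get(gene_id)
        if refs is None:
            unmapped += 1
        else:
            mapped |= refs
    return GeneSet(gene_set.species_tag, frozenset(mapped), namespace=namespace), unmapped


def venn_partition(sets: list[GeneSet], force: bool = False) -> VennPartition:
    """Exhaustive overlap partition of 2-4 gene sets.

    Sets must declare a common namespace (or none); pass ``force=True`` to
    override.  Tags must be unique.
    """
    if not (2 <= len(sets) <= 4):
        raise ValueError("venn_partition takes between 2 and 4 sets")
    tags = tuple(s.species_tag for s in sets)
    if len(set(tags)) != len(tags):
        raise ValueError("species tags must be unique")
    namespaces = {s.namespace for s in sets if s.namespace is not None}
    if len(namespaces) > 1 and not force:
        raise ValueError(
            f"gene sets declare different namespaces {sorted(namespaces)}; "
            "map them to a common reference first (or force)"
        )

    membership: dict[str, tuple[str, ...]] = {}
    for gene_id in set().union(*(s.ids for s in sets)):
        membership[gene_id] = tuple(t for t, s in zip(tags, sets) if gene_id in s.ids)

    counts: dict[tuple[str, ...], int] = {}
    members: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(tags) + 1):
        for sig in combinations(tags, r):
            counts[sig] = 0
            members[sig] = []
    for gene_id, sig in membership.items():
        counts[sig] += 1
        members[sig].append(gene_id)
    return VennPartition(
        tags,
        counts,
        {sig: tuple(sorted(ms)) for sig, ms in members.items()},
    )


def overlap_significance(set_a: GeneSet, set_b: GeneSet, universe: int) -> OverlapTest:
    """Hypergeometric upper-tail test of the overlap between two sets."""
    union = len(set_a.ids | set_b.ids)
    if universe < union:
        raise ValueError(f"universe {universe} smaller than |A ∪ B| = {union}")
    k = len(set_a.ids & set_b.ids)
    na, nb = len(set_a), len(set_b)
    if na == 0 or nb == 0:
        return OverlapTest(k, na, nb, universe, p_value=1.0, fold=0.0)
    p = float(hypergeom.sf(k - 1, universe, na, nb))
    fold = k * universe / (na * nb)
    return OverlapTest(k, na, nb, universe, p_value=min(p, 1.0), fold=fold)
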