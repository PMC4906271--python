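"""Motif scanning, fold-enrichment against sampled non-coding background,
k-mer over-representation and anchored binding-site arrays.

Fold enrichment follows the ChIP-versus-background design: the motif's hit
density (hits/kb, both strands) over the ChIP-pulled foreground sequences is
divided by its mean density over ``n_draws`` random sets of non-coding
sequences, each set length-matched to the foreground.  The empirical p-value
uses the add-one correction ``(1 + #{draws >= foreground}) / (n_draws + 1)``
so it is never 0.

Binding-site arrays anchor every library motif's hits at signed offsets from
a reference coordinate (a ChIP-determined anchor such as a peak summit), so
the cis-regulatory neighbourhood of the same anchor can be compared across
species at single-site resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import (
    IUPAC_BASES,
    GeneModel,
    GenomicInterval,
    MotifModel,
    SequenceRecord,
    revcomp,
    revcomp_iupac,
)

__all__ = [
    "MotifHit",
    "FoldEnrichment",
    "BindingSiteArray",
    "ArrayComparison",
    "scan",
    "sample_noncoding",
    "fold_enrichment",
    "kmer_enrichment",
    "anchor_array",
    "compare_arrays",
    "builtin_library",
]


@dataclass(frozen=True)
class MotifHit:
    """A motif match within a scanned sequence.

    ``position`` is the 0-based start of the matched window on the forward
    strand regardless of hit strand.  ``score`` is the log-odds score in
    matrix mode and 1.0 in consensus mode.
    """

    motif_id: str
    position: int
    strand: str
    score: float = 1.0


@dataclass(frozen=True)
class FoldEnrichment:
    """Foreground-vs-background motif density ratio with empirical p."""

    motif_id: str
    fg_density: float        # hits per kb over the foreground
    bg_mean_density: float
    bg_sd: float
    fold: float              # inf (flagged) when bg density is 0 but fg > 0
    fold_undefined: bool
    empirical_p: float
    n_background_draws: int


@dataclass(frozen=True)
class BindingSiteArray:
    """Ordered TF hits at signed offsets around an anchor coordinate.

    ``hits`` are ``(tf_name, offset, strand)`` tuples, offset measured from
    the anchor midpoint to the hit start, sorted by offset then tf_name.
    """

    anchor_midpoint: int
    window_bp: int
    hits: tuple[tuple[str, int, str], ...]
    anchor: GenomicInterval | None = None

    @property
    def tf_names(self) -> frozenset[str]:
        return frozenset(tf for tf, _, _ in self.hits)


@dataclass(frozen=True)
class ArrayComparison:
    """TF-level presence/absence partition of two binding-site arrays."""

    shared_tfs: frozenset[str]
    a_only_tfs: frozenset[str]
    b_only_tfs: frozenset[str]
    #: for each shared TF, (offset in A, nearest offset in B) per A hit
    per_tf_offset_pairs: dict[str, tuple[tuple[int, int], ...]]


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@lru_cache(maxsize=512)
def _iupac_regex(pattern: str) -> "re.Pattern[str]":
    """Overlap-tolerant regex for an IUPAC pattern.

    A sequence 'N' never satisfies a non-N motif code; the motif code 'N'
    matches any base including 'N'.
    """
    parts = []
    for code in pattern:
        chars = sorted(IUPAC_BASES[code])
        if code == "N":
            chars.append("N")
        parts.append("[" + "".join(chars) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


_SEQ_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _SEQ_CODE[_b] = _i


def _encode(sequence: str) -> np.ndarray:
    return _SEQ_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _matrix_positions(log_odds: np.ndarray, codes: np.ndarray, threshold: float):
    length = log_odds.shape[0]
    if codes.size < length:
        return np.empty(0, dtype=int), np.empty(0)
    # 5th column = N, which never matches: -inf sinks any window containing N
    lo = np.hstack([log_odds, np.full((length, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    scores = lo[np.arange(length)[None, :], windows].sum(axis=1)
    idx = np.nonzero(scores >= threshold)[0]
    return idx, scores[idx]


def scan(motif: MotifModel, sequence: str, both_strands: bool = True) -> list[MotifHit]:
    """All hits of a motif in a sequence.

    Consensus motifs match exactly (per-position IUPAC set membership);
    matrix motifs report windows whose log-odds score against a uniform
    background reaches the motif's threshold.  Reverse-strand hits are
    reported at the forward-strand coordinate of the match start.  A motif
    longer than the sequence yields an empty list.
    """
    sequence = sequence.upper()
    hits: list[MotifHit] = []
    if len(motif) > len(sequence):
        return hits
    if motif.is_consensus:
        for m in _iupac_regex(motif.iupac).finditer(sequence):
            hits.append(MotifHit(motif.motif_id, m.start(), "+"))
        if both_strands:
            for m in _iupac_regex(revcomp_iupac(motif.iupac)).finditer(sequence):
                hits.append(MotifHit(motif.motif_id, m.start(), "-"))
    else:
        codes = _encode(sequence)
        lo = motif.log_odds
        idx, scores = _matrix_positions(lo, codes, motif.score_threshold)
        hits.extend(
            MotifHit(motif.motif_id, int(i), "+", float(s)) for i, s in zip(idx, scores)
        )
        if both_strands:
            lo_rc = lo[::-1, ::-1]  # reverse positions, complement columns
            idx, scores = _matrix_positions(lo_rc, codes, motif.score_threshold)
            hits.extend(
                MotifHit(motif.motif_id, int(i), "-", float(s))
                for i, s in zip(idx, scores)
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _count_hits(motif: MotifModel, sequences, both_strands: bool = True) -> int:
    return sum(len(scan(motif, s, both_strands)) for s in sequences)


# ---------------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------------

def sample_noncoding(
    genome: list[SequenceRecord],
    genes: list[GeneModel],
    n: int,
    lengths: list[int],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw ``n`` random non-coding sequences of the given lengths.

    Positions are uniform over the genome; candidate windows intersecting a
    gene body or containing 'N' are rejected and redrawn.  After ``10*n``
    rejections the non-coding space is deemed insufficient and a
    ``ValueError`` is raised.  Deterministic under ``seed``.
    """
    if n != len(lengths):
        raise ValueError("n must equal len(lengths)")
    if rng is None:
        rng = np.random.default_rng(seed)
    scaffolds = [rec.residues for rec in genome]
    sizes = np.array([len(s) for s in scaffolds], dtype=float)
    weights = sizes / sizes.sum()
    gene_bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for rec in genome:
        sub = [g.interval for g in genes if g.interval.scaffold == rec.id]
        sub.sort(key=lambda iv: iv.start)
        gene_bounds[rec.id] = (
            np.array([iv.start for iv in sub]),
            np.array([iv.end for iv in sub]),
        )

    draws: list[str] = []
    rejections = 0
    budget = 10 * n
    for length in lengths:
        while True:
            si = int(rng.choice(len(scaffolds), p=weights))
            rec = genome[si]
            limit = len(rec.residues) - length
            ok = limit >= 0
            if ok:
                start = int(rng.integers(0, limit + 1))
                starts, ends = gene_bounds[rec.id]
                # overlap iff some gene has start < candidate_end and end > candidate_start
                i = np.searchsorted(starts, start + length)
                ok = not np.any(ends[:i] > start)
            if ok:
                window = rec.residues[start : start + length]
                ok = "N" not in window
            if ok:
                draws.append(window)
                break
            rejections += 1
            if rejections > budget:
                raise ValueError(
                    f"insufficient non-coding space: {rejections} rejected draws "
                    f"(budget 10*n = {budget})"
                )
    return draws


def fold_enrichment(
    fg_sequences: list[str],
    motif: MotifModel,
    genome: list[SequenceRecord],
    genes: list[GeneModel],
    n_draws: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FoldEnrichment:
    """Motif fold-enrichment in foreground sequences versus random
    non-coding background.

    Each background draw is a fresh set of non-coding sequences with the
    same multiset of lengths as the foreground.  Densities are hits/kb over
    the concatenated set, both strands.
    """
    if not fg_sequences:
        raise ValueError("foreground must be non-empty")
    if n_draws < 20:
        raise ValueError("n_draws must be >= 20")
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = [len(s) for s in fg_sequences]
    total_kb = sum(lengths) / 1000.0
    fg_density = _count_hits(motif, fg_sequences) / total_kb

    bg = np.empty(n_draws)
    for d in range(n_draws):
        seqs = sample_noncoding(genome, genes, len(lengths), lengths, rng=rng)
        bg[d] = _count_hits(motif, seqs) / total_kb
    bg_mean = float(bg.mean())
    bg_sd = float(bg.std(ddof=1)) if n_draws > 1 else 0.0
    if bg_mean > 0:
        fold, undefined = fg_density / bg_mean, False
    elif fg_density > 0:
        fold, undefined = float("inf"), True
    else:
        fold, undefined = 0.0, False
    empirical_p = (1 + int(np.sum(bg >= fg_density))) / (n_draws + 1)
    return FoldEnrichment(
        motif_id=motif.motif_id,
        fg_density=fg_density,
        bg_mean_density=bg_mean,
        bg_sd=bg_sd,
        fold=fold,
        fold_undefined=undefined,
        empirical_p=empirical_p,
        n_background_draws=n_draws,
    )


# ---------------------------------------------------------------------------
# k-mer over-representation
# ---------------------------------------------------------------------------

def _canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _kmer_counts(sequences, k: int) -> tuple[dict[str, int], float]:
    counts: dict[str, int] = {}
    total_kb = 0.0
    for seq in sequences:
        seq = seq.upper()
        total_kb += len(seq) / 1000.0
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            canon = _canonical_kmer(kmer)
            counts[canon] = counts.get(canon, 0) + 1
    return counts, total_kb


def kmer_enrichment(
    fg_sequences: list[str],
    bg_sequences: list[str],
    k: int,
    top_n: int | None = None,
) -> list[tuple[str, float, float, float]]:
    """Canonical k-mer over-representation of foreground versus background.

    Frequencies are occurrences per kb; the background frequency receives a
    pseudo-frequency of 0.5 occurrences so the fold is always defined.
    Returns ``(kmer, fg_freq, bg_freq, fold)`` ranked by descending fold,
    ties broken lexicographically; a stand-in for de-novo motif discovery.
    """
    if not (4 <= k <= 12):
        raise ValueError("k must be within [4, 12]")
    shortest = min(len(s) for s in list(fg_sequences) + list(bg_sequences))
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest sequence length {shortest}")
    fg_counts, fg_kb = _kmer_counts(fg_sequences, k)
    bg_counts, bg_kb = _kmer_counts(bg_sequences, k)
    rows = []
    for kmer in set(fg_counts) | set(bg_counts):
        fg_freq = fg_counts.get(kmer, 0) / fg_kb
        bg_freq = (bg_counts.get(kmer, 0) + 0.5) / bg_kb
        rows.append((kmer, fg_freq, bg_freq, fg_freq / bg_freq))
    rows.sort(key=lambda r: (-r[3], r[0]))
    return rows[:top_n] if top_n is not None else rows


# ---------------------------------------------------------------------------
# anchored binding-site arrays
# ---------------------------------------------------------------------------

def anchor_array(
    sequence: str,
    anchor_midpoint: int,
    library: list[MotifModel],
    window_bp: int = 500,
    anchor: GenomicInterval | None = None,
) -> BindingSiteArray:
    """Map every library motif's hits around an anchor coordinate.

    Hits (both strands) whose start lies within ``anchor_midpoint +/-
    window_bp`` are kept, at signed offsets from the anchor midpoint, sorted
    by offset then TF name.
    """
    if not (0 <= anchor_midpoint < len(sequence)):
        raise ValueError("anchor midpoint outside the sequence")
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    hits: list[tuple[str, int, str]] = []
    for motif in library:
        for h in scan(motif, sequence, both_strands=True):
            offset = h.position - anchor_midpoint
            if abs(offset) <= window_bp:
                hits.append((motif.tf_name, offset, h.strand))
    hits.sort(key=lambda t: (t[1], t[0], t[2]))
    return BindingSiteArray(
        anchor_midpoint=anchor_midpoint,
        window_bp=window_bp,
        hits=tuple(hits),
        anchor=anchor,
    )


def compare_arrays(a: BindingSiteArray, b: BindingSiteArray) -> ArrayComparison:
    """Presence/absence partition of the TFs hit in two arrays.

    For TFs present in both, each A offset is paired with the nearest B
    offset (ties towards the smaller offset).
    """
    tfs_a, tfs_b = a.tf_names, b.tf_names
    shared = tfs_a & tfs_b
    pairs: dict[str, tuple[tuple[int, int], ...]] = {}
    for tf in sorted(shared):
        offs_a = sorted(off for name, off, _ in a.hits if name == tf)
        offs_b = sorted(off for name, off, _ in b.hits if name == tf)
        pairs[tf] = tuple(
            (oa, min(offs_b, key=lambda ob: (abs(ob - oa), ob))) for oa in offs_a
        )
    return ArrayComparison(
        shared_tfs=frozenset(shared),
        a_only_tfs=frozenset(tfs_a - tfs_b),
        b_only_tfs=frozenset(tfs_b - tfs_a),
        per_tf_offset_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# bundled motif library
# ---------------------------------------------------------------------------

def builtin_library() -> list[MotifModel]:
    """Documented IUPAC approximations of the TF motifs used throughout.

    Hox/Ubx sites carry the TAAT core; ATAATS is the extended Ubx consensus
    (S = G or C).  Adf-1's 16-mer contains the 8-mer MAD1 site GCCGTCGC;
    GCTGCCCGCCGC is the honeybee MAD1 variant.  GAGAG repeats are the GAF
    (GAGA factor) recognition element.  Users supply real matrices for
    production scans.
    """
    return [
        MotifModel("Ubx", "Ubx", iupac="ATAATS"),
        MotifModel("UbxCore", "Ubx", iupac="TAAT"),
        MotifModel("Adf1", "Adf-1", iupac="TGGCTGCCGTCGCGAT"),
        MotifModel("MAD1", "MAD1", iupac="GCCGTCGC"),
        MotifModel("MAD1_Apis", "MAD1", iupac="GCTGCCCGCCGC"),
        MotifModel("GAF", "GAF", iupac="GAGAGAG"),
    ]
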