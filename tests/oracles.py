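"""Independent brute-force oracles used to verify the library.

Everything here is deliberately naive (per-position loops, closed-form
combinatorics, literal enumeration of draws) and shares no code with the
implementation under test.
"""

from itertools import combinations
from math import comb

# independent IUPAC table (sequence 'N' only satisfies the motif code 'N')
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _revcomp_seq(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _window_matches(pattern: str, window: str) -> bool:
    for code, base in zip(pattern, window):
        if base == "N":
            if code != "N":
                return False
        elif base not in IUPAC[code]:
            return False
    return True


def scan_oracle(pattern: str, sequence: str, both_strands: bool):
    """All (position, strand) IUPAC matches by sliding-window comparison.

    Reverse-strand hits are found by reverse-complementing each *window*
    and testing it against the original pattern (the implementation goes the
    other way round, via the reverse-complemented pattern)."""
    L = len(pattern)
    hits = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        if _window_matches(pattern, window):
            hits.append((i, "+"))
        if both_strands and _window_matches(pattern, _revcomp_seq(window)):
            hits.append((i, "-"))
    hits.sort()
    return hits


def nearest_gene_oracle(peaks, genes, max_distance_bp):
    """O(n*m) scan over all peak x gene pairs.

    Returns sorted tuples (peak_index, gene_id, distance, relation, tie).
    """
    out = []
    for pi, peak in enumerate(peaks):
        best_d = None
        best = []
        for gene in genes:
            if gene.interval.scaffold != peak.interval.scaffold:
                continue
            if gene.interval.end <= peak.interval.start:
                d = peak.interval.start - gene.interval.end
                rel = "downstream"
            elif gene.interval.start >= peak.interval.end:
                d = gene.interval.start - peak.interval.end
                rel = "upstream"
            else:
                d = 0
                rel = "overlapping"
            if best_d is None or d < best_d:
                best_d, best = d, [(gene.gene_id, rel)]
            elif d == best_d:
                best.append((gene.gene_id, rel))
        if best_d is None or best_d > max_distance_bp:
            continue
        tie = len(best) > 1
        for gene_id, rel in sorted(best):
            out.append((pi, gene_id, best_d, rel, tie))
    return sorted(out)


def hypergeom_tail_closed_form(k: int, universe: int, size_a: int, size_b: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe, size_a, size_b), by direct
    summation of binomial coefficients."""
    total = comb(universe, size_b)
    upper = min(size_a, size_b)
    return sum(
        comb(size_a, j) * comb(universe - size_a, size_b - j) for j in range(k, upper + 1)
    ) / total


def hypergeom_tail_enumeration(k: int, universe: int, size_a: int, size_b: int) -> float:
    """P(X >= k) by literally enumerating every size_b draw from the
    universe (feasible for universe <= ~20)."""
    items = range(universe)
    marked = set(range(size_a))
    hits = total = 0
    for draw in combinations(items, size_b):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total
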