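"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
All in-memory coordinates are **0-based, half-open** (``[start, end)``), the
BED convention.  BED files are read and written verbatim.  GFF3 files use
1-based closed coordinates on disk; they are shifted to ``(start-1, end)`` on
read and shifted back on write, so a GFF3 -> internal -> GFF3 round trip
preserves the printed numbers.

Sequences are restricted to the alphabet ``{A, C, G, T, N}`` and are
case-folded to upper case on read.  Parse errors always name the offending
line number.

Motif library dialect
---------------------
A motif library is a JSON array of objects, one per motif::

    {"id": "UbxCore", "tf": "Ubx", "iupac": "TAAT"}
    {"id": "X1", "tf": "X", "matrix": [[9,1,0,0], ...], "threshold": 6.2}

``iupac`` uses the 15 standard IUPAC nucleotide codes.  ``matrix`` rows are
per-position base weights in column order A, C, G, T; each row receives a
pseudocount of 0.01 per cell and is then normalised to sum to 1.
``threshold`` is a log-odds score cutoff (base 2, versus a uniform
background); if omitted it defaults to 80% of the motif's maximum achievable
score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParseError",
    "SequenceRecord",
    "GenomicInterval",
    "GeneModel",
    "Peak",
    "MotifModel",
    "IUPAC_BASES",
    "revcomp",
    "revcomp_iupac",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_motif_library",
    "write_motif_library",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


DNA_ALPHABET = frozenset("ACGTN")

#: IUPAC nucleotide codes -> set of plain bases each code stands for.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse complement of a plain {A,C,G,T,N} sequence."""
    return sequence.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC consensus pattern."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal character {sorted(bad)[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a scaffold.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.scaffold:
            raise ValueError("scaffold name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance in bp; 0 if the intervals overlap.

        Raises ``ValueError`` for intervals on different scaffolds, for which
        no distance is defined.
        """
        if self.scaffold != other.scaffold:
            raise ValueError("gap undefined across scaffolds")
        return max(0, other.start - self.end, self.start - other.end)

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.scaffold, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body: the unit to which peaks are assigned."""

    gene_id: str
    interval: GenomicInterval
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass(frozen=True)
class Peak:
    """A ChIP peak: a genomic interval with score and replicate provenance.

    ``summit_offset`` is relative to ``interval.start``; when absent the
    summit is taken to be the interval midpoint.
    """

    interval: GenomicInterval
    score: float = 0.0
    summit_offset: int | None = None
    replicate_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score must be non-negative")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside [0, {len(self.interval)})"
            )
        object.__setattr__(self, "replicate_ids", frozenset(self.replicate_ids))

    @property
    def summit(self) -> int:
        """Absolute summit coordinate (midpoint when no summit was recorded)."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


class MotifModel:
    """A TF binding motif: IUPAC consensus string or position probability matrix.

    Exactly one of ``iupac`` / ``matrix`` must be given.  Matrix columns are
    A, C, G, T; rows must sum to 1 (within 1e-9).  ``score_threshold`` applies
    to matrix mode only and is a base-2 log-odds cutoff against a uniform
    background; it defaults to 80% of the maximum achievable score.
    """

    def __init__(
        self,
        motif_id: str,
        tf_name: str,
        iupac: str | None = None,
        matrix: np.ndarray | None = None,
        score_threshold: float | None = None,
    ) -> None:
        if (iupac is None) == (matrix is None):
            raise ValueError("exactly one of iupac / matrix must be provided")
        self.motif_id = motif_id
        self.tf_name = tf_name
        self.iupac = iupac.upper() if iupac is not None else None
        self.matrix = None
        self.score_threshold = None
        if self.iupac is not None:
            if not self.iupac:
                raise ValueError("empty IUPAC consensus")
            bad = set(self.iupac) - set(IUPAC_BASES)
            if bad:
                raise ValueError(f"unknown IUPAC code {sorted(bad)[0]!r} in motif {motif_id}")
        else:
            m = np.asarray(matrix, dtype=float)
            if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
                raise ValueError(f"motif {motif_id}: matrix must have shape (length, 4)")
            sums = m.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError(f"motif {motif_id}: matrix rows must sum to 1")
            self.matrix = m
            if score_threshold is None:
                score_threshold = 0.8 * self.max_score
            self.score_threshold = float(score_threshold)

    def __len__(self) -> int:
        return len(self.iupac) if self.iupac is not None else self.matrix.shape[0]

    @property
    def is_consensus(self) -> bool:
        return self.iupac is not None

    @property
    def log_odds(self) -> np.ndarray:
        """Base-2 log-odds matrix against a uniform background (matrix mode)."""
        if self.matrix is None:
            raise ValueError("log_odds defined for matrix motifs only")
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"iupac={self.iupac!r}" if self.is_consensus else f"matrix{self.matrix.shape}"
        return f"MotifModel({self.motif_id!r}, tf={self.tf_name!r}, {kind})"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are upper-cased; characters outside {A,C,G,T,N} raise
    :class:`ParseError` naming the line.  Record order follows the file.
    """
    records: list[SequenceRecord] = []
    seq_id: str | None = None
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        if seq_id is None:
            return
        if not chunks:
            raise ParseError(f"line {line_no}: record {seq_id!r} has no sequence")
        records.append(SequenceRecord(seq_id, "".join(chunks)))

    with open(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                seq_id = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                if not seq_id:
                    raise ParseError(f"line {line_no}: empty FASTA header")
                chunks = []
            else:
                if seq_id is None:
                    raise ParseError(f"line {line_no}: sequence data before first '>' header")
                seq = line.upper()
                bad = set(seq) - DNA_ALPHABET
                if bad:
                    raise ParseError(
                        f"line {line_no}: illegal character {sorted(bad)[0]!r} in sequence {seq_id!r}"
                    )
                chunks.append(seq)
        _flush(line_no + 1)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, replicate_id: str | None = None) -> list[Peak]:
    """Read a BED3+ file into a list of :class:`Peak`.

    Columns: chrom, start, end, [name], [score], [strand], [summit_offset].
    The optional 7th column is this package's documented summit-offset
    extension (offset from ``start``).  A missing score reads as 0.
    ``replicate_id``, if given, is recorded on every peak.
    """
    peaks: list[Peak] = []
    reps = frozenset() if replicate_id is None else frozenset({replicate_id})
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ParseError(f"line {line_no}: BED needs >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"line {line_no}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"line {line_no}: start {start} >= end {end}")
            score = 0.0
            if len(cols) >= 5 and cols[4] not in ("", "."):
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise ParseError(f"line {line_no}: non-numeric score {cols[4]!r}") from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            summit = None
            if len(cols) >= 7 and cols[6] not in ("", "."):
                try:
                    summit = int(cols[6])
                except ValueError as exc:
                    raise ParseError(f"line {line_no}: non-integer summit offset") from exc
            try:
                peaks.append(
                    Peak(
                        GenomicInterval(cols[0], start, end, strand),
                        score=score,
                        summit_offset=summit,
                        replicate_ids=reps,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return peaks


def write_bed(peaks, path, name_prefix: str = "peak") -> None:
    """Write peaks as BED6 plus the documented summit-offset column 7."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            summit = p.summit_offset if p.summit_offset is not None else "."
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\t"
                f"{p.score:g}\t{iv.strand}\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key] = value
    return out


def read_gff3(path) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file.

    On-disk 1-based closed coordinates become internal 0-based half-open
    ``(start-1, end)``.  ``gene_id`` comes from the ``ID`` attribute; a
    duplicate or missing ID is a :class:`ParseError`.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"line {line_no}: GFF3 needs 9 columns")
            if cols[2] != "gene":
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"line {line_no}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"line {line_no}: invalid GFF3 coordinates {start1}..{end1}")
            attrs = _parse_gff_attributes(cols[8])
            gene_id = attrs.get("ID")
            if not gene_id:
                raise ParseError(f"line {line_no}: gene feature missing ID attribute")
            if gene_id in seen:
                raise ParseError(f"line {line_no}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            strand = cols[6] if cols[6] in ("+", "-") else "."
            genes.append(
                GeneModel(
                    gene_id,
                    GenomicInterval(cols[0], start1 - 1, end1, strand),
                    name=attrs.get("Name"),
                )
            )
    return genes


def write_gff3(genes, path, source: str = "cistarget_compare") -> None:
    """Write gene models as GFF3 (internal half-open -> 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            strand = iv.strand if iv.strand != "." else "."
            fh.write(
                f"{iv.scaffold}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# motif library (JSON dialect)
# ---------------------------------------------------------------------------

MATRIX_PSEUDOCOUNT = 0.01


def _normalise_matrix(rows, motif_id: str) -> np.ndarray:
    m = np.asarray(rows, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ParseError(f"motif {motif_id}: matrix must have 4 columns (A,C,G,T)")
    if np.any(m < 0):
        raise ParseError(f"motif {motif_id}: negative matrix entry")
    if np.any(m.sum(axis=1) == 0):
        raise ParseError(f"motif {motif_id}: matrix row sums to zero")
    m = m + MATRIX_PSEUDOCOUNT
    return m / m.sum(axis=1, keepdims=True)


def read_motif_library(path) -> list[MotifModel]:
    """Read the JSON motif dialect documented in this module."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ParseError("motif library must be a JSON array")
    motifs: list[MotifModel] = []
    seen: set[str] = set()
    for i, obj in enumerate(data):
        if not isinstance(obj, dict) or "id" not in obj or "tf" not in obj:
            raise ParseError(f"motif #{i}: object must carry 'id' and 'tf'")
        motif_id = obj["id"]
        if motif_id in seen:
            raise ParseError(f"duplicate motif id {motif_id!r}")
        seen.add(motif_id)
        if ("iupac" in obj) == ("matrix" in obj):
            raise ParseError(f"motif {motif_id}: exactly one of 'iupac'/'matrix' required")
        try:
            if "iupac" in obj:
                motifs.append(MotifModel(motif_id, obj["tf"], iupac=obj["iupac"]))
            else:
                motifs.append(
                    MotifModel(
                        motif_id,
                        obj["tf"],
                        matrix=_normalise_matrix(obj["matrix"], motif_id),
                        score_threshold=obj.get("threshold"),
                    )
                )
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    return motifs


def write_motif_library(motifs, path) -> None:
    out = []
    for m in motifs:
        obj: dict = {"id": m.motif_id, "tf": m.tf_name}
        if m.is_consensus:
            obj["iupac"] = m.iupac
        else:
            obj["matrix"] = [[round(x, 10) for x in row] for row in m.matrix]
            obj["threshold"] = m.score_threshold
        out.append(obj)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
        fh.write("\n")


def read_jaspar_pfm(path, tf_name: str | None = None) -> list[MotifModel]:
    """Convenience importer for JASPAR-style PFM text.

    Records look like::

        >MA0001.1 NAME
        A  [ 4 19  0 ... ]
        C  [16  0 20 ... ]
        ...

    Counts are pseudocounted and row-normalised exactly like the JSON dialect.
    """
    motifs = []
    with open(path) as fh:
        header = None
        rows: dict[str, list[float]] = {}
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    motifs.append(_pfm_to_motif(header, rows, tf_name))
                header = line[1:].split()
                rows = {}
            else:
                base = line[0].upper()
                nums = line[1:].replace("[", " ").replace("]", " ").split()
                rows[base] = [float(x) for x in nums]
        if header is not None:
            motifs.append(_pfm_to_motif(header, rows, tf_name))
    return motifs


def _pfm_to_motif(header, rows, tf_name):
    motif_id = header[0]
    name = tf_name or (header[1] if len(header) > 1 else motif_id)
    try:
        counts = np.array([rows[b] for b in "ACGT"], dtype=float).T
    except KeyError as exc:
        raise ParseError(f"motif {motif_id}: missing base row {exc}") from exc
    return MotifModel(motif_id, name, matrix=_normalise_matrix(counts, motif_id))
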