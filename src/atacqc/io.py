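"""Readers and writers for the external formats the toolkit consumes.

Supported: BED3/BED6, ENCODE 10-column narrowPeak, SAM/BAM (via pysam) and a
plain BED6 fragment dialect, FASTA (via pyfaidx), JASPAR text PFMs, and BED12
or refFlat gene models. Every parser validates aggressively and reports the
offending line number; all coordinates are kept 0-based half-open internally.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

from .core import AlignedFragment, GeneModelRecord, GenomicInterval

DEFAULT_MITO_NAMES = frozenset({"chrM", "chrMT", "MT", "M"})

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _data_lines(path: str) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_interval_fields(
    fields: list[str], path: str, lineno: int
) -> GenomicInterval:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}:{lineno}: malformed BED line") from exc
    if end <= start:
        raise FormatError(f"{path}:{lineno}: end <= start ({start} >= {end})")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in ("+", "-", "."):
        raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
    return GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, in file order.

    Track/comment lines are skipped; malformed or degenerate (end <= start)
    lines raise :class:`FormatError` naming the line number.
    """
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
        out.append(_parse_interval_fields(fields, path, lineno))
    return out


def write_bed(path: str, intervals: Sequence[GenomicInterval]) -> None:
    """Write intervals as BED6 (BED3 when no interval carries metadata)."""
    bed6 = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                score = "0" if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(path: str) -> list[GenomicInterval]:
    """Read an ENCODE 10-column narrowPeak file.

    signalValue (column 7) becomes the interval score; the summit offset
    (column 10) is retained when >= 0 and recorded as absent for -1.
    """
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 10:
            raise FormatError(
                f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
            )
        iv = _parse_interval_fields(fields[:6], path, lineno)
        iv.score = float(fields[6])
        summit = int(fields[9])
        iv.summit = summit if summit >= 0 else None
        out.append(iv)
    return out


def write_narrowpeak(path: str, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            summit = -1 if iv.summit is None else iv.summit
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                f"{iv.strand}\t{0.0 if iv.score is None else iv.score:g}\t"
                f"-1\t-1\t{summit}\n"
            )


@dataclass
class AlignmentScan:
    """Fragments passing filters plus bookkeeping tallies.

    ``contig_tallies`` counts every fragment scanned per contig (including
    fragments on excluded contigs, which feed the mitochondrial-read metric
    but are not emitted); ``low_mapq`` / ``improper`` / ``secondary`` count
    fragments or reads dropped by the corresponding filter.
    """

    fragments: list[AlignedFragment] = field(default_factory=list)
    contig_tallies: Counter = field(default_factory=Counter)
    low_mapq: int = 0
    improper: int = 0
    secondary: int = 0
    duplicates_removed: int = 0


def read_alignments(
    path: str,
    min_mapq: int = 0,
    exclude_contigs: frozenset[str] | set[str] = DEFAULT_MITO_NAMES,
    dedup: bool = False,
    keep_secondary: bool = False,
) -> AlignmentScan:
    """Load paired-end fragments from SAM/BAM or the BED6 fragment dialect.

    For SAM/BAM only proper pairs contribute (one fragment per pair, taken
    from read 1); secondary/supplementary alignments are skipped unless
    ``keep_secondary``. Duplicate fragments are kept unless ``dedup``, which
    collapses on (chrom, start, end, strand).
    """
    if path.endswith((".bed", ".bed.gz", ".fragments")):
        scan = _read_fragment_bed(path, min_mapq)
    else:
        scan = _read_sam(path, min_mapq, keep_secondary)
    if exclude_contigs:
        scan.fragments = [
            f for f in scan.fragments if f.chrom not in exclude_contigs
        ]
    if dedup:
        seen: set[tuple] = set()
        kept = []
        for f in scan.fragments:
            key = (f.chrom, f.start, f.end, f.strand)
            if key in seen:
                scan.duplicates_removed += 1
            else:
                seen.add(key)
                kept.append(f)
        scan.fragments = kept
    return scan


def _read_fragment_bed(path: str, min_mapq: int) -> AlignmentScan:
    scan = AlignmentScan()
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
        iv = _parse_interval_fields(fields, path, lineno)
        mapq = int(iv.score) if iv.score is not None else 60
        scan.contig_tallies[iv.chrom] += 1
        if mapq < min_mapq:
            scan.low_mapq += 1
            continue
        scan.fragments.append(
            AlignedFragment(
                iv.chrom, iv.start, iv.end,
                strand=iv.strand if iv.strand != "." else "+",
                mapq=mapq,
            )
        )
    return scan


def _read_sam(path: str, min_mapq: int, keep_secondary: bool) -> AlignmentScan:
    scan = AlignmentScan()
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.mate_is_unmapped:
                continue
            if (read.is_secondary or read.is_supplementary) and not keep_secondary:
                scan.secondary += 1
                continue
            if not read.is_read1:
                continue  # one fragment per pair
            if not read.is_proper_pair:
                scan.improper += 1
                continue
            tlen = read.template_length
            if tlen == 0:
                scan.improper += 1
                continue
            start = min(read.reference_start, read.next_reference_start)
            end = start + abs(tlen)
            scan.contig_tallies[read.reference_name] += 1
            if read.mapping_quality < min_mapq:
                scan.low_mapq += 1
                continue
            scan.fragments.append(
                AlignedFragment(
                    read.reference_name, start, end,
                    strand="-" if read.is_reverse else "+",
                    mapq=read.mapping_quality,
                )
            )
    return scan


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

@dataclass
class PositionFrequencyMatrix:
    """Base counts per motif position, rows ordered A, C, G, T."""

    counts: np.ndarray  # shape (4, W)
    motif_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise FormatError("PFM must have 4 rows (A, C, G, T)")
        if self.width < 4:
            raise FormatError(f"PFM width must be >= 4, got {self.width}")
        if np.any(self.counts < 0):
            raise FormatError("PFM counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise FormatError("every PFM column must have positive total")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))


def read_pfm(path: str) -> PositionFrequencyMatrix:
    """Parse a JASPAR text PFM: '>ID name' header then 4 whitespace rows."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    motif_id, name = "", ""
    if lines and lines[0].startswith(">"):
        parts = lines[0][1:].split(None, 1)
        motif_id = parts[0] if parts else ""
        name = parts[1] if len(parts) > 1 else ""
        lines = lines[1:]
    if len(lines) != 4:
        raise FormatError(f"{path}: expected 4 count rows, got {len(lines)}")
    rows = []
    for ln in lines:
        # tolerate the bracketed JASPAR variant "A [ 1 2 3 ]"
        ln = ln.lstrip("ACGTacgt ").strip("[] ")
        try:
            rows.append([float(x) for x in ln.split()])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric PFM entry in {ln!r}") from exc
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged PFM rows, lengths {sorted(widths)}")
    return PositionFrequencyMatrix(np.array(rows), motif_id=motif_id, name=name)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_model(path: str, dialect: str = "bed12") -> list[GeneModelRecord]:
    """Read gene models from a BED12 or refFlat-style tab file."""
    if dialect not in ("bed12", "refflat"):
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    out = []
    for lineno, fields in _data_lines(path):
        try:
            if dialect == "bed12":
                rec = _parse_bed12(fields)
            else:
                rec = _parse_refflat(fields)
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        out.append(rec)
    return out


def _parse_bed12(f: list[str]) -> GeneModelRecord:
    if len(f) < 12:
        raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
    chrom, start, end = f[0], int(f[1]), int(f[2])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
        raise ValueError("blockCount does not match block lists")
    exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    return GeneModelRecord(chrom, f[5], start, end, exons=exons, name=f[3])


def _parse_refflat(f: list[str]) -> GeneModelRecord:
    # geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    # exonCount, exonStarts, exonEnds
    if len(f) < 11:
        raise ValueError(f"refFlat requires 11 columns, got {len(f)}")
    starts = [int(x) for x in f[9].rstrip(",").split(",")]
    ends = [int(x) for x in f[10].rstrip(",").split(",")]
    return GeneModelRecord(
        f[2], f[3], int(f[4]), int(f[5]),
        exons=list(zip(starts, ends)), name=f[0],
    )


def write_bed12(path: str, genes: Sequence[GeneModelRecord]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or [(g.tx_start, g.tx_end)]
            sizes = ",".join(str(e - s) for s, e in exons)
            offs = ",".join(str(s - g.tx_start) for s, e in exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t0\t{len(exons)}\t{sizes}\t{offs}\n"
            )


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

class Genome:
    """In-memory genome: uppercase sequences plus cached uint8 base codes.

    Codes: A=0 C=1 G=2 T=3, anything else 4. Intended for desk-scale
    genomes (the motif scan, mappability catalog and hexamer model walk the
    whole sequence).
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one sequence")
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self._codes: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        fa = Fasta(path, sequence_always_upper=True, build_index=True)
        genome = cls({name: str(fa[name][:]) for name in fa.keys()})
        fa.close()
        return genome

    def codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._codes:
            seq = self.sequences[chrom].encode("ascii")
            arr = np.frombuffer(seq, dtype=np.uint8)
            codes = np.full(len(arr), 4, dtype=np.uint8)
            for base, code in _BASE_CODE.items():
                codes[arr == ord(base)] = code
            self._codes[chrom] = codes
        return self._codes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_fasta(path: str, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    # drop any stale pyfaidx index so re-reads see the new file
    idx = path + ".fai"
    if os.path.exists(idx):
        os.remove(idx)
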