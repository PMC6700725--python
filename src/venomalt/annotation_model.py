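"""Transcript annotation models: loci, transcripts, exons, junction support.

Coordinates are stored 0-based half-open internally. GTF input (1-based,
inclusive) is converted on read and restored on write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ExonInterval",
    "TranscriptModel",
    "GeneLocus",
    "JunctionSupport",
    "AnnotationError",
    "read_annotation",
    "write_annotation",
    "classify_novel_intergenic",
    "multi_transcript_census",
    "attach_junction_support",
    "read_junction_table",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation records or invalid transcript models."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """A stranded exon, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"empty or inverted exon interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "ExonInterval") -> bool:
        """Positional overlap, strand ignored."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain on a single chromosome and strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[ExonInterval, ...]
    source: str = "reference"

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} mixes chromosomes/strands: "
                f"{sorted(chroms)} {sorted(strands)}"
            )
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons as (start, end), half-open."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def exons_tx_order(self) -> tuple[ExonInterval, ...]:
        """Exons in transcription order (reversed on the minus strand)."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class GeneLocus:
    """All transcripts sharing one gene id."""

    gene_id: str
    transcripts: list[TranscriptModel]
    homology_label: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"locus {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"transcript {t.transcript_id} (gene {t.gene_id}) "
                    f"placed in locus {self.gene_id}"
                )

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    def exons(self) -> list[ExonInterval]:
        return [e for t in self.transcripts for e in t.exons]


@dataclass(frozen=True)
class JunctionSupport:
    """Spliced-read support for one intron."""

    chrom: str
    start: int
    end: int
    strand: str | None
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise AnnotationError("junction read_count must be >= 0")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_annotation(path: str, source: str = "reference") -> list[GeneLocus]:
    """Read a GTF file into a list of :class:`GeneLocus`.

    Only ``exon`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes. 1-based inclusive coordinates are converted
    to 0-based half-open. Loci are returned in order of first appearance.

    Raises
    ------
    AnnotationError
        On a malformed record (named by line number) or a transcript whose
        exons mix chromosomes or strands.
    """
    exons_by_tx: dict[str, list[ExonInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from None
            attr = _parse_attributes(attrs)
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise AnnotationError(
                    f"{path}:{lineno}: exon record lacks gene_id/transcript_id"
                )
            try:
                exon = ExonInterval(chrom, start_i - 1, end_i, strand)
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            tid, gid = attr["transcript_id"], attr["gene_id"]
            prev_gene = tx_gene.setdefault(tid, gid)
            if prev_gene != gid:
                raise AnnotationError(
                    f"{path}:{lineno}: transcript {tid} assigned to genes "
                    f"{prev_gene} and {gid}"
                )
            if gid not in gene_order:
                gene_order.append(gid)
            exons_by_tx.setdefault(tid, []).append(exon)

    by_gene: dict[str, list[TranscriptModel]] = {g: [] for g in gene_order}
    for tid, exons in exons_by_tx.items():
        tx = TranscriptModel(tid, tx_gene[tid], tuple(exons), source=source)
        by_gene[tx.gene_id].append(tx)
    return [GeneLocus(gid, txs) for gid, txs in by_gene.items()]


def write_annotation(loci: Iterable[GeneLocus], path: str, source: str = "venomalt") -> None:
    """Write loci back to GTF, restoring 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for locus in loci:
            for tx in locus.transcripts:
                for e in tx.exons:
                    attrs = f'gene_id "{locus.gene_id}"; transcript_id "{tx.transcript_id}";'
                    fh.write(
                        "\t".join(
                            [e.chrom, source, "exon", str(e.start + 1), str(e.end),
                             ".", e.strand, ".", attrs]
                        )
                        + "\n"
                    )


def classify_novel_intergenic(
    query: list[GeneLocus], reference: list[GeneLocus]
) -> dict[str, str]:
    """Label each query locus ``novel_intergenic`` or ``other``.

    A query locus is novel intergenic iff none of its exons positionally
    overlaps any reference exon on either strand (strand is deliberately
    ignored). An empty reference labels everything novel_intergenic.
    """
    ref_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for locus in reference:
        for e in locus.exons():
            ref_by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
    for chrom in ref_by_chrom:
        ref_by_chrom[chrom].sort()

    import bisect

    def any_overlap(e: ExonInterval) -> bool:
        ivs = ref_by_chrom.get(e.chrom)
        if not ivs:
            return False
        # candidates: intervals with start < e.end; check last few by end
        idx = bisect.bisect_left(ivs, (e.end, -1))
        for s, t in ivs[:idx]:
            if t > e.start:
                return True
        return False

    result: dict[str, str] = {}
    for locus in query:
        hit = any(any_overlap(e) for e in locus.exons())
        result[locus.gene_id] = "other" if hit else "novel_intergenic"
    return result


def multi_transcript_census(loci: Iterable[GeneLocus]) -> tuple[int, int]:
    """Count (single-transcript, multi-transcript) loci."""
    n_single = n_multi = 0
    for locus in loci:
        if locus.n_transcripts >= 2:
            n_multi += 1
        else:
            n_single += 1
    return n_single, n_multi


def read_junction_table(path: str) -> list[JunctionSupport]:
    """Read a tab-separated junction table (chrom, start, end, strand, count).

    A header line is permitted and detected by a non-integer start field. A
    strand field of ``.`` or empty means unknown.
    """
    rows: list[JunctionSupport] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >=5 columns in junction table"
                )
            chrom, start, end, strand, count = fields[:5]
            if lineno == 1 and not start.lstrip("-").isdigit():
                continue  # header
            strand_val = strand if strand in ("+", "-") else None
            rows.append(JunctionSupport(chrom, int(start), int(end), strand_val, int(count)))
    return rows


def attach_junction_support(
    locus: GeneLocus, table: Iterable[JunctionSupport]
) -> dict[tuple[str, int, int, str], int]:
    """Map every intron of every transcript at the locus to its read support.

    Keys are (chrom, start, end, strand) of the intron. Table entries match
    on (chrom, start, end); a table strand, when present, must also match.
    Introns absent from the table map to 0.
    """
    by_coord: dict[tuple[str, int, int], int] = {}
    by_coord_strand: dict[tuple[str, int, int, str], int] = {}
    for row in table:
        if row.strand is None:
            by_coord[(row.chrom, row.start, row.end)] = row.read_count
        else:
            by_coord_strand[(row.chrom, row.start, row.end, row.strand)] = row.read_count

    support: dict[tuple[str, int, int, str], int] = {}
    for tx in locus.transcripts:
        for s, e in tx.introns():
            key = (tx.chrom, s, e, tx.strand)
            if key in by_coord_strand:
                support[key] = by_coord_strand[key]
            else:
                support[key] = by_coord.get((tx.chrom, s, e), 0)
    return support
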