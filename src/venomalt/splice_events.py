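"""Seven-class alternative-transcription event classification.

Events between two transcript models at a locus are labelled with one of
{A5SS, A3SS, EXON_SKIP, MXE, AFE, ALE, INTRON_RETENTION}. Definitions are
strand-aware; "first"/"last" refer to transcription order. Boundary
comparisons are exact (no fuzz window).

Definitions (all coordinates 0-based half-open):

- EXON_SKIP: an internal exon of one transcript lies entirely inside an
  intron of the other whose boundaries match the flanking junctions of the
  skipped exon.
- MXE: two non-overlapping internal exons, one per transcript, enclosed by
  the same pair of shared flanking junction boundaries.
- A5SS: two introns share their acceptor, differ at the donor, and the
  donor-side exons overlap.
- A3SS: two introns share their donor, differ at the acceptor, and the
  acceptor-side exons overlap.
- INTRON_RETENTION: an intron of one transcript is contained in an exon of
  the other and the exon boundaries flanking the intron coincide.
- AFE: non-overlapping first exons, each splicing into a shared downstream
  acceptor.
- ALE: non-overlapping last exons, each spliced from a shared upstream donor.

The donor/acceptor-side exon-overlap requirement on A5SS/A3SS confines those
labels to genuine alternative splice sites of one exon; without it every
skipped exon or alternative terminal exon would also be double-counted as a
splice-site shift at the same junctions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .annotation_model import GeneLocus, TranscriptModel
from .util import percent

__all__ = [
    "EVENT_LABELS",
    "EventRecord",
    "classify_pair",
    "locus_event_summary",
    "event_frequency_table",
]

EVENT_LABELS = (
    "A5SS",
    "A3SS",
    "EXON_SKIP",
    "MXE",
    "AFE",
    "ALE",
    "INTRON_RETENTION",
)

Interval = tuple[int, int]


@dataclass(frozen=True)
class EventRecord:
    """A witnessed event: label plus the defining coordinates.

    ``coords`` holds the witnessing interval(s), sorted, so that records are
    symmetric in the transcript pair and deduplicate across pairs at a locus.
    """

    label: str
    gene_id: str
    coords: tuple[Interval, ...]
    transcripts: tuple[str, str]

    def key(self) -> tuple[str, tuple[Interval, ...]]:
        return (self.label, self.coords)


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _donor_acceptor(intron: Interval, strand: str) -> tuple[int, int]:
    """(donor, acceptor) boundary coordinates of an intron."""
    return (intron[0], intron[1]) if strand == "+" else (intron[1], intron[0])


def classify_pair(a: TranscriptModel, b: TranscriptModel) -> set[EventRecord]:
    """Classify all events witnessed between two transcripts.

    Both transcripts must share chromosome and strand and have different ids.
    Identical exon chains yield the empty set. A pair may witness several
    labels at once.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError(
            f"cannot compare {a.transcript_id} ({a.chrom}{a.strand}) with "
            f"{b.transcript_id} ({b.chrom}{b.strand})"
        )
    if a.transcript_id == b.transcript_id:
        raise ValueError("transcript ids must differ")

    strand = a.strand
    gene = a.gene_id
    pair = tuple(sorted((a.transcript_id, b.transcript_id)))
    records: set[EventRecord] = set()

    ex_a = [(e.start, e.end) for e in a.exons]
    ex_b = [(e.start, e.end) for e in b.exons]
    in_a = list(a.introns())
    in_b = list(b.introns())

    def add(label: str, *coords: Interval) -> None:
        records.add(EventRecord(label, gene, tuple(sorted(coords)), pair))

    # --- A5SS / A3SS over all intron pairs -------------------------------
    for i, ia in enumerate(in_a):
        for j, ib in enumerate(in_b):
            if ia == ib:
                continue
            da, aa = _donor_acceptor(ia, strand)
            db, ab = _donor_acceptor(ib, strand)
            # donor-side exon flanks the intron at its donor boundary
            donor_ex_a = ex_a[i] if strand == "+" else ex_a[i + 1]
            donor_ex_b = ex_b[j] if strand == "+" else ex_b[j + 1]
            acc_ex_a = ex_a[i + 1] if strand == "+" else ex_a[i]
            acc_ex_b = ex_b[j + 1] if strand == "+" else ex_b[j]
            if aa == ab and da != db and _overlap(donor_ex_a, donor_ex_b):
                add("A5SS", ia, ib)
            if da == db and aa != ab and _overlap(acc_ex_a, acc_ex_b):
                add("A3SS", ia, ib)

    # --- EXON_SKIP and INTRON_RETENTION (both directions) ----------------
    for exons, introns_other in (((ex_a, in_a), in_b), ((ex_b, in_b), in_a)):
        (ex, ins), other_introns = exons, introns_other
        other_set = set(other_introns)
        for k in range(1, len(ex) - 1):
            left, right = ins[k - 1], ins[k]
            if (left[0], right[1]) in other_set:
                add("EXON_SKIP", ex[k])

    for ins, ex_other, ex_self in ((in_a, ex_b, ex_a), (in_b, ex_a, ex_b)):
        ex_self_set = set(ex_self)
        for s, e in ins:
            for x1, x2 in ex_other:
                if x1 <= s and e <= x2 and (x1, s) in ex_self_set and (e, x2) in ex_self_set:
                    add("INTRON_RETENTION", (s, e))

    # --- MXE -------------------------------------------------------------
    for i in range(1, len(ex_a) - 1):
        la, ra = in_a[i - 1], in_a[i]
        for j in range(1, len(ex_b) - 1):
            lb, rb = in_b[j - 1], in_b[j]
            if (
                not _overlap(ex_a[i], ex_b[j])
                and la[0] == lb[0]
                and ra[1] == rb[1]
            ):
                add("MXE", ex_a[i], ex_b[j])

    # --- AFE / ALE -------------------------------------------------------
    if len(ex_a) >= 2 and len(ex_b) >= 2:
        tx_a = ex_a if strand == "+" else list(reversed(ex_a))
        tx_b = ex_b if strand == "+" else list(reversed(ex_b))
        ins_tx_a = in_a if strand == "+" else list(reversed(in_a))
        ins_tx_b = in_b if strand == "+" else list(reversed(in_b))

        first_a, first_b = tx_a[0], tx_b[0]
        _, acc_a = _donor_acceptor(ins_tx_a[0], strand)
        _, acc_b = _donor_acceptor(ins_tx_b[0], strand)
        if not _overlap(first_a, first_b) and acc_a == acc_b:
            add("AFE", first_a, first_b)

        last_a, last_b = tx_a[-1], tx_b[-1]
        don_a, _ = _donor_acceptor(ins_tx_a[-1], strand)
        don_b, _ = _donor_acceptor(ins_tx_b[-1], strand)
        if not _overlap(last_a, last_b) and don_a == don_b:
            add("ALE", last_a, last_b)

    return records


def locus_event_summary(locus: GeneLocus) -> list[EventRecord]:
    """Events at a locus, deduplicated by (label, defining coordinates).

    The union over all unordered transcript pairs is taken; a skipped exon
    (say) witnessed by several pairs is counted once. Single-transcript loci
    yield an empty list.
    """
    seen: dict[tuple, EventRecord] = {}
    txs = locus.transcripts
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            for rec in classify_pair(txs[i], txs[j]):
                seen.setdefault(rec.key(), rec)
    return sorted(
        seen.values(), key=lambda r: (r.label, r.coords, r.transcripts)
    )


def event_frequency_table(
    loci: Iterable[GeneLocus],
) -> tuple[dict[str, tuple[int, float]], int]:
    """Per-label (count, percent of total events) plus the total.

    Percents are rounded half-up to one decimal. With zero events every
    percent is reported as 0.0 (flagged by the zero total).
    """
    counts: Counter[str] = Counter()
    for locus in loci:
        if locus.n_transcripts >= 2:
            for rec in locus_event_summary(locus):
                counts[rec.label] += 1
    total = sum(counts.values())
    table = {
        label: (
            counts.get(label, 0),
            percent(counts.get(label, 0), total) if total else 0.0,
        )
        for label in EVENT_LABELS
    }
    return table, total
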