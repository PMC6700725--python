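"""ORF scanning and per-transcript protein prediction.

One protein is predicted per transcript: among all open reading frames
longer than a nucleotide cutoff (default: >90 nt, i.e. >=91), the longest in
the reading frame of the best homology hit is chosen, or the longest overall
when no hit exists. Predictions are then trimmed to the first methionine and
100%-identical proteins collapsed.

An ORF here is a maximal stop-free stretch in one of the three sense-strand
frames, ending at a stop codon or at the transcript end; it is not anchored
at ATG (the Met trimming happens downstream). Codons containing N translate
to X and do not terminate an ORF. Stop codons: TAA, TAG, TGA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "Orf",
    "HomologyHit",
    "PredictedProtein",
    "find_orfs",
    "select_protein",
    "trim_to_met",
    "deduplicate_proteins",
    "best_hits",
    "read_hit_table",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    """A stop-free stretch in one sense frame, transcript coordinates half-open."""

    frame: int
    start: int
    end: int
    aa_sequence: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF length must be a codon multiple")
        if "*" in self.aa_sequence:
            raise ValueError("ORF contains an internal stop")

    @property
    def nt_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomologyHit:
    transcript_id: str
    subject_description: str
    e_value: float
    frame: int

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e-value must be positive")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")


@dataclass(frozen=True)
class PredictedProtein:
    transcript_id: str
    full_sequence: str
    met_trimmed: str | None
    selection_basis: str  # "hit_frame" | "longest_overall"
    frame: int = 0

    @property
    def flagged_no_met(self) -> bool:
        return self.met_trimmed is None


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


def find_orfs(tx_seq: str, min_nt: int = 91) -> list[Orf]:
    """All ORFs of nucleotide length >= ``min_nt`` in the three sense frames.

    The stop codon (when present) is not part of the ORF; stretches running
    off the transcript end (truncated models) are kept. Trailing partial
    codons are ignored.
    """
    seq = tx_seq.upper()
    orfs: list[Orf] = []
    for frame in (0, 1, 2):
        run_start = frame
        aa: list[str] = []
        pos = frame
        while pos + 3 <= len(seq):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if pos - run_start >= min_nt:
                    orfs.append(Orf(frame, run_start, pos, "".join(aa)))
                run_start = pos + 3
                aa = []
            else:
                aa.append(_translate_codon(codon))
            pos += 3
        if pos - run_start >= min_nt:
            orfs.append(Orf(frame, run_start, pos, "".join(aa)))
    orfs.sort(key=lambda o: (o.frame, o.start))
    return orfs


def select_protein(
    orfs: Sequence[Orf],
    transcript_id: str,
    hit: HomologyHit | None = None,
) -> PredictedProtein:
    """Pick the transcript's protein by the hit-frame-first rule.

    With a hit whose frame contains at least one ORF, the longest ORF in
    that frame wins (ties: smallest start). Otherwise the longest ORF over
    all frames wins (ties: smallest frame, then smallest start).
    """
    if not orfs:
        raise ValueError(f"no ORFs passed the length cutoff for {transcript_id}")
    candidates = list(orfs)
    basis = "longest_overall"
    if hit is not None:
        in_frame = [o for o in candidates if o.frame == hit.frame]
        if in_frame:
            candidates = in_frame
            basis = "hit_frame"
    best = min(candidates, key=lambda o: (-o.nt_length, o.frame, o.start))
    return PredictedProtein(
        transcript_id=transcript_id,
        full_sequence=best.aa_sequence,
        met_trimmed=None,
        selection_basis=basis,
        frame=best.frame,
    )


def trim_to_met(p: PredictedProtein) -> PredictedProtein:
    """Trim ``full_sequence`` to the suffix starting at the first methionine.

    Proteins without any M are flagged (``met_trimmed`` stays absent).
    """
    if not p.full_sequence:
        raise ValueError("empty protein sequence")
    idx = p.full_sequence.find("M")
    trimmed = p.full_sequence[idx:] if idx >= 0 else None
    return PredictedProtein(
        p.transcript_id, p.full_sequence, trimmed, p.selection_basis, p.frame
    )


def deduplicate_proteins(
    proteins: Iterable[PredictedProtein],
) -> list[set[str]]:
    """Cluster transcript ids by 100%-identical Met-trimmed proteins.

    Met-less (flagged) proteins form singleton clusters. The number of
    clusters is the number of distinct predicted proteins.
    """
    clusters: dict[str, set[str]] = {}
    singletons: list[set[str]] = []
    for p in proteins:
        if p.met_trimmed is None:
            singletons.append({p.transcript_id})
        else:
            clusters.setdefault(p.met_trimmed, set()).add(p.transcript_id)
    out = [members for _, members in sorted(clusters.items())]
    out.extend(singletons)
    return out


def best_hits(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    """Best (smallest e-value) hit per transcript; ties keep input order."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.transcript_id)
        if cur is None or h.e_value < cur.e_value:
            best[h.transcript_id] = h
    return best


def read_hit_table(path: str) -> list[HomologyHit]:
    """Tab-separated hit table: transcript_id, subject, e_value, frame."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            if lineno == 1 and fields[0] in ("transcript_id", "transcript"):
                continue
            hits.append(
                HomologyHit(fields[0], fields[1], float(fields[2]), int(fields[3]))
            )
    return hits
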