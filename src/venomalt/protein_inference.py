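"""Peptide-parsimony protein inference with min/max enumeration.

From a filtered peptide evidence table the module decides which proteins are
identified, removes proteins lacking independent evidence (peptide set a
strict subset of another protein's), merges proteins with identical peptide
sets into identification groups, and enumerates a conservative minimum (one
protein per identification) and a permissive maximum (every distinct member
sequence) of the venom protein count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PeptideObservation",
    "Identification",
    "VenomInventory",
    "filter_evidence",
    "infer_identifications",
    "enumerate_counts",
    "purge_contaminants",
    "gene_contribution_summary",
    "read_evidence_table",
    "write_evidence_table",
]


@dataclass(frozen=True)
class PeptideObservation:
    peptide_sequence: str
    peptide_probability: float
    matched_protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.peptide_probability <= 1.0:
            raise ValueError("peptide probability must be in [0, 1]")
        if not self.matched_protein_ids:
            raise ValueError("matched protein set must be nonempty")


@dataclass(frozen=True)
class Identification:
    """One identified protein or indistinguishable protein group."""

    member_protein_ids: frozenset[str]
    kind: str  # "unique" | "group_distinct" | "group_identical"
    peptide_set: frozenset[str]
    flags: tuple[str, ...] = ()

    @property
    def n_members(self) -> int:
        return len(self.member_protein_ids)


@dataclass(frozen=True)
class VenomInventory:
    identifications: tuple[Identification, ...]
    min_count: int
    max_count: int
    kind_tally: Mapping[str, int]


def _trim_met(seq: str) -> str:
    idx = seq.find("M")
    return seq[idx:] if idx >= 0 else seq


def filter_evidence(
    observations: Iterable[PeptideObservation],
    protein_probabilities: Mapping[str, float],
    peptide_p_min: float = 0.95,
    protein_p_min: float = 0.99,
    min_peptides: int = 2,
) -> list[PeptideObservation]:
    """Apply the peptide/protein probability and >=2-peptide filters.

    Thresholds are inclusive (a peptide at exactly ``peptide_p_min``
    survives). Proteins failing the protein probability or the distinct
    surviving peptide minimum are dropped from every matched set;
    observations whose matched set empties are discarded.
    """
    surviving = [o for o in observations if o.peptide_probability >= peptide_p_min]

    peptides_per_protein: dict[str, set[str]] = {}
    for obs in surviving:
        for pid in obs.matched_protein_ids:
            peptides_per_protein.setdefault(pid, set()).add(obs.peptide_sequence)

    kept_proteins = {
        pid
        for pid, peps in peptides_per_protein.items()
        if protein_probabilities.get(pid, 0.0) >= protein_p_min
        and len(peps) >= min_peptides
    }

    out: list[PeptideObservation] = []
    for obs in surviving:
        matched = frozenset(obs.matched_protein_ids & kept_proteins)
        if matched:
            out.append(
                PeptideObservation(obs.peptide_sequence, obs.peptide_probability, matched)
            )
    return out


def infer_identifications(
    observations: Iterable[PeptideObservation],
    protein_sequences: Mapping[str, str],
    il_equivalent: bool = False,
) -> list[Identification]:
    """Group proteins by peptide evidence under Occam parsimony.

    Proteins whose peptide set is a strict subset of another surviving
    protein's are removed (no independent evidence). Proteins with identical
    peptide sets merge into one identification; its kind is ``unique`` for a
    single member, ``group_identical`` when all member sequences (after
    first-Met trimming) are equal, else ``group_distinct``. Proteins with
    overlapping but incomparable peptide sets stay separate identifications,
    flagged ``overlapping_evidence``.
    """
    peptide_sets: dict[str, frozenset[str]] = {}
    for obs in observations:
        for pid in obs.matched_protein_ids:
            peptide_sets[pid] = peptide_sets.get(pid, frozenset()) | {obs.peptide_sequence}

    for pid in peptide_sets:
        if pid not in protein_sequences:
            raise KeyError(f"no sequence for matched protein {pid}")

    # subsumption: strict subset of any other protein's set
    pids = sorted(peptide_sets)
    surviving = [
        pid
        for pid in pids
        if not any(
            peptide_sets[pid] < peptide_sets[other]
            for other in pids
            if other != pid
        )
    ]

    by_set: dict[frozenset[str], list[str]] = {}
    for pid in surviving:
        by_set.setdefault(peptide_sets[pid], []).append(pid)

    def norm(seq: str) -> str:
        seq = _trim_met(seq)
        return seq.replace("I", "L") if il_equivalent else seq

    identifications: list[Identification] = []
    for pep_set, members in sorted(by_set.items(), key=lambda kv: sorted(kv[1])):
        seqs = {norm(protein_sequences[m]) for m in members}
        if len(members) == 1:
            kind = "unique"
        elif len(seqs) == 1:
            kind = "group_identical"
        else:
            kind = "group_distinct"
        flags = ()
        if any(
            pep_set & other and pep_set != other
            for other in by_set
            if other is not pep_set
        ):
            flags = ("overlapping_evidence",)
        identifications.append(
            Identification(frozenset(members), kind, pep_set, flags)
        )
    return identifications


def enumerate_counts(
    identifications: Sequence[Identification],
    protein_sequences: Mapping[str, str] | None = None,
) -> VenomInventory:
    """Minimum and maximum distinct-protein counts over the identifications.

    min = one protein per identification; max = sum over identifications of
    the number of distinct member sequences (Met-trimmed; all members counted
    when no sequences are supplied for a group_distinct identification).
    """
    min_count = len(identifications)
    max_count = 0
    tally = {"unique": 0, "group_distinct": 0, "group_identical": 0}
    for ident in identifications:
        tally[ident.kind] += 1
        if ident.kind in ("unique", "group_identical"):
            max_count += 1
        elif protein_sequences is not None:
            max_count += len(
                {_trim_met(protein_sequences[m]) for m in ident.member_protein_ids}
            )
        else:
            max_count += ident.n_members
    return VenomInventory(tuple(identifications), min_count, max_count, tally)


def purge_contaminants(
    identifications: Sequence[Identification],
    contaminant_labels: Sequence[str],
    protein_labels: Mapping[str, str | None],
) -> list[Identification]:
    """Drop identifications whose every member is a contaminant.

    Matching is case-insensitive substring search of each contaminant label
    in the member's homology description. Mixed groups are retained with a
    ``contaminant_member`` flag.
    """
    if not contaminant_labels:
        return list(identifications)
    needles = [c.lower() for c in contaminant_labels]

    def is_contaminant(pid: str) -> bool:
        label = protein_labels.get(pid)
        return label is not None and any(n in label.lower() for n in needles)

    out: list[Identification] = []
    for ident in identifications:
        contaminated = [is_contaminant(m) for m in ident.member_protein_ids]
        if all(contaminated):
            continue
        if any(contaminated):
            ident = Identification(
                ident.member_protein_ids,
                ident.kind,
                ident.peptide_set,
                ident.flags + ("contaminant_member",),
            )
        out.append(ident)
    return out


def gene_contribution_summary(
    transcript_gene: Mapping[str, str],
    protein_transcript: Mapping[str, str],
    protein_sequences: Mapping[str, str],
    identifications: Sequence[Identification],
) -> dict[str, tuple[int, int, int, int]]:
    """Per-gene (n_transcripts, n_distinct_proteins, n_unambiguous, n_possible).

    n_unambiguous counts identifications whose members all map to the gene
    (each such identification guarantees at least one of the gene's proteins
    in venom — the minimum-style count). n_possible counts the gene's
    distinct member sequences over all identifications touching the gene.

    Raises ``KeyError`` naming any protein id without a transcript link.
    """
    for ident in identifications:
        for pid in ident.member_protein_ids:
            if pid not in protein_transcript:
                raise KeyError(f"identified protein {pid} has no transcript link")
            tid = protein_transcript[pid]
            if tid not in transcript_gene:
                raise KeyError(f"transcript {tid} (protein {pid}) has no gene link")

    genes = sorted(set(transcript_gene.values()))
    tx_per_gene: dict[str, set[str]] = {g: set() for g in genes}
    for tid, gid in transcript_gene.items():
        tx_per_gene[gid].add(tid)
    prot_seqs_per_gene: dict[str, set[str]] = {g: set() for g in genes}
    for pid, tid in protein_transcript.items():
        prot_seqs_per_gene[transcript_gene[tid]].add(_trim_met(protein_sequences[pid]))

    out: dict[str, tuple[int, int, int, int]] = {}
    for gene in genes:
        unambiguous = 0
        possible_seqs: set[str] = set()
        for ident in identifications:
            member_genes = {
                transcript_gene[protein_transcript[pid]]
                for pid in ident.member_protein_ids
            }
            if gene not in member_genes:
                continue
            if member_genes == {gene}:
                unambiguous += 1
            possible_seqs.update(
                _trim_met(protein_sequences[pid])
                for pid in ident.member_protein_ids
                if transcript_gene[protein_transcript[pid]] == gene
            )
        out[gene] = (
            len(tx_per_gene[gene]),
            len(prot_seqs_per_gene[gene]),
            unambiguous,
            len(possible_seqs),
        )
    return out


def read_evidence_table(path: str) -> tuple[list[PeptideObservation], dict[str, float]]:
    """Read a tab-separated evidence table.

    Columns: peptide_sequence, peptide_probability, protein_ids
    (semicolon-joined), protein_probability. The protein probability on a row
    applies to every protein listed on it (the maximum across rows wins).
    """
    observations: list[PeptideObservation] = []
    protein_probs: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            if lineno == 1 and fields[0] in ("peptide_sequence", "peptide"):
                continue
            pep, pep_p, pids, prot_p = fields[:4]
            id_set = frozenset(p for p in pids.split(";") if p)
            observations.append(PeptideObservation(pep, float(pep_p), id_set))
            for pid in id_set:
                protein_probs[pid] = max(protein_probs.get(pid, 0.0), float(prot_p))
    return observations, protein_probs


def write_evidence_table(
    observations: Iterable[PeptideObservation],
    protein_probabilities: Mapping[str, float],
    path: str,
) -> None:
    with open(path, "w") as fh:
        fh.write("peptide_sequence\tpeptide_probability\tprotein_ids\tprotein_probability\n")
        for obs in observations:
            pids = sorted(obs.matched_protein_ids)
            prot_p = min(protein_probabilities.get(p, 0.0) for p in pids)
            fh.write(
                f"{obs.peptide_sequence}\t{obs.peptide_probability:g}\t"
                f"{';'.join(pids)}\t{prot_p:g}\n"
            )
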