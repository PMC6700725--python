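"""Seeded synthetic fixtures with known ground truth for every stage.

Fixtures emulate the data shapes of a venom-gland study: multi-transcript
loci carrying chosen splice-event classes, transcript sequences with one
designed ORF each, peptide evidence realizing a planned
unique/grouped/subsumed ambiguity structure, and negative-binomial count
matrices (4 tissues x 2 replicates) with a planted venom-gland-upregulated
transcript set.

Locus geometry. Each locus is laid out in 1 kb blocks on its own
chromosome: an optional alternative-first-exon block, anchor blocks, one
block per planted internal event, a coding block hosting the designed ORF,
and an optional alternative-last-exon block. A backbone transcript takes
variant 1 in every block; each planted event adds one transcript taking
variant 2 in its own block only, so every transcript pair at the locus
witnesses exactly the planted events, once each, after locus-level
deduplication.

Sequence design. Genomic background is tiled with an 11-mer that places a
stop codon in all three phases every <=21 nt, so no background ORF reaches
the >90 nt cutoff even across splice junctions. The coding block carries
ATG + designed codons + TAA, with shifted-frame stop motifs interleaved so
the planted ORF is the only one passing the cutoff, making the predicted,
Met-trimmed protein per transcript exactly the designed one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import (
    ExonInterval,
    GeneLocus,
    TranscriptModel,
    write_annotation,
)
from .expression_analysis import TISSUES, ExpressionMatrix
from .protein_inference import PeptideObservation, write_evidence_table

__all__ = [
    "FixturePlanError",
    "EventPlan",
    "EvidencePlan",
    "CountsPlan",
    "FixtureSpec",
    "AnnotationFixture",
    "EvidenceFixture",
    "CountsFixture",
    "make_annotation_fixture",
    "make_protein_db",
    "make_evidence_fixture",
    "make_counts_fixture",
    "write_fixture_suite",
]


class FixturePlanError(ValueError):
    """A fixture plan that cannot be realized."""


# --------------------------------------------------------------------------
# plans
# --------------------------------------------------------------------------

INTERNAL_EVENTS = ("A5SS", "A3SS", "EXON_SKIP", "MXE", "INTRON_RETENTION")
TERMINAL_EVENTS = ("AFE", "ALE")


@dataclass(frozen=True)
class EventPlan:
    """Events to plant at one locus (a list of event labels)."""

    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in INTERNAL_EVENTS + TERMINAL_EVENTS:
                raise FixturePlanError(f"unknown event label {lab!r}")
        for lab in TERMINAL_EVENTS:
            if self.labels.count(lab) > 1:
                raise FixturePlanError(
                    f"at most one {lab} can be planted per locus "
                    f"(a transcript has a single {'first' if lab == 'AFE' else 'last'} exon)"
                )


@dataclass(frozen=True)
class EvidencePlan:
    n_unique: int = 3
    n_group_distinct: int = 2
    n_group_identical: int = 1
    n_subsumed: int = 1
    group_size: int = 2
    peptide_length: int = 10
    peptides_per_identification: int = 2
    n_low_probability: int = 0  # decoy rows below the peptide threshold

    def __post_init__(self) -> None:
        if min(
            self.n_unique,
            self.n_group_distinct,
            self.n_group_identical,
            self.n_subsumed,
            self.n_low_probability,
        ) < 0:
            raise FixturePlanError("evidence plan counts must be >= 0")
        if self.group_size < 2:
            raise FixturePlanError("groups need >= 2 members")
        if self.peptides_per_identification < 2:
            raise FixturePlanError("identifications need >= 2 peptides")


@dataclass(frozen=True)
class CountsPlan:
    n_transcripts: int = 200
    n_planted: int = 20
    fold_change: float = 8.0
    dispersion: float = 0.1
    n_replicates: int = 2
    base_mean_log_mu: float = 4.0
    base_mean_log_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_transcripts:
            raise FixturePlanError("cannot plant more transcripts than exist")
        if self.fold_change <= 1:
            raise FixturePlanError("planted fold change must exceed 1")
        if self.dispersion < 0:
            raise FixturePlanError("dispersion must be >= 0")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    event_plans: tuple[EventPlan, ...] = (
        EventPlan(("EXON_SKIP",)),
        EventPlan(("A5SS", "A3SS")),
        EventPlan(("MXE", "INTRON_RETENTION")),
        EventPlan(("AFE", "ALE")),
        EventPlan(()),
    )
    evidence: EvidencePlan = EvidencePlan()
    counts: CountsPlan = CountsPlan()
    contaminants: tuple[str, ...] = ("keratin", "trypsin", "hemocyanin")


# --------------------------------------------------------------------------
# annotation + sequence fixture
# --------------------------------------------------------------------------

BLOCK = 1000
# 11-mer with TAA starting at offsets 0, 4 and 8: a stop in every phase.
STOP_TILE = "TAAGTAAGTAA"
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
# codon pairs whose +1/+2 frame readings contain TAA
_SHIFT_STOP_PAIRS = (("ATA", "ATA"), ("AAT", "AAA"))

Interval = tuple[int, int]


def _block_geometry(label: str, o: int) -> tuple[list[Interval], list[Interval], tuple[str, tuple[Interval, ...]]]:
    """(variant1 exons, variant2 exons, (label, witness coords)) for a block."""
    if label == "EXON_SKIP":
        v1 = [(o, o + 100), (o + 400, o + 500), (o + 800, o + 900)]
        v2 = [(o, o + 100), (o + 800, o + 900)]
        witness: tuple[Interval, ...] = ((o + 400, o + 500),)
    elif label == "MXE":
        v1 = [(o, o + 100), (o + 300, o + 400), (o + 800, o + 900)]
        v2 = [(o, o + 100), (o + 500, o + 600), (o + 800, o + 900)]
        witness = ((o + 300, o + 400), (o + 500, o + 600))
    elif label == "A5SS":
        v1 = [(o, o + 200), (o + 600, o + 700)]
        v2 = [(o, o + 300), (o + 600, o + 700)]
        witness = ((o + 200, o + 600), (o + 300, o + 600))
    elif label == "A3SS":
        v1 = [(o, o + 100), (o + 500, o + 700)]
        v2 = [(o, o + 100), (o + 600, o + 700)]
        witness = ((o + 100, o + 500), (o + 100, o + 600))
    elif label == "INTRON_RETENTION":
        v1 = [(o, o + 100), (o + 300, o + 500)]
        v2 = [(o, o + 500)]
        witness = ((o + 100, o + 300),)
    elif label == "AFE":
        v1 = [(o, o + 100), (o + 600, o + 800)]
        v2 = [(o + 300, o + 400), (o + 600, o + 800)]
        witness = ((o, o + 100), (o + 300, o + 400))
    elif label == "ALE":
        v1 = [(o, o + 200), (o + 300, o + 400)]
        v2 = [(o, o + 200), (o + 600, o + 700)]
        witness = ((o + 300, o + 400), (o + 600, o + 700))
    else:
        raise FixturePlanError(f"unknown event label {label!r}")
    return v1, v2, (label, tuple(sorted(witness)))


@dataclass
class GroundTruth:
    """Planted truth for a fixture suite (events, proteins, partitions, DE)."""

    events: dict[str, list[tuple[str, tuple[Interval, ...]]]] = field(default_factory=dict)
    protein_by_transcript: dict[str, str] = field(default_factory=dict)
    transcript_gene: dict[str, str] = field(default_factory=dict)
    identification_partition: list[dict] = field(default_factory=list)
    subsumed_proteins: list[str] = field(default_factory=list)
    min_count: int = 0
    max_count: int = 0
    vgtup: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "events": {
                g: [[lab, [list(c) for c in coords]] for lab, coords in evs]
                for g, evs in self.events.items()
            },
            "protein_by_transcript": self.protein_by_transcript,
            "transcript_gene": self.transcript_gene,
            "identification_partition": self.identification_partition,
            "subsumed_proteins": self.subsumed_proteins,
            "min_count": self.min_count,
            "max_count": self.max_count,
            "vgtup": self.vgtup,
        }


@dataclass
class AnnotationFixture:
    loci: list[GeneLocus]
    transcript_seqs: dict[str, str]
    chrom_seqs: dict[str, str]
    truth: GroundTruth

    def write(self, gtf_path: str | Path, fasta_path: str | Path) -> None:
        write_annotation(self.loci, str(gtf_path))
        with open(fasta_path, "w") as fh:
            for tid in sorted(self.transcript_seqs):
                seq = self.transcript_seqs[tid]
                fh.write(f">{tid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def _background(length: int, rng: np.random.Generator) -> list[str]:
    """Stop-tiled background so every phase hits a stop within <=32 nt."""
    out: list[str] = []
    bases = "ACGT"
    while len(out) < length:
        out.extend(rng.choice(list(bases), size=10))
        out.extend(STOP_TILE)
    return out[:length]


def _designed_cds(n_codons: int, rng: np.random.Generator) -> tuple[str, str]:
    """(nucleotide cassette, encoded protein) with shifted frames suppressed.

    The cassette is pad + ATG + codons + TAA + pad, pads from the stop tile
    (which contains no ATG); every 6 designed codons a motif pair with stops
    in the +1/+2 readings is inserted.
    """
    from Bio.Seq import Seq

    codons: list[str] = ["ATG"]
    i = 0
    while len(codons) - 1 < n_codons:
        if i % 6 == 4:
            pair = _SHIFT_STOP_PAIRS[(i // 6) % 2]
            codons.extend(pair)
            i += 2
        else:
            codons.append(str(rng.choice(_NON_STOP_CODONS)))
            i += 1
    codons = codons[: n_codons + 1]
    nt = "".join(codons)
    protein = str(Seq(nt).translate())
    pad = (STOP_TILE * 3)[:24]
    return pad + nt + "TAA" + pad, protein


def make_annotation_fixture(
    event_plans: Sequence[EventPlan],
    seed: int = 0,
    n_cds_codons: int = 40,
) -> AnnotationFixture:
    """Build loci (one chromosome each, + strand) realizing the event plans.

    Each planted label is witnessed by exactly one transcript pair and the
    locus-level event summary equals the plan. All transcripts of one locus
    share a designed ORF, hence one known protein per locus.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    loci: list[GeneLocus] = []
    tx_seqs: dict[str, str] = {}
    chrom_seqs: dict[str, str] = {}
    seen_proteins: set[str] = set()

    for li, plan in enumerate(event_plans):
        gene = f"G{li + 1:04d}"
        chrom = f"chr{li + 1}"
        labels = list(plan.labels)
        internal = [l for l in labels if l in INTERNAL_EVENTS]
        has_afe = "AFE" in labels
        has_ale = "ALE" in labels

        # block order: [AFE] cap internal... cds cap [ALE]
        block_labels: list[str | None] = []
        if has_afe:
            block_labels.append("AFE")
        else:
            block_labels.append(None)  # leading cap
        block_labels.extend(internal)
        block_labels.append("CDS")
        block_labels.append(None)  # trailing cap
        if has_ale:
            block_labels.append("ALE")

        backbone: list[Interval] = []
        variants: dict[int, tuple[str, list[Interval], tuple]] = {}
        cds_exon: Interval | None = None
        for bi, lab in enumerate(block_labels):
            o = bi * BLOCK
            if lab is None:
                backbone.append((o, o + 200))
            elif lab == "CDS":
                cds_exon = (o, o + 400)
                backbone.append(cds_exon)
            else:
                v1, v2, witness = _block_geometry(lab, o)
                start_idx = len(backbone)
                backbone.extend(v1)
                variants[bi] = (lab, v2, (start_idx, start_idx + len(v1), witness))
        assert cds_exon is not None

        # genome
        glen = len(block_labels) * BLOCK + 200
        seq = _background(glen, rng)
        while True:
            cassette, protein = _designed_cds(n_cds_codons, rng)
            if protein not in seen_proteins:
                seen_proteins.add(protein)
                break
        cs, _ce = cds_exon
        seq[cs + 50 : cs + 50 + len(cassette)] = list(cassette)
        genome = "".join(seq)
        chrom_seqs[chrom] = genome

        def tx(tid: str, exons: list[Interval], source: str) -> TranscriptModel:
            model = TranscriptModel(
                tid,
                gene,
                tuple(ExonInterval(chrom, s, e, "+") for s, e in exons),
                source=source,
            )
            tx_seqs[tid] = "".join(genome[s:e] for s, e in exons)
            truth.protein_by_transcript[tid] = protein
            truth.transcript_gene[tid] = gene
            return model

        transcripts = [tx(f"{gene}.t1", backbone, "reference")]
        events: list[tuple[str, tuple[Interval, ...]]] = []
        for k, bi in enumerate(sorted(variants), start=2):
            lab, v2, (i0, i1, witness) = variants[bi]
            exons = backbone[:i0] + v2 + backbone[i1:]
            transcripts.append(tx(f"{gene}.t{k}", exons, "novel"))
            events.append(witness)
        truth.events[gene] = sorted(events)
        loci.append(GeneLocus(gene, transcripts))

    return AnnotationFixture(loci, tx_seqs, chrom_seqs, truth)


# --------------------------------------------------------------------------
# peptide evidence fixture
# --------------------------------------------------------------------------

_AA = "ACDEFGHIKNPQRSTVWY"  # no M (so Met trimming cannot bite), no L


def _random_protein(rng: np.random.Generator, length: int = 60) -> str:
    return "M" + "".join(rng.choice(list(_AA), size=length - 1))


def make_protein_db(plan: EvidencePlan, rng: np.random.Generator) -> tuple[dict[str, str], dict]:
    """Protein sequences realizing the ambiguity plan.

    Returns (id -> sequence, layout) where layout records which ids play
    which role. Distinct groups share two planted motifs; identical groups
    repeat one sequence under several ids; each subsumed protein contains
    exactly one peptide of a dedicated unique protein.
    """
    k = plan.peptide_length
    proteins: dict[str, str] = {}
    layout = {"unique": [], "group_distinct": [], "group_identical": [], "subsumed": []}

    if plan.n_subsumed > plan.n_unique:
        raise FixturePlanError(
            "each subsumed protein shadows one unique protein; "
            f"need n_unique >= n_subsumed ({plan.n_unique} < {plan.n_subsumed})"
        )

    for i in range(plan.n_unique):
        proteins[f"U{i + 1:03d}"] = _random_protein(rng)
        layout["unique"].append(f"U{i + 1:03d}")

    for g in range(plan.n_group_distinct):
        m1 = "".join(rng.choice(list(_AA), size=k))
        m2 = "".join(rng.choice(list(_AA), size=k))
        members = []
        for j in range(plan.group_size):
            pid = f"D{g + 1:03d}_{j + 1}"
            body = "".join(rng.choice(list(_AA), size=20))
            tail = "".join(rng.choice(list(_AA), size=10))
            proteins[pid] = "M" + body[:10] + m1 + body[10:] + m2 + tail
            members.append(pid)
        layout["group_distinct"].append({"members": members, "motifs": [m1, m2]})

    for g in range(plan.n_group_identical):
        seq = _random_protein(rng)
        members = []
        for j in range(plan.group_size):
            pid = f"I{g + 1:03d}_{j + 1}"
            proteins[pid] = seq
            members.append(pid)
        layout["group_identical"].append({"members": members})

    for s in range(plan.n_subsumed):
        # two shared peptides: the subsumed protein passes the >=2-peptide
        # filter and is then removed by strict-subset subsumption
        host = layout["unique"][s]
        host_seq = proteins[host]
        seg1 = host_seq[5 : 5 + k]
        seg2 = host_seq[5 + k + 3 : 5 + 2 * k + 3]
        pid = f"S{s + 1:03d}"
        proteins[pid] = (
            "M"
            + "".join(rng.choice(list(_AA), size=8))
            + seg1
            + "".join(rng.choice(list(_AA), size=5))
            + seg2
            + "".join(rng.choice(list(_AA), size=8))
        )
        layout["subsumed"].append(
            {"id": pid, "host": host, "shared_peptides": [seg1, seg2]}
        )

    # sanity: motifs and peptides must be unique where the plan requires it
    return proteins, layout


def _unique_peptides(
    seq: str, proteins: Mapping[str, str], owner_ids: set[str], k: int, n: int
) -> list[str]:
    """``n`` k-mers of ``seq`` found only in ``owner_ids`` proteins."""
    found: list[str] = []
    for start in range(1, len(seq) - k):  # skip leading M
        pep = seq[start : start + k]
        owners = {pid for pid, s in proteins.items() if pep in s}
        if owners == owner_ids and pep not in found:
            found.append(pep)
            if len(found) == n:
                return found
    raise FixturePlanError(
        f"could not find {n} peptides unique to {sorted(owner_ids)}"
    )


@dataclass
class EvidenceFixture:
    observations: list[PeptideObservation]
    protein_probabilities: dict[str, float]
    proteins: dict[str, str]
    truth: GroundTruth

    def write(self, evidence_path: str | Path, fasta_path: str | Path) -> None:
        write_evidence_table(
            self.observations, self.protein_probabilities, str(evidence_path)
        )
        with open(fasta_path, "w") as fh:
            for pid in sorted(self.proteins):
                fh.write(f">{pid}\n{self.proteins[pid]}\n")


def make_evidence_fixture(
    plan: EvidencePlan,
    proteins: Mapping[str, str] | None = None,
    seed: int = 0,
) -> EvidenceFixture:
    """Peptide evidence realizing exactly the planned identification partition.

    When ``proteins`` is omitted a database matching the plan is generated.
    Supplying a database that cannot realize the plan (not enough sequences
    with the required sharing structure) raises :class:`FixturePlanError`.
    """
    rng = np.random.default_rng(seed)
    if proteins is None:
        proteins, layout = make_protein_db(plan, rng)
    else:
        proteins = dict(proteins)
        layout = _layout_from_db(plan, proteins)

    k = plan.peptide_length
    npp = plan.peptides_per_identification
    observations: list[PeptideObservation] = []
    truth = GroundTruth()

    def match_set(pep: str) -> frozenset[str]:
        return frozenset(pid for pid, s in proteins.items() if pep in s)

    def add_obs(pep: str, prob: float = 0.99) -> None:
        observations.append(PeptideObservation(pep, prob, match_set(pep)))

    for pid in layout["unique"]:
        shadowed = next(
            (s for s in layout["subsumed"] if s["host"] == pid), None
        )
        if shadowed:
            pair = frozenset({pid, shadowed["id"]})
            for pep in shadowed["shared_peptides"]:
                if match_set(pep) != pair:
                    raise FixturePlanError(
                        "subsumed shared peptide is not private to the pair"
                    )
                add_obs(pep)
            peps = _unique_peptides(proteins[pid], proteins, {pid}, k, max(1, npp - 2))
        else:
            peps = _unique_peptides(proteins[pid], proteins, {pid}, k, npp)
        for pep in peps:
            add_obs(pep)
        truth.identification_partition.append(
            {"kind": "unique", "members": [pid]}
        )

    for group in layout["group_distinct"]:
        members = set(group["members"])
        for pep in group["motifs"][:npp]:
            if match_set(pep) != frozenset(members):
                raise FixturePlanError("group motif is not private to the group")
            add_obs(pep)
        truth.identification_partition.append(
            {"kind": "group_distinct", "members": sorted(members)}
        )

    for group in layout["group_identical"]:
        members = set(group["members"])
        peps = _unique_peptides(
            proteins[group["members"][0]], proteins, members, k, npp
        )
        for pep in peps:
            add_obs(pep)
        truth.identification_partition.append(
            {"kind": "group_identical", "members": sorted(members)}
        )

    truth.subsumed_proteins = [s["id"] for s in layout["subsumed"]]

    for _ in range(plan.n_low_probability):
        pid = str(rng.choice(sorted(proteins)))
        seq = proteins[pid]
        start = int(rng.integers(1, len(seq) - k))
        add_obs(seq[start : start + k], prob=0.5)

    truth.min_count = len(truth.identification_partition)
    truth.max_count = sum(
        len({proteins[m] for m in ident["members"]})
        for ident in truth.identification_partition
    )
    protein_probabilities = {pid: 0.999 for pid in proteins}
    return EvidenceFixture(observations, protein_probabilities, proteins, truth)


def _layout_from_db(plan: EvidencePlan, proteins: Mapping[str, str]) -> dict:
    """Recover a plan layout from a caller-supplied database, or fail."""
    by_seq: dict[str, list[str]] = {}
    for pid, seq in sorted(proteins.items()):
        by_seq.setdefault(seq, []).append(pid)
    dup_groups = [ids for ids in by_seq.values() if len(ids) >= plan.group_size]
    singles = [ids[0] for ids in by_seq.values() if len(ids) == 1]
    if len(dup_groups) < plan.n_group_identical:
        raise FixturePlanError(
            "database lacks enough identical-sequence sets for the plan"
        )
    if plan.n_group_distinct > 0:
        raise FixturePlanError(
            "distinct groups need planted shared motifs; omit `proteins` to "
            "generate a compatible database"
        )
    needed = plan.n_unique + plan.n_subsumed
    if len(singles) < needed:
        raise FixturePlanError("database has too few distinct sequences for the plan")
    layout = {
        "unique": singles[: plan.n_unique],
        "group_distinct": [],
        "group_identical": [
            {"members": dup_groups[i][: plan.group_size]}
            for i in range(plan.n_group_identical)
        ],
        "subsumed": [],
    }
    if plan.n_subsumed:
        raise FixturePlanError(
            "subsumed proteins need planted shared peptides; omit `proteins`"
        )
    return layout


# --------------------------------------------------------------------------
# count matrix fixture
# --------------------------------------------------------------------------


@dataclass
class CountsFixture:
    matrix: ExpressionMatrix
    truth: GroundTruth

    def write(
        self,
        counts_path: str | Path,
        lengths_path: str | Path,
        tissues_path: str | Path,
    ) -> None:
        self.matrix.counts.to_csv(counts_path, sep="\t", index_label="transcript_id")
        self.matrix.lengths.rename("length").to_csv(
            lengths_path, sep="\t", index_label="transcript_id"
        )
        with open(tissues_path, "w") as fh:
            fh.write("library_id\ttissue\n")
            for lib in self.matrix.counts.columns:
                fh.write(f"{lib}\t{self.matrix.tissue_of[lib]}\n")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def make_counts_fixture(
    plan: CountsPlan,
    seed: int = 0,
    transcript_ids: Sequence[str] | None = None,
) -> CountsFixture:
    """NB count matrix over 4 tissues with planted venom-gland upregulation.

    Planted transcripts have mean ``fold_change`` times higher in venom gland
    than in each other tissue; variance follows mu + alpha*mu^2.
    """
    rng = np.random.default_rng(seed)
    n = plan.n_transcripts
    if transcript_ids is None:
        transcript_ids = [f"T{i + 1:05d}" for i in range(n)]
    elif len(transcript_ids) != n:
        raise FixturePlanError("transcript_ids length must match n_transcripts")

    base = np.exp(
        rng.normal(plan.base_mean_log_mu, plan.base_mean_log_sigma, size=n)
    )
    planted_idx = rng.choice(n, size=plan.n_planted, replace=False)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted_idx] = True

    libs: list[str] = []
    tissue_of: dict[str, str] = {}
    cols: dict[str, np.ndarray] = {}
    for tissue in TISSUES:
        mean = base.copy()
        if tissue == "venom_gland":
            mean = np.where(planted_mask, base * plan.fold_change, base)
        for r in range(plan.n_replicates):
            lib = f"{tissue}_{r + 1}"
            libs.append(lib)
            tissue_of[lib] = tissue
            cols[lib] = _nb_draw(rng, mean, plan.dispersion)

    counts = pd.DataFrame(cols, index=pd.Index(transcript_ids, name="transcript_id"))
    lengths = pd.Series(
        rng.integers(500, 3000, size=n), index=counts.index, name="length"
    )
    matrix = ExpressionMatrix(counts, lengths, tissue_of)
    truth = GroundTruth()
    truth.vgtup = sorted(np.asarray(transcript_ids)[planted_mask])
    return CountsFixture(matrix, truth)


# --------------------------------------------------------------------------
# whole-suite writer (CLI `simulate`)
# --------------------------------------------------------------------------


def write_fixture_suite(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    """Write every fixture file plus a merged ground-truth JSON; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ann = make_annotation_fixture(spec.event_plans, seed=spec.seed)
    ev = make_evidence_fixture(spec.evidence, seed=spec.seed + 1)
    cnt = make_counts_fixture(spec.counts, seed=spec.seed + 2)

    paths = {
        "gtf": str(out / "annotation.gtf"),
        "transcripts_fasta": str(out / "transcripts.fa"),
        "evidence": str(out / "evidence.tsv"),
        "proteins_fasta": str(out / "proteins.fa"),
        "counts": str(out / "counts.tsv"),
        "lengths": str(out / "lengths.tsv"),
        "tissues": str(out / "tissues.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    ann.write(paths["gtf"], paths["transcripts_fasta"])
    ev.write(paths["evidence"], paths["proteins_fasta"])
    cnt.write(paths["counts"], paths["lengths"], paths["tissues"])

    merged = ann.truth.to_json()
    ev_json = ev.truth.to_json()
    cnt_json = cnt.truth.to_json()
    merged["identification_partition"] = ev_json["identification_partition"]
    merged["subsumed_proteins"] = ev_json["subsumed_proteins"]
    merged["min_count"] = ev_json["min_count"]
    merged["max_count"] = ev_json["max_count"]
    merged["vgtup"] = cnt_json["vgtup"]
    with open(paths["ground_truth"], "w") as fh:
        json.dump(merged, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
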