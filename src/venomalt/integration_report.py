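"""Headline tables and in-report statistics joining all pipeline layers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .protein_inference import Identification
from .util import percent

__all__ = [
    "PROTEIN_CATEGORIES",
    "DEFAULT_KEYWORD_RULES",
    "categorize",
    "two_proportion_chisq",
    "build_table1",
    "report_percent",
]

PROTEIN_CATEGORIES = (
    "Latrotoxin",
    "Latrodectin",
    "CRISP",
    "ICK",
    "Protease",
    "OtherEnzyme",
    "LRR",
    "Uncharacterized",
    "NovelFamily",
    "NoHit",
)

# Ordered first-match-wins keyword rules mapping homology descriptions to
# categories. Free-text labels make any such table heuristic; it is a
# user-editable default, not a fixed vocabulary.
DEFAULT_KEYWORD_RULES: tuple[tuple[str, str], ...] = (
    ("latrotoxin", "Latrotoxin"),
    ("latrodectin", "Latrodectin"),
    ("alpha-latrocrustotoxin", "Latrotoxin"),
    ("cysteine-rich secretory", "CRISP"),
    ("crisp", "CRISP"),
    ("cystine knot", "ICK"),
    ("ick", "ICK"),
    ("metalloproteinase", "Protease"),
    ("metalloprotease", "Protease"),
    ("protease", "Protease"),
    ("proteinase", "Protease"),
    ("peptidase", "Protease"),
    ("chitinase", "OtherEnzyme"),
    ("hyaluronidase", "OtherEnzyme"),
    ("phospholipase", "OtherEnzyme"),
    ("esterase", "OtherEnzyme"),
    ("enzyme", "OtherEnzyme"),
    ("-ase", "OtherEnzyme"),
    ("leucine-rich repeat", "LRR"),
    ("lrr", "LRR"),
    ("novel family", "NovelFamily"),
    ("uncharacterized", "Uncharacterized"),
    ("hypothetical", "Uncharacterized"),
)


def categorize(
    homology_label: str | None,
    keyword_rules: Sequence[tuple[str, str]] = DEFAULT_KEYWORD_RULES,
) -> str:
    """Assign a protein category from a free-text homology description.

    First matching rule wins (case-insensitive substring). An absent label is
    NoHit; a label matching no rule is Uncharacterized.
    """
    if homology_label is None:
        return "NoHit"
    label = homology_label.lower()
    for needle, category in keyword_rules:
        if needle.lower() in label:
            return category
    return "Uncharacterized"


def two_proportion_chisq(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, int, float]:
    """Pooled two-proportion chi-square without continuity correction.

    With pooled p = (k1+k2)/(n1+n2), the statistic is
    (k1/n1 - k2/n2)^2 / (p*(1-p)*(1/n1 + 1/n2)), referred to chi-square with
    1 df. A degenerate pooled proportion (0 or 1) gives statistic 0.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1, 1.0
    diff = k1 / n1 - k2 / n2
    statistic = diff * diff / (pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), 1, p_value


def report_percent(k: int, n: int) -> float:
    """100*k/n rounded half-up to one decimal (printed-table convention)."""
    if n == 0:
        raise ValueError("percentage undefined for n == 0")
    return percent(k, n)


def build_table1(
    identifications: Sequence[Identification],
    vgtup: set[str],
    protein_category: Mapping[str, str],
    protein_transcript: Mapping[str, str],
    protein_sequences: Mapping[str, str] | None = None,
) -> dict[str, dict[str, int]]:
    """Per-category venom-inventory rows.

    Columns: ``min_in_venom`` (one per identification, attributed to the
    category of its first member by sorted id — members of one group share a
    category in practice), ``max_in_venom`` (distinct member sequences, all
    members when sequences are not given), ``n_vgtup`` (distinct
    venom-gland-upregulated transcripts among members of the category), and
    ``n_both`` (VGTup transcripts within the maximum-estimate member set, as
    the caption convention dictates).
    """

    def seq_count(ident: Identification) -> int:
        if ident.kind in ("unique", "group_identical"):
            return 1
        if protein_sequences is None:
            return ident.n_members
        trimmed = set()
        for pid in ident.member_protein_ids:
            s = protein_sequences[pid]
            i = s.find("M")
            trimmed.add(s[i:] if i >= 0 else s)
        return len(trimmed)

    rows = {
        c: {"min_in_venom": 0, "max_in_venom": 0, "n_vgtup": 0, "n_both": 0}
        for c in PROTEIN_CATEGORIES
    }
    vgtup_tx_per_cat: dict[str, set[str]] = {c: set() for c in PROTEIN_CATEGORIES}
    both_tx_per_cat: dict[str, set[str]] = {c: set() for c in PROTEIN_CATEGORIES}

    for ident in identifications:
        members = sorted(ident.member_protein_ids)
        for pid in members:
            if pid not in protein_category:
                raise KeyError(f"no category for protein {pid}")
            if pid not in protein_transcript:
                raise KeyError(f"no transcript link for protein {pid}")
        category = protein_category[members[0]]
        rows[category]["min_in_venom"] += 1
        rows[category]["max_in_venom"] += seq_count(ident)
        for pid in members:
            tid = protein_transcript[pid]
            if tid in vgtup:
                both_tx_per_cat[protein_category[pid]].add(tid)

    for pid, category in protein_category.items():
        tid = protein_transcript.get(pid)
        if tid is not None and tid in vgtup:
            vgtup_tx_per_cat[category].add(tid)

    for c in PROTEIN_CATEGORIES:
        rows[c]["n_vgtup"] = len(vgtup_tx_per_cat[c])
        rows[c]["n_both"] = len(both_tx_per_cat[c])
    return rows
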