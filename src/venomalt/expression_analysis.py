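"""Expression analysis: TPM, venom-gland upregulation calls, pattern classes.

The differential-expression engine is a deliberately simple two-condition
negative-binomial exact test (median-of-ratios library-size normalization,
method-of-moments common dispersion, conditional test on per-group sums)
with Benjamini–Hochberg FDR control. It is NOT numerically equivalent to the
empirical-Bayes engine used in the original study; the surrounding logic —
the +5 pseudocount, the three pairwise venom-gland comparisons at 5% FDR,
and the intersection defining the upregulated set — is implemented exactly.
The engine is pluggable: any callable with the same signature as
:func:`nb_exact_test` may be passed to :func:`pairwise_upregulated`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TISSUES",
    "ExpressionMatrix",
    "UpregulationCall",
    "add_pseudocount",
    "compute_tpm",
    "size_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "pairwise_upregulated",
    "vgtup_set",
    "call_upregulation",
    "expression_rank_flags",
    "pattern_classify",
]

TISSUES = ("venom_gland", "silk_gland", "ovary", "cephalothorax")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Transcripts x libraries count matrix with lengths and tissue labels."""

    counts: pd.DataFrame  # rows: transcript ids, columns: library ids
    lengths: pd.Series  # effective length in nt per transcript
    tissue_of: Mapping[str, str]  # library id -> tissue

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.tissue_of)
        if missing:
            raise ValueError(f"libraries without a tissue label: {sorted(missing)}")
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths must share the transcript index")

    def libraries(self, tissue: str) -> list[str]:
        return [lib for lib in self.counts.columns if self.tissue_of[lib] == tissue]


@dataclass(frozen=True)
class UpregulationCall:
    transcript_id: str
    per_comparison: tuple[bool, bool, bool]

    @property
    def in_vgtup(self) -> bool:
        return all(self.per_comparison)


def add_pseudocount(m: ExpressionMatrix, c: int = 5) -> ExpressionMatrix:
    """Add ``c`` to every count cell (underflow guard); lengths untouched."""
    if c < 0:
        raise ValueError("pseudocount must be >= 0")
    return replace(m, counts=m.counts + c)


def compute_tpm(m: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6/library."""
    if (m.lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rates = m.counts.div(m.lengths, axis=0)
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero total rate in libraries {bad}")
    return rates.div(totals, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors over rows positive everywhere."""
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no transcript has positive counts in all libraries")
    log_ratios = log_counts.loc[usable].sub(log_geo[usable], axis=0)
    return np.exp(log_ratios.median(axis=0))


def estimate_common_dispersion(norm_counts: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion (variance = mu + alpha*mu^2).

    Per transcript, within-group mean/variance give alpha estimates that are
    pooled by the median across transcripts; clipped below at 1e-8.
    """
    alphas = []
    for idx in groups:
        sub = norm_counts[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / np.square(mu)
        alphas.append(a)
    stacked = np.nanmean(np.column_stack(alphas), axis=1)
    stacked = stacked[np.isfinite(stacked)]
    if stacked.size == 0:
        return 1e-8
    return float(max(np.median(stacked), 1e-8))


def _nb_logpmf(x: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    size = 1.0 / alpha
    p = size / (size + mean)
    return stats.nbinom.logpmf(x, size, p)


def nb_exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, alpha: float
) -> float:
    """Two-sided exact NB test on group sums, conditional on the total.

    Sums of ``n`` iid NB(mu, alpha) variables are NB(n*mu, alpha/n); under
    the null of equal per-library means the conditional probability of the
    observed split of the total is compared against all possible splits
    (edgeR's classic exact-test construction).
    """
    na, nb = len(counts_a), len(counts_b)
    sa = int(round(counts_a.sum()))
    sb = int(round(counts_b.sum()))
    total = sa + sb
    if total == 0:
        return 1.0
    mu0 = total / (na + nb)
    xs = np.arange(total + 1)
    log_pa = _nb_logpmf(xs, na * mu0, alpha / na)
    log_pb = _nb_logpmf(xs[::-1], nb * mu0, alpha / nb)
    joint = log_pa + log_pb
    joint -= joint.max()
    probs = np.exp(joint)
    probs /= probs.sum()
    p_obs = probs[sa]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def pairwise_upregulated(
    m: ExpressionMatrix,
    tissue_b: str,
    tissue_a: str = "venom_gland",
    fdr: float = 0.05,
    engine: Callable[[np.ndarray, np.ndarray, float], float] = nb_exact_test,
    pseudocount: int = 5,
) -> set[str]:
    """Transcripts significantly higher in ``tissue_a`` than ``tissue_b``.

    Counts are pseudocounted, normalized by median-of-ratios size factors,
    tested per transcript with ``engine``, and controlled by
    Benjamini–Hochberg at ``fdr``; the returned set further requires a higher
    normalized mean in ``tissue_a``.
    """
    libs_a = m.libraries(tissue_a)
    libs_b = m.libraries(tissue_b)
    if len(libs_a) < 2 or len(libs_b) < 2:
        raise ValueError(
            f"need >=2 replicate libraries per tissue ({tissue_a}: {len(libs_a)}, "
            f"{tissue_b}: {len(libs_b)})"
        )
    sub = add_pseudocount(m, pseudocount).counts[libs_a + libs_b]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    arr = norm.to_numpy(dtype=float)
    ia = np.arange(len(libs_a))
    ib = np.arange(len(libs_a), len(libs_a) + len(libs_b))
    alpha = estimate_common_dispersion(arr, [ia, ib])

    pvals = np.array([engine(row[ia], row[ib], alpha) for row in arr])
    reject = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    higher = arr[:, ia].mean(axis=1) > arr[:, ib].mean(axis=1)
    ids = norm.index.to_numpy()
    return set(ids[reject & higher])


def vgtup_set(comparison_sets: Sequence[set[str]]) -> set[str]:
    """Intersection of the three pairwise upregulated sets."""
    if len(comparison_sets) != 3:
        raise ValueError("exactly three comparison sets are required")
    a, b, c = comparison_sets
    return a & b & c


def call_upregulation(
    m: ExpressionMatrix,
    fdr: float = 0.05,
    engine: Callable[[np.ndarray, np.ndarray, float], float] = nb_exact_test,
    pseudocount: int = 5,
) -> tuple[list[UpregulationCall], set[str]]:
    """Full three-comparison venom-gland upregulation calling."""
    others = [t for t in TISSUES if t != "venom_gland"]
    sets = [
        pairwise_upregulated(m, t, fdr=fdr, engine=engine, pseudocount=pseudocount)
        for t in others
    ]
    final = vgtup_set(sets)
    calls = [
        UpregulationCall(tid, tuple(tid in s for s in sets))
        for tid in m.counts.index
    ]
    return calls, final


def expression_rank_flags(
    tpm: pd.DataFrame,
    tissue_of: Mapping[str, str],
    tissue: str = "venom_gland",
) -> pd.DataFrame:
    """Percentile and top-1%/top-5% flags of mean TPM in one tissue.

    Ranks are over all transcripts; ties share the better (lower) rank. The
    top-q cutoff admits the best ``max(1, floor(q*n))`` ranks.
    """
    libs = [lib for lib in tpm.columns if tissue_of[lib] == tissue]
    if not libs:
        raise ValueError(f"no libraries for tissue {tissue}")
    mean_tpm = tpm[libs].mean(axis=1)
    rank = mean_tpm.rank(method="min", ascending=False)
    n = len(mean_tpm)
    top1_k = max(1, int(np.floor(0.01 * n)))
    top5_k = max(1, int(np.floor(0.05 * n)))
    return pd.DataFrame(
        {
            "mean_tpm": mean_tpm,
            "rank": rank.astype(int),
            "percentile": rank / n * 100.0,
            "top1": rank <= top1_k,
            "top5": rank <= top5_k,
        }
    )


PATTERN_LABELS = (
    "zero_in_vg",
    "highest_avg_in_vg",
    "higher_elsewhere",
    "broad_expression",
    "order_of_magnitude_elsewhere",
)


def pattern_classify(
    tissue_means: Mapping[str, float], vg_tissue: str = "venom_gland"
) -> set[str]:
    """Expression-pattern labels from per-tissue mean TPM of one transcript."""
    vg = tissue_means[vg_tissue]
    others = {t: v for t, v in tissue_means.items() if t != vg_tissue}
    labels: set[str] = set()
    if vg == 0:
        labels.add("zero_in_vg")
    if all(vg > v for v in others.values()):
        labels.add("highest_avg_in_vg")
    if any(v > vg for v in others.values()):
        labels.add("higher_elsewhere")
    if all(v > 5 for v in tissue_means.values()):
        labels.add("broad_expression")
    if vg == 0:
        if any(v > 0 for v in others.values()):
            labels.add("order_of_magnitude_elsewhere")
    elif any(v >= 10 * vg for v in others.values()):
        labels.add("order_of_magnitude_elsewhere")
    return labels


def tissue_mean_tpm(tpm: pd.DataFrame, tissue_of: Mapping[str, str]) -> pd.DataFrame:
    """Per-tissue mean TPM matrix (transcripts x tissues)."""
    tissues = sorted(set(tissue_of.values()))
    return pd.DataFrame(
        {
            t: tpm[[lib for lib in tpm.columns if tissue_of[lib] == t]].mean(axis=1)
            for t in tissues
        }
    )
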