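"""Per-sample clonotype diversity statistics and tissue-group comparisons.

Diversity is summarized as clonotype richness, Shannon entropy over
clonotype relative abundances, and top-k clonality (the summed abundance
of the k most frequent clonotypes). Group comparisons support paired
t-tests, Kruskal-Wallis omnibus with pairwise follow-ups, and Wilcoxon
tests, with Bonferroni adjustment across the pairwise family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .repertoire_io import KeyScheme, RepertoireSample

FREQ_TOL = 1e-9


class InsufficientDataError(ValueError):
    """A paired comparison has no complete pairs."""


def shannon_entropy(frequencies: Sequence[float], base: float | None = None) -> float:
    """Shannon entropy H = -sum p*log(p), 0*log(0) := 0.

    Natural log by default; pass ``base=2`` for bits. Frequencies must be
    non-negative and sum to 1 within 1e-9.
    """
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any():
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > FREQ_TOL:
        raise ValueError(f"frequencies sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def top_k_abundance(
    sample: RepertoireSample,
    k: int = 100,
    scheme: KeyScheme | str = KeyScheme.aa,
) -> float:
    """Summed relative abundance of the k most-abundant clonotypes.

    Ties at the cut are broken by lexicographic key order so the result
    is deterministic. Returns 1.0 whenever richness <= k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    freqs = sample.key_frequencies(scheme)
    ordered = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    return float(sum(f for _, f in ordered[:k]))


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    level: str
    n_clonotypes: int
    entropy: float
    top_k_abundance: float
    k: int


def sample_diversity(
    sample: RepertoireSample,
    scheme: KeyScheme | str = KeyScheme.aa,
    k: int = 100,
    base: float | None = None,
) -> DiversityResult:
    freqs = sample.key_frequencies(scheme)
    return DiversityResult(
        sample_id=sample.sample_id,
        level=KeyScheme(scheme).value,
        n_clonotypes=len(freqs),
        entropy=shannon_entropy(freqs.to_numpy(), base=base),
        top_k_abundance=top_k_abundance(sample, k=k, scheme=scheme),
        k=k,
    )


def entropy_clonality_correlation(
    results: Sequence[DiversityResult],
) -> tuple[float, float]:
    """Pearson r between entropy and top-k abundance, with t-test p-value."""
    if len(results) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    x = np.array([r.entropy for r in results])
    y = np.array([r.top_k_abundance for r in results])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni adjustment: multiply by the family size, cap at 1."""
    return min(1.0, p * n_comparisons)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    n: int
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparisonReport:
    test: str
    paired: bool
    omnibus_p: float | None
    comparisons: tuple[PairwiseComparison, ...]


def compare_groups(
    groups: Mapping[str, Mapping[str, float]],
    test: str = "paired_t",
    paired: bool = True,
) -> GroupComparisonReport:
    """Compare a per-patient statistic across tissue groups.

    ``groups`` maps group label -> {patient_id: value}. Paired tests use
    only patients present in both groups of each pairwise comparison.
    ``kruskal_wallis`` adds an omnibus p over all groups (restricted to
    patients contributing every group when ``paired``), with pairwise
    Wilcoxon follow-ups; p-values of the pairwise family are Bonferroni
    adjusted.
    """
    if test not in ("paired_t", "kruskal_wallis", "wilcoxon"):
        raise ValueError(f"unknown test: {test!r}")
    labels = list(groups)
    if any(len(groups[g]) == 0 for g in labels):
        raise ValueError("empty group")
    pairs = list(combinations(labels, 2))
    n_comp = len(pairs)

    omnibus_p: float | None = None
    if test == "kruskal_wallis":
        if paired:
            common = set.intersection(*(set(groups[g]) for g in labels))
            if not common:
                raise InsufficientDataError("no patient contributes all groups")
            arrays = [
                [groups[g][pid] for pid in sorted(common)] for g in labels
            ]
        else:
            arrays = [list(groups[g].values()) for g in labels]
        try:
            omnibus_p = float(stats.kruskal(*arrays).pvalue)
        except ValueError:  # all values identical
            omnibus_p = 1.0

    comparisons: list[PairwiseComparison] = []
    for a, b in pairs:
        if paired:
            common = sorted(set(groups[a]) & set(groups[b]))
            if not common:
                raise InsufficientDataError(
                    f"no complete pairs for {a} vs {b}"
                )
            xa = np.array([groups[a][pid] for pid in common])
            xb = np.array([groups[b][pid] for pid in common])
            p = _paired_p(xa, xb, test)
            n = len(common)
        else:
            xa = np.array(list(groups[a].values()))
            xb = np.array(list(groups[b].values()))
            p = _unpaired_p(xa, xb, test)
            n = len(xa) + len(xb)
        comparisons.append(
            PairwiseComparison(a, b, n, p, bonferroni(p, n_comp))
        )
    return GroupComparisonReport(
        test=test, paired=paired, omnibus_p=omnibus_p,
        comparisons=tuple(comparisons),
    )


def _paired_p(xa: np.ndarray, xb: np.ndarray, test: str) -> float:
    if test == "paired_t":
        return float(stats.ttest_rel(xa, xb).pvalue)
    # wilcoxon / kruskal_wallis follow-up: signed-rank on complete pairs
    if np.all(xa == xb):
        return 1.0
    return float(stats.wilcoxon(xa, xb).pvalue)


def _unpaired_p(xa: np.ndarray, xb: np.ndarray, test: str) -> float:
    if test == "paired_t":
        return float(stats.ttest_ind(xa, xb).pvalue)
    if np.all(xa == xa[0]) and np.all(xb == xa[0]):
        return 1.0
    return float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
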