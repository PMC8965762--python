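"""V/J/VJ gene-usage matrices, differential usage tests, dominant-pairing
selection, and PCA on scaled VJ usage.

A usage matrix is samples x features with relative read abundances; the
feature set is always the full gene grid (48 V, 13 J, or 624 VJ), with
unobserved features as explicit zeros, so matrices from different sample
sets are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .diversity import bonferroni
from .repertoire_io import GeneUniverse, RepertoireSample, default_universe

logger = logging.getLogger(__name__)

LEVELS = ("V", "J", "VJ")


def usage_matrix(
    samples: Sequence[RepertoireSample],
    level: str = "VJ",
    universe: GeneUniverse | None = None,
) -> pd.DataFrame:
    """Samples x features relative-abundance matrix at V, J or VJ level.

    Only reads whose genes are in the universe are usable; samples with
    zero usable reads are excluded with a warning. Every row sums to 1.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    universe = universe or default_universe()
    if level == "V":
        columns = list(universe.v_genes)
    elif level == "J":
        columns = list(universe.j_genes)
    else:
        columns = list(universe.vj_pairings)
    v_set, j_set = universe.v_set, universe.j_set

    rows: dict[str, dict[str, float]] = {}
    for s in samples:
        counts: dict[str, float] = {}
        for r in s.records:
            if r.v_gene not in v_set or r.j_gene not in j_set:
                continue
            if level == "V":
                feat = r.v_gene
            elif level == "J":
                feat = r.j_gene
            else:
                feat = f"{r.v_gene}_{r.j_gene}"
            counts[feat] = counts.get(feat, 0) + r.count
        total = sum(counts.values())
        if total == 0:
            logger.warning(
                "sample %s has zero usable reads; excluded from usage matrix",
                s.sample_id,
            )
            continue
        rows[s.sample_id] = {k: v / total for k, v in counts.items()}

    mat = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=columns, fill_value=0.0
    ).fillna(0.0)
    mat.index.name = "sample_id"
    return mat


@dataclass
class FeatureTest:
    feature: str
    omnibus_p: float | None
    pairwise_p: dict[str, float]  # adjusted; keys like "T_vs_N"


def group_usage_test(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    paired_by: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis omnibus plus Bonferroni-adjusted
    pairwise Wilcoxon follow-ups across tissue groups.

    ``groups`` maps sample_id -> group label. When ``paired_by`` maps
    sample_id -> patient_id, the omnibus is restricted to patients
    contributing every group and the follow-ups are paired signed-rank
    tests on complete pairs; otherwise tests are unpaired. Features that
    are constant across all samples get NA p-values.
    """
    sample_ids = [s for s in matrix.index if s in groups]
    # canonical tissue order (T, N, B) when applicable, else alphabetical
    _order = {"T": 0, "N": 1, "B": 2}
    labels = sorted({groups[s] for s in sample_ids},
                    key=lambda g: (_order.get(g, 99), g))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {
        g: [s for s in sample_ids if groups[s] == g] for g in labels
    }
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("each group needs at least 2 samples")
    pairs = list(combinations(labels, 2))
    n_comp = len(pairs)

    if paired_by is not None:
        # patients contributing all groups, for the omnibus
        patients_by_group = {
            g: {paired_by[s]: s for s in by_group[g]} for g in labels
        }
        complete = sorted(
            set.intersection(*(set(patients_by_group[g]) for g in labels))
        )

    out_rows = []
    for feat in matrix.columns:
        col = matrix[feat]
        row: dict = {"feature": feat}
        if col.nunique() <= 1:
            row["kw_p"] = np.nan
            for a, b in pairs:
                row[f"{a}_vs_{b}_p_adj"] = np.nan
            out_rows.append(row)
            continue
        # omnibus
        if paired_by is not None:
            arrays = [
                col.loc[[patients_by_group[g][p] for p in complete]].to_numpy()
                for g in labels
            ]
        else:
            arrays = [col.loc[by_group[g]].to_numpy() for g in labels]
        try:
            row["kw_p"] = float(stats.kruskal(*arrays).pvalue)
        except ValueError:
            row["kw_p"] = 1.0
        # pairwise follow-ups
        for a, b in pairs:
            if paired_by is not None:
                common = sorted(
                    set(patients_by_group[a]) & set(patients_by_group[b])
                )
                xa = col.loc[[patients_by_group[a][p] for p in common]].to_numpy()
                xb = col.loc[[patients_by_group[b][p] for p in common]].to_numpy()
                if len(common) == 0 or np.all(xa == xb):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(xa, xb).pvalue)
            else:
                xa = col.loc[by_group[a]].to_numpy()
                xb = col.loc[by_group[b]].to_numpy()
                if np.all(xa == xa[0]) and np.all(xb == xa[0]):
                    p = 1.0
                else:
                    p = float(
                        stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
                    )
            row[f"{a}_vs_{b}_p_adj"] = bonferroni(p, n_comp)
        out_rows.append(row)
    return pd.DataFrame(out_rows).set_index("feature")


def dominant_vj(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    mean_min: float = 0.01,
    p_max: float = 0.01,
) -> list[str]:
    """VJ pairings with mean abundance strictly > ``mean_min`` across all
    samples AND Kruskal-Wallis p < ``p_max`` across the groups."""
    tests = group_usage_test(matrix, groups, paired_by=None)
    means = matrix.mean(axis=0)
    keep = [
        str(f)
        for f in matrix.columns
        if means[f] > mean_min
        and np.isfinite(tests.loc[f, "kw_p"])
        and tests.loc[f, "kw_p"] < p_max
    ]
    return keep


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x [PC1, PC2]
    explained_variance_ratio: np.ndarray  # all components
    dropped_features: list[str]


def pca_usage(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of the usage matrix after per-feature z-scoring.

    Zero-variance features are dropped with a warning. Component signs
    follow a fixed convention (the largest-magnitude loading of each
    component is positive) so coordinates are reproducible.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    var = matrix.var(axis=0, ddof=0)
    dropped = [str(c) for c in matrix.columns[var == 0]]
    if dropped:
        logger.warning("dropping %d zero-variance features", len(dropped))
    x = matrix.loc[:, var > 0].to_numpy(dtype=float)
    if scale:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    else:
        x = x - x.mean(axis=0)
    pca = PCA(n_components=min(x.shape[0] - 1, x.shape[1]), svd_solver="full")
    scores = pca.fit_transform(x)
    # deterministic sign: largest-magnitude loading positive
    for i in range(pca.components_.shape[0]):
        load = pca.components_[i]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[i] *= -1
            scores[:, i] *= -1
    coords = pd.DataFrame(
        scores[:, :2], index=matrix.index, columns=["PC1", "PC2"]
    )
    return PCAResult(
        coordinates=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_features=dropped,
    )
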