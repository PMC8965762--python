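"""Cross-tissue sharing, clonal-expansion ratios, public clonotypes and
clonotype-clinical association.

Two sharing statistics are always computed together:

* shared **clone** fraction ``f`` — abundance of the shared clonotype set
  in the focal sample (reads of shared clonotypes / total reads);
* shared **clonotype** fraction ``c`` — number of shared clonotypes /
  clonotype richness of the focal sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire_io import KeyScheme, RepertoireSample

logger = logging.getLogger(__name__)


class EmptySampleError(ValueError):
    """Sharing fractions are undefined for a sample without reads."""


class UndefinedExpansionError(ValueError):
    """Expansion ratio undefined: the TNB set has zero abundance in blood."""


class DegenerateTableError(ValueError):
    """A contingency table has an empty margin."""


@dataclass(frozen=True)
class PairwiseShared:
    """Sharing between samples X and Y. ``f_*``: abundance fractions in the
    focal sample; ``c_*``: clonotype-count fractions."""

    f_x: float
    f_y: float
    c_x: float
    c_y: float
    n_shared: int


def pairwise_shared(
    sample_x: RepertoireSample,
    sample_y: RepertoireSample,
    scheme: KeyScheme | str = KeyScheme.v_aa_j,
) -> PairwiseShared:
    if sample_x.total_reads == 0 or sample_y.total_reads == 0:
        raise EmptySampleError("sharing fractions undefined for empty sample")
    fx = sample_x.key_frequencies(scheme)
    fy = sample_y.key_frequencies(scheme)
    shared = fx.index.intersection(fy.index)
    return PairwiseShared(
        f_x=float(fx.loc[shared].sum()),
        f_y=float(fy.loc[shared].sum()),
        c_x=len(shared) / len(fx),
        c_y=len(shared) / len(fy),
        n_shared=len(shared),
    )


@dataclass
class OverlapResult:
    """Per-patient sharing fractions keyed like ``"TN|T"`` or ``"TNB|B"``."""

    patient_id: str
    shared_clone_fraction: dict[str, float]
    shared_clonotype_fraction: dict[str, float]


def patient_overlap(
    samples_by_tissue: Mapping[str, RepertoireSample],
    scheme: KeyScheme | str = KeyScheme.v_aa_j,
    patient_id: str = "",
) -> OverlapResult:
    """All pairwise and (when T, N and B are all present) three-way
    sharing fractions for one patient."""
    f: dict[str, float] = {}
    c: dict[str, float] = {}
    tissues = [t for t in ("T", "N", "B") if t in samples_by_tissue]
    for x, y in combinations(tissues, 2):
        ps = pairwise_shared(samples_by_tissue[x], samples_by_tissue[y], scheme)
        f[f"{x}{y}|{x}"], f[f"{x}{y}|{y}"] = ps.f_x, ps.f_y
        c[f"{x}{y}|{x}"], c[f"{x}{y}|{y}"] = ps.c_x, ps.c_y
    if set("TNB") <= set(tissues):
        three = threeway_shared(
            samples_by_tissue["T"], samples_by_tissue["N"],
            samples_by_tissue["B"], scheme,
        )
        f.update(three.shared_clone_fraction)
        c.update(three.shared_clonotype_fraction)
    return OverlapResult(patient_id, f, c)


def threeway_shared(
    t: RepertoireSample,
    n: RepertoireSample,
    b: RepertoireSample,
    scheme: KeyScheme | str = KeyScheme.v_aa_j,
) -> OverlapResult:
    """Sharing fractions of the T∩N∩B clonotype set in each tissue."""
    freqs = {"T": t.key_frequencies(scheme), "N": n.key_frequencies(scheme),
             "B": b.key_frequencies(scheme)}
    shared = freqs["T"].index.intersection(freqs["N"].index).intersection(
        freqs["B"].index
    )
    f = {f"TNB|{x}": float(freqs[x].loc[shared].sum()) for x in "TNB"}
    c = {f"TNB|{x}": len(shared) / len(freqs[x]) for x in "TNB"}
    return OverlapResult(t.metadata.patient_id, f, c)


@dataclass(frozen=True)
class ExpansionResult:
    """Clonal-expansion degree of the TNB shared set relative to blood."""

    patient_id: str
    e_t: float
    e_n: float


def expansion_degree(overlap: OverlapResult) -> ExpansionResult:
    f = overlap.shared_clone_fraction
    for key in ("TNB|T", "TNB|N", "TNB|B"):
        if key not in f:
            raise UndefinedExpansionError(f"missing three-way fraction {key}")
    if f["TNB|B"] <= 0:
        raise UndefinedExpansionError(
            f"patient {overlap.patient_id}: TNB abundance in blood is zero"
        )
    return ExpansionResult(
        patient_id=overlap.patient_id,
        e_t=f["TNB|T"] / f["TNB|B"],
        e_n=f["TNB|N"] / f["TNB|B"],
    )


def expansion_summary(
    expansions: Sequence[ExpansionResult],
    overlaps: Sequence[OverlapResult] | None = None,
) -> dict:
    """Cohort-level expansion summary.

    Reports both the mean of per-patient ratios and the ratio of cohort
    mean fractions (the two conventions are not equivalent), plus a
    paired Wilcoxon p comparing E_N vs E_T across patients.
    """
    et = np.array([e.e_t for e in expansions])
    en = np.array([e.e_n for e in expansions])
    out: dict = {
        "n_patients": len(expansions),
        "mean_ratio_T": float(et.mean()) if len(et) else None,
        "mean_ratio_N": float(en.mean()) if len(en) else None,
    }
    if overlaps:
        ft = np.array([o.shared_clone_fraction["TNB|T"] for o in overlaps])
        fn = np.array([o.shared_clone_fraction["TNB|N"] for o in overlaps])
        fb = np.array([o.shared_clone_fraction["TNB|B"] for o in overlaps])
        if fb.mean() > 0:
            out["ratio_of_means_T"] = float(ft.mean() / fb.mean())
            out["ratio_of_means_N"] = float(fn.mean() / fb.mean())
    if len(et) >= 2 and not np.all(et == en):
        out["wilcoxon_p_N_vs_T"] = float(stats.wilcoxon(en, et).pvalue)
    return out


@dataclass
class SharingComparison:
    within: list[float]
    between: list[float]
    p_value: float | None


def interpatient_sharing(
    samples: Sequence[RepertoireSample],
    scheme: KeyScheme | str = KeyScheme.v_aa_j,
) -> SharingComparison:
    """Shared-abundance of every unordered sample pair, split into
    within-patient vs between-patient, with an unpaired Wilcoxon p.

    Each pair contributes the mean of its two focal abundance fractions.
    """
    if len({s.metadata.patient_id for s in samples}) < 1:
        raise ValueError("no samples")
    freqs = {s.sample_id: s.key_frequencies(scheme) for s in samples}
    within: list[float] = []
    between: list[float] = []
    for a, b in combinations(samples, 2):
        fa, fb = freqs[a.sample_id], freqs[b.sample_id]
        shared = fa.index.intersection(fb.index)
        val = float((fa.loc[shared].sum() + fb.loc[shared].sum()) / 2)
        if a.metadata.patient_id == b.metadata.patient_id:
            within.append(val)
        else:
            between.append(val)
    p = None
    if within and between:
        p = float(
            stats.mannwhitneyu(within, between, alternative="two-sided").pvalue
        )
    return SharingComparison(within=within, between=between, p_value=p)


@dataclass(frozen=True)
class PublicClonotype:
    key: str
    prevalence: int
    mean_fraction: float


def public_clonotypes(
    samples: Sequence[RepertoireSample],
    min_prevalence: int,
    scheme: KeyScheme | str = KeyScheme.v_aa_j,
) -> list[PublicClonotype]:
    """Clonotypes present in >= ``min_prevalence`` samples, sorted by
    prevalence then mean fraction (mean over all samples, absent = 0)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    freqs = [s.key_frequencies(scheme) for s in samples]
    table = pd.concat(freqs, axis=1).fillna(0.0)
    prevalence = (table > 0).sum(axis=1)
    keep = prevalence[prevalence >= min_prevalence]
    out = [
        PublicClonotype(
            key=str(k),
            prevalence=int(prevalence.loc[k]),
            mean_fraction=float(table.loc[k].mean()),
        )
        for k in keep.index
    ]
    out.sort(key=lambda pc: (-pc.prevalence, -pc.mean_fraction, pc.key))
    return out


def prevalence_band(
    samples: Sequence[RepertoireSample],
    min_frac: float = 0.47,
    max_frac: float = 0.80,
    scheme: KeyScheme | str = KeyScheme.v_aa_j,
) -> list[PublicClonotype]:
    """Clonotypes present in a band of sample prevalence (default
    47%-80%), the candidates tested for clinical association."""
    n = len(samples)
    lo = int(np.ceil(min_frac * n))
    hi = int(np.floor(max_frac * n))
    return [
        pc for pc in public_clonotypes(samples, min_prevalence=lo, scheme=scheme)
        if pc.prevalence <= hi
    ]


def clinical_association(
    presence: Mapping[str, bool],
    covariate: Mapping[str, str],
) -> tuple[float, float]:
    """Chi-square test of independence between clonotype presence and a
    categorical clinical covariate (no continuity correction).

    ``presence`` and ``covariate`` are keyed by patient/sample id; only
    ids present in both are used.
    """
    ids = sorted(set(presence) & set(covariate))
    if not ids:
        raise DegenerateTableError("no overlapping ids")
    df = pd.DataFrame(
        {"present": [bool(presence[i]) for i in ids],
         "covariate": [covariate[i] for i in ids]}
    )
    table = pd.crosstab(df["present"], df["covariate"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError("contingency table has an empty margin")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has an empty margin")
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), float(res.pvalue)
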