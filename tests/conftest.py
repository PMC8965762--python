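"""Shared fixtures: hand-built toy samples and small simulated panels.

Heavy simulated fixtures are session-scoped so the suite pays for them
once.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from repdx.repertoire_io import (
    ClonotypeRecord,
    RepertoireSample,
    SampleMetadata,
)
from repdx.synthetic_data import SimConfig, simulate_cohorts, simulate_patients


def build_sample(
    counts: dict[str, int],
    sample_id: str = "S1",
    patient_id: str = "P1",
    tissue: str = "B",
    cohort: str = "case",
    v_gene: str = "TRBV9",
    j_gene: str = "TRBJ1-1",
) -> RepertoireSample:
    """Sample whose clonotypes are named by their CDR3 aa string."""
    md = SampleMetadata(sample_id=sample_id, patient_id=patient_id,
                        tissue=tissue, cohort=cohort)
    records = [
        ClonotypeRecord(sample_id, v_gene, j_gene, "".join("GCA" for _ in aa),
                        aa, c)
        for aa, c in counts.items()
    ]
    return RepertoireSample(metadata=md, records=records)


@pytest.fixture
def make_sample():
    return build_sample


@pytest.fixture(scope="session")
def tissue_panel():
    """Small T/N/B panel with planted structure (4 patients)."""
    cfg = SimConfig(n_patients=4, clonotypes_per_sample=300,
                    reads_per_sample=10000, seed=7)
    samples, truth = simulate_patients(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def cohort_panel():
    """Small case/control blood panel with 20 planted VJ markers."""
    cfg = SimConfig(n_cohorts=2, n_case=20, n_control=60, n_diff_features=20,
                    effect_size=8.0, reads_per_sample=4000, seed=11)
    samples, truth = simulate_cohorts(cfg)
    return cfg, samples, truth


# ---------------------------------------------------------------- oracles

def exact_signed_rank_p(x, y) -> float:
    """Two-sided paired Wilcoxon p by full sign-flip enumeration (n<=12)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for s, r in zip(signs, ranks) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def exact_rank_sum_p(x, y) -> float:
    """Two-sided unpaired Wilcoxon p by full label-assignment enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array([
        ranks[list(idx)].sum() - n * (n + 1) / 2
        for idx in itertools.combinations(range(n + m), n)
    ])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
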