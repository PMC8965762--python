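"""Synthetic multi-tissue repertoires and two-cohort blood panels with
recorded ground truth.

Two generators are provided:

* :func:`simulate_patients` — per-patient tumor (T), adjacent non-tumor
  (N) and blood (B) repertoires. Blood clone sizes follow a shallow
  power law (high entropy); T and N are built from overlapping clonotype
  subsets with a designated expanded subset whose weight is boosted in
  both tissues (more strongly in N), and a configurable fraction of
  tissue clonotypes is drawn from the blood set. A handful of public
  clonotypes is injected into every blood sample.

* :func:`simulate_cohorts` — case/control blood panels whose per-sample
  VJ-pairing usage is Dirichlet-distributed around a cohort base; the
  case base differs from the control base on a planted set of pairings
  by a configurable fold change.

All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning, so runs are bit-reproducible and
per-patient streams are independent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .repertoire_io import (
    ClonotypeRecord,
    GeneUniverse,
    RepertoireSample,
    SampleMetadata,
    default_universe,
    write_airr,
    write_metadata,
)

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT_ALPHABET = np.array(list("ACGT"))

#: fraction of a tissue sample designated as the expanded clone subset
EXPANDED_FRACTION = 0.1


class SimConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass
class SimConfig:
    n_patients: int = 10
    tissues: tuple[str, ...] = ("T", "N", "B")
    clonotypes_per_sample: int = 400
    reads_per_sample: int = 20000
    clone_size_exponent: float = 0.6
    expansion_factor: float = 20.0
    frac_shared_TN: float = 0.5
    frac_shared_blood: float = 0.3
    n_public: int = 3
    public_freq: float = 0.005
    n_cohorts: int = 1
    n_case: int = 43
    n_control: int = 439
    n_diff_features: int = 20
    effect_size: float = 8.0
    dirichlet_concentration: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0 or self.clonotypes_per_sample < 1:
            raise SimConfigError("counts must be positive")
        if self.reads_per_sample < 1:
            raise SimConfigError("reads_per_sample must be >= 1")
        for name in ("frac_shared_TN", "frac_shared_blood"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size <= 0:
            raise SimConfigError("effect_size must be > 0")
        if self.n_cohorts not in (1, 2):
            raise SimConfigError("n_cohorts must be 1 or 2")
        universe = default_universe()
        if self.n_diff_features > len(universe.vj_pairings):
            raise SimConfigError(
                f"n_diff_features exceeds the {len(universe.vj_pairings)} "
                "available VJ pairings"
            )
        if not set(self.tissues) <= {"T", "N", "B"}:
            raise SimConfigError(f"unknown tissue in {self.tissues}")
        if self.n_public * self.public_freq >= 1.0:
            raise SimConfigError("public clonotypes would exceed unit mass")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic tables."""

    shared: dict = field(default_factory=dict)   # patient -> {TN,TB,NB,TNB: [keys]}
    public: list = field(default_factory=list)   # clonotype keys
    diff_features: list = field(default_factory=list)  # {feature, direction, effect_size}
    usage_probs: dict = field(default_factory=dict)    # sample_id -> [p per VJ]
    feature_names: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class _Clonotype:
    v: str
    j: str
    nt: str
    aa: str

    @property
    def key(self) -> str:
        return f"{self.v}_{self.aa}_{self.j}"


def _random_clonotypes(
    rng: np.random.Generator,
    n: int,
    universe: GeneUniverse,
    seen: set[str],
) -> list[_Clonotype]:
    """Draw n novel clonotypes (unique keys against ``seen``)."""
    out: list[_Clonotype] = []
    while len(out) < n:
        length = int(rng.integers(8, 21))
        aa = "".join(rng.choice(AA_ALPHABET, size=length))
        nt = "".join(rng.choice(NT_ALPHABET, size=3 * length))
        v = str(rng.choice(universe.v_genes))
        j = str(rng.choice(universe.j_genes))
        c = _Clonotype(v, j, nt, aa)
        if c.key in seen:
            continue
        seen.add(c.key)
        out.append(c)
    return out


def _powerlaw_weights(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Zipf-style weights (rank+1)^-exponent in random rank order."""
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return rng.permutation(w)


def _emit_sample(
    sample_id: str,
    metadata: SampleMetadata,
    clonotypes: Sequence[_Clonotype],
    weights: np.ndarray,
    reads: int,
    rng: np.random.Generator,
) -> RepertoireSample:
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(reads, p)
    records = [
        ClonotypeRecord(sample_id, c.v, c.j, c.nt, c.aa, int(k))
        for c, k in zip(clonotypes, counts)
        if k > 0
    ]
    return RepertoireSample(metadata=metadata, records=records)


def simulate_patient(
    config: SimConfig,
    patient_id: str,
    rng: np.random.Generator,
    public: Sequence[_Clonotype] = (),
    universe: GeneUniverse | None = None,
) -> tuple[dict[str, RepertoireSample], dict[str, list[str]]]:
    """One patient's requested tissue samples plus their truth fragment.

    The truth fragment records the shared key sets (TN, TB, NB, TNB) of
    the *emitted* tables, so every truth key is guaranteed present.
    """
    config.validate()
    universe = universe or default_universe()
    seen: set[str] = {c.key for c in public}
    n_c = config.clonotypes_per_sample

    blood = _random_clonotypes(rng, n_c, universe, seen)
    blood_w = _powerlaw_weights(rng, n_c, config.clone_size_exponent)
    blood_by_idx = dict(enumerate(blood))

    # T: a fraction of blood clonotypes plus fresh tissue-only ones
    n_tb = round(config.frac_shared_blood * n_c)
    t_blood_idx = sorted(rng.choice(n_c, size=n_tb, replace=False).tolist())
    t_clonos = [blood_by_idx[i] for i in t_blood_idx] + _random_clonotypes(
        rng, n_c - n_tb, universe, seen
    )
    t_w = _powerlaw_weights(rng, n_c, config.clone_size_exponent)

    # N: a fraction of T's clonotypes, plus blood-shared and fresh ones
    n_tn = round(config.frac_shared_TN * n_c)
    n_from_t_idx = sorted(rng.choice(n_c, size=n_tn, replace=False).tolist())
    n_clonos = [t_clonos[i] for i in n_from_t_idx]
    n_rest = n_c - n_tn
    nb_pool = [i for i in range(n_c) if i not in set(t_blood_idx)]
    n_nb = min(round(config.frac_shared_blood * n_rest), len(nb_pool))
    if n_nb > 0:
        pick = rng.choice(len(nb_pool), size=n_nb, replace=False)
        n_clonos += [blood_by_idx[nb_pool[i]] for i in sorted(pick.tolist())]
    n_clonos += _random_clonotypes(rng, n_rest - n_nb, universe, seen)
    n_w = _powerlaw_weights(rng, n_c, config.clone_size_exponent)

    # expanded subset: prefer clonotypes present in all three tissues
    t_keys = {c.key: i for i, c in enumerate(t_clonos)}
    n_keys = {c.key: i for i, c in enumerate(n_clonos)}
    b_keys = {c.key for c in blood}
    tn_keys = [k for k in t_keys if k in n_keys]
    tnb_keys = [k for k in tn_keys if k in b_keys]
    candidates = tnb_keys if len(tnb_keys) >= 3 else tn_keys
    n_exp = min(max(1, round(EXPANDED_FRACTION * n_c)), len(candidates))
    if n_exp > 0 and config.expansion_factor != 1.0:
        idx = rng.choice(len(candidates), size=n_exp, replace=False)
        boost_t = config.expansion_factor ** 0.75
        for i in sorted(idx.tolist()):
            k = candidates[i]
            t_w[t_keys[k]] *= boost_t
            n_w[n_keys[k]] *= config.expansion_factor

    # blood gets the public clonotypes at ~public_freq each
    b_clonos = list(blood)
    b_w = blood_w.copy()
    if public:
        pf = config.public_freq
        w_pub = pf * b_w.sum() / (1.0 - len(public) * pf)
        b_clonos += list(public)
        b_w = np.concatenate([b_w, np.full(len(public), w_pub)])

    samples: dict[str, RepertoireSample] = {}
    spec = {"T": (t_clonos, t_w), "N": (n_clonos, n_w), "B": (b_clonos, b_w)}
    for tissue in config.tissues:
        sid = f"{patient_id}_{tissue}"
        md = SampleMetadata(
            sample_id=sid, patient_id=patient_id, tissue=tissue, cohort="case"
        )
        clonos, w = spec[tissue]
        samples[tissue] = _emit_sample(
            sid, md, clonos, w, config.reads_per_sample, rng
        )

    emitted = {t: s.key_set("v_aa_j") for t, s in samples.items()}
    truth: dict[str, list[str]] = {}
    if {"T", "N"} <= emitted.keys():
        truth["TN"] = sorted(emitted["T"] & emitted["N"])
    if {"T", "B"} <= emitted.keys():
        truth["TB"] = sorted(emitted["T"] & emitted["B"])
    if {"N", "B"} <= emitted.keys():
        truth["NB"] = sorted(emitted["N"] & emitted["B"])
    if {"T", "N", "B"} <= emitted.keys():
        truth["TNB"] = sorted(emitted["T"] & emitted["N"] & emitted["B"])
    return samples, truth


def simulate_patients(
    config: SimConfig,
) -> tuple[list[RepertoireSample], SimTruth]:
    """The full multi-patient, multi-tissue panel with its ground truth."""
    config.validate()
    universe = default_universe()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients + 1)
    pub_rng = np.random.default_rng(children[0])
    public = (
        _random_clonotypes(pub_rng, config.n_public, universe, set())
        if config.n_public > 0 and "B" in config.tissues
        else []
    )
    samples: list[RepertoireSample] = []
    truth = SimTruth(public=sorted(c.key for c in public))
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(children[i + 1])
        tissue_samples, fragment = simulate_patient(
            config, pid, rng, public=public, universe=universe
        )
        samples.extend(tissue_samples[t] for t in config.tissues)
        truth.shared[pid] = fragment
    return samples, truth


def simulate_cohorts(
    config: SimConfig,
) -> tuple[list[RepertoireSample], SimTruth]:
    """Case/control blood panels with a planted VJ-usage shift.

    Per-sample VJ probabilities are Dirichlet around a cohort base; the
    case base is shifted on ``n_diff_features`` pairings (alternating
    up/down in cases) by ``effect_size``-fold, drawn from the more
    abundant half of the grid so markers are observable at finite reads.
    """
    config.validate()
    if config.n_cohorts != 2:
        raise SimConfigError("simulate_cohorts requires n_cohorts=2")
    universe = default_universe()
    features = list(universe.vj_pairings)
    n_feat = len(features)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.n_case + config.n_control)
    base_rng = np.random.default_rng(children[0])

    control_base = base_rng.gamma(shape=0.5, scale=1.0, size=n_feat)
    control_base /= control_base.sum()
    case_base = control_base.copy()
    diff: list[dict] = []
    if config.n_diff_features > 0 and config.effect_size != 1.0:
        top = np.argsort(control_base)[::-1][: max(config.n_diff_features, 150)]
        planted = base_rng.choice(
            top[:150], size=config.n_diff_features, replace=False
        )
        for rank, j in enumerate(sorted(planted.tolist())):
            if rank % 2 == 0:
                case_base[j] *= config.effect_size
                direction = "up_in_case"
            else:
                case_base[j] /= config.effect_size
                direction = "up_in_control"
            diff.append(
                {
                    "feature": features[j],
                    "direction": direction,
                    "effect_size": config.effect_size,
                }
            )
        case_base /= case_base.sum()

    truth = SimTruth(diff_features=diff, feature_names=features)
    samples: list[RepertoireSample] = []
    conc = config.dirichlet_concentration
    plan = [("case", config.n_case, case_base), ("control", config.n_control, control_base)]
    child_iter = iter(children[1:])
    for cohort, n, base in plan:
        alpha = np.maximum(conc * base, 1e-6)
        for i in range(n):
            rng = np.random.default_rng(next(child_iter))
            sid = f"{cohort}{i + 1:03d}"
            p = rng.dirichlet(alpha)
            counts = rng.multinomial(config.reads_per_sample, p)
            records = _cohort_records(sid, counts, universe, rng)
            md = SampleMetadata(
                sample_id=sid, patient_id=sid, tissue="B", cohort=cohort
            )
            samples.append(RepertoireSample(metadata=md, records=records))
            truth.usage_probs[sid] = [round(float(x), 8) for x in p]
    return samples, truth


def _cohort_records(
    sample_id: str,
    vj_counts: np.ndarray,
    universe: GeneUniverse,
    rng: np.random.Generator,
) -> list[ClonotypeRecord]:
    """Split each VJ pairing's reads across one or two random clonotypes."""
    records: list[ClonotypeRecord] = []
    nz = np.nonzero(vj_counts)[0]
    n_j = len(universe.j_genes)
    lengths = rng.integers(8, 21, size=2 * len(nz))
    for pos, fi in enumerate(nz):
        v = universe.v_genes[fi // n_j]
        j = universe.j_genes[fi % n_j]
        total = int(vj_counts[fi])
        parts = [total] if total < 50 else [total - total // 3, total // 3]
        for pi, cnt in enumerate(parts):
            length = int(lengths[2 * pos + pi])
            aa = "".join(rng.choice(AA_ALPHABET, size=length))
            nt = "".join(rng.choice(NT_ALPHABET, size=3 * length))
            records.append(ClonotypeRecord(sample_id, v, j, nt, aa, cnt))
    return records


def simulate(config: SimConfig) -> tuple[list[RepertoireSample], SimTruth]:
    """Dispatch on ``n_cohorts``: 1 -> tissue panel, 2 -> cohort panel."""
    if config.n_cohorts == 2:
        return simulate_cohorts(config)
    return simulate_patients(config)


def write_fixture(
    samples: Sequence[RepertoireSample],
    truth: SimTruth,
    out_dir: str | Path,
) -> list[Path]:
    """Write one AIRR TSV per sample, metadata.tsv and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for s in samples:
        path = out_dir / f"{s.sample_id}.tsv"
        write_airr(s, path)
        written.append(path)
    meta_path = out_dir / "metadata.tsv"
    write_metadata(samples, meta_path)
    written.append(meta_path)
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    written.append(truth_path)
    return written
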