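"""Clonotype-table and sample-metadata I/O.

Reads AIRR Rearrangement-style TSV tables (``v_call``, ``j_call``,
``junction``/``junction_aa``, ``duplicate_count``) together with a
sample-metadata TSV, normalizes gene calls to the gene level (allele
suffixes stripped at ``*``), aggregates duplicate rows, and exposes the
frozen TRBV/TRBJ gene universe used by every downstream analysis.

Clonotype identity is configurable via :class:`KeyScheme`:

``aa``
    CDR3 amino-acid string alone.
``nt``
    CDR3 nucleotide string alone.
``v_aa_j``
    ``"<v_gene>_<cdr3_aa>_<j_gene>"`` — the default, matching how shared
    clonotypes are reported throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("T", "N", "B")
COHORTS = ("case", "control")

#: AIRR columns consumed by :func:`read_airr`. ``junction``/``junction_aa``:
#: at least one must be present.
AIRR_COLUMNS = ("v_call", "j_call", "junction", "junction_aa", "duplicate_count")

METADATA_COLUMNS = ("sample_id", "patient_id", "tissue", "cohort")


class RepertoireError(Exception):
    """Base class for all errors raised by this package's I/O layer."""


class FormatError(RepertoireError):
    """A table is missing a required column or otherwise malformed."""


class CountParseError(FormatError):
    """A duplicate_count value is not a non-negative integer."""


class MetadataJoinError(RepertoireError):
    """A sample present in the clonotype table has no metadata row."""


class KeySchemeError(RepertoireError):
    """A clonotype key was requested from a record lacking a required field."""


class ValidationError(RepertoireError):
    """Strict validation hit an invalid record."""


class KeyScheme(str, Enum):
    aa = "aa"
    nt = "nt"
    v_aa_j = "v_aa_j"


def strip_allele(gene: str) -> str:
    """Collapse an allele-qualified gene call to the gene name.

    ``"TRBV20-1*01" -> "TRBV20-1"``; names without ``*`` pass through
    unchanged, so the operation is idempotent.
    """
    return gene.split("*", 1)[0].strip()


@dataclass(frozen=True)
class GeneUniverse:
    """The fixed grid of TRBV/TRBJ gene names and their VJ pairings."""

    v_genes: tuple[str, ...]
    j_genes: tuple[str, ...]

    @property
    def vj_pairings(self) -> tuple[str, ...]:
        return tuple(f"{v}_{j}" for v in self.v_genes for j in self.j_genes)

    @property
    def v_set(self) -> frozenset:
        return frozenset(self.v_genes)

    @property
    def j_set(self) -> frozenset:
        return frozenset(self.j_genes)


@lru_cache(maxsize=1)
def default_universe() -> GeneUniverse:
    """Load the packaged functional TRBV (48) and TRBJ (13) gene lists."""
    pkg = resources.files("repdx.data")
    v = tuple(pkg.joinpath("trbv_genes.txt").read_text().split())
    j = tuple(pkg.joinpath("trbj_genes.txt").read_text().split())
    return GeneUniverse(v_genes=v, j_genes=j)


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype observation in one sample."""

    sample_id: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    count: int


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    patient_id: str
    tissue: str
    cohort: str = "case"
    clinical: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(
                f"tissue must be one of {TISSUES}, got {self.tissue!r}"
            )


def make_clonotype_key(
    record: ClonotypeRecord, scheme: KeyScheme | str = KeyScheme.v_aa_j
) -> str:
    """Deterministic clonotype identity string under the given scheme."""
    scheme = KeyScheme(scheme)
    if scheme is KeyScheme.aa:
        if not record.cdr3_aa:
            raise KeySchemeError("scheme 'aa' requires a non-empty cdr3_aa")
        return record.cdr3_aa
    if scheme is KeyScheme.nt:
        if not record.cdr3_nt:
            raise KeySchemeError("scheme 'nt' requires a non-empty cdr3_nt")
        return record.cdr3_nt
    for f in ("v_gene", "cdr3_aa", "j_gene"):
        if not getattr(record, f):
            raise KeySchemeError(f"scheme 'v_aa_j' requires a non-empty {f}")
    return f"{record.v_gene}_{record.cdr3_aa}_{record.j_gene}"


@dataclass
class RepertoireSample:
    """A sample's aggregated clonotype table plus its metadata."""

    metadata: SampleMetadata
    records: list[ClonotypeRecord]

    @property
    def sample_id(self) -> str:
        return self.metadata.sample_id

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.records)

    def aggregate(self) -> "RepertoireSample":
        """Merge records sharing (v_gene, j_gene, cdr3_nt, cdr3_aa).

        Idempotent; counts of duplicates are summed. Record order is
        normalized to the sorted full-identity tuple.
        """
        merged: dict[tuple, int] = {}
        for r in self.records:
            k = (r.v_gene, r.j_gene, r.cdr3_nt, r.cdr3_aa)
            merged[k] = merged.get(k, 0) + r.count
        records = [
            ClonotypeRecord(self.sample_id, v, j, nt, aa, c)
            for (v, j, nt, aa), c in sorted(merged.items())
        ]
        return RepertoireSample(metadata=self.metadata, records=records)

    def key_counts(self, scheme: KeyScheme | str = KeyScheme.v_aa_j) -> pd.Series:
        """Read counts grouped by clonotype key under ``scheme``."""
        counts: dict[str, int] = {}
        for r in self.records:
            k = make_clonotype_key(r, scheme)
            counts[k] = counts.get(k, 0) + r.count
        return pd.Series(counts, dtype=float).sort_index()

    def key_frequencies(
        self, scheme: KeyScheme | str = KeyScheme.v_aa_j
    ) -> pd.Series:
        """Relative abundances by clonotype key (sum to 1)."""
        counts = self.key_counts(scheme)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"sample {self.sample_id} has zero reads")
        return counts / total

    def key_set(self, scheme: KeyScheme | str = KeyScheme.v_aa_j) -> set:
        return {make_clonotype_key(r, scheme) for r in self.records}


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read the sample-metadata TSV into ``{sample_id: SampleMetadata}``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"metadata is missing required column: {col}")
    clinical_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    out: dict[str, SampleMetadata] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = d["sample_id"]
        if sid in out:
            raise FormatError(f"duplicate sample_id in metadata: {sid}")
        out[sid] = SampleMetadata(
            sample_id=sid,
            patient_id=d["patient_id"],
            tissue=d["tissue"],
            cohort=d["cohort"],
            clinical={c: d[c] for c in clinical_cols},
        )
    return out


def _records_from_frame(df: pd.DataFrame, sample_id: str) -> list[ClonotypeRecord]:
    missing = [c for c in ("v_call", "j_call", "duplicate_count") if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column: {missing[0]}")
    if "junction" not in df.columns and "junction_aa" not in df.columns:
        raise FormatError("missing required column: junction/junction_aa")
    try:
        counts = df["duplicate_count"].astype(int)
    except (ValueError, TypeError) as exc:
        raise CountParseError(
            f"non-integer duplicate_count in sample {sample_id}: {exc}"
        ) from exc
    if (counts < 0).any():
        raise CountParseError(f"negative duplicate_count in sample {sample_id}")
    nt = df["junction"] if "junction" in df.columns else pd.Series("", index=df.index)
    aa = df["junction_aa"] if "junction_aa" in df.columns else pd.Series("", index=df.index)
    records = [
        ClonotypeRecord(
            sample_id=sample_id,
            v_gene=strip_allele(str(v)),
            j_gene=strip_allele(str(j)),
            cdr3_nt="" if pd.isna(n) else str(n),
            cdr3_aa="" if pd.isna(a) else str(a),
            count=int(c),
        )
        for v, j, n, a, c in zip(df["v_call"], df["j_call"], nt, aa, counts)
    ]
    return records


def read_airr(
    path: str | Path, metadata_path: str | Path
) -> list[RepertoireSample]:
    """Read clonotype table(s) plus metadata into repertoire samples.

    ``path`` may be a single combined TSV carrying a ``sample_id`` column,
    or a directory of per-sample TSVs named ``<sample_id>.tsv``. Records
    are aggregated by full clonotype identity; allele suffixes stripped.
    """
    meta = read_metadata(metadata_path)
    path = Path(path)
    meta_resolved = Path(metadata_path).resolve()
    frames: list[tuple[str, pd.DataFrame]] = []
    if path.is_dir():
        for f in sorted(path.glob("*.tsv")):
            if f.name == "metadata.tsv" or f.resolve() == meta_resolved:
                continue
            frames.append((f.stem, pd.read_csv(f, sep="\t", dtype=str)))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if len(df) == 0:
            logger.warning("clonotype table %s contains only a header", path)
            return []
        if "sample_id" not in df.columns:
            raise FormatError("missing required column: sample_id")
        for sid, sub in df.groupby("sample_id", sort=True):
            frames.append((str(sid), sub.reset_index(drop=True)))

    samples: list[RepertoireSample] = []
    for sid, df in frames:
        if sid not in meta:
            raise MetadataJoinError(f"sample {sid!r} has no metadata row")
        if len(df) == 0:
            logger.warning("sample %s table contains only a header", sid)
            records: list[ClonotypeRecord] = []
        else:
            records = _records_from_frame(df, sid)
        sample = RepertoireSample(metadata=meta[sid], records=records).aggregate()
        samples.append(sample)
    return samples


def write_airr(sample: RepertoireSample, path: str | Path) -> None:
    """Write one sample back out as an AIRR-style TSV (round-trippable)."""
    df = pd.DataFrame(
        {
            "v_call": [r.v_gene for r in sample.records],
            "j_call": [r.j_gene for r in sample.records],
            "junction": [r.cdr3_nt for r in sample.records],
            "junction_aa": [r.cdr3_aa for r in sample.records],
            "duplicate_count": [r.count for r in sample.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_metadata(samples: Sequence[RepertoireSample], path: str | Path) -> None:
    clinical_cols: list[str] = []
    for s in samples:
        for c in s.metadata.clinical:
            if c not in clinical_cols:
                clinical_cols.append(c)
    rows = []
    for s in samples:
        m = s.metadata
        row = {
            "sample_id": m.sample_id,
            "patient_id": m.patient_id,
            "tissue": m.tissue,
            "cohort": m.cohort,
        }
        row.update({c: m.clinical.get(c, "") for c in clinical_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_normalized(
    samples: Sequence[RepertoireSample], path: str | Path
) -> None:
    """Write the combined normalized clonotype table with frequencies."""
    rows = []
    for s in samples:
        total = s.total_reads
        for r in s.records:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "v_gene": r.v_gene,
                    "j_gene": r.j_gene,
                    "cdr3_nt": r.cdr3_nt,
                    "cdr3_aa": r.cdr3_aa,
                    "count": r.count,
                    "frequency": r.count / total if total else 0.0,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa",
            "count", "frequency",
        ],
    ).to_csv(path, sep="\t", index=False)


@dataclass
class RejectedRecord:
    sample_id: str
    record: ClonotypeRecord
    reason: str


@dataclass
class ValidationReport:
    n_records: dict[str, int]
    rejected: list[RejectedRecord]
    samples: list[RepertoireSample]

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def validate_samples(
    samples: Iterable[RepertoireSample],
    policy: str = "quarantine",
    universe: GeneUniverse | None = None,
) -> ValidationReport:
    """Check records against the gene universe and count invariants.

    ``strict`` raises :class:`ValidationError` on the first violation;
    ``quarantine`` drops offending records and logs them in the report.
    """
    if policy not in ("strict", "quarantine"):
        raise ValueError(f"unknown validation policy: {policy!r}")
    universe = universe or default_universe()
    v_set, j_set = universe.v_set, universe.j_set
    rejected: list[RejectedRecord] = []
    n_records: dict[str, int] = {}
    cleaned: list[RepertoireSample] = []
    for s in samples:
        keep: list[ClonotypeRecord] = []
        for r in s.records:
            reason = None
            if r.count < 1:
                reason = f"count {r.count} < 1"
            elif r.v_gene and r.v_gene not in v_set:
                reason = f"unknown gene {r.v_gene}"
            elif r.j_gene and r.j_gene not in j_set:
                reason = f"unknown gene {r.j_gene}"
            if reason is None:
                keep.append(r)
            elif policy == "strict":
                raise ValidationError(f"sample {s.sample_id}: {reason}")
            else:
                logger.warning("sample %s: dropped record (%s)", s.sample_id, reason)
                rejected.append(RejectedRecord(s.sample_id, r, reason))
        n_records[s.sample_id] = len(keep)
        cleaned.append(RepertoireSample(metadata=s.metadata, records=keep))
    return ValidationReport(n_records=n_records, rejected=rejected, samples=cleaned)
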