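"""Domain types and tabular I/O shared by every pipeline stage.

Tables are UTF-8 tab-delimited text with a header row. Count tables carry the
feature id in the first column, one column per sample, and feature annotations
in trailing columns prefixed ``meta_`` so a single file is self-describing.
Sample metadata lives in its own table keyed by ``sample_id``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
WARMING = "warming"
TREATMENTS = (CONTROL, WARMING)

#: environmental covariates carried in sample metadata (units in docs/methods.md)
ENV_COVARIATES = (
    "soil_temperature",
    "moisture",
    "pH",
    "NH4_N",
    "NO3_N",
    "DOC",
    "SOC",
    "NDVI",
    "root_biomass",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class SampleMetadata:
    """One sample of a paired warming/control field design."""

    sample_id: str
    block_id: str
    treatment: str
    year: int
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: treatment must be one of {TREATMENTS}, "
                f"got {self.treatment!r}"
            )
        soc = self.env.get("SOC")
        if soc is not None and not soc > 0:
            raise ValidationError(f"sample {self.sample_id!r}: SOC must be > 0, got {soc}")


@dataclass
class CountTable:
    """Features x samples non-negative integer matrix with per-feature annotations.

    ``feature_meta`` maps feature id -> annotation record, e.g. a taxonomy
    lineage for ASVs or ``length_bp``/``family`` labels for genes.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    feature_meta: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            bad = np.argwhere(np.abs(self.counts - rounded) > 1e-9)
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {self.counts[i, j]}"
                )
            self.counts = rounded.astype(np.int64)
        bad = np.argwhere(self.counts < 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.counts[i, j]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            feature_meta=self.feature_meta,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df


@dataclass
class PairedDesignSummary:
    """Roster of a validated paired design."""

    blocks: list[str]
    n_pairs: int
    years: list[int]


@dataclass
class IncubationRecord:
    """Raw observables of one 24 h isotope-labelled water incubation.

    Holds everything needed to evaluate respiration (headspace CO2 against an
    empty blank vial), DNA production from the heavy-oxygen excess of the DNA
    extract, and biomass C from the fumigation-extraction flush.
    """

    sample_id: str
    co2_sample_ppm: float
    co2_blank_ppm: float
    o_total_ug: float
    at18O_labelled_pct: float
    at18O_natural_pct: float
    dna_mic_ug_per_g: float
    c_fumigated_ug_per_g: float
    c_unfumigated_ug_per_g: float
    o_label_pct: float = 20.0
    vial_volume_ml: float = 50.0
    soil_dry_mass_g: float = 0.3
    duration_h: float = 24.0
    temp_C: float = 15.0

    def __post_init__(self) -> None:
        for name in ("vial_volume_ml", "soil_dry_mass_g", "duration_h"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{self.sample_id}: {name} must be > 0")
        for name in ("at18O_labelled_pct", "at18O_natural_pct", "o_label_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{self.sample_id}: {name}={v} outside [0, 100]")
        if self.co2_sample_ppm < 0:
            raise ValidationError(f"{self.sample_id}: co2_sample_ppm < 0")


@dataclass
class AminoSugarProfile:
    """Amino-sugar contents of one sample (ug per g dry soil)."""

    sample_id: str
    glun_ug_per_g: float
    galn_ug_per_g: float
    mura_ug_per_g: float

    def __post_init__(self) -> None:
        for name in ("glun_ug_per_g", "galn_ug_per_g", "mura_ug_per_g"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.sample_id}: {name} must be >= 0")


@dataclass
class FractionRecord:
    """Masses and C concentrations of the three density/size SOM fractions."""

    sample_id: str
    initial_mass_g: float
    poc_mass_g: float
    heavy_poc_mass_g: float
    maom_mass_g: float
    poc_c_g_kg: float
    heavy_poc_c_g_kg: float
    maoc_c_g_kg: float
    bulk_soc_g_kg: float

    def __post_init__(self) -> None:
        for name in ("initial_mass_g", "poc_mass_g", "heavy_poc_mass_g", "maom_mass_g"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.sample_id}: {name} must be >= 0")
        if self.mass_recovery() > 1.05:
            raise ValidationError(
                f"{self.sample_id}: mass recovery {self.mass_recovery():.3f} > 1.05"
            )

    def mass_recovery(self) -> float:
        return (self.poc_mass_g + self.heavy_poc_mass_g + self.maom_mass_g) / self.initial_mass_g


@dataclass
class PairedExperiment:
    """The full study object: paired metadata plus every measurement table."""

    metadata: list[SampleMetadata]
    asv_prok: CountTable | None = None
    asv_fungi: CountTable | None = None
    genes: CountTable | None = None
    incubations: list[IncubationRecord] = field(default_factory=list)
    amino_sugars: list[AminoSugarProfile] = field(default_factory=list)
    fractions: list[FractionRecord] = field(default_factory=list)
    rh_series: pd.DataFrame | None = None  # columns: sample_id, date, rh

    def __post_init__(self) -> None:
        ids = {m.sample_id for m in self.metadata}
        for table in (self.asv_prok, self.asv_fungi, self.genes):
            if table is not None:
                unknown = set(table.sample_ids) - ids
                if unknown:
                    raise ValidationError(f"count-table samples not in metadata: {sorted(unknown)}")
        for rec_list in (self.incubations, self.amino_sugars, self.fractions):
            for rec in rec_list:
                if rec.sample_id not in ids:
                    raise ValidationError(f"record sample {rec.sample_id!r} not in metadata")
        if len({m.block_id for m in self.metadata}) < 2:
            raise ValidationError("a paired experiment needs at least 2 blocks")

    def metadata_by_sample(self) -> dict[str, SampleMetadata]:
        return {m.sample_id: m for m in self.metadata}

    def samples_by_treatment(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in TREATMENTS}
        for m in self.metadata:
            out[m.treatment].append(m.sample_id)
        return out


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

META_PREFIX = "meta_"


def read_count_table(path: str | Path, meta_columns: Sequence[str] | None = None) -> CountTable:
    """Read a count table from TSV (first column feature id, ``meta_`` columns
    become feature annotations). Row and column order are preserved."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    feature_col = df.columns[0]
    meta_cols = [c for c in df.columns[1:] if c.startswith(META_PREFIX)]
    if meta_columns is not None:
        missing = [c for c in meta_columns if META_PREFIX + c not in meta_cols]
        if missing:
            raise ValidationError(f"{path}: missing annotation columns {missing}")
    sample_cols = [c for c in df.columns[1:] if not c.startswith(META_PREFIX)]
    feature_ids = df[feature_col].astype(str).tolist()
    _check_unique(feature_ids, "feature id")
    counts = df[sample_cols].to_numpy()
    meta: dict[str, dict[str, Any]] = {}
    if meta_cols:
        for fid, row in zip(feature_ids, df[meta_cols].itertuples(index=False)):
            meta[fid] = {c[len(META_PREFIX):]: v for c, v in zip(meta_cols, row)}
    return CountTable(feature_ids, sample_cols, counts, meta)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.to_dataframe().reset_index()
    meta_keys: list[str] = []
    for fid in table.feature_ids:
        for k in table.feature_meta.get(fid, {}):
            if k not in meta_keys:
                meta_keys.append(k)
    for k in meta_keys:
        df[META_PREFIX + k] = [table.feature_meta.get(f, {}).get(k, "") for f in table.feature_ids]
    df.to_csv(path, sep="\t", index=False)


METADATA_FIXED = ("sample_id", "block_id", "treatment", "year")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "block_id": str})
    missing = [c for c in METADATA_FIXED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    env_cols = [c for c in df.columns if c not in METADATA_FIXED]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        env = {c: float(d[c]) for c in env_cols if pd.notna(d[c])}
        out.append(
            SampleMetadata(
                sample_id=str(d["sample_id"]),
                block_id=str(d["block_id"]),
                treatment=str(d["treatment"]),
                year=int(d["year"]),
                env=env,
            )
        )
    _check_unique([m.sample_id for m in out], "sample id")
    return out


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    env_keys: list[str] = []
    for m in metadata:
        for k in m.env:
            if k not in env_keys:
                env_keys.append(k)
    rows = []
    for m in metadata:
        row: dict[str, Any] = {
            "sample_id": m.sample_id,
            "block_id": m.block_id,
            "treatment": m.treatment,
            "year": m.year,
        }
        row.update({k: m.env.get(k, np.nan) for k in env_keys})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_records(path: str | Path, cls):
    """Read a list of dataclass records (one per row) from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    fields = {f.name for f in dataclasses.fields(cls)}
    cols = [c for c in df.columns if c in fields]
    return [cls(**{c: row[c] for c in cols}) for _, row in df.iterrows()]


def write_records(records: Sequence[Any], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Rarefaction and design validation
# ---------------------------------------------------------------------------


def min_depth(table: CountTable) -> int:
    """Minimum per-sample sequence count (the rarefaction depth convention)."""
    if not table.sample_ids:
        raise ValidationError("empty table has no minimum depth")
    return int(table.sample_sums().min())


def rarefy_table(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Per-sample draws are multivariate hypergeometric, so a sample whose total
    already equals ``depth`` is returned unchanged. Deterministic given seed.
    """
    if depth <= 0:
        raise ValidationError("depth must be a positive integer")
    sums = table.sample_sums()
    short = [s for s, tot in zip(table.sample_ids, sums) if tot < depth]
    if short:
        raise ValidationError(f"depth {depth} exceeds total counts of samples: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(len(table.sample_ids)):
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(list(table.feature_ids), list(table.sample_ids), out, table.feature_meta)


def validate_paired_design(metadata: Sequence[SampleMetadata]) -> PairedDesignSummary:
    """Check each (block, year) has exactly one control and one warming sample."""
    _check_unique([m.sample_id for m in metadata], "sample id")
    groups: dict[tuple[str, int], dict[str, int]] = {}
    for m in metadata:
        tally = groups.setdefault((m.block_id, m.year), {t: 0 for t in TREATMENTS})
        tally[m.treatment] += 1
    bad = [key for key, tally in groups.items() if any(v != 1 for v in tally.values())]
    if bad:
        names = ", ".join(f"block {b!r} year {y}" for b, y in sorted(bad))
        raise ValidationError(f"unbalanced paired design in: {names}")
    blocks = sorted({b for b, _ in groups})
    years = sorted({y for _, y in groups})
    return PairedDesignSummary(blocks=blocks, n_pairs=len(groups), years=years)


def paired_arrays(
    metadata: Sequence[SampleMetadata], values: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Align a per-sample value map into block-paired (control, warming) arrays."""
    validate_paired_design(metadata)
    by_key: dict[tuple[str, int], dict[str, float]] = {}
    for m in metadata:
        if m.sample_id in values:
            by_key.setdefault((m.block_id, m.year), {})[m.treatment] = values[m.sample_id]
    keys = sorted(k for k, v in by_key.items() if len(v) == 2)
    ctrl = np.array([by_key[k][CONTROL] for k in keys])
    warm = np.array([by_key[k][WARMING] for k in keys])
    return ctrl, warm, keys
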