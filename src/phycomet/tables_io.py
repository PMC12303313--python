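"""Readers, writers and validated containers for the tabular pipeline inputs.

The central object is the :class:`FeatureTable`: an MS1 feature list (m/z and
retention-time envelopes) together with a feature x sample intensity matrix.
Samples are described by a :class:`PhenoData` design table mapping each sample
to (species, compartment, culture, polarity, replicate).  Growth curves and
suspect lists (curated catalogues of metabolites known for each organism) have
their own lightweight containers.

Conventions
-----------
* Retention time is in seconds everywhere; readers accept ``rt_minutes=True``
  to multiply by 60 on ingest.
* Intensity 0 is the canonical missing value; blank cells are read as 0.
* Matrices are addressed by ``sample_id``, never by column position, but the
  sample order of the source file is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError, ValidationError

ENVELOPE_COLUMNS = ("mz_min", "mz_med", "mz_max", "rt_min", "rt_med", "rt_max")

SPECIES_TOKENS = {"SM", "PP", "BLANK"}
COMPARTMENT_TOKENS = {"endo", "exo"}
CULTURE_TOKENS = {"mono", "co"}
POLARITY_TOKENS = {"pos", "neg"}

_PHENO_COLUMNS = ("sample_id", "species", "compartment", "culture", "polarity", "replicate")


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """MS1 features (envelope columns) plus a feature x sample intensity matrix.

    ``features`` is indexed by ``feature_id`` with the six envelope columns;
    ``intensities`` shares the index and has one column per sample.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in ENVELOPE_COLUMNS if c not in self.features.columns]
        if missing:
            raise SchemaError(f"feature table missing column(s): {', '.join(missing)}")
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature_id(s): {dupes}")
        if not self.features.index.equals(self.intensities.index):
            raise ValidationError("features and intensities are not aligned on feature_id")
        f = self.features
        bad_mz = f.index[(f["mz_min"] > f["mz_med"]) | (f["mz_med"] > f["mz_max"])]
        if len(bad_mz):
            raise ValidationError(f"m/z envelope violated for feature_id {bad_mz[0]!r}")
        bad_rt = f.index[(f["rt_min"] > f["rt_med"]) | (f["rt_med"] > f["rt_max"])]
        if len(bad_rt):
            raise ValidationError(f"RT envelope violated for feature_id {bad_rt[0]!r}")
        vals = self.intensities.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite intensity value")
        if (vals < 0).any():
            raise ValidationError("negative intensity value")

    # -- conveniences -------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.loc[:, list(sample_ids)].copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.copy())

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([self.features, self.intensities], axis=1)
        out.insert(0, "feature_id", out.index)
        return out.reset_index(drop=True)

    def write(self, path: str | Path, sep: str | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep=_sep_for(path, sep), index=False)


def read_feature_table(
    path: str | Path, sep: str | None = None, rt_minutes: bool = False
) -> FeatureTable:
    """Read a peak-picking-software-style feature table export (TSV/CSV).

    Expected header: ``feature_id``, the six envelope columns, then one column
    per sample.  Blank intensity cells are read as 0 (the pipeline's missing
    value); non-numeric cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    required = ("feature_id",) + ENVELOPE_COLUMNS
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {', '.join(missing)}")
    sample_cols = [c for c in raw.columns if c not in required]
    if not sample_cols:
        raise SchemaError("feature table has no sample columns")
    features = raw.set_index("feature_id")[list(ENVELOPE_COLUMNS)].astype(float)
    if rt_minutes:
        features[["rt_min", "rt_med", "rt_max"]] *= 60.0
    raw_inten = raw.set_index("feature_id")[sample_cols]
    blank = raw_inten.isna()
    try:
        # float() parsing is exact (round-trips shortest repr); blanks become 0
        inten = raw_inten.where(~blank, "0").astype(float)
    except ValueError as e:
        raise ValidationError(f"non-numeric intensity cell: {e}") from e
    return FeatureTable(features, inten)


# ---------------------------------------------------------------------------
# PhenoData
# ---------------------------------------------------------------------------

@dataclass
class PhenoData:
    """Sample design table: sample_id -> (species, compartment, culture, polarity, replicate)."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in _PHENO_COLUMNS[1:] if c not in self.table.columns]
        if missing:
            raise SchemaError(f"phenodata missing column(s): {', '.join(missing)}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        for col, allowed in (
            ("species", SPECIES_TOKENS),
            ("compartment", COMPARTMENT_TOKENS),
            ("culture", CULTURE_TOKENS),
            ("polarity", POLARITY_TOKENS),
        ):
            bad = set(self.table[col].unique()) - allowed
            if bad:
                raise ValidationError(
                    f"unknown {col} token(s) {sorted(bad)}; allowed: {sorted(allowed)}"
                )
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be positive")
        key = self.table[["species", "compartment", "culture", "polarity", "replicate"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (species, compartment, culture, polarity, replicate)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_for(
        self,
        species: str | None = None,
        compartment: str | None = None,
        culture: str | None = None,
        polarity: str | None = None,
    ) -> list[str]:
        """Sample ids matching every given design level (None = any)."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in (
            ("species", species),
            ("compartment", compartment),
            ("culture", culture),
            ("polarity", polarity),
        ):
            if val is not None:
                mask &= self.table[col] == val
        return list(self.table.index[mask])

    def write(self, path: str | Path, sep: str | None = None) -> None:
        path = Path(path)
        out = self.table.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, sep=_sep_for(path, sep), index=False)


_CASE_MAPS = {
    "species": {t.lower(): t for t in SPECIES_TOKENS},
    "compartment": {t.lower(): t for t in COMPARTMENT_TOKENS},
    "culture": {t.lower(): t for t in CULTURE_TOKENS},
    "polarity": {t.lower(): t for t in POLARITY_TOKENS},
}


def read_phenodata(path: str | Path, sep: str | None = None) -> PhenoData:
    """Read and validate a phenodata table; enum tokens are case-insensitive."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    missing = [c for c in _PHENO_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"phenodata missing column(s): {', '.join(missing)}")
    for col, mapping in _CASE_MAPS.items():
        tokens = raw[col].str.strip().str.lower()
        unknown = set(tokens.unique()) - set(mapping)
        if unknown:
            raise ValidationError(
                f"unknown {col} token(s) {sorted(unknown)}; "
                f"allowed: {sorted(set(mapping.values()))}"
            )
        raw[col] = tokens.map(mapping)
    raw["replicate"] = raw["replicate"].astype(int)
    return PhenoData(raw.set_index("sample_id"))


# ---------------------------------------------------------------------------
# GrowthSeries
# ---------------------------------------------------------------------------

GROWTH_DAYS = (0, 2, 4, 6, 8)


@dataclass
class GrowthSeries:
    """One replicate's chlorophyll-a fluorescence time course (RFU vs day)."""

    species: str
    culture: str
    replicate: int
    observations: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES_TOKENS:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.culture not in CULTURE_TOKENS:
            raise ValidationError(f"unknown culture {self.culture!r}")
        extra = set(self.observations) - set(GROWTH_DAYS)
        if extra:
            raise ValidationError(f"days must lie in {GROWTH_DAYS}; got {sorted(extra)}")
        for day, rfu in self.observations.items():
            if not math.isfinite(rfu) or rfu < 0:
                raise ValidationError(f"RFU must be finite and >= 0 (day {day}: {rfu})")


def growth_series_to_frame(series: Iterable[GrowthSeries]) -> pd.DataFrame:
    """Wide layout matching the supplementary fluorescence table: one column per day."""
    rows = []
    for s in series:
        row: dict[str, object] = {
            "species": s.species,
            "culture": s.culture,
            "replicate": s.replicate,
        }
        for day in GROWTH_DAYS:
            if day in s.observations:
                row[f"d{day}"] = s.observations[day]
        rows.append(row)
    return pd.DataFrame(rows)


def write_growth_series(series: Iterable[GrowthSeries], path: str | Path,
                        sep: str | None = None) -> None:
    path = Path(path)
    growth_series_to_frame(series).to_csv(path, sep=_sep_for(path, sep), index=False)


def read_growth_series(path: str | Path, sep: str | None = None) -> list[GrowthSeries]:
    """Read growth curves in the wide d0..d8 layout (species, culture, replicate, d0, ...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path, sep), float_precision="round_trip")
    for col in ("species", "culture", "replicate"):
        if col not in raw.columns:
            raise SchemaError(f"growth table missing column {col!r}")
    day_cols = [c for c in raw.columns if c.startswith("d") and c[1:].isdigit()]
    if not day_cols:
        raise SchemaError("growth table has no day columns (d0, d2, ...)")
    out = []
    for _, row in raw.iterrows():
        obs = {int(c[1:]): float(row[c]) for c in day_cols if pd.notna(row[c])}
        out.append(
            GrowthSeries(
                species=str(row["species"]).strip().upper(),
                culture=str(row["culture"]).strip().lower(),
                replicate=int(row["replicate"]),
                observations=obs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# SuspectEntry
# ---------------------------------------------------------------------------

@dataclass
class SuspectEntry:
    """One catalogued metabolite known for an organism (a 'suspect')."""

    name: str
    formula: str = ""
    monoisotopic_mass: float | None = None
    smiles: str = ""
    inchi: str = ""
    source_species: str = "BOTH"  # SM | PP | BOTH

    def __post_init__(self) -> None:
        if not (self.name or self.smiles or self.inchi):
            raise ValidationError("suspect entry needs at least one of name/smiles/inchi")
        if self.monoisotopic_mass is not None and not self.monoisotopic_mass > 0:
            raise ValidationError(f"suspect mass must be > 0, got {self.monoisotopic_mass}")
        if self.source_species not in {"SM", "PP", "BOTH"}:
            raise ValidationError(f"source_species must be SM/PP/BOTH, got {self.source_species!r}")


def read_suspect_list(path: str | Path, sep: str | None = None) -> list[SuspectEntry]:
    """Read a suspect list (name + structure identifiers + source organism)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str).fillna("")
    if "name" not in raw.columns:
        raise SchemaError("suspect list missing column 'name'")
    if not ({"smiles", "inchi"} & set(raw.columns)):
        raise SchemaError("suspect list needs a structure column (smiles or inchi)")
    entries: list[SuspectEntry] = []
    for _, row in raw.iterrows():
        mass_raw = str(row.get("monoisotopic_mass", "")).strip()
        try:
            mass: float | None = float(mass_raw)
        except ValueError:
            mass = None  # "n/a" and friends: mass stored as absent, entry kept
        source = str(row.get("source_species", "BOTH")).strip().upper() or "BOTH"
        name = str(row["name"]).strip()
        smiles = str(row.get("smiles", "")).strip()
        inchi = str(row.get("inchi", "")).strip()
        if not (name or smiles or inchi):
            continue
        entries.append(
            SuspectEntry(
                name=name,
                formula=str(row.get("formula", "")).strip(),
                monoisotopic_mass=mass,
                smiles=smiles,
                inchi=inchi,
                source_species=source,
            )
        )
    if not entries:
        raise DegenerateDataError(f"no parseable suspect rows in {path}")
    return entries


def check_samples_covered(table: FeatureTable, pheno: PhenoData) -> None:
    """Every intensity column must have a phenodata row."""
    missing = [s for s in table.sample_ids if s not in pheno.sample_ids]
    if missing:
        raise ValidationError(f"sample(s) without phenodata row: {missing}")
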