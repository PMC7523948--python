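"""Domain types and tidy-table I/O for community and diet samples.

Input data are long ("tidy") plain-text tables: a taxon catalog giving the
taxonomic rank path, origin (aquatic vs terrestrial) and life stage of every
taxon; sample events with section/season/period metadata, gear and sampling
effort; one observation row per taxon per sample (with optional body-length
measurements); and, for diet data, one row per fish.  Wide sample x taxon
assemblage matrices are built on demand with :func:`build_matrix`.

CSV dialect: UTF-8, comma separated, header row required, ``""`` = missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Taxonomic ranks, coarsest first.  Trailing levels of a rank path may be
# absent (e.g. partially digested prey identified only to Order).
RANKS: tuple[str, ...] = ("class", "order", "family", "genus", "species")

ORIGINS = frozenset({"aquatic", "terrestrial"})
LIFE_STAGES = frozenset({"larva", "pupa", "adult", "unknown"})
SECTIONS = frozenset({"Estuary", "LE", "ME", "TR", "LME"})
SEASONS = frozenset({"spring", "summer"})
PERIODS = frozenset({"Pre", "2012", "2013", "2014"})
HABITATS = frozenset({"mainstem", "floodplain", "estuary", "tributary"})
GEARS = frozenset({"benthic", "fallout", "drift", "diet"})
EFFORT_UNITS = frozenset({"m2", "m3", "per_fish"})
MEASUREMENT_METRICS = frozenset({"total_length", "head_capsule_width"})
BASES = frozenset({"count", "count_density", "energy", "energy_density"})

#: gear -> required effort unit
GEAR_UNITS: Mapping[str, str] = {
    "benthic": "m2",
    "fallout": "m2",
    "drift": "m3",
    "diet": "per_fish",
}

#: fork length (mm) at or below which a fish is young-of-year
YOY_MAX_FORK_LENGTH_MM = 70.0

TAXON_COLUMNS = ["taxon_id", *RANKS, "origin", "life_stage"]
SAMPLE_COLUMNS = [
    "sample_id", "section", "season", "period", "habitat", "gear",
    "effort", "effort_unit",
]
OBS_COLUMNS = ["sample_id", "fish_id", "taxon_id", "count", "metric", "lengths_mm"]
FISH_COLUMNS = ["fish_id", "sample_id", "species", "fork_length_mm", "mass_g",
                "empty_stomach"]


class DataModelError(ValueError):
    """Malformed or referentially inconsistent input data."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataModelError(f"{what}: missing column(s) {missing}")


def parse_lengths(cell) -> list[float]:
    """Parse a semicolon-joined measurement cell like ``"3.2;4.1"``."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    if isinstance(cell, (int, float)):
        return [float(cell)]
    return [float(tok) for tok in str(cell).split(";") if tok.strip() != ""]


def format_lengths(values: Iterable[float]) -> str:
    return ";".join(repr(float(v)) for v in values)


class TaxonCatalog:
    """Registry of taxa: rank path, aquatic/terrestrial origin, life stage.

    Backed by a DataFrame indexed by ``taxon_id`` with one column per rank
    in :data:`RANKS` plus ``origin`` and ``life_stage``.
    """

    def __init__(self, table: pd.DataFrame):
        _require_columns(table, TAXON_COLUMNS, "taxon catalog")
        t = table.copy()
        if t["taxon_id"].duplicated().any():
            dups = sorted(t.loc[t["taxon_id"].duplicated(), "taxon_id"])
            raise DataModelError(f"duplicate taxon_id(s): {dups}")
        bad_origin = set(t["origin"]) - ORIGINS
        if bad_origin:
            raise DataModelError(f"invalid origin value(s): {sorted(bad_origin)}")
        t["life_stage"] = t["life_stage"].fillna("unknown").replace("", "unknown")
        bad_stage = set(t["life_stage"]) - LIFE_STAGES
        if bad_stage:
            raise DataModelError(f"invalid life_stage value(s): {sorted(bad_stage)}")
        for r in RANKS:
            t[r] = t[r].replace("", np.nan)
        if t[list(RANKS)].isna().all(axis=1).any():
            empty = t.loc[t[list(RANKS)].isna().all(axis=1), "taxon_id"].tolist()
            raise DataModelError(f"taxa with empty rank path: {empty}")
        self.table = t.set_index("taxon_id", drop=False)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.table.index)

    def rank_path(self, taxon_id: str) -> dict[str, str]:
        """Defined rank levels for a taxon, coarsest first."""
        row = self.table.loc[taxon_id]
        return {r: row[r] for r in RANKS if pd.notna(row[r])}

    def origin(self, taxon_id: str) -> str:
        return self.table.at[taxon_id, "origin"]

    def life_stage(self, taxon_id: str) -> str:
        return self.table.at[taxon_id, "life_stage"]

    def label_at_rank(self, taxon_id: str, rank: str) -> tuple[str, bool]:
        """Aggregation label for ``taxon_id`` at ``rank``.

        Returns ``(label, resolved)``.  If the taxon is identified only to a
        coarser level than ``rank`` (e.g. unidentifiable "Diptera" fragments
        when aggregating at family), it keeps its own column labelled by its
        finest available level and is flagged ``resolved=False``.
        """
        if rank == "finest":
            path = self.rank_path(taxon_id)
            return list(path.values())[-1], True
        if rank not in RANKS:
            raise DataModelError(f"unknown rank {rank!r}")
        row = self.table.loc[taxon_id]
        if pd.notna(row[rank]):
            return row[rank], True
        # finest defined level coarser than the requested rank
        want = RANKS.index(rank)
        finest = None
        for i, r in enumerate(RANKS[: want + 1]):
            if pd.notna(row[r]):
                finest = row[r]
        if finest is None:
            raise DataModelError(
                f"taxon {taxon_id!r} has no level at or above rank {rank!r}")
        return finest, False


@dataclass
class SampleSet:
    """Sample events, observations and (optionally) fish records.

    ``samples``: one row per sample event (:data:`SAMPLE_COLUMNS`).
    ``observations``: one row per taxon per sample (per fish for diets);
    gains an ``energy_j`` column after :func:`foodwebkit.energetics.annotate_energy`.
    ``fish``: one row per fish, or None for environment-only data.
    """

    samples: pd.DataFrame
    observations: pd.DataFrame
    fish: pd.DataFrame | None = None

    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def sample_meta(self) -> pd.DataFrame:
        return self.samples.set_index("sample_id", drop=False)

    def subset(self, sample_ids: Sequence[str]) -> "SampleSet":
        keep = set(sample_ids)
        s = self.samples[self.samples["sample_id"].isin(keep)].copy()
        o = self.observations[self.observations["sample_id"].isin(keep)].copy()
        f = None
        if self.fish is not None:
            f = self.fish[self.fish["sample_id"].isin(keep)].copy()
        return SampleSet(s, o, f)


def _validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    _require_columns(samples, SAMPLE_COLUMNS, "sample table")
    s = samples.copy()
    if s["sample_id"].duplicated().any():
        dups = sorted(s.loc[s["sample_id"].duplicated(), "sample_id"])
        raise DataModelError(f"duplicate sample_id(s): {dups}")
    for col, allowed in (("section", SECTIONS), ("season", SEASONS),
                         ("period", PERIODS), ("habitat", HABITATS),
                         ("gear", GEARS), ("effort_unit", EFFORT_UNITS)):
        bad = set(s[col].astype(str)) - set(allowed)
        if bad:
            raise DataModelError(f"invalid {col} value(s): {sorted(bad)}")
    s["effort"] = pd.to_numeric(s["effort"], errors="raise")
    if (s["effort"] <= 0).any():
        bad = s.loc[s["effort"] <= 0, "sample_id"].tolist()
        raise DataModelError(f"non-positive effort for sample(s): {bad}")
    for _, row in s.iterrows():
        want = GEAR_UNITS[row["gear"]]
        if row["effort_unit"] != want:
            raise DataModelError(
                f"sample {row['sample_id']!r}: gear {row['gear']!r} requires "
                f"effort unit {want!r}, got {row['effort_unit']!r}")
    return s


def _validate_observations(obs: pd.DataFrame, catalog: TaxonCatalog,
                           samples: pd.DataFrame,
                           fish: pd.DataFrame | None) -> pd.DataFrame:
    _require_columns(obs, ["sample_id", "taxon_id", "count"], "observation table")
    o = obs.copy()
    if "fish_id" not in o.columns:
        o["fish_id"] = np.nan
    if "metric" not in o.columns:
        o["metric"] = np.nan
    if "lengths_mm" not in o.columns:
        o["lengths_mm"] = ""
    known_samples = set(samples["sample_id"])
    known_fish = set(fish["fish_id"]) if fish is not None else set()
    for i, row in o.reset_index(drop=True).iterrows():
        rowno = i + 2  # 1-based with header line
        if row["taxon_id"] not in catalog:
            raise DataModelError(
                f"observation row {rowno}: unknown taxon_id {row['taxon_id']!r}")
        if row["sample_id"] not in known_samples:
            raise DataModelError(
                f"observation row {rowno}: unknown sample_id {row['sample_id']!r}")
        if pd.notna(row["fish_id"]) and str(row["fish_id"]) != "":
            if fish is None or row["fish_id"] not in known_fish:
                raise DataModelError(
                    f"observation row {rowno}: unknown fish_id {row['fish_id']!r}")
        try:
            count = int(row["count"])
        except (TypeError, ValueError) as exc:
            raise DataModelError(
                f"observation row {rowno}: malformed count {row['count']!r}") from exc
        if count < 0:
            raise DataModelError(f"observation row {rowno}: negative count")
        try:
            lengths = parse_lengths(row["lengths_mm"])
        except ValueError as exc:
            raise DataModelError(
                f"observation row {rowno}: malformed lengths_mm "
                f"{row['lengths_mm']!r}") from exc
        if any(v <= 0 for v in lengths):
            raise DataModelError(f"observation row {rowno}: non-positive length")
        if len(lengths) > count:
            raise DataModelError(
                f"observation row {rowno}: {len(lengths)} measurements exceed "
                f"count {count}")
        if lengths and (pd.isna(row["metric"]) or row["metric"] == ""):
            raise DataModelError(
                f"observation row {rowno}: measurements present but metric missing")
        if pd.notna(row["metric"]) and row["metric"] != "" \
                and row["metric"] not in MEASUREMENT_METRICS:
            raise DataModelError(
                f"observation row {rowno}: invalid metric {row['metric']!r}")
    o["count"] = o["count"].astype(int)
    return o


def _validate_fish(fish: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    _require_columns(fish, FISH_COLUMNS, "fish table")
    f = fish.copy()
    if f["fish_id"].duplicated().any():
        dups = sorted(f.loc[f["fish_id"].duplicated(), "fish_id"])
        raise DataModelError(f"duplicate fish_id(s): {dups}")
    known = set(samples["sample_id"])
    unknown = set(f["sample_id"]) - known
    if unknown:
        raise DataModelError(f"fish referencing unknown sample(s): {sorted(unknown)}")
    f["fork_length_mm"] = pd.to_numeric(f["fork_length_mm"], errors="raise")
    f["mass_g"] = pd.to_numeric(f["mass_g"], errors="raise")
    f["empty_stomach"] = f["empty_stomach"].map(
        {True: True, False: False, "True": True, "False": False,
         "true": True, "false": False, 1: True, 0: False, "1": True, "0": False})
    if f["empty_stomach"].isna().any():
        raise DataModelError("fish table: empty_stomach must be boolean")
    f["age_class"] = np.where(
        f["fork_length_mm"] <= YOY_MAX_FORK_LENGTH_MM, "YOY", "one_plus")
    return f


def load_tables(taxon_path, sample_path, observation_path,
                fish_path=None) -> tuple[TaxonCatalog, SampleSet]:
    """Read the four CSV tables and enforce referential integrity.

    Every observation must reference a known taxon and sample (and fish, for
    diet rows); errors name the offending row.  Fish flagged as empty
    stomachs must have no diet observations.
    """
    read = lambda p: pd.read_csv(p, dtype={"lengths_mm": str},
                                 keep_default_na=True, na_values=[""])
    catalog = TaxonCatalog(read(taxon_path))
    samples = _validate_samples(read(sample_path))
    fish = _validate_fish(read(fish_path), samples) if fish_path else None
    obs = _validate_observations(read(observation_path), catalog, samples, fish)
    if fish is not None:
        fed = set(obs.loc[obs["count"] > 0, "fish_id"].dropna())
        bad = sorted(set(fish.loc[fish["empty_stomach"], "fish_id"]) & fed)
        if bad:
            raise DataModelError(
                f"fish flagged empty_stomach but with diet observations: {bad}")
    return catalog, SampleSet(samples, obs, fish)


def write_tables(catalog: TaxonCatalog, sampleset: SampleSet, out_dir,
                 prefix: str = "") -> dict[str, Path]:
    """Write catalog + sample set back to the documented CSV dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    t = catalog.table.reset_index(drop=True)[TAXON_COLUMNS]
    paths["taxa"] = out / f"{prefix}taxa.csv"
    t.to_csv(paths["taxa"], index=False)
    paths["samples"] = out / f"{prefix}samples.csv"
    sampleset.samples[SAMPLE_COLUMNS].to_csv(paths["samples"], index=False)
    obs = sampleset.observations.copy()
    for c in OBS_COLUMNS:
        if c not in obs.columns:
            obs[c] = np.nan
    paths["observations"] = out / f"{prefix}observations.csv"
    obs[OBS_COLUMNS].to_csv(paths["observations"], index=False)
    if sampleset.fish is not None:
        paths["fish"] = out / f"{prefix}fish.csv"
        sampleset.fish[FISH_COLUMNS].to_csv(paths["fish"], index=False)
    return paths


@dataclass
class AssemblageMatrix:
    """Samples x taxa abundance matrix with row metadata.

    ``data``: DataFrame indexed by row id (sample_id, or fish_id for
    per-fish diet matrices) with one column per taxon label at ``rank``.
    ``meta``: row metadata aligned to ``data.index``.
    ``basis``: one of count / count_density / energy / energy_density.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    basis: str
    rank: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.basis not in BASES:
            raise DataModelError(f"invalid basis {self.basis!r}")
        if (self.data.values < 0).any():
            raise DataModelError("assemblage matrix has negative cells")
        if not self.data.index.equals(self.meta.index):
            raise DataModelError("data/meta row index mismatch")

    def copy(self) -> "AssemblageMatrix":
        return AssemblageMatrix(self.data.copy(), self.meta.copy(), self.basis,
                                self.rank, dict(self.provenance))

    def to_tsv(self, path) -> None:
        """Export as TSV with sample metadata columns first."""
        pd.concat([self.meta, self.data], axis=1).to_csv(path, sep="\t",
                                                         index=False)


def build_matrix(sampleset: SampleSet, catalog: TaxonCatalog,
                 basis: str = "count", rank: str = "family",
                 level: str = "sample") -> AssemblageMatrix:
    """Aggregate observations into a wide assemblage matrix.

    Counts (or joules, for energy bases) of all taxon descendants are summed
    into one column per label at ``rank``; density bases divide each row by
    its sampling effort.  ``level="fish"`` builds per-stomach rows for diet
    data.  Samples (or fish) with zero total are retained as all-zero rows.
    """
    if basis not in BASES:
        raise DataModelError(f"invalid basis {basis!r}")
    obs = sampleset.observations
    meta = sampleset.sample_meta()
    if basis in ("energy", "energy_density") and "energy_j" not in obs.columns:
        raise DataModelError(
            "energy basis requires energetics annotation (run annotate_energy)")

    if level == "fish":
        if sampleset.fish is None:
            raise DataModelError("level='fish' requires fish records")
        row_ids = list(sampleset.fish["fish_id"])
        obs = obs[obs["fish_id"].notna()]
        row_key = "fish_id"
        row_meta = sampleset.fish.set_index("fish_id", drop=False).join(
            meta.drop(columns=["sample_id"]), on="sample_id")
        effort = pd.Series(1.0, index=row_ids)
    elif level == "sample":
        row_ids = sampleset.sample_ids()
        row_key = "sample_id"
        row_meta = meta
        effort = meta["effort"].astype(float)
    else:
        raise DataModelError(f"invalid level {level!r}")

    value = obs["energy_j"] if basis in ("energy", "energy_density") \
        else obs["count"].astype(float)
    labels = {}
    unresolved = set()
    for tid in pd.unique(obs["taxon_id"]):
        lab, ok = catalog.label_at_rank(tid, rank)
        labels[tid] = lab
        if not ok:
            unresolved.add(lab)

    tall = pd.DataFrame({
        "row": obs[row_key].values,
        "col": obs["taxon_id"].map(labels).values,
        "value": value.values,
    })
    wide = tall.pivot_table(index="row", columns="col", values="value",
                            aggfunc="sum", fill_value=0.0)
    wide = wide.reindex(index=row_ids, fill_value=0.0)
    wide = wide.reindex(columns=sorted(wide.columns))
    wide.index.name = row_key
    if basis in ("count_density", "energy_density"):
        wide = wide.div(effort.reindex(row_ids).values, axis=0)
    return AssemblageMatrix(
        wide, row_meta.reindex(row_ids), basis, rank,
        provenance={"level": level, "unresolved_labels": sorted(unresolved)})


def pool_sections(matrix: AssemblageMatrix, mapping: Mapping[str, str],
                  seasons: Sequence[str] | None = None) -> AssemblageMatrix:
    """Relabel sections (e.g. {LE,ME} -> LME for spring rows); values untouched.

    ``seasons`` restricts pooling to the given seasons (default: all rows).
    Raises if a pooled label collides with an existing unpooled section.
    """
    out = matrix.copy()
    targets = set(mapping.values())
    existing = set(out.meta["section"]) - set(mapping)
    collide = targets & existing
    if collide:
        raise DataModelError(
            f"pooled label(s) collide with unpooled section(s): {sorted(collide)}")
    rows = out.meta["section"].isin(mapping)
    if seasons is not None:
        rows &= out.meta["season"].isin(set(seasons))
    out.meta.loc[rows, "section"] = out.meta.loc[rows, "section"].map(mapping)
    out.provenance["pooled"] = dict(mapping)
    return out
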