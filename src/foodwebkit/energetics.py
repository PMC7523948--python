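"""Length -> dry mass -> energy conversion with taxonomic fallback.

Invertebrate body measurements (total length or head-capsule width, mm) are
converted to dry mass with the standard power-law model ``DM = a * L**b``
(mg), and dry mass to energy with a per-taxon energy density (J per mg dry
mass).  Conversion coefficients are keyed by a rank-path prefix plus life
stage; lookups resolve at the most specific matching level and fall back
species -> genus -> family -> order -> class, trying the exact life stage at
each level before stage-unspecific entries.  Tables should carry class-level
defaults so every catalogued taxon resolves.

Energy densities expressed per wet mass are supported via the percent dry
mass column: wet mass = DM / pDM, energy = wet * ED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (RANKS, LIFE_STAGES, MEASUREMENT_METRICS, SampleSet,
                         TaxonCatalog, parse_lengths)


class EnergeticsError(ValueError):
    """Unresolvable taxon or inconsistent conversion inputs."""


@dataclass(frozen=True)
class MassRegression:
    """``DM = a * L**b`` with DM in mg and L in mm."""
    metric: str           # total_length | head_capsule_width
    a: float              # mg * mm^-b
    b: float              # dimensionless exponent
    valid_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise EnergeticsError("mass regression requires a > 0 and b > 0")
        if self.metric not in MEASUREMENT_METRICS:
            raise EnergeticsError(f"invalid metric {self.metric!r}")


@dataclass(frozen=True)
class EnergyFactor:
    """Energy density (J per mg) and percent dry mass (fraction of wet)."""
    energy_density: float   # J per mg
    percent_dry_mass: float = 1.0
    basis: str = "dry"      # 'dry': ED per mg dry mass; 'wet': per mg wet mass

    def __post_init__(self):
        if self.energy_density <= 0:
            raise EnergeticsError("energy density must be > 0")
        if not (0 < self.percent_dry_mass <= 1):
            raise EnergeticsError("percent_dry_mass must be in (0, 1]")
        if self.basis not in ("dry", "wet"):
            raise EnergeticsError(f"invalid ED basis {self.basis!r}")


# columns of a conversion table CSV (mirrors the S3/S4 layout: one row per
# rank-path prefix x stage; 'mass' rows carry metric/a/b, 'energy' rows
# carry ed/pdm/ed_basis and an optional default per-individual energy)
CONVERSION_COLUMNS = [
    "kind", *RANKS, "life_stage", "metric", "a", "b", "lmin", "lmax",
    "ed", "pdm", "ed_basis", "default_ind_j",
]


class ConversionTable:
    """Mass-regression and energy-factor entries keyed by rank-path prefix.

    Resolution is deterministic: permuting row order never changes the
    returned entry (ties on key are broken by sorted row content).
    """

    def __init__(self, table: pd.DataFrame):
        t = table.copy()
        for c in CONVERSION_COLUMNS:
            if c not in t.columns:
                t[c] = np.nan
        bad_kind = set(t["kind"]) - {"mass", "energy"}
        if bad_kind:
            raise EnergeticsError(f"invalid kind value(s): {sorted(bad_kind)}")
        t["life_stage"] = t["life_stage"].fillna("unknown").replace("", "unknown")
        bad_stage = set(t["life_stage"]) - LIFE_STAGES
        if bad_stage:
            raise EnergeticsError(f"invalid life_stage value(s): {sorted(bad_stage)}")
        for r in RANKS:
            t[r] = t[r].replace("", np.nan)
        # key depth = finest specified rank (0 = class ... 4 = species)
        depth = np.full(len(t), -1)
        for i, r in enumerate(RANKS):
            depth = np.where(t[r].notna(), i, depth)
        if (depth < 0).any():
            raise EnergeticsError("conversion entries must specify >= 1 rank level")
        t["_depth"] = depth
        # determinism under row permutation
        t = t.sort_values(by=["kind", *RANKS, "life_stage", "metric"],
                          na_position="last", kind="mergesort")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "ConversionTable":
        return cls(pd.read_csv(path, keep_default_na=True, na_values=[""]))

    def _candidates(self, kind: str, path: dict[str, str]) -> pd.DataFrame:
        t = self.table[self.table["kind"] == kind]
        ok = np.ones(len(t), dtype=bool)
        for r in RANKS:
            spec = t[r].notna().to_numpy()
            match = (t[r] == path.get(r)).to_numpy()
            ok &= ~spec | match
        return t[ok]

    def _resolve(self, kind: str, catalog: TaxonCatalog, taxon_id: str,
                 life_stage: str) -> pd.Series:
        path = catalog.rank_path(taxon_id)
        cand = self._candidates(kind, path)
        if len(cand):
            # most specific level first; exact stage beats stage-unspecific
            for depth in range(max(cand["_depth"]), -1, -1):
                for stage in (life_stage, "unknown"):
                    hit = cand[(cand["_depth"] == depth)
                               & (cand["life_stage"] == stage)]
                    if len(hit):
                        row = hit.iloc[0].copy()
                        row["_fallback_rank"] = RANKS[depth]
                        return row
                    if stage == life_stage == "unknown":
                        break
        raise EnergeticsError(
            f"no {kind} conversion entry resolves taxon {taxon_id!r} "
            f"(stage {life_stage!r}); add a class-level default")

    def resolve_factors(self, catalog: TaxonCatalog, taxon_id: str,
                        life_stage: str | None = None,
                        ) -> tuple[MassRegression, EnergyFactor, dict]:
        """Most specific (mass regression, energy factor) for a taxon.

        ``life_stage`` defaults to the catalog's stage for the taxon.
        Returns the pair plus a record of the fallback rank used for each.
        """
        if life_stage is None:
            life_stage = catalog.life_stage(taxon_id)
        m = self._resolve("mass", catalog, taxon_id, life_stage)
        e = self._resolve("energy", catalog, taxon_id, life_stage)
        vr = None
        if pd.notna(m["lmin"]) and pd.notna(m["lmax"]):
            vr = (float(m["lmin"]), float(m["lmax"]))
        reg = MassRegression(metric=m["metric"], a=float(m["a"]),
                             b=float(m["b"]), valid_range=vr)
        ef = EnergyFactor(
            energy_density=float(e["ed"]),
            percent_dry_mass=1.0 if pd.isna(e["pdm"]) else float(e["pdm"]),
            basis="dry" if pd.isna(e["ed_basis"]) else str(e["ed_basis"]))
        default_j = None if pd.isna(e["default_ind_j"]) else float(e["default_ind_j"])
        info = {"mass_fallback_rank": m["_fallback_rank"],
                "energy_fallback_rank": e["_fallback_rank"],
                "default_ind_j": default_j}
        return reg, ef, info


def individual_energy(value_mm: float, reg: MassRegression,
                      ef: EnergyFactor, metric: str | None = None,
                      ) -> tuple[float, float]:
    """Energy of one measured individual: ``(dry mass mg, joules)``.

    Values outside the regression's valid range are still computed, with a
    warning.  ``metric`` (if given) must match the regression's metric.
    """
    if value_mm <= 0:
        raise EnergeticsError("measurement must be > 0 mm")
    if metric is not None and metric != reg.metric:
        raise EnergeticsError(
            f"measurement metric {metric!r} does not match regression "
            f"metric {reg.metric!r}")
    if reg.valid_range is not None:
        lo, hi = reg.valid_range
        if not (lo <= value_mm <= hi):
            warnings.warn(
                f"measurement {value_mm} mm outside regression valid range "
                f"[{lo}, {hi}]", stacklevel=2)
    dm = reg.a * value_mm ** reg.b
    if ef.basis == "wet":
        joules = (dm / ef.percent_dry_mass) * ef.energy_density
    else:
        joules = dm * ef.energy_density
    return dm, joules


def _observation_energies(obs: pd.DataFrame, catalog: TaxonCatalog,
                          table: ConversionTable) -> pd.DataFrame:
    """Per-observation measured energy sums, counts and per-entry defaults."""
    rows = []
    cache: dict[str, tuple] = {}
    for idx, row in obs.iterrows():
        tid = row["taxon_id"]
        if tid not in cache:
            cache[tid] = table.resolve_factors(catalog, tid)
        reg, ef, info = cache[tid]
        lengths = parse_lengths(row.get("lengths_mm"))
        metric = row.get("metric")
        if isinstance(metric, float) and np.isnan(metric):
            metric = None
        energies = [individual_energy(v, reg, ef, metric)[1] for v in lengths]
        rows.append({
            "idx": idx,
            "taxon_id": row["taxon_id"],
            "sample_id": row["sample_id"],
            "count": int(row["count"]),
            "n_measured": len(energies),
            "measured_j": float(np.sum(energies)) if energies else 0.0,
            "default_ind_j": info["default_ind_j"],
        })
    return pd.DataFrame(rows).set_index("idx")


def annotate_energy(sampleset: SampleSet, catalog: TaxonCatalog,
                    table: ConversionTable) -> SampleSet:
    """Attach total joules to every observation.

    Each observation's energy is the sum of its measured individuals plus
    (unmeasured count x an imputed per-individual energy).  Imputation
    chain for unmeasured individuals: mean of measured conspecifics in the
    same sample -> taxon-level mean across the whole sample set ->
    order-level mean -> the conversion table's per-taxon default -> error.
    """
    obs = sampleset.observations.copy()
    if len(obs) == 0:
        obs["energy_j"] = pd.Series(dtype=float)
        return SampleSet(sampleset.samples.copy(), obs,
                         None if sampleset.fish is None else sampleset.fish.copy())
    per = _observation_energies(obs, catalog, table)

    def _mean(measured_j, n_measured):
        n = n_measured.sum()
        return measured_j.sum() / n if n > 0 else np.nan

    sample_taxon_mean = per.groupby(["sample_id", "taxon_id"]).apply(
        lambda g: _mean(g["measured_j"], g["n_measured"]), include_groups=False)
    taxon_mean = per.groupby("taxon_id").apply(
        lambda g: _mean(g["measured_j"], g["n_measured"]), include_groups=False)
    per["order"] = [catalog.rank_path(t).get("order") for t in per["taxon_id"]]
    order_mean = per.dropna(subset=["order"]).groupby("order").apply(
        lambda g: _mean(g["measured_j"], g["n_measured"]), include_groups=False)

    energy = np.zeros(len(per))
    for i, (idx, row) in enumerate(per.iterrows()):
        unmeasured = row["count"] - row["n_measured"]
        total = row["measured_j"]
        if unmeasured > 0:
            imputed = sample_taxon_mean.get((row["sample_id"], row["taxon_id"]),
                                            np.nan)
            if np.isnan(imputed):
                imputed = taxon_mean.get(row["taxon_id"], np.nan)
            if np.isnan(imputed) and pd.notna(row["order"]):
                imputed = order_mean.get(row["order"], np.nan)
            if np.isnan(imputed) and row["default_ind_j"] is not None:
                imputed = row["default_ind_j"]
            if np.isnan(imputed):
                raise EnergeticsError(
                    f"taxon {row['taxon_id']!r}: no measured individuals "
                    "anywhere and no default per-individual energy")
            total += unmeasured * imputed
        energy[i] = total
    obs["energy_j"] = pd.Series(energy, index=per.index)
    return SampleSet(sampleset.samples.copy(), obs,
                     None if sampleset.fish is None else sampleset.fish.copy())


def energy_density(sampleset: SampleSet, sample_id: str) -> float:
    """Per-sample energy density: total joules / effort.

    Units follow the sample's gear: J/m^3 for drift, kJ/m^2 for estuary
    benthic and fallout gears (matching the field's reporting convention),
    J per fish for diet events.
    """
    obs = sampleset.observations
    if "energy_j" not in obs.columns:
        raise EnergeticsError("sample set lacks energetics annotation")
    meta = sampleset.sample_meta().loc[sample_id]
    total = obs.loc[obs["sample_id"] == sample_id, "energy_j"].sum()
    dens = total / float(meta["effort"])
    if meta["effort_unit"] == "m2":
        dens /= 1000.0  # report kJ/m^2
    return float(dens)
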