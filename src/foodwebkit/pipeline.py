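"""End-to-end orchestration of the disturbance food-web analysis.

``run_pipeline`` reproduces the standard analysis sequence on an ingested
or simulated data set: univariate metrics with ANOVA/Tukey letters,
resemblance matrices, PERMANOVA main and pairwise tests, ANOSIM pooling
checks, SIMPER decompositions for significant year pairs, nMDS ordination
with centroid trajectories, and IRI/selectivity tables.  Outputs are a
pure function of (inputs, config, seed); every result carries the seed and
permutation counts in its log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data_model as dm
from . import energetics as en
from . import metrics as me
from . import permstats as ps
from . import resemblance as rs
from . import selectivity as sel


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``transform`` defaults follow the convention square-root for drift
    density and fourth-root for everything else; pooling of LE+ME into LME
    for spring rows mirrors the reduced spring sampling design and can be
    disabled.
    """

    seed: int = 0
    n_perm: int = 999
    alpha: float = 0.05
    dummy_value: float = 0.1
    transform_drift: str = "sqrt"
    transform_other: str = "fourth_root"
    rank: str = "family"
    pool_spring_lme: bool = True
    anosim_pooling_checks: bool = True
    group_by: Sequence[str] = ("section", "season", "period")
    output_dir: str | None = None


def _transform_for(config: RunConfig, gear: str) -> str:
    return config.transform_drift if gear == "drift" else config.transform_other


def _prepared_matrix(sampleset: dm.SampleSet, catalog: dm.TaxonCatalog,
                     config: RunConfig, basis: str, level: str = "sample",
                     ) -> tuple[dm.AssemblageMatrix, pd.DataFrame]:
    mat = dm.build_matrix(sampleset, catalog, basis=basis, rank=config.rank,
                          level=level)
    if config.pool_spring_lme and {"LE", "ME"} <= set(mat.meta["section"]):
        mat = dm.pool_sections(mat, {"LE": "LME", "ME": "LME"},
                               seasons=["spring"])
    gear = mat.meta["gear"].iloc[0] if len(mat.meta) else "drift"
    kind = _transform_for(config, gear)
    data = rs.transform(rs.add_dummy(mat.data, config.dummy_value), kind)
    return mat, data


def _permanova_block(data: pd.DataFrame, meta: pd.DataFrame,
                     config: RunConfig, rng: np.random.Generator) -> dict:
    """Per-season PERMANOVA (crossed year x section when possible) with
    pairwise year tests inside each section, plus SIMPER for significant
    pairs."""
    out = {}
    for season, rows in meta.groupby("season", observed=True):
        idx = rows.index
        if len(idx) < 6:
            continue
        sub = data.loc[idx]
        dis = rs.bray_curtis(sub, as_="dissimilarity")
        design = rows[["period"]].copy()
        crossed = rows["section"].nunique() >= 2
        if crossed:
            design["section"] = rows["section"]
        if design["period"].nunique() < 2:
            continue
        try:
            main = ps.permanova(dis, design, n_perm=config.n_perm,
                                seed=int(rng.integers(2 ** 31 - 1)))
        except ps.PermStatsError as exc:
            raise PipelineError(f"permanova failed for season {season}: {exc}")
        season_out = {"main": main, "pairwise": {}, "simper": {}}
        labels = rows["period"].to_numpy()
        for section, srows in rows.groupby("section", observed=True):
            if srows["period"].nunique() < 2:
                continue
            mask = np.isin(np.arange(len(idx)), [idx.get_loc(i)
                                                 for i in srows.index])
            pw = ps.pairwise(dis, labels, n_perm=config.n_perm,
                             seed=int(rng.integers(2 ** 31 - 1)),
                             alpha_family=config.alpha, slice_mask=mask)
            season_out["pairwise"][section] = pw
            for res in pw:
                if res.significant:
                    sl = srows[srows["period"].isin([res.group_a,
                                                     res.group_b])]
                    season_out["simper"][(section, res.group_a,
                                          res.group_b)] = ps.simper(
                        data.loc[sl.index], sl["period"],
                        res.group_a, res.group_b)
        out[season] = season_out
    return out


def _ordination_block(data: pd.DataFrame, meta: pd.DataFrame,
                      config: RunConfig, rng: np.random.Generator) -> dict:
    out = {}
    for season, rows in meta.groupby("season", observed=True):
        if len(rows) < 4:
            continue
        dis = rs.bray_curtis(data.loc[rows.index], as_="dissimilarity")
        nm = ps.nmds(dis, k=2, restarts=4,
                     seed=int(rng.integers(2 ** 31 - 1)))
        cm = rs.centroid_matrix(
            dis, list(zip(rows["section"], rows["period"])))
        out[season] = {
            "coordinates": pd.DataFrame(nm.coordinates, index=rows.index,
                                        columns=["MDS1", "MDS2"]),
            "stress": nm.stress,
            "stress_acceptable": nm.stress <= 0.2,
            "centroids": cm,
            "trajectories": rs.centroid_trajectories(cm),
        }
    return out


def run_pipeline(community: dm.SampleSet, catalog: dm.TaxonCatalog,
                 config: RunConfig,
                 conversions: en.ConversionTable | None = None,
                 diet: dm.SampleSet | None = None) -> dict:
    """Run the full analysis sequence; returns a result bundle dict.

    Stages: (1) univariate metric tables with ANOVA/Tukey letters; (2)
    resemblance matrices; (3) PERMANOVA main + pairwise + SIMPER; (4)
    ANOSIM pooling checks on diet data (species, age class); (5) nMDS +
    centroid trajectories; (6) IRI / selectivity tables (when diets are
    present).  Any stage failure aborts with the stage name.
    """
    rng = np.random.default_rng(config.seed)
    bundle: dict = {"log": {"seed": config.seed, "n_perm": config.n_perm,
                            "warnings": []}}

    stage = "energetics"
    try:
        if conversions is not None:
            community = en.annotate_energy(community, catalog, conversions)
            if diet is not None:
                diet = en.annotate_energy(diet, catalog, conversions)

        stage = "univariate"
        stab = me.sample_metrics_table(community, catalog)
        bundle["sample_metrics"] = stab
        bundle["sample_summary"] = {
            m: me.group_summary(stab, m, by=config.group_by)
            for m in ("numeric_density", "taxa_richness", "terrestrial_pct")
            if stab[m].notna().any()}
        bundle["anova"] = {}
        for m in ("numeric_density", "taxa_richness", "terrestrial_pct"):
            for season, srows in stab.groupby("season", observed=True):
                try:
                    key = f"{m}|{season}"
                    two_way = srows["section"].nunique() >= 2
                    bundle["anova"][key] = me.anova_tukey(
                        srows, m, ["period", "section"],
                        design="two_way" if two_way else "one_way",
                        alpha=config.alpha)
                except me.MetricsError as exc:
                    bundle["log"]["warnings"].append(f"anova {key}: {exc}")
        if diet is not None:
            bundle["diet_metrics"] = me.diet_metrics_table(diet, catalog)

        stage = "resemblance"
        basis = "count_density" if conversions is None else "energy_density"
        mat, data = _prepared_matrix(community, catalog, config, basis)
        bundle["community_matrix"] = mat
        bundle["community_resemblance"] = rs.bray_curtis(
            data, as_="similarity")

        stage = "permanova"
        bundle["permanova"] = _permanova_block(data, mat.meta, config, rng)

        stage = "anosim"
        bundle["anosim"] = {}
        if diet is not None and config.anosim_pooling_checks:
            dmat = dm.build_matrix(diet, catalog, basis="count",
                                   rank=config.rank, level="fish")
            nonempty = ~dmat.meta["empty_stomach"].astype(bool)
            ddata = rs.transform(rs.add_dummy(dmat.data[nonempty],
                                              config.dummy_value),
                                 config.transform_other)
            ddis = rs.bray_curtis(ddata, as_="dissimilarity")
            for factor in ("species", "age_class"):
                labels = dmat.meta.loc[nonempty, factor]
                if labels.nunique() < 2:
                    continue
                res = ps.anosim(ddis, labels, n_perm=min(config.n_perm, 999),
                                seed=int(rng.integers(2 ** 31 - 1)))
                bundle["anosim"][factor] = {
                    "R": res.r, "P": res.p,
                    "pool": res.p > config.alpha or abs(res.r) < 0.25}

        stage = "ordination"
        bundle["ordination"] = _ordination_block(data, mat.meta, config, rng)

        stage = "selectivity"
        if diet is not None and conversions is not None:
            env_iri = sel.iri_by_group(community, catalog, "environment")
            diet_iri = sel.iri_by_group(diet, catalog, "diet")
            bundle["iri"] = {"environment": env_iri, "diet": diet_iri}
            coords = {}
            if len(env_iri) and len(diet_iri):
                keys = ["section", "season", "period"]
                for key, erows in env_iri.groupby(keys, observed=True):
                    drows = diet_iri[
                        (diet_iri[keys] == pd.Series(key, index=keys)).all(axis=1)]
                    if not len(drows):
                        continue
                    coords[key] = sel.classify_selection(
                        sel.selectivity_coords(erows, drows))
            bundle["selectivity"] = coords
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if config.output_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["sample_metrics"].to_csv(out / "sample_metrics.tsv", sep="\t",
                                    index=False)
    for name, tab in bundle.get("sample_summary", {}).items():
        tab.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
    bundle["community_resemblance"].to_tsv(out / "resemblance.tsv")
    perm = {}
    for season, blk in bundle.get("permanova", {}).items():
        perm[season] = {
            "main": blk["main"].table().to_dict(orient="records"),
            "pairwise": {
                sec: [vars(r) for r in pw]
                for sec, pw in blk["pairwise"].items()},
        }
    (out / "permanova.json").write_text(json.dumps(perm, indent=2,
                                                   default=str))
    for season, blk in bundle.get("ordination", {}).items():
        blk["coordinates"].to_csv(out / f"nmds_{season}.tsv", sep="\t")
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2,
                                                default=str))
    (out / "log.json").write_text(json.dumps(bundle["log"], indent=2,
                                             default=str))
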