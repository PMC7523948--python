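"""Synthetic invertebrate communities and fish diets with known structure.

The generator emulates a multi-year disturbance monitoring design: river
sections (impacted and reference), two seasons, a pre-disturbance period
and three disturbance years.  Per-taxon baseline densities are log-normal
(a standard overdispersed community model); sample counts are Poisson in
``effort x density x disturbance factor``, where the disturbance factor is
a per-section x period multiplier on aquatic taxa (e.g. 0.04 imposes a 96%
decline) and terrestrial taxa can be enriched instead.  Diets draw a
negative-binomial number of prey per stomach, composed multinomially with
probability proportional to availability times a per-Order selectivity
weight.  Ground truth (factors, weights, lost taxa, baselines) is always
returned alongside — and written to a JSON sidecar on export — so analyses
can be checked against what was imposed.

All randomness flows from a single seed: the same seed reproduces the
sample set bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import SampleSet, TaxonCatalog, write_tables
from .energetics import ConversionTable

# (class, order, family, origin) pools; families are drawn in order
AQUATIC_POOL = [
    ("Insecta", "Ephemeroptera", "Baetidae"),
    ("Insecta", "Ephemeroptera", "Heptageniidae"),
    ("Insecta", "Ephemeroptera", "Ephemerellidae"),
    ("Insecta", "Plecoptera", "Chloroperlidae"),
    ("Insecta", "Plecoptera", "Nemouridae"),
    ("Insecta", "Plecoptera", "Perlodidae"),
    ("Insecta", "Trichoptera", "Hydropsychidae"),
    ("Insecta", "Trichoptera", "Limnephilidae"),
    ("Insecta", "Trichoptera", "Glossosomatidae"),
    ("Insecta", "Diptera", "Chironomidae"),
    ("Insecta", "Diptera", "Simuliidae"),
    ("Insecta", "Diptera", "Tipulidae"),
    ("Insecta", "Coleoptera", "Elmidae"),
    ("Insecta", "Megaloptera", "Sialidae"),
    ("Clitellata", "Haplotaxida", "Naididae"),
    ("Malacostraca", "Amphipoda", "Corophiidae"),
    ("Ostracoda", "Podocopida", "Cyprididae"),
    ("Arachnida", "Trombidiformes", "Hydrachnidae"),
]
TERRESTRIAL_POOL = [
    ("Insecta", "Hemiptera", "Aphididae"),
    ("Insecta", "Hemiptera", "Cicadellidae"),
    ("Insecta", "Lepidoptera", "Tortricidae"),
    ("Insecta", "Hymenoptera", "Formicidae"),
    ("Insecta", "Coleoptera", "Carabidae"),
    ("Insecta", "Psocodea", "Psocidae"),
    ("Arachnida", "Araneae", "Linyphiidae"),
    ("Collembola", "Entomobryomorpha", "Entomobryidae"),
]

PERIOD_ORDER = ("Pre", "2012", "2013", "2014")


@dataclass
class SimParams:
    """Generator settings; defaults emulate a drift-sampling field design."""

    n_aquatic: int = 18
    n_terrestrial: int = 8
    sections: Sequence[str] = ("LE", "ME", "TR")
    seasons: Sequence[str] = ("spring", "summer")
    periods: Sequence[str] = PERIOD_ORDER
    samples_per_cell: int = 8          # site sample events per section/season/period
    effort_mean_m3: float = 30.0       # drift volume filtered per event
    effort_sigma: float = 0.3
    total_aquatic_density: float = 9.0    # expected No/m^3 summed over aquatic taxa
    total_terrestrial_density: float = 0.9
    density_sigma: float = 1.0         # log-normal spread of per-taxon baselines
    #: (section, period) -> multiplier on aquatic taxon density
    disturbance: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        ("LE", "2012"): 0.15, ("LE", "2013"): 0.04, ("LE", "2014"): 0.5,
        ("ME", "2013"): 0.7, ("ME", "2014"): 0.8,
    })
    #: (section, period) -> multiplier on terrestrial taxon density
    terrestrial_enrichment: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("LE", "2012"): 2.5, ("LE", "2013"): 2.0})
    #: per-period probability that an aquatic family drops out entirely
    taxon_loss_prob: Mapping[str, float] = field(default_factory=dict)
    # diets
    fish_per_event: int = 5
    prey_nb_r: float = 3.0             # negative-binomial shape
    prey_mean: float = 15.0            # mean prey items per non-empty stomach
    empty_prob: float = 0.05
    #: Order -> relative feeding weight (unlisted Orders get 1.0)
    selectivity_weights: Mapping[str, float] = field(default_factory=dict)
    diet_measured_fraction: float = 0.6  # prey individuals measurable (digestion)

    def __post_init__(self):
        if self.n_aquatic + self.n_terrestrial == 0:
            raise ValueError("need at least one taxon")
        if self.n_aquatic > len(AQUATIC_POOL) * 3 \
                or self.n_terrestrial > len(TERRESTRIAL_POOL) * 3:
            raise ValueError("taxon pool exhausted")
        for p, v in self.taxon_loss_prob.items():
            if not 0 <= v <= 1:
                raise ValueError("taxon_loss_prob must be in [0, 1]")
        if not 0 <= self.empty_prob <= 1:
            raise ValueError("empty_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    baseline_density: dict        # taxon_id -> No/m^3
    disturbance: dict             # "section|period" -> factor
    terrestrial_enrichment: dict
    lost_taxa: dict               # period -> [taxon_id]
    selectivity_weights: dict | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _build_catalog(params: SimParams) -> pd.DataFrame:
    rows = []
    for origin, pool, n in (("aquatic", AQUATIC_POOL, params.n_aquatic),
                            ("terrestrial", TERRESTRIAL_POOL,
                             params.n_terrestrial)):
        for i in range(n):
            cls, order, family = pool[i % len(pool)]
            suffix = "" if i < len(pool) else f"_{i // len(pool) + 1}"
            tid = f"{family}{suffix}_{origin[0]}"
            rows.append({"taxon_id": tid, "class": cls, "order": order,
                         "family": family + suffix, "genus": np.nan,
                         "species": np.nan, "origin": origin,
                         "life_stage": "larva" if origin == "aquatic" else "adult"})
    return pd.DataFrame(rows)


def make_conversion_table(catalog: TaxonCatalog,
                          seed: int | None = 0) -> ConversionTable:
    """Family-level power-law mass regressions and energy densities, plus
    class-level defaults, drawn once from realistic invertebrate ranges."""
    rng = np.random.default_rng(seed)
    rows = []
    seen_classes = set()
    for tid in catalog.taxon_ids:
        path = catalog.rank_path(tid)
        terrestrial = catalog.origin(tid) == "terrestrial"
        rows.append({"kind": "mass", "class": path["class"],
                     "order": path["order"], "family": path["family"],
                     "life_stage": "unknown", "metric": "total_length",
                     "a": rng.uniform(0.002, 0.01),
                     "b": rng.uniform(2.2, 3.0)})
        rows.append({"kind": "energy", "class": path["class"],
                     "order": path["order"], "family": path["family"],
                     "life_stage": "unknown",
                     "ed": rng.uniform(22, 30) if terrestrial
                     else rng.uniform(18, 26),
                     "pdm": rng.uniform(0.15, 0.35),
                     # keeps digested (unmeasurable) diet items convertible
                     "default_ind_j": rng.uniform(3, 8)})
        if path["class"] not in seen_classes:
            seen_classes.add(path["class"])
            rows.append({"kind": "mass", "class": path["class"],
                         "life_stage": "unknown", "metric": "total_length",
                         "a": 0.005, "b": 2.6})
            rows.append({"kind": "energy", "class": path["class"],
                         "life_stage": "unknown", "ed": 22.0, "pdm": 0.25,
                         "default_ind_j": 5.0})
    return ConversionTable(pd.DataFrame(rows))


def _taxon_lengths(catalog: TaxonCatalog, rng) -> dict[str, float]:
    out = {}
    for tid in catalog.taxon_ids:
        lo, hi = (3.0, 10.0) if catalog.origin(tid) == "terrestrial" else (2.0, 8.0)
        out[tid] = rng.uniform(lo, hi)
    return out


def simulate_community(params: SimParams, seed: int,
                       ) -> tuple[TaxonCatalog, SampleSet, GroundTruth]:
    """Draw a full multi-section, multi-period community sample set.

    Returns the taxon catalog, the environmental sample set (drift gear),
    and the imposed ground truth.
    """
    rng = np.random.default_rng(seed)
    catalog = TaxonCatalog(_build_catalog(params))
    taxa = catalog.taxon_ids
    origin = {t: catalog.origin(t) for t in taxa}

    n_a = max(params.n_aquatic, 1)
    n_t = max(params.n_terrestrial, 1)
    mu_a = np.log(params.total_aquatic_density / n_a) \
        - params.density_sigma ** 2 / 2
    mu_t = np.log(max(params.total_terrestrial_density, 1e-9) / n_t) \
        - params.density_sigma ** 2 / 2
    baseline = {
        t: float(rng.lognormal(mu_a if origin[t] == "aquatic" else mu_t,
                               params.density_sigma))
        for t in taxa}
    mean_len = _taxon_lengths(catalog, rng)

    lost: dict[str, list[str]] = {}
    for period in params.periods:
        prob = params.taxon_loss_prob.get(period, 0.0)
        lost[period] = [t for t in taxa
                        if origin[t] == "aquatic" and rng.random() < prob]

    samples, observations = [], []
    for section in params.sections:
        for season in params.seasons:
            for period in params.periods:
                f_aq = params.disturbance.get((section, period), 1.0)
                f_te = params.terrestrial_enrichment.get((section, period), 1.0)
                for i in range(params.samples_per_cell):
                    sid = f"{section}-{season[:3]}-{period}-s{i:02d}"
                    effort = float(rng.lognormal(
                        np.log(params.effort_mean_m3)
                        - params.effort_sigma ** 2 / 2, params.effort_sigma))
                    samples.append({
                        "sample_id": sid, "section": section,
                        "season": season, "period": period,
                        "habitat": "tributary" if section == "TR" else "mainstem",
                        "gear": "drift", "effort": effort, "effort_unit": "m3"})
                    for t in taxa:
                        if t in lost[period]:
                            continue
                        factor = f_aq if origin[t] == "aquatic" else f_te
                        lam = effort * baseline[t] * factor
                        count = int(rng.poisson(lam))
                        if count == 0:
                            continue
                        lengths = rng.lognormal(np.log(mean_len[t]), 0.25,
                                                size=count)
                        observations.append({
                            "sample_id": sid, "fish_id": np.nan,
                            "taxon_id": t, "count": count,
                            "metric": "total_length",
                            "lengths_mm": ";".join(f"{v:.3f}" for v in lengths)})
    sampleset = SampleSet(pd.DataFrame(samples),
                          pd.DataFrame(observations,
                                       columns=["sample_id", "fish_id",
                                                "taxon_id", "count", "metric",
                                                "lengths_mm"]))
    truth = GroundTruth(
        baseline_density=baseline,
        disturbance={f"{s}|{p}": float(v)
                     for (s, p), v in params.disturbance.items()},
        terrestrial_enrichment={f"{s}|{p}": float(v)
                                for (s, p), v in
                                params.terrestrial_enrichment.items()},
        lost_taxa=lost)
    return catalog, sampleset, truth


def simulate_diets(availability: SampleSet, catalog: TaxonCatalog,
                   params: SimParams, seed: int,
                   ) -> tuple[SampleSet, GroundTruth]:
    """Draw fish stomachs feeding on a simulated availability sample set.

    One diet sample event is created per availability event; each fish
    draws its prey multinomially with probability proportional to the
    event's availability counts times the per-Order selectivity weight.
    A taxon with weight 0 never appears in diets; all-zero availability
    yields an (extra) empty stomach.
    """
    rng = np.random.default_rng(seed)
    weights = dict(params.selectivity_weights)
    order_of = {t: catalog.rank_path(t).get("order") for t in catalog.taxon_ids}
    mean_len = _taxon_lengths(catalog, np.random.default_rng(seed + 1))

    avail_obs = availability.observations
    samples, fish_rows, observations = [], [], []
    p_nb = params.prey_nb_r / (params.prey_nb_r + params.prey_mean)
    for _, ev in availability.samples.iterrows():
        sid = f"D-{ev['sample_id']}"
        samples.append({"sample_id": sid, "section": ev["section"],
                        "season": ev["season"], "period": ev["period"],
                        "habitat": ev["habitat"], "gear": "diet",
                        "effort": params.fish_per_event,
                        "effort_unit": "per_fish"})
        sub = avail_obs[avail_obs["sample_id"] == ev["sample_id"]]
        taxa = list(sub["taxon_id"])
        avail = sub["count"].to_numpy(dtype=float)
        w = np.array([weights.get(order_of[t], 1.0) for t in taxa])
        probs = avail * w
        total = probs.sum()
        for j in range(params.fish_per_event):
            fid = f"{sid}-f{j}"
            fl = float(rng.uniform(45, 160))
            empty = rng.random() < params.empty_prob or total <= 0
            fish_rows.append({"fish_id": fid, "sample_id": sid,
                              "species": "O. mykiss",
                              "fork_length_mm": round(fl, 1),
                              "mass_g": round(0.00001 * fl ** 3, 2),
                              "empty_stomach": bool(empty)})
            if empty:
                continue
            n_prey = int(rng.negative_binomial(params.prey_nb_r, p_nb)) + 1
            counts = rng.multinomial(n_prey, probs / total)
            for t, c in zip(taxa, counts):
                if c == 0:
                    continue
                n_meas = int(rng.binomial(c, params.diet_measured_fraction))
                lengths = rng.lognormal(np.log(mean_len[t]), 0.25, size=n_meas)
                observations.append({
                    "sample_id": sid, "fish_id": fid, "taxon_id": t,
                    "count": int(c),
                    "metric": "total_length" if n_meas else np.nan,
                    "lengths_mm": ";".join(f"{v:.3f}" for v in lengths)})
    diet = SampleSet(pd.DataFrame(samples),
                     pd.DataFrame(observations,
                                  columns=["sample_id", "fish_id", "taxon_id",
                                           "count", "metric", "lengths_mm"]),
                     pd.DataFrame(fish_rows))
    if diet.fish is not None:
        diet.fish["age_class"] = np.where(
            diet.fish["fork_length_mm"] <= 70, "YOY", "one_plus")
    truth = GroundTruth(baseline_density={}, disturbance={},
                        terrestrial_enrichment={}, lost_taxa={},
                        selectivity_weights={
                            o: float(weights.get(o, 1.0))
                            for o in set(order_of.values())})
    return diet, truth


def export(catalog: TaxonCatalog, community: SampleSet, truth: GroundTruth,
           out_dir, diet: SampleSet | None = None,
           conversions: ConversionTable | None = None) -> dict:
    """Write the simulated study to the CSV schema ``load_tables`` ingests,
    with the ground truth as a JSON sidecar."""
    out = Path(out_dir)
    paths = write_tables(catalog, community, out, prefix="env_")
    if diet is not None:
        paths.update({f"diet_{k}": v for k, v in
                      write_tables(catalog, diet, out, prefix="diet_").items()})
    if conversions is not None:
        p = out / "conversions.csv"
        conversions.table.drop(columns=["_depth"]).to_csv(p, index=False)
        paths["conversions"] = p
    truth_path = out / "ground_truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
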