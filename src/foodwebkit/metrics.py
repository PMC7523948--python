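"""Univariate sample and diet metrics, group summaries, percent change,
and the fixed-factor ANOVA + Tukey HSD contract.

Metrics follow the field conventions for prey-availability monitoring:
numeric density (individuals per m^2 or m^3), energy density (kJ/m^2 for
areal gears, J/m^3 for drift), taxa richness at the finest identified
level, and the percentage of terrestrial-origin individuals (or energy).
Headline disturbance effects are expressed as percent declines between a
pre-disturbance mean and a during-disturbance mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data_model import SampleSet, TaxonCatalog


class MetricsError(ValueError):
    pass


@dataclass
class SampleMetrics:
    sample_id: str
    numeric_density: float      # No/m^2 or No/m^3
    energy_density: float | None  # kJ/m^2 (areal) or J/m^3 (drift); None if unannotated
    taxa_richness: int
    terrestrial_pct: float      # 0-100
    terrestrial_pct_defined: bool  # False when the sample grand total is zero


@dataclass
class DietMetrics:
    fish_id: str
    prey_items: int
    prey_richness: int
    prey_energy_kj: float | None
    terrestrial_pct: float      # of total kJ (count basis if unannotated)
    terrestrial_pct_defined: bool
    empty: bool


def _terrestrial_pct(values: pd.Series, origins: pd.Series) -> tuple[float, bool]:
    total = float(values.sum())
    if total <= 0:
        return 0.0, False
    terr = float(values[origins == "terrestrial"].sum())
    return 100.0 * terr / total, True


def sample_metrics(sampleset: SampleSet, catalog: TaxonCatalog,
                   sample_id: str,
                   terrestrial_basis: str = "count") -> SampleMetrics:
    """Numeric/energy density, richness and terrestrial percentage of a sample.

    Richness counts unique taxa at the finest identified level.  A sample
    with zero grand total reports terrestrial_pct = 0 flagged undefined.
    """
    obs = sampleset.observations
    sub = obs[(obs["sample_id"] == sample_id)]
    meta = sampleset.sample_meta().loc[sample_id]
    effort = float(meta["effort"])
    annotated = "energy_j" in obs.columns
    if terrestrial_basis == "energy" and not annotated:
        raise MetricsError("terrestrial_basis='energy' requires annotation")

    count_total = int(sub["count"].sum())
    numeric_density = count_total / effort
    edens = None
    if annotated:
        edens = float(sub["energy_j"].sum()) / effort
        if meta["effort_unit"] == "m2":
            edens /= 1000.0
    richness = int(sub.loc[sub["count"] > 0, "taxon_id"].nunique())
    origins = sub["taxon_id"].map(catalog.origin)
    vals = sub["energy_j"] if terrestrial_basis == "energy" \
        else sub["count"].astype(float)
    pct, defined = _terrestrial_pct(vals, origins)
    return SampleMetrics(sample_id, numeric_density, edens, richness, pct,
                         defined)


def diet_metrics(sampleset: SampleSet, catalog: TaxonCatalog,
                 fish_id: str) -> DietMetrics:
    """Per-stomach prey items, richness, total prey energy and terrestrial %."""
    if sampleset.fish is None:
        raise MetricsError("sample set has no fish records")
    frow = sampleset.fish.set_index("fish_id").loc[fish_id]
    obs = sampleset.observations
    sub = obs[obs["fish_id"] == fish_id]
    annotated = "energy_j" in obs.columns
    prey_items = int(sub["count"].sum())
    richness = int(sub.loc[sub["count"] > 0, "taxon_id"].nunique())
    origins = sub["taxon_id"].map(catalog.origin)
    if annotated:
        kj = float(sub["energy_j"].sum()) / 1000.0
        pct, defined = _terrestrial_pct(sub["energy_j"], origins)
    else:
        kj = None
        pct, defined = _terrestrial_pct(sub["count"].astype(float), origins)
    return DietMetrics(fish_id, prey_items, richness, kj, pct, defined,
                       empty=bool(frow["empty_stomach"]))


def sample_metrics_table(sampleset: SampleSet, catalog: TaxonCatalog,
                         terrestrial_basis: str = "count") -> pd.DataFrame:
    """Per-sample metrics joined with sample metadata (one row per sample)."""
    meta = sampleset.sample_meta()
    rows = []
    for sid in sampleset.sample_ids():
        m = sample_metrics(sampleset, catalog, sid, terrestrial_basis)
        rows.append({**meta.loc[sid,
                                ["sample_id", "section", "season", "period",
                                 "habitat", "gear"]].to_dict(),
                     "numeric_density": m.numeric_density,
                     "energy_density": m.energy_density,
                     "taxa_richness": m.taxa_richness,
                     "terrestrial_pct": m.terrestrial_pct})
    return pd.DataFrame(rows)


def diet_metrics_table(sampleset: SampleSet,
                       catalog: TaxonCatalog) -> pd.DataFrame:
    """Per-fish diet metrics joined with the fish's sample metadata."""
    meta = sampleset.sample_meta()
    rows = []
    for fid in sampleset.fish["fish_id"]:
        m = diet_metrics(sampleset, catalog, fid)
        srow = sampleset.fish.set_index("fish_id").loc[fid]
        smeta = meta.loc[srow["sample_id"]]
        rows.append({"fish_id": fid, "sample_id": srow["sample_id"],
                     "section": smeta["section"], "season": smeta["season"],
                     "period": smeta["period"],
                     "age_class": srow.get("age_class"),
                     "species": srow.get("species"),
                     "prey_items": m.prey_items,
                     "prey_richness": m.prey_richness,
                     "prey_energy_kj": m.prey_energy_kj,
                     "terrestrial_pct": m.terrestrial_pct,
                     "empty": m.empty})
    return pd.DataFrame(rows)


def group_summary(table: pd.DataFrame, value: str,
                  by: Sequence[str] = ("section", "season", "period"),
                  ) -> pd.DataFrame:
    """Mean +/- sample SD (n-1 denominator) and n per group.

    Groups of n = 1 report SD as missing (NaN); empty groups are omitted.
    """
    by = list(by)
    if not set(by) <= set(table.columns):
        raise MetricsError(f"grouping columns {by} not all present")
    out = (table.dropna(subset=[value])
           .groupby(by, observed=True)[value]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
           .reset_index())
    return out[out["n"] > 0].reset_index(drop=True)


def percent_change(pre_mean: float, during_mean: float,
                   digits: int | None = None) -> float:
    """Percent decline ``100 * (1 - during/pre)``; positive = decline.

    ``digits=0`` rounds to the nearest whole percent, the convention for
    reporting headline declines.
    """
    if pre_mean <= 0:
        raise MetricsError("percent_change undefined for pre_mean <= 0")
    pc = 100.0 * (1.0 - during_mean / pre_mean)
    if digits is not None:
        pc = round(pc, digits) if digits > 0 else float(round(pc))
    return pc


TRANSFORMS = {
    "none": lambda x, c=0.0: np.asarray(x, dtype=float),
    "log10_plus": lambda x, c=1.0: np.log10(np.asarray(x, dtype=float) + c),
    "arcsine_sqrt": lambda x, c=0.0: np.arcsin(
        np.sqrt(np.asarray(x, dtype=float) / 100.0)),
}


def _compact_letters(levels: Sequence[str],
                     differ: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display from an all-pairs 'significantly different' map.

    Insert-and-absorb algorithm: maintain letter groups (sets of levels that
    are mutually non-different); every level gets the letters of all groups
    containing it.
    """
    groups: list[set[str]] = [set(levels)]
    for (a, b), sig in differ.items():
        if not sig:
            continue
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            ga, gb = g - {b}, g - {a}
            for cand in (ga, gb):
                if not any(cand <= other for other in groups):
                    groups.append(cand)
    groups.sort(key=lambda g: min(list(levels).index(x) for x in g))
    letters = {lv: "" for lv in levels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for lv in sorted(g, key=list(levels).index):
            letters[lv] += ch
    return letters


def anova_tukey(table: pd.DataFrame, value: str, factors: Sequence[str],
                design: str = "one_way", alpha: float = 0.05,
                transform: str = "none") -> dict:
    """Fixed-factor ANOVA with Tukey HSD letters on significant terms.

    ``design='one_way'`` uses the first factor; ``'two_way'`` fits both
    factors plus their interaction.  The optional transformation (one of
    ``none``, ``log10_plus``, ``arcsine_sqrt``) is applied to the response
    before testing.  Returns ``{"anova": effect table, "tukey": {term:
    pairwise frame}, "letters": {term: compact letter display}}``.
    """
    if design not in ("one_way", "two_way"):
        raise MetricsError(f"invalid design {design!r}")
    factors = list(factors)[: (1 if design == "one_way" else 2)]
    if design == "two_way" and len(factors) < 2:
        raise MetricsError("two_way design needs two factors")
    df = table.dropna(subset=[value, *factors]).copy()
    df["_y"] = TRANSFORMS[transform](df[value].to_numpy())
    for f in factors:
        if df[f].nunique() < 2:
            raise MetricsError(f"factor {f!r} needs >= 2 levels")
    if design == "one_way":
        formula = f"_y ~ C({factors[0]})"
        typ = 2
    else:
        formula = (f"_y ~ C({factors[0]}, Sum) * C({factors[1]}, Sum)")
        typ = 3
    fit = smf.ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=typ)
    if "Intercept" in aov.index:
        aov = aov.drop(index="Intercept")

    tukey_out, letters_out = {}, {}
    term_groups = {factors[0]: df[factors[0]].astype(str)}
    if design == "two_way":
        term_groups[factors[1]] = df[factors[1]].astype(str)
        term_groups["interaction"] = (df[factors[0]].astype(str) + ":"
                                      + df[factors[1]].astype(str))
    aov_terms = [t for t in aov.index if t != "Residual"]
    for name, groups in term_groups.items():
        match = [t for t in aov_terms
                 if name == "interaction" and ":" in t
                 or (name != "interaction" and name in t and ":" not in t)]
        if not match or groups.nunique() < 2:
            continue
        pval = float(aov.loc[match[0], "PR(>F)"])
        if np.isnan(pval) or pval > alpha:
            continue
        if groups.value_counts().min() < 2:
            continue  # Tukey needs replication in every cell
        hsd = pairwise_tukeyhsd(df["_y"].to_numpy(), groups.to_numpy(),
                                alpha=alpha)
        frame = pd.DataFrame(hsd.summary().data[1:],
                             columns=hsd.summary().data[0])
        tukey_out[name] = frame
        lv = list(dict.fromkeys(groups))
        differ = {(str(r["group1"]), str(r["group2"])): bool(r["reject"])
                  for _, r in frame.iterrows()}
        letters_out[name] = _compact_letters(lv, differ)
    return {"anova": aov, "tukey": tukey_out, "letters": letters_out}
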