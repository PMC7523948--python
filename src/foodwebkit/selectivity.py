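"""Energy-based Index of Relative Importance and prey-selectivity analysis.

For each prey Order within a section x season x period group,

    IRI = F * (N + J)

where F is the frequency-of-occurrence percentage (share of sampling units
containing the Order), N the numerical percentage (share of total
individuals) and J the energetic percentage (share of total joules) — the
classical IRI with prey energy content substituted for volume.  IRI values
are standardized by the group total so %IRI sums to 100 within a group.

Selectivity compares environmental %IRI (availability) against diet %IRI
(consumption) on log10 axes: Orders above the 1:1 line are selected by
fish, below it avoided.  Contributions under a floor (default 0.1%) are
clamped to the floor, i.e. plotted at -2 on the log scale.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import SampleSet, TaxonCatalog


class SelectivityError(ValueError):
    pass


def iri(sampleset: SampleSet, catalog: TaxonCatalog, source: str,
        rank: str = "order", include_empty_stomachs: bool = False,
        ) -> pd.DataFrame:
    """IRI table for one group of samples (already subset to the group).

    ``source='environment'`` uses site sample events as the occurrence
    unit; ``source='diet'`` uses individual stomachs (empty stomachs are
    excluded from the F denominator unless ``include_empty_stomachs``).
    Requires energetics annotation.  Returns one row per Order with
    columns F, N, J, IRI, pct_iri.
    """
    if source not in ("environment", "diet"):
        raise SelectivityError(f"invalid source {source!r}")
    obs = sampleset.observations
    if "energy_j" not in obs.columns:
        raise SelectivityError("IRI requires energetics annotation")
    if source == "diet":
        if sampleset.fish is None:
            raise SelectivityError("diet IRI requires fish records")
        fish = sampleset.fish
        if not include_empty_stomachs:
            fish = fish[~fish["empty_stomach"]]
        units = list(fish["fish_id"])
        obs = obs[obs["fish_id"].isin(set(units))]
        unit_key = "fish_id"
    else:
        units = sampleset.sample_ids()
        obs = obs[obs["fish_id"].isna()] if "fish_id" in obs.columns else obs
        unit_key = "sample_id"
    n_units = len(units)
    if n_units == 0:
        raise SelectivityError("group contains no sampling units")

    work = obs[obs["count"] > 0].copy()
    work["order"] = [
        catalog.label_at_rank(t, rank)[0] for t in work["taxon_id"]]
    total_count = work["count"].sum()
    total_j = work["energy_j"].sum()
    if total_count == 0 and total_j == 0:
        out = pd.DataFrame(columns=["order", "F", "N", "J", "IRI", "pct_iri"])
        out.attrs["empty_group"] = True
        return out

    g = work.groupby("order")
    f_pct = 100.0 * g[unit_key].nunique() / n_units
    n_pct = 100.0 * g["count"].sum() / total_count if total_count > 0 else 0.0
    j_pct = 100.0 * g["energy_j"].sum() / total_j if total_j > 0 else 0.0
    out = pd.DataFrame({"F": f_pct, "N": n_pct, "J": j_pct})
    out["IRI"] = out["F"] * (out["N"] + out["J"])
    out["pct_iri"] = 100.0 * out["IRI"] / out["IRI"].sum()
    out = out.sort_values("pct_iri", ascending=False, kind="mergesort")
    out.attrs["empty_group"] = False
    out.attrs["source"] = source
    return out.rename_axis("order").reset_index()


def iri_by_group(sampleset: SampleSet, catalog: TaxonCatalog, source: str,
                 by: Sequence[str] = ("section", "season", "period"),
                 **kw) -> pd.DataFrame:
    """IRI tables for every section x season x period group, stacked."""
    meta = sampleset.sample_meta()
    frames = []
    for key, rows in meta.groupby(list(by), observed=True):
        sub = sampleset.subset(list(rows["sample_id"]))
        try:
            tab = iri(sub, catalog, source, **kw)
        except SelectivityError:
            continue
        for col, val in zip(by, key if isinstance(key, tuple) else (key,)):
            tab[col] = val
        frames.append(tab)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def selectivity_coords(env_table: pd.DataFrame, diet_table: pd.DataFrame,
                       floor_pct: float = 0.1,
                       floor_coord: float = -2.0) -> pd.DataFrame:
    """Paired log10 %IRI coordinates (x = environment, y = diet) per Order.

    Orders consumed by fish but absent from environmental samples (e.g.
    plankton, fish prey) are excluded.  Contributions below ``floor_pct``
    are plotted at the axis minimum ``floor_coord`` (the conventional axes
    run from -2 for trace contributions to +2 for 100%).
    """
    env = env_table.set_index("order")["pct_iri"]
    diet = diet_table.set_index("order")["pct_iri"]
    floor_log = floor_coord
    rows = []
    for order, env_pct in env.items():
        diet_pct = float(diet.get(order, 0.0))
        x = math.log10(env_pct) if env_pct >= floor_pct else floor_log
        y = math.log10(diet_pct) if diet_pct >= floor_pct else floor_log
        rows.append({"order": order, "env_pct_iri": float(env_pct),
                     "diet_pct_iri": diet_pct, "x": x, "y": y})
    return pd.DataFrame(rows)


def classify_selection(coords: pd.DataFrame, eps: float = 0.0) -> pd.DataFrame:
    """Label each Order selected / neutral / avoided from its (x, y) point.

    Selected when y > x + eps (consumed more than available), avoided when
    y < x - eps; the default eps = 0 is an exact comparison to the 1:1
    line.
    """
    def lab(row):
        if row["y"] > row["x"] + eps:
            return "selected"
        if row["y"] < row["x"] - eps:
            return "avoided"
        return "neutral"

    out = coords.copy()
    out["selection"] = out.apply(lab, axis=1) if len(out) else []
    return out
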