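"""Abundance transformations, dummy species, Bray-Curtis resemblance,
diet-availability overlap, and group-centroid distance matrices.

Bray-Curtis similarity between two abundance rows x1, x2 is
``100 * (1 - sum|x1j - x2j| / sum(x1j + x2j))``: 0 = no shared taxa,
100 = identical composition.  The coefficient is undefined when both rows
are all-zero; following standard practice for sparse community data, a
dummy species with abundance 0.1 is added to every sample (before any
power transformation) so every pair is defined.  Bray-Curtis is a
semi-metric: the triangle inequality is not guaranteed and is not relied
upon anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import AssemblageMatrix

DUMMY_NAME = "__dummy__"


class ResemblanceError(ValueError):
    pass


@dataclass
class ResemblanceMatrix:
    """Symmetric pairwise resemblance with labels and provenance.

    ``kind='similarity'`` / ``'dissimilarity'`` are on the 0-100 Bray-Curtis
    scale (diagonal exactly 100 / 0); ``kind='distance'`` holds unscaled
    distances (e.g. between group centroids).
    """

    labels: list
    values: np.ndarray
    kind: str = "similarity"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ResemblanceError("resemblance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ResemblanceError("resemblance matrix must be symmetric")
        if self.kind in ("similarity", "dissimilarity"):
            if v.min() < -1e-9 or v.max() > 100 + 1e-9:
                raise ResemblanceError("Bray-Curtis entries must lie in [0, 100]")
            want = 100.0 if self.kind == "similarity" else 0.0
            if not np.allclose(np.diag(v), want, atol=1e-9):
                raise ResemblanceError(f"diagonal must be {want}")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def as_dissimilarity(self) -> "ResemblanceMatrix":
        if self.kind == "dissimilarity":
            return self
        if self.kind != "similarity":
            raise ResemblanceError("not on the Bray-Curtis 0-100 scale")
        return ResemblanceMatrix(list(self.labels), 100.0 - self.values,
                                 "dissimilarity", dict(self.provenance))

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def transform(data: pd.DataFrame, kind: str = "fourth_root") -> pd.DataFrame:
    """Elementwise power transform to balance common vs rare taxa.

    ``sqrt`` is conventional for drift density, ``fourth_root`` for other
    community data sets.  Cells must be non-negative; zeros map to zero.
    """
    if kind == "none":
        return data.copy()
    if kind not in ("sqrt", "fourth_root"):
        raise ResemblanceError(f"invalid transform {kind!r}")
    if (data.values < 0).any():
        raise ResemblanceError("transform requires non-negative cells")
    power = 0.5 if kind == "sqrt" else 0.25
    return data.pow(power)


def add_dummy(data: pd.DataFrame, value: float = 0.1,
              name: str = DUMMY_NAME) -> pd.DataFrame:
    """Append a dummy species column with the given abundance to all rows.

    Applied to raw abundances before transformation, so empty samples get a
    shared non-zero coordinate and no Bray-Curtis pair is undefined.
    """
    if name in data.columns:
        raise ResemblanceError(f"dummy column {name!r} already present")
    out = data.copy()
    out[name] = float(value)
    return out


def remove_dummy(data: pd.DataFrame, name: str = DUMMY_NAME) -> pd.DataFrame:
    return data.drop(columns=[name])


def bray_curtis(data: pd.DataFrame, as_: str = "similarity",
                ) -> ResemblanceMatrix:
    """Pairwise Bray-Curtis of the rows of an abundance table (0-100 scale).

    Raises on a pair of all-zero rows (undefined 0/0); add the dummy
    species first to avoid that.
    """
    if data.shape[0] < 2:
        raise ResemblanceError("need at least 2 rows")
    x = data.to_numpy(dtype=float)
    if (x < 0).any():
        raise ResemblanceError("Bray-Curtis requires non-negative cells")
    zero_rows = np.where(x.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        ids = [data.index[i] for i in zero_rows]
        raise ResemblanceError(
            f"undefined Bray-Curtis pair(s): all-zero rows {ids}; "
            "add a dummy species")
    with np.errstate(invalid="ignore"):
        dis = squareform(pdist(x, metric="braycurtis"))
    dis = 100.0 * np.nan_to_num(dis, nan=0.0)
    np.fill_diagonal(dis, 0.0)
    prov = {"n_taxa": data.shape[1], "dummy": DUMMY_NAME in data.columns}
    if as_ == "dissimilarity":
        return ResemblanceMatrix(list(data.index), dis, "dissimilarity", prov)
    if as_ != "similarity":
        raise ResemblanceError(f"invalid output kind {as_!r}")
    return ResemblanceMatrix(list(data.index), 100.0 - dis, "similarity", prov)


def relativize(data: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to relative abundance (rows sum to 1).

    All-zero rows are left at zero.
    """
    totals = data.sum(axis=1)
    out = data.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return out


def diet_availability_overlap(diet: pd.DataFrame, env: pd.DataFrame,
                              pairing: Mapping, dummy: float = 0.001,
                              ) -> pd.DataFrame:
    """Bray-Curtis similarity between paired diet and availability rows.

    ``pairing`` maps a diet row label (typically the per-event mean diet)
    to the environmental row label of the same site sample event.  Both
    assemblages are standardized to relative abundance first — counts per
    stomach and density per m^2/m^3 are not on comparable scales — and a
    small dummy cell keeps pairs with an empty side defined.  Unpaired diet
    rows are skipped.  Returns one row per event with the coefficient.
    """
    cols = sorted(set(diet.columns) | set(env.columns))
    d = relativize(diet.reindex(columns=cols, fill_value=0.0))
    e = relativize(env.reindex(columns=cols, fill_value=0.0))
    rows = []
    for dlab, elab in pairing.items():
        if dlab not in d.index or elab not in e.index:
            continue
        x1 = np.append(d.loc[dlab].to_numpy(), dummy)
        x2 = np.append(e.loc[elab].to_numpy(), dummy)
        num = np.abs(x1 - x2).sum()
        den = (x1 + x2).sum()
        rows.append({"diet_event": dlab, "env_event": elab,
                     "similarity": 100.0 * (1.0 - num / den)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# principal-coordinate embedding and group centroids

def pcoa_embedding(dissimilarity: np.ndarray,
                   tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Real coordinate blocks (Y+, Y-) of a PCoA of a dissimilarity matrix.

    Gower-centers ``-0.5 * D**2`` and splits the eigensystem into positive
    and negative eigenvalue blocks, so that the centered inner-product
    matrix is exactly ``Y+ Y+' - Y- Y-'``.  Bray-Curtis is non-Euclidean,
    hence the explicit negative block ("imaginary part" correction).
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    G = (G + G.T) / 2.0
    w, V = np.linalg.eigh(G)
    scale = max(abs(w).max(), 1.0)
    pos = w > tol * scale
    neg = w < -tol * scale
    Ypos = V[:, pos] * np.sqrt(w[pos])
    Yneg = V[:, neg] * np.sqrt(-w[neg])
    return Ypos, Yneg


def centroid_matrix(resemblance: ResemblanceMatrix, groups: Sequence,
                    ) -> ResemblanceMatrix:
    """Pairwise distances between group centroids in PCoA space.

    Centroids are taken separately in the positive and negative eigenvalue
    blocks; squared centroid distance is the positive-block squared
    distance minus the negative-block one, clamped at zero before the
    square root.  Empty groups are omitted.
    """
    dis = resemblance.as_dissimilarity() if resemblance.kind == "similarity" \
        else resemblance
    Ypos, Yneg = pcoa_embedding(dis.values)
    groups = pd.Series(list(groups), index=range(len(groups)))
    if len(groups) != dis.values.shape[0]:
        raise ResemblanceError("groups length must match matrix size")
    levels = [g for g in pd.unique(groups) if (groups == g).sum() > 0]
    cpos = np.vstack([Ypos[(groups == g).to_numpy()].mean(axis=0)
                      for g in levels]) if Ypos.shape[1] else np.zeros((len(levels), 0))
    cneg = np.vstack([Yneg[(groups == g).to_numpy()].mean(axis=0)
                      for g in levels]) if Yneg.shape[1] else np.zeros((len(levels), 0))
    k = len(levels)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d2 = np.sum((cpos[i] - cpos[j]) ** 2) - np.sum((cneg[i] - cneg[j]) ** 2)
            out[i, j] = out[j, i] = np.sqrt(max(d2, 0.0))
    return ResemblanceMatrix(list(levels), out, "distance",
                             {"source": "centroid", "n_groups": k})


def centroid_trajectories(centroids: ResemblanceMatrix,
                          order: Sequence[str] = ("Pre", "2012", "2013", "2014"),
                          ) -> pd.DataFrame:
    """Per-section step distances between consecutive periods.

    Expects centroid labels of the form ``(section, period)`` (tuples) and
    lists, per section, the centroid distance of each Pre->2012->2013->2014
    step that is present.
    """
    labels = list(centroids.labels)
    frame = centroids.to_frame()
    rows = []
    sections = sorted({lab[0] for lab in labels})
    for sec in sections:
        present = [p for p in order if (sec, p) in labels]
        for a, b in zip(present[:-1], present[1:]):
            rows.append({"section": sec, "from": a, "to": b,
                         "distance": float(frame.loc[[(sec, a)], [(sec, b)]]
                                           .iloc[0, 0])})
    return pd.DataFrame(rows)
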