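"""Permutational multivariate statistics, written from scratch:

* PERMANOVA — one-way and two-way crossed fixed designs with Type III
  partial sums of squares, permutation of residuals under the reduced
  model (Freedman-Lane), and a Monte Carlo fallback for tests with few
  unique permutations;
* pairwise pseudo-t comparisons with Bonferroni-adjusted significance;
* ANOSIM — Clarke's rank-based R with label permutation;
* SIMPER — decomposition of average between-group Bray-Curtis
  dissimilarity into per-taxon contributions;
* nMDS — Kruskal stress-1 minimized by iterated isotonic regression and
  Guttman (SMACOF) updates.

The distance-based sums of squares follow the Gower-centered inner-product
construction: with ``G = -1/2 J D^2 J`` and a hat matrix ``H`` of a design
matrix including the intercept, the SS explained is ``tr(H G)``.  Because
Bray-Curtis is non-Euclidean, G is carried as signed coordinate blocks
(Y+, Y-) from its eigensystem, so permuted statistics remain exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .resemblance import ResemblanceMatrix, pcoa_embedding


class PermStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# helpers

def _as_dissimilarity(D) -> np.ndarray:
    if isinstance(D, ResemblanceMatrix):
        D = D.as_dissimilarity().values if D.kind != "distance" else D.values
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise PermStatsError("D must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-8):
        raise PermStatsError("D must be symmetric")
    return D


def _sum_coded(labels: pd.Series) -> tuple[np.ndarray, list]:
    """Deviation (sum-to-zero) coding: n x (a-1) columns."""
    levels = sorted(pd.unique(labels.astype(str)))
    a = len(levels)
    if a < 2:
        raise PermStatsError("factor needs >= 2 levels")
    idx = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(labels), a - 1))
    for i, lab in enumerate(labels.astype(str)):
        j = idx[lab]
        if j < a - 1:
            Z[i, j] = 1.0
        else:
            Z[i, :] = -1.0
    return Z, levels


def _interaction(Za: np.ndarray, Zb: np.ndarray) -> np.ndarray:
    cols = [Za[:, i] * Zb[:, j]
            for i in range(Za.shape[1]) for j in range(Zb.shape[1])]
    return np.column_stack(cols) if cols else np.zeros((Za.shape[0], 0))


def _orthobasis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space (rank-safe hat factor)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int(np.sum(s > tol * (s[0] if len(s) else 1.0)))
    return U[:, :r]


def _ss(Q: np.ndarray, Ypos: np.ndarray, Yneg: np.ndarray) -> float:
    """tr(H G) for H = Q Q' and G = Y+ Y+' - Y- Y-'."""
    out = float(np.sum((Q.T @ Ypos) ** 2))
    if Yneg.shape[1]:
        out -= float(np.sum((Q.T @ Yneg) ** 2))
    return out


def _total_ss(Ypos: np.ndarray, Yneg: np.ndarray) -> float:
    out = float(np.sum(Ypos ** 2))
    if Yneg.shape[1]:
        out -= float(np.sum(Yneg ** 2))
    return out


def n_distinct_permutations(group_sizes) -> int:
    """Distinct relabelings of group memberships (multinomial coefficient)."""
    n = sum(group_sizes)
    out = math.factorial(n)
    for k in group_sizes:
        out //= math.factorial(k)
    return out


def monte_carlo_p(f_null: np.ndarray, f_obs: float) -> float:
    """Pearson-III (shifted gamma) tail probability matched to the first
    three moments of the permutation F distribution.

    Used when the number of unique permutations is too small for a precise
    permutation P.  Falls back to a normal approximation when the sample
    skewness is not positive.
    """
    f_null = np.asarray(f_null, dtype=float)
    m = f_null.mean()
    v = f_null.var(ddof=1)
    if not np.isfinite(v) or v <= 0:
        return 1.0 if f_obs <= m else 0.5
    g = float(sps.skew(f_null, bias=False))
    if g > 0.05:
        a = 4.0 / g ** 2
        scale = math.sqrt(v / a)
        loc = m - a * scale
        return float(sps.gamma.sf(f_obs, a, loc=loc, scale=scale))
    return float(sps.norm.sf(f_obs, loc=m, scale=math.sqrt(v)))


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermTermResult:
    term: str
    df: int
    ss: float              # Type III partial SS
    pseudo_f: float | None
    ecv: float | None      # signed sqrt of the estimated variation component
    p: float | None
    p_monte_carlo: float | None
    n_unique_perms: int | None


@dataclass
class PermTestResult:
    terms: list[PermTermResult]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    seed: int | None = None

    def table(self) -> pd.DataFrame:
        rows = [{
            "Source": t.term, "df": t.df, "SS(III)": t.ss, "ECV": t.ecv,
            "Perm": t.n_unique_perms, "Pseudo-F": t.pseudo_f, "P": t.p,
            "P(MC)": t.p_monte_carlo,
        } for t in self.terms]
        rows.append({"Source": "Residual", "df": self.residual_df,
                     "SS(III)": self.residual_ss,
                     "ECV": math.sqrt(self.residual_ss / self.residual_df)
                     if self.residual_df else None,
                     "Perm": None, "Pseudo-F": None, "P": None, "P(MC)": None})
        return pd.DataFrame(rows)

    def __getitem__(self, term: str) -> PermTermResult:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)


def _signed_sqrt(x: float) -> float:
    return math.copysign(math.sqrt(abs(x)), x)


def permanova(D, design: pd.DataFrame, n_perm: int = 9999,
              seed: int | None = None, permutations: str = "random",
              ) -> PermTestResult:
    """Distance-based MANOVA by permutation.

    ``design``: DataFrame with one factor column (one-way) or two factor
    columns (two-way crossed with interaction), aligned with the rows of
    ``D``.  Per term, the Type III partial SS is the trace reduction
    between the full model and the model omitting that term; significance
    comes from Freedman-Lane permutation of the reduced-model residuals in
    PCoA coordinate space.  ``permutations='exhaustive'`` enumerates all
    n! row permutations (small n only); the P estimator always counts the
    observed statistic: ``(b + 1) / (m + 1)``.

    ECV is the signed square root of the estimated component of variation,
    ``(MS_term - MS_res) / q`` with q = N / (number of level combinations
    of the term's factors) — the balanced expected-mean-squares
    coefficient, with average cell size standing in for unbalanced designs.
    """
    D = _as_dissimilarity(D)
    n = D.shape[0]
    if len(design) != n:
        raise PermStatsError("design rows must match D")
    factors = list(design.columns)
    if len(factors) not in (1, 2):
        raise PermStatsError("design must have 1 or 2 factor columns")
    if n_perm < 99:
        raise PermStatsError("n_perm must be >= 99")

    blocks: dict[str, np.ndarray] = {}
    n_levels: dict[str, int] = {}
    Za, levels_a = _sum_coded(design[factors[0]])
    blocks[factors[0]] = Za
    n_levels[factors[0]] = len(levels_a)
    if len(factors) == 2:
        Zb, levels_b = _sum_coded(design[factors[1]])
        inter = f"{factors[0]} x {factors[1]}"
        blocks[factors[1]] = Zb
        blocks[inter] = _interaction(Za, Zb)
        n_levels[factors[1]] = len(levels_b)
        n_levels[inter] = len(levels_a) * len(levels_b)

    ones = np.ones((n, 1))
    X_full = np.hstack([ones] + list(blocks.values()))
    Q_full = _orthobasis(X_full)
    Ypos, Yneg = pcoa_embedding(D)
    ss_total = _total_ss(Ypos, Yneg)
    ss_full = _ss(Q_full, Ypos, Yneg)
    ss_res = ss_total - ss_full
    df_res = n - Q_full.shape[1]
    if df_res <= 0:
        raise PermStatsError("no residual degrees of freedom")
    ms_res = ss_res / df_res

    rng = np.random.default_rng(seed)
    if permutations == "exhaustive":
        perms = [np.asarray(p) for p in
                 itertools.permutations(range(n))][1:]  # skip identity
    elif permutations == "random":
        perms = [rng.permutation(n) for _ in range(n_perm)]
    else:
        raise PermStatsError(f"invalid permutations mode {permutations!r}")

    results = []
    for term, Z in blocks.items():
        others = [ones] + [blocks[t] for t in blocks if t != term]
        Q_red = _orthobasis(np.hstack(others))
        df_t = Z.shape[1]
        ss_t = ss_full - _ss(Q_red, Ypos, Yneg)
        f_obs = (ss_t / df_t) / ms_res if ms_res > 0 else np.inf

        # Freedman-Lane: fitted + permuted residuals of the reduced model
        Fp = Q_red @ (Q_red.T @ Ypos)
        Rp = Ypos - Fp
        Fn = Q_red @ (Q_red.T @ Yneg) if Yneg.shape[1] else Yneg
        Rn = Yneg - Fn
        f_null = np.empty(len(perms))
        seen = set()
        for i, pi in enumerate(perms):
            Yp = Fp + Rp[pi]
            Yn = Fn + Rn[pi] if Yneg.shape[1] else Yneg
            sf = _ss(Q_full, Yp, Yn)
            sr = _ss(Q_red, Yp, Yn)
            ssr_star = _total_ss(Yp, Yn) - sf
            f_null[i] = ((sf - sr) / df_t) / (ssr_star / df_res) \
                if ssr_star > 0 else np.inf
            seen.add(tuple(pi))
        b = int(np.sum(f_null >= f_obs - 1e-12))
        p = (b + 1) / (len(perms) + 1)

        q = n / n_levels[term]
        ecv = _signed_sqrt(((ss_t / df_t) - ms_res) / q)
        finite = f_null[np.isfinite(f_null)]
        mc = monte_carlo_p(finite, f_obs) if len(finite) >= 3 else None
        results.append(PermTermResult(term, df_t, ss_t, f_obs, ecv, p, mc,
                                      len(seen)))
    return PermTestResult(results, df_res, ss_res, ss_total,
                          n_perm=len(perms), seed=seed)


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    df: int
    n_unique_perms: int
    pseudo_t: float
    p: float
    monte_carlo: bool
    alpha_adjusted: float
    significant: bool


def pairwise(D, labels, n_perm: int = 9999, seed: int | None = None,
             alpha_family: float = 0.05, slice_mask=None,
             monte_carlo_threshold: int = 40) -> list[PairwiseResult]:
    """All-pairs one-way pseudo-t comparisons with Bonferroni adjustment.

    ``pseudo_t = sqrt(pseudo_F)`` of the two-group one-way test.  The number
    of distinct relabelings is the binomial coefficient C(n1+n2, n1); pairs
    below ``monte_carlo_threshold`` enumerate the exact permutation
    distribution and report the moment-matched Monte Carlo P, flagged.  The
    family-wise significance threshold is ``alpha_family / n_comparisons``.
    """
    D = _as_dissimilarity(D)
    labels = pd.Series(list(labels)).astype(str)
    if slice_mask is not None:
        keep = np.asarray(slice_mask, dtype=bool)
        D = D[np.ix_(keep, keep)]
        labels = labels[keep].reset_index(drop=True)
    levels = sorted(labels.unique())
    pairs = list(itertools.combinations(levels, 2))
    if not pairs:
        raise PermStatsError("need >= 2 groups")
    alpha_adj = alpha_family / len(pairs)
    out = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        keep = labels.isin([a, b]).to_numpy()
        sub = D[np.ix_(keep, keep)]
        sublab = labels[keep].reset_index(drop=True)
        n1 = int((sublab == a).sum())
        n2 = int((sublab == b).sum())
        uniq = n_distinct_permutations([n1, n2])
        if min(n1, n2) < 1 or uniq < 2:
            continue
        sub_design = pd.DataFrame({"g": sublab})
        nsub = n1 + n2
        if uniq < monte_carlo_threshold and nsub <= 8:
            res = permanova(sub, sub_design, n_perm=max(99, n_perm),
                            seed=int(rng.integers(2 ** 31 - 1)),
                            permutations="exhaustive")
        else:
            res = permanova(sub, sub_design, n_perm=n_perm,
                            seed=int(rng.integers(2 ** 31 - 1)))
        term = res.terms[0]
        mc = uniq < monte_carlo_threshold
        p = term.p_monte_carlo if (mc and term.p_monte_carlo is not None) \
            else term.p
        out.append(PairwiseResult(
            a, b, df=res.residual_df, n_unique_perms=uniq,
            pseudo_t=math.sqrt(max(term.pseudo_f, 0.0)), p=p,
            monte_carlo=mc, alpha_adjusted=alpha_adj,
            significant=p <= alpha_adj))
    return out


# ---------------------------------------------------------------------------
# ANOSIM

@dataclass
class AnosimResult:
    r: float
    p: float
    n_perm: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n = (1 + math.isqrt(1 + 8 * len(ranks))) // 2
    denom = n * (n - 1) / 4.0
    return float((ranks[~within].mean() - ranks[within].mean()) / denom)


def anosim(D, labels, n_perm: int = 999, seed: int | None = None,
           ) -> AnosimResult:
    """Clarke's analysis of similarities.

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group) / (n(n-1)/4), with mid-ranks for ties; R in [-1, 1] and
    ~0 under the null.  P by permutation of group labels.
    """
    D = _as_dissimilarity(D)
    labels = np.asarray(list(labels))
    if len(labels) != D.shape[0]:
        raise PermStatsError("labels must match D")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise PermStatsError("need >= 2 groups")
    if (counts == 1).all():
        raise PermStatsError("all groups are singletons")
    ranks = sps.rankdata(squareform(D, checks=False))
    n = D.shape[0]
    iu = np.triu_indices(n, 1)

    def within_mask(lab):
        return lab[iu[0]] == lab[iu[1]]

    r_obs = _anosim_r(ranks, within_mask(labels))
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, within_mask(perm)) >= r_obs - 1e-12:
            b += 1
    return AnosimResult(r_obs, (b + 1) / (n_perm + 1), n_perm)


# ---------------------------------------------------------------------------
# SIMPER

def simper(data: pd.DataFrame, labels, group_a, group_b,
           cutoff_pct: float = 2.0) -> pd.DataFrame:
    """Per-taxon contributions to average between-group dissimilarity.

    For each taxon j, the contribution is the mean over all between-group
    sample pairs of ``100 |x1j - x2j| / sum_k (x1k + x2k)``; contributions
    sum to the average between-group Bray-Curtis dissimilarity.  Rows are
    sorted by contribution, with ``report`` flagging taxa at or above
    ``cutoff_pct`` percent of the total.  Input should already be
    transformed as desired.
    """
    labels = pd.Series(list(labels)).astype(str)
    x1 = data[ (labels == str(group_a)).to_numpy() ].to_numpy(dtype=float)
    x2 = data[ (labels == str(group_b)).to_numpy() ].to_numpy(dtype=float)
    if len(x1) == 0 or len(x2) == 0:
        raise PermStatsError("both groups must be non-empty")
    contrib = np.zeros(data.shape[1])
    npairs = 0
    for i in range(len(x1)):
        for j in range(len(x2)):
            den = (x1[i] + x2[j]).sum()
            if den <= 0:
                continue
            contrib += 100.0 * np.abs(x1[i] - x2[j]) / den
            npairs += 1
    if npairs == 0:
        raise PermStatsError("no defined between-group pairs")
    contrib /= npairs
    total = contrib.sum()
    out = pd.DataFrame({
        "taxon": data.columns,
        "mean_abund_a": x1.mean(axis=0),
        "mean_abund_b": x2.mean(axis=0),
        "contribution": contrib,
        "contribution_pct": 100.0 * contrib / total if total > 0
        else np.zeros_like(contrib),
    }).sort_values("contribution", ascending=False, kind="mergesort")
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    out["report"] = out["contribution_pct"] >= cutoff_pct
    out.attrs["average_dissimilarity"] = float(total)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# nMDS

@dataclass
class NMDSResult:
    coordinates: np.ndarray
    stress: float
    k: int
    restarts_used: int
    converged: bool


def _kruskal_stress(d: np.ndarray, dhat: np.ndarray) -> float:
    den = float(np.sum(d ** 2))
    if den == 0:
        return 0.0
    return math.sqrt(float(np.sum((d - dhat) ** 2)) / den)


def _principal_orient(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    Xr = X @ Vt.T
    for j in range(Xr.shape[1]):
        i = int(np.argmax(np.abs(Xr[:, j])))
        if Xr[i, j] < 0:
            Xr[:, j] = -Xr[:, j]
    return Xr


def nmds(D, k: int = 2, restarts: int = 4, max_iter: int = 300,
         tol: float = 1e-9, seed: int | None = None,
         extra_inits: list[np.ndarray] | None = None) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Each restart alternates an isotonic-regression fit of the disparities
    to the configuration distances (in dissimilarity rank order, ties
    pooled) with a Guttman/SMACOF configuration update; the best (lowest
    stress) configuration ever visited is kept.  The first start is the
    metric PCoA configuration, the rest are random.  The returned
    configuration is centered and rotated to its principal axes, with a
    deterministic sign convention.
    """
    D = _as_dissimilarity(D)
    n = D.shape[0]
    if k >= n:
        raise PermStatsError("k must be < number of points")
    dcond = squareform(D, checks=False)
    order = np.argsort(dcond, kind="mergesort")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    rng = np.random.default_rng(seed)

    Ypos, _ = pcoa_embedding(D)
    pco = np.zeros((n, k))
    m = min(k, Ypos.shape[1])
    pco[:, :m] = Ypos[:, :m]
    inits = [pco] + list(extra_inits or [])
    inits += [rng.standard_normal((n, k)) * (dcond.mean() or 1.0)
              for _ in range(max(0, restarts - 1))]

    best_X, best_stress, converged = None, np.inf, False
    for X in inits:
        X = np.array(X, dtype=float)
        prev = np.inf
        this_converged = False
        for _ in range(max_iter):
            d = pdist(X)
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(dcond[order], d[order])
            stress = _kruskal_stress(d, dhat)
            if stress < best_stress:
                best_stress, best_X = stress, X.copy()
            if abs(prev - stress) < tol or stress < 1e-12:
                this_converged = True
                break
            prev = stress
            # Guttman transform with current disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = -squareform(ratio, checks=False)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
        converged = converged or this_converged
    return NMDSResult(_principal_orient(best_X), best_stress, k,
                      restarts_used=len(inits), converged=converged)


def nmds_scree(D, ks=(1, 2, 3), restarts: int = 4,
               seed: int | None = None, **kw) -> dict[int, NMDSResult]:
    """nMDS over increasing k, seeding each k with the previous solution
    padded by a zero column; guarantees stress is non-increasing in k."""
    out: dict[int, NMDSResult] = {}
    prev = None
    for k in sorted(ks):
        extra = []
        if prev is not None and prev.k < k:
            pad = np.zeros((prev.coordinates.shape[0], k - prev.k))
            extra = [np.hstack([prev.coordinates, pad])]
        out[k] = nmds(D, k=k, restarts=restarts, seed=seed,
                      extra_inits=extra, **kw)
        prev = out[k]
    return out
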