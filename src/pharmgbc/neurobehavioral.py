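"""Mass-univariate brain–behavior mapping and single-subject projections.

A behavioral score (e.g. a behavioral PC score) is regressed onto Δ-GBC at
every parcel; the Z-scored coefficient map is the neuro-behavioral map.
Family-wise error over parcels is controlled by subject-shuffle permutation:
max-statistic correction by default, with threshold-free cluster enhancement
(TFCE) over a k-nearest-neighbour parcel adjacency as an option.  Subject
projections correlate each subject's Δ map with a reference map and Z-score
the r-values across the cohort; the gene-coupling analysis correlates the
per-subject SST−PVALB association difference with those projection scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import InvalidArgumentError

TFCE_E = 0.5
TFCE_H = 2.0
TFCE_STEPS = 50


@dataclass
class NeuroBehavioralMap:
    """Z-scored regression-coefficient map with permutation-corrected p."""

    coef: np.ndarray                       # raw per-parcel slopes
    coef_z: np.ndarray                     # Z-scored across parcels
    score_name: str = "score"
    p_corrected: Optional[np.ndarray] = None
    n_perm: int = 0


@dataclass
class SubjectProjection:
    """Per-subject similarity to a reference map: raw r and cohort Z."""

    r: np.ndarray
    z: np.ndarray
    valid: np.ndarray = field(repr=False, default=None)


def _slopes(delta_maps: np.ndarray, score_std: np.ndarray) -> np.ndarray:
    """Per-parcel OLS slope of Δ-GBC on a standardized score (vectorized)."""
    s = len(score_std)
    mc = delta_maps - delta_maps.mean(axis=0)
    return score_std @ mc / (s - 1)  # var(score_std) == 1


def _standardize_score(score: np.ndarray) -> np.ndarray:
    score = np.asarray(score, float)
    sd = score.std(ddof=1)
    if sd == 0:
        raise InvalidArgumentError("score has zero variance")
    return (score - score.mean()) / sd


def mass_univariate_map(
    delta_maps: np.ndarray, score: np.ndarray, score_name: str = "score"
) -> NeuroBehavioralMap:
    """Regress the (standardized) behavioral score onto Δ-GBC at each parcel.

    Coefficient magnitude reflects the strength of the brain–behavior
    relationship at that parcel; coefficients are Z-scored across parcels.
    """
    delta_maps = np.asarray(delta_maps, float)
    if delta_maps.shape[0] < 5:
        raise InvalidArgumentError("need >= 5 subjects")
    if delta_maps.shape[0] != len(score):
        raise InvalidArgumentError("score length must equal subject count")
    coef = _slopes(delta_maps, _standardize_score(score))
    coef_z = (coef - coef.mean()) / coef.std()
    return NeuroBehavioralMap(coef=coef, coef_z=coef_z, score_name=score_name)


def mass_univariate_maps(
    delta_maps: np.ndarray, scores: pd.DataFrame
) -> dict[str, NeuroBehavioralMap]:
    """One coefficient map per behavioral score column.

    Each column is standardized and regressed independently, so every map
    equals the single-score :func:`mass_univariate_map` of that column.
    """
    return {
        str(name): mass_univariate_map(delta_maps, scores[name].to_numpy(float),
                                       score_name=str(name))
        for name in scores.columns
    }


def knn_adjacency(centroids: np.ndarray, k: int = 6) -> np.ndarray:
    """Symmetric k-nearest-neighbour adjacency over parcel centroids."""
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(np.asarray(centroids, float)))
    p = d.shape[0]
    nn = np.argsort(d, axis=1)[:, 1 : k + 1]
    adj = np.zeros((p, p), bool)
    rows = np.repeat(np.arange(p), k)
    adj[rows, nn.ravel()] = True
    return adj | adj.T


def _tfce(stat: np.ndarray, adjacency: np.ndarray, e: float = TFCE_E,
          h: float = TFCE_H, n_steps: int = TFCE_STEPS,
          max_stat: Optional[float] = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a non-negative statistic map
    over a graph adjacency (connected-component formulation)."""
    top = float(stat.max()) if max_stat is None else max_stat
    if top <= 0:
        return np.zeros_like(stat)
    dh = top / n_steps
    heights = dh * (np.arange(n_steps) + 0.5)
    out = np.zeros_like(stat)
    for height in heights:
        above = stat >= height
        if not above.any():
            break
        sub = adjacency[np.ix_(above, above)]
        n_comp, labels = connected_components(coo_matrix(sub), directed=False)
        sizes = np.bincount(labels, minlength=n_comp)
        out[above] += (sizes[labels] ** e) * (height**h) * dh
    return out


def permutation_correct(
    delta_maps: np.ndarray,
    score: np.ndarray,
    n_perm: int = 5000,
    method: str = "max_stat",
    adjacency: Optional[np.ndarray] = None,
    seed: int = 0,
) -> NeuroBehavioralMap:
    """Family-wise-error-corrected p per parcel by subject-shuffle permutation.

    The score vector is permuted across subjects each iteration and the
    per-parcel |slope| recomputed.  ``max_stat`` compares each observed
    statistic with the permutation distribution of the map-wise maximum;
    ``tfce`` first enhances the statistic map over the parcel adjacency
    (E=0.5, H=2, graph connected components).  A disconnected adjacency is
    handled component-wise (with a warning).
    """
    if method not in ("max_stat", "tfce"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    if method == "tfce":
        if adjacency is None:
            raise InvalidArgumentError("tfce requires a parcel adjacency")
        n_comp, _ = connected_components(coo_matrix(adjacency), directed=False)
        if n_comp > 1:
            warnings.warn(
                f"adjacency has {n_comp} connected components; TFCE clusters "
                "cannot span components"
            )
    delta_maps = np.asarray(delta_maps, float)
    z = _standardize_score(score)
    nb = mass_univariate_map(delta_maps, score)
    obs = np.abs(nb.coef)
    if method == "tfce":
        obs = _tfce(obs, adjacency)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    mc = delta_maps - delta_maps.mean(axis=0)
    null_slopes = np.abs(perms @ mc / (len(z) - 1))  # (n_perm, P)
    if method == "max_stat":
        null_max = null_slopes.max(axis=1)
    else:
        cap = max(float(null_slopes.max()), float(np.abs(nb.coef).max()))
        null_max = np.array(
            [_tfce(row, adjacency, max_stat=cap).max() for row in null_slopes]
        )
        obs = _tfce(np.abs(nb.coef), adjacency, max_stat=cap)
    p = (1.0 + (null_max[:, None] >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    nb.p_corrected = p
    nb.n_perm = n_perm
    return nb


def subject_projection(
    delta_maps: np.ndarray, reference_map: np.ndarray
) -> SubjectProjection:
    """Correlate each subject's Δ map with a reference map; Z-score the
    r-values across subjects.  Constant subject maps get a null (NaN) score."""
    delta_maps = np.asarray(delta_maps, float)
    ref = np.asarray(reference_map, float)
    if delta_maps.shape[1] != len(ref):
        raise InvalidArgumentError("maps and reference must share parcel support")
    refc = ref - ref.mean()
    mc = delta_maps - delta_maps.mean(axis=1, keepdims=True)
    den = np.sqrt((mc**2).sum(axis=1) * (refc**2).sum())
    scale = np.abs(delta_maps).max(axis=1) + 1.0
    valid = den > 1e-12 * scale  # constant maps up to rounding are invalid
    r = np.full(len(delta_maps), np.nan)
    r[valid] = (mc[valid] @ refc) / den[valid]
    z = np.full_like(r, np.nan)
    z[valid] = (r[valid] - r[valid].mean()) / r[valid].std()
    return SubjectProjection(r=r, z=z, valid=valid)


@dataclass
class GeneCouplingResult:
    r: Optional[float]
    p: Optional[float]
    p_perm: Optional[float] = None
    degenerate: bool = False


def gene_coupling_correlation(
    profiles: pd.DataFrame,
    projections: SubjectProjection,
    gene_a: str = "SST",
    gene_b: str = "PVALB",
    n_perm: int = 0,
    seed: int = 0,
) -> GeneCouplingResult:
    """Correlate the per-subject gene-association difference (r_A − r_B) with
    the neuro-behavioral projection score."""
    d = (profiles[f"r_{gene_a}"] - profiles[f"r_{gene_b}"]).to_numpy(float)
    z = projections.z
    if len(d) != len(z):
        raise InvalidArgumentError("profiles and projections must share subjects")
    ok = np.isfinite(d) & np.isfinite(z)
    d, z = d[ok], z[ok]
    if d.std() == 0 or z.std() == 0:
        return GeneCouplingResult(r=None, p=None, degenerate=True)
    r, p = stats.pearsonr(d, z)
    p_perm = None
    if n_perm:
        rng = np.random.default_rng(seed)
        null = np.array(
            [abs(stats.pearsonr(rng.permutation(d), z)[0]) for _ in range(n_perm)]
        )
        p_perm = float((1.0 + np.sum(null >= abs(r))) / (n_perm + 1.0))
    return GeneCouplingResult(r=float(r), p=float(p), p_perm=p_perm)
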