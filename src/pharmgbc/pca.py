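"""PCA of per-subject Δ-GBC maps with permutation significance.

The decomposition runs across subjects with parcels as features (features
centered, not variance-scaled).  Component significance uses the
parcel-shuffle permutation null: each subject's parcel vector is shuffled
independently, the PCA refit, and the variance fraction at each component
rank compared with the observed one.  Also provides Z-scored component maps,
correlations with the mean Δ-GBC map, and association-vs-sensory network
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ParcelAtlas
from .errors import DegenerateInputError, InvalidArgumentError


@dataclass
class PcaSolution:
    """loadings (P, K) unit-norm columns; scores (S, K); eigenvalues (K,)
    non-increasing; var_frac (K,) summing to 1; perm_p filled by the
    permutation test."""

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    var_frac: np.ndarray
    mean_map: np.ndarray
    perm_p: Optional[np.ndarray] = None
    scaled: bool = False
    column_sd: Optional[np.ndarray] = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def significant(self) -> np.ndarray:
        """1-based ranks of the retained components: the leading run of
        components with permutation p < 0.05.  Retention is sequential — a
        component is only interpretable if every larger component is also
        above chance, so the first non-significant rank stops the scan
        (otherwise K marginally-uniform p-values would admit ~0.05·K false
        components under the null)."""
        if self.perm_p is None:
            raise InvalidArgumentError("run permutation_significance first")
        below = self.perm_p < 0.05
        stop = np.argmin(below) if not below.all() else len(below)
        return np.arange(1, stop + 1)

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def _prepare(maps: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    maps = np.asarray(maps, float)
    if maps.ndim != 2 or maps.shape[0] < 3:
        raise InvalidArgumentError("need a (subjects >= 3) x parcels matrix")
    if np.isnan(maps).any():
        raise InvalidArgumentError("missing values not allowed; impute first")
    mean_map = maps.mean(axis=0)
    X = maps - mean_map
    sd = X.std(axis=0, ddof=1)
    if scale:
        if np.any(sd == 0):
            raise DegenerateInputError(
                f"zero-variance columns: {np.flatnonzero(sd == 0).tolist()}"
            )
        X = X / sd
    elif not np.any(sd > 0):
        raise DegenerateInputError("all maps identical: nothing to decompose")
    return X, mean_map, sd


def _fix_signs(loadings: np.ndarray, scores: np.ndarray, mean_map: np.ndarray) -> None:
    """Deterministic sign convention: each loading correlates non-negatively
    with the mean map; exact ties resolved by making the largest-|loading|
    parcel positive."""
    mc = mean_map - mean_map.mean()
    for k in range(loadings.shape[1]):
        v = loadings[:, k]
        c = float((v - v.mean()) @ mc)
        if c == 0.0:
            c = v[np.argmax(np.abs(v))]
        if c < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1


def fit_pca(maps: np.ndarray, scale: bool = False) -> PcaSolution:
    """SVD-based PCA across subjects; retains K = min(S−1, P) components."""
    X, mean_map, sd = _prepare(maps, scale)
    s_n, p_n = X.shape
    k = min(s_n - 1, p_n)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    eig = s**2 / (s_n - 1)
    total = X.var(axis=0, ddof=1).sum()
    loadings = vt.T.copy()
    scores = u * s
    _fix_signs(loadings, scores, mean_map)
    return PcaSolution(
        loadings=loadings,
        scores=scores,
        eigenvalues=eig,
        var_frac=eig / total,
        mean_map=mean_map,
        scaled=scale,
        column_sd=sd if scale else None,
    )


def fit_delta_pca(maps: np.ndarray) -> PcaSolution:
    """PCA of subjects × parcels Δ-GBC maps (features centered, not scaled)."""
    return fit_pca(maps, scale=False)


def _perm_var_frac(maps: np.ndarray, n_perm: int, scale: bool, seed) -> np.ndarray:
    """(n_perm, K) variance fractions under within-subject parcel shuffling."""
    maps = np.asarray(maps, float)
    s_n, p_n = maps.shape
    k = min(s_n - 1, p_n)
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, k))
    for i in range(n_perm):
        perm = rng.permuted(maps, axis=1)  # independent shuffle per subject row
        X = perm - perm.mean(axis=0)
        if scale:
            X = X / X.std(axis=0, ddof=1)
        sv = np.linalg.svd(X, compute_uv=False)[:k]
        eig = sv**2
        out[i] = eig / (X.var(axis=0, ddof=1).sum() * (s_n - 1))
    return out


def permutation_significance(
    maps: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    scale: bool = False,
    solution: Optional[PcaSolution] = None,
) -> PcaSolution:
    """Permutation p-value per component rank.

    For each of ``n_perm`` permutations every subject's parcel vector is
    shuffled independently and the PCA refit; p_k = (1 + #{permuted
    var_frac_k ≥ observed}) / (n_perm + 1).  Components with p < 0.05 are
    marked significant.
    """
    if n_perm < 100:
        raise InvalidArgumentError("need n_perm >= 100")
    sol = solution if solution is not None else fit_pca(maps, scale=scale)
    null = _perm_var_frac(maps, n_perm, scale=sol.scaled, seed=seed)
    exceed = (null >= sol.var_frac[None, : null.shape[1]]).sum(axis=0)
    sol.perm_p = (1.0 + exceed) / (n_perm + 1.0)
    return sol


def pc_zmap(solution: PcaSolution, k: int) -> np.ndarray:
    """Component-k loading standardized to mean 0, sd 1 across parcels."""
    if not 1 <= k <= solution.n_components:
        raise InvalidArgumentError(f"component {k} out of range")
    v = solution.loadings[:, k - 1]
    return (v - v.mean()) / v.std()


def zscore_map(values: np.ndarray) -> np.ndarray:
    """Z-score any parcel map across parcels."""
    v = np.asarray(values, float)
    sd = v.std()
    if sd == 0:
        raise DegenerateInputError("constant map cannot be Z-scored")
    return (v - v.mean()) / sd


def correlate_with_mean(
    solution: PcaSolution,
    mean_map: Optional[np.ndarray] = None,
    components: Optional[np.ndarray] = None,
    surrogate_ensembles: Optional[dict] = None,
) -> pd.DataFrame:
    """Pearson r between each (significant) component map and the mean map,
    with Bonferroni-adjusted p.

    When a surrogate ensemble (from :mod:`pharmgbc.genemap`) is supplied per
    component, the p-value comes from the spatial-autocorrelation-preserving
    surrogate test; otherwise it is parametric.
    """
    mean_map = solution.mean_map if mean_map is None else np.asarray(mean_map, float)
    if components is None:
        components = solution.significant if solution.perm_p is not None else (
            np.arange(solution.n_components) + 1
        )
    rows = []
    m = len(components)
    for k in components:
        v = solution.loadings[:, k - 1]
        if surrogate_ensembles and k in surrogate_ensembles:
            from .genemap import surrogate_correlation_test

            res = surrogate_correlation_test(v, mean_map, surrogate_ensembles[k])
            r, p = res.r_obs, res.p
        else:
            r, p = stats.pearsonr(v, mean_map)
        rows.append({"component": int(k), "r": r, "p": p, "p_bonferroni": min(1.0, p * m)})
    return pd.DataFrame(rows)


@dataclass
class NetworkSummary:
    network_means: pd.Series = field(repr=False)
    class_means: pd.Series = field(repr=False)
    contrast: float = 0.0        # mean(association) − mean(sensory)
    p: float = 1.0               # two-tailed label-permutation p
    n_perm: int = 0


def network_summary(
    zmap: np.ndarray,
    atlas: ParcelAtlas,
    n_perm: int = 10_000,
    seed: int = 0,
) -> NetworkSummary:
    """Per-network mean Z plus the association-vs-sensory contrast.

    The contrast p-value comes from a two-tailed permutation of the
    association/sensory labels across parcels (parcels within a network are
    not independent, so a parametric two-sample test is not assumed valid).
    """
    zmap = np.asarray(zmap, float)
    if zmap.shape != (atlas.n_parcels,):
        raise InvalidArgumentError("zmap length must equal atlas size")
    assoc = atlas.is_association
    if assoc.sum() < 2 or (~assoc).sum() < 2:
        raise InvalidArgumentError("need >= 2 parcels per class")
    df = pd.DataFrame({"z": zmap, "network": atlas.networks, "klass": atlas.klass})
    net_means = df.groupby("network", sort=True)["z"].mean()
    cls_means = df.groupby("klass", sort=True)["z"].mean()
    obs = float(zmap[assoc].mean() - zmap[~assoc].mean())

    rng = np.random.default_rng(seed)
    n_a = int(assoc.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(atlas.n_parcels)
        d = zmap[perm[:n_a]].mean() - zmap[perm[n_a:]].mean()
        if abs(d) >= abs(obs) - 1e-15:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return NetworkSummary(
        network_means=net_means, class_means=cls_means, contrast=obs, p=p, n_perm=n_perm
    )
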