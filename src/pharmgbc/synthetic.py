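"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a parcel atlas with
centroids on the unit sphere, per-subject drug-minus-placebo (Δ) GBC maps with
a planted low-rank inter-individual structure, single-session BOLD time series
under a one-factor connectivity model, spatially autocorrelated cortical
gene-expression maps with a controlled correlation to a target map, and
behavioral item matrices coupled to the planted subject scores.  Generators
are pure functions of their arguments and a seed, so every downstream stage
has an exact recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import ASSOCIATION_NETWORKS, SENSORY_NETWORKS, ParcelAtlas
from .errors import DegenerateGeometryError, InvalidArgumentError

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class GroundTruth:
    """Planted quantities behind a simulated dataset (test oracle container).

    component_maps : (K, P) orthonormal rows — the planted spatial components.
    subject_scores : (S, K) — per-subject loadings on those components.
    eigenspectrum  : (K,) non-increasing positive — planted component variances.
    behavior_coupling : (K, M) or None — linear map from scores to behavior items.
    gene_target_corr : per-gene planted correlation with the target map.
    flagged_frames : per-scan indices of injected motion spikes.
    """

    component_maps: np.ndarray
    subject_scores: np.ndarray
    eigenspectrum: np.ndarray
    behavior_coupling: Optional[np.ndarray] = None
    gene_target_corr: dict = field(default_factory=dict)
    flagged_frames: dict = field(default_factory=dict)
    mean_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        U = np.asarray(self.component_maps, float)
        G = U @ U.T
        if not np.allclose(G, np.eye(len(U)), atol=1e-8):
            raise InvalidArgumentError("component_maps must be orthonormal")
        lam = np.asarray(self.eigenspectrum, float)
        if np.any(np.diff(lam) > 0):
            raise InvalidArgumentError("eigenspectrum must be non-increasing")


def make_atlas(n_parcels: int, n_networks: int = 12, seed: int = 0) -> ParcelAtlas:
    """Build a synthetic parcel atlas emulating a 12-network whole-brain layout.

    Centroids sit on a Fibonacci lattice over the unit sphere (deterministic,
    with non-degenerate pairwise distances); the hemisphere is the sign of the
    first coordinate; parcels are split evenly-as-possible across ``n_networks``
    networks, half association and half sensory.
    """
    if n_networks % 2:
        raise InvalidArgumentError("n_networks must be even (half association, half sensory)")
    if n_parcels < 2 * n_networks:
        raise InvalidArgumentError("need at least 2 parcels per network")

    i = np.arange(n_parcels)
    z = 1.0 - 2.0 * (i + 0.5) / n_parcels
    r = np.sqrt(1.0 - z**2)
    phi = _GOLDEN_ANGLE * i
    xyz = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    half = n_networks // 2
    names = list(ASSOCIATION_NETWORKS[:half]) + list(SENSORY_NETWORKS[:half])
    # pad with generated labels if more networks than the canonical 12
    while len(names) < n_networks:
        k = len(names)
        names.insert(half, f"ASSOC{k}") if k % 2 == 0 else names.append(f"SENS{k}")
    klass_of = {n: ("association" if j < half else "sensory") for j, n in enumerate(names)}

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_parcels)
    network = np.empty(n_parcels, dtype=object)
    for j, chunk in enumerate(np.array_split(order, n_networks)):
        network[chunk] = names[j]

    table = pd.DataFrame(
        {
            "parcel_id": np.arange(1, n_parcels + 1),
            "hemisphere": np.where(xyz[:, 0] >= 0, "R", "L"),
            "network": network,
            "klass": [klass_of[n] for n in network],
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )
    return ParcelAtlas(table)


def _planted_components(atlas: ParcelAtlas, k: int, rng: np.random.Generator) -> np.ndarray:
    """K orthonormal parcel maps; the first contrasts association vs sensory."""
    p = atlas.n_parcels
    contrast = np.where(atlas.is_association, 1.0, -1.0)
    contrast = contrast - contrast.mean()
    basis = [contrast / np.linalg.norm(contrast)]
    for _ in range(k - 1):
        v = rng.standard_normal(p)
        for b in basis:
            v -= (v @ b) * b
        basis.append(v / np.linalg.norm(v))
    return np.array(basis)


def simulate_delta_gbc(
    atlas: ParcelAtlas,
    n_subjects: int,
    k: int,
    eigenspectrum: Sequence[float],
    noise_sd: float,
    seed: int = 0,
    mean_map: Optional[np.ndarray] = None,
    orthonormal_scores: bool = False,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate per-subject Δ-GBC maps with planted low-rank structure.

    maps = mean_map + Σ_k score_sk √λ_k u_k + iid N(0, noise_sd²).  The first
    component u_1 loads oppositely on association and sensory parcels so that
    network-contrast analyses have planted signal; subject scores are iid
    standard normal.

    With ``orthonormal_scores=True`` the score columns are orthonormalized
    and rescaled so the cohort's sample covariance spectrum equals the planted
    eigenspectrum exactly (up to noise) — use this when a condition's
    effective dimensionality itself is the planted quantity, so that it does
    not fluctuate with the score draw.
    """
    lam = np.asarray(eigenspectrum, float)
    if lam.shape != (k,):
        raise InvalidArgumentError(f"eigenspectrum must have length k={k}")
    if np.any(lam <= 0):
        raise InvalidArgumentError("eigenspectrum entries must be strictly positive")
    if np.any(np.diff(lam) > 0):
        raise InvalidArgumentError("eigenspectrum must be non-increasing")
    p = atlas.n_parcels
    if not k < min(n_subjects, p):
        raise InvalidArgumentError("need k < min(n_subjects, n_parcels)")

    rng = np.random.default_rng(seed)
    U = _planted_components(atlas, k, rng)
    scores = rng.standard_normal((n_subjects, k))
    if orthonormal_scores:
        scores = scores - scores.mean(axis=0)
        q, _ = np.linalg.qr(scores)
        scores = q * np.sqrt(n_subjects - 1)
    mu = np.zeros(p) if mean_map is None else np.asarray(mean_map, float)
    maps = mu + (scores * np.sqrt(lam)) @ U
    if noise_sd > 0:
        maps = maps + noise_sd * rng.standard_normal((n_subjects, p))
    truth = GroundTruth(
        component_maps=U, subject_scores=scores, eigenspectrum=lam, mean_map=mu
    )
    return maps, truth


def simulate_session(
    atlas: ParcelAtlas,
    n_frames: int,
    gbc_weight_map: np.ndarray,
    motion_spikes: Sequence[int] = (),
    seed: int = 0,
    tr: float = 0.7,
):
    """One resting-state scan under a one-factor connectivity model.

    x_p(t) = w_p g(t) + ε_p(t) with g, ε iid standard normal, so the expected
    inter-parcel correlation r_pq = w_p w_q / sqrt((w_p²+1)(w_q²+1)) increases
    monotonically with the weights, tying the planted weight map to GBC.
    Motion spikes are injected into the FD/RMS traces only; the BOLD data are
    left clean so scrubbing is exercised on the flags, not on artifact content.
    """
    from .connectivity import ParcelTimeSeries  # local import avoids a cycle

    w = np.asarray(gbc_weight_map, float)
    if w.shape != (atlas.n_parcels,):
        raise InvalidArgumentError("gbc_weight_map length must equal atlas size")
    if n_frames < 50:
        raise InvalidArgumentError("need n_frames >= 50")

    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_frames)
    data = np.outer(g, w) + rng.standard_normal((n_frames, atlas.n_parcels))

    fd = np.clip(np.abs(rng.normal(0.08, 0.04, n_frames)), 0.0, 0.3)
    rms = np.abs(rng.normal(1.0, 0.02, n_frames))
    spikes = np.asarray(sorted(motion_spikes), int)
    if spikes.size:
        if spikes.min() < 0 or spikes.max() >= n_frames:
            raise InvalidArgumentError("motion_spikes out of frame range")
        fd[spikes] = rng.uniform(0.6, 1.2, spikes.size)
        rms[spikes] *= 2.5
    return ParcelTimeSeries(data=data, tr=tr, fd=fd, rms=rms)


def simulate_gene_map(
    atlas: ParcelAtlas,
    smooth_scale: float,
    target_map: np.ndarray,
    target_corr: float,
    seed: int = 0,
) -> np.ndarray:
    """Spatially autocorrelated gene-expression map with a planted correlation.

    Draws a Gaussian random field with exponential spatial covariance
    exp(−d / smooth_scale) over parcel centroids, then mixes it with the
    standardized target map so the population correlation equals
    ``target_corr``.  Output is standardized (mean 0, sd 1).
    """
    if not abs(target_corr) < 1:
        raise InvalidArgumentError("|target_corr| must be < 1")
    if smooth_scale <= 0:
        raise InvalidArgumentError("smooth_scale must be positive")
    t = np.asarray(target_map, float)
    if t.shape != (atlas.n_parcels,):
        raise InvalidArgumentError("target_map length must equal atlas size")

    d = atlas.distances()
    off = d[~np.eye(len(d), dtype=bool)]
    if off.min() == 0:
        raise DegenerateGeometryError("duplicate parcel centroids")
    cov = np.exp(-d / smooth_scale)
    # tiny jitter keeps the Cholesky stable for very smooth fields
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    rng = np.random.default_rng(seed)
    f = L @ rng.standard_normal(atlas.n_parcels)
    if target_corr == 0:
        return (f - f.mean()) / f.std()
    if t.std() == 0:
        raise InvalidArgumentError("target_map is constant; cannot plant a correlation")
    t_hat = (t - t.mean()) / t.std()
    f = f - (f @ t_hat) / (t_hat @ t_hat) * t_hat  # orthogonal to target
    f_hat = (f - f.mean()) / f.std()
    g = target_corr * t_hat + np.sqrt(1 - target_corr**2) * f_hat
    return (g - g.mean()) / g.std()


def simulate_behavior(
    n_subjects: int,
    n_items: int,
    subject_scores: np.ndarray,
    coupling: np.ndarray,
    noise_sd: float,
    seed: int = 0,
    missing_cells: Sequence[tuple[int, int]] = (),
) -> np.ndarray:
    """Behavioral item matrix B = scores · coupling + iid noise.

    ``missing_cells`` optionally blanks (subject, item) entries with NaN for
    imputation tests.
    """
    scores = np.asarray(subject_scores, float)
    C = np.asarray(coupling, float)
    if scores.shape[0] != n_subjects:
        raise InvalidArgumentError("subject_scores row count must equal n_subjects")
    if C.shape != (scores.shape[1], n_items):
        raise InvalidArgumentError("coupling must be (K, n_items)")
    if not np.isfinite(C).all():
        raise InvalidArgumentError("coupling must be finite")
    rng = np.random.default_rng(seed)
    B = scores @ C
    if noise_sd > 0:
        B = B + noise_sd * rng.standard_normal((n_subjects, n_items))
    for i, j in missing_cells:
        B[i, j] = np.nan
    return B
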