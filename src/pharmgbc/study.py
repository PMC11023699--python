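"""End-to-end synthetic study: sessions → Δ-GBC → behavior → neuro-behavioral map.

Ties every pipeline stage together under planted ground truth: paired
placebo/drug sessions whose drug-session connectivity weights shift along a
planted spatial component in proportion to a per-subject score, a behavioral
battery coupled to the same score, and the neuro-behavioral mapping that
should recover both the component map and the subject ordering.

The chain runs the connectivity pipeline without global signal regression:
the one-factor generator's global factor g(t) *is* the planted connectivity
signal and the planted contrast map is mean-zero across parcels, so GSR would
cancel the score-linear part of Δ-GBC exactly.  (On real data GSR removes
spatially persistent artifact; the generator plants no such artifact.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .behavior import DEFAULT_ITEMS, BehaviorMatrix, fit_behavior_pca
from .connectivity import delta_gbc, session_gbc
from .neurobehavioral import (
    NeuroBehavioralMap,
    SubjectProjection,
    mass_univariate_map,
    subject_projection,
)
from .synthetic import _planted_components, make_atlas, simulate_behavior, simulate_session


@dataclass
class ChainResult:
    """Outputs and planted truth of one synthetic study run."""

    atlas: ParcelAtlas
    planted_map: np.ndarray          # unit-norm spatial component, mean zero
    planted_scores: np.ndarray       # per-subject drive of the drug effect
    delta_maps: np.ndarray           # (S, P) Δ(drug − placebo) GBC
    behavior: BehaviorMatrix
    behavior_pc1: np.ndarray         # subject scores on behavioral PC1
    nb_map: NeuroBehavioralMap       # neuro-behavioral PC1 map
    projections: SubjectProjection   # subject similarity to nb_map


def simulate_paired_delta_gbc(
    atlas: ParcelAtlas,
    scores: np.ndarray,
    component: np.ndarray,
    amplitude: float = 2.0,
    baseline_weight: float = 0.5,
    n_frames: int = 400,
    seed: int = 0,
) -> np.ndarray:
    """Δ-GBC maps from paired sessions with a planted drug effect.

    Placebo sessions use a flat connectivity-weight map ``baseline_weight``;
    each drug session shifts the weights by ``amplitude · score_s ·
    component``.  Both sessions run through the scrub → denoise → FC → GBC
    pipeline (no GSR; see module docstring).
    """
    rng = np.random.default_rng(seed)
    w0 = np.full(atlas.n_parcels, baseline_weight)
    deltas = []
    for score in scores:
        ts_p = simulate_session(atlas, n_frames, w0, seed=int(rng.integers(2**31)))
        ts_d = simulate_session(
            atlas, n_frames, w0 + amplitude * score * component,
            seed=int(rng.integers(2**31)),
        )
        g_p = session_gbc(ts_p, gsr=False)
        g_d = session_gbc(ts_d, gsr=False)
        deltas.append(delta_gbc(g_d, g_p).values)
    return np.asarray(deltas)


def run_neurobehavioral_chain(
    seed: int,
    n_parcels: int = 200,
    n_networks: int = 12,
    n_subjects: int = 40,
    n_items: int = 31,
    n_frames: int = 400,
    amplitude: float = 2.0,
    behavior_noise_sd: float = 1.0,
) -> ChainResult:
    """Simulate the full study once and run the neuro-behavioral mapping.

    One planted component drives both the drug effect on connectivity and the
    behavioral battery, mirroring a drug whose symptom response and network
    reorganization share an inter-individual axis.
    """
    atlas = make_atlas(n_parcels, n_networks, seed=0)
    rng = np.random.default_rng(seed)
    component = _planted_components(atlas, 1, rng)[0]
    scores = rng.standard_normal(n_subjects)

    deltas = simulate_paired_delta_gbc(
        atlas, scores, component, amplitude=amplitude, n_frames=n_frames,
        seed=int(rng.integers(2**31)),
    )

    coupling = rng.uniform(0.5, 1.0, size=(1, n_items)) * np.sign(
        rng.standard_normal((1, n_items))
    )
    raw = simulate_behavior(
        n_subjects, n_items, scores[:, None], coupling, behavior_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    items = DEFAULT_ITEMS[:n_items] if n_items <= len(DEFAULT_ITEMS) else [
        f"item{j}" for j in range(n_items)
    ]
    behavior = BehaviorMatrix(pd.DataFrame(raw, columns=items))
    pc1 = fit_behavior_pca(behavior).scores[:, 0]

    nb = mass_univariate_map(deltas, pc1, score_name="behavior_PC1")
    proj = subject_projection(deltas, nb.coef_z)
    return ChainResult(
        atlas=atlas,
        planted_map=component,
        planted_scores=scores,
        delta_maps=deltas,
        behavior=behavior,
        behavior_pc1=pc1,
        nb_map=nb,
        projections=proj,
    )
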