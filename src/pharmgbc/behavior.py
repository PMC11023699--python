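"""Behavioral Δ matrices, behavioral PCA, subscales, and paired-variance test.

The behavioral battery mirrors an acute-pharmacology psychosis assessment: 30
PANSS items (Positive 7, Negative 7, General 16) plus one cognition score
from a spatial working-memory task — 31 Δ(drug − placebo) variables per
subject.  The behavioral PCA standardizes items to unit variance; component
significance uses a column-wise subject-shuffle permutation null.  The
Pitman–Morgan test compares the variances of two paired score vectors (e.g.
PC1 vs PC2 subject scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateInputError, InvalidArgumentError
from .pca import PcaSolution, fit_pca

PANSS_ITEMS = (
    [f"P{i}" for i in range(1, 8)]
    + [f"N{i}" for i in range(1, 8)]
    + [f"G{i}" for i in range(1, 17)]
)
COGNITION_ITEM = "COG"
DEFAULT_ITEMS = PANSS_ITEMS + [COGNITION_ITEM]

#: Conventional PANSS three-factor model: every item in exactly one subscale.
THREE_FACTOR = {
    "Positive": [f"P{i}" for i in range(1, 8)],
    "Negative": [f"N{i}" for i in range(1, 8)],
    "General": [f"G{i}" for i in range(1, 17)],
}

#: Five-factor consensus model (Wallwork 20-item): Positive, Negative,
#: Disorganized, Excited, Depressed; by design it does not cover all items.
FIVE_FACTOR = {
    "Positive": ["P1", "P3", "P5", "G9"],
    "Negative": ["N1", "N2", "N3", "N4", "N6", "G7"],
    "Disorganized": ["P2", "N5", "G11"],
    "Excited": ["P4", "P7", "G8", "G14"],
    "Depressed": ["G2", "G3", "G6"],
}

SUBSCALE_SCHEMES = {
    # scheme -> (config, must cover every PANSS item exactly once?)
    "three_factor": (THREE_FACTOR, True),
    "five_factor": (FIVE_FACTOR, False),
}


def load_subscale_scheme(path) -> str:
    """Register a subscale scheme from a YAML file and return its name.

    The file holds ``name``, ``full_coverage`` and a ``subscales`` mapping of
    subscale name to item list.  The shipped three- and five-factor schemes
    live in ``pharmgbc/configs/``.
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text())
    name = cfg["name"]
    SUBSCALE_SCHEMES[name] = (
        {k: list(v) for k, v in cfg["subscales"].items()},
        bool(cfg.get("full_coverage", False)),
    )
    return name


@dataclass
class BehaviorMatrix:
    """Subjects × items Δ-score table (no missing values after imputation)."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise InvalidArgumentError("behavior matrix contains missing values")

    @property
    def items(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(float)


def assemble_delta_behavior(
    ketamine: pd.DataFrame, placebo: pd.DataFrame, impute: bool = True
) -> BehaviorMatrix:
    """Δ = drug − placebo item matrix, with column-mean imputation.

    Missing cells in either condition propagate to Δ and are then replaced by
    the Δ column mean over observed subjects (which leaves column means
    unchanged).
    """
    if list(ketamine.columns) != list(placebo.columns) or len(ketamine) != len(placebo):
        raise InvalidArgumentError("conditions must share subjects and items")
    delta = ketamine.astype(float) - placebo.astype(float)
    if delta.isna().all().any():
        bad = delta.columns[delta.isna().all()].tolist()
        raise InvalidArgumentError(f"columns entirely missing: {bad}")
    if impute:
        delta = delta.fillna(delta.mean())
    return BehaviorMatrix(delta)


def fit_behavior_pca(b: BehaviorMatrix) -> PcaSolution:
    """PCA of the Δ behavior matrix with items scaled to unit variance."""
    X = b.to_numpy()
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [b.items[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateInputError(f"zero-variance items: {bad}")
    return fit_pca(X, scale=True)


def permute_behavior_significance(
    b: BehaviorMatrix, n_perm: int = 5000, seed: int = 0
) -> PcaSolution:
    """Column-shuffle permutation significance for the behavioral PCA.

    Each permutation independently shuffles subject order within every item
    column before refitting; p_k = (1 + #{var_frac_k ≥ observed}) / (n_perm+1);
    the retained set is {k : p_k < 0.05}.
    """
    if n_perm < 100:
        raise InvalidArgumentError("need n_perm >= 100")
    X = b.to_numpy()
    sol = fit_behavior_pca(b)
    s_n = X.shape[0]
    k = sol.n_components
    rng = np.random.default_rng(seed)
    exceed = np.zeros(k, int)
    for _ in range(n_perm):
        perm = rng.permuted(X, axis=0)  # independent subject shuffle per item
        Xp = perm - perm.mean(axis=0)
        Xp = Xp / Xp.std(axis=0, ddof=1)
        sv = np.linalg.svd(Xp, compute_uv=False)[:k]
        vf = sv**2 / (Xp.var(axis=0, ddof=1).sum() * (s_n - 1))
        exceed += vf >= sol.var_frac[:k]
    sol.perm_p = (1.0 + exceed) / (n_perm + 1.0)
    return sol


def subscale_scores(b: BehaviorMatrix, scheme: str = "three_factor") -> pd.DataFrame:
    """Subjects × subscales table: each subscale is the sum of its member
    item Δ values."""
    if scheme not in SUBSCALE_SCHEMES:
        raise ConfigError(f"unknown scheme {scheme!r}")
    config, full_coverage = SUBSCALE_SCHEMES[scheme]
    used: list[str] = [item for items in config.values() for item in items]
    if len(used) != len(set(used)):
        dup = sorted({i for i in used if used.count(i) > 1})
        raise ConfigError(f"items in multiple subscales: {dup}")
    missing = [i for i in used if i not in b.items]
    if missing:
        raise ConfigError(f"subscale items absent from behavior matrix: {missing}")
    if full_coverage:
        panss_present = [i for i in b.items if i in PANSS_ITEMS]
        uncovered = sorted(set(panss_present) - set(used))
        if uncovered:
            raise ConfigError(f"scheme must cover all PANSS items; missing {uncovered}")
    return pd.DataFrame(
        {name: b.data[items].sum(axis=1) for name, items in config.items()}
    )


@dataclass
class PitmanMorganResult:
    t: float
    df: int
    p: float


def pitman_morgan(x: Sequence[float], y: Sequence[float]) -> PitmanMorganResult:
    """Pitman–Morgan test of equal variances for paired samples.

    With F = s_x²/s_y² and r = corr(x, y):
    t = (F − 1)·√(S − 2) / (2·√(F·(1 − r²))), df = S − 2, two-tailed p.
    At r → ±1 with F ≠ 1 the statistic diverges (t → ±inf, p → 0); F = 1
    gives t = 0 regardless of r.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be paired 1-D vectors")
    s = len(x)
    if s < 4:
        raise InvalidArgumentError("need S >= 4 pairs")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise DegenerateInputError("zero variance in a paired sample")
    F = vx / vy
    r = float(np.corrcoef(x, y)[0, 1])
    df = s - 2
    if F == 1.0:
        t = 0.0
    elif abs(r) >= 1.0:
        t = np.inf if F > 1 else -np.inf
    else:
        t = (F - 1.0) * np.sqrt(df) / (2.0 * np.sqrt(F * (1.0 - r**2)))
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return PitmanMorganResult(t=float(t), df=df, p=float(p))
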