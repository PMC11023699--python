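"""From parcellated BOLD time series to Δ-GBC maps.

Implements the resting-state denoising and connectivity chain: motion
scrubbing (framewise-displacement and intensity-RMS flags with neighbor
discard and whole-subject exclusion), high-pass filtering, nuisance
regression with derivatives and optional global signal regression, Fisher-z
functional connectivity, global brain connectivity (GBC) — each parcel's mean
connectivity with all other parcels — and the drug-minus-placebo Δ-GBC map.

High-pass filtering is implemented as discrete-cosine basis regression (all
DCT regressors below the cutoff removed), which removes DC exactly, has no
filter ringing, and composes with the nuisance design in a single joint OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import (
    FlaggedParcelError,
    InvalidArgumentError,
    TooFewFramesError,
)

R_CLIP = 1.0 - 1e-7  # |r| clip before atanh, bounds z for degenerate pairs


@dataclass
class ParcelTimeSeries:
    """One scan: frames × parcels BOLD matrix plus motion traces.

    data : (F, P) BOLD, arbitrary units
    tr   : repetition time, seconds
    fd   : per-frame framewise displacement, mm
    rms  : per-frame normalized intensity RMS (unitless)
    flags: boolean per frame, True = motion-contaminated
    """

    data: np.ndarray
    tr: float
    fd: np.ndarray
    rms: np.ndarray
    flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.fd = np.asarray(self.fd, float)
        self.rms = np.asarray(self.rms, float)
        f = self.n_frames
        if self.tr <= 0:
            raise InvalidArgumentError("tr must be positive")
        if len(self.fd) != f or len(self.rms) != f:
            raise InvalidArgumentError("fd/rms length must equal frame count")
        if self.flags is not None and len(self.flags) != f:
            raise InvalidArgumentError("flags length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class ScrubResult:
    """Outcome of scrubbing: a cleaned series or a subject-exclusion marker."""

    excluded: bool
    flagged_fraction: float
    ts: Optional[ParcelTimeSeries] = None


@dataclass
class FcMatrix:
    """Fisher-z functional connectivity matrix (diagonal stored as 0)."""

    z: np.ndarray
    n_frames_used: int

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]


@dataclass
class GbcMap:
    """Per-parcel mean Fisher-z connectivity with all other parcels."""

    values: np.ndarray
    subject_id: Optional[str] = None
    condition: Optional[str] = None


def compute_frame_flags(
    fd: np.ndarray,
    rms: np.ndarray,
    fd_thresh: float = 0.5,
    rms_mult: float = 1.6,
) -> np.ndarray:
    """Flag motion-contaminated frames.

    A frame is flagged when FD exceeds ``fd_thresh`` (mm) or its intensity RMS
    exceeds ``rms_mult`` times the scan's median RMS; the frames immediately
    before and after any flagged frame are flagged as well.
    """
    fd = np.asarray(fd, float)
    rms = np.asarray(rms, float)
    if fd.size == 0 or rms.size == 0:
        raise InvalidArgumentError("empty motion trace")
    if fd.shape != rms.shape:
        raise InvalidArgumentError("fd and rms must have equal length")
    base = (fd > fd_thresh) | (rms > rms_mult * np.median(rms))
    flags = base.copy()
    flags[:-1] |= base[1:]   # frame before a flagged frame
    flags[1:] |= base[:-1]   # frame after a flagged frame
    return flags


def scrub(
    ts: ParcelTimeSeries,
    max_flag_frac: float = 0.5,
    min_frames: int = 30,
    fd_thresh: float = 0.5,
    rms_mult: float = 1.6,
) -> ScrubResult:
    """Remove flagged frames; exclude the subject if too many are flagged.

    Flags are taken from ``ts.flags`` when present, otherwise computed from
    the motion traces.  A flagged fraction above ``max_flag_frac`` yields an
    exclusion marker instead of data.
    """
    flags = ts.flags
    if flags is None:
        flags = compute_frame_flags(ts.fd, ts.rms, fd_thresh, rms_mult)
    flags = np.asarray(flags, bool)
    frac = float(flags.mean())
    if frac > max_flag_frac:
        return ScrubResult(excluded=True, flagged_fraction=frac)
    keep = ~flags
    if keep.sum() < min_frames:
        raise TooFewFramesError(
            f"only {int(keep.sum())} frames survive scrubbing (minimum {min_frames})"
        )
    clean = ParcelTimeSeries(
        data=ts.data[keep],
        tr=ts.tr,
        fd=ts.fd[keep],
        rms=ts.rms[keep],
        flags=np.zeros(int(keep.sum()), bool),
    )
    return ScrubResult(excluded=False, flagged_fraction=frac, ts=clean)


def dct_basis(n_frames: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine regressors with frequency below ``cutoff`` (Hz).

    Column j (j ≥ 1) of the full DCT-II basis has frequency j / (2 N tr); the
    returned matrix holds the non-constant columns below the cutoff.  An empty
    (F, 0) matrix means only the intercept is removed.
    """
    n_keep = int(np.floor(2.0 * n_frames * tr * cutoff))
    t = np.arange(n_frames)
    cols = [
        np.cos(np.pi * j * (2 * t + 1) / (2.0 * n_frames)) for j in range(1, n_keep + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


def _ols_residuals(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize columns of ``data`` against ``design``, dropping collinear
    design columns with a warning."""
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} collinear nuisance column(s)",
            stacklevel=3,
        )
        q, _ = np.linalg.qr(design[:, keep])
    return data - q @ (q.T @ data)


def highpass(ts: ParcelTimeSeries, cutoff: float = 0.008) -> ParcelTimeSeries:
    """High-pass filter by removing sub-cutoff discrete-cosine components."""
    nyquist = 0.5 / ts.tr
    if cutoff >= nyquist:
        raise InvalidArgumentError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    if ts.n_frames < 50:
        raise InvalidArgumentError("need at least 50 frames")
    design = np.column_stack([np.ones(ts.n_frames), dct_basis(ts.n_frames, ts.tr, cutoff)])
    return replace(ts, data=_ols_residuals(ts.data, design))


def nuisance_regress(
    ts: ParcelTimeSeries,
    nuisance: Optional[np.ndarray] = None,
    add_derivatives: bool = True,
    gsr: bool = True,
    highpass_cutoff: Optional[float] = None,
) -> ParcelTimeSeries:
    """Joint OLS denoising: nuisance signals, their first derivatives,
    optional global-signal regression, optional DCT high-pass — one design.

    Derivatives are backward differences with a zero first row (preserves
    frame count).  Residuals are exactly orthogonal to every regressor.
    """
    f = ts.n_frames
    cols = [np.ones((f, 1))]
    signals = []
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != f:
            raise InvalidArgumentError("nuisance row count must equal frame count")
        signals.append(nuisance)
    if gsr:
        signals.append(ts.data.mean(axis=1, keepdims=True))
    if signals:
        S = np.hstack(signals)
        cols.append(S)
        if add_derivatives:
            dS = np.vstack([np.zeros((1, S.shape[1])), np.diff(S, axis=0)])
            cols.append(dS)
    if highpass_cutoff is not None:
        cols.append(dct_basis(f, ts.tr, highpass_cutoff))
    design = np.hstack(cols)
    return replace(ts, data=_ols_residuals(ts.data, design))


def fc_matrix(ts: ParcelTimeSeries) -> FcMatrix:
    """Fisher-z functional connectivity: z = atanh(r) with |r| clipped."""
    if ts.n_frames < 30:
        raise TooFewFramesError(f"need >= 30 frames, got {ts.n_frames}")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise FlaggedParcelError(dead.tolist())
    r = np.corrcoef(ts.data, rowvar=False)
    np.clip(r, -R_CLIP, R_CLIP, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return FcMatrix(z=z, n_frames_used=ts.n_frames)


def gbc(fc: FcMatrix, include_self: bool = False) -> GbcMap:
    """Global brain connectivity: each parcel's mean Fisher-z FC with all
    other parcels.  The self-connection is excluded by default (including it
    would add atanh(1), which is unbounded)."""
    z = fc.z
    if not np.allclose(z, z.T):
        raise InvalidArgumentError("FC matrix must be symmetric")
    p = fc.n_parcels
    if include_self:
        values = z.mean(axis=1)
    else:
        values = z.sum(axis=1) / (p - 1)  # diagonal is stored as 0
    return GbcMap(values=values)


def delta_gbc(drug: GbcMap, placebo: GbcMap) -> GbcMap:
    """Δ(drug − placebo) GBC map for one subject."""
    if drug.values.shape != placebo.values.shape:
        raise InvalidArgumentError("GBC maps are on different atlases")
    if drug.subject_id is not None and placebo.subject_id is not None:
        if drug.subject_id != placebo.subject_id:
            raise InvalidArgumentError("GBC maps belong to different subjects")
    return GbcMap(
        values=drug.values - placebo.values,
        subject_id=drug.subject_id,
        condition="delta",
    )


def session_gbc(
    ts: ParcelTimeSeries,
    nuisance: Optional[np.ndarray] = None,
    gsr: bool = True,
    highpass_cutoff: float = 0.008,
    max_flag_frac: float = 0.5,
) -> Optional[GbcMap]:
    """Full single-session chain: scrub → joint denoise → FC → GBC.

    Returns None when the subject is excluded by the scrubbing rule.
    """
    res = scrub(ts, max_flag_frac=max_flag_frac)
    if res.excluded:
        return None
    clean = nuisance_regress(
        res.ts, nuisance=nuisance, gsr=gsr, highpass_cutoff=highpass_cutoff
    )
    return gbc(fc_matrix(clean))
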