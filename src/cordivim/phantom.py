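"""Synthetic cervical-cord diffusion phantom with known IVIM ground truth.

The generator emulates the statistical structure a scan-rescan IVIM study
assumes: a cohort of subjects, each scanned in two sessions, with three
in-plane diffusion-encoding directions, many repetitions per b-value, a
cord-like geometry (central grey-matter region with elevated microvascular
fraction inside a white-matter annulus) and Rician magnitude noise.

Variance components
-------------------
* between-subject: each subject's tissue parameters are drawn once from
  Normal(tissue mean, between-subject SD), clipped into the fit bounds;
* between-session: an independent zero-mean Normal perturbation per session
  (the sole within-subject source besides thermal noise);
* thermal: complex Gaussian noise of SD chosen so the single-repetition b=0
  SNR equals ``snr_single_rep``; magnitude images are therefore Rician.

Tissue means and between-subject SDs default to the voxel-wise one-step
session-1 cohort values for cervical-cord white and grey matter; the
single-repetition SNR default of 27 puts the repetition-averaged data in the
SNR ~ 120 regime (27 * sqrt(20)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import model as _m
from .exceptions import GeometryError, InvalidSpecError
from .model import BValueScheme, ivim_signal

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "GroundTruth",
    "make_geometry",
    "sample_ground_truth",
    "simulate_dataset",
    "DEFAULT_TISSUE_MEANS",
    "DEFAULT_BETWEEN_SUBJECT_SD",
]


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue IVIM parameter triple (F fraction, D* and D in mm^2/s)."""

    F: float
    Dstar: float
    D: float


#: Cohort mean parameters: cervical-cord WM and GM (voxel-wise one-step, session 1).
DEFAULT_TISSUE_MEANS: dict[str, TissueParams] = {
    "WM": TissueParams(F=0.0545, Dstar=24.41e-3, D=3.74e-4),
    "GM": TissueParams(F=0.0961, Dstar=17.14e-3, D=4.17e-4),
}

#: Between-subject SDs on the same scales (cohort SD columns).
DEFAULT_BETWEEN_SUBJECT_SD: dict[str, TissueParams] = {
    "WM": TissueParams(F=0.0075, Dstar=2.61e-3, D=0.49e-4),
    "GM": TissueParams(F=0.0155, Dstar=2.89e-3, D=0.42e-4),
}

#: Session perturbation SD as a fraction of the tissue mean, per parameter.
#: Calibrated so simulated within-subject CVs land in the few-percent range
#: typical of voxel-wise scan-rescan cord data (see docs/methods.md).
DEFAULT_SESSION_EFFECT_REL: dict[str, float] = {"F": 0.05, "Dstar": 0.03, "D": 0.02}


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one simulated cohort."""

    n_subjects: int = 10
    grid: tuple[int, int, int] = (16, 16, 4)
    scheme: BValueScheme = field(default_factory=BValueScheme)
    n_repetitions: int = 20  # total per b-value per direction (2 x 10 phase-encode splits)
    directions: tuple[str, ...] = ("60", "180", "-60")
    tissue_means: Mapping[str, TissueParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS)
    )
    between_subject_sd: Mapping[str, TissueParams] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SUBJECT_SD)
    )
    session_effect_rel: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SESSION_EFFECT_REL)
    )
    snr_single_rep: float = 27.0  # b=0 SNR of one repetition; np.inf = noiseless
    s0: float = 1000.0
    anisotropy: tuple[float, ...] = (1.0, 0.9, 1.1)  # per-direction factor on D
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidSpecError("need at least one subject")
        if not np.isfinite(self.snr_single_rep) and self.snr_single_rep != np.inf:
            raise InvalidSpecError("snr_single_rep must be positive or inf")
        if self.snr_single_rep <= 0:
            raise InvalidSpecError("snr_single_rep must be positive")
        if len(self.anisotropy) != len(self.directions):
            raise InvalidSpecError("one anisotropy factor per direction required")
        if self.n_repetitions < 1:
            raise InvalidSpecError("need at least one repetition")

    @property
    def noiseless(self) -> bool:
        return np.isinf(self.snr_single_rep)


@dataclass
class Geometry:
    """Cord geometry shared by all subjects and sessions."""

    cord_mask: np.ndarray  # (nx, ny, nz) bool
    wm_prob: np.ndarray  # (nx, ny, nz) float in [0, 1]
    gm_prob: np.ndarray
    labels: np.ndarray  # (nx, ny, nz) int: 0 none, 1 WM, 2 GM
    levels: np.ndarray  # (nz,) int vertebral-level analogue per slice


@dataclass
class GroundTruth:
    """Lossless record of the generating parameters for recovery scoring.

    ``subject_params[subject][tissue]`` is the subject-level TissueParams;
    ``session_params[(subject, session)][tissue]`` the per-session value;
    ``maps[(subject, session, direction)]`` holds per-voxel (F, Dstar, D)
    arrays after the direction anisotropy factor is applied to D.
    """

    geometry: Geometry
    subject_params: dict[int, dict[str, TissueParams]]
    session_params: dict[tuple[int, int], dict[str, TissueParams]]
    maps: dict[tuple[int, int, str], dict[str, np.ndarray]]


def make_geometry(grid: tuple[int, int, int]) -> Geometry:
    """Build an elliptical cord cross-section with a central GM region.

    The same geometry is used for every subject and session (data are
    generated pre-aligned in a common space).  Probabilistic WM and GM masks
    have a soft boundary band and sum to <= 1 per voxel; hard tissue labels
    assign each cord voxel to its dominant tissue.
    """
    nx, ny, nz = grid
    if nx < 12 or ny < 12 or nz < 1:
        raise GeometryError(f"grid {grid} too small for a >= 5-voxel cord")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    # elliptical radii scale mildly with the grid but stay cord-like
    rx, ry = min(4.5, 0.30 * nx), min(3.5, 0.26 * ny)
    r_cord = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2)
    cord2d = r_cord <= 1.0
    if cord2d.sum() < 20:
        raise GeometryError("cord cross-section too small")
    # central GM ellipse with a linear soft band between r=0.7 and r=1.3
    gx, gy = 0.42 * rx, 0.40 * ry
    r_gm = np.sqrt(((x - cx) / gx) ** 2 + ((y - cy) / gy) ** 2)
    gm2d = np.clip((1.3 - r_gm) / 0.6, 0.0, 1.0)
    gm2d[~cord2d] = 0.0
    # WM fills the annulus, tapering at the cord edge against CSF
    edge_taper = np.clip((1.0 - r_cord) / 0.15, 0.0, 1.0)
    wm2d = (1.0 - gm2d) * edge_taper
    wm2d[~cord2d] = 0.0

    cord = np.repeat(cord2d[:, :, None], nz, axis=2)
    wm = np.repeat(wm2d[:, :, None], nz, axis=2)
    gm = np.repeat(gm2d[:, :, None], nz, axis=2)
    labels = np.zeros(grid, dtype=np.int8)
    labels[cord & (gm > wm)] = 2
    labels[cord & (gm <= wm)] = 1
    # slices split evenly into three vertebral-level analogues
    levels = 1 + (3 * np.arange(nz)) // max(nz, 1)
    levels = np.minimum(levels, 3).astype(int)
    return Geometry(cord_mask=cord, wm_prob=wm, gm_prob=gm, labels=labels, levels=levels)


def _clip_tissue(t: TissueParams) -> TissueParams:
    return TissueParams(
        F=float(np.clip(t.F, *_m.F_BOUNDS)),
        Dstar=float(np.clip(t.Dstar, *_m.DSTAR_BOUNDS)),
        D=float(np.clip(t.D, *_m.D_BOUNDS)),
    )


def sample_ground_truth(spec: PhantomSpec, geometry: Geometry | None = None) -> GroundTruth:
    """Draw subject- and session-level tissue parameters and per-voxel maps.

    Subject values ~ Normal(tissue mean, between-subject SD); the session
    value adds an independent Normal(0, session SD) perturbation per session;
    D carries an additional per-direction anisotropy factor.  F and D* are
    direction-independent.  All draws are clipped into the fit bounds.
    """
    geo = geometry if geometry is not None else make_geometry(spec.grid)
    rng = np.random.default_rng(spec.seed)
    subject_params: dict[int, dict[str, TissueParams]] = {}
    session_params: dict[tuple[int, int], dict[str, TissueParams]] = {}
    maps: dict[tuple[int, int, str], dict[str, np.ndarray]] = {}
    tissues = list(spec.tissue_means)
    for subj in range(spec.n_subjects):
        subject_params[subj] = {}
        for tis in tissues:
            mu, sd = spec.tissue_means[tis], spec.between_subject_sd[tis]
            subject_params[subj][tis] = _clip_tissue(
                TissueParams(
                    F=mu.F + sd.F * rng.standard_normal(),
                    Dstar=mu.Dstar + sd.Dstar * rng.standard_normal(),
                    D=mu.D + sd.D * rng.standard_normal(),
                )
            )
        for sess in (1, 2):
            session_params[(subj, sess)] = {}
            for tis in tissues:
                base = subject_params[subj][tis]
                mu = spec.tissue_means[tis]
                rel = spec.session_effect_rel
                session_params[(subj, sess)][tis] = _clip_tissue(
                    TissueParams(
                        F=base.F + rel["F"] * mu.F * rng.standard_normal(),
                        Dstar=base.Dstar + rel["Dstar"] * mu.Dstar * rng.standard_normal(),
                        D=base.D + rel["D"] * mu.D * rng.standard_normal(),
                    )
                )
            for d_idx, direction in enumerate(spec.directions):
                fmap = np.zeros(spec.grid)
                dsmap = np.zeros(spec.grid)
                dmap = np.zeros(spec.grid)
                for code, tis in ((1, "WM"), (2, "GM")):
                    if tis not in session_params[(subj, sess)]:
                        continue
                    t = session_params[(subj, sess)][tis]
                    sel = geo.labels == code
                    fmap[sel] = t.F
                    dsmap[sel] = t.Dstar
                    dmap[sel] = float(
                        np.clip(t.D * spec.anisotropy[d_idx], *_m.D_BOUNDS)
                    )
                maps[(subj, sess, direction)] = {"F": fmap, "Dstar": dsmap, "D": dmap}
    return GroundTruth(
        geometry=geo,
        subject_params=subject_params,
        session_params=session_params,
        maps=maps,
    )


def simulate_dataset(
    spec: PhantomSpec, truth: GroundTruth | None = None
) -> tuple[dict[tuple[int, int, str], np.ndarray], np.ndarray, GroundTruth]:
    """Generate raw repetition-resolved magnitude volumes for a whole cohort.

    Returns
    -------
    volumes : dict
        ``volumes[(subject, session, direction)]`` is an
        ``(nx, ny, nz, n_b * n_rep)`` array; frames are ordered b-major
        (all repetitions of b[0], then of b[1], ...).  Voxels outside the
        cord carry pure noise magnitude (or 0 in the noiseless limit).
    bvals : (n_b * n_rep,) array
        FSL-dialect b-value per frame.
    truth : GroundTruth

    Noise is complex Gaussian of SD ``s0 / snr_single_rep`` added to the
    noiseless signal before taking the magnitude, i.e. Rician; the SD -> 0
    limit (``snr_single_rep=inf``) reproduces the forward model exactly.
    """
    truth = truth if truth is not None else sample_ground_truth(spec)
    geo = truth.geometry
    b = spec.scheme.b
    n_b, n_rep = b.size, spec.n_repetitions
    bvals = np.repeat(b, n_rep)
    sigma = 0.0 if spec.noiseless else spec.s0 / spec.snr_single_rep
    rng = np.random.default_rng(spec.seed + 1)
    volumes: dict[tuple[int, int, str], np.ndarray] = {}
    cord = geo.cord_mask
    for subj in range(spec.n_subjects):
        for sess in (1, 2):
            for direction in spec.directions:
                tm = truth.maps[(subj, sess, direction)]
                nvox = int(cord.sum())
                sig = ivim_signal(
                    b[None, :],
                    spec.s0,
                    tm["F"][cord][:, None],
                    tm["Dstar"][cord][:, None],
                    tm["D"][cord][:, None],
                )  # (nvox, n_b)
                vol = np.zeros(spec.grid + (n_b * n_rep,))
                clean = np.zeros(spec.grid + (n_b,))
                clean[cord] = sig
                clean_frames = np.repeat(clean, n_rep, axis=3)
                if sigma == 0.0:
                    vol = clean_frames
                else:
                    re = clean_frames + sigma * rng.standard_normal(clean_frames.shape)
                    im = sigma * rng.standard_normal(clean_frames.shape)
                    vol = np.hypot(re, im)
                volumes[(subj, sess, direction)] = vol
    return volumes, bvals, truth
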