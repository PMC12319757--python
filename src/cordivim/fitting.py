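"""Constrained one-step and two-step IVIM fitting.

Two standard constrained algorithms are provided:

* **one-step** — a prior D is estimated from the mono-exponential high-b tail
  (b > cut-off), then all four parameters (S0, F, D*, D) are fitted jointly
  over all b-values by Differential Evolution inside hard physical bounds,
  followed by a fine-tuning pass in which every parameter's search window is
  shrunk to 95-105 % of its global-stage estimate.
* **two-step (segmented)** — D is fixed to the mono-exponential high-b
  estimate and only (S0, F, D*) are fitted globally, then fine-tuned; the
  returned D is exactly the closed-form high-b log-linear slope (clipped to
  the D bounds).

The estimator is scikit-learn shaped: construct with hyperparameters, call
``fit(X)`` on an ``(n_decays, n_bvalues)`` array, read fitted attributes
(``params_``, ``r2_``, ``converged_``).  Thin module-level functions wrap it
for single decays, voxel grids and probabilistic ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from . import model as _m
from .exceptions import (
    EmptyMaskError,
    EmptyROIError,
    InsufficientDataError,
    InvalidSignalError,
    LogDomainError,
)
from .model import BValueScheme, IVIMParams, SignalDecay, ivim_signal, r_squared

__all__ = [
    "FitConfig",
    "FitResult",
    "IVIMFitter",
    "estimate_D_monoexp",
    "fit_one_step",
    "fit_two_step",
    "fit_voxelwise",
    "roi_average_decay",
    "fit_roiwise",
    "PARAM_MAP_NAMES",
]

#: Map volumes produced by voxel-wise fitting, in output order.
PARAM_MAP_NAMES = ("S0", "F", "Dstar", "D", "FDstar", "R2")

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "F": _m.F_BOUNDS,
    "Dstar": _m.DSTAR_BOUNDS,
    "D": _m.D_BOUNDS,
}


@dataclass(frozen=True)
class FitConfig:
    """Full configuration of a fit.

    ``bounds`` uses internal units (F as a fraction, diffusivities in mm^2/s).
    ``s0_window`` bounds S0 relative to the observed b=0 signal; S0 is fitted
    as a free nuisance parameter so noise in the b=0 frames is absorbed
    (normalisation-only handling available via ``fit_s0=False``).
    ``narrow_D_from_prior`` optionally shrinks the D search interval to
    [0.5, 2.0] x the mono-exponential prior (intersected with the global
    bounds); by default the published global bounds alone constrain D.
    """

    algorithm: str = "one_step"  # {"one_step", "two_step"}
    mode: str = "voxel_wise"  # {"voxel_wise", "roi_wise"} — provenance only
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    cutoff_b: float = _m.DEFAULT_CUTOFF_B
    finetune_window: tuple[float, float] = (0.95, 1.05)
    s0_window: tuple[float, float] = (0.5, 1.5)
    fit_s0: bool = True
    narrow_D_from_prior: bool = False
    popsize: int = 15  # population = popsize * n_free_parameters
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    tol: float = 1e-7
    maxiter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("one_step", "two_step"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.mode not in ("voxel_wise", "roi_wise"):
            raise ValueError(f"unknown mode {self.mode!r}")
        lo, hi = self.finetune_window
        if not lo < 1.0 < hi:
            raise ValueError("finetune_window must straddle 1.0")

    def bound(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, _DEFAULT_BOUNDS[name]))  # type: ignore[return-value]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one decay fit: parameters, goodness of fit and provenance."""

    params: IVIMParams
    r2: float
    converged: bool
    n_points: int
    provenance: dict


def estimate_D_monoexp(
    decay: SignalDecay, cutoff_b: float | None = None
) -> tuple[float, float]:
    """Prior estimate of D from the mono-exponential tail above the cut-off.

    A least-squares line is fitted to ln S against b restricted to
    b > ``cutoff_b``; the slope gives D (clipped into the physical D bounds)
    and the intercept the extrapolated high-b amplitude.

    Returns
    -------
    (D, S0_highb)
        Slope-derived diffusion coefficient (mm^2/s, clipped into bounds) and
        the intercept amplitude exp(a) of the log-linear fit.

    Raises
    ------
    InsufficientDataError
        Fewer than two b-values above the cut-off.
    LogDomainError
        Non-positive signal at any used b-value.
    """
    if cutoff_b is None:
        cutoff_b = decay.scheme.cutoff
    b = decay.scheme.b
    y = decay.y
    sel = b > cutoff_b
    if int(sel.sum()) < 2:
        raise InsufficientDataError(
            f"need >= 2 b-values above {cutoff_b}, got {int(sel.sum())}"
        )
    if np.any(y[sel] <= 0):
        raise LogDomainError("non-positive signal above the cut-off b-value")
    slope, intercept = np.polyfit(b[sel], np.log(y[sel]), 1)
    lo, hi = _m.D_BOUNDS
    d = float(np.clip(-slope, lo, hi))
    return d, float(np.exp(intercept))


class IVIMFitter:
    """Constrained IVIM model fitting, scikit-learn style.

    Parameters mirror :class:`FitConfig`; pass either individual keyword
    arguments or a ready-made ``config``.

    After ``fit(X)`` on an ``(n_decays, n_b)`` array the estimator exposes

    - ``params_`` : ``(n_decays, 4)`` array of (S0, F, Dstar, D),
    - ``fdstar_`` : derived F*D* per decay,
    - ``r2_`` : coefficient of determination per decay,
    - ``converged_`` : boolean per decay,
    - ``results_`` : list of :class:`FitResult`.

    The fit is bit-reproducible for a fixed ``seed`` and independent of the
    order of the rows of ``X``.
    """

    def __init__(
        self,
        scheme: BValueScheme | None = None,
        *,
        config: FitConfig | None = None,
        **overrides,
    ) -> None:
        self.scheme = scheme if scheme is not None else BValueScheme()
        base = config if config is not None else FitConfig()
        self.config = replace(base, **overrides) if overrides else base

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"scheme": self.scheme, "config": self.config}

    def set_params(self, **params) -> "IVIMFitter":
        if "scheme" in params:
            self.scheme = params.pop("scheme")
        if "config" in params:
            self.config = params.pop("config")
        if params:
            self.config = replace(self.config, **params)
        return self

    # -- core single-decay machinery --------------------------------------
    def _validate_decay(self, y: np.ndarray) -> None:
        if y.shape != (len(self.scheme),):
            raise InvalidSignalError(
                f"decay length {y.shape} does not match scheme ({len(self.scheme)})"
            )
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise InvalidSignalError("decay must be finite and non-negative")
        if np.all(y == 0):
            raise InvalidSignalError("all-zero decay cannot be fitted")

    def _stage_bounds(self, y: np.ndarray, prior_d: float) -> list[tuple[float, float]]:
        cfg = self.config
        s0_obs = float(y[0]) if y[0] > 0 else float(np.max(y))
        s0_lo, s0_hi = cfg.s0_window[0] * s0_obs, cfg.s0_window[1] * s0_obs
        if not cfg.fit_s0:
            s0_lo = s0_hi = s0_obs
        d_lo, d_hi = cfg.bound("D")
        if cfg.narrow_D_from_prior:
            d_lo = max(d_lo, 0.5 * prior_d)
            d_hi = min(d_hi, 2.0 * prior_d)
            if d_lo >= d_hi:  # prior at a bound: fall back to global interval
                d_lo, d_hi = cfg.bound("D")
        return [(s0_lo, s0_hi), cfg.bound("F"), cfg.bound("Dstar"), (d_lo, d_hi)]

    def _global_stage(
        self,
        y: np.ndarray,
        bounds: list[tuple[float, float]],
        fixed: dict[int, float],
        x_seed: np.ndarray,
    ) -> tuple[np.ndarray, bool]:
        """Differential Evolution over the free parameters; returns full x."""
        cfg = self.config
        b = self.scheme.b
        free = [i for i in range(4) if i not in fixed]
        fixed_idx = np.array(sorted(fixed), dtype=int)
        fixed_val = np.array([fixed[i] for i in sorted(fixed)], dtype=float)
        free_bounds = [bounds[i] for i in free]

        def objective(xt: np.ndarray) -> np.ndarray:
            # vectorized: xt has shape (n_free, S)
            xt = np.atleast_2d(xt)
            if xt.shape[0] != len(free):
                xt = xt.T
            full = np.empty((4, xt.shape[1]))
            full[free, :] = xt
            if fixed_idx.size:
                full[fixed_idx, :] = fixed_val[:, None]
            s = ivim_signal(b[:, None], full[0], full[1], full[2], full[3])
            return np.sum((s - y[:, None]) ** 2, axis=0)

        n_free = len(free)
        rng = np.random.default_rng(cfg.seed)
        lo = np.array([bb[0] for bb in free_bounds])
        hi = np.array([bb[1] for bb in free_bounds])
        span = hi - lo
        npop = max(cfg.popsize * n_free, 5)
        init = lo + rng.random((npop, n_free)) * span
        # seed one individual with the prior-informed guess
        init[0] = np.clip(x_seed[free], lo, hi)
        if np.any(span == 0):  # degenerate axes confuse DE; jitter epsilon
            init[:, span == 0] = lo[span == 0]
        result = differential_evolution(
            objective,
            bounds=[(l, h if h > l else l + 1e-300) for l, h in free_bounds],
            init=init,
            mutation=cfg.mutation,
            recombination=cfg.recombination,
            tol=cfg.tol,
            maxiter=cfg.maxiter,
            seed=cfg.seed,
            polish=True,
            updating="deferred",
            vectorized=True,
        )
        full = np.empty(4)
        full[free] = np.clip(result.x, lo, hi)
        for i, v in fixed.items():
            full[i] = v
        return full, bool(result.success)

    def _finetune_stage(
        self,
        y: np.ndarray,
        x2: np.ndarray,
        global_bounds: list[tuple[float, float]],
        fixed: dict[int, float],
    ) -> np.ndarray:
        """Refinement with each free parameter confined to w0..w1 x its estimate.

        The shrunk window is intersected with the global bounds so the
        refinement can never exit physical ranges; a parameter whose window
        collapses (estimate at 0 or pinned by the intersection) stays fixed.
        """
        cfg = self.config
        w0, w1 = cfg.finetune_window
        b = self.scheme.b
        lo = np.empty(4)
        hi = np.empty(4)
        for i in range(4):
            gl, gh = global_bounds[i]
            est = x2[i]
            wl, wh = sorted((w0 * est, w1 * est))
            lo[i] = max(gl, wl)
            hi[i] = min(gh, wh)
            if lo[i] > hi[i]:  # estimate sits on a bound: one-sided window
                lo[i] = hi[i] = float(np.clip(est, gl, gh))
        for i, v in fixed.items():
            lo[i] = hi[i] = v
        free = [i for i in range(4) if hi[i] - lo[i] > 1e-15 * max(abs(hi[i]), 1e-30)]
        if not free:
            return np.clip(x2, lo, hi)
        x_full = np.clip(x2, lo, hi)

        def residuals(xf: np.ndarray) -> np.ndarray:
            full = x_full.copy()
            full[free] = xf
            return ivim_signal(b, *full) - y

        sol = least_squares(
            residuals,
            x0=x_full[free],
            bounds=(lo[free], hi[free]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        x_full[free] = sol.x
        return np.clip(x_full, lo, hi)

    def _fit_single(self, y: np.ndarray) -> FitResult:
        self._validate_decay(y)
        cfg = self.config
        decay = SignalDecay(self.scheme, tuple(y.tolist()))
        prior_d, s0_highb = estimate_D_monoexp(decay, cfg.cutoff_b)
        bounds = self._stage_bounds(y, prior_d)
        f_mid = 0.5 * sum(cfg.bound("F"))
        ds_mid = float(np.sqrt(np.prod(np.clip(cfg.bound("Dstar"), 1e-12, None))))
        s0_obs = float(y[0]) if y[0] > 0 else float(np.max(y))
        x_seed = np.array([s0_obs, f_mid, ds_mid, prior_d])

        fixed: dict[int, float] = {}
        if cfg.algorithm == "two_step":
            fixed[3] = prior_d  # D held at the segmented estimate throughout
        if not cfg.fit_s0:
            fixed[0] = s0_obs

        x2, success = self._global_stage(y, bounds, fixed, x_seed)
        unidentifiable = x2[1] <= 1e-6  # no perfusion compartment: D* arbitrary
        if unidentifiable:
            x2[2] = cfg.bound("Dstar")[0]
        x3 = self._finetune_stage(y, x2, bounds, fixed)
        if unidentifiable:
            x3[2] = cfg.bound("Dstar")[0]
        params = IVIMParams(S0=float(x3[0]), F=float(x3[1]), Dstar=float(x3[2]), D=float(x3[3]))
        fit_y = ivim_signal(self.scheme.b, *x3)
        try:
            r2 = r_squared(y, fit_y)
        except Exception:
            r2 = float("nan")
        return FitResult(
            params=params,
            r2=r2,
            converged=success,
            n_points=len(self.scheme),
            provenance={
                "algorithm": cfg.algorithm,
                "mode": cfg.mode,
                "seed": cfg.seed,
                "prior_D": prior_d,
                "Dstar_unidentifiable": bool(unidentifiable),
            },
        )

    # -- public API --------------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "IVIMFitter":
        """Fit every row of ``X`` (``(n_decays, n_b)``) independently.

        Byte-identical rows are fitted once and shared (the fit is a pure
        function of the decay for a fixed configuration).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        results: list[FitResult] = []
        cache: dict[bytes, FitResult] = {}
        for row in X:
            key = row.tobytes()
            res = cache.get(key)
            if res is None:
                res = self._fit_single(row)
                cache[key] = res
            results.append(res)
        self.results_ = results
        self.params_ = np.array(
            [[r.params.S0, r.params.F, r.params.Dstar, r.params.D] for r in results]
        )
        self.fdstar_ = np.array([r.params.FDstar for r in results])
        self.r2_ = np.array([r.r2 for r in results])
        self.converged_ = np.array([r.converged for r in results])
        return self

    def fit_decay(self, decay: SignalDecay) -> FitResult:
        """Fit a single :class:`SignalDecay` and return its :class:`FitResult`."""
        if tuple(decay.scheme.bvalues) != tuple(self.scheme.bvalues):
            self.scheme = decay.scheme
        return self._fit_single(decay.y)


def fit_one_step(decay: SignalDecay, config: FitConfig | None = None) -> FitResult:
    """One-step constrained fit of a single decay (prior D, global DE, fine-tune)."""
    cfg = replace(config, algorithm="one_step") if config else FitConfig(algorithm="one_step")
    return IVIMFitter(decay.scheme, config=cfg).fit_decay(decay)


def fit_two_step(decay: SignalDecay, config: FitConfig | None = None) -> FitResult:
    """Two-step (segmented) fit: D fixed from the high-b tail, then F and D*."""
    cfg = replace(config, algorithm="two_step") if config else FitConfig(algorithm="two_step")
    return IVIMFitter(decay.scheme, config=cfg).fit_decay(decay)


def fit_voxelwise(
    volume: np.ndarray,
    mask: np.ndarray,
    scheme: BValueScheme,
    config: FitConfig | None = None,
) -> dict[str, np.ndarray]:
    """Fit each masked voxel of a repetition-averaged 4D volume.

    Parameters
    ----------
    volume : (nx, ny, nz, n_b) array
        One frame per b-value (already averaged across repetitions), for a
        single diffusion-encoding direction.
    mask : (nx, ny, nz) boolean array
    scheme, config
        Acquisition scheme and fit configuration.

    Returns
    -------
    dict mapping each of ``PARAM_MAP_NAMES`` to an (nx, ny, nz) float map,
    NaN outside the mask.  F is stored as a fraction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape[:3]:
        raise InvalidSignalError("mask grid does not match volume grid")
    if not mask.any():
        raise EmptyMaskError("mask selects no voxels")
    cfg = config if config is not None else FitConfig()
    idx = np.argwhere(mask)
    X = volume[mask]  # (n_voxels, n_b)
    fitter = IVIMFitter(scheme, config=cfg).fit(X)
    maps = {name: np.full(volume.shape[:3], np.nan) for name in PARAM_MAP_NAMES}
    vals = {
        "S0": fitter.params_[:, 0],
        "F": fitter.params_[:, 1],
        "Dstar": fitter.params_[:, 2],
        "D": fitter.params_[:, 3],
        "FDstar": fitter.fdstar_,
        "R2": fitter.r2_,
    }
    for name in PARAM_MAP_NAMES:
        maps[name][idx[:, 0], idx[:, 1], idx[:, 2]] = vals[name]
    return maps


def roi_average_decay(
    volume: np.ndarray,
    prob_mask: np.ndarray,
    slice_index: int,
    scheme: BValueScheme,
) -> SignalDecay:
    """Probability-weighted average decay of one slice of a probabilistic ROI.

    For each b-value returns sum(p_i * s_i) / sum(p_i) over the voxels of the
    slice.

    Raises
    ------
    EmptyROIError
        If the slice carries zero total probability.
    """
    p = np.asarray(prob_mask, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidSignalError("probabilities must lie in [0, 1]")
    p_slice = p[:, :, slice_index]
    total = float(p_slice.sum())
    if total <= 0:
        raise EmptyROIError(f"slice {slice_index} has zero ROI probability")
    sig = volume[:, :, slice_index, :]  # (nx, ny, n_b)
    avg = np.tensordot(p_slice, sig, axes=([0, 1], [0, 1])) / total
    return SignalDecay(scheme=scheme, values=tuple(avg.tolist()), weight=total)


def fit_roiwise(
    volume: np.ndarray,
    prob_mask: np.ndarray,
    scheme: BValueScheme,
    config: FitConfig | None = None,
    *,
    _cache: dict | None = None,
) -> dict[int, FitResult]:
    """ROI-wise fit: weighted-average decay per slice, then one fit per slice.

    Slices with no ROI support are skipped (absent from the result, never
    zero-filled); a failing slice is recorded as absent as well.
    """
    cfg = replace(config, mode="roi_wise") if config else FitConfig(mode="roi_wise")
    fitter = IVIMFitter(scheme, config=cfg)
    out: dict[int, FitResult] = {}
    cache = _cache if _cache is not None else {}
    for k in range(volume.shape[2]):
        try:
            decay = roi_average_decay(volume, prob_mask, k, scheme)
        except EmptyROIError:
            continue
        key = decay.y.tobytes()
        res = cache.get(key)
        if res is None:
            res = fitter.fit_decay(decay)
            cache[key] = res
        out[k] = res
    return out
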