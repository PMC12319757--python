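"""Study orchestration: dataset I/O, QC, fitting passes and reporting.

A study runs, per subject and session:

1. repetition averaging per b-value and direction;
2. voxel-wise SNR QC on the b=0 repetitions (mean/SD scaled by sqrt(Nrep));
3. IVIM fits in each diffusion-encoding direction, in the configured
   approaches (voxel-wise, ROI-wise) and algorithms (one-step, two-step);
4. averaging of parameter maps across directions;
5. cord-periphery mask erosion and metric extraction over the configured
   vertebral-level range;

and finally the test-retest reliability battery on the per-subject session
pairs.  Everything is deterministic under fixed seeds and every artifact is
recorded in a JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DatasetError, EmptyMaskError
from .fitting import FitConfig, fit_roiwise, fit_voxelwise
from .model import BValueScheme
from .phantom import Geometry, GroundTruth, PhantomSpec, make_geometry, simulate_dataset
from .reliability import cv_design_from_table, reliability_report, rm_anova_2x2

__all__ = [
    "DiffusionDataset",
    "PipelineConfig",
    "StudyResult",
    "read_dataset",
    "write_dataset",
    "average_repetitions",
    "compute_snr_map",
    "erode_mask",
    "sphere_element",
    "average_maps_across_directions",
    "extract_metrics",
    "run_study",
]

log = logging.getLogger("cordivim")

_EXTRACT_PARAMS = ("F", "Dstar", "FDstar", "D")


@dataclass
class DiffusionDataset:
    """One cohort's diffusion data plus masks and slice-level labels.

    ``volumes[(subject, session, direction)]`` is a 4D array whose 4th axis
    is described frame-by-frame by ``bvals`` (FSL dialect: repetitions appear
    as repeated b-value entries).
    """

    volumes: dict[tuple[int, int, str], np.ndarray]
    bvals: np.ndarray
    scheme: BValueScheme
    cord_mask: np.ndarray
    wm_prob: np.ndarray
    gm_prob: np.ndarray
    levels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        grid = self.cord_mask.shape
        for key, vol in self.volumes.items():
            if vol.shape[:3] != grid:
                raise DatasetError(f"volume {key} grid {vol.shape[:3]} != mask grid {grid}")
            if vol.shape[3] != self.bvals.size:
                raise DatasetError(
                    f"volume {key} has {vol.shape[3]} frames for {self.bvals.size} b-table entries"
                )
        scheme_b = set(self.scheme.b.tolist())
        if set(self.bvals.tolist()) != scheme_b:
            raise DatasetError("b-table values do not match the scheme")
        counts = {b: int(np.sum(self.bvals == b)) for b in scheme_b}
        if len(set(counts.values())) != 1:
            raise DatasetError(f"unequal repetition counts per b-value: {counts}")
        if self.levels.shape[0] != grid[2]:
            raise DatasetError("one level label per slice required")

    @property
    def n_repetitions(self) -> int:
        return int(np.sum(self.bvals == self.bvals[0]))

    @property
    def subjects(self) -> list[int]:
        return sorted({k[0] for k in self.volumes})

    @property
    def directions(self) -> list[str]:
        seen: list[str] = []
        for k in self.volumes:
            if k[2] not in seen:
                seen.append(k[2])
        return seen


@dataclass
class PipelineConfig:
    """End-to-end study configuration."""

    fit: FitConfig = field(default_factory=FitConfig)
    phantom: PhantomSpec | None = None  # simulate mode when present
    erosion_radius: int = 1
    level_range: tuple[int, int] | None = None  # inclusive; None = all levels
    approaches: tuple[str, ...] = ("voxel_wise", "roi_wise")
    algorithms: tuple[str, ...] = ("one_step", "two_step")
    weighted_extraction: bool = True  # probability-weighted voxel-wise ROI means
    out_dir: Path | None = None
    write_maps: bool = False


@dataclass
class StudyResult:
    """All study outputs: tables, reports and the provenance manifest."""

    test_retest: pd.DataFrame
    report: pd.DataFrame
    anova: dict[tuple[str, str], pd.DataFrame]
    snr_summary: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# I/O


def write_dataset(data: DiffusionDataset, out_dir: str | Path) -> dict:
    """Write a dataset as NIfTI volumes + FSL bval text + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bval_path = out / "bvals.txt"
    bval_path.write_text(" ".join(f"{b:g}" for b in data.bvals) + "\n")
    entries = []
    for (subj, sess, direction), vol in data.volumes.items():
        name = f"sub-{subj:02d}_ses-{sess}_dir-{direction}_dwi.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float64), data.affine), out / name)
        entries.append(
            {"subject": subj, "session": sess, "direction": direction, "file": name}
        )
    for name, arr in (
        ("cord_mask.nii", data.cord_mask.astype(np.uint8)),
        ("wm_prob.nii", data.wm_prob.astype(np.float64)),
        ("gm_prob.nii", data.gm_prob.astype(np.float64)),
    ):
        nib.save(nib.Nifti1Image(arr, data.affine), out / name)
    manifest = {
        "bvals": "bvals.txt",
        "cutoff_b": data.scheme.cutoff,
        "levels": data.levels.tolist(),
        "volumes": entries,
        "masks": {"cord": "cord_mask.nii", "wm": "wm_prob.nii", "gm": "gm_prob.nii"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(in_dir: str | Path) -> DiffusionDataset:
    """Read a dataset written by :func:`write_dataset`, validating consistency.

    Raises :class:`DatasetError` with a precise message on frame-count vs
    b-table mismatch, grid mismatch or unreadable components.
    """
    root = Path(in_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise DatasetError(f"no manifest.json under {root}")
    manifest = json.loads(manifest_path.read_text())
    try:
        bvals = np.array(
            [float(t) for t in (root / manifest["bvals"]).read_text().split()]
        )
    except ValueError as err:
        raise DatasetError(f"unparsable b-table: {err}") from err
    unique_b = np.unique(bvals)
    scheme = BValueScheme(bvalues=tuple(unique_b.tolist()), cutoff=manifest.get("cutoff_b", 400.0))
    volumes = {}
    affine = None
    for entry in manifest["volumes"]:
        img = nib.load(root / entry["file"])
        affine = img.affine if affine is None else affine
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise DatasetError(f"{entry['file']} is not 4-D")
        if vol.shape[3] != bvals.size:
            raise DatasetError(
                f"{entry['file']}: {vol.shape[3]} frames but b-table has {bvals.size} entries"
            )
        volumes[(entry["subject"], entry["session"], entry["direction"])] = vol
    masks = {
        key: np.asarray(nib.load(root / fname).dataobj, dtype=float)
        for key, fname in manifest["masks"].items()
    }
    return DiffusionDataset(
        volumes=volumes,
        bvals=bvals,
        scheme=scheme,
        cord_mask=masks["cord"] > 0.5,
        wm_prob=masks["wm"],
        gm_prob=masks["gm"],
        levels=np.asarray(manifest["levels"], dtype=int),
        affine=affine if affine is not None else np.eye(4),
    )


# ---------------------------------------------------------------------------
# QC and averaging


def average_repetitions(vol: np.ndarray, bvals: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Average frames across repetitions per b-value.

    Returns (averaged volume with one frame per unique b, the unique
    b-values in ascending order, the repetition count).  Unequal repetition
    counts across b-values are rejected.
    """
    bvals = np.asarray(bvals, dtype=float)
    unique_b = np.unique(bvals)
    counts = {b: int(np.sum(bvals == b)) for b in unique_b}
    if len(set(counts.values())) != 1:
        raise DatasetError(f"incomplete repetitions: {counts}")
    n_rep = counts[unique_b[0]]
    out = np.empty(vol.shape[:3] + (unique_b.size,))
    for i, b in enumerate(unique_b):
        out[..., i] = vol[..., bvals == b].mean(axis=3)
    return out, unique_b, n_rep


def compute_snr_map(vol: np.ndarray, bvals: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
    """Voxel-wise SNR of the b=0 repetitions, scaled to the averaged signal.

    SNR = (mean across b=0 repetitions / SD across repetitions) * sqrt(Nrep),
    the sqrt(Nrep) factor representing the repetition-averaged signal that is
    fed to the fitting algorithm.  Zero-SD voxels (possible in noiseless
    simulation) are flagged NaN and excluded from the summary with a count.

    Returns (snr map with NaN outside mask/degenerate voxels, summary dict
    with mean/sd/min/max/n_excluded).
    """
    bvals = np.asarray(bvals, dtype=float)
    sel = bvals == 0
    if int(sel.sum()) < 2:
        raise DatasetError("SNR needs >= 2 b=0 repetitions")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("empty mask for SNR computation")
    reps = vol[..., sel]
    n_rep = int(sel.sum())
    mean = reps.mean(axis=3)
    sd = reps.std(axis=3, ddof=1)
    snr = np.full(vol.shape[:3], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = mean / sd * np.sqrt(n_rep)
    ok = mask & (sd > 0)
    snr[ok] = vals[ok]
    inside = snr[mask]
    finite = inside[np.isfinite(inside)]
    summary = {
        "mean": float(finite.mean()) if finite.size else float("nan"),
        "sd": float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
        "min": float(finite.min()) if finite.size else float("nan"),
        "max": float(finite.max()) if finite.size else float("nan"),
        "n_excluded": int(mask.sum() - finite.size),
        "n_rep": n_rep,
    }
    return snr, summary


def sphere_element(radius: int) -> np.ndarray:
    """Discrete spherical structuring element (voxels within Euclidean radius)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (x**2 + y**2 + z**2) <= r**2


def erode_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological erosion with a sphere kernel; radius 0 is the identity.

    Erosion to an empty mask is allowed but logged as a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    out = ndimage.binary_erosion(mask, structure=sphere_element(radius))
    if mask.any() and not out.any():
        log.warning("erosion radius %d removed every voxel of the mask", radius)
    return out


def average_maps_across_directions(maps_per_direction: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Voxel-wise arithmetic mean of per-direction parameter maps.

    A voxel missing (NaN) in any direction is missing in the average.
    """
    if not maps_per_direction:
        raise ValueError("no direction maps supplied")
    names = maps_per_direction[0].keys()
    out = {}
    for name in names:
        stack = np.stack([m[name] for m in maps_per_direction], axis=0)
        out[name] = stack.mean(axis=0)  # NaN propagates by design
    return out


# ---------------------------------------------------------------------------
# Metric extraction


def _level_slice_mask(levels: np.ndarray, level_range: tuple[int, int] | None) -> np.ndarray:
    if level_range is None:
        return np.ones(levels.shape[0], dtype=bool)
    lo, hi = level_range
    return (levels >= lo) & (levels <= hi)


def extract_metrics(
    maps: dict[str, np.ndarray],
    prob_mask: np.ndarray,
    levels: np.ndarray,
    level_range: tuple[int, int] | None = None,
    weighted: bool = True,
) -> dict[str, float]:
    """Probability-weighted ROI mean of each parameter map over a level range.

    With ``weighted=False`` a plain mean over prob > 0.5 voxels is used.
    Voxels with NaN map values (outside the fitted region) are excluded.
    """
    slice_ok = _level_slice_mask(levels, level_range)
    p = np.asarray(prob_mask, dtype=float).copy()
    p[:, :, ~slice_ok] = 0.0
    out = {}
    for name, vol in maps.items():
        good = np.isfinite(vol) & (p > 0)
        if weighted:
            w = p[good]
        else:
            good = np.isfinite(vol) & (p > 0.5)
            w = np.ones(int(good.sum()))
        if w.sum() == 0:
            out[name] = float("nan")
            continue
        out[name] = float(np.sum(vol[good] * w) / np.sum(w))
    return out


# ---------------------------------------------------------------------------
# Orchestration


def _roi_prob_masks(data: DiffusionDataset, erosion_radius: int) -> dict[str, np.ndarray]:
    """WM/GM probabilistic masks restricted to the eroded cord periphery."""
    eroded_cord = erode_mask(data.cord_mask, erosion_radius)
    return {
        "WM": np.where(eroded_cord, data.wm_prob, 0.0),
        "GM": np.where(eroded_cord, data.gm_prob, 0.0),
    }


def run_study(config: PipelineConfig, data: DiffusionDataset | None = None) -> StudyResult:
    """Execute the full analysis and reliability battery.

    Either ``config.phantom`` (simulate mode) or ``data`` must be provided.
    """
    if data is None:
        if config.phantom is None:
            raise ValueError("provide a dataset or a PhantomSpec")
        spec = config.phantom
        volumes, bvals, truth = simulate_dataset(spec)
        geo = truth.geometry
        data = DiffusionDataset(
            volumes=volumes,
            bvals=bvals,
            scheme=spec.scheme,
            cord_mask=geo.cord_mask,
            wm_prob=geo.wm_prob,
            gm_prob=geo.gm_prob,
            levels=geo.levels,
            truth=truth,
        )
    scheme = data.scheme
    roi_probs = _roi_prob_masks(data, config.erosion_radius)
    snr_rows = []
    records = []
    roi_cache: dict = {}
    for (subj, sess, direction), vol in sorted(data.volumes.items()):
        avg, unique_b, n_rep = average_repetitions(vol, data.bvals)
        if n_rep >= 2:
            _, snr_summary = compute_snr_map(vol, data.bvals, erode_mask(data.cord_mask, config.erosion_radius))
            snr_rows.append(
                dict(subject=subj, session=sess, direction=direction, **snr_summary)
            )
        for algorithm in config.algorithms:
            fit_cfg = replace(config.fit, algorithm=algorithm)
            if "voxel_wise" in config.approaches:
                maps = fit_voxelwise(avg, data.cord_mask, scheme, replace(fit_cfg, mode="voxel_wise"))
                records.append(
                    dict(
                        subject=subj, session=sess, direction=direction,
                        algorithm=algorithm, approach="voxel_wise", maps=maps,
                    )
                )
            if "roi_wise" in config.approaches:
                for roi, p in roi_probs.items():
                    slice_fits = fit_roiwise(
                        avg, p, scheme, replace(fit_cfg, mode="roi_wise"), _cache=roi_cache
                    )
                    records.append(
                        dict(
                            subject=subj, session=sess, direction=direction,
                            algorithm=algorithm, approach="roi_wise", roi=roi,
                            slice_fits=slice_fits,
                        )
                    )
        log.info(
            "fitted subject %d session %d direction %s (%d cord voxels)",
            subj, sess, direction, int(data.cord_mask.sum()),
        )

    # direction averaging + metric extraction -> tidy test-retest rows
    tr_rows = []
    slice_ok = _level_slice_mask(data.levels, config.level_range)
    for subj in data.subjects:
        for sess in (1, 2):
            for algorithm in config.algorithms:
                if "voxel_wise" in config.approaches:
                    per_dir = [
                        r["maps"]
                        for r in records
                        if r["approach"] == "voxel_wise"
                        and (r["subject"], r["session"], r["algorithm"]) == (subj, sess, algorithm)
                    ]
                    avg_maps = average_maps_across_directions(per_dir)
                    for roi, p in roi_probs.items():
                        vals = extract_metrics(
                            avg_maps, p, data.levels, config.level_range,
                            weighted=config.weighted_extraction,
                        )
                        for param in _EXTRACT_PARAMS:
                            tr_rows.append(
                                dict(
                                    subject=subj, session=sess, roi=roi, parameter=param,
                                    approach="voxel_wise", algorithm=algorithm,
                                    value=vals[param],
                                )
                            )
                if "roi_wise" in config.approaches:
                    for roi in roi_probs:
                        recs = [
                            r
                            for r in records
                            if r["approach"] == "roi_wise"
                            and r.get("roi") == roi
                            and (r["subject"], r["session"], r["algorithm"]) == (subj, sess, algorithm)
                        ]
                        # mean across directions of per-slice fits over the level range
                        per_param: dict[str, list[float]] = {p: [] for p in _EXTRACT_PARAMS}
                        for r in recs:
                            for k, fit in r["slice_fits"].items():
                                if not slice_ok[k]:
                                    continue
                                d = fit.params.as_dict()
                                for p in _EXTRACT_PARAMS:
                                    per_param[p].append(d[p])
                        for param in _EXTRACT_PARAMS:
                            vals = per_param[param]
                            tr_rows.append(
                                dict(
                                    subject=subj, session=sess, roi=roi, parameter=param,
                                    approach="roi_wise", algorithm=algorithm,
                                    value=float(np.mean(vals)) if vals else float("nan"),
                                )
                            )
    tidy = pd.DataFrame(tr_rows)
    wide = (
        tidy.pivot_table(
            index=["subject", "roi", "parameter", "approach", "algorithm"],
            columns="session", values="value",
        )
        .rename(columns={1: "session1", 2: "session2"})
        .reset_index()
    )
    wide.columns.name = None
    report = reliability_report(wide)

    anova: dict[tuple[str, str], pd.DataFrame] = {}
    if set(config.approaches) == {"voxel_wise", "roi_wise"} and set(config.algorithms) == {
        "one_step",
        "two_step",
    }:
        for roi in sorted(wide["roi"].unique()):
            for param in _EXTRACT_PARAMS:
                try:
                    y = cv_design_from_table(wide, roi, param)
                    anova[(roi, param)] = rm_anova_2x2(y)
                except Exception as err:  # degenerate CV designs stay absent from the report
                    log.info("ANOVA skipped for %s/%s: %s", roi, param, err)

    snr_summary = pd.DataFrame(snr_rows)
    manifest = {
        "seed_fit": config.fit.seed,
        "phantom": None
        if config.phantom is None
        else {
            "seed": config.phantom.seed,
            "n_subjects": config.phantom.n_subjects,
            "grid": list(config.phantom.grid),
            "snr_single_rep": config.phantom.snr_single_rep
            if np.isfinite(config.phantom.snr_single_rep)
            else "inf",
            "n_repetitions": config.phantom.n_repetitions,
        },
        "bounds": {k: list(config.fit.bound(k)) for k in ("F", "Dstar", "D")},
        "cutoff_b": config.fit.cutoff_b,
        "erosion_radius": config.erosion_radius,
        "approaches": list(config.approaches),
        "algorithms": list(config.algorithms),
        "n_cord_voxels": int(data.cord_mask.sum()),
    }
    result = StudyResult(
        test_retest=wide, report=report, anova=anova, snr_summary=snr_summary, manifest=manifest
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        wide.to_csv(out / "test_retest.csv", index=False)
        report.to_csv(out / "reliability_report.csv", index=False)
        snr_summary.to_csv(out / "snr_summary.csv", index=False)
        for (roi, param), tab in anova.items():
            tab.to_csv(out / f"anova_{roi}_{param}.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
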