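"""Test-retest reliability statistics for paired scan-rescan data.

Implements the standard repeatability battery for two-session designs:

* within-subject coefficient of variation (wsCV), per subject;
* intraclass correlation coefficient, two-way model, absolute agreement,
  single measures (McGraw & Wong ICC(A,1));
* Bland-Altman bias and 95 % limits of agreement;
* Pearson correlation between sessions;
* a 2 x 2 repeated-measures ANOVA on the CVs with fitting *approach*
  (voxel-wise vs ROI-wise) and fitting *algorithm* (one-step vs two-step) as
  within-subject factors and subject as the blocking factor.

The ICC and the balanced repeated-measures ANOVA are computed closed-form
from the two-way mean squares; independent library implementations serve as
cross-checks in the test suite, never as the computation itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateVarianceError,
    InsufficientDataError,
    MissingCellError,
    UndefinedCVError,
)

__all__ = [
    "within_subject_cv",
    "icc_absolute_agreement",
    "icc_label",
    "bland_altman",
    "BlandAltman",
    "pearson_between_sessions",
    "rm_anova_2x2",
    "reliability_report",
]

#: Interpretation scale for ICC values (Cicchetti convention).
_ICC_SCALE = ((0.4, "poor"), (0.6, "fair"), (0.75, "good"), (np.inf, "excellent"))


def within_subject_cv(x1: float, x2: float) -> float:
    """Within-subject CV in percent: 100 * SD(x1, x2) / mean(x1, x2).

    Uses the sample (n-1) SD, hence CV = 100 * |x1 - x2| / (sqrt(2) * mean).

    Raises
    ------
    UndefinedCVError
        If the two-session mean is zero.
    """
    mu = 0.5 * (x1 + x2)
    if mu == 0:
        raise UndefinedCVError("zero mean: CV undefined")
    sd = abs(x1 - x2) / np.sqrt(2.0)
    return float(100.0 * sd / mu)


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float, int, int]:
    """Rows/columns/error mean squares of a complete two-way (n x k) table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D (subjects x sessions)")
    n, k = t.shape
    if not np.all(np.isfinite(t)):
        raise ValueError("table contains non-finite cells")
    gm = t.mean()
    row_m = t.mean(axis=1)
    col_m = t.mean(axis=0)
    ss_rows = k * np.sum((row_m - gm) ** 2)
    ss_cols = n * np.sum((col_m - gm) ** 2)
    ss_err = np.sum((t - row_m[:, None] - col_m[None, :] + gm) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc_absolute_agreement(table: np.ndarray) -> float:
    """ICC, two-way model, absolute agreement, single measures (ICC(A,1)).

    With n subjects (rows) and k sessions (columns)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

    where MSR, MSC, MSE are the rows, columns and error mean squares of the
    two-way ANOVA decomposition.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 subjects.
    DegenerateVarianceError
        A constant table (all cells equal), where the ratio is 0/0.
    """
    t = np.asarray(table, dtype=float)
    msr, msc, mse, n, k = _two_way_mean_squares(t)
    if n < 3:
        raise InsufficientDataError("ICC needs at least 3 subjects")
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateVarianceError("constant table: ICC undefined")
    return float((msr - mse) / denom)


def icc_label(icc: float) -> str:
    """Qualitative ICC label: poor < 0.4 < fair < 0.6 < good < 0.75 < excellent."""
    for cut, name in _ICC_SCALE:
        if icc < cut:
            return name
    return "excellent"


@dataclass(frozen=True)
class BlandAltman:
    """Bias, 95 % limits of agreement and the paired points for plotting.

    Differences are oriented session1 - session2 throughout.
    """

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(table: np.ndarray) -> BlandAltman:
    """Bland-Altman analysis of a (subjects x 2 sessions) table.

    bias = mean(session1 - session2); limits = bias +/- 1.96 SD(differences).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise InsufficientDataError("Bland-Altman needs >= 2 subjects x 2 sessions")
    diff = t[:, 0] - t[:, 1]
    mean = t.mean(axis=1)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        means=mean,
        differences=diff,
    )


def pearson_between_sessions(table: np.ndarray) -> float:
    """Pearson product-moment correlation between the two session columns."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 3:
        raise InsufficientDataError("Pearson needs >= 3 subjects x 2 sessions")
    if np.ptp(t[:, 0]) == 0 or np.ptp(t[:, 1]) == 0:
        raise DegenerateVarianceError("constant session column: r undefined")
    r, _ = stats.pearsonr(t[:, 0], t[:, 1])
    return float(r)


def rm_anova_2x2(y: np.ndarray, repeated_measures: bool = True) -> pd.DataFrame:
    """Two-way ANOVA of a balanced 2 x 2 within-subject design.

    Parameters
    ----------
    y : (n_subjects, 2, 2) array
        ``y[s, a, g]`` is subject s's response at approach level a and
        algorithm level g (e.g. a CV value per fitting configuration).
    repeated_measures : bool
        If True (default), each factor's F statistic is tested against its
        factor-by-subject interaction mean square (subject as blocking
        factor).  If False, a plain two-way fixed-effects ANOVA on the pooled
        cells is returned for comparison.

    Returns
    -------
    DataFrame indexed by effect (approach, algorithm, interaction) with
    columns ``ss``, ``df``, ``ms``, ``F``, ``p``, plus the error strata.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise MissingCellError("expected a complete (n, 2, 2) design")
    n = y.shape[0]
    if n < 3:
        raise InsufficientDataError("ANOVA needs at least 3 subjects")
    if not np.all(np.isfinite(y)):
        raise MissingCellError("design contains non-finite cells")

    gm = y.mean()
    m_a = y.mean(axis=(0, 2))  # approach means (2,)
    m_g = y.mean(axis=(0, 1))  # algorithm means (2,)
    m_ag = y.mean(axis=0)  # (2, 2)
    m_s = y.mean(axis=(1, 2))  # subject means (n,)
    m_sa = y.mean(axis=2)  # (n, 2)
    m_sg = y.mean(axis=1)  # (n, 2)

    ss_a = 2 * n * np.sum((m_a - gm) ** 2)
    ss_g = 2 * n * np.sum((m_g - gm) ** 2)
    ss_ag = n * np.sum((m_ag - m_a[:, None] - m_g[None, :] + gm) ** 2)
    ss_s = 4 * np.sum((m_s - gm) ** 2)
    ss_sa = 2 * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_sg = 2 * np.sum((m_sg - m_s[:, None] - m_g[None, :] + gm) ** 2)
    ss_tot = np.sum((y - gm) ** 2)
    ss_sag = ss_tot - (ss_a + ss_g + ss_ag + ss_s + ss_sa + ss_sg)

    rows = []
    if repeated_measures:
        for name, ss, err_ss in (
            ("approach", ss_a, ss_sa),
            ("algorithm", ss_g, ss_sg),
            ("interaction", ss_ag, ss_sag),
        ):
            df1, df2 = 1, n - 1
            ms, mse = ss / df1, err_ss / df2
            if mse > 0:
                f = ms / mse
                p = float(stats.f.sf(f, df1, df2))
            elif ms == 0:  # fully degenerate stratum (e.g. all-zero CVs)
                f, p = np.nan, np.nan
            else:
                f, p = np.inf, 0.0
            rows.append((name, ss, df1, ms, f, p))
        rows.append(("subject", ss_s, n - 1, ss_s / (n - 1), np.nan, np.nan))
        for name, ss in (
            ("approach x subject", ss_sa),
            ("algorithm x subject", ss_sg),
            ("interaction x subject", ss_sag),
        ):
            rows.append((name, ss, n - 1, ss / (n - 1), np.nan, np.nan))
    else:
        ss_err = ss_s + ss_sa + ss_sg + ss_sag
        df_err = 4 * n - 4
        mse = ss_err / df_err
        for name, ss in (("approach", ss_a), ("algorithm", ss_g), ("interaction", ss_ag)):
            f = (ss / 1) / mse if mse > 0 else np.inf
            p = float(stats.f.sf(f, 1, df_err)) if np.isfinite(f) else 0.0
            rows.append((name, ss, 1, ss, f, p))
        rows.append(("error", ss_err, df_err, mse, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["effect", "ss", "df", "ms", "F", "p"])
    return out.set_index("effect")


def reliability_report(table: pd.DataFrame) -> pd.DataFrame:
    """Full reliability battery on a tidy test-retest table.

    Parameters
    ----------
    table : DataFrame
        Tidy table with columns ``subject``, ``roi``, ``parameter``,
        ``approach``, ``algorithm``, ``session1``, ``session2`` — one row per
        subject and fitting configuration.

    Returns
    -------
    Tidy DataFrame with one row per (roi, parameter, approach, algorithm,
    statistic).  ICC/Pearson that are undefined on degenerate input (e.g. a
    perfectly repeatable noiseless phantom) are reported as NaN with the
    reason in the ``note`` column rather than silently fabricated.
    """
    required = {"subject", "roi", "parameter", "approach", "algorithm", "session1", "session2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"test-retest table missing columns {sorted(missing)}")
    rows = []
    group_cols = ["roi", "parameter", "approach", "algorithm"]
    for key, grp in table.groupby(group_cols, sort=True):
        roi, param, approach, algorithm = key
        grp = grp.sort_values("subject")
        mat = grp[["session1", "session2"]].to_numpy(dtype=float)
        cvs = np.array([within_subject_cv(a, b) for a, b in mat])

        def add(stat, value, note=""):
            rows.append(
                dict(
                    roi=roi,
                    parameter=param,
                    approach=approach,
                    algorithm=algorithm,
                    statistic=stat,
                    value=value,
                    note=note,
                )
            )

        add("cv_mean", float(cvs.mean()))
        add("cv_sd", float(cvs.std(ddof=1)) if len(cvs) > 1 else np.nan)
        try:
            icc = icc_absolute_agreement(mat)
            add("icc", icc, icc_label(icc))
        except (DegenerateVarianceError, InsufficientDataError) as err:
            add("icc", np.nan, f"undefined: {err}")
        ba = bland_altman(mat)
        add("bias", ba.bias)
        add("loa_low", ba.loa_low)
        add("loa_high", ba.loa_high)
        try:
            add("pearson_r", pearson_between_sessions(mat))
        except (DegenerateVarianceError, InsufficientDataError) as err:
            add("pearson_r", np.nan, f"undefined: {err}")
        rows.append(
            dict(
                roi=roi,
                parameter=param,
                approach=approach,
                algorithm=algorithm,
                statistic="n_subjects",
                value=float(len(grp)),
                note="",
            )
        )
    return pd.DataFrame(rows)


def cv_design_from_table(table: pd.DataFrame, roi: str, parameter: str) -> np.ndarray:
    """Assemble the (n, 2, 2) CV design for one ROI and parameter.

    Axis 1 orders approaches (voxel_wise, roi_wise); axis 2 algorithms
    (one_step, two_step).  Raises MissingCellError on an incomplete design.
    """
    sel = table[(table["roi"] == roi) & (table["parameter"] == parameter)]
    subjects = sorted(sel["subject"].unique())
    approaches = ("voxel_wise", "roi_wise")
    algorithms = ("one_step", "two_step")
    y = np.full((len(subjects), 2, 2), np.nan)
    for i, subj in enumerate(subjects):
        for a, app in enumerate(approaches):
            for g, alg in enumerate(algorithms):
                row = sel[
                    (sel["subject"] == subj)
                    & (sel["approach"] == app)
                    & (sel["algorithm"] == alg)
                ]
                if len(row) != 1:
                    raise MissingCellError(
                        f"subject {subj} missing cell ({app}, {alg}) for {roi}/{parameter}"
                    )
                y[i, a, g] = within_subject_cv(
                    float(row["session1"].iloc[0]), float(row["session2"].iloc[0])
                )
    return y
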