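"""Intraclass correlations for device agreement and test-retest reliability.

Two-way mixed-effects model (subjects random, raters fixed), single-measure
forms per McGraw & Wong: consistency ICC(C,1) = (MS_R - MS_E) /
(MS_R + (k-1) MS_E) and absolute agreement ICC(A,1) = (MS_R - MS_E) /
(MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)), where MS_R, MS_C, MS_E are the
row (subject), column (rater) and error mean squares of the two-way ANOVA.
Device comparisons use devices as raters; test-retest uses the two recording
days as raters and reports absolute agreement. Confidence intervals come
from bootstrap resampling of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Qualitative reliability labels; intervals closed on the left.
ICC_THRESHOLDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


def classify_icc(value: float) -> str:
    """Map an ICC to poor / moderate / good / excellent (left-closed bins:
    below 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, 0.9 and above excellent)."""
    if not np.isfinite(value):
        raise ValueError("ICC must be finite")
    for cut, label in ICC_THRESHOLDS:
        if value >= cut:
            return label
    return "poor"


@dataclass
class IccResult:
    icc: float
    kind: str                   # 'agreement' | 'consistency'
    design: str                 # 'device-comparison' | 'test-retest'
    ci95: tuple
    n_subjects: int
    k_raters: int
    ms: tuple                   # (MS_rows, MS_cols, MS_error)
    label: str

    def summary(self) -> str:
        lo, hi = self.ci95
        ci = f" [{lo:.3f}, {hi:.3f}]" if np.isfinite(lo) else ""
        return (f"ICC({self.kind}, single) = {self.icc:.3f}{ci} ({self.label}); "
                f"n={self.n_subjects} subjects, k={self.k_raters} raters")


def _anova_ms(data: np.ndarray):
    """Two-way (rows x columns, one observation per cell) mean squares."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid ** 2)
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_single(data, kind: str = "agreement", design: str = "device-comparison",
               ci: bool = False, n_boot: int = 2000, seed: int = 0) -> IccResult:
    """Single-measure ICC of a subjects x raters matrix.

    Rows with missing values are dropped. ``ci=True`` adds a subject-level
    bootstrap 95% interval.
    """
    if kind not in ("agreement", "consistency"):
        raise ValueError("kind must be 'agreement' or 'consistency'")
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a subjects x raters matrix")
    data = data[~np.isnan(data).any(axis=1)]
    n, k = data.shape
    if n < 5:
        raise ValueError(f"need >= 5 complete subjects, got {n}")
    if k < 2:
        raise ValueError("need >= 2 raters")
    if np.allclose(data, data.flat[0]):
        raise ValueError("zero total variance: ICC undefined")

    def _icc(mat):
        nn, kk = mat.shape
        ms_r, ms_c, ms_e = _anova_ms(mat)
        denom = ms_r + (kk - 1) * ms_e
        if kind == "agreement":
            denom = denom + (kk / nn) * (ms_c - ms_e)
        return (ms_r - ms_e) / denom, (ms_r, ms_c, ms_e)

    value, ms = _icc(data)
    if ci:
        lo, hi = bootstrap_ci(lambda mat: _icc(mat)[0], data,
                              n_boot=n_boot, seed=seed)
    else:
        lo, hi = (np.nan, np.nan)
    return IccResult(icc=float(value), kind=kind, design=design, ci95=(lo, hi),
                     n_subjects=n, k_raters=k, ms=tuple(float(m) for m in ms),
                     label=classify_icc(value))


def device_pair_matrix(table: pd.DataFrame, device_a: str, device_b: str,
                       feature: str, session=None) -> np.ndarray:
    """Subjects x 2 matrix of one feature for a device pair (matched subjects)."""
    t = table[table["feature"] == feature]
    if session is not None:
        t = t[t["session"] == session]
    a = t[t["device"] == device_a].groupby("subject")["value"].mean()
    b = t[t["device"] == device_b].groupby("subject")["value"].mean()
    merged = pd.concat([a, b], axis=1, join="inner")
    return merged.to_numpy()


def test_retest(day1: pd.DataFrame, day8: pd.DataFrame, device: str,
                feature: str, ci: bool = False, n_boot: int = 2000,
                seed: int = 0) -> IccResult:
    """Absolute-agreement ICC between two sessions of one device."""

    def _col(t):
        t = t[(t["device"] == device) & (t["feature"] == feature)]
        return t.groupby("subject")["value"].mean()

    merged = pd.concat([_col(day1), _col(day8)], axis=1, join="inner")
    if len(merged) < 5:
        raise ValueError(f"only {len(merged)} matched subjects for {device}/{feature}")
    return icc_single(merged.to_numpy(), kind="agreement", design="test-retest",
                      ci=ci, n_boot=n_boot, seed=seed)


def bootstrap_ci(statistic, table, n_boot: int = 2000, seed: int = 0,
                 max_redraws: int = 100):
    """Percentile bootstrap 95% CI, resampling subjects (rows) with
    replacement. A resample on which the statistic fails is redrawn (count
    capped); pandas tables are resampled on their rows."""
    rng = np.random.default_rng(seed)
    is_frame = isinstance(table, pd.DataFrame)
    n = len(table)
    if n < 5:
        raise ValueError("need >= 5 rows to bootstrap")
    stats, redraws = [], 0
    while len(stats) < n_boot:
        idx = rng.integers(0, n, size=n)
        sample = table.iloc[idx] if is_frame else np.asarray(table)[idx]
        try:
            stats.append(float(statistic(sample)))
        except Exception:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("bootstrap statistic failed repeatedly")
    return tuple(np.percentile(stats, [2.5, 97.5]))


def icc_grid(table: pd.DataFrame, reference_device: str = "standard",
             kinds=("agreement", "consistency"), session=None,
             ci: bool = False, n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Tidy grid of device-vs-reference ICCs for every feature in a table."""
    rows = []
    devices = [d for d in table["device"].unique() if d != reference_device]
    for feature in table["feature"].unique():
        for dev in devices:
            mat = device_pair_matrix(table, reference_device, dev, feature,
                                     session=session)
            for kind in kinds:
                try:
                    res = icc_single(mat, kind=kind, ci=ci, n_boot=n_boot, seed=seed)
                except ValueError:
                    continue
                rows.append({"feature": feature, "device": dev, "kind": kind,
                             "icc": res.icc, "label": res.label,
                             "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                             "n_subjects": res.n_subjects})
    return pd.DataFrame(rows)
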