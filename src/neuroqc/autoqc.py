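"""Automated good/bad flagging, ROC cutoff calibration and study summaries.

Metric values are z-scored against a reference population, flagged against
acceptance intervals, and a scan is ruled bad when the count of bad metrics
reaches a threshold (default 3).  Cutoffs are calibrated by sweeping z-score
cutoffs from -5 to 5 in 0.05 steps under stratified threefold cross
validation, choosing the cutoff maximising (sensitivity + specificity) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateInputError, ValidationError

GOOD, BAD, UNAVAILABLE = "good", "bad", "unavailable"
DIRECTIONS = ("lower-is-worse", "higher-is-worse", "two-sided")

SWEEP_LO, SWEEP_HI, SWEEP_STEP = -5.0, 5.0, 0.05


@dataclass(frozen=True)
class MetricReference:
    """Reference population mean/SD and quality direction for one metric."""

    metric: str
    mean: float
    sd: float
    directionality: str = "lower-is-worse"
    profile: str = "t1"

    def __post_init__(self):
        if self.sd <= 0:
            raise ValidationError(f"reference SD for {self.metric!r} must be > 0")
        if self.directionality not in DIRECTIONS:
            raise ValidationError(f"unknown directionality {self.directionality!r}")


@dataclass(frozen=True)
class CutoffRange:
    """Acceptance interval for one metric; bounds on the z or raw scale."""

    metric: str
    lower: float | None = None
    upper: float | None = None
    scale: str = "z"

    def __post_init__(self):
        if self.lower is None and self.upper is None:
            raise ValidationError(f"cutoff for {self.metric!r} needs at least one bound")
        if (self.lower is not None and self.upper is not None
                and not self.lower < self.upper):
            raise ValidationError(f"cutoff for {self.metric!r}: lower must be < upper")
        if self.scale not in ("z", "raw"):
            raise ValidationError(f"unknown cutoff scale {self.scale!r}")


@dataclass
class CaseDecision:
    flags: dict[str, str]
    n_bad: int
    verdict: str  # good | bad | undetermined
    threshold: int
    rationale: list[str] = field(default_factory=list)


@dataclass
class ROCResult:
    metric: str
    auc: float
    best_cutoff_z: float
    best_cutoff_raw: float
    sensitivity: float
    specificity: float
    accuracy: float  # (sensitivity + specificity) / 2 on held-out folds
    directionality: str
    fold_assignments: np.ndarray
    sweep_grid: np.ndarray
    fold_cutoffs: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class HistogramDensity:
    bin_edges: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if edges.size != heights.size + 1:
            raise ValidationError("bin edge / height size mismatch")
        area = float(np.sum(heights * np.diff(edges)))
        if abs(area - 1.0) > 1e-9:
            raise ValidationError(f"density must integrate to 1, got {area}")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "heights", heights)


def zscore(value: float, reference: MetricReference) -> float:
    """(value - reference mean) / reference SD."""
    return (value - reference.mean) / reference.sd


def flag_metric(value: float | None, cutoff: CutoffRange,
                reference: MetricReference | None = None) -> str:
    """Flag a metric good/bad against its acceptance interval.

    Values exactly on a bound are good (closed interval); ``None`` values
    flag as unavailable and are never counted as bad.
    """
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return UNAVAILABLE
    if cutoff.scale == "z":
        if reference is None:
            raise ValidationError(f"z-scale cutoff for {cutoff.metric!r} needs a reference")
        value = zscore(value, reference)
    if cutoff.lower is not None and value < cutoff.lower:
        return BAD
    if cutoff.upper is not None and value > cutoff.upper:
        return BAD
    return GOOD


def decide_case(flags: dict[str, str], bad_threshold: int = 3,
                rule: str = "at-least") -> CaseDecision:
    """Scan-level verdict: bad when the bad-metric count reaches the threshold.

    ``rule="at-least"`` (default) rules bad when ``n_bad >= bad_threshold``;
    ``rule="more-than"`` requires a strictly greater count.
    """
    available = {m: f for m, f in flags.items() if f != UNAVAILABLE}
    if not available:
        return CaseDecision(flags=dict(flags), n_bad=0, verdict="undetermined",
                            threshold=bad_threshold,
                            rationale=["all metrics unavailable"])
    bad_metrics = sorted(m for m, f in available.items() if f == BAD)
    n_bad = len(bad_metrics)
    if rule == "at-least":
        is_bad = n_bad >= bad_threshold
    elif rule == "more-than":
        is_bad = n_bad > bad_threshold
    else:
        raise ValidationError(f"unknown decision rule {rule!r}")
    rationale = [f"{m} flagged bad" for m in bad_metrics]
    return CaseDecision(flags=dict(flags), n_bad=n_bad,
                        verdict=BAD if is_bad else GOOD,
                        threshold=bad_threshold, rationale=rationale)


def _sweep_grid() -> np.ndarray:
    n = int(round((SWEEP_HI - SWEEP_LO) / SWEEP_STEP))
    return SWEEP_LO + SWEEP_STEP * np.arange(n + 1)


def _bad_predictions(z: np.ndarray, cutoff: float, directionality: str) -> np.ndarray:
    if directionality == "lower-is-worse":
        return z < cutoff
    if directionality == "higher-is-worse":
        return z > cutoff
    return np.abs(z) > abs(cutoff)


def _sens_spec(pred_bad: np.ndarray, is_bad: np.ndarray) -> tuple[float, float]:
    sens = float(pred_bad[is_bad].mean()) if is_bad.any() else np.nan
    spec = float((~pred_bad[~is_bad]).mean()) if (~is_bad).any() else np.nan
    return sens, spec


def _roc_auc(z: np.ndarray, is_bad: np.ndarray, grid: np.ndarray,
             directionality: str) -> float:
    tpr, fpr = [], []
    for c in grid:
        pred = _bad_predictions(z, c, directionality)
        s, p = _sens_spec(pred, is_bad)
        tpr.append(s)
        fpr.append(1.0 - p)
    order = np.argsort(fpr, kind="stable")
    fpr = np.concatenate([[0.0], np.asarray(fpr)[order], [1.0]])
    tpr = np.concatenate([[0.0], np.asarray(tpr)[order], [1.0]])
    return float(np.trapezoid(tpr, fpr))


def _pick_cutoff(z: np.ndarray, is_bad: np.ndarray, grid: np.ndarray,
                 directionality: str) -> float:
    """Best cutoff by (sens+spec)/2; ties break toward fewer bad calls."""
    best_score, best_cut, best_n_bad = -np.inf, grid[0], np.inf
    for c in grid:
        pred = _bad_predictions(z, c, directionality)
        s, p = _sens_spec(pred, is_bad)
        score = (s + p) / 2.0
        n_pred_bad = int(pred.sum())
        if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12 and n_pred_bad < best_n_bad):
            best_score, best_cut, best_n_bad = score, float(c), n_pred_bad
    return best_cut


def calibrate_cutoffs(values: pd.DataFrame, labels, directionality: dict[str, str],
                      n_folds: int = 3, seed: int = 0,
                      min_samples_warn: int = 30) -> dict[str, ROCResult]:
    """ROC cutoff calibration per metric under stratified cross validation.

    Parameters
    ----------
    values
        One column per metric, one row per scan.
    labels
        Boolean/int array, True/1 = bad scan.
    directionality
        Metric -> sweep direction.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValidationError("calibration needs both good and bad examples")
    if labels.size < min_samples_warn:
        import warnings
        warnings.warn(f"calibrating on only {labels.size} scans", stacklevel=2)
    grid = _sweep_grid()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.zeros(labels.size, dtype=int)
    splits = list(skf.split(np.zeros(labels.size), labels))
    for k, (_, test_idx) in enumerate(splits):
        folds[test_idx] = k

    results: dict[str, ROCResult] = {}
    for metric in values.columns:
        v = np.asarray(values[metric], dtype=float)
        ok = np.isfinite(v)
        vv, ll, ff = v[ok], labels[ok], folds[ok]
        mean, sd = float(vv.mean()), float(vv.std(ddof=0))
        if sd == 0:
            raise DegenerateInputError(f"metric {metric!r} is constant; cannot calibrate")
        z = (vv - mean) / sd
        direction = directionality.get(metric, "lower-is-worse")
        sens_folds, spec_folds, fold_cuts = [], [], []
        for k in range(n_folds):
            train, test = ff != k, ff == k
            if ll[train].all() or not ll[train].any() or not test.any():
                continue
            cut = _pick_cutoff(z[train], ll[train], grid, direction)
            fold_cuts.append(cut)
            pred = _bad_predictions(z[test], cut, direction)
            s, p = _sens_spec(pred, ll[test])
            if np.isfinite(s):
                sens_folds.append(s)
            if np.isfinite(p):
                spec_folds.append(p)
        best_z = _pick_cutoff(z, ll, grid, direction)
        sens = float(np.mean(sens_folds)) if sens_folds else np.nan
        spec = float(np.mean(spec_folds)) if spec_folds else np.nan
        results[metric] = ROCResult(
            metric=metric,
            auc=_roc_auc(z, ll, grid, direction),
            best_cutoff_z=best_z,
            best_cutoff_raw=best_z * sd + mean,
            sensitivity=sens, specificity=spec,
            accuracy=(sens + spec) / 2.0,
            directionality=direction,
            fold_assignments=folds.copy(),
            sweep_grid=grid,
            fold_cutoffs=fold_cuts)
    return results


def cutoff_from_roc(result: ROCResult) -> CutoffRange:
    """Convert a calibrated one-sided cutoff into an acceptance interval."""
    if result.directionality == "lower-is-worse":
        return CutoffRange(metric=result.metric, lower=result.best_cutoff_z, scale="z")
    if result.directionality == "higher-is-worse":
        return CutoffRange(metric=result.metric, upper=result.best_cutoff_z, scale="z")
    c = abs(result.best_cutoff_z)
    return CutoffRange(metric=result.metric, lower=-c, upper=c, scale="z")


def histogram_density(values, n_bins: int, shared_range: tuple[float, float]) -> HistogramDensity:
    """Area-normalised histogram on a shared bin grid."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("cannot build a density from an empty sample")
    lo, hi = shared_range
    if not lo < hi:
        raise ValidationError("shared_range must be increasing")
    heights, edges = np.histogram(values, bins=n_bins, range=(lo, hi), density=True)
    area = float(np.sum(heights * np.diff(edges)))
    if area <= 0:
        raise DegenerateInputError("all values fall outside the shared range")
    return HistogramDensity(bin_edges=edges, heights=heights / area)


def dice_overlap(h1: HistogramDensity, h2: HistogramDensity) -> float:
    """Overlap of two unit-area densities: sum of binwise minima times width.

    Equals 2|A n B| / (|A| + |B|) for unit areas; 1 iff the histograms are
    identical on the shared grid, 0 for disjoint supports.
    """
    if not np.array_equal(h1.bin_edges, h2.bin_edges):
        raise ValidationError("histograms must share one bin grid")
    widths = np.diff(h1.bin_edges)
    return float(np.sum(np.minimum(h1.heights, h2.heights) * widths))


def metric_correlation_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between metrics; diagonal 1."""
    return values.corr(method="pearson")


def study_summary(reports: pd.DataFrame, grouping_keys: list[str],
                  metric_columns: list[str] | None = None,
                  verdict_column: str = "verdict") -> pd.DataFrame:
    """Per-group scan counts, metric means/SDs and verdict counts."""
    if metric_columns is None:
        metric_columns = [c for c in reports.columns
                          if c not in grouping_keys + [verdict_column]
                          and pd.api.types.is_numeric_dtype(reports[c])]
    rows = []
    for keys, grp in reports.groupby(grouping_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(grouping_keys, keys))
        row["n_scans"] = len(grp)
        for m in metric_columns:
            row[f"{m}_mean"] = float(grp[m].mean())
            row[f"{m}_sd"] = float(grp[m].std(ddof=0))
        if verdict_column in reports.columns:
            counts = grp[verdict_column].value_counts()
            for v in (GOOD, BAD, "undetermined"):
                row[f"n_{v}"] = int(counts.get(v, 0))
        rows.append(row)
    return pd.DataFrame(rows)
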