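"""Permutation-resampling model evaluation.

Each iteration redraws the control sample at the fixed case:control ratio,
refits every model family on the identical resampled cohort, and records a
full metric report; medians and 2.5/97.5 percentiles over iterations give
the point estimates and 95% CIs, and paired iteration-wise comparisons give
model-comparison p-values:

    P = (1/N) * #{iterations where metric(model_1) >= metric(model_2)}

with model_1 the model hypothesized inferior and ties counted in the
numerator (so two identical models give P = 1).

AUROC is the Mann-Whitney pairwise statistic with tie correction; AUPRC is
the step-wise precision-recall integral (no interpolation).  The decision
threshold for confusion-matrix metrics maximizes the Matthews correlation
coefficient over all midpoints between distinct sorted scores.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import cohort as cohort_mod
from . import modeling

logger = logging.getLogger(__name__)

THRESHOLD_METRICS = ("mcc", "f1", "accuracy", "precision", "recall",
                     "specificity")
ALL_METRICS = ("auprc", "auroc") + THRESHOLD_METRICS


def compute_metrics(labels, scores) -> tuple[float, float]:
    """(AUPRC, AUROC) of a score vector; raises on one-class input."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute metrics")
    return (float(average_precision_score(y, s)),
            float(roc_auc_score(y, s)))


@dataclass
class MetricReport:
    auprc: float
    auroc: float
    threshold: float
    mcc: float
    f1: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    degenerate: bool = False

    def to_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in ALL_METRICS + ("threshold",)}


def _confusion_at(y: np.ndarray, s: np.ndarray, thr: float):
    pred = s >= thr
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fp, fn, tn


def mcc_threshold_metrics(labels, scores) -> MetricReport:
    """Full metric report at the MCC-maximizing decision threshold.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores ("predict positive" means score >= threshold); exact MCC
    ties resolve to the smallest threshold.  When MCC is undefined at every
    candidate (degenerate confusion rows), it is reported as 0 with the
    degenerate flag set.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    auprc, auroc = compute_metrics(y, s)

    order = np.argsort(s, kind="stable")
    ss, ys = s[order], y[order]
    boundaries = np.flatnonzero(ss[:-1] != ss[1:])
    P, N = int(y.sum()), int((1 - y).sum())
    best_thr, best_mcc = None, -np.inf
    for i in boundaries:
        thr = (ss[i] + ss[i + 1]) / 2.0
        fn = int(ys[:i + 1].sum())
        tn = (i + 1) - fn
        tp, fp = P - fn, N - tn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            continue
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
        if mcc > best_mcc + 1e-15:
            best_mcc, best_thr = mcc, thr

    degenerate = best_thr is None
    if degenerate:
        best_thr, best_mcc = float(ss[0]), 0.0
    tp, fp, fn, tn = _confusion_at(y, s, best_thr)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    accuracy = (tp + tn) / len(y)
    return MetricReport(auprc, auroc, float(best_thr), float(best_mcc),
                        f1, accuracy, precision, recall, specificity,
                        degenerate)


# ---------------------------------------------------------------------------
# permutation resampling
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """One model to evaluate inside the permutation loop: a family plus its
    per-patient feature frame (indexed by patient id)."""

    name: str
    family: str
    features: pd.DataFrame
    enet_grid: modeling.ElasticNetGrid | None = None
    cv_folds: int = 5


@dataclass
class ModelResult:
    name: str
    draws: pd.DataFrame            # iteration rows x metric columns
    resample_hashes: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        q = self.draws.quantile([0.5, 0.025, 0.975])
        q.index = ["median", "ci_lo", "ci_hi"]
        return q


@dataclass
class PermutationResult:
    models: dict[str, ModelResult]
    iteration_seeds: list[int]
    n_requested: int
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        frames = []
        for name, res in self.models.items():
            f = res.summary()
            f.insert(0, "model", name)
            frames.append(f.reset_index(names="stat"))
        return pd.concat(frames, ignore_index=True)

    def draws_long(self) -> pd.DataFrame:
        frames = []
        for name, res in self.models.items():
            f = res.draws.copy()
            f.insert(0, "model", name)
            f.insert(0, "iteration", np.arange(len(f)))
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _hash_ids(ids) -> str:
    return hashlib.sha1("|".join(ids).encode()).hexdigest()[:16]


def run_permutation(cases: dict[str, float], control_pool: list[str],
                    model_specs: list[ModelSpec],
                    covariates: pd.DataFrame,
                    n_iter: int = 1000, base_seed: int = 0, ratio: int = 3,
                    max_failure_frac: float = 0.05) -> PermutationResult:
    """The resampling loop: per iteration, redraw controls (seed =
    base_seed + i), refit the demographic offset model and every model spec
    on the identical resample, and record metric reports.

    ``covariates`` is indexed by patient id with columns ``age``, ``sex``,
    and any number of ``PC*`` columns for the offset model.  Iteration
    failures are logged and skipped; more than ``max_failure_frac`` of them
    aborts.
    """
    pc_cols = [c for c in covariates.columns if c.startswith("PC")]
    draws: dict[str, list[dict]] = {s.name: [] for s in model_specs}
    hashes: dict[str, list[str]] = {s.name: [] for s in model_specs}
    seeds, n_failed = [], 0
    for i in range(n_iter):
        seed = base_seed + i
        try:
            sample = cohort_mod.sample_case_control(
                cases, control_pool, ratio=ratio, seed=seed)
            ids = sample.ids
            y = sample.labels()
            cov = covariates.loc[ids]
            offset_model = modeling.fit_offset_model(
                y, cov["age"].to_numpy(), cov["sex"].to_numpy(),
                cov[pc_cols].to_numpy() if pc_cols else None)
            tag = _hash_ids(ids)
            for spec in model_specs:
                _, pred = modeling.fit_genetic_model(
                    spec.features.loc[ids], y, offset_model.offsets,
                    spec.family, cv_folds=spec.cv_folds,
                    enet_grid=spec.enet_grid, seed=seed,
                    offset_covariates=cov)
                report = mcc_threshold_metrics(y, pred.yhat)
                draws[spec.name].append(report.to_dict())
                hashes[spec.name].append(tag)
            seeds.append(seed)
        except Exception as exc:  # noqa: BLE001 - failures are data
            n_failed += 1
            logger.warning("permutation iteration %d failed: %s", i, exc)
            if n_failed > max_failure_frac * n_iter:
                raise RuntimeError(
                    f"{n_failed} of {i + 1} permutation iterations failed "
                    f"(> {max_failure_frac:.0%}); aborting") from exc
    if n_failed:
        logger.warning("run_permutation: %d/%d iterations failed and were "
                       "skipped", n_failed, n_iter)
    models = {name: ModelResult(name, pd.DataFrame(rows), hashes[name])
              for name, rows in draws.items()}
    return PermutationResult(models, seeds, n_iter, n_failed)


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Paired permutation comparison.  ``model_1`` is the comparator
    hypothesized inferior; ties count toward the numerator, so identical
    models give P = 1.  A zero count is displayed as '< 1/N'."""

    metric: str
    model_1: str
    model_2: str
    count: int
    n: int
    direction: str = "P = #(metric_1 >= metric_2) / N; model_1 hypothesized inferior"

    @property
    def p_value(self) -> float:
        return self.count / self.n

    @property
    def display(self) -> str:
        if self.count == 0:
            return f"< {1.0 / self.n:g}"
        return f"{self.p_value:g}"


def compare_models(results_1: ModelResult, results_2: ModelResult,
                   metric: str) -> ModelComparison:
    """P-value that model_1 (hypothesized inferior) matches or beats
    model_2 on ``metric`` across paired permutation iterations."""
    if len(results_1.draws) != len(results_2.draws):
        raise ValueError("unpaired results: different iteration counts")
    if results_1.resample_hashes != results_2.resample_hashes:
        raise ValueError("unpaired results: iteration resamples differ")
    a = results_1.draws[metric].to_numpy()
    b = results_2.draws[metric].to_numpy()
    count = int(np.sum(a >= b))
    return ModelComparison(metric, results_1.name, results_2.name,
                           count, len(a))
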