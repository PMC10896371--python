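"""Offset-corrected genetic risk models.

Demographic effects (age, sex, ancestry-specific PCs) are regressed out
first by a logistic fit on those variables alone; its fitted linear
predictor enters every genetic model as a fixed offset, so the genetic
coefficients capture risk beyond demographics and population structure:

    yhat_i = g^{-1}(b0 + b1 x_i1 + ... + bp x_ip + offset_i)

Four model families are supported: ``apoe`` (the e4 allele count alone),
``single_prs`` (one standardized PRS), ``multi_prs`` (several PRSs), all
unpenalized, and ``enet_snp`` — Elastic Net over individual SNP dosages,
with the penalty strength and L1/L2 mixing chosen by nested cross-validation
maximizing AUPRC inside each training split.  Out-of-fold predictions from
the 5 stratified outer folds are pooled into one held-out prediction vector
per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

FAMILIES = ("apoe", "single_prs", "multi_prs", "enet_snp")


# ---------------------------------------------------------------------------
# demographic offset model
# ---------------------------------------------------------------------------

@dataclass
class DemographicOffsetModel:
    feature_names: list[str]
    params: np.ndarray           # intercept first
    offsets: np.ndarray          # fitted linear predictor, log-odds scale
    dropped: list[str] = field(default_factory=list)
    ridge_fallback: bool = False

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return sm.add_constant(X, has_constant="add") @ self.params


def _fit_logistic(y: np.ndarray, Xc: np.ndarray, offset: np.ndarray | None,
                  ) -> tuple[np.ndarray, bool]:
    """ML logistic fit; falls back to a tiny ridge penalty when the fit
    separates or diverges.  ``Xc`` includes the constant column."""
    model = sm.GLM(y, Xc, family=sm.families.Binomial(), offset=offset)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=200)
        params = np.asarray(res.params)
        if np.all(np.isfinite(params)) and np.abs(params).max() < 1e3:
            return params, False
    except Exception:  # PerfectSeparation and friends
        pass
    logger.warning("logistic fit separated or diverged; refitting with "
                   "ridge penalty 1e-6")
    res = model.fit_regularized(method="elastic_net", alpha=1e-6, L1_wt=0.0)
    return np.asarray(res.params), True


def fit_offset_model(labels: np.ndarray, age: np.ndarray, sex: np.ndarray,
                     group_pcs: np.ndarray | None = None,
                     ) -> DemographicOffsetModel:
    """Logistic regression of case status on age, sex, and within-group PCs.

    The per-sample offset is the fitted linear predictor (log-odds).
    Constant covariate columns are dropped with a notice; perfect separation
    triggers a ridge (1e-6) fallback with a warning.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one case and one control")
    cols = {"age": np.asarray(age, dtype=float),
            "sex": np.asarray(sex, dtype=float)}
    if group_pcs is not None:
        pcs = np.atleast_2d(np.asarray(group_pcs, dtype=float))
        for j in range(pcs.shape[1]):
            cols[f"PC{j + 1}"] = pcs[:, j]
    names, dropped, keep = [], [], []
    for name, col in cols.items():
        if np.isnan(col).any():
            raise ValueError(f"missing values in covariate {name}")
        if np.ptp(col) == 0:
            dropped.append(name)
            logger.info("fit_offset_model: constant covariate %s dropped",
                        name)
        else:
            names.append(name)
            keep.append(col)
    X = np.column_stack(keep) if keep else np.empty((len(y), 0))
    Xc = sm.add_constant(X, has_constant="add")
    params, ridge = _fit_logistic(y, Xc, None)
    offsets = Xc @ params
    return DemographicOffsetModel(names, params, offsets, dropped, ridge)


# ---------------------------------------------------------------------------
# genetic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElasticNetGrid:
    """Hyperparameter grid for the enet_snp family: L1/L2 mixing values,
    penalty strengths, and the inner-CV fold count used to choose them."""

    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    alphas: tuple[float, ...] = tuple(np.logspace(-4, 0, 20))
    n_inner: int = 3


# reduced log-spaced grid used inside permutation loops, where the full
# default grid would be prohibitively slow; one decade around the penalty
# scale appropriate for a few hundred samples and ~100 features
SMALL_GRID = ElasticNetGrid(l1_ratios=(0.5,),
                            alphas=(0.01, 0.022, 0.047, 0.1), n_inner=3)

# grid for support-recovery analyses at biobank scale (n ~ 2000, p ~ 300):
# the penalty scale shrinks roughly with sqrt(log p / n), and
# prediction-optimal penalties systematically over-shrink weak true
# effects out of the support, so the upper end stops below them
RECOVERY_GRID = ElasticNetGrid(l1_ratios=(0.5,),
                               alphas=(0.005, 0.011, 0.024), n_inner=3)


@dataclass
class GeneticRiskModel:
    family: str
    feature_names: list[str]
    intercept: float
    coef: np.ndarray                       # raw (input) feature scale
    coef_standardized: np.ndarray | None   # per-SD scale (enet_snp)
    hyperparams: dict = field(default_factory=dict)
    threshold: float | None = None
    fold_assignments: np.ndarray | None = None
    seed: int = 0

    def predict(self, X: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        return expit(self.intercept + X @ self.coef + offsets)

    def to_dict(self) -> dict:
        return {
            "family": self.family, "features": self.feature_names,
            "intercept": self.intercept, "coef": self.coef.tolist(),
            "coef_standardized": (None if self.coef_standardized is None
                                  else self.coef_standardized.tolist()),
            "hyperparams": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in self.hyperparams.items()},
            "threshold": self.threshold, "seed": self.seed,
        }


@dataclass
class RiskPrediction:
    """Pooled out-of-fold predicted probabilities; each sample is predicted
    exactly once, in the fold where it was held out."""

    yhat: np.ndarray
    fold_ids: np.ndarray


def elastic_net_logistic(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                         alpha: float, l1_ratio: float,
                         max_iter: int = 5000, tol: float = 1e-9,
                         ) -> np.ndarray:
    """Elastic-net penalized logistic regression with a fixed offset.

    Minimizes the mean negative log-likelihood of
    ``p_i = expit(b0 + x_i b + offset_i)`` plus
    ``alpha * (l1_ratio * |b|_1 + (1 - l1_ratio)/2 * |b|_2^2)`` with the
    intercept unpenalized, by accelerated proximal gradient (FISTA) with
    adaptive restart.  Soft-thresholding yields exact zeros, so the fitted
    coefficient vector is sparse for any positive L1 weight.

    Returns ``[b0, b1..bp]``.  The objective matches statsmodels'
    ``GLM.fit_regularized(method="elastic_net")`` parameterization (penalty
    on the per-observation average log-likelihood scale).
    """
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    l1 = alpha * l1_ratio
    l2 = alpha * (1.0 - l1_ratio)
    # Lipschitz constant of the smooth part: logistic curvature <= 1/4
    L = np.linalg.norm(Xc, 2) ** 2 / (4.0 * n) + l2
    step = 1.0 / L

    def _grad(b):
        eta = Xc @ b + offset
        resid = expit(eta) - y
        g = Xc.T @ resid / n
        g[1:] += l2 * b[1:]
        return g

    def _objective(b):
        eta = Xc @ b + offset
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        return (nll + l1 * np.abs(b[1:]).sum()
                + 0.5 * l2 * (b[1:] ** 2).sum())

    b = np.zeros(p + 1)
    z = b.copy()
    t = 1.0
    obj_prev = _objective(b)
    for _ in range(max_iter):
        b_new = z - step * _grad(z)
        b_new[1:] = np.sign(b_new[1:]) * np.maximum(
            np.abs(b_new[1:]) - step * l1, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = b_new + ((t - 1.0) / t_new) * (b_new - b)
        obj = _objective(b_new)
        if obj > obj_prev:  # adaptive restart of the momentum
            z, t_new = b_new.copy(), 1.0
        if abs(obj_prev - obj) < tol * (1.0 + abs(obj)):
            b = b_new
            break
        b, t, obj_prev = b_new, t_new, obj
    return b


def _fit_enet(y, X, offset, alpha, l1_ratio) -> np.ndarray:
    return elastic_net_logistic(np.asarray(y, dtype=float), X,
                                np.asarray(offset, dtype=float),
                                alpha, l1_ratio)


def _standardize(train: np.ndarray, other: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z_train = (train - mu) / sd
    z_other = None if other is None else (other - mu) / sd
    return z_train, z_other, mu, sd


def _select_enet_hyperparams(y, X, offset, grid: ElasticNetGrid, seed: int,
                             ) -> tuple[float, float]:
    """Inner CV over the grid, maximizing mean out-of-fold AUPRC."""
    combos = [(a, l1) for l1 in grid.l1_ratios for a in grid.alphas]
    if len(combos) == 1:
        return combos[0]
    inner = StratifiedKFold(grid.n_inner, shuffle=True, random_state=seed)
    scores = np.zeros(len(combos))
    for tr, te in inner.split(X, y):
        z_tr, z_te, _, _ = _standardize(X[tr], X[te])
        for c, (a, l1) in enumerate(combos):
            params = _fit_enet(y[tr], z_tr, offset[tr], a, l1)
            yhat = expit(params[0] + z_te @ params[1:] + offset[te])
            if y[te].min() == y[te].max():
                continue
            scores[c] += average_precision_score(y[te], yhat)
    best = int(np.argmax(scores))
    return combos[best]


def fit_genetic_model(features: pd.DataFrame, labels: np.ndarray,
                      offsets: np.ndarray, family: str,
                      cv_folds: int = 5,
                      enet_grid: ElasticNetGrid | None = None,
                      seed: int = 0,
                      offset_covariates: pd.DataFrame | None = None,
                      ) -> tuple[GeneticRiskModel, RiskPrediction]:
    """Fit one model family with 5-fold stratified CV under the offset
    contract; returns the full-data model and pooled out-of-fold
    predictions.

    Family/feature contract: ``apoe`` takes exactly one column (the e4
    count), ``single_prs`` one standardized PRS, ``multi_prs`` several
    PRSs, ``enet_snp`` a SNP dosage matrix.  The enet_snp penalty is chosen
    by inner CV on each training split; other families are unpenalized.

    When ``offset_covariates`` (age, sex, PC* columns, row-aligned with
    ``features``) is given, the demographic offset model is refitted inside
    each training fold and hold-out offsets come from that fold's fit, so
    the pooled out-of-fold predictions are honest with respect to the
    demographic stage as well; ``offsets`` then only feeds the final
    full-data fit.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected {FAMILIES}")
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    y = np.asarray(labels, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if family in ("apoe", "single_prs") and X.shape[1] != 1:
        raise ValueError(f"{family} family requires exactly one feature, "
                         f"got {X.shape[1]}")
    if int(y.sum()) < cv_folds or int((1 - y).sum()) < cv_folds:
        raise ValueError(
            f"stratified {cv_folds}-fold CV impossible: "
            f"{int(y.sum())} cases / {int((1 - y).sum())} controls")
    grid = enet_grid or ElasticNetGrid()

    if offset_covariates is not None:
        cov_cols = [c for c in ("age", "sex") if c in offset_covariates] + \
            [c for c in offset_covariates.columns if c.startswith("PC")]
        C = offset_covariates[cov_cols].to_numpy(dtype=float)

    outer = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    yhat = np.full(len(y), np.nan)
    fold_ids = np.full(len(y), -1)
    for k, (tr, te) in enumerate(outer.split(X, y)):
        if offset_covariates is not None:
            om = fit_offset_model(
                y[tr], offset_covariates["age"].to_numpy()[tr],
                offset_covariates["sex"].to_numpy()[tr],
                C[tr, 2:] if C.shape[1] > 2 else None)
            off_tr = om.offsets
            if om.feature_names:
                te_design = C[te][:, [cov_cols.index(n)
                                      for n in om.feature_names]]
            else:
                te_design = np.empty((len(te), 0))
            off_te = om.linear_predictor(te_design)
        else:
            off_tr, off_te = offsets[tr], offsets[te]
        if family == "enet_snp":
            a, l1 = _select_enet_hyperparams(y[tr], X[tr], off_tr,
                                             grid, seed + k)
            z_tr, z_te, _, _ = _standardize(X[tr], X[te])
            params = _fit_enet(y[tr], z_tr, off_tr, a, l1)
            yhat[te] = expit(params[0] + z_te @ params[1:] + off_te)
        else:
            Xc = sm.add_constant(X[tr], has_constant="add")
            params, _ = _fit_logistic(y[tr], Xc, off_tr)
            Xt = sm.add_constant(X[te], has_constant="add")
            yhat[te] = expit(Xt @ params + off_te)
        fold_ids[te] = k

    # final full-data fit for coefficients / transfer
    if family == "enet_snp":
        a, l1 = _select_enet_hyperparams(y, X, offsets, grid, seed)
        z, _, mu, sd = _standardize(X)
        params = _fit_enet(y, z, offsets, a, l1)
        coef_std = params[1:]
        coef_raw = coef_std / sd
        intercept = float(params[0] - (mu * coef_raw).sum())
        hyper = {"alpha": a, "l1_ratio": l1,
                 "grid_alphas": tuple(grid.alphas),
                 "grid_l1_ratios": tuple(grid.l1_ratios)}
    else:
        Xc = sm.add_constant(X, has_constant="add")
        params, ridge = _fit_logistic(y, Xc, offsets)
        intercept, coef_raw = float(params[0]), params[1:]
        coef_std, hyper = None, {"ridge_fallback": ridge}

    model = GeneticRiskModel(family, names, intercept, coef_raw, coef_std,
                             hyper, fold_assignments=fold_ids, seed=seed)
    return model, RiskPrediction(yhat, fold_ids)


# ---------------------------------------------------------------------------
# importance and transfer
# ---------------------------------------------------------------------------

def feature_importance(model: GeneticRiskModel, features: pd.DataFrame,
                       ) -> pd.Series:
    """Normalized importance ``|beta_j| * SD(feature_j)`` over features with
    nonzero coefficients (sums to 1); empty with a notice when the model
    selected nothing."""
    sd = features.to_numpy(dtype=float).std(axis=0)
    raw = np.abs(model.coef) * sd
    nz = raw > 0
    if not nz.any():
        logger.info("feature_importance: no nonzero coefficients")
        return pd.Series(dtype=float)
    imp = pd.Series(raw[nz] / raw[nz].sum(),
                    index=np.asarray(model.feature_names)[nz])
    return imp.sort_values(ascending=False)


def transfer_model(model: GeneticRiskModel, target_features: pd.DataFrame,
                   target_labels: np.ndarray, target_age: np.ndarray,
                   target_sex: np.ndarray,
                   target_group_pcs: np.ndarray | None = None,
                   ) -> tuple[RiskPrediction, DemographicOffsetModel]:
    """Apply frozen genetic coefficients to a new cohort.

    Demographic offsets are re-derived by fitting the offset model *within*
    the target sample; the genetic coefficients are used unchanged.  Missing
    model features raise, listing them.
    """
    missing = [f for f in model.feature_names
               if f not in target_features.columns]
    if missing:
        raise ValueError(f"target cohort missing model feature(s): {missing}")
    if len(target_features) == 0:
        raise ValueError("empty target cohort")
    offset_model = fit_offset_model(target_labels, target_age, target_sex,
                                    target_group_pcs)
    X = target_features[model.feature_names].to_numpy(dtype=float)
    yhat = model.predict(X, offset_model.offsets)
    return RiskPrediction(yhat, np.zeros(len(yhat), dtype=int)), offset_model
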