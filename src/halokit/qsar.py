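"""QSAR analysis of the brominated benzotriazole series.

Activities span 0.27 µM (TBBt) to the >2000 µM bound of the inactive
parent, so the response everywhere is log10(IC50/µM).  Three prespecified
models mirror the analysis of the compound table:

* ordinary least squares of log10(IC50) on molecular volume and pKa —
  hydrophobic bulk plus ionic-equilibrium contribution;
* a single-predictor fit on the summed ab initio free energies
  ΔG_diss + ΔG_solv(anion);
* the correlation of log10(IC50) with docking binding free energy.

The censored parent compound (activity known only as a lower bound) is
handled by an explicit policy: excluded, or included at its bound.
Principal component screening of the descriptor block and leave-one-out
diagnostics support the small-n fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .compounds import CompoundRecord, as_frame
from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "build_matrix",
    "QSARLinearModel",
    "fit_linear_qsar",
    "DescriptorPCA",
    "pca_descriptors",
    "correlate_binding",
    "loo_diagnostics",
]

DESCRIPTOR_COLUMNS = [
    "pKa",
    "Cw",
    "Vmol",
    "dG_diss",
    "dG_solv_anion",
    "dG_bind_neutral",
    "dG_bind_anion",
    "rmsf",
    "rmsd",
]


def build_matrix(
    records: Sequence[CompoundRecord], censor: str = "bound"
) -> pd.DataFrame:
    """Descriptor matrix with response ``log_ic50`` = log10(IC50/µM).

    ``censor="exclude"`` drops censored compounds; ``"bound"`` keeps them
    at the reported activity bound.  A derived column ``dG_sum`` holds
    ΔG_diss + ΔG_solv(anion).
    """
    if censor not in ("exclude", "bound"):
        raise ValueError("censor must be 'exclude' or 'bound'")
    df = as_frame(list(records))
    if censor == "exclude":
        df = df[~df["ic50_censored"]]
    df = df.copy()
    df["log_ic50"] = np.log10(df["ic50"])
    df["dG_sum"] = df["dG_diss"] + df["dG_solv_anion"]
    return df


class QSARLinearModel(BaseEstimator, RegressorMixin):
    """OLS of log10(IC50) on a named set of descriptor columns.

    Fitted attributes: ``coef_`` (pd.Series by predictor), ``intercept_``,
    ``r2_``, ``f_stat_``, ``df_`` = (k, n−k−1), ``fitted_``,
    ``residuals_``.  The F statistic satisfies
    F = (R²/k) / ((1−R²)/(n−k−1)) identically.
    """

    def __init__(self, predictors: Sequence[str] = ("Vmol", "pKa")):
        self.predictors = predictors

    def fit(self, X: pd.DataFrame, y=None):
        preds = list(self.predictors)
        missing = [p for p in preds if p not in X.columns]
        if missing:
            raise KeyError(f"predictors not in matrix: {missing}")
        if y is None:
            if "log_ic50" not in X.columns:
                raise KeyError("matrix lacks 'log_ic50'; pass y explicitly")
            y = X["log_ic50"]
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        n, k = len(X), len(preds)
        if n < k + 2:
            raise InsufficientDataError(f"need n >= {k + 2} rows for {k} predictors")
        design = sm.add_constant(X[preds].astype(float))
        if np.linalg.matrix_rank(design.values) < design.shape[1]:
            raise np.linalg.LinAlgError("singular design matrix")
        res = sm.OLS(y, design).fit()
        self.model_ = res
        self.coef_ = res.params[preds]
        self.intercept_ = float(res.params["const"])
        self.r2_ = float(res.rsquared)
        self.f_stat_ = float(res.fvalue)
        self.df_ = (int(res.df_model), int(res.df_resid))
        self.fitted_ = res.fittedvalues
        self.residuals_ = res.resid
        self.n_ = n
        return self

    def predict(self, X: pd.DataFrame):
        design = sm.add_constant(X[list(self.predictors)].astype(float), has_constant="add")
        return np.asarray(self.model_.predict(design))


def fit_linear_qsar(
    matrix: pd.DataFrame, predictors: Sequence[str], handle_censored: Optional[str] = None
) -> QSARLinearModel:
    """Fit OLS of log10(IC50) on *predictors*.

    *handle_censored* re-applies a censor policy on a matrix that still
    carries the ``ic50_censored`` column: "exclude" drops censored rows
    (bound substitution is what `build_matrix` already did).
    """
    if handle_censored == "exclude" and "ic50_censored" in matrix.columns:
        matrix = matrix[~matrix["ic50_censored"]]
    return QSARLinearModel(predictors=predictors).fit(matrix)


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame  # descriptors x components, orthonormal columns
    explained_variance_ratio: np.ndarray


class DescriptorPCA(BaseEstimator):
    """PCA of the standardized descriptor block (correlation-matrix eigen-
    decomposition), used to screen which descriptors dominate activity."""

    def __init__(self, columns: Optional[Sequence[str]] = None):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        cols = list(self.columns) if self.columns is not None else [
            c for c in DESCRIPTOR_COLUMNS if c in X.columns
        ]
        block = X[cols].astype(float)
        sd = block.std(ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise DegenerateDataError(f"constant descriptor columns: {bad}")
        corr = np.corrcoef(((block - block.mean()) / sd).values, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.clip(evals, 0.0, None)
        self.loadings_ = pd.DataFrame(
            evecs, index=cols, columns=[f"PC{i + 1}" for i in range(len(cols))]
        )
        self.explained_variance_ratio_ = evals / evals.sum()
        self.columns_ = cols
        return self

    def result(self) -> PCAResult:
        return PCAResult(self.loadings_, self.explained_variance_ratio_)


def pca_descriptors(matrix: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> PCAResult:
    """Screen descriptors by PCA of their correlation matrix."""
    return DescriptorPCA(columns=columns).fit(matrix).result()


@dataclass(frozen=True)
class BindingCorrelation:
    """log10(IC50) vs binding free energy, with per-compound residuals."""

    energy_column: str
    slope: float  # log10 units per kcal/mol
    intercept: float
    r: float  # Pearson correlation
    r2: float
    residuals_log: pd.Series  # observed - fitted, log10 units
    residuals_kcal: pd.Series  # residual / slope: kcal/mol equivalents


def correlate_binding(matrix: pd.DataFrame, energy_column: str = "dG_bind_neutral") -> BindingCorrelation:
    """Correlate activity with docking binding free energy.

    Residuals are also expressed in kcal/mol equivalents (log-residual
    divided by the fitted slope); a compound more active than its binding
    energy predicts shows up as binding underestimated by that amount.
    """
    y = matrix["log_ic50"].astype(float)
    x = matrix[energy_column].astype(float)
    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    slope = float(res.params[energy_column])
    resid = y - res.fittedvalues
    return BindingCorrelation(
        energy_column=energy_column,
        slope=slope,
        intercept=float(res.params["const"]),
        r=float(np.sign(slope) * np.sqrt(res.rsquared)),
        r2=float(res.rsquared),
        residuals_log=resid,
        residuals_kcal=resid / slope,
    )


@dataclass(frozen=True)
class LooResult:
    q2: float
    deleted_residuals: pd.Series  # observed - prediction from the fold excluding the row


def loo_diagnostics(matrix: pd.DataFrame, predictors: Sequence[str]) -> LooResult:
    """Leave-one-out cross-validation of a linear activity model.

    Q² = 1 − PRESS/TSS; with tiny n this is the standard robustness check
    for descriptor regressions.
    """
    if len(matrix) < 4:
        raise InsufficientDataError("leave-one-out needs n >= 4")
    y = matrix["log_ic50"].astype(float)
    deleted = {}
    for name in matrix.index:
        train = matrix.drop(index=name)
        model = QSARLinearModel(predictors=predictors).fit(train)
        pred = model.predict(matrix.loc[[name]])[0]
        deleted[name] = float(y.loc[name] - pred)
    deleted = pd.Series(deleted, name="deleted_residual").loc[matrix.index]
    press = float((deleted**2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return LooResult(q2=1.0 - press / tss, deleted_residuals=deleted)
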