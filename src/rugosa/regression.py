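"""Univariate biomass regression on canopy roughness.

Five trendline-style model families relate plot-level canopy roughness x
(m^2) to measured aboveground biomass y (g/m^2):

    linear        y = a*x + b
    power         y = a * x^b          (fit in log-log space)
    exponential   y = a * e^(b*x)      (fit in semilog space)
    polynomial2   y = a*x^2 + b*x + c
    logarithmic   y = a*ln(x) + b

Model strength is evaluated with leave-one-out cross-validation and four
error statistics over the out-of-fold predictions:

    RMSE  = sqrt(sum_i (yhat_i - y_i)^2 / n)              [g/m^2]
    RRMSE = 100 * RMSE / mean(y)                          [%]
    ASE   = (100/n) * sum_i (yhat_i - y_i) / y_i          [%] (signed bias)
    MPSE  = (100/n) * sum_i |yhat_i - y_i| / y_i          [%]

Plots with gross trait/biomass mismatch are rejected iteratively by
standardized residual before the final fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIES", "EvaluationSet", "ModelSpec", "ModelReport", "fit_model",
    "predict", "loocv", "error_metrics", "reject_plot_outliers",
    "genotype_report",
]

FAMILIES = ("linear", "power", "exponential", "polynomial2", "logarithmic")
_N_COEF = {"linear": 2, "power": 2, "exponential": 2,
           "polynomial2": 3, "logarithmic": 2}


@dataclass
class EvaluationSet:
    """Aligned per-plot trait (x), biomass (y_obs) and genotype vectors."""

    plot_ids: list[str]
    x: np.ndarray
    y_obs: np.ndarray
    genotype: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).ravel()
        self.y_obs = np.asarray(self.y_obs, dtype=np.float64).ravel()
        self.plot_ids = [str(p) for p in self.plot_ids]
        if not self.genotype:
            self.genotype = [""] * len(self.x)
        if not (len(self.plot_ids) == len(self.x) == len(self.y_obs)
                == len(self.genotype)):
            raise ValueError("plot_ids, x, y_obs and genotype must align")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, index: np.ndarray) -> "EvaluationSet":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EvaluationSet(
            [self.plot_ids[i] for i in idx], self.x[idx], self.y_obs[idx],
            [self.genotype[i] for i in idx])

    @classmethod
    def from_traits(cls, traits, agb: dict[str, float] | None = None
                    ) -> "EvaluationSet":
        """Build from PlotTrait records; AGB taken from the trait or a map."""
        ids, x, y, g = [], [], [], []
        for t in traits:
            obs = t.agb if t.agb is not None else (agb or {}).get(t.plot_id)
            if obs is None:
                raise ValueError(f"plot {t.plot_id!r}: no AGB observation")
            ids.append(t.plot_id)
            x.append(t.cr)
            y.append(obs)
            g.append(t.genotype)
        return cls(ids, np.asarray(x), np.asarray(y), g)


@dataclass
class ModelSpec:
    """A fitted model family with its coefficients."""

    family: str
    coefficients: tuple

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.coefficients = tuple(float(c) for c in self.coefficients)
        if len(self.coefficients) != _N_COEF[self.family]:
            raise ValueError(
                f"{self.family} needs {_N_COEF[self.family]} coefficients, "
                f"got {len(self.coefficients)}")


@dataclass
class ModelReport:
    """LOOCV evaluation of one model family."""

    model: ModelSpec
    r2: float                      # squared Pearson r, out-of-fold pred vs obs
    r2_sse: float                  # 1 - SSE/SST variant, for transparency
    rmse: float
    rrmse: float
    ase: float
    mpse: float
    plot_ids: list[str]
    loocv_predictions: np.ndarray  # NaN where a fold was skipped
    y_obs: np.ndarray
    outliers_removed: list[str] = field(default_factory=list)
    skipped_folds: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "family": self.model.family,
            "coefficients": list(self.model.coefficients),
            "r2": self.r2, "r2_sse": self.r2_sse, "rmse": self.rmse,
            "rrmse": self.rrmse, "ase": self.ase, "mpse": self.mpse,
            "outliers_removed": self.outliers_removed,
            "skipped_folds": self.skipped_folds,
        }


def _check_domain(data: EvaluationSet, family: str) -> None:
    bad: list[str] = []
    if family in ("power", "logarithmic"):
        bad += [p for p, xv in zip(data.plot_ids, data.x) if xv <= 0]
    if family in ("power", "exponential"):
        bad += [p for p, yv in zip(data.plot_ids, data.y_obs) if yv <= 0]
    if bad:
        raise ValueError(
            f"{family} fit undefined for plots {sorted(set(bad))} "
            "(requires x > 0 and/or y > 0)")


def fit_model(data: EvaluationSet, family: str) -> ModelSpec:
    """Least-squares fit of one family.

    linear/polynomial2/logarithmic are ordinary least squares; power and
    exponential are fitted by log-linearization (ln y on ln x, resp. x) and
    back-transformed — the deterministic spreadsheet-trendline convention.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if len(data) < _N_COEF[family]:  # exact interpolation is the floor
        raise ValueError(f"{family} needs at least {_N_COEF[family]} plots")
    _check_domain(data, family)
    x, y = data.x, data.y_obs
    if family == "linear":
        a, b = np.polyfit(x, y, 1)
        return ModelSpec(family, (a, b))
    if family == "polynomial2":
        a, b, c = np.polyfit(x, y, 2)
        return ModelSpec(family, (a, b, c))
    if family == "logarithmic":
        a, b = np.polyfit(np.log(x), y, 1)
        return ModelSpec(family, (a, b))
    if family == "power":
        b, ln_a = np.polyfit(np.log(x), np.log(y), 1)
        return ModelSpec(family, (np.exp(ln_a), b))
    # exponential
    b, ln_a = np.polyfit(x, np.log(y), 1)
    return ModelSpec(family, (np.exp(ln_a), b))


def predict(model: ModelSpec, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    c = model.coefficients
    if model.family == "linear":
        return c[0] * x + c[1]
    if model.family == "polynomial2":
        return c[0] * x ** 2 + c[1] * x + c[2]
    if model.family == "logarithmic":
        return c[0] * np.log(x) + c[1]
    if model.family == "power":
        return c[0] * x ** c[1]
    return c[0] * np.exp(c[1] * x)


def error_metrics(y_pred: np.ndarray, y_obs: np.ndarray
                  ) -> tuple[float, float, float, float]:
    """(RMSE, RRMSE %, ASE %, MPSE %) of predictions against observations.

    ASE keeps the sign of the relative errors (systematic bias); MPSE takes
    their absolute values, so MPSE >= |ASE| always.
    """
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    y_obs = np.asarray(y_obs, dtype=np.float64).ravel()
    if y_pred.shape != y_obs.shape:
        raise ValueError("prediction/observation length mismatch")
    if y_pred.size == 0:
        raise ValueError("empty metric input")
    if np.any(y_obs == 0) or y_obs.mean() == 0:
        raise ValueError("relative metrics undefined for zero observations")
    err = y_pred - y_obs
    rmse = float(np.sqrt(np.mean(err ** 2)))
    rrmse = float(100.0 * rmse / y_obs.mean())
    rel = err / y_obs
    ase = float(100.0 * rel.mean())
    mpse = float(100.0 * np.abs(rel).mean())
    return rmse, rrmse, ase, mpse


def _pearson_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    if pred.size < 2 or np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def loocv(data: EvaluationSet, family: str) -> ModelReport:
    """Leave-one-out cross-validation of one model family.

    Each plot is predicted by a model fitted to the remaining n-1 plots; the
    error statistics are computed over the out-of-fold predictions. Folds
    that violate a family's domain constraints are skipped and logged, with
    metrics taken over the completed folds.
    """
    n = len(data)
    if n < _N_COEF[family] + 1:  # each fold must still determine a fit
        raise ValueError(f"LOOCV with {family} needs at least "
                         f"{_N_COEF[family] + 1} plots")
    preds = np.full(n, np.nan)
    skipped: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            spec = fit_model(data.subset(mask), family)
            preds[i] = predict(spec, data.x[i : i + 1])[0]
        except ValueError:
            skipped.append(data.plot_ids[i])
    done = ~np.isnan(preds)
    if done.sum() < 2:
        raise ValueError(f"LOOCV completed only {int(done.sum())} folds")
    rmse, rrmse, ase, mpse = error_metrics(preds[done], data.y_obs[done])
    pred_d, obs_d = preds[done], data.y_obs[done]
    sst = float(np.sum((obs_d - obs_d.mean()) ** 2))
    r2_sse = float(1.0 - np.sum((pred_d - obs_d) ** 2) / sst) if sst > 0 else float("nan")
    return ModelReport(
        model=fit_model(data, family),
        r2=_pearson_r2(pred_d, obs_d), r2_sse=r2_sse,
        rmse=rmse, rrmse=rrmse, ase=ase, mpse=mpse,
        plot_ids=list(data.plot_ids), loocv_predictions=preds,
        y_obs=data.y_obs.copy(), skipped_folds=skipped,
    )


def reject_plot_outliers(data: EvaluationSet, family: str, limit: float = 2.0
                         ) -> tuple[EvaluationSet, list[str]]:
    """Iteratively drop plots with |standardized residual| > limit.

    At each pass the family is fitted to the surviving plots, residuals are
    standardized by their sample standard deviation and every plot beyond the
    limit is removed; iteration stops when the maximum standardized residual
    is within the limit. Raises if removal would exhaust the data before
    convergence.
    """
    removed: list[str] = []
    current = data
    min_n = _N_COEF[family] + 3  # keep LOOCV feasible afterwards
    while True:
        spec = fit_model(current, family)
        resid = current.y_obs - predict(spec, current.x)
        sd = resid.std(ddof=1)
        if sd == 0:
            return current, removed
        standardized = resid / sd
        over = np.abs(standardized) > limit
        if not over.any():
            return current, removed
        if len(current) - int(over.sum()) < min_n:
            raise ValueError(
                "outlier rejection would exhaust the data before convergence")
        removed += [current.plot_ids[i] for i in np.flatnonzero(over)]
        current = current.subset(~over)


def genotype_report(report: ModelReport, data: EvaluationSet,
                    min_plots: int = 3) -> pd.DataFrame:
    """Per-genotype error metrics over the LOOCV predictions.

    Genotypes with fewer than ``min_plots`` plots are omitted; the best and
    worst genotypes by RRMSE are flagged.
    """
    pred_by_id = dict(zip(report.plot_ids, report.loocv_predictions))
    rows = []
    df = pd.DataFrame({"plot_id": data.plot_ids, "genotype": data.genotype,
                       "y_obs": data.y_obs})
    df["pred"] = df["plot_id"].map(pred_by_id)
    df = df.dropna(subset=["pred"])
    for genotype, grp in df.groupby("genotype", sort=True):
        if len(grp) < min_plots:
            continue
        rmse, rrmse, ase, mpse = error_metrics(grp["pred"].to_numpy(),
                                               grp["y_obs"].to_numpy())
        rows.append({"genotype": genotype, "n_plots": len(grp), "rmse": rmse,
                     "rrmse": rrmse, "ase": ase, "mpse": mpse})
    table = pd.DataFrame(rows, columns=["genotype", "n_plots", "rmse",
                                        "rrmse", "ase", "mpse"])
    if len(table):
        table["flag"] = ""
        table.loc[table["rrmse"].idxmin(), "flag"] = "best"
        table.loc[table["rrmse"].idxmax(), "flag"] = "worst"
    return table
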