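"""Model evaluation: discrimination, calibration, information criteria and
bias-corrected bootstrap confidence intervals.

* AUC is the Mann-Whitney probability that a random death outranks a random
  survivor, with ties counted one half.
* The Hosmer-Lemeshow statistic groups patients into deciles of predicted
  risk (quantile bins, ties to the lower bin) and sums
  ``(O - E)^2 / (E (1 - E/n_bin))`` over bins for the event counts.
* Calibration curves bin predictions into equal-count groups, attach exact
  binomial intervals to the observed rates, and summarise with an ordinary
  least-squares line of observed on predicted bin means.
* Confidence intervals use the bias-corrected (BC) percentile bootstrap with
  patient-level resampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import PatientRecord
from .wadp import SeverityTable

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Invalid input to an evaluation statistic."""


def auc(predictions: np.ndarray, outcomes: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney with ties counted 1/2)."""
    y = np.asarray(outcomes).astype(bool)
    p = np.asarray(predictions, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise EvaluationError("AUC undefined: outcome has a single class")
    r = stats.rankdata(p)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def hosmer_lemeshow(
    predictions: np.ndarray,
    outcomes: np.ndarray,
    groups: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Hosmer-Lemeshow grouped calibration statistic and its bin table.

    Deciles-of-risk grouping: quantile bins of the predictions with ties
    assigned to the lower bin.  Bins emptied by tie collapsing are dropped
    with a warning (the effective group count shrinks).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes).astype(float)
    if len(p) < groups:
        raise EvaluationError(f"need at least {groups} observations for {groups} groups")
    if (p <= 0).any() or (p >= 1).any():
        raise EvaluationError("predictions must lie strictly in (0,1)")
    edges = np.quantile(p, np.linspace(0, 1, groups + 1)[1:-1])
    bin_idx = np.searchsorted(edges, p, side="left")
    tab = (
        pd.DataFrame({"bin": bin_idx, "p": p, "y": y})
        .groupby("bin")
        .agg(n=("y", "size"), observed=("y", "sum"), expected=("p", "sum"),
             mean_pred=("p", "mean"))
    )
    if len(tab) < groups:
        logger.warning(
            "HL grouping collapsed to %d bins (ties); statistic uses %d groups",
            len(tab),
            len(tab),
        )
    O, E, n = (tab[c].to_numpy(float) for c in ("observed", "expected", "n"))
    denom = E * (1.0 - E / n)
    if (denom <= 0).any():
        raise EvaluationError("degenerate HL bin with zero expected variance")
    statistic = float(np.sum((O - E) ** 2 / denom))
    return statistic, tab.reset_index()


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, ``2k - 2 loglik``."""
    if k < 0:
        raise EvaluationError("k must be nonnegative")
    return 2.0 * k - 2.0 * loglik


def bernoulli_loglik(predictions: np.ndarray, outcomes: np.ndarray) -> float:
    """Log-likelihood of binary outcomes under the given probabilities."""
    p = np.clip(np.asarray(predictions, float), 1e-12, 1 - 1e-12)
    y = np.asarray(outcomes).astype(float)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# Bias-corrected bootstrap
# ---------------------------------------------------------------------------


def _bc_interval(
    replicates: np.ndarray, point: float, level: float
) -> tuple[float, float]:
    """Bias-corrected percentile interval from bootstrap replicates."""
    reps = np.asarray(replicates, dtype=float)
    if np.ptp(reps) == 0 and reps[0] == point:
        return float(point), float(point)
    b = len(reps)
    frac = np.mean(reps < point)
    frac = np.clip(frac, 1.0 / (b + 1), 1.0 - 1.0 / (b + 1))
    z0 = stats.norm.ppf(frac)
    zlo = stats.norm.ppf((1 - level) / 2)
    zhi = stats.norm.ppf(1 - (1 - level) / 2)
    a_lo = stats.norm.cdf(2 * z0 + zlo)
    a_hi = stats.norm.cdf(2 * z0 + zhi)
    return float(np.quantile(reps, a_lo)), float(np.quantile(reps, a_hi))


def bootstrap_ci(
    metric: Callable[..., float],
    *data: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_failure_rate: float = 0.01,
) -> tuple[float, float]:
    """Bias-corrected bootstrap CI of ``metric(*data)``.

    Resampling is at the observation (patient) level, jointly across the data
    arrays.  Resamples on which the metric raises (e.g. a single-class AUC
    draw) are skipped, up to ``max_failure_rate`` of ``n_boot``.
    """
    arrays = [np.asarray(d) for d in data]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise EvaluationError("data arrays must share a length")
    point = float(metric(*arrays))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    failures = 0
    got = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            reps[got] = metric(*(a[idx] for a in arrays))
            got += 1
        except Exception:
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise EvaluationError(
            f"metric failed on {failures}/{n_boot} bootstrap resamples"
        )
    return _bc_interval(reps[:got], point, level)


# ---------------------------------------------------------------------------
# Calibration curve
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Binned calibration table and its ordinary least-squares summary."""

    table: pd.DataFrame  # bin, n, mean_pred, observed_rate, ci_lo, ci_hi
    slope: float
    intercept: float
    r_squared: float


def calibration_curve(
    predictions: np.ndarray,
    outcomes: np.ndarray,
    bins: int = 20,
) -> CalibrationResult:
    """Equal-count binned calibration with an OLS line of observed on predicted.

    Observed per-bin mortality carries an exact (Clopper-Pearson) binomial
    95% interval.  Bins collapsed away by ties are merged into their lower
    neighbour and logged.
    """
    if bins < 2:
        raise EvaluationError("need at least 2 calibration bins")
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes).astype(float)
    edges = np.quantile(p, np.linspace(0, 1, bins + 1)[1:-1])
    bin_idx = np.searchsorted(edges, p, side="left")
    tab = (
        pd.DataFrame({"bin": bin_idx, "p": p, "y": y})
        .groupby("bin")
        .agg(n=("y", "size"), deaths=("y", "sum"), mean_pred=("p", "mean"))
        .reset_index()
    )
    if len(tab) < bins:
        logger.warning(
            "calibration binning merged %d degenerate bin(s)", bins - len(tab)
        )
    if len(tab) < 2:
        raise EvaluationError("fewer than 2 distinct calibration bins")
    tab["observed_rate"] = tab["deaths"] / tab["n"]
    lo, hi = [], []
    for _, row in tab.iterrows():
        ci = stats.binomtest(int(row["deaths"]), int(row["n"])).proportion_ci(0.95)
        lo.append(ci.low)
        hi.append(ci.high)
    tab["ci_lo"], tab["ci_hi"] = lo, hi
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = stats.linregress(tab["mean_pred"], tab["observed_rate"])
    return CalibrationResult(
        table=tab,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Validation-set performance of one model."""

    name: str
    n: int
    auc: float
    auc_ci: tuple[float, float]
    hl: float
    hl_ci: tuple[float, float]
    hl_groups: int
    aic: float
    k_params: int
    calibration: CalibrationResult
    predictions: np.ndarray = field(repr=False, default=None)

    def row(self) -> dict:
        return {
            "model": self.name,
            "n": self.n,
            "roc": self.auc,
            "roc_ci_lo": self.auc_ci[0],
            "roc_ci_hi": self.auc_ci[1],
            "hl": self.hl,
            "hl_ci_lo": self.hl_ci[0],
            "hl_ci_hi": self.hl_ci[1],
            "aic": self.aic,
            "calib_slope": self.calibration.slope,
            "calib_intercept": self.calibration.intercept,
            "calib_r2": self.calibration.r_squared,
        }


def evaluate_predictions(
    name: str,
    predictions: np.ndarray,
    outcomes: np.ndarray,
    k_params: int,
    n_boot: int = 1000,
    seed: int = 0,
    hl_groups: int = 10,
    calibration_bins: int = 20,
) -> EvalReport:
    """Full evaluation of one prediction vector on a validation set.

    The AIC uses the validation-set Bernoulli log-likelihood of the supplied
    predictions with the model's parameter count, so competing models are
    ranked on the same held-out data.
    """
    predictions = np.asarray(predictions, float)
    outcomes = np.asarray(outcomes).astype(float)
    point_auc = auc(predictions, outcomes)
    auc_ci = bootstrap_ci(auc, predictions, outcomes, n_boot=n_boot, seed=seed)
    hl_stat, hl_table = hosmer_lemeshow(predictions, outcomes, groups=hl_groups)
    hl_ci = bootstrap_ci(
        lambda p, y: hosmer_lemeshow(p, y, groups=hl_groups)[0],
        predictions,
        outcomes,
        n_boot=n_boot,
        seed=seed + 1,
    )
    report = EvalReport(
        name=name,
        n=len(outcomes),
        auc=point_auc,
        auc_ci=auc_ci,
        hl=hl_stat,
        hl_ci=hl_ci,
        hl_groups=len(hl_table),
        aic=aic(bernoulli_loglik(predictions, outcomes), k_params),
        k_params=k_params,
        calibration=calibration_curve(predictions, outcomes, bins=calibration_bins),
        predictions=predictions,
    )
    return report


def compare_models(
    patients: Sequence[PatientRecord],
    models: Mapping[str, tuple["MortalityResults", SeverityTable]],
    n_boot: int = 1000,
    seed: int = 0,
    hl_groups: int = 10,
    calibration_bins: int = 20,
) -> list[EvalReport]:
    """Evaluate fitted models on a common validation set; ranked by AIC.

    ``models`` maps a display name to (fitted results, severity table); the
    table is the WADP dictionary for IMP/SWI and the MARC dictionary for the
    TMPM comparator.  Inputs are not mutated and the report is reproducible
    under the seed.
    """
    if len(models) < 2:
        raise EvaluationError("compare_models needs at least two models")
    y = np.array([bool(p.died) for p in patients], dtype=float)
    reports = []
    for name, (results, table) in models.items():
        preds = results.predict_patients(patients, table)
        reports.append(
            evaluate_predictions(
                name,
                preds,
                y,
                k_params=results.k_params,
                n_boot=n_boot,
                seed=seed,
                hl_groups=hl_groups,
                calibration_bins=calibration_bins,
            )
        )
    reports.sort(key=lambda r: r.aic)
    return reports


def report_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Model-comparison table: one row per model (ROC [CI], HL [CI], AIC)."""
    return pd.DataFrame([r.row() for r in reports])


def report_json(reports: Sequence[EvalReport]) -> dict:
    out = {}
    for r in reports:
        out[r.name] = {
            **{k: v for k, v in r.row().items() if k != "model"},
            "hl_groups": r.hl_groups,
            "k_params": r.k_params,
            "calibration_bins": r.calibration.table[
                ["n", "mean_pred", "observed_rate", "ci_lo", "ci_hi"]
            ].to_dict(orient="list"),
        }
    return out


def plot_calibration(reports: Sequence[EvalReport], path) -> None:
    """Binned observed-vs-predicted mortality with a perfect-calibration line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(reports), figsize=(4.2 * len(reports), 4.0), squeeze=False
    )
    for ax, rep in zip(axes[0], reports):
        t = rep.calibration.table
        yerr = np.vstack(
            [t["observed_rate"] - t["ci_lo"], t["ci_hi"] - t["observed_rate"]]
        )
        ax.errorbar(
            t["mean_pred"], t["observed_rate"], yerr=yerr, fmt="o-", ms=3, lw=1
        )
        lim = max(t["mean_pred"].max(), t["observed_rate"].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k:", lw=1)
        ax.set_xlabel("predicted mortality")
        ax.set_ylabel("observed mortality")
        ax.set_title(f"{rep.name} (R² = {rep.calibration.r_squared:.4f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "EvaluationError",
    "CalibrationResult",
    "EvalReport",
    "auc",
    "hosmer_lemeshow",
    "aic",
    "bernoulli_loglik",
    "bootstrap_ci",
    "calibration_curve",
    "evaluate_predictions",
    "compare_models",
    "report_frame",
    "report_json",
    "plot_calibration",
]
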