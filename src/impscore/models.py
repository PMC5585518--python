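"""Stage-2 mortality models: IMP, SWI and the TMPM comparator.

Feature construction
--------------------
* **IMP** (injury mortality prediction): the five largest severity-dictionary
  values among the patient's injuries in decreasing order (zero-padded below
  five injuries), an indicator that the worst and second-worst injuries share
  a body region, the product of the two worst values, and two fractional-
  polynomial terms of the number of injured body regions, ``ln(NBR)`` and
  ``NBR^0.382``.
* **SWI** (single worst injury): the largest value alone.
* **TMPM**: the same structure as IMP but computed on an externally supplied
  MARC severity dictionary.

Each model is a logistic regression of in-hospital death on those features,
optionally augmented with ln(age), sex and injury-mechanism dummies, with a
cluster-robust (hospital-clustered sandwich) covariance because outcomes
within a trauma centre are correlated.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry import MECHANISMS, PatientRecord, RegistryError, injury_table, patient_table
from .wadp import SeverityTable

logger = logging.getLogger(__name__)

NBR_EXPONENT = 0.382  # fractional-polynomial power for the NBR term

ModelKind = Literal["imp", "swi", "tmpm"]

_MECH_DUMMIES = [f"mech_{m}" for m in MECHANISMS if m != "low_fall"]
AUGMENT_COLUMNS = ["ln_age", "sex_male"] + _MECH_DUMMIES


class ModelError(RuntimeError):
    """Feature-construction or fitting failure."""


@dataclass(frozen=True)
class IMPFeatures:
    """The anatomic feature vector of the IMP model for one patient."""

    w1: float
    w2: float
    w3: float
    w4: float
    w5: float
    same_br: int
    w1w2: float
    ln_nbr: float
    nbr_pow: float

    def as_dict(self) -> dict[str, float]:
        return {
            "w1": self.w1,
            "w2": self.w2,
            "w3": self.w3,
            "w4": self.w4,
            "w5": self.w5,
            "same_br": float(self.same_br),
            "w1w2": self.w1w2,
            "ln_nbr": self.ln_nbr,
            "nbr_pow": self.nbr_pow,
        }


def _sorted_injuries(
    patient: PatientRecord, table: SeverityTable
) -> list[tuple[float, int, str]]:
    """(value, region, predot) per injury, sorted worst-first.

    Ties in value break by body region then predot so the ordering (and the
    same-region flag) is deterministic under any input permutation.
    """
    if not patient.injuries:
        raise ModelError(f"patient {patient.patient_id} has no injuries")
    items = [
        (table.lookup(inj.code.predot), inj.code.body_region, inj.code.predot)
        for inj in patient.injuries
    ]
    return sorted(items, key=lambda t: (-t[0], t[1], t[2]))


def build_imp_features(patient: PatientRecord, table: SeverityTable) -> IMPFeatures:
    """IMP feature vector for one patient (see module docstring)."""
    items = _sorted_injuries(patient, table)
    vals = [v for v, _, _ in items[:5]] + [0.0] * max(0, 5 - len(items))
    if len(items) >= 2:
        same_br = int(items[0][1] == items[1][1])
        w1w2 = items[0][0] * items[1][0]
    else:
        same_br, w1w2 = 0, 0.0
    nbr = patient.nbr
    return IMPFeatures(
        w1=vals[0],
        w2=vals[1],
        w3=vals[2],
        w4=vals[3],
        w5=vals[4],
        same_br=same_br,
        w1w2=w1w2,
        ln_nbr=float(np.log(nbr)),
        nbr_pow=float(nbr**NBR_EXPONENT),
    )


def build_swi_features(patient: PatientRecord, table: SeverityTable) -> float:
    """The worst (largest) severity value among the patient's injuries."""
    if not patient.injuries:
        raise ModelError(f"patient {patient.patient_id} has no injuries")
    return max(table.lookup(inj.code.predot) for inj in patient.injuries)


def build_tmpm_features(patient: PatientRecord, marc: SeverityTable) -> IMPFeatures:
    """TMPM comparator features: IMP structure over the MARC dictionary."""
    return build_imp_features(patient, marc)


def imp_feature_frame(
    patients: Sequence[PatientRecord], table: SeverityTable
) -> pd.DataFrame:
    """Vectorised IMP feature matrix, one row per patient (input order)."""
    inj = injury_table(patients)
    if (inj.groupby("patient_id").size().reindex(
        [p.patient_id for p in patients]
    ).fillna(0) == 0).any():
        raise ModelError("every patient needs at least one injury")
    inj["value"] = table.values_for(inj["predot"].tolist())
    inj = inj.sort_values(
        ["patient_id", "value", "region", "predot"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    inj["rank"] = inj.groupby("patient_id").cumcount()
    pid = [p.patient_id for p in patients]
    top = inj[inj["rank"] < 5]
    wide = top.pivot(index="patient_id", columns="rank", values="value").reindex(pid)
    W = wide.reindex(columns=range(5)).fillna(0.0).to_numpy()
    reg = top.pivot(index="patient_id", columns="rank", values="region").reindex(pid)
    r0 = reg[0].to_numpy()
    r1 = reg[1].to_numpy() if 1 in reg.columns else np.full(len(pid), np.nan)
    multi = ~pd.isna(r1)
    same_br = np.where(multi, r0 == r1, False).astype(float)
    w1w2 = np.where(multi, W[:, 0] * W[:, 1], 0.0)
    nbr = (
        inj.groupby("patient_id")["region"].nunique().reindex(pid).to_numpy(float)
    )
    out = pd.DataFrame(
        {
            "w1": W[:, 0],
            "w2": W[:, 1],
            "w3": W[:, 2],
            "w4": W[:, 3],
            "w5": W[:, 4],
            "same_br": same_br,
            "w1w2": w1w2,
            "ln_nbr": np.log(nbr),
            "nbr_pow": nbr**NBR_EXPONENT,
        },
        index=pd.Index(pid, name="patient_id"),
    )
    return out


def augment_features(
    features: pd.DataFrame, patients: Sequence[PatientRecord]
) -> pd.DataFrame:
    """Append ln(age), a male indicator and mechanism dummies (ref low_fall)."""
    pt = patient_table(patients)
    unknown = set(pt["mechanism"]) - set(MECHANISMS)
    if unknown:
        raise ModelError(f"unknown mechanism level(s): {sorted(unknown)}")
    X = features.copy()
    X["ln_age"] = np.log(pt["age"].to_numpy(float))
    X["sex_male"] = (pt["sex"] == "male").to_numpy(float)
    for mech in MECHANISMS:
        if mech == "low_fall":
            continue
        X[f"mech_{mech}"] = (pt["mechanism"] == mech).to_numpy(float)
    return X


def feature_frame(
    patients: Sequence[PatientRecord],
    table: SeverityTable,
    kind: ModelKind = "imp",
    augment: bool = False,
) -> pd.DataFrame:
    """Design matrix (without intercept) for a model kind."""
    if kind in ("imp", "tmpm"):
        X = imp_feature_frame(patients, table)
    elif kind == "swi":
        X = imp_feature_frame(patients, table)[["w1"]].rename(columns={"w1": "swi"})
    else:
        raise RegistryError(f"unknown model kind {kind!r}")
    if augment:
        X = augment_features(X, patients)
    return X


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class MortalityModel:
    """Logistic mortality model on severity-dictionary features.

    Statsmodels-style: construct from data (or via :meth:`from_patients`),
    then :meth:`fit` returns a :class:`MortalityResults`.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: pd.DataFrame,
        clusters: Sequence | None = None,
        kind: ModelKind = "imp",
        augmented: bool = False,
    ) -> None:
        y = np.asarray(endog, dtype=float)
        if y.min() == y.max():
            raise ModelError("outcome is constant; nothing to fit")
        if len(exog) != len(y):
            raise ModelError("endog/exog length mismatch")
        self.endog = y
        self.exog = exog.astype(float)
        self.clusters = None if clusters is None else np.asarray(clusters)
        if self.clusters is not None and len(self.clusters) != len(y):
            raise ModelError("cluster vector length mismatch")
        self.kind = kind
        self.augmented = augmented

    @classmethod
    def from_patients(
        cls,
        patients: Sequence[PatientRecord],
        table: SeverityTable,
        kind: ModelKind = "imp",
        augment: bool = False,
    ) -> "MortalityModel":
        X = feature_frame(patients, table, kind=kind, augment=augment)
        y = np.array([bool(p.died) for p in patients], dtype=float)
        clusters = np.array([p.hospital_id for p in patients])
        return cls(y, X, clusters=clusters, kind=kind, augmented=augment)

    def fit(self, cov_correction: bool = False, maxiter: int = 1000) -> "MortalityResults":
        """Maximum-likelihood fit with hospital-clustered sandwich covariance.

        ``cov_correction`` applies the Stata-style small-sample factor; off by
        default, so with one observation per cluster the covariance is exactly
        the HC0 sandwich.
        """
        X = sm.add_constant(self.exog, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(self.endog, X)
            try:
                cov_opts = {}
                if self.clusters is not None:
                    cov_opts = dict(
                        cov_type="cluster",
                        cov_kwds={
                            "groups": pd.Series(self.clusters)
                            .astype("category")
                            .cat.codes.to_numpy(),
                            "use_correction": cov_correction,
                        },
                    )
                res = model.fit(
                    disp=0, maxiter=maxiter, method="lbfgs", pgtol=1e-9,
                    factr=1e2, **cov_opts,
                )
                if not res.mle_retvals.get("converged", True):
                    # near-collinear designs can stall L-BFGS short of the
                    # tight gradient tolerance; polish with Newton steps
                    res = model.fit(
                        disp=0, maxiter=100, method="newton",
                        start_params=res.params, **cov_opts,
                    )
            except Exception as exc:
                raise ModelError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise ModelError("non-finite coefficients (separation?)")
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            raise ModelError("logistic fit did not converge")
        return MortalityResults(
            kind=self.kind,
            augmented=self.augmented,
            feature_names=list(X.columns),
            params=res.params.copy(),
            cov=pd.DataFrame(
                res.cov_params(), index=X.columns, columns=X.columns
            ),
            llf=float(res.llf),
            nobs=int(res.nobs),
            converged=converged,
            n_iterations=int(res.mle_retvals.get("iterations", -1)),
            _sm_result=res,
        )


@dataclass
class MortalityResults:
    """Fitted mortality model: coefficients, cluster-robust covariance,
    likelihood and AIC, with prediction and serialisation."""

    kind: ModelKind
    augmented: bool
    feature_names: list[str]
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    nobs: int
    converged: bool
    n_iterations: int
    _sm_result: object | None = None

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(features.astype(float), has_constant="add")
        missing = set(self.feature_names) - set(X.columns)
        extra = set(X.columns) - set(self.feature_names)
        if missing or extra:
            raise ModelError(
                f"feature mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        X = X[self.feature_names]
        return X.to_numpy() @ self.params.to_numpy()

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Death probability via the inverse logit, kept strictly inside
        (0,1) (extreme linear predictors would otherwise underflow to 0/1 in
        floating point)."""
        lp = self.linear_predictor(features)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-lp))
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def predict_patients(
        self, patients: Sequence[PatientRecord], table: SeverityTable
    ) -> np.ndarray:
        X = feature_frame(patients, table, kind=self.kind, augment=self.augmented)
        return self.predict(X)

    def summary(self) -> str:
        label = self.kind.upper() + (" + age/sex/mechanism" if self.augmented else "")
        head = [
            f"Mortality model: {label}",
            "=" * 58,
            f"n = {self.nobs}   log-likelihood = {self.llf:.2f}   AIC = {self.aic:.2f}",
            f"{'term':<12}{'coef':>12}{'robust SE':>12}{'z':>10}",
            "-" * 58,
        ]
        rows = [
            f"{name:<12}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
            f"{self.params[name] / self.bse[name]:>10.2f}"
            for name in self.params.index
        ]
        return "\n".join(head + rows)

    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.kind,
            "augmented": self.augmented,
            "feature_names": self.feature_names,
            "params": {k: float(v) for k, v in self.params.items()},
            "cov": self.cov.to_numpy().tolist(),
            "llf": self.llf,
            "aic": self.aic,
            "nobs": self.nobs,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "MortalityResults":
        with open(path) as fh:
            payload = json.load(fh)
        names = payload["feature_names"]
        return cls(
            kind=payload["kind"],
            augmented=payload["augmented"],
            feature_names=names,
            params=pd.Series(payload["params"]).reindex(names),
            cov=pd.DataFrame(payload["cov"], index=names, columns=names),
            llf=payload["llf"],
            nobs=payload["nobs"],
            converged=payload["converged"],
            n_iterations=payload["n_iterations"],
        )


__all__ = [
    "IMPFeatures",
    "ModelError",
    "MortalityModel",
    "MortalityResults",
    "NBR_EXPONENT",
    "AUGMENT_COLUMNS",
    "build_imp_features",
    "build_swi_features",
    "build_tmpm_features",
    "imp_feature_frame",
    "augment_features",
    "feature_frame",
]
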