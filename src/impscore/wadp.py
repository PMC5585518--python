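"""Stage-1 severity derivation: from a derivation cohort to a per-code
severity dictionary.

The pipeline is

1. **TMR** — the empirical trauma mortality rate of each AIS predot code,
   smoothed at the endpoints: codes with zero observed deaths get the floor
   ``0.008 x 0.618`` (the US crude death rate of roughly 0.8% scaled by the
   golden ratio point), and codes with 100% observed mortality get
   ``d / (n + 1)`` (one survivor added).
2. **Component models** — three logistic regressions of in-hospital death on,
   respectively, a TMR summary of the patient's codes, the total GCS, and
   injured-body-region indicators; each also carries the comprehensive
   covariates (number of body regions, ln age, sex, mechanism, hospital fixed
   effects).
3. **TDP** — each patient's traumatic death probability, a convex blend of the
   three component predictions whose weights are chosen by a simplex grid
   search maximising AUC on an internal held-out fold.
4. **WADP** — per predot code, the mean of the 3 highest transformed TDPs
   among the patients carrying the code.  By default the TMR component of
   each (patient, code) score is anchored at the code's own TMR (see
   :func:`derive_wadp_anchored`); the purely patient-level aggregation is
   available via ``DerivationConfig(anchor="patient")``.  The default
   transform is the cumulative hazard ``h(p) = -ln(1-p)``, which keeps small
   probabilities essentially unchanged while letting near-certain deaths
   score above 1.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry import PatientRecord, RegistryError, injury_table, patient_table
from .simulate import hazard

logger = logging.getLogger(__name__)

#: Zero-death smoothing floor: 0.8% US crude death rate times the 0.618 point.
TMR_FLOOR = 0.008 * 0.618

Transform = Literal["neg-log-survival", "identity"]


class DerivationError(RuntimeError):
    """Raised when a derivation stage cannot be completed."""


def _transform_fn(name: Transform) -> Callable[[np.ndarray], np.ndarray]:
    if name == "neg-log-survival":
        return hazard
    if name == "identity":
        return lambda p: np.asarray(p, dtype=float)
    raise RegistryError(f"unknown severity transform {name!r}")


# ---------------------------------------------------------------------------
# TMR
# ---------------------------------------------------------------------------


def compute_tmr(
    patients: Sequence[PatientRecord],
    floor: float = TMR_FLOOR,
) -> pd.DataFrame:
    """Per-code trauma mortality rate with endpoint smoothing.

    Returns a frame indexed by predot with columns ``n_patients``,
    ``n_deaths``, ``tmr``.  A patient carrying the same code twice counts
    once.  After smoothing every TMR lies strictly inside (0, 1).
    """
    if len(patients) == 0:
        raise DerivationError("empty derivation set")
    inj = injury_table(patients).drop_duplicates(["patient_id", "predot"])
    grp = inj.groupby("predot")["died"]
    tab = pd.DataFrame({"n_patients": grp.size(), "n_deaths": grp.sum().astype(int)})
    n, d = tab["n_patients"].to_numpy(float), tab["n_deaths"].to_numpy(float)
    tmr = d / n
    tmr[d == 0] = floor
    full = d == n
    tmr[full] = d[full] / (n[full] + 1.0)
    tab["tmr"] = tmr
    assert ((tab["tmr"] > 0) & (tab["tmr"] < 1)).all()
    return tab


def lookup_tmr(tmr_table: pd.DataFrame, predot: str) -> float:
    """Strict TMR lookup; codes never observed in derivation raise."""
    try:
        return float(tmr_table.loc[predot, "tmr"])
    except KeyError:
        raise DerivationError(f"no TMR for code {predot!r} (not in derivation set)")


# ---------------------------------------------------------------------------
# Component logistic models
# ---------------------------------------------------------------------------


def _logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    return np.log(p / (1 - p))


def comprehensive_covariates(
    patients: Sequence[PatientRecord],
    hospital_levels: Sequence[str] | None = None,
    min_hospital_n: int = 30,
) -> tuple[pd.DataFrame, list[str]]:
    """NBR, ln age, sex, mechanism dummies and hospital fixed effects.

    The largest hospital is the fixed-effect reference; hospitals with fewer
    than ``min_hospital_n`` patients are pooled into ``"other"`` to avoid
    separation.  Returns the design columns and the hospital level order used
    (reference first) so estimation/validation sets can reuse it.
    """
    pt = patient_table(patients)
    X = pd.DataFrame(index=pt.index)
    X["nbr"] = pt["nbr"].astype(float)
    X["ln_age"] = np.log(pt["age"].astype(float))
    X["sex_male"] = (pt["sex"] == "male").astype(float)
    for mech in ("mvc", "violence", "blunt", "stab", "gunshot"):  # ref: low_fall
        X[f"mech_{mech}"] = (pt["mechanism"] == mech).astype(float)
    if hospital_levels is None:
        counts = pt["hospital_id"].value_counts()
        big = counts[counts >= min_hospital_n]
        hospital_levels = list(big.index)  # largest first = reference
        if len(hospital_levels) == 0:
            hospital_levels = [counts.index[0]]
    hosp = pt["hospital_id"].where(
        pt["hospital_id"].isin(hospital_levels), other="other"
    )
    for hid in list(hospital_levels)[1:] + (
        ["other"] if (hosp == "other").any() or "other" in hospital_levels else []
    ):
        if hid == "other" and not (hosp == "other").any():
            continue
        X[f"hosp_{hid}"] = (hosp == hid).astype(float)
    return X, list(hospital_levels)


@dataclass
class ComponentModel:
    """A fitted component logistic model plus the spec of its covariate."""

    component: str
    result: sm.discrete.discrete_model.BinaryResultsWrapper
    columns: list[str]
    hospital_levels: list[str]
    tmr_summary: str = "max-logit"

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    def design(
        self, patients: Sequence[PatientRecord], tmr_table: pd.DataFrame | None
    ) -> pd.DataFrame:
        X = _component_design(
            self.component,
            patients,
            tmr_table,
            hospital_levels=self.hospital_levels,
            tmr_summary=self.tmr_summary,
        )
        return X.reindex(columns=self.columns, fill_value=0.0)

    def predict(
        self, patients: Sequence[PatientRecord], tmr_table: pd.DataFrame | None = None
    ) -> np.ndarray:
        """Predicted death probability; NaN where the covariate is missing."""
        X = self.design(patients, tmr_table)
        keep = ~X.isna().any(axis=1)
        out = np.full(len(X), np.nan)
        if keep.any():
            out[keep.to_numpy()] = self.result.predict(X[keep])
        return out


def _patient_tmr_covariate(
    patients: Sequence[PatientRecord],
    tmr_table: pd.DataFrame,
    summary: str,
    floor: float = TMR_FLOOR,
) -> np.ndarray:
    """Patient-level summary of the TMRs of the carried codes.

    Codes unseen in derivation fall back to the smoothing floor (logged).
    """
    tmr_map = tmr_table["tmr"]
    vals = []
    n_fallback = 0
    for p in patients:
        tmrs = []
        for inj in p.injuries:
            t = tmr_map.get(inj.code.predot)
            if t is None:
                t = floor
                n_fallback += 1
            tmrs.append(t)
        arr = np.asarray(tmrs, dtype=float)
        if summary == "max-logit":
            vals.append(_logit(arr.max()))
        elif summary == "sum-logit":
            vals.append(_logit(arr).sum())
        elif summary == "mean-logit":
            vals.append(_logit(arr).mean())
        else:
            raise RegistryError(f"unknown TMR summary {summary!r}")
    if n_fallback:
        logger.warning("TMR fallback to floor for %d injuries", n_fallback)
    return np.asarray(vals)


def _component_design(
    component: str,
    patients: Sequence[PatientRecord],
    tmr_table: pd.DataFrame | None,
    hospital_levels: Sequence[str] | None = None,
    min_hospital_n: int = 30,
    tmr_summary: str = "max-logit",
) -> pd.DataFrame:
    X, _ = comprehensive_covariates(
        patients, hospital_levels=hospital_levels, min_hospital_n=min_hospital_n
    )
    if component == "tmr":
        if tmr_table is None:
            raise DerivationError("TMR component requires a TMR table")
        X.insert(0, "tmr_score", _patient_tmr_covariate(patients, tmr_table, tmr_summary))
    elif component == "gcs":
        gcs = np.array(
            [np.nan if p.gcs is None else float(p.gcs) for p in patients]
        )
        X.insert(0, "gcs", gcs)
    elif component == "br":
        regions = sorted({inj.code.body_region for p in patients for inj in p.injuries})
        inj = injury_table(patients)
        hit = (
            inj.drop_duplicates(["patient_id", "region"])
            .assign(v=1.0)
            .pivot(index="patient_id", columns="region", values="v")
        )
        pid = [p.patient_id for p in patients]
        hit = hit.reindex(index=pid, columns=regions).fillna(0.0)
        for r in regions:
            X.insert(len(X.columns) - 0, f"br_{r}", hit[r].to_numpy())
    else:
        raise RegistryError(f"unknown component {component!r}")
    X.insert(0, "const", 1.0)
    return X


def fit_component_model(
    component: str,
    patients: Sequence[PatientRecord],
    tmr_table: pd.DataFrame | None = None,
    min_hospital_n: int = 30,
    tmr_summary: str = "max-logit",
) -> ComponentModel:
    """Fit one of the TMR / GCS / BR component logistic models.

    The GCS model is fitted only on patients with an observed GCS.  Raises
    :class:`DerivationError` on an all-one-outcome cohort or non-convergence.
    """
    component = component.lower()
    y = np.array([bool(p.died) for p in patients], dtype=float)
    if y.min() == y.max():
        raise DerivationError("cannot fit a component model: outcome is constant")
    _, hospital_levels = comprehensive_covariates(patients, min_hospital_n=min_hospital_n)
    X = _component_design(
        component,
        patients,
        tmr_table,
        hospital_levels=hospital_levels,
        tmr_summary=tmr_summary,
    )
    keep = ~X.isna().any(axis=1)
    Xf, yf = X[keep], y[keep.to_numpy()]
    if yf.min() == yf.max():
        raise DerivationError(f"{component} component: outcome constant after drops")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yf, Xf).fit(
                disp=0, maxiter=1000, method="lbfgs", pgtol=1e-9, factr=1e2
            )
            if not res.mle_retvals.get("converged", True):
                res = sm.Logit(yf, Xf).fit(
                    disp=0, maxiter=100, method="newton", start_params=res.params
                )
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise DerivationError(f"{component} component failed to fit: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise DerivationError(f"{component} component did not converge")
    if not np.all(np.isfinite(res.params)):
        raise DerivationError(f"{component} component: non-finite coefficients")
    return ComponentModel(
        component=component,
        result=res,
        columns=list(X.columns),
        hospital_levels=hospital_levels,
        tmr_summary=tmr_summary,
    )


# ---------------------------------------------------------------------------
# Blending
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlendWeights:
    """Convex weights over the (TMR, GCS, BR) component predictions."""

    w_tmr: float
    w_gcs: float
    w_br: float

    def __post_init__(self) -> None:
        w = np.array([self.w_tmr, self.w_gcs, self.w_br])
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
            raise RegistryError(f"blend weights must lie on the simplex, got {w}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_tmr, self.w_gcs, self.w_br])


def blend_tdp(
    p_tmr: np.ndarray,
    p_gcs: np.ndarray,
    p_br: np.ndarray,
    weights: BlendWeights,
) -> np.ndarray:
    """Convex blend of component probabilities into the per-patient TDP.

    Where ``p_gcs`` is NaN (missing GCS) the weights are renormalised over
    the TMR and BR components.
    """
    p_tmr = np.asarray(p_tmr, float)
    p_gcs = np.asarray(p_gcs, float)
    p_br = np.asarray(p_br, float)
    w = weights.as_array()
    have_gcs = ~np.isnan(p_gcs)
    out = np.empty_like(p_tmr)
    out[have_gcs] = (
        w[0] * p_tmr[have_gcs] + w[1] * p_gcs[have_gcs] + w[2] * p_br[have_gcs]
    )
    denom = w[0] + w[2]
    if (~have_gcs).any():
        if denom <= 0:
            raise DerivationError(
                "all blend weight on GCS but GCS missing for some patients"
            )
        out[~have_gcs] = (w[0] * p_tmr[~have_gcs] + w[2] * p_br[~have_gcs]) / denom
    return out


def simplex_grid(step: float) -> list[BlendWeights]:
    """All weight triples on the simplex lattice with the given step."""
    if not (0 < step <= 1):
        raise RegistryError("grid step must be in (0, 1]")
    k = int(round(1.0 / step))
    out = []
    for i, j in itertools.product(range(k + 1), repeat=2):
        if i + j <= k:
            out.append(BlendWeights(i / k, j / k, (k - i - j) / k))
    return out


def _rank_auc(pred: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata

    y = y.astype(bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DerivationError("AUC undefined: single-class outcome")
    r = rankdata(pred)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def optimize_blend_weights(
    p_tmr: np.ndarray,
    p_gcs: np.ndarray,
    p_br: np.ndarray,
    died: np.ndarray,
    grid_step: float = 0.05,
    holdout_frac: float = 0.2,
    seed: int = 0,
) -> tuple[BlendWeights, pd.DataFrame]:
    """Exhaustive simplex grid search for the blend weights.

    The objective is the AUC of the blended TDP against death on a seeded
    held-out fold of the derivation set; ties break toward larger ``w_tmr``
    (then larger ``w_gcs``).  Returns the winner and the full grid log.
    """
    candidates = simplex_grid(grid_step)
    if not candidates:
        raise DerivationError("empty blend-weight grid")
    rng = np.random.default_rng(seed)
    n = len(died)
    idx = rng.permutation(n)
    n_hold = max(1, int(round(holdout_frac * n)))
    hold = idx[:n_hold]
    died_h = np.asarray(died, float)[hold]
    rows = []
    any_missing_gcs = bool(np.isnan(p_gcs).any())
    for w in candidates:
        if any_missing_gcs and w.w_tmr + w.w_br == 0:
            continue
        tdp = blend_tdp(p_tmr[hold], p_gcs[hold], p_br[hold], w)
        rows.append((w.w_tmr, w.w_gcs, w.w_br, _rank_auc(tdp, died_h)))
    grid = pd.DataFrame(rows, columns=["w_tmr", "w_gcs", "w_br", "auc"])
    best = grid.sort_values(
        ["auc", "w_tmr", "w_gcs"], ascending=False, kind="mergesort"
    ).iloc[0]
    winner = BlendWeights(best["w_tmr"], best["w_gcs"], best["w_br"])
    logger.info(
        "blend grid (%d candidates): winner %s with holdout AUC %.4f",
        len(grid),
        winner,
        best["auc"],
    )
    return winner, grid


# ---------------------------------------------------------------------------
# WADP aggregation
# ---------------------------------------------------------------------------


def derive_wadp(
    patients: Sequence[PatientRecord],
    tdp: np.ndarray,
    transform: Transform = "neg-log-survival",
    top_k: int = 3,
    top_weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Aggregate per-patient TDPs into the per-code severity dictionary.

    For each predot code, collect the transformed TDP of every derivation
    patient carrying it (once per patient) and average the ``top_k`` largest
    (all of them when fewer).  ``top_weights`` optionally replaces the plain
    mean with a weighted mean over the descending top values.
    """
    if len(tdp) != len(patients):
        raise DerivationError("tdp vector length must match patients")
    h = _transform_fn(transform)
    tdp = np.asarray(tdp, dtype=float)
    if np.isnan(tdp).any():
        raise DerivationError("every derivation patient must have a TDP")
    pid_tdp = dict(zip((p.patient_id for p in patients), h(tdp)))
    inj = injury_table(patients).drop_duplicates(["patient_id", "predot"])
    inj["score"] = inj["patient_id"].map(pid_tdp)
    if top_weights is not None:
        tw = np.asarray(top_weights, dtype=float)
        if len(tw) != top_k or tw.sum() <= 0:
            raise RegistryError("top_weights must have length top_k and positive sum")
    rows = []
    for predot, grp in inj.groupby("predot"):
        scores = np.sort(grp["score"].to_numpy())[::-1]
        top = scores[:top_k]
        if top_weights is None:
            wadp = float(top.mean())
        else:
            w = np.asarray(top_weights, float)[: len(top)]
            wadp = float((top * w).sum() / w.sum())
        rows.append(
            {
                "predot": predot,
                "wadp": wadp,
                "n_support": int(len(grp)),
                "top_tdps": ";".join(f"{v:.6g}" for v in top),
            }
        )
    return pd.DataFrame(rows).set_index("predot")


def derive_wadp_anchored(
    patients: Sequence[PatientRecord],
    tmr_table: pd.DataFrame,
    tmr_component: ComponentModel,
    p_gcs: np.ndarray,
    p_br: np.ndarray,
    weights: BlendWeights,
    transform: Transform = "neg-log-survival",
    top_k: int = 3,
    top_weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """WADP with the TMR covariate anchored at each code's own TMR.

    For a (patient, code) pair the TMR-component prediction is evaluated with
    the code's own TMR substituted for the patient-level TMR summary, while
    the patient's remaining covariates (and the GCS/BR component predictions)
    are kept; the blended score is then aggregated per code as the mean of the
    ``top_k`` largest transformed values.  Unlike the patient-level
    :func:`derive_wadp`, this keeps a minor code's severity value low even
    when some of its carriers die of unrelated co-injuries, which is what lets
    the dictionary span the full lethality range.
    """
    h = _transform_fn(transform)
    X = tmr_component.design(patients, tmr_table)
    lp = X.to_numpy() @ tmr_component.params.to_numpy()
    coef = float(tmr_component.params["tmr_score"])
    rest = lp - coef * X["tmr_score"].to_numpy()
    pid = [p.patient_id for p in patients]
    rest_map = dict(zip(pid, rest))
    gcs_map = dict(zip(pid, np.asarray(p_gcs, float)))
    br_map = dict(zip(pid, np.asarray(p_br, float)))
    inj = injury_table(patients).drop_duplicates(["patient_id", "predot"])
    tmr_c = tmr_table["tmr"].reindex(inj["predot"]).to_numpy(float)
    if np.isnan(tmr_c).any():
        raise DerivationError("injury code missing from the TMR table")
    lp_ic = inj["patient_id"].map(rest_map).to_numpy(float) + coef * _logit(tmr_c)
    p_tmr_ic = 1.0 / (1.0 + np.exp(-lp_ic))
    tdp_ic = blend_tdp(
        p_tmr_ic,
        inj["patient_id"].map(gcs_map).to_numpy(float),
        inj["patient_id"].map(br_map).to_numpy(float),
        weights,
    )
    inj = inj.assign(score=h(tdp_ic))
    if top_weights is not None:
        tw = np.asarray(top_weights, dtype=float)
        if len(tw) != top_k or tw.sum() <= 0:
            raise RegistryError("top_weights must have length top_k and positive sum")
    rows = []
    for predot, grp in inj.groupby("predot"):
        scores = np.sort(grp["score"].to_numpy())[::-1]
        top = scores[:top_k]
        if top_weights is None:
            val = float(top.mean())
        else:
            w = np.asarray(top_weights, float)[: len(top)]
            val = float((top * w).sum() / w.sum())
        rows.append(
            {
                "predot": predot,
                "wadp": val,
                "n_support": int(len(grp)),
                "top_tdps": ";".join(f"{v:.6g}" for v in top),
            }
        )
    return pd.DataFrame(rows).set_index("predot")


# ---------------------------------------------------------------------------
# Severity dictionary container (WADP or MARC)
# ---------------------------------------------------------------------------


class SeverityTable:
    """Code -> severity value dictionary (the WADP table, or a MARC table).

    Lookups for codes absent from the table fall back to the TMR smoothing
    floor pushed through the severity transform, with a warning; this covers
    codes lost to the 60% derivation sample.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        transform: Transform = "neg-log-survival",
        floor: float = TMR_FLOOR,
    ) -> None:
        if "wadp" not in table.columns:
            raise RegistryError("severity table needs a 'wadp' column")
        self.table = table
        self.transform = transform
        self.fallback = float(_transform_fn(transform)(np.array([floor]))[0])
        self._map = table["wadp"].to_dict()
        self._n_fallbacks = 0

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, predot: str) -> bool:
        return predot in self._map

    def lookup(self, predot: str) -> float:
        val = self._map.get(predot)
        if val is None:
            self._n_fallbacks += 1
            logger.warning(
                "code %s absent from severity table; using fallback %.6g",
                predot,
                self.fallback,
            )
            return self.fallback
        return float(val)

    def values_for(self, predots: Sequence[str]) -> np.ndarray:
        return np.array([self.lookup(p) for p in predots])

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SeverityTable":
        df = pd.read_csv(path, dtype={"predot": str}).set_index("predot")
        return cls(df, **kwargs)

    def to_csv(self, path) -> None:
        cols = [
            c
            for c in ("wadp", "n_support", "n_deaths", "tmr", "top_tdps")
            if c in self.table.columns
        ]
        self.table.reset_index()[["predot"] + cols].to_csv(
            path, index=False, float_format="%.10g"
        )


# ---------------------------------------------------------------------------
# Model-style front end
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DerivationConfig:
    """Tunables of the stage-1 derivation."""

    tmr_floor: float = TMR_FLOOR
    transform: Transform = "neg-log-survival"
    anchor: Literal["code", "patient"] = "code"
    top_k: int = 3
    top_weights: tuple[float, ...] | None = None
    grid_step: float = 0.05
    holdout_frac: float = 0.2
    seed: int = 0
    min_hospital_n: int = 30
    tmr_summary: str = "max-logit"


class WADPDeriver:
    """Statsmodels-style front end: build from a derivation cohort, ``fit()``
    to obtain a :class:`WADPDerivationResult` holding the severity dictionary.
    """

    def __init__(
        self,
        patients: Sequence[PatientRecord],
        config: DerivationConfig | None = None,
    ) -> None:
        if len(patients) == 0:
            raise DerivationError("empty derivation set")
        self.patients = list(patients)
        self.config = config or DerivationConfig()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: DerivationConfig | None = None
    ) -> "WADPDeriver":
        from .registry import frame_to_patients

        return cls(frame_to_patients(df), config=config)

    def fit(self) -> "WADPDerivationResult":
        cfg = self.config
        patients = self.patients
        tmr = compute_tmr(patients, floor=cfg.tmr_floor)
        components = {}
        for name in ("tmr", "gcs", "br"):
            try:
                components[name] = fit_component_model(
                    name,
                    patients,
                    tmr_table=tmr,
                    min_hospital_n=cfg.min_hospital_n,
                    tmr_summary=cfg.tmr_summary,
                )
            except DerivationError:
                if name == "gcs":
                    logger.warning("GCS component could not be fitted; skipping")
                    components[name] = None
                else:
                    raise
        p_tmr = components["tmr"].predict(patients, tmr)
        p_br = components["br"].predict(patients)
        if components["gcs"] is not None:
            p_gcs = components["gcs"].predict(patients)
        else:
            p_gcs = np.full(len(patients), np.nan)
        weights, grid = optimize_blend_weights(
            p_tmr,
            p_gcs,
            p_br,
            np.array([bool(p.died) for p in patients], float),
            grid_step=cfg.grid_step,
            holdout_frac=cfg.holdout_frac,
            seed=cfg.seed,
        )
        tdp = blend_tdp(p_tmr, p_gcs, p_br, weights)
        if cfg.anchor == "code":
            wadp = derive_wadp_anchored(
                patients,
                tmr,
                components["tmr"],
                p_gcs,
                p_br,
                weights,
                transform=cfg.transform,
                top_k=cfg.top_k,
                top_weights=cfg.top_weights,
            )
        else:
            wadp = derive_wadp(
                patients,
                tdp,
                transform=cfg.transform,
                top_k=cfg.top_k,
                top_weights=cfg.top_weights,
            )
        wadp = wadp.join(tmr)
        return WADPDerivationResult(
            config=cfg,
            tmr_table=tmr,
            components=components,
            blend_weights=weights,
            blend_grid=grid,
            tdp=pd.DataFrame(
                {
                    "patient_id": [p.patient_id for p in patients],
                    "p_tmr": p_tmr,
                    "p_gcs": p_gcs,
                    "p_br": p_br,
                    "tdp": tdp,
                }
            ),
            wadp_table=wadp,
        )


@dataclass
class WADPDerivationResult:
    """Fitted stage-1 artifacts: TMR table, component models, blend weights,
    per-patient TDPs and the WADP severity dictionary."""

    config: DerivationConfig
    tmr_table: pd.DataFrame
    components: Mapping[str, ComponentModel | None]
    blend_weights: BlendWeights
    blend_grid: pd.DataFrame
    tdp: pd.DataFrame
    wadp_table: pd.DataFrame

    @property
    def severity_table(self) -> SeverityTable:
        return SeverityTable(
            self.wadp_table, transform=self.config.transform, floor=self.config.tmr_floor
        )

    def summary(self) -> str:
        w = self.wadp_table["wadp"]
        lines = [
            "WADP derivation",
            "=" * 48,
            f"derivation patients        {len(self.tdp):>10d}",
            f"codes with WADP            {len(self.wadp_table):>10d}",
            f"WADP range                 {w.min():>10.4f} .. {w.max():.4f}",
            f"blend weights (TMR/GCS/BR) "
            f"{self.blend_weights.w_tmr:.2f}/{self.blend_weights.w_gcs:.2f}/"
            f"{self.blend_weights.w_br:.2f}",
            f"severity transform         {self.config.transform:>10s}",
            f"TMR anchoring              {self.config.anchor:>10s}",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.severity_table.to_csv(path)


__all__ = [
    "TMR_FLOOR",
    "DerivationError",
    "DerivationConfig",
    "BlendWeights",
    "ComponentModel",
    "SeverityTable",
    "WADPDeriver",
    "WADPDerivationResult",
    "compute_tmr",
    "lookup_tmr",
    "fit_component_model",
    "blend_tdp",
    "simplex_grid",
    "optimize_blend_weights",
    "derive_wadp",
    "derive_wadp_anchored",
    "comprehensive_covariates",
]
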