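"""Trauma-registry data model: AIS code parsing, patient records, the exclusion
cascade, train/estimate/validate splitting, and CSV readers/writers.

The registry is a patient-level table where each patient carries one or more
anatomic injuries coded on the Abbreviated Injury Scale (AIS).  An AIS code is
written ``PPPPPP.S``: a six-digit "predot" identifier naming the injury and a
postdot severity integer (1 minor ... 6 unsurvivable, 9 unknown).  The predot
code is the unit for which empirical severity values are later derived; the
postdot severity is used here only for the single-injury-severity-9 exclusion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MECHANISMS = ("low_fall", "mvc", "violence", "blunt", "stab", "gunshot")
SEXES = ("female", "male")
VALID_SEVERITIES = frozenset({1, 2, 3, 4, 5, 6, 9})

#: Default body-region chapter from the first predot digit (standard AIS
#: convention): 1 head, 2 face, 3 neck, 4 thorax, 5 abdomen, 6 spine,
#: 7 upper extremity, 8 lower extremity, 9 external/other.
DEFAULT_REGION_MAP = {str(d): d for d in range(1, 10)}

_AIS_RE = re.compile(r"^(\d{6})\.(\d)$")


class RegistryError(ValueError):
    """Malformed registry input (codes, schema, or configuration)."""


@dataclass(frozen=True)
class AISCode:
    """One AIS code: predot identifier, postdot severity, body region."""

    predot: str
    severity: int
    body_region: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"\d{6}", self.predot):
            raise RegistryError(f"predot must be 6 digits, got {self.predot!r}")
        if self.severity not in VALID_SEVERITIES:
            raise RegistryError(
                f"severity must be one of 1-6 or 9, got {self.severity!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return format_ais_code(self)


@dataclass(frozen=True)
class InjuryRecord:
    """A single coded injury carried by a patient."""

    code: AISCode


@dataclass(frozen=True)
class PatientRecord:
    """One registry patient: demographics, physiology, outcome and injuries.

    ``age``, ``sex``, ``died`` and ``los_days`` may be missing (None) before
    the exclusion cascade runs; ``gcs`` may legitimately remain missing.
    The three boolean flags are supplied by the data source (the synthetic
    generator sets them) because the underlying diagnosis/disposition codes
    are not modelled here.
    """

    patient_id: str
    age: int | None
    sex: str | None
    mechanism: str
    gcs: int | None
    hospital_id: str
    died: bool | None
    los_days: int | None
    injuries: tuple[InjuryRecord, ...]
    nontrauma: bool = False
    dead_on_arrival: bool = False
    transferred: bool = False

    @property
    def n_injuries(self) -> int:
        return len(self.injuries)

    @property
    def nbr(self) -> int:
        """Number of distinct injured body regions."""
        return len({inj.code.body_region for inj in self.injuries})


def parse_ais_code(text: str, region_map: Mapping[str, int] | None = None) -> AISCode:
    """Parse an AIS code string ``"PPPPPP.S"`` into an :class:`AISCode`.

    The body region defaults to the first predot digit; a custom
    ``region_map`` (first digit -> region label) may be supplied, e.g. to
    realise a 12-region scheme.
    """
    if not isinstance(text, str) or not text:
        raise RegistryError(f"AIS code must be a nonempty string, got {text!r}")
    m = _AIS_RE.match(text.strip())
    if m is None:
        raise RegistryError(f"malformed AIS code {text!r}: expected 'PPPPPP.S'")
    predot, sev_txt = m.groups()
    severity = int(sev_txt)
    if severity not in VALID_SEVERITIES:
        raise RegistryError(
            f"malformed AIS code {text!r}: severity {severity} not in 1-6, 9"
        )
    rmap = DEFAULT_REGION_MAP if region_map is None else region_map
    first = predot[0]
    if first not in rmap:
        raise RegistryError(
            f"malformed AIS code {text!r}: no body region for leading digit {first!r}"
        )
    return AISCode(predot=predot, severity=severity, body_region=int(rmap[first]))


def format_ais_code(code: AISCode) -> str:
    """Inverse of :func:`parse_ais_code` over valid codes."""
    return f"{code.predot}.{code.severity}"


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

#: Rule names in cascade order; each excluded patient is attributed to the
#: first rule it violates.
EXCLUSION_RULES = (
    "no_ais_codes",
    "burn_or_nontraumatic",
    "missing_data",
    "single_severity_9",
    "age_out_of_range",
    "dead_on_arrival",
    "transfer_out",
    "low_volume_hospital",
)


@dataclass(frozen=True)
class ExclusionConfig:
    """Configuration of the exclusion cascade.

    ``rules`` lists the rules to apply, in order; unknown names raise.
    ``min_hospital_volume`` is the minimum annual patient count per hospital
    (applied to the cohort surviving all earlier rules).
    """

    rules: tuple[str, ...] = EXCLUSION_RULES
    age_min: int = 1
    age_max: int = 89
    min_hospital_volume: int = 500

    def __post_init__(self) -> None:
        for name in self.rules:
            if name not in EXCLUSION_RULES:
                raise RegistryError(f"unknown exclusion rule {name!r}")


@dataclass(frozen=True)
class ExclusionAudit:
    """Per-rule excluded counts (in rule order), retained count, hospitals."""

    excluded: tuple[tuple[str, int], ...]
    n_retained: int
    n_hospitals: int

    @property
    def n_input(self) -> int:
        return self.n_retained + sum(n for _, n in self.excluded)

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.excluded) + [("retained", self.n_retained)]
        return pd.DataFrame(rows, columns=["rule", "n"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _violates(patient: PatientRecord, rule: str, cfg: ExclusionConfig) -> bool:
    if rule == "no_ais_codes":
        return len(patient.injuries) == 0
    if rule == "burn_or_nontraumatic":
        return patient.nontrauma
    if rule == "missing_data":
        return (
            patient.age is None
            or patient.sex is None
            or patient.los_days is None
            or patient.died is None
        )
    if rule == "single_severity_9":
        return len(patient.injuries) == 1 and patient.injuries[0].code.severity == 9
    if rule == "age_out_of_range":
        return patient.age < cfg.age_min or patient.age > cfg.age_max
    if rule == "dead_on_arrival":
        return patient.dead_on_arrival
    if rule == "transfer_out":
        return patient.transferred
    raise RegistryError(f"unknown exclusion rule {rule!r}")  # pragma: no cover


def apply_exclusions(
    patients: Sequence[PatientRecord],
    config: ExclusionConfig | None = None,
) -> tuple[list[PatientRecord], ExclusionAudit]:
    """Run the exclusion cascade and return (retained patients, audit).

    Rules run in the configured order and each patient is removed by the
    first rule it violates, so the audit counts are mutually exclusive and
    sum (with the retained count) to the input count.  The hospital-volume
    rule is evaluated last on the cohort surviving all record-level rules.
    """
    cfg = config or ExclusionConfig()
    counts: dict[str, int] = {name: 0 for name in cfg.rules}
    surviving: list[PatientRecord] = []
    record_rules = [r for r in cfg.rules if r != "low_volume_hospital"]
    for p in patients:
        hit = next((r for r in record_rules if _violates(p, r, cfg)), None)
        if hit is None:
            surviving.append(p)
        else:
            counts[hit] += 1
    if "low_volume_hospital" in cfg.rules and cfg.min_hospital_volume > 0:
        volume = pd.Series([p.hospital_id for p in surviving]).value_counts()
        keep_hosp = set(volume.index[volume >= cfg.min_hospital_volume])
        retained = [p for p in surviving if p.hospital_id in keep_hosp]
        counts["low_volume_hospital"] = len(surviving) - len(retained)
    else:
        retained = surviving
    audit = ExclusionAudit(
        excluded=tuple((name, counts[name]) for name in cfg.rules),
        n_retained=len(retained),
        n_hospitals=len({p.hospital_id for p in retained}),
    )
    for name, n in audit.excluded:
        if n:
            logger.info("exclusion %s removed %d patients", name, n)
    logger.info(
        "retained %d patients in %d hospitals", audit.n_retained, audit.n_hospitals
    )
    return retained, audit


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------


def split_dataset(
    patients: Sequence[PatientRecord],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    stratify_by_hospital: bool = False,
) -> tuple[list[PatientRecord], list[PatientRecord], list[PatientRecord]]:
    """Partition patients into (derivation, estimation, validation) sets.

    The split is by patient, via a seeded shuffle; with
    ``stratify_by_hospital`` the shuffle-and-cut runs within each hospital so
    split shares are balanced across centres.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise RegistryError(f"split fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)

    def _cut(group: Sequence[PatientRecord]):
        order = rng.permutation(len(group))
        n = len(group)
        n1 = int(round(fractions[0] * n))
        n2 = int(round((fractions[0] + fractions[1]) * n))
        idx = [group[i] for i in order]
        return idx[:n1], idx[n1:n2], idx[n2:]

    if not stratify_by_hospital:
        return _cut(list(patients))
    parts: tuple[list, list, list] = ([], [], [])
    by_hosp: dict[str, list[PatientRecord]] = {}
    for p in patients:
        by_hosp.setdefault(p.hospital_id, []).append(p)
    for hid in sorted(by_hosp):
        for dest, chunk in zip(parts, _cut(by_hosp[hid])):
            dest.extend(chunk)
    return parts


# ---------------------------------------------------------------------------
# CSV I/O and frame conversion
# ---------------------------------------------------------------------------

_INJURY_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "mechanism",
    "gcs",
    "hospital_id",
    "died",
    "los_days",
    "ais_code",
    "nontrauma",
    "dead_on_arrival",
    "transferred",
]


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def patients_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    """One row per injury, the registry CSV layout."""
    rows = []
    for p in patients:
        base = dict(
            patient_id=p.patient_id,
            age="" if p.age is None else p.age,
            sex="" if p.sex is None else p.sex,
            mechanism=p.mechanism,
            gcs="" if p.gcs is None else p.gcs,
            hospital_id=p.hospital_id,
            died="" if p.died is None else int(p.died),
            los_days="" if p.los_days is None else p.los_days,
            nontrauma=int(p.nontrauma),
            dead_on_arrival=int(p.dead_on_arrival),
            transferred=int(p.transferred),
        )
        if p.injuries:
            for inj in p.injuries:
                rows.append({**base, "ais_code": format_ais_code(inj.code)})
        else:
            rows.append({**base, "ais_code": ""})
    return pd.DataFrame(rows, columns=_INJURY_COLUMNS)


def frame_to_patients(
    df: pd.DataFrame, region_map: Mapping[str, int] | None = None
) -> list[PatientRecord]:
    """Assemble PatientRecords from an injury-level or patient-level frame.

    A patient-level variant with a ;-separated ``ais_codes`` column is also
    accepted.
    """
    df = df.copy()
    if "ais_codes" in df.columns and "ais_code" not in df.columns:
        df = df.rename(columns={"ais_codes": "ais_code"})
        df["ais_code"] = df["ais_code"].fillna("")
        df = df.assign(ais_code=df["ais_code"].str.split(";")).explode("ais_code")
    missing = {"patient_id", "mechanism", "hospital_id", "ais_code"} - set(df.columns)
    if missing:
        raise RegistryError(f"registry table missing columns: {sorted(missing)}")
    for col in ("nontrauma", "dead_on_arrival", "transferred"):
        if col not in df.columns:
            df[col] = 0
    patients: list[PatientRecord] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        first = grp.iloc[0]
        codes = [c for c in grp["ais_code"].tolist() if isinstance(c, str) and c]
        injuries = tuple(
            InjuryRecord(parse_ais_code(c, region_map=region_map)) for c in codes
        )
        died = _opt_int(first["died"]) if "died" in grp.columns else None
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                age=_opt_int(first.get("age")),
                sex=first["sex"] if first.get("sex") in SEXES else None,
                mechanism=str(first["mechanism"]),
                gcs=_opt_int(first.get("gcs")),
                hospital_id=str(first["hospital_id"]),
                died=None if died is None else bool(died),
                los_days=_opt_int(first.get("los_days")),
                injuries=injuries,
                nontrauma=bool(int(first["nontrauma"])),
                dead_on_arrival=bool(int(first["dead_on_arrival"])),
                transferred=bool(int(first["transferred"])),
            )
        )
    return patients


def read_registry(path, region_map: Mapping[str, int] | None = None) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"ais_code": str, "ais_codes": str}, keep_default_na=True)
    return frame_to_patients(df, region_map=region_map)


def write_registry(patients: Iterable[PatientRecord], path) -> None:
    patients_to_frame(patients).to_csv(path, index=False)


def injury_table(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flat per-injury frame used by the numeric stages.

    Columns: patient_id, predot, severity, region, died.
    """
    pid, predot, sev, region, died = [], [], [], [], []
    for p in patients:
        for inj in p.injuries:
            pid.append(p.patient_id)
            predot.append(inj.code.predot)
            sev.append(inj.code.severity)
            region.append(inj.code.body_region)
            died.append(bool(p.died))
    return pd.DataFrame(
        {
            "patient_id": pid,
            "predot": predot,
            "severity": sev,
            "region": region,
            "died": died,
        }
    )


def patient_table(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Patient-level frame: demographics, outcome, injury summaries."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age for p in patients],
            "sex": [p.sex for p in patients],
            "mechanism": [p.mechanism for p in patients],
            "gcs": [np.nan if p.gcs is None else p.gcs for p in patients],
            "hospital_id": [p.hospital_id for p in patients],
            "died": [bool(p.died) for p in patients],
            "n_injuries": [p.n_injuries for p in patients],
            "nbr": [p.nbr for p in patients],
        }
    )


__all__ = [
    "AISCode",
    "InjuryRecord",
    "PatientRecord",
    "ExclusionConfig",
    "ExclusionAudit",
    "RegistryError",
    "MECHANISMS",
    "SEXES",
    "DEFAULT_REGION_MAP",
    "EXCLUSION_RULES",
    "parse_ais_code",
    "format_ais_code",
    "apply_exclusions",
    "split_dataset",
    "read_registry",
    "write_registry",
    "patients_to_frame",
    "frame_to_patients",
    "injury_table",
    "patient_table",
]
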