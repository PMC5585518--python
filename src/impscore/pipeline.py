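"""End-to-end orchestration: registry (real or simulated) -> exclusions ->
60/20/20 split -> severity derivation -> model fitting -> evaluation.

Every run writes its artifacts (severity dictionary, model files, comparison
report, exclusion audit, config snapshot, log) into one output directory and
stamps them with a hash of the resolved configuration, so a rerun with the
same configuration reproduces identical files.

The three splits are kept strictly separate: the WADP dictionary sees only
the 60% derivation set, coefficients are estimated on the 20% estimation set,
and all performance statistics are computed on the untouched 20% validation
set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import evaluation, models, registry, simulate, wadp

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "impscore_run"
    registry_path: str | None = None  # when None, simulate
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    exclusions: dict = field(default_factory=dict)  # ExclusionConfig overrides
    derivation: dict = field(default_factory=dict)  # DerivationConfig overrides
    model_kinds: tuple[str, ...] = ("imp", "swi")
    marc_path: str | None = None  # enables the TMPM comparator
    augmented: bool = True  # also fit +age/sex/mechanism variants
    n_boot: int = 1000
    boot_seed: int = 0
    hl_groups: int = 10
    calibration_bins: int = 20
    make_plot: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        d["model_kinds"] = list(self.model_kinds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        if "model_kinds" in d:
            d["model_kinds"] = tuple(d["model_kinds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a manifest of the written artifacts."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("impscore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "config"
    try:
        cfg.to_yaml(out / "config_snapshot.yaml")
        manifest = {"config_hash": cfg.config_hash, "out_dir": str(out)}

        stage = "load"
        if cfg.registry_path is not None:
            path = Path(cfg.registry_path)
            if not path.exists():
                raise PipelineError(f"registry file not found: {path}")
            patients = registry.read_registry(path)
        else:
            gen_cfg = simulate.GeneratorConfig(**cfg.simulate)
            patients, _truth = simulate.generate_registry(gen_cfg)

        stage = "exclusions"
        excl_cfg = registry.ExclusionConfig(**cfg.exclusions)
        patients, audit = registry.apply_exclusions(patients, excl_cfg)
        audit.to_csv(out / "exclusion_audit.csv")
        manifest["n_patients"] = audit.n_retained

        stage = "split"
        derivation, estimation, validation = registry.split_dataset(
            patients, fractions=cfg.fractions, seed=cfg.split_seed
        )

        stage = "derive-wadp"
        deriver = wadp.WADPDeriver(
            derivation, config=wadp.DerivationConfig(**cfg.derivation)
        )
        derived = deriver.fit()
        derived.to_csv(out / "wadp.csv")
        table = derived.severity_table
        manifest["wadp_csv"] = str(out / "wadp.csv")
        logger.info("%s", derived.summary())

        stage = "fit"
        marc = (
            wadp.SeverityTable.from_csv(cfg.marc_path)
            if cfg.marc_path is not None
            else None
        )
        fitted: dict[str, tuple[models.MortalityResults, wadp.SeverityTable]] = {}
        for kind in cfg.model_kinds:
            tab = marc if kind == "tmpm" else table
            if tab is None:
                raise PipelineError("tmpm model requested without a MARC table")
            variants = [(kind.upper(), False)]
            if cfg.augmented:
                variants.append((f"{kind.upper()}+demog", True))
            for name, aug in variants:
                res = models.MortalityModel.from_patients(
                    estimation, tab, kind=kind, augment=aug
                ).fit()
                res.to_json(out / f"model_{name.replace('+', '_')}.json")
                fitted[name] = (res, tab)

        stage = "evaluate"
        reports = evaluation.compare_models(
            validation,
            fitted,
            n_boot=cfg.n_boot,
            seed=cfg.boot_seed,
            hl_groups=cfg.hl_groups,
            calibration_bins=cfg.calibration_bins,
        )
        frame = evaluation.report_frame(reports)
        frame.to_csv(out / "report.csv", index=False, float_format="%.10g")
        payload = {
            "config_hash": cfg.config_hash,
            "n_validation": len(validation),
            "models": evaluation.report_json(reports),
        }
        (out / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        if cfg.make_plot:
            evaluation.plot_calibration(reports, out / "calibration.png")
        manifest["report_json"] = str(out / "report.json")
        manifest["report_csv"] = str(out / "report.csv")
        manifest["models"] = sorted(fitted)
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        logger.exception("stage %s failed", stage)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        handler.close()
        root.removeHandler(handler)


__all__ = ["RunConfig", "PipelineError", "run_pipeline"]
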