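"""Run configuration and the end-to-end evaluation workflow.

A :class:`RunConfig` (YAML-serializable) fully determines a run:
synthesize or load experiments, fit the candidate models, write
self-reproducibility and extrapolability WFI tables, the
model-comparison ranking and the pathway rate-ratio table.  Reruns with
the same config and seed reproduce identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .error_model import AssumedErrorTable, ErrorModelParams, calibrate
from .fitting import FitSpec, compare_models, extrapolability_check, self_reproducibility
from .reaction_network import BUILTIN_MODELS
from .simulator import (
    Conditions,
    Experiment,
    pathway_rates_at,
    simulate,
    write_timecourses,
)
from .synthetic_data import NoiseSpec, make_study, read_study, write_study

__all__ = ["RunConfig", "run_workflow"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full evaluation run.

    ``data_dir`` may be None, in which case a synthetic study is
    generated with ``seed``.  Yields in all files are on the percent
    scale; the library converts at the boundary.
    """

    models: list[str] = field(default_factory=lambda: ["borderline", "sn1", "sn2"])
    data_dir: str | None = None
    out_dir: str = "kinwfi_out"
    objective: str = "wls"
    seed: int = 0
    n_starts: int = 8
    error_params: dict = field(
        default_factory=lambda: {"a": 1.0, "b": -9.0, "k": -10.0, "floor": 0.005}
    )
    assumed_error_table: str | None = None  # CSV path; calibrated if given
    ratio_temps_C: list[float] = field(
        default_factory=lambda: [float(t) for t in range(0, 81, 5)]
    )
    ratio_time_min: float = 10.0
    ratio_bnbr_eq: float = 1.1
    ratio_aniline_0: float = 0.344

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(BUILTIN_MODELS)
        if unknown:
            raise ValueError(
                f"unknown model(s) {sorted(unknown)}; built-ins: {sorted(BUILTIN_MODELS)}"
            )

    def resolve_error_params(self) -> ErrorModelParams:
        if self.assumed_error_table:
            table = AssumedErrorTable.from_csv(self.assumed_error_table)
            result = calibrate(table, floor=self.error_params.get("floor", 0.005))
            logger.info("calibrated error curve: a=%.4g b=%.4g k=%.4g",
                        result.params.a, result.params.b, result.params.k)
            return result.params
        return ErrorModelParams(**self.error_params)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


def _load_experiments(config: RunConfig) -> tuple[list[Experiment], list[Experiment]]:
    if config.data_dir is None:
        logger.info("no data_dir given: generating the default synthetic study (seed=%d)",
                    config.seed)
        study = make_study(noise=NoiseSpec(seed=config.seed))
        return study.training, study.extrapolation
    experiments, _ = read_study(config.data_dir)
    training = [e for e in experiments if e.role == "training"]
    held_out = [e for e in experiments if e.role == "extrapolation"]
    if not training:
        raise ValueError(f"no training experiments found in {config.data_dir}")
    return training, held_out


def run_workflow(config: RunConfig) -> dict[str, Path]:
    """Execute synthesize/load -> fit -> evaluate -> compare -> ratio.

    Returns a name -> path map of the written artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    error_params = config.resolve_error_params()
    training, held_out = _load_experiments(config)
    logger.info(
        "workflow: %d training + %d held-out experiments; models %s; "
        "floor=%.4g; t=0 points excluded from WFI",
        len(training), len(held_out), config.models, error_params.floor,
    )

    artifacts: dict[str, Path] = {}
    if config.data_dir is None:
        study_dir = out / "synthetic_study"
        write_study(make_study(noise=NoiseSpec(seed=config.seed)), study_dir)
        artifacts["synthetic_study"] = study_dir

    specs = [
        FitSpec(
            model_name=name,
            experiments=training,
            error_params=error_params,
            objective=config.objective,
            n_starts=config.n_starts,
            seed=config.seed,
        )
        for name in config.models
    ]
    table, results = compare_models(specs, held_out=held_out or None)

    params_doc = {}
    for name, res in results.items():
        params_doc[name] = {
            "objective": res.objective_value,
            "success": res.success,
            "message": res.message,
            "param_hash": res.param_hash,
            "params": {
                label: {"k_ref_298K": p.k_ref(), "Ea_J_per_mol": p.Ea}
                for label, p in res.params.items()
            },
        }
        self_rep = self_reproducibility(res)
        p = out / f"wfi_self_{name}.csv"
        self_rep.to_csv(p)
        artifacts[f"wfi_self_{name}"] = p
        if held_out:
            extrap = extrapolability_check(res, held_out)
            p = out / f"wfi_extrapolation_{name}.csv"
            extrap.to_csv(p)
            artifacts[f"wfi_extrapolation_{name}"] = p
        sims = {
            e.id: simulate(res.model, e.conditions, e.observed.times_min)
            for e in (*training, *held_out)
        }
        p = out / f"simulated_{name}.csv"
        write_timecourses(sims, p)
        artifacts[f"simulated_{name}"] = p

    p = out / "fitted_params.json"
    p.write_text(json.dumps(params_doc, indent=2) + "\n")
    artifacts["fitted_params"] = p

    p = out / "model_comparison.csv"
    table.to_csv(p)
    artifacts["model_comparison"] = p

    if "borderline" in results:
        res = results["borderline"]
        rows = []
        for T_C in config.ratio_temps_C:
            cond = Conditions(
                initial_concentrations={
                    "1": config.ratio_aniline_0,
                    "BnBr": config.ratio_aniline_0 * config.ratio_bnbr_eq,
                },
                temperature_C=float(T_C),
                duration_min=max(config.ratio_time_min, 1.0),
            )
            pr = pathway_rates_at(res.model, cond, t_min=config.ratio_time_min)
            rows.append(
                {
                    "temp_C": T_C,
                    "sn1_rate_M_per_s": pr.sn1_rate,
                    "sn2_rate_M_per_s": pr.sn2_rate,
                    "sn1_over_sn2": pr.ratio,
                }
            )
        p = out / "pathway_ratio.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        artifacts["pathway_ratio"] = p

    cfg_path = out / "run_config.yaml"
    cfg_path.write_text(config.to_yaml())
    artifacts["run_config"] = cfg_path
    return artifacts
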