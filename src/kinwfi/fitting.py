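"""Multi-experiment parameter estimation and model evaluation.

Kinetic parameters are estimated by bounded trust-region least squares
on band-weighted residuals ``(Y_s - Y_e) / w`` pooled across species and
experiments, with deterministic multi-starts (a data-driven initial
guess, the box center, and an unscrambled Sobol grid).  Each step is
parameterized as ``(log10 k at 298.15 K, Ea)`` rather than ``(A, Ea)``
to decorrelate the search directions; in the ionization branch the fast
mono-capture constant is fixed and only the di/mono capture ratio is
free (the only identifiable direction when capture is fast).

Model evaluation follows the two-stage validity check: a
self-reproducibility WFI table on the training experiments, and an
extrapolability WFI table on held-out conditions predicted with *no*
refitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .error_model import (
    DEFAULT_ERROR_PARAMS,
    ErrorModelParams,
    WFIReport,
    band_half_width,
    wfi_report,
)
from .reaction_network import (
    CAPTURE_RATE_FIXED,
    ArrheniusParams,
    KineticModel,
    builtin_model,
)
from .simulator import Experiment, SimulationError, TimeCourse, simulate

__all__ = [
    "FreeParam",
    "FitSpec",
    "FitResult",
    "IdentifiabilityError",
    "default_free_params",
    "fit",
    "self_reproducibility",
    "extrapolability_check",
    "compare_models",
]

logger = logging.getLogger(__name__)


class IdentifiabilityError(ValueError):
    """The requested free parameters cannot be determined from the data."""


@dataclass(frozen=True)
class FreeParam:
    """One coordinate of the fit vector.

    ``kind`` is ``log10_kref`` (decadic log of k at 298.15 K),
    ``Ea_kJ`` (activation energy in kJ/mol) or ``log10_capture_ratio``
    (di/mono cation-capture ratio, step-independent).
    """

    name: str
    kind: str
    step: str | None
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in ("log10_kref", "Ea_kJ", "log10_capture_ratio"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if not self.lo < self.hi:
            raise ValueError(f"empty bounds for {self.name}")


def _rate_free(step: str) -> list[FreeParam]:
    return [
        FreeParam(f"{step}.log10_kref", "log10_kref", step, -8.0, 2.0),
        FreeParam(f"{step}.Ea_kJ", "Ea_kJ", step, 0.0, 200.0),
    ]


def default_free_params(model_name: str) -> list[FreeParam]:
    """The identifiable free-parameter set for each built-in model."""
    if model_name == "sn2":
        return _rate_free("sn2_mono") + _rate_free("sn2_di")
    if model_name == "sn1":
        return _rate_free("ionization") + [
            FreeParam("capture_ratio.log10", "log10_capture_ratio", None, -2.0, 2.0)
        ]
    if model_name == "borderline":
        return default_free_params("sn2") + default_free_params("sn1")
    raise ValueError(f"no default parameterization for model {model_name!r}")


def params_from_vector(
    model_name: str, x: np.ndarray, free: list[FreeParam]
) -> dict[str, ArrheniusParams]:
    """Decode a fit vector into per-step Arrhenius parameters.

    Capture steps get the fixed fast mono-capture constant scaled by the
    fitted ratio, with Ea = 0 (barrierless capture).
    """
    by_step: dict[str, dict[str, float]] = {}
    ratio = None
    for p, v in zip(free, x):
        if p.kind == "log10_capture_ratio":
            ratio = 10.0**v
        else:
            by_step.setdefault(p.step, {})[p.kind] = float(v)
    out: dict[str, ArrheniusParams] = {}
    for step, vals in by_step.items():
        if "log10_kref" not in vals:
            raise ValueError(f"step {step!r}: Ea free but k_ref not — unsupported")
        out[step] = ArrheniusParams.from_kref(
            10.0 ** vals["log10_kref"], vals.get("Ea_kJ", 0.0) * 1e3
        )
    if model_name in ("sn1", "borderline"):
        out["capture_mono"] = ArrheniusParams.from_kref(CAPTURE_RATE_FIXED, 0.0)
        out["capture_di"] = ArrheniusParams.from_kref(
            CAPTURE_RATE_FIXED * (ratio if ratio is not None else 1.0), 0.0
        )
    return out


@dataclass
class FitSpec:
    """What to fit: model, data, objective and optimizer settings.

    ``objective`` is ``wls`` (weighted least squares on band-scaled
    residuals) or ``wfi`` (same residual engine; the reported objective
    is the pooled mean absolute band ratio, i.e. the WFI itself).
    """

    model_name: str
    experiments: list[Experiment]
    error_params: ErrorModelParams = DEFAULT_ERROR_PARAMS
    objective: str = "wls"
    free: list[FreeParam] | None = None
    n_starts: int = 8
    seed: int = 0
    fit_rtol: float = 1e-7
    fit_atol: float = 1e-9
    exclude_t0: bool = True

    def __post_init__(self) -> None:
        if self.objective not in ("wls", "wfi"):
            raise ValueError(f"objective must be wls|wfi, got {self.objective!r}")
        if not self.experiments:
            raise ValueError("training set is empty")
        if self.free is None:
            self.free = default_free_params(self.model_name)
        if not self.free:
            raise ValueError("at least one free parameter required")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        self._check_identifiability()

    def _check_identifiability(self) -> None:
        if any(p.kind == "Ea_kJ" for p in self.free):
            temps = set()
            for e in self.experiments:
                tc = e.conditions.temperature_C
                temps.add(round(float(tc), 6) if np.isscalar(tc) else tuple(tc))
            if len(temps) < 2:
                raise IdentifiabilityError(
                    "activation energies are free but all experiments share one "
                    "temperature; include >= 2 distinct temperatures or fix Ea"
                )


@dataclass
class FitResult:
    """Best-fit parameters plus multi-start and residual diagnostics."""

    spec: FitSpec
    x: np.ndarray
    params: dict[str, ArrheniusParams]
    model: KineticModel
    objective_value: float
    cost: float  # 0.5 * sum of squared weighted residuals at the optimum
    starts: pd.DataFrame
    residuals: dict[str, np.ndarray]
    success: bool
    message: str
    param_hash: str = field(init=False)

    def __post_init__(self) -> None:
        doc = {
            label: (round(p.A, 12), round(p.Ea, 6))
            for label, p in sorted(self.params.items())
        }
        self.param_hash = hashlib.sha256(json.dumps(doc).encode()).hexdigest()

    def params_summary(self) -> pd.DataFrame:
        rows = [
            {
                "step": label,
                "k_ref_298K": p.k_ref(),
                "Ea_kJ_per_mol": p.Ea / 1e3,
                "A": p.A,
            }
            for label, p in self.params.items()
        ]
        return pd.DataFrame(rows).set_index("step")


# ---------------------------------------------------------------------------
# Residuals and starts
# ---------------------------------------------------------------------------


def _residual_points(
    model: KineticModel, exp: Experiment, error_params, exclude_t0, rtol, atol
) -> np.ndarray:
    """Band-scaled residuals (Ys - Ye)/w for one experiment, all species."""
    obs = exp.observed
    keep = obs.times_min > 0 if exclude_t0 else np.ones(obs.n_points, bool)
    sim_tc = simulate(model, exp.conditions, obs.times_min[keep], rtol=rtol, atol=atol)
    res = []
    for sp in model.observable_names:
        if sp not in obs.yields:
            continue
        ys = sim_tc.yields[sp]
        ye = obs.yields[sp][keep]
        w = band_half_width(ys, error_params)
        res.append((ys - ye) / w)
    if not res:
        raise ValueError(f"experiment {exp.id!r} shares no observable species with the model")
    return np.concatenate(res)


def _stacked_residuals(spec: FitSpec, x: np.ndarray) -> np.ndarray:
    params = params_from_vector(spec.model_name, x, spec.free)
    model = builtin_model(spec.model_name, params)
    out = []
    for exp in spec.experiments:
        try:
            out.append(
                _residual_points(
                    model, exp, spec.error_params, spec.exclude_t0,
                    spec.fit_rtol, spec.fit_atol,
                )
            )
        except SimulationError:
            # Penalize pathological parameter regions instead of aborting
            # the whole optimization run.
            n = sum(
                (exp.observed.times_min > 0).sum() if spec.exclude_t0 else exp.observed.n_points
                for _ in exp.observed.species
            )
            out.append(np.full(max(n, 1), 1e6))
    return np.concatenate(out)


def _flux_scale_guess(spec: FitSpec) -> tuple[float, float, float] | None:
    """Crude overall flux scale from early substrate consumption.

    The earliest positive-time yield of species ``1`` in each experiment
    gives a pseudo-second-order effective constant; an Arrhenius line
    through those estimates sets the decade of k(298 K), an effective
    Ea, and the typical substrate concentration.  Returns
    ``(k2_298, Ea_kJ, a0_mean)`` or None when the data lack species 1.
    """
    logks, inv_T, a0s = [], [], []
    for e in spec.experiments:
        obs = e.observed
        if "1" not in obs.yields:
            return None
        pos = obs.times_min > 0
        if not pos.any():
            return None
        i = int(np.argmax(pos))
        t_sec = obs.times_min[i] * 60.0
        a0 = e.conditions.initial_concentrations.get("1", 0.0)
        bnbr0 = e.conditions.initial_concentrations.get("BnBr", a0)
        frac_left = float(np.clip(obs.yields["1"][i], 1e-6, 1.0 - 1e-3))
        # pseudo-first-order decay of 1 at ~constant [BnBr]
        k_eff = -math.log(frac_left) / t_sec / max(bnbr0, 1e-12)
        logks.append(math.log(k_eff))
        inv_T.append(1.0 / float(e.conditions.temperature_K(0.0)))
        a0s.append(a0)
    if len(logks) >= 2 and (max(inv_T) - min(inv_T)) > 1e-9:
        slope, _ = np.polyfit(inv_T, logks, 1)
        Ea_kJ = float(np.clip(-slope * 8.314 / 1e3, 5.0, 195.0))
    else:
        Ea_kJ = 60.0
    k298 = math.exp(
        float(np.mean(logks)) + (float(np.mean(inv_T)) - 1 / 298.15) * (-Ea_kJ * 1e3 / 8.314)
    )
    return k298, Ea_kJ, float(np.mean(a0s))


def _data_driven_starts(spec: FitSpec) -> list[np.ndarray]:
    """Starts that allocate the observed flux differently between branches.

    The dominant ambiguity in a two-branch model is how the total flux
    splits between them, so one start assumes a balanced split and two
    assume either branch dominates.  Ionization constants are scaled by
    the substrate concentration to account for their different units
    (1/s vs L/(mol s)).
    """
    scale = _flux_scale_guess(spec)
    if scale is None:
        return []
    k298, Ea_kJ, a0 = scale
    starts = []
    for frac_sn1 in (0.5, 0.9, 0.1):
        x0 = []
        for p in spec.free:
            if p.kind == "log10_kref":
                if p.step == "ionization":
                    guess = k298 * frac_sn1 * max(a0, 1e-12)
                elif p.step == "sn2_di":
                    guess = k298 * (1.0 - frac_sn1) / 2.0
                else:
                    guess = k298 * (1.0 - frac_sn1)
                x0.append(float(np.clip(math.log10(max(guess, 1e-12)),
                                        p.lo + 0.01, p.hi - 0.01)))
            elif p.kind == "Ea_kJ":
                x0.append(float(np.clip(Ea_kJ, p.lo + 1.0, p.hi - 1.0)))
            else:  # capture ratio
                x0.append(0.0)
        starts.append(np.asarray(x0))
    return starts


def _starting_points(spec: FitSpec) -> list[np.ndarray]:
    lo = np.array([p.lo for p in spec.free])
    hi = np.array([p.hi for p in spec.free])
    data_starts = _data_driven_starts(spec)
    # order: balanced data-driven guess, box center, branch-heavy guesses
    starts = data_starts[:1] + [(lo + hi) / 2.0] + data_starts[1:]
    n_extra = max(spec.n_starts - len(starts), 0)
    if n_extra:
        sob = qmc.Sobol(d=len(spec.free), scramble=False)
        # drop the all-zero corner and the box center (already a start)
        pts = sob.random(max(8, n_extra + 2))[2:]
        starts.extend(lo + p * (hi - lo) for p in pts[:n_extra])
    return starts[: spec.n_starts]


# ---------------------------------------------------------------------------
# Fit and evaluation
# ---------------------------------------------------------------------------


def _pooled_wfi(spec: FitSpec, x: np.ndarray) -> float:
    r = _stacked_residuals(spec, x)
    return float(np.mean(np.abs(r)))


def fit(spec: FitSpec) -> FitResult:
    """Estimate the free parameters jointly over all training experiments.

    Deterministic for a given spec and seed.  The best start's optimum is
    returned; all starts are tabulated in ``FitResult.starts``.
    """
    lo = np.array([p.lo for p in spec.free])
    hi = np.array([p.hi for p in spec.free])
    x_scale = np.array(
        [50.0 if p.kind == "Ea_kJ" else 1.0 for p in spec.free]
    )
    rows, best = [], None
    for i, x0 in enumerate(_starting_points(spec)):
        sol = least_squares(
            lambda x: _stacked_residuals(spec, x),
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            x_scale=x_scale,
            # FD step large enough that residual changes dominate the
            # ODE-integration error; the default sqrt(eps) step gives
            # noise-corrupted gradients and premature trust-region collapse
            diff_step=1e-4,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-10,
        )
        obj = (
            float(2.0 * sol.cost)
            if spec.objective == "wls"
            else _pooled_wfi(spec, sol.x)
        )
        logger.info(
            "start %d/%d: objective=%.6g success=%s nfev=%d",
            i + 1, spec.n_starts, obj, sol.success, sol.nfev,
        )
        rows.append(
            {"start": i, "objective": obj, "success": bool(sol.success), "nfev": sol.nfev,
             **{p.name: float(v) for p, v in zip(spec.free, sol.x)}}
        )
        if best is None or obj < best[0]:
            best = (obj, sol)
    obj, sol = best
    params = params_from_vector(spec.model_name, sol.x, spec.free)
    model = builtin_model(spec.model_name, params)
    residuals = {
        e.id: _residual_points(
            model, e, spec.error_params, spec.exclude_t0, spec.fit_rtol, spec.fit_atol
        )
        for e in spec.experiments
    }
    active = np.isclose(sol.x, lo, atol=1e-9) | np.isclose(sol.x, hi, atol=1e-9)
    message = sol.message
    if active.any():
        names = [p.name for p, a in zip(spec.free, active) if a]
        message += f"; active bounds: {names}"
        logger.warning("fit finished on bounds: %s", names)
    return FitResult(
        spec=spec,
        x=sol.x,
        params=params,
        model=model,
        objective_value=obj,
        cost=float(sol.cost),
        starts=pd.DataFrame(rows),
        residuals=residuals,
        success=bool(sol.success),
        message=message,
    )


def _simulate_at_observed(
    result: FitResult, experiments: list[Experiment], rtol=1e-8, atol=1e-10
) -> tuple[dict[str, TimeCourse], dict[str, TimeCourse]]:
    sims, obs = {}, {}
    for e in experiments:
        sims[e.id] = simulate(result.model, e.conditions, e.observed.times_min,
                              rtol=rtol, atol=atol)
        obs[e.id] = e.observed
    return sims, obs


def self_reproducibility(result: FitResult) -> WFIReport:
    """WFI table of the fitted model against its own training experiments."""
    sims, obs = _simulate_at_observed(result, result.spec.experiments)
    return wfi_report(
        sims, obs, result.spec.error_params,
        species=result.model.observable_names,
        exclude_t0=result.spec.exclude_t0,
    )


def extrapolability_check(result: FitResult, held_out: list[Experiment]) -> WFIReport:
    """WFI table on held-out conditions, predicted with no refitting.

    The parameter hash is checked before and after prediction to assert
    the no-refit guarantee.
    """
    hash_before = result.param_hash
    sims, obs = _simulate_at_observed(result, held_out)
    report = wfi_report(
        sims, obs, result.spec.error_params,
        species=result.model.observable_names,
        exclude_t0=result.spec.exclude_t0,
    )
    assert result.param_hash == hash_before, "parameters changed during extrapolation"
    return report


def compare_models(
    candidates: list[FitSpec],
    held_out: list[Experiment] | None = None,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit each candidate and rank by pooled self-reproducibility WFI.

    Returns the comparison table (one row per candidate; training and
    extrapolation pooled average WFI; convergence flag) and the fit
    results keyed by model name.  Non-converged candidates keep their
    row but are excluded from the ranking.
    """
    rows, results = [], {}
    for spec in candidates:
        res = fit(spec)
        results[spec.model_name] = res
        train = self_reproducibility(res)
        row = {
            "model": spec.model_name,
            "converged": res.success,
            "train_wfi": train.pooled_average,
            "objective": res.objective_value,
        }
        if held_out:
            row["extrap_wfi"] = extrapolability_check(res, held_out).pooled_average
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")
    ranked = table[table["converged"]].sort_values("train_wfi")
    table["rank"] = pd.Series(
        range(1, len(ranked) + 1), index=ranked.index, dtype="float"
    )
    return table.sort_values("rank"), results
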