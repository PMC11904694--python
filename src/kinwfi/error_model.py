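"""Simulation-centered weighted error band and the weighted fitting index.

Experimental conversion yields carry a relative error that is large at
low conversion (data noise dominates small peaks) and settles to a
plateau at high conversion.  That decay is described by a Stirling-type
exponential-decay curve

    f(x) = a + (b/k) * (exp(k x) - 1),        b < 0, k < 0,

which starts at ``f(0) = a`` and converges to the plateau ``a - b/k``.
Applying ``f`` to each *simulated* yield defines a continuous error band
centered on the simulation curve; the weighted fitting index (WFI) of an
experimental series is the mean, over data points, of the absolute
simulated-vs-experimental deviation divided by the band half-width:

    WFI = (1/n) * sum_i |Y_s,i - Y_e,i| / w_i,
    w_i = max(f(Y_s,i) * Y_s,i, floor).

WFI < 1 means the average distance stays within the weighted range.
Centering the band on the simulation (not on the data) makes the index
a test of the model's curve shape rather than of the data's scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulator import TimeCourse

__all__ = [
    "ErrorModelParams",
    "AssumedErrorTable",
    "CalibrationResult",
    "CalibrationWarning",
    "WFIReport",
    "stirling_error",
    "calibrate",
    "error_band",
    "band_half_width",
    "absolute_error",
    "wfi",
    "wfi_report",
    "DEFAULT_ERROR_PARAMS",
]


@dataclass(frozen=True)
class ErrorModelParams:
    """Parameters of the weighted relative-error curve.

    ``a`` is the relative error at zero conversion, ``b`` the initial
    decay slope, ``k`` the exponential decay rate (both negative), all
    on the fraction scale.  ``floor`` is the minimum absolute band
    half-width in yield fraction (an analytical limit-of-quantitation
    allowance; it also removes the divide-by-zero at zero simulated
    yield).
    """

    a: float
    b: float
    k: float
    floor: float = 0.005

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.b > 0 or self.k > 0:
            raise ValueError(f"b and k must be <= 0, got b={self.b}, k={self.k}")
        if not self.floor > 0:
            raise ValueError(f"floor must be > 0, got {self.floor}")
        if self.plateau <= 0:
            raise ValueError(
                f"plateau a - b/k = {self.plateau:g} must stay positive "
                f"(relative error never vanishes)"
            )

    @property
    def plateau(self) -> float:
        """Limiting relative error at full conversion, ``a - b/k``."""
        if self.k == 0:
            return float("inf") if self.b < 0 else self.a
        return self.a - self.b / self.k


#: Reference curve: 100% relative error at zero conversion decaying to a
#: 10% plateau (a=1, b=-9, k=-10 on the fraction scale).
DEFAULT_ERROR_PARAMS = ErrorModelParams(a=1.0, b=-9.0, k=-10.0)


def stirling_error(x, params: ErrorModelParams):
    """Relative-error fraction at simulated yield ``x`` (fraction scale).

    The ``k == 0`` degenerate case uses the analytic limit
    ``f(x) = a + b x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("yield fraction must be >= 0")
    if params.k == 0.0:
        out = params.a + params.b * x
    else:
        out = params.a + (params.b / params.k) * (np.exp(params.k * x) - 1.0)
    return out if out.ndim else float(out)


def band_half_width(Ys, params: ErrorModelParams):
    """Absolute half-width of the weighted band at simulated yield ``Ys``.

    ``w = max(f(Ys) * Ys, floor)`` in yield-fraction units.
    """
    Ys = np.asarray(Ys, dtype=float)
    w = np.maximum(stirling_error(Ys, params) * Ys, params.floor)
    return w if w.ndim else float(w)


def error_band(Ys, params: ErrorModelParams):
    """Weighted error band ``(lower, upper)`` centered on the simulated yield.

    The lower edge is clipped at zero (yields cannot be negative).
    """
    Ys = np.asarray(Ys, dtype=float)
    w = band_half_width(Ys, params)
    lower = np.clip(Ys - w, 0.0, None)
    upper = Ys + w
    if np.ndim(Ys) == 0:
        return float(lower), float(upper)
    return lower, upper


def absolute_error(Ys, Ye):
    """Absolute deviation ``|Ys - Ye|`` between simulated and experimental yield."""
    out = np.abs(np.asarray(Ys, dtype=float) - np.asarray(Ye, dtype=float))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Calibration from an assumed-error table
# ---------------------------------------------------------------------------


class CalibrationWarning(UserWarning):
    pass


@dataclass
class AssumedErrorTable:
    """Assumed relative error at a handful of reaction stages.

    Rows pair a simulated yield fraction ``x`` in [0, 1] (strictly
    increasing) with the relative error fraction assumed there.
    """

    x: np.ndarray
    rel_error: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rel_error = np.asarray(self.rel_error, dtype=float)
        if self.x.shape != self.rel_error.shape or self.x.ndim != 1:
            raise ValueError("x and rel_error must be 1-D arrays of equal length")
        if np.any(self.x < 0) or np.any(self.x > 1):
            raise ValueError("yield fractions must lie in [0, 1]")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("yield fractions must be strictly increasing")
        if np.any(self.rel_error <= 0) or np.any(self.rel_error > 1.5):
            raise ValueError("relative errors must lie in (0, 1.5]")

    @classmethod
    def reference(cls) -> "AssumedErrorTable":
        """The illustrative stage table: 100% error at x=0 decaying to 10%."""
        return cls(
            x=np.array([0.0, 0.1, 0.3, 0.5, 1.0]),
            rel_error=np.array([1.0, 0.5, 0.15, 0.1, 0.1]),
        )

    @classmethod
    def from_csv(cls, path) -> "AssumedErrorTable":
        """Read a two-column CSV (yield_pct, rel_error_pct), percent scale."""
        df = pd.read_csv(path)
        missing = {"yield_pct", "rel_error_pct"} - set(df.columns)
        if missing:
            raise ValueError(f"assumed-error CSV {path} lacks columns {sorted(missing)}")
        df = df.sort_values("yield_pct")
        return cls(
            x=df["yield_pct"].to_numpy(dtype=float) / 100.0,
            rel_error=df["rel_error_pct"].to_numpy(dtype=float) / 100.0,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"yield_pct": self.x * 100.0, "rel_error_pct": self.rel_error * 100.0}
        ).to_csv(path, index=False)


@dataclass
class CalibrationResult:
    params: ErrorModelParams
    residuals: np.ndarray
    cost: float
    converged: bool


# Deterministic multi-start grid over (a, b, k); bounds a in (0, 1.5],
# b, k in [-100, 0).  Multiple starts guard against the local minima of
# the exponential-decay fit.
_CAL_STARTS = [
    (1.0, -9.0, -10.0),
    (0.5, -1.0, -2.0),
    (1.2, -20.0, -30.0),
    (0.8, -5.0, -5.0),
    (1.0, -50.0, -60.0),
]
_CAL_BOUNDS = ([1e-6, -100.0, -100.0], [1.5, -1e-9, -1e-9])


def calibrate(table: AssumedErrorTable, floor: float = 0.005) -> CalibrationResult:
    """Least-squares fit of the Stirling curve to an assumed-error table.

    Needs at least three rows (three free parameters).  Non-convergence
    is reported with the best candidate and a :class:`CalibrationWarning`
    rather than an exception.
    """
    if table.x.size < 3:
        raise ValueError(
            f"calibration needs >= 3 rows, got {table.x.size} (underdetermined)"
        )

    def resid(theta: np.ndarray) -> np.ndarray:
        p = ErrorModelParams(a=theta[0], b=theta[1], k=theta[2], floor=floor)
        return stirling_error(table.x, p) - table.rel_error

    best = None
    for x0 in _CAL_STARTS:
        try:
            sol = least_squares(resid, x0, bounds=_CAL_BOUNDS, xtol=1e-14, ftol=1e-14)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("calibration failed from every starting point")
    converged = bool(best.success)
    if not converged:
        warnings.warn(
            f"calibration did not converge cleanly ({best.message}); "
            f"returning best candidate",
            CalibrationWarning,
            stacklevel=2,
        )
    params = ErrorModelParams(a=best.x[0], b=best.x[1], k=best.x[2], floor=floor)
    return CalibrationResult(
        params=params,
        residuals=resid(best.x),
        cost=float(best.cost),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# WFI
# ---------------------------------------------------------------------------


def _matched_series(
    sim: TimeCourse, exp: TimeCourse, species: str, exclude_t0: bool
) -> tuple[np.ndarray, np.ndarray]:
    if sim.n_points != exp.n_points or not np.allclose(
        sim.times_min, exp.times_min, rtol=0, atol=1e-9
    ):
        raise ValueError(
            "simulated and experimental series must be sampled at the same times "
            "(simulate at the exact experimental sample times)"
        )
    if species not in sim.yields or species not in exp.yields:
        raise KeyError(f"species {species!r} missing from one of the series")
    keep = sim.times_min > 0 if exclude_t0 else np.ones(sim.n_points, bool)
    if not keep.any():
        raise ValueError("no data points left after excluding t = 0")
    return sim.yields[species][keep], exp.yields[species][keep]


def wfi(
    sim,
    exp,
    params: ErrorModelParams,
    species: str | None = None,
    exclude_t0: bool = True,
) -> float:
    """Weighted fitting index of one experimental series against its simulation.

    ``sim``/``exp`` may be plain yield-fraction arrays (already matched
    point-for-point) or :class:`~kinwfi.simulator.TimeCourse` objects
    sharing identical sample times, in which case ``species`` selects the
    series (optional when only one species is present).  The t = 0 point
    is excluded by default: both curves pass through the initial value
    exactly, so it carries no information about fit quality.
    """
    if isinstance(sim, TimeCourse) or isinstance(exp, TimeCourse):
        if not (isinstance(sim, TimeCourse) and isinstance(exp, TimeCourse)):
            raise TypeError("sim and exp must both be TimeCourse or both arrays")
        if species is None:
            shared = [s for s in sim.species if s in exp.yields]
            if len(shared) != 1:
                raise ValueError(
                    f"species must be given when series share {len(shared)} species; "
                    f"use wfi_report for multi-species tables"
                )
            species = shared[0]
        ys, ye = _matched_series(sim, exp, species, exclude_t0)
    else:
        ys = np.asarray(sim, dtype=float)
        ye = np.asarray(exp, dtype=float)
        if ys.shape != ye.shape or ys.ndim != 1:
            raise ValueError("matched 1-D arrays of equal length required")
    if ys.size == 0:
        raise ValueError("empty series")
    w = band_half_width(ys, params)
    return float(np.mean(absolute_error(ys, ye) / w))


@dataclass
class WFIReport:
    """Per-experiment, per-species WFI values with row averages.

    ``table`` has one row per experiment, one column per species plus an
    ``Ave.`` column holding the arithmetic mean of the per-species
    values present in that row.
    """

    table: pd.DataFrame
    n_points: pd.DataFrame = field(repr=False, default=None)

    @property
    def experiments(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> list[str]:
        return [c for c in self.table.columns if c != "Ave."]

    def average(self, experiment_id: str) -> float:
        return float(self.table.loc[experiment_id, "Ave."])

    @property
    def pooled_average(self) -> float:
        """Mean of the per-experiment averages across the whole report."""
        return float(self.table["Ave."].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="experiment_id", float_format="%.4f")

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.2f}")


def wfi_report(
    simulated: dict[str, TimeCourse],
    experimental: dict[str, TimeCourse],
    params: ErrorModelParams,
    species: list[str] | None = None,
    exclude_t0: bool = True,
) -> WFIReport:
    """WFI table over experiments and species, with per-experiment averages.

    ``simulated`` and ``experimental`` map experiment ids to matched
    time courses.  A species missing from an experiment is reported as
    NaN and excluded from that row's average, with a warning.
    """
    if set(simulated) != set(experimental):
        raise ValueError(
            f"experiment ids differ: {sorted(simulated)} vs {sorted(experimental)}"
        )
    if species is None:
        species = []
        for tc in simulated.values():
            for sp in tc.species:
                if sp not in species:
                    species.append(sp)
    rows, counts = {}, {}
    for exp_id, sim_tc in simulated.items():
        exp_tc = experimental[exp_id]
        row, nrow = {}, {}
        for sp in species:
            if sp not in sim_tc.yields or sp not in exp_tc.yields:
                warnings.warn(
                    f"experiment {exp_id!r}: species {sp!r} absent; excluded from average",
                    stacklevel=2,
                )
                row[sp], nrow[sp] = np.nan, 0
                continue
            ys, ye = _matched_series(sim_tc, exp_tc, sp, exclude_t0)
            w = band_half_width(ys, params)
            row[sp] = float(np.mean(absolute_error(ys, ye) / w))
            nrow[sp] = ys.size
        row["Ave."] = float(np.nanmean([row[sp] for sp in species]))
        rows[exp_id] = row
        counts[exp_id] = nrow
    table = pd.DataFrame.from_dict(rows, orient="index")[[*species, "Ave."]]
    npts = pd.DataFrame.from_dict(counts, orient="index")[species]
    return WFIReport(table=table, n_points=npts)
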