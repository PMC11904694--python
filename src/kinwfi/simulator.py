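"""Mass-action ODE integration of kinetic models under batch conditions.

Concentrations are carried in mol/L and time in seconds inside the
integrator; user-facing time courses use minutes and conversion yields
(fraction of the initial limiting substrate, aniline ``1``).  The
borderline mechanism is stiff when cation capture is fast, so a stiff
solver (LSODA) with tight tolerances is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .reaction_network import R_GAS, KineticModel

__all__ = [
    "Conditions",
    "TimeCourse",
    "Experiment",
    "SimulationError",
    "MassActionRHS",
    "build_rate_equations",
    "simulate",
    "simulate_concentrations",
    "pathway_rates",
    "PathwayRates",
    "read_timecourses",
    "write_timecourses",
]

_CELSIUS_OFFSET = 273.15


class SimulationError(RuntimeError):
    """Integrator failure, reported with solver diagnostics."""


@dataclass
class Conditions:
    """Batch-experiment conditions.

    Parameters
    ----------
    initial_concentrations : dict
        Species name -> mol/L at t = 0.  Unlisted species start at 0.
    temperature_C : float or list of (time_min, celsius)
        Constant internal temperature, or a piecewise-linear profile of
        the monitored internal temperature covering [0, duration].
    duration_min : float
        Batch time in minutes.
    """

    initial_concentrations: dict[str, float]
    temperature_C: float | list[tuple[float, float]]
    duration_min: float

    def __post_init__(self) -> None:
        for name, c in self.initial_concentrations.items():
            if c < 0:
                raise ValueError(f"initial concentration of {name!r} is negative: {c}")
        if not self.duration_min > 0:
            raise ValueError(f"duration must be > 0, got {self.duration_min}")
        if not np.isscalar(self.temperature_C):
            prof = sorted((float(t), float(c)) for t, c in self.temperature_C)
            if prof[0][0] > 0 or prof[-1][0] < self.duration_min:
                raise ValueError(
                    f"temperature profile [{prof[0][0]}, {prof[-1][0]}] min does not "
                    f"cover [0, {self.duration_min}] min"
                )
            self.temperature_C = prof

    def temperature_K(self, t_min: float | np.ndarray) -> float | np.ndarray:
        """Internal temperature in kelvin at time ``t_min`` (minutes)."""
        if np.isscalar(self.temperature_C):
            T = float(self.temperature_C) + _CELSIUS_OFFSET
            return T if np.isscalar(t_min) else np.full_like(np.asarray(t_min, float), T)
        times, temps = zip(*self.temperature_C)
        return np.interp(t_min, times, temps) + _CELSIUS_OFFSET


@dataclass
class TimeCourse:
    """Sampled per-species conversion yields along one experiment.

    Yields are stored as fractions of the initial aniline concentration
    (0-1); CSV I/O converts to/from the user-facing percent scale.
    """

    times_min: np.ndarray
    yields: dict[str, np.ndarray]
    source: str = "simulated"  # simulated | experimental
    temps_C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.times_min.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times_min < 0):
            raise ValueError("times must be >= 0")
        self.yields = {k: np.asarray(v, dtype=float) for k, v in self.yields.items()}
        for name, y in self.yields.items():
            if y.shape != self.times_min.shape:
                raise ValueError(
                    f"series {name!r} has {y.size} points for {self.times_min.size} times"
                )

    @property
    def species(self) -> list[str]:
        return list(self.yields)

    @property
    def n_points(self) -> int:
        return self.times_min.size

    def to_frame(self, experiment_id: str = "exp") -> pd.DataFrame:
        """Long-format frame with yields on the percent scale."""
        rows = []
        temps = self.temps_C
        for name, y in self.yields.items():
            for i, t in enumerate(self.times_min):
                rows.append(
                    {
                        "experiment_id": experiment_id,
                        "time_min": t,
                        "temp_C": float(temps[i]) if temps is not None else np.nan,
                        "species": name,
                        "yield_pct": y[i] * 100.0,
                        "source": self.source,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class Experiment:
    """One batch experiment: its conditions and observed time course."""

    id: str
    conditions: Conditions
    observed: TimeCourse
    role: str = "training"  # training | extrapolation

    def __post_init__(self) -> None:
        if self.role not in ("training", "extrapolation"):
            raise ValueError(f"experiment role must be training|extrapolation, got {self.role!r}")


# ---------------------------------------------------------------------------
# Rate equations
# ---------------------------------------------------------------------------


class MassActionRHS:
    """Vectorized mass-action right-hand side for a kinetic model.

    Each step ``j`` contributes rate ``k_j(T) * prod_i c_i^nu_ij`` and the
    species derivatives are ``dc/dt = N @ rates`` with ``N`` the signed
    stoichiometry matrix.  Callable as ``rhs(t_sec, c, T_kelvin)``.
    """

    def __init__(self, model: KineticModel):
        model.validate()
        self.model = model
        names = model.species_names
        self.index = {n: i for i, n in enumerate(names)}
        n_sp, n_st = len(names), len(model.steps)
        self.nu = np.zeros((n_sp, n_st))  # reactant orders
        self.N = np.zeros((n_sp, n_st))  # net stoichiometry
        self.A = np.empty(n_st)
        self.Ea = np.empty(n_st)
        for j, step in enumerate(model.steps):
            for name, coeff in step.reactants.items():
                self.nu[self.index[name], j] = coeff
                self.N[self.index[name], j] -= coeff
            for name, coeff in step.products.items():
                self.N[self.index[name], j] += coeff
            self.A[j] = step.rate_params.A
            self.Ea[j] = step.rate_params.Ea

    def rate_constants(self, T: float) -> np.ndarray:
        """Per-step rate constants at ``T`` kelvin (s^-1 or L mol^-1 s^-1)."""
        return self.A * np.exp(-self.Ea / (R_GAS * T))

    def step_rates(self, c: np.ndarray, T: float) -> np.ndarray:
        """Per-step mass-action rates at concentrations ``c`` (mol/L)."""
        conc = np.clip(c, 0.0, None)
        # prod_i c_i^nu_ij for molecularity <= 2; nu entries are 0/1/2
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(self.nu > 0, conc[:, None] ** self.nu, 1.0)
        return self.rate_constants(T) * factors.prod(axis=0)

    def __call__(self, t_sec: float, c: np.ndarray, T: float) -> np.ndarray:
        return self.N @ self.step_rates(c, T)

    def jacobian(self, t_sec: float, c: np.ndarray, T: float) -> np.ndarray:
        """Analytic Jacobian d(dc/dt)/dc, supplied to the stiff solver."""
        conc = np.clip(c, 0.0, None)
        k = self.rate_constants(T)
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(self.nu > 0, conc[:, None] ** self.nu, 1.0)
        rates = k * factors.prod(axis=0)
        # d(rate_j)/dc_i = rate_j * nu_ij / c_i  (nu_ij * c^(nu-1) * rest)
        drdc = np.zeros_like(self.nu)
        for j in range(self.nu.shape[1]):
            for i in np.nonzero(self.nu[:, j])[0]:
                others = factors[:, j].prod() / factors[i, j] if factors[i, j] != 0 else 0.0
                nu = self.nu[i, j]
                drdc[i, j] = k[j] * nu * (conc[i] ** (nu - 1)) * others
        return self.N @ drdc.T


def build_rate_equations(model: KineticModel) -> MassActionRHS:
    """Compile a model's steps into a mass-action ODE right-hand side."""
    return MassActionRHS(model)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_concentrations(
    model: KineticModel,
    conditions: Conditions,
    times_min,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Integrate the model and return concentrations at the sample times.

    Returns ``(times_min, {species: mol/L})``.  Times must lie within
    ``[0, duration]``.  Solver failures raise :class:`SimulationError`
    with the solver message; yields are never silently NaN.
    """
    times_min = np.asarray(times_min, dtype=float)
    if times_min.size == 0:
        raise ValueError("no sample times given")
    if np.any(times_min < 0) or np.any(times_min > conditions.duration_min + 1e-9):
        raise ValueError(
            f"sample times must lie in [0, {conditions.duration_min}] min"
        )
    rhs = build_rate_equations(model)
    c0 = np.zeros(len(model.species))
    for name, conc in conditions.initial_concentrations.items():
        if name not in rhs.index:
            raise ValueError(f"initial concentration for unknown species {name!r}")
        c0[rhs.index[name]] = conc

    isothermal = np.isscalar(conditions.temperature_C)
    if isothermal:
        T_const = conditions.temperature_K(0.0)
        fun = lambda t, c: rhs(t, c, T_const)  # noqa: E731
        jac = lambda t, c: rhs.jacobian(t, c, T_const)  # noqa: E731
    else:
        fun = lambda t, c: rhs(t, c, conditions.temperature_K(t / 60.0))  # noqa: E731
        jac = lambda t, c: rhs.jacobian(t, c, conditions.temperature_K(t / 60.0))  # noqa: E731

    t_span = (0.0, float(times_min.max() * 60.0)) if times_min.max() > 0 else (0.0, 1.0)
    t_eval = times_min * 60.0
    sol = solve_ivp(
        fun,
        t_span,
        c0,
        method="LSODA",
        t_eval=t_eval if times_min.max() > 0 else None,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        raise SimulationError(
            f"integration of model {model.name!r} failed: {sol.message}"
        )
    if times_min.max() > 0:
        y = sol.y
    else:  # degenerate all-zero time request
        y = np.repeat(c0[:, None], times_min.size, axis=1)
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"integration of model {model.name!r} produced non-finite values")
    # integrator wobble below zero (up to ~1e-6 mol/L on fast transients)
    # is expected and clipped; beyond 1e-5 mol/L signals a genuine failure
    if np.any(y < -1e-5):
        raise SimulationError(
            f"integration of model {model.name!r} produced significantly negative "
            f"concentrations (min {y.min():g})"
        )
    conc = {name: np.clip(y[i], 0.0, None) for name, i in rhs.index.items()}
    return times_min, conc


def simulate(
    model: KineticModel,
    conditions: Conditions,
    times_min,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    reference_species: str = "1",
) -> TimeCourse:
    """Simulate and express observable species as conversion yields.

    Yields are fractions of the initial concentration of
    ``reference_species`` (the limiting substrate, aniline by default).
    """
    ref0 = conditions.initial_concentrations.get(reference_species, 0.0)
    if not ref0 > 0:
        raise ValueError(
            f"reference species {reference_species!r} needs a positive initial "
            f"concentration to define conversion yields"
        )
    times_min, conc = simulate_concentrations(model, conditions, times_min, rtol, atol)
    yields = {name: conc[name] / ref0 for name in model.observable_names}
    return TimeCourse(
        times_min=times_min,
        yields=yields,
        source="simulated",
        temps_C=np.asarray(conditions.temperature_K(times_min)) - _CELSIUS_OFFSET,
    )


# ---------------------------------------------------------------------------
# Pathway-rate analysis
# ---------------------------------------------------------------------------


@dataclass
class PathwayRates:
    """Instantaneous branch rates of the borderline mechanism.

    ``sn1_rate`` is the ionization flux ``k_ion [BnBr]`` and ``sn2_rate``
    the direct-substitution flux ``k_sn2 [1][BnBr]``, both mol/(L s).
    ``ratio`` is sn1/sn2; ``defined`` is False when both rates vanish.
    """

    sn1_rate: float
    sn2_rate: float
    ratio: float
    defined: bool
    temperature_K: float


def pathway_rates(
    model: KineticModel,
    state: dict[str, float],
    T: float,
) -> PathwayRates:
    """Per-pathway rates and their ratio at one concentration state.

    Comparing rates (not rate constants) puts the two branches on a
    common mol/(L s) scale despite their different rate-constant units.
    """
    labels = {s.label for s in model.steps}
    if not {"ionization", "sn2_mono"} <= labels:
        raise ValueError(
            f"model {model.name!r} lacks one of the branches "
            f"(needs steps 'ionization' and 'sn2_mono')"
        )
    k_ion = model.step("ionization").rate_params.k(T) if T > 0 else 0.0
    k_sn2 = model.step("sn2_mono").rate_params.k(T)
    bnbr = max(state.get("BnBr", 0.0), 0.0)
    aniline = max(state.get("1", 0.0), 0.0)
    sn1 = k_ion * bnbr
    sn2 = k_sn2 * aniline * bnbr
    if sn1 == 0.0 and sn2 == 0.0:
        return PathwayRates(0.0, 0.0, float("nan"), defined=False, temperature_K=T)
    ratio = sn1 / sn2 if sn2 > 0 else float("inf")
    return PathwayRates(sn1, sn2, ratio, defined=True, temperature_K=T)


def pathway_rates_at(
    model: KineticModel,
    conditions: Conditions,
    t_min: float = 10.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PathwayRates:
    """Branch rates along a simulated trajectory at ``t_min`` (default 10 min)."""
    _, conc = simulate_concentrations(model, conditions, [t_min], rtol=rtol, atol=atol)
    state = {name: float(c[0]) for name, c in conc.items()}
    return pathway_rates(model, state, float(conditions.temperature_K(t_min)))


# ---------------------------------------------------------------------------
# Time-course CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["experiment_id", "time_min", "temp_C", "species", "yield_pct", "source"]


def write_timecourses(courses: dict[str, TimeCourse], path) -> None:
    """Write time courses to the long-format CSV dialect.

    Columns: experiment_id, time_min, temp_C, species, yield_pct, source.
    Yields on the percent scale; comma-separated, dot decimal, header row.
    """
    frames = [tc.to_frame(exp_id) for exp_id, tc in courses.items()]
    pd.concat(frames, ignore_index=True)[_CSV_COLUMNS].to_csv(path, index=False)


def read_timecourses(path) -> dict[str, TimeCourse]:
    """Read the time-course CSV dialect back into fraction-scale courses."""
    df = pd.read_csv(path, dtype={"experiment_id": str, "species": str})
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"time-course CSV {path} lacks columns {sorted(missing)}")
    if df["yield_pct"].isna().any():
        raise ValueError(f"time-course CSV {path} contains missing yields")
    out: dict[str, TimeCourse] = {}
    for exp_id, g in df.groupby("experiment_id", sort=False):
        times = np.array(sorted(g["time_min"].unique()), dtype=float)
        yields = {}
        for sp, gs in g.groupby("species", sort=False):
            gs = gs.sort_values("time_min")
            if not np.array_equal(gs["time_min"].to_numpy(dtype=float), times):
                raise ValueError(
                    f"experiment {exp_id!r}: species {sp!r} sampled at different times"
                )
            yields[sp] = gs["yield_pct"].to_numpy(dtype=float) / 100.0
        g1 = g[g["species"] == next(iter(yields))].sort_values("time_min")
        temps = g1["temp_C"].to_numpy(dtype=float)
        sources = g["source"].unique()
        out[str(exp_id)] = TimeCourse(
            times_min=times,
            yields=yields,
            source=str(sources[0]) if len(sources) == 1 else "mixed",
            temps_C=None if np.isnan(temps).all() else temps,
        )
    return out
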