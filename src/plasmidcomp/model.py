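"""Four-compartment model of competition between two conjugative plasmid variants.

The model tracks densities of plasmid-free cells (``N0``), cells carrying the
wildtype plasmid (``NW``), the mutant plasmid (``NM``), or both (``NWM``).
Cells replicate logistically at maximal rate ``rho`` with carrying capacity
``K`` and die at rate ``gamma``; plasmid carriage imposes a replication cost
``c``.  Conjugation is mass-action with rate constants ``beta_W`` and
``beta_M``; co-infected cells donate each variant with probability 1/2, so the
force of infection of variant *i* is ``lambda_i = beta_i * (N_i + NWM / 2)``.
Entry exclusion reduces conjugation into already-infected cells by a factor
``1 - k``.  During replication a co-infected cell loses all copies of the
wildtype (mutant) variant with probability ``s_W`` (``s_M``), reverting to
single carriage; singly infected cells never lose their plasmid.

The mutant's horizontal advantage is ``a_H = beta_M / beta_W`` and its
vertical advantage is ``a_V = s_W / s_M`` (the wildtype is lost more often
during co-infected replication when ``a_V > 1``).  An optional influx
``epsilon`` of plasmid-free cells models immigration of susceptible hosts.

The governing equations are::

    dN0/dt  = N0 [rho (1 - T/K) - gamma - lambda_M - lambda_W] + epsilon
    dNW/dt  = NW [(1-c) rho (1 - T/K) - gamma] + N0 lambda_W
              - (1-k) NW lambda_M + NWM s_M (1-c) rho (1 - T/K)
    dNM/dt  = NM [(1-c) rho (1 - T/K) - gamma] + N0 lambda_M
              - (1-k) NM lambda_W + NWM s_W (1-c) rho (1 - T/K)
    dNWM/dt = NWM [(1 - s_W - s_M) (1-c) rho (1 - T/K) - gamma]
              + (1-k) [NW lambda_M + NM lambda_W]

with ``T = N0 + NW + NM + NWM`` and ``s_W + s_M <= 1``.  Time and densities
are in arbitrary units.

By default (``displacement_flux=True``) conjugation into an already
co-infected cell additionally displaces the resident variant with probability
1/2, moving the cell back to single carriage of the incoming variant
(``+(1-k) NWM lambda_i / 2`` into ``N_i``, matching losses from ``NWM``).
This displacement step is what makes a pure transmission advantage decisive:
without it (``displacement_flux=False``, the bare equations above) a mutant
with only a horizontal advantage settles into stable coexistence with the
wildtype instead of replacing it.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "PopulationState",
    "Trajectory",
    "ReplacementCriterion",
    "SweepResult",
    "SerialTransferResult",
    "NO_REPLACEMENT",
    "force_of_infection",
    "derivatives",
    "single_plasmid_equilibrium",
    "standard_initial_state",
    "simulate",
    "replacement_time",
    "sweep_advantages",
    "sweep_influx",
    "sweep_parameter",
    "simulate_serial_transfer",
    "load_scenario",
]

#: Sentinel replacement time meaning "criterion never met before t_max".
NO_REPLACEMENT = math.inf

#: Default horizon for declaring no replacement, in model time units.
DEFAULT_T_MAX = 1e5


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the competition model (arbitrary time units).

    Defaults are the standard parameter set used for all sweeps:
    ``rho=1, c=0.1, gamma=0.1, K=1, beta_W=beta_M=1, s_W=s_M=0.1, k=0.99,
    epsilon=0``.
    """

    rho: float = 1.0  # maximal replication rate
    c: float = 0.1  # plasmid fitness cost, fraction of replication
    gamma: float = 0.1  # death rate
    K: float = 1.0  # carrying capacity
    beta_W: float = 1.0  # wildtype conjugation rate constant
    beta_M: float = 1.0  # mutant conjugation rate constant
    s_W: float = 0.1  # wildtype segregational-loss probability
    s_M: float = 0.1  # mutant segregational-loss probability
    k: float = 0.99  # entry-exclusion strength
    epsilon: float = 0.0  # influx of plasmid-free cells
    displacement_flux: bool = True  # co-infection displacement (see module docstring)

    def __post_init__(self) -> None:
        for name in ("rho", "gamma", "K", "beta_W", "beta_M", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.c < 1.0:
            raise ValueError(f"cost c must be in [0, 1), got {self.c}")
        if not 0.0 <= self.s_W <= 1.0 or not 0.0 <= self.s_M <= 1.0:
            raise ValueError("segregational-loss probabilities must be in [0, 1]")
        if self.s_W + self.s_M > 1.0 + 1e-12:
            raise ValueError(f"s_W + s_M must be <= 1, got {self.s_W + self.s_M}")
        if self.k > 1.0:
            raise ValueError(f"entry exclusion k must be <= 1, got {self.k}")

    @property
    def a_H(self) -> float:
        """Horizontal advantage of the mutant, beta_M / beta_W."""
        return self.beta_M / self.beta_W

    @property
    def a_V(self) -> float:
        """Vertical advantage of the mutant, s_W / s_M."""
        return self.s_W / self.s_M

    def with_advantages(self, a_H: float = 1.0, a_V: float = 1.0) -> "ModelParams":
        """Return a copy with ``beta_M = a_H * beta_W`` and ``s_W = a_V * s_M``."""
        if a_H < 0 or a_V < 0:
            raise ValueError("advantages must be >= 0")
        return dataclasses.replace(
            self, beta_M=a_H * self.beta_W, s_W=a_V * self.s_M
        )


@dataclass(frozen=True)
class PopulationState:
    """Cell densities of the four compartments (cells per unit volume)."""

    N0: float = 0.0
    NW: float = 0.0
    NM: float = 0.0
    NWM: float = 0.0

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("densities must be finite")
        if np.any(arr < 0):
            raise ValueError(f"densities must be >= 0, got {tuple(arr)}")

    @property
    def total(self) -> float:
        return self.N0 + self.NW + self.NM + self.NWM

    def as_array(self) -> np.ndarray:
        return np.array([self.N0, self.NW, self.NM, self.NWM], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "PopulationState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class ReplacementCriterion:
    """When the wildtype plasmid counts as replaced.

    ``absolute_density`` compares the summed density of the wildtype-carrying
    compartments against ``threshold`` (cells per unit volume, default 0.01);
    ``relative_frequency`` compares their frequency among all cells against
    ``threshold`` (default 0.01, i.e. 1%).  By default both co-infected and
    singly infected carriers count as wildtype-carrying.
    """

    mode: str = "absolute_density"
    threshold: float = 0.01
    wildtype_compartments: tuple[str, ...] = ("NW", "NWM")

    _INDEX = {"N0": 0, "NW": 1, "NM": 2, "NWM": 3}

    def __post_init__(self) -> None:
        if self.mode not in ("absolute_density", "relative_frequency"):
            raise ValueError(f"unknown criterion mode {self.mode!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        unknown = set(self.wildtype_compartments) - set(self._INDEX)
        if unknown:
            raise ValueError(f"unknown compartments {sorted(unknown)}")

    def indices(self) -> list[int]:
        return [self._INDEX[name] for name in self.wildtype_compartments]

    def signal(self, y: np.ndarray) -> np.ndarray:
        """Criterion signal; replacement is the first down-crossing of zero.

        ``y`` has the compartments on its first axis.
        """
        y = np.asarray(y, dtype=float)
        wt = np.sum(np.take(y, self.indices(), axis=0), axis=0)
        if self.mode == "absolute_density":
            return wt - self.threshold
        total = np.sum(y, axis=0)
        return wt - self.threshold * total


@dataclass
class Trajectory:
    """Solution of the competition model over time."""

    t: np.ndarray
    y: np.ndarray  # shape (4, len(t)); rows N0, NW, NM, NWM
    params: ModelParams
    t_max: float
    rtol: float
    atol: float
    replacement_time: float | None = None  # None when no criterion was supplied

    COMPARTMENTS = ("N0", "NW", "NM", "NWM")

    def state_at(self, index: int) -> PopulationState:
        return PopulationState.from_array(np.clip(self.y[:, index], 0.0, None))

    @property
    def final_state(self) -> PopulationState:
        return self.state_at(-1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.t, **{c: self.y[i] for i, c in enumerate(self.COMPARTMENTS)}}
        )


@dataclass
class SweepResult:
    """Replacement times on a parameter grid.

    ``times[i, j]`` is the replacement time at ``(x_values[i], y_values[j])``;
    entries are ``inf`` where the criterion was not met before ``t_max``
    (``censored`` is True there) and ``nan`` where the parameter combination is
    invalid (``invalid`` is True, e.g. ``s_W + s_M > 1``).
    """

    x_name: str
    y_name: str
    x_values: np.ndarray
    y_values: np.ndarray
    times: np.ndarray
    censored: np.ndarray
    invalid: np.ndarray
    t_max: float
    criterion: ReplacementCriterion
    base_params: ModelParams

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x_values, self.y_values, indexing="ij")
        return pd.DataFrame(
            {
                self.x_name: xx.ravel(),
                self.y_name: yy.ravel(),
                "time": self.times.ravel(),
                "censored": self.censored.ravel(),
                "invalid": self.invalid.ravel(),
            }
        )


def _rhs(t: float, y: np.ndarray, p: ModelParams) -> np.ndarray:
    N0, NW, NM, NWM = y
    T = N0 + NW + NM + NWM
    growth = p.rho * (1.0 - T / p.K)
    pg = (1.0 - p.c) * growth  # plasmid-carrier per-capita replication term
    lam_W = p.beta_W * (NW + 0.5 * NWM)
    lam_M = p.beta_M * (NM + 0.5 * NWM)
    one_minus_k = 1.0 - p.k

    dN0 = N0 * (growth - p.gamma - lam_M - lam_W) + p.epsilon
    dNW = (
        NW * (pg - p.gamma)
        + N0 * lam_W
        - one_minus_k * NW * lam_M
        + NWM * p.s_M * pg
    )
    dNM = (
        NM * (pg - p.gamma)
        + N0 * lam_M
        - one_minus_k * NM * lam_W
        + NWM * p.s_W * pg
    )
    dNWM = (
        NWM * ((1.0 - p.s_W - p.s_M) * pg - p.gamma)
        + one_minus_k * (NW * lam_M + NM * lam_W)
    )
    if p.displacement_flux:
        # Model variant: conjugation into an already co-infected cell displaces
        # the resident variant with probability 1/2, converting the cell to
        # single carriage of the incoming variant.
        disp_W = one_minus_k * 0.5 * NWM * lam_W
        disp_M = one_minus_k * 0.5 * NWM * lam_M
        dNW += disp_W
        dNM += disp_M
        dNWM -= disp_W + disp_M
    return np.array([dN0, dNW, dNM, dNWM])


def force_of_infection(
    state: PopulationState, params: ModelParams
) -> tuple[float, float]:
    """Per-capita conjugation pressure of each variant.

    Returns ``(lambda_W, lambda_M)`` with
    ``lambda_i = beta_i * (N_i + NWM / 2)``: co-infected cells donate either
    variant with probability 1/2.
    """
    lam_W = params.beta_W * (state.NW + 0.5 * state.NWM)
    lam_M = params.beta_M * (state.NM + 0.5 * state.NWM)
    return lam_W, lam_M


def derivatives(state: PopulationState, params: ModelParams) -> np.ndarray:
    """Rates of change ``(dN0, dNW, dNM, dNWM)/dt`` at the given state."""
    return _rhs(0.0, state.as_array(), params)


def single_plasmid_equilibrium(params: ModelParams) -> float:
    """Equilibrium density of a single plasmid-carrying population.

    With only one variant present (``N0 = NM = NWM = 0``, ``epsilon = 0``) the
    carriers grow logistically with effective rate ``(1-c) rho`` and die at
    ``gamma``; the stationary density is ``K * (1 - gamma / ((1-c) rho))``.
    Returns 0 (with a warning) when the carriers cannot persist,
    i.e. ``(1-c) rho <= gamma``.
    """
    net = (1.0 - params.c) * params.rho
    if net <= params.gamma:
        if net < params.gamma:
            warnings.warn(
                "plasmid-carrying population cannot persist: (1-c)*rho <= gamma",
                RuntimeWarning,
                stacklevel=2,
            )
        return 0.0
    return params.K * (1.0 - params.gamma / net)


def standard_initial_state(
    params: ModelParams, invader_density: float = 0.01
) -> PopulationState:
    """Resident wildtype at its single-plasmid equilibrium plus a small
    inoculum of co-infected cells (default ``NWM = 0.01`` cells per unit
    volume)."""
    return PopulationState(
        N0=0.0,
        NW=single_plasmid_equilibrium(params),
        NM=0.0,
        NWM=invader_density,
    )


def simulate(
    params: ModelParams,
    initial: PopulationState,
    t_max: float,
    criterion: ReplacementCriterion | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    stop_at_event: bool = True,
) -> Trajectory:
    """Integrate the model from ``initial`` over ``[0, t_max]``.

    When ``criterion`` is given, the integrator tracks the first down-crossing
    of the criterion signal by event detection (root-refined on dense output)
    and, if ``stop_at_event``, terminates there;
    ``Trajectory.replacement_time`` records the crossing or ``inf``.

    Compartments may dip below zero only within integrator tolerance: values
    in ``[-10*atol, 0)`` are clipped to zero in the returned trajectory, and
    anything below that aborts with an error.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    y0 = initial.as_array()

    events = None
    if criterion is not None:
        # Skip event detection while the signal is still above threshold at t=0
        # only in the trivial sense: a start already below threshold counts as
        # an immediate crossing.
        if criterion.signal(y0) <= 0:
            t = np.array([0.0])
            return Trajectory(
                t=t,
                y=y0[:, None].copy(),
                params=params,
                t_max=t_max,
                rtol=rtol,
                atol=atol,
                replacement_time=0.0,
            )

        def crossing(t, y, _p):  # noqa: ANN001
            return criterion.signal(np.asarray(y))

        crossing.terminal = stop_at_event
        crossing.direction = -1.0
        events = [crossing]

    sol = solve_ivp(
        _rhs,
        (0.0, t_max),
        y0,
        args=(params,),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=events,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    y = sol.y
    floor = -10.0 * atol
    if np.any(y < floor):
        worst = float(y.min())
        raise RuntimeError(
            f"negative density beyond tolerance during integration (min {worst:g})"
        )
    y = np.clip(y, 0.0, None)

    rep_time: float | None = None
    if criterion is not None:
        rep_time = (
            float(sol.t_events[0][0]) if len(sol.t_events[0]) else NO_REPLACEMENT
        )

    return Trajectory(
        t=sol.t,
        y=y,
        params=params,
        t_max=t_max,
        rtol=rtol,
        atol=atol,
        replacement_time=rep_time,
    )


def replacement_time(
    params: ModelParams,
    criterion: ReplacementCriterion | None = None,
    t_max: float = DEFAULT_T_MAX,
    initial: PopulationState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """First time the wildtype falls below the replacement criterion.

    Starts from the standard initial condition (wildtype at its single-plasmid
    equilibrium, ``NWM = 0.01``) unless ``initial`` is given.  Returns
    :data:`NO_REPLACEMENT` (``inf``) when the criterion is not met before
    ``t_max``.
    """
    if criterion is None:
        criterion = ReplacementCriterion()
    if initial is None:
        initial = standard_initial_state(params)
    traj = simulate(
        params, initial, t_max, criterion=criterion, rtol=rtol, atol=atol
    )
    assert traj.replacement_time is not None
    return traj.replacement_time


def _sweep(
    x_name: str,
    y_name: str,
    x_values: Iterable[float],
    y_values: Iterable[float],
    param_builder,
    criterion: ReplacementCriterion,
    t_max: float,
    base: ModelParams,
) -> SweepResult:
    xs = np.asarray(list(x_values), dtype=float)
    ys = np.asarray(list(y_values), dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("sweep grids must be nonempty")
    times = np.full((xs.size, ys.size), np.nan)
    censored = np.zeros_like(times, dtype=bool)
    invalid = np.zeros_like(times, dtype=bool)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            try:
                p = param_builder(x, y)
            except ValueError:
                invalid[i, j] = True
                continue
            t = replacement_time(p, criterion=criterion, t_max=t_max)
            times[i, j] = t
            censored[i, j] = not math.isfinite(t)
    return SweepResult(
        x_name=x_name,
        y_name=y_name,
        x_values=xs,
        y_values=ys,
        times=times,
        censored=censored,
        invalid=invalid,
        t_max=t_max,
        criterion=criterion,
        base_params=base,
    )


def sweep_advantages(
    aH_grid: Iterable[float],
    aV_grid: Iterable[float],
    base: ModelParams | None = None,
    criterion: ReplacementCriterion | None = None,
    t_max: float = DEFAULT_T_MAX,
) -> SweepResult:
    """Replacement times over a grid of horizontal x vertical advantages.

    For each cell, ``beta_M = a_H * beta_W`` and ``s_W = a_V * s_M`` on top of
    ``base``; cells where ``s_W + s_M > 1`` are marked invalid.
    """
    base = base or ModelParams()
    criterion = criterion or ReplacementCriterion()
    return _sweep(
        "a_H",
        "a_V",
        aH_grid,
        aV_grid,
        lambda aH, aV: base.with_advantages(aH, aV),
        criterion,
        t_max,
        base,
    )


def sweep_influx(
    aH_grid: Iterable[float],
    epsilon_grid: Iterable[float],
    base: ModelParams | None = None,
    criterion: ReplacementCriterion | None = None,
    t_max: float = DEFAULT_T_MAX,
) -> SweepResult:
    """Replacement times over horizontal advantage x plasmid-free influx.

    Segregational loss is symmetric (``s_W = s_M``, i.e. ``a_V = 1``); only
    the horizontal advantage and the influx ``epsilon`` vary.
    """
    base = base or ModelParams()
    criterion = criterion or ReplacementCriterion()

    def build(aH: float, eps: float) -> ModelParams:
        return dataclasses.replace(base.with_advantages(aH, 1.0), epsilon=eps)

    return _sweep(
        "a_H", "epsilon", aH_grid, epsilon_grid, build, criterion, t_max, base
    )


_SWEEPABLE = {"beta_W", "s_M", "k"}


def sweep_parameter(
    name: str,
    values: Iterable[float],
    aH_grid: Iterable[float],
    aV_grid: Iterable[float],
    base: ModelParams | None = None,
    criterion: ReplacementCriterion | None = None,
    t_max: float = DEFAULT_T_MAX,
) -> list[SweepResult]:
    """One advantage sweep per value of a baseline parameter.

    ``name`` is one of ``beta_W``, ``s_M`` or ``k``.  When ``beta_W`` is
    varied, ``beta_M`` tracks ``a_H * beta_W``; when ``s_M`` is varied,
    ``s_W`` tracks ``a_V * s_M``.  The default criterion for these sweeps is
    the wildtype frequency falling below 1%.
    """
    if name not in _SWEEPABLE:
        raise ValueError(f"unknown sweepable parameter {name!r}; use one of {sorted(_SWEEPABLE)}")
    base = base or ModelParams()
    criterion = criterion or ReplacementCriterion(mode="relative_frequency", threshold=0.01)
    results = []
    for value in values:
        modified = dataclasses.replace(base, **{name: float(value)})
        results.append(
            sweep_advantages(aH_grid, aV_grid, modified, criterion, t_max)
        )
    return results


@dataclass
class SerialTransferResult:
    """Outcome of a serial-transfer (daily batch dilution) simulation."""

    day_end_states: list[PopulationState]
    day_start_states: list[PopulationState]
    segments: list[Trajectory]
    params: ModelParams

    def to_frame(self):
        import pandas as pd

        rows = []
        for day, (start, end) in enumerate(
            zip(self.day_start_states, self.day_end_states), start=1
        ):
            rows.append(
                {
                    "day": day,
                    **{f"start_{c}": getattr(start, c) for c in Trajectory.COMPARTMENTS},
                    **{f"end_{c}": getattr(end, c) for c in Trajectory.COMPARTMENTS},
                }
            )
        return pd.DataFrame(rows)


def simulate_serial_transfer(
    params: ModelParams,
    initial: PopulationState,
    n_days: int,
    hours_per_day: float = 24.0,
    dilution_factor: float = 100.0,
    immigrant_ratio: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SerialTransferResult:
    """Alternate within-day continuous growth with daily batch dilution.

    Each day the model runs continuously for ``hours_per_day`` time units;
    the culture is then diluted ``dilution_factor``-fold.  When
    ``immigrant_ratio > 0``, plasmid-free immigrants are mixed with the
    resident culture before dilution at ``immigrant_ratio : 1``
    (immigrants : residents, e.g. 95 for a 95:1 passage), assuming the
    immigrant culture is at the same total density as the resident one, so
    residents make up ``1 / (1 + immigrant_ratio)`` of the diluted inoculum.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    if immigrant_ratio < 0:
        raise ValueError("immigrant_ratio must be >= 0")
    segments: list[Trajectory] = []
    starts: list[PopulationState] = []
    ends: list[PopulationState] = []
    state = initial
    for _ in range(n_days):
        starts.append(state)
        traj = simulate(params, state, hours_per_day, rtol=rtol, atol=atol)
        segments.append(traj)
        end = traj.final_state
        ends.append(end)
        y = end.as_array()
        if immigrant_ratio > 0:
            f_res = 1.0 / (1.0 + immigrant_ratio)
            total = end.total
            y = y * f_res
            y[0] += total * (1.0 - f_res)
        y = y / dilution_factor
        state = PopulationState.from_array(y)
    return SerialTransferResult(
        day_end_states=ends, day_start_states=starts, segments=segments, params=params
    )


def load_scenario(path) -> tuple[ModelParams, PopulationState, ReplacementCriterion]:
    """Read a YAML scenario file.

    Keys under ``params`` mirror :class:`ModelParams` fields (missing keys
    keep the standard defaults); optional ``initial`` holds compartment
    densities (default: wildtype equilibrium plus ``NWM = 0.01``) and optional
    ``criterion`` holds ``mode``/``threshold``/``wildtype_compartments``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    params = ModelParams(**(doc.get("params") or {}))
    if "initial" in doc and doc["initial"] is not None:
        initial = PopulationState(**doc["initial"])
    else:
        initial = standard_initial_state(params)
    crit_doc = doc.get("criterion") or {}
    if "wildtype_compartments" in crit_doc:
        crit_doc["wildtype_compartments"] = tuple(crit_doc["wildtype_compartments"])
    criterion = ReplacementCriterion(**crit_doc)
    return params, initial, criterion
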