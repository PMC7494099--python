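"""Random parameter search for deterministically oscillating circuits.

Rate constants and thresholds are drawn log10-uniformly over three orders of
magnitude (basal degradation 0.01-10 /hr, targeted degradation 1-1000 /hr,
Hill thresholds 1-1000), Hill coefficients uniformly over the integers 2-8.
Each draw is integrated deterministically from 10% of the maximal steady
state; a set is accepted when every species shows *regular* oscillation --
more than 10 complete cycles with less than 5% consecutive-cycle relative
change in both period and amplitude.  Accepted sets are rescaled in time so
the limit-cycle period is 24 h before any stochastic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .models import (LeakageConfig, ModelSpec, NO_LEAKAGE, NO_PERTURBATION,
                     PerturbationConfig, build_model, compile_model,
                     rhs_function)

#: Table of search ranges per slot class (log10-uniform for rates/thresholds).
SEARCH_RANGES = {
    "gamma": (0.01, 10.0),
    "gamma_deg": (1.0, 1000.0),
    "kappa": (1.0, 1000.0),
}
HILL_N_RANGE = (2, 8)            # inclusive, integers
TARGET_PERIOD = 24.0             # hr
REGULARITY_TOL = 0.05            # max consecutive-cycle relative change
MIN_CYCLES = 11                  # > 10 complete cycles
DEFAULT_T_END = 2000.0           # hr, screening horizon
DEFAULT_DT = 0.2                 # hr, screening record step
PEAK_PROMINENCE_FRAC = 0.01      # of p_max


@dataclass
class ParameterSet:
    """One sampled realization of all rate constants and Hill parameters."""

    model_id: str
    values: dict[str, float]
    seed: Optional[int] = None
    period: Optional[float] = None      # current limit-cycle period, hr
    period_prescale: Optional[float] = None

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass
class Trajectory:
    """State series on a uniform recording grid."""

    times: np.ndarray                    # hr
    values: np.ndarray                   # (n_times, n_species)
    species: tuple[str, ...]
    kind: str = "deterministic"          # or "stochastic"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]


@dataclass
class CycleStats:
    """Per-species peak times, periods, amplitudes and their relative
    consecutive-cycle changes (|x1-x2| / min(x1,x2))."""

    peak_times: dict[str, np.ndarray]
    peak_values: dict[str, np.ndarray]
    periods: dict[str, np.ndarray]
    amplitudes: dict[str, np.ndarray]

    @staticmethod
    def _rel_change(x: np.ndarray) -> np.ndarray:
        if len(x) < 2:
            return np.empty(0)
        lo = np.minimum(x[:-1], x[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(lo > 0, np.abs(np.diff(x)) / lo, np.inf)

    def rel_period_change(self, sp: str) -> np.ndarray:
        return self._rel_change(self.periods[sp])

    def rel_amplitude_change(self, sp: str) -> np.ndarray:
        return self._rel_change(self.amplitudes[sp])


def sample_parameters(model_id: str, rng: np.random.Generator,
                      seed: Optional[int] = None) -> ParameterSet:
    """Draw one parameter set from the search ranges for ``model_id``."""
    spec = build_model(model_id)
    values: dict[str, float] = {}
    for slot, cls in spec.sampled_slots().items():
        if cls == "n":
            values[slot] = float(rng.integers(HILL_N_RANGE[0], HILL_N_RANGE[1] + 1))
        elif cls == "rho":
            values[slot] = float(rng.uniform(0.0, 1.0))
        else:
            lo, hi = SEARCH_RANGES[cls]
            values[slot] = float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))
    return ParameterSet(model_id, values, seed=seed)


def integrate_ode(model: ModelSpec, params: ParameterSet | Mapping[str, float],
                  t_end: float, dt_record: float = DEFAULT_DT,
                  leakage: LeakageConfig = NO_LEAKAGE,
                  perturbation: PerturbationConfig = NO_PERTURBATION,
                  y0: Optional[np.ndarray] = None,
                  rtol: float = 1e-6, atol: float = 1e-3,
                  record_from: float = 0.0) -> Trajectory:
    """Integrate the deterministic model on a uniform grid (LSODA).

    The default initial condition is 10% of the maximal steady state (100)
    for every species.  ``record_from`` starts the recording grid late (the
    integration still covers [0, t_end]).  Raises ``RuntimeError`` on
    integrator failure so the caller can discard the parameter set.
    """
    values = params.values if isinstance(params, ParameterSet) else params
    cm = compile_model(model, values, leakage, perturbation)
    if y0 is None:
        y0 = np.full(cm.n_species, 0.1 * cm.p_max)
    times = np.arange(record_from, t_end + 0.5 * dt_record, dt_record)
    times = times[times <= t_end]
    sol = solve_ivp(rhs_function(cm), (0.0, float(t_end)), np.asarray(y0, float),
                    method="LSODA", t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(sol.t, np.clip(sol.y.T, 0.0, None), cm.species,
                      "deterministic")


def _refine_peak(t: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic interpolation of a grid local maximum at index i."""
    if i == 0 or i == len(v) - 1:
        return t[i], v[i]
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return t[i], v[i]
    d = 0.5 * (y0 - y2) / denom
    d = float(np.clip(d, -0.5, 0.5))
    dt = t[1] - t[0]
    return t[i] + d * dt, y1 - 0.25 * (y0 - y2) * d


def cycle_stats(traj: Trajectory, p_max: float = 1000.0,
                transient_frac: float = 0.2,
                skip_cycles: int = 5) -> CycleStats:
    """Detect peaks (prominence floor 1% of p_max, quadratic refinement) and
    build per-cycle period and amplitude series.

    The transient is excluded: peaks inside the first ``transient_frac`` of
    the window or among the first ``skip_cycles`` cycles are dropped,
    whichever cut removes more.
    """
    t_cut = traj.times[0] + transient_frac * (traj.times[-1] - traj.times[0])
    peak_times, peak_values, periods, amplitudes = {}, {}, {}, {}
    for k, sp in enumerate(traj.species):
        v = traj.values[:, k]
        idx, _ = find_peaks(v, prominence=PEAK_PROMINENCE_FRAC * p_max)
        keep = idx[traj.times[idx] >= t_cut]
        if len(idx) - len(keep) < skip_cycles:
            keep = idx[skip_cycles:]
        refined = np.array([_refine_peak(traj.times, v, i) for i in keep]) \
            if len(keep) else np.empty((0, 2))
        pt = refined[:, 0] if len(refined) else np.empty(0)
        pv = refined[:, 1] if len(refined) else np.empty(0)
        amps = np.array([pv[j] - v[keep[j]:keep[j + 1] + 1].min()
                         for j in range(len(keep) - 1)])
        # period fiducial: the upward mid-level crossing preceding each
        # peak.  Relaxation waveforms sit on a flat plateau for much of the
        # cycle, where the grid argmax wanders across the top by hours; the
        # rising edge is steep and pins the phase.
        crossings = []
        for j in range(1, len(keep)):
            lo = int(np.argmin(v[keep[j - 1]:keep[j] + 1])) + keep[j - 1]
            level = 0.5 * (v[lo] + v[keep[j]])
            seg = v[lo:keep[j] + 1]
            i = int(np.argmax(seg >= level)) + lo
            if i <= lo or v[i] == v[i - 1]:
                crossings.append(traj.times[i])
            else:
                f = (level - v[i - 1]) / (v[i] - v[i - 1])
                crossings.append(traj.times[i - 1] +
                                 f * (traj.times[i] - traj.times[i - 1]))
        peak_times[sp], peak_values[sp] = pt, pv
        periods[sp] = np.diff(np.asarray(crossings))
        amplitudes[sp] = amps
    return CycleStats(peak_times, peak_values, periods, amplitudes)


def is_regular_oscillation(stats: CycleStats) -> bool:
    """True iff every species shows >= 11 complete cycles with all
    consecutive-cycle relative changes of period and amplitude < 5%."""
    for sp in stats.periods:
        per = stats.periods[sp]
        amp = stats.amplitudes[sp]
        if len(per) < MIN_CYCLES or len(amp) < MIN_CYCLES - 1:
            return False
        if np.any(stats.rel_period_change(sp) >= REGULARITY_TOL):
            return False
        if np.any(stats.rel_amplitude_change(sp) >= REGULARITY_TOL):
            return False
    return True


def measure_period(stats: CycleStats, species: str = "X") -> float:
    per = stats.periods[species]
    if len(per) == 0:
        raise ValueError("no complete cycles detected")
    return float(np.mean(per))


def rescale_to_24h(params: ParameterSet, observed_period: float) -> ParameterSet:
    """Multiply every rate parameter by observed_period/24 so the rescaled
    limit cycle has a 24 h period; thresholds and Hill coefficients are
    untouched (beta is derived from gamma and rescales implicitly)."""
    if observed_period <= 0:
        raise ValueError("observed_period must be positive")
    factor = observed_period / TARGET_PERIOD
    spec = build_model(params.model_id)
    classes = spec.sampled_slots()
    values = {slot: (val * factor if classes[slot] in ("gamma", "gamma_deg") else val)
              for slot, val in params.values.items()}
    return ParameterSet(params.model_id, values, seed=params.seed,
                        period=TARGET_PERIOD, period_prescale=observed_period)


def screen_parameters(spec: ModelSpec, ps: ParameterSet,
                      t_short: float = 400.0, dt_short: float = 0.05,
                      t_long: float = DEFAULT_T_END, dt_long: float = 0.25,
                      ) -> Optional[float]:
    """Deterministic regularity screen for one sampled set.

    Returns the limit-cycle period (hr) when the set oscillates regularly,
    else ``None``.  The screen is two-stage: a short window on a fine grid
    catches the (common) fast oscillators, whose periods run well below an
    hour and would be aliased on any grid coarse enough for the full
    horizon; candidates too slow to complete >10 cycles in the short window
    are re-screened over the full ``t_long`` horizon.  Oscillators needing
    more than ``t_long`` for >10 post-transient cycles are rejected with it.
    """
    # stage 0: most draws settle to a fixed point quickly; reject them on a
    # cheap short run before paying for the full screening windows
    try:
        probe = integrate_ode(spec, ps, 120.0, dt_short)
    except RuntimeError:
        return None
    pstats = cycle_stats(probe, transient_frac=0.2, skip_cycles=0)
    tail = probe.values[int(0.75 * len(probe.times)):, 0]
    if all(len(pstats.peak_times[s]) == 0 for s in spec.species) and \
            tail.max() - tail.min() < PEAK_PROMINENCE_FRAC * 1000.0:
        return None
    try:
        traj = integrate_ode(spec, ps, t_short, dt_short)
    except RuntimeError:
        return None
    stats = cycle_stats(traj)
    per_x = stats.periods["X"]
    if len(per_x) >= MIN_CYCLES:
        t1 = float(np.median(per_x))
        if t1 < 40 * dt_short:  # under-resolved: re-record a fine window
            window = 14.0 * t1
            try:
                fine = integrate_ode(spec, ps, t_short, dt_record=t1 / 60.0,
                                     record_from=t_short - window)
            except RuntimeError:
                return None
            stats = cycle_stats(fine, transient_frac=0.0, skip_cycles=1)
            if len(stats.periods["X"]) < MIN_CYCLES:
                return None
        if is_regular_oscillation(stats):
            return measure_period(stats)
        return None
    # too few cycles in the short window: settled, or a slow oscillator
    x = traj.values[:, 0]
    tail = x[int(0.75 * len(x)):]
    if len(stats.peak_times["X"]) == 0 and tail.max() - tail.min() < \
            PEAK_PROMINENCE_FRAC * 1000.0:
        return None  # converged to a fixed point
    try:
        long_traj = integrate_ode(spec, ps, t_long, dt_long)
    except RuntimeError:
        return None
    stats = cycle_stats(long_traj)
    if is_regular_oscillation(stats):
        return measure_period(stats)
    return None


@dataclass
class SearchResult:
    sets: list[ParameterSet]
    n_attempts: int

    @property
    def acceptance_rate(self) -> float:
        return len(self.sets) / self.n_attempts if self.n_attempts else 0.0


def search_oscillating_sets(model_id: str, n_target: int,
                            rng: np.random.Generator | int,
                            t_end: float = DEFAULT_T_END,
                            max_attempts: Optional[int] = None) -> SearchResult:
    """Sample -> integrate -> screen until ``n_target`` accepted sets,
    each rescaled to a 24 h period; reproducible from the seed."""
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if max_attempts is None:
        max_attempts = 3000 * n_target
    spec = build_model(model_id)
    accepted: list[ParameterSet] = []
    attempts = 0
    while len(accepted) < n_target:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"exhausted {max_attempts} attempts with only "
                f"{len(accepted)}/{n_target} accepted sets for {model_id}")
        attempts += 1
        ps = sample_parameters(model_id, rng, seed=attempts)
        period = screen_parameters(spec, ps, t_long=t_end)
        if period is None:
            continue
        accepted.append(rescale_to_24h(ps, period))
    return SearchResult(accepted, attempts)


# ---------------------------------------------------------------------------
# serialization of accepted cohorts
# ---------------------------------------------------------------------------

def parameter_sets_to_frame(sets: Iterable[ParameterSet]) -> pd.DataFrame:
    rows = []
    for i, ps in enumerate(sets):
        row = {"set_id": i, "model_id": ps.model_id, "seed": ps.seed,
               "period": ps.period, "period_prescale": ps.period_prescale}
        row.update(ps.values)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_parameter_sets(df: pd.DataFrame) -> list[ParameterSet]:
    meta = {"set_id", "model_id", "seed", "period", "period_prescale"}
    sets = []
    for _, row in df.iterrows():
        values = {k: float(row[k]) for k in df.columns
                  if k not in meta and pd.notna(row[k])}
        sets.append(ParameterSet(str(row["model_id"]), values,
                                 seed=None if pd.isna(row.get("seed")) else int(row["seed"]),
                                 period=row.get("period"),
                                 period_prescale=row.get("period_prescale")))
    return sets
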