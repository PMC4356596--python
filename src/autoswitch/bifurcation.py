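"""Numerical bifurcation protocol: slow-drift sweeps, bistability and
limit-cycle detection, oscillation periods and phase durations, and
two-parameter regime maps.

The sweep technique augments the network with a very slow zeroth-order
source (up sweep) or saturating sink (down sweep) acting on the free monomer
pool of the drifted input, so that all other processes stay in pseudo steady
state while the input level crawls across the range; the system then tracks
stable steady states and stable limit cycles, which is exactly what a
hysteresis experiment measures.  Unstable branches are invisible to this
protocol by construction.  For rate-constant sweeps (which have no monomer
pool to drift) a stepped quasi-static continuation is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .network import ReactionNetwork
from .odesim import (
    Drift,
    MassActionSystem,
    ObservableSet,
    SimulationError,
    apply_stress,
    find_steady_state,
    simulate,
)

#: molecule type drifted for each input parameter
_INPUT_MOLECULES = {"ampk_star": "AMPK", "rapamycin_star": "rapa"}

#: default number of characteristic response times (1/u0) that the drift
#: takes to traverse the full sweep range
_DRIFT_RESPONSE_TIMES = 5000.0


class BifurcationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepConfig:
    """Configuration of one slow-drift sweep.

    ``k_eps`` (copies/cell/s) defaults to ``(hi - lo) * u0 / 5000``: the full
    range is traversed in 5,000 characteristic response times (1/u0 = 100 s
    nominally), slow enough that halving it moves branch values by well under
    1% (see :func:`check_drift_rate`).
    """

    param: str
    lo: float
    hi: float
    direction: str = "up"  # "up" | "down"
    k_eps: Optional[float] = None
    n_out: int = 4000
    settle: float = 3e5     # s of relaxation at the starting input
    rtol: float = 1e-6
    atol: float = 1e-3

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"unknown sweep direction {self.direction!r}")
        if not self.hi >= self.lo >= 0:
            raise ValueError("sweep range must satisfy 0 <= lo <= hi")

    def default_k_eps(self, params: dict[str, float]) -> float:
        span = max(self.hi - self.lo, 1.0)
        return span * params["u0"] / _DRIFT_RESPONSE_TIMES


@dataclass
class Sweep:
    """Raw sweep output: observable series against the drifting input level."""

    param: str
    direction: str
    input: np.ndarray        # current input level per sample (copies/cell)
    frac_ambra: np.ndarray
    frac_eif: np.ndarray
    t: np.ndarray
    k_eps: float
    warning: Optional[str] = None

    def branch(self, grid: np.ndarray) -> np.ndarray:
        """frac_AMBRA1_P interpolated on an input grid (for comparisons)."""
        order = np.argsort(self.input, kind="stable")
        return np.interp(grid, self.input[order], self.frac_ambra[order])


def slow_drift_sweep(network: ReactionNetwork, params: dict[str, float],
                     config: SweepConfig,
                     y_start: Optional[np.ndarray] = None) -> Sweep:
    """Sweep an input (or rate constant) across its range; record observables.

    A zero-width range degenerates to plain relaxation at the fixed input.
    """
    if config.param not in _INPUT_MOLECULES:
        if config.param not in params:
            raise BifurcationError(f"unknown sweep parameter {config.param!r}")
        return _stepped_sweep(network, params, config, y_start)

    k_eps = config.k_eps or config.default_k_eps(params)
    mtype = _INPUT_MOLECULES[config.param]
    weights = network.species_total(mtype)
    seed_idx = next(
        idx for idx, _ in network.seeds
        if len(network.species[idx].molecules) == 1
        and network.species[idx].molecules[0].type == mtype
    )

    start = config.lo if config.direction == "up" else config.hi
    p0 = dict(params)
    p0[config.param] = start
    if y_start is None:
        if config.settle > 0:
            y_start = simulate(network, p0, config.settle, n_points=2,
                               rtol=config.rtol, atol=config.atol).final_state()
        else:
            y_start = network.initial_state(p0)
    else:
        y_start = apply_stress(network, p0, y_start, **{
            {"ampk_star": "ampk_star", "rapamycin_star": "rapamycin_star"}[config.param]: start
        })

    if config.hi == config.lo:
        y_ss, _ = find_steady_state(network, p0, y0=y_start)
        f = ObservableSet(network)
        vals = f.evaluate(y_ss[None, :])
        names = f.names
        return Sweep(config.param, config.direction,
                     np.array([config.lo]),
                     np.array([vals[names.index("frac_AMBRA1_P"), 0]]),
                     np.array([vals[names.index("frac_EIF4EBP1_P"), 0]]),
                     np.array([0.0]), k_eps=0.0)

    mode = "source" if config.direction == "up" else "sink"
    drift = Drift(seed_idx, k_eps, mode=mode)
    duration = (config.hi - config.lo) / k_eps * (1.2 if mode == "source" else 2.0)

    target = config.hi if mode == "source" else config.lo

    def reached(t, y):
        return float(weights @ y) - target
    reached.terminal = True
    reached.direction = 1.0 if mode == "source" else -1.0

    traj = simulate(network, params, duration, y0=y_start, drift=drift,
                    n_points=config.n_out, rtol=config.rtol, atol=config.atol,
                    events=[reached])
    inputs = traj.y @ weights
    warning = None
    end = inputs[-1]
    span = config.hi - config.lo
    if mode == "sink" and end > config.lo + 0.02 * span:
        warning = f"down sweep stalled at input {end:.0f}"
    return Sweep(config.param, config.direction, inputs,
                 traj.observable("frac_AMBRA1_P"),
                 traj.observable("frac_EIF4EBP1_P"),
                 traj.t, k_eps, warning)


def _stepped_sweep(network: ReactionNetwork, params: dict[str, float],
                   config: SweepConfig,
                   y_start: Optional[np.ndarray]) -> Sweep:
    """Quasi-static continuation in a rate constant: relax at each of a
    sequence of values, carrying the state forward between steps."""
    n_steps = max(8, config.n_out // 100)
    values = np.linspace(config.lo, config.hi, n_steps)
    if config.direction == "down":
        values = values[::-1]
    p = dict(params)
    p[config.param] = values[0]
    y = (simulate(network, p, config.settle, n_points=2, rtol=config.rtol,
                  atol=config.atol).final_state()
         if y_start is None else np.asarray(y_start, float).copy())
    step_t = max(config.settle, 20.0 / max(params["u2"], 1e-12) / n_steps)
    inputs, ambra, eif, times = [], [], [], []
    t0 = 0.0
    pts = max(20, config.n_out // n_steps)
    for v in values:
        p[config.param] = v
        traj = simulate(network, p, step_t, y0=y, n_points=pts,
                        rtol=config.rtol, atol=config.atol)
        y = traj.final_state()
        keep = traj.t >= 0.5 * step_t  # discard the re-equilibration half
        inputs.append(np.full(keep.sum(), v))
        ambra.append(traj.observable("frac_AMBRA1_P")[keep])
        eif.append(traj.observable("frac_EIF4EBP1_P")[keep])
        times.append(traj.t[keep] + t0)
        t0 += step_t
    return Sweep(config.param, config.direction, np.concatenate(inputs),
                 np.concatenate(ambra), np.concatenate(eif),
                 np.concatenate(times), k_eps=0.0)


def check_drift_rate(network: ReactionNetwork, params: dict[str, float],
                     config: SweepConfig, grid_n: int = 50) -> tuple[Sweep, float]:
    """Self-consistency check: run the sweep at k_eps and k_eps/2 and report
    the largest branch discrepancy (fraction units) on a common grid."""
    k = config.k_eps or config.default_k_eps(params)
    cfg_half = SweepConfig(config.param, config.lo, config.hi, config.direction,
                           k_eps=k / 2, n_out=config.n_out,
                           settle=config.settle, rtol=config.rtol,
                           atol=config.atol)
    cfg_full = SweepConfig(config.param, config.lo, config.hi, config.direction,
                           k_eps=k, n_out=config.n_out, settle=config.settle,
                           rtol=config.rtol, atol=config.atol)
    s1 = slow_drift_sweep(network, params, cfg_full)
    s2 = slow_drift_sweep(network, params, cfg_half)
    grid = np.linspace(config.lo, config.hi, grid_n)
    dev = float(np.max(np.abs(s1.branch(grid) - s2.branch(grid))))
    return s1, dev


# ---------------------------------------------------------------------------
# Bistability
# ---------------------------------------------------------------------------


def detect_bistability(up: Sweep, down: Sweep, threshold: float = 0.2,
                       grid_n: int = 400) -> list[tuple[float, float]]:
    """Input intervals where the up and down sweeps disagree by more than
    ``threshold`` in frac_AMBRA1_P (hysteresis loops).  Empty when
    monostable."""
    lo = max(up.input.min(), down.input.min())
    hi = min(up.input.max(), down.input.max())
    if hi <= lo:
        return []
    grid = np.linspace(lo, hi, grid_n)
    diff = np.abs(up.branch(grid) - down.branch(grid))
    mask = diff > threshold
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = grid[i]
        elif not flag and start is not None:
            intervals.append((start, grid[i - 1]))
            start = None
    if start is not None:
        intervals.append((start, grid[-1]))
    return intervals


# ---------------------------------------------------------------------------
# Limit cycles at fixed inputs
# ---------------------------------------------------------------------------


@dataclass
class LimitCycle:
    """Asymptotic classification at fixed inputs."""

    oscillating: bool
    label: str               # translation | autophagy | oscillatory | undetermined
    env_min: float
    env_max: float
    period: Optional[float]  # s, None unless oscillating
    mean: float
    t: np.ndarray = field(repr=False, default=None)
    series: np.ndarray = field(repr=False, default=None)

    @property
    def amplitude(self) -> float:
        return self.env_max - self.env_min


def _window_metrics(t: np.ndarray, x: np.ndarray, amp_thresh: float):
    amp = float(x.max() - x.min())
    prominence = max(0.3 * amp, 0.003)
    peaks, _ = find_peaks(x, prominence=prominence)
    period = None
    if len(peaks) >= 2:
        if amp >= 0.05:
            mid = 0.5 * (x.max() + x.min())
            above = x > mid
            up = np.nonzero(~above[:-1] & above[1:])[0]
            if len(up) >= 2:
                # linear-interpolated crossing times
                tc = t[up] + (mid - x[up]) / (x[up + 1] - x[up]) * (t[up + 1] - t[up])
                period = float(np.mean(np.diff(tc)))
        if period is None:
            period = float(np.mean(np.diff(t[peaks])))
    oscillating = amp > amp_thresh and len(peaks) >= 2
    return oscillating, amp, period, len(peaks)


def detect_limit_cycle(network: ReactionNetwork, params: dict[str, float],
                       ampk_star: float, rapamycin_star: float,
                       base_state: Optional[np.ndarray] = None,
                       window: float = 1.44e5,
                       transient: float = 1.44e5,
                       amp_thresh: float = 0.01,
                       max_windows: int = 5,
                       n_points: int = 1200,
                       rtol: float = 1e-6, atol: float = 1e-3) -> LimitCycle:
    """Classify the attractor at fixed inputs.

    Integrates a transient (default 40 h, discarded), then analysis windows
    of 40 h until two consecutive windows agree on the classification (and,
    when oscillating, on the period within 5%).  Oscillation criterion:
    frac_AMBRA1_P peak-to-trough exceeds ``amp_thresh`` with at least two
    detected peaks.  The period is the mean mid-level crossing interval,
    falling back to the mean peak spacing for small-amplitude cycles.
    """
    p = dict(params)
    p["ampk_star"] = ampk_star
    p["rapamycin_star"] = rapamycin_star
    if base_state is None:
        y = network.initial_state(p)
    else:
        y = apply_stress(network, p, base_state, ampk_star=ampk_star,
                         rapamycin_star=rapamycin_star)
    if transient > 0:
        y = simulate(network, p, transient, y0=y, n_points=2,
                     rtol=rtol, atol=atol).final_state()

    prev = None
    for _ in range(max_windows):
        traj = simulate(network, p, window, y0=y, n_points=n_points,
                        rtol=rtol, atol=atol)
        y = traj.final_state()
        x = traj.observable("frac_AMBRA1_P")
        osc, amp, period, n_peaks = _window_metrics(traj.t, x, amp_thresh)
        cur = (osc, period)
        if prev is not None:
            p_osc, p_period = prev
            agree = osc == p_osc
            if agree and osc and period and p_period:
                agree = abs(period - p_period) / p_period < 0.05
            if agree:
                label = "oscillatory" if osc else (
                    "autophagy" if x.mean() > 0.5 else "translation")
                return LimitCycle(osc, label, float(x.min()), float(x.max()),
                                  period if osc else None, float(x.mean()),
                                  t=traj.t, series=x)
        prev = cur
    return LimitCycle(False, "undetermined", float(x.min()), float(x.max()),
                      None, float(x.mean()), t=traj.t, series=x)


def measure_phase_durations(t: np.ndarray, x: np.ndarray,
                            level: float = 0.5) -> tuple[float, float]:
    """Mean autophagy-phase and translation-phase durations of an oscillating
    frac_AMBRA1_P series.

    The autophagy (translation) phase is the part of each cycle spent above
    (below) ``level``; the two durations sum to the period.  Raises
    :class:`BifurcationError` unless at least two full cycles cross the
    level.
    """
    above = x > level
    up = np.nonzero(~above[:-1] & above[1:])[0]
    down = np.nonzero(above[:-1] & ~above[1:])[0]
    if len(up) < 2 or len(down) < 2:
        raise BifurcationError("series does not oscillate across the level")

    def cross(idx):
        return t[idx] + (level - x[idx]) / (x[idx + 1] - x[idx]) * (t[idx + 1] - t[idx])

    t_up, t_down = cross(up), cross(down)
    # pair each up-crossing with the next down-crossing and vice versa
    auto_durs, trans_durs = [], []
    for tu in t_up:
        nxt = t_down[t_down > tu]
        if nxt.size:
            auto_durs.append(nxt[0] - tu)
    for td in t_down:
        nxt = t_up[t_up > td]
        if nxt.size:
            trans_durs.append(nxt[0] - td)
    if not auto_durs or not trans_durs:
        raise BifurcationError("could not pair level crossings")
    return float(np.mean(auto_durs)), float(np.mean(trans_durs))


# ---------------------------------------------------------------------------
# Windowed regime labeling along a sweep
# ---------------------------------------------------------------------------


def label_sweep_windows(sweep: Sweep, n_windows: int = 40,
                        amp_thresh: float = 0.01,
                        jump_thresh: float = 0.2) -> tuple[np.ndarray, list[str]]:
    """Partition a sweep into input bins and label each bin.

    Labels: ``translation`` / ``autophagy`` (quiet, mean below/above 0.5),
    ``oscillatory`` (repeated peaks with peak-to-trough above ``amp_thresh``),
    or ``transition`` (a single large excursion — a jump between branches or
    a cycle slower than the bin, left unclassified).
    """
    lo, hi = float(sweep.input.min()), float(sweep.input.max())
    edges = np.linspace(lo, hi, n_windows + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    labels: list[str] = []
    for k in range(n_windows):
        m = (sweep.input >= edges[k]) & (sweep.input <= edges[k + 1])
        x = sweep.frac_ambra[m]
        t = sweep.t[m]
        if x.size < 5:
            labels.append("transition")
            continue
        osc, amp, _, _ = _window_metrics(t, x, amp_thresh)
        if osc:
            labels.append("oscillatory")
        elif amp > jump_thresh:
            labels.append("transition")
        else:
            labels.append("autophagy" if x.mean() > 0.5 else "translation")
    return centers, labels


# ---------------------------------------------------------------------------
# Two-parameter regime maps
# ---------------------------------------------------------------------------


@dataclass
class Diagram2D:
    """Regime labels on a (x input) x (y parameter) grid."""

    xparam: str
    yparam: str
    x_centers: np.ndarray
    y_values: np.ndarray
    labels: list[list[str]]  # labels[y][x]

    def count(self, label: str, row: Optional[int] = None) -> int:
        rows = self.labels if row is None else [self.labels[row]]
        return sum(lab == label for r in rows for lab in r)

    def to_dict(self) -> dict:
        return {
            "xparam": self.xparam,
            "yparam": self.yparam,
            "x_centers": [float(v) for v in self.x_centers],
            "y_values": [float(v) for v in self.y_values],
            "labels": self.labels,
        }


def two_param_diagram(network: ReactionNetwork, params: dict[str, float],
                      xparam: str, xlo: float, xhi: float, nx: int,
                      yparam: str, y_values: Sequence[float],
                      amp_thresh: float = 0.01,
                      sweep_kwargs: Optional[dict] = None) -> Diagram2D:
    """Regime map built as a stack of 1D up/down sweeps.

    For each value of ``yparam`` the input ``xparam`` is swept up and down;
    each grid cell is labeled ``oscillatory`` if either sweep oscillates
    there, ``bistable`` if the sweeps disagree by more than 0.2 while quiet,
    else ``translation``/``autophagy`` by the mean level.  Cells where only a
    branch jump is seen inherit the label of the mean.  Labels are exhaustive
    and mutually exclusive per cell, and the construction is deterministic.
    """
    sweep_kwargs = sweep_kwargs or {}
    x_centers = None
    labels: list[list[str]] = []
    for yv in y_values:
        p = dict(params)
        p[yparam] = float(yv)
        up = slow_drift_sweep(network, p, SweepConfig(xparam, xlo, xhi, "up",
                                                      **sweep_kwargs))
        down = slow_drift_sweep(network, p, SweepConfig(xparam, xlo, xhi, "down",
                                                        **sweep_kwargs))
        centers, lab_up = label_sweep_windows(up, nx, amp_thresh)
        _, lab_down = label_sweep_windows(down, nx, amp_thresh)
        grid = centers
        bu, bd = up.branch(grid), down.branch(grid)
        row: list[str] = []
        for k in range(nx):
            if "oscillatory" in (lab_up[k], lab_down[k]):
                row.append("oscillatory")
            elif abs(bu[k] - bd[k]) > 0.2:
                row.append("bistable")
            else:
                row.append("autophagy" if 0.5 * (bu[k] + bd[k]) > 0.5 else
                           "translation")
        labels.append(row)
        x_centers = centers
    return Diagram2D(xparam, yparam, x_centers, np.asarray(y_values, float), labels)
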