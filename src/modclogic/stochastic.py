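"""Continuous-time stochastic simulation of logical networks (MaBoSS-style).

The asynchronous transitions of the logical network are given exponential
clocks: a component whose rule points above its current level jumps up one
level with its ``rate_up``, below with ``rate_down`` (all rates default to 1
per time unit).  Trajectories are sampled with the Gillespie algorithm and
binned on a uniform time grid; stable states are absorbing.  Mean occupancy
curves of marker combinations reproduce the cell-commitment read-out of the
moDC study (probability of each ON/OFF pattern of selected markers over
time, averaged over the ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import LogicalNetwork, NetworkError, State


@dataclass
class RateSpec:
    """Per-component up/down transition rates (1/time); default 1.0."""

    rate_up: dict[str, float] = field(default_factory=dict)
    rate_down: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.rate_up, self.rate_down):
            for name, r in d.items():
                if not r > 0:
                    raise NetworkError(f"rate for {name} must be strictly positive")

    def rates_for(self, network: LogicalNetwork) -> tuple[np.ndarray, np.ndarray]:
        up = np.ones(len(network.components))
        down = np.ones(len(network.components))
        for name, r in self.rate_up.items():
            up[network.index[name]] = r
        for name, r in self.rate_down.items():
            down[network.index[name]] = r
        return up, down


@dataclass
class TrajectoryEnsemble:
    """Grid-binned trajectories of a CTMC simulation."""

    network: LogicalNetwork
    time_grid: np.ndarray  # increasing, from 0 to t_max
    grid_states: np.ndarray  # (n_runs, n_grid, n_components) int8
    n_runs: int
    seed: int | None = None

    def occupancy(self, state: State) -> np.ndarray:
        """P(exactly this state) at each grid time."""
        target = np.asarray(state, dtype=np.int8)
        return (self.grid_states == target).all(axis=2).mean(axis=0)

    def terminal_states(self) -> np.ndarray:
        return self.grid_states[:, -1, :]


def simulate_ctmc(
    network: LogicalNetwork,
    initial: State,
    t_max: float = 50.0,
    n_runs: int = 1000,
    rates: RateSpec | None = None,
    seed: int | None = None,
    n_grid: int = 200,
) -> TrajectoryEnsemble:
    """Gillespie sampling of the asynchronous CTMC; reproducible given seed."""
    if t_max <= 0:
        raise NetworkError("t_max must be > 0")
    if n_runs < 1:
        raise NetworkError("n_runs must be >= 1")
    network.check_state(initial)
    up, down = (rates or RateSpec()).rates_for(network)
    rng = np.random.default_rng(seed)
    n_comp = len(network.components)
    time_grid = np.linspace(0.0, t_max, n_grid)
    grid_states = np.empty((n_runs, n_grid, n_comp), dtype=np.int8)
    targets = network._targets

    for run in range(n_runs):
        state = list(initial)
        t = 0.0
        g = 0
        while g < n_grid:
            tstate = tuple(state)
            moves = []
            props = []
            for i in range(n_comp):
                tgt = targets[i](tstate)
                if tgt > state[i]:
                    moves.append((i, 1))
                    props.append(up[i])
                elif tgt < state[i]:
                    moves.append((i, -1))
                    props.append(down[i])
            if not moves:  # absorbed at a stable state
                grid_states[run, g:, :] = state
                break
            total = float(np.sum(props))
            t_next = t + rng.exponential(1.0 / total)
            while g < n_grid and time_grid[g] <= t_next:
                grid_states[run, g, :] = state
                g += 1
            if g >= n_grid:
                break
            j = rng.choice(len(moves), p=np.asarray(props) / total)
            i, step = moves[j]
            state[i] += step
            t = t_next
    return TrajectoryEnsemble(network, time_grid, grid_states, n_runs, seed)


def marker_probability_curves(
    ensemble: TrajectoryEnsemble, markers: list[str]
) -> pd.DataFrame:
    """Tidy table (time, combination, probability) for ON/OFF marker patterns.

    A combination labels the markers at level >= 1, joined by "+" ("none"
    when all are off); probabilities sum to 1 at every grid time.
    """
    network = ensemble.network
    idx = []
    for m in markers:
        if m not in network.index:
            raise NetworkError(f"unknown marker {m!r}")
        idx.append(network.index[m])
    on = ensemble.grid_states[:, :, idx] >= 1  # (runs, grid, markers)
    powers = 1 << np.arange(len(idx))
    codes = (on * powers).sum(axis=2)  # (runs, grid)
    labels = {}
    for code in np.unique(codes):
        names = [markers[i] for i in range(len(idx)) if code & (1 << i)]
        labels[int(code)] = "+".join(names) if names else "none"
    rows = []
    n_runs = ensemble.n_runs
    for g, t in enumerate(ensemble.time_grid):
        vals, counts = np.unique(codes[:, g], return_counts=True)
        for v, c in zip(vals, counts):
            rows.append((float(t), labels[int(v)], c / n_runs))
    return pd.DataFrame(rows, columns=["time", "combination", "probability"])


def curves_to_tsv(curves: pd.DataFrame, ensemble: TrajectoryEnsemble, path) -> None:
    """Write curves as tidy TSV with provenance columns (n_runs, seed)."""
    out = curves.copy()
    out["n_runs"] = ensemble.n_runs
    out["seed"] = ensemble.seed if ensemble.seed is not None else ""
    out.to_csv(path, sep="\t", index=False)


QUIESCENT_ON = ("IRF8", "FOS", "AP1", "CREB", "ELK4")


def quiescent_monocyte_state(network: LogicalNetwork, csf2: int, il4: int) -> State:
    """Quiescent monocyte initial condition: IRF8, FOS, AP1, CREB, ELK4 ON.

    All other components start at 0, with the CSF2/IL4 inputs set to the
    scenario under study.
    """
    levels = [0] * len(network.components)
    for name in QUIESCENT_ON + ("CSF2", "IL4"):
        if name not in network.index:
            raise NetworkError(f"network lacks required component {name!r}")
    for name in QUIESCENT_ON:
        levels[network.index[name]] = 1
    levels[network.index["CSF2"]] = csf2
    levels[network.index["IL4"]] = il4
    state = tuple(levels)
    network.check_state(state)
    return state
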