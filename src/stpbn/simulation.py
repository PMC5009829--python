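"""Trajectory iteration, attractor entry and pulse time-courses.

A deterministic n-node network revisits a state within 2ⁿ steps from any
initial condition, after which it cycles forever.  A trajectory therefore
decomposes into a transient prefix (possibly empty) followed by a periodic
attractor cycle: trajectories that start on the attractor show a single
periodic phase ("one-phase pulse"), all others a transient phase followed
by the periodic one ("two-phase pulse").  Per-node 0/1 time series of a
periodic trajectory are square waves with the attractor's period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TrajectoryError
from .network import BooleanNetwork, TransitionMatrix, transition_matrix_direct
from .stp import decode_state

__all__ = ["Trajectory", "simulate", "decompose_phases", "pulse_table"]


@dataclass(frozen=True)
class Trajectory:
    """A simulated state sequence with its phase annotation.

    ``states`` holds integrated-state indices including the initial state,
    so ``len(states) == steps + 1``.  ``transient`` and ``cycle`` are
    filled when the run is long enough to detect the revisit (``period``
    is ``None`` otherwise); ``transient`` is the prefix strictly before
    the first attractor state.
    """

    n: int
    states: tuple[int, ...]
    node_names: tuple[str, ...]
    transient: tuple[int, ...] | None
    cycle: tuple[int, ...] | None
    period: int | None

    @property
    def one_phase(self) -> bool | None:
        """True when the trajectory starts on its attractor (empty transient)."""
        if self.transient is None:
            return None
        return len(self.transient) == 0

    def per_node_series(self) -> np.ndarray:
        """0/1 array of shape (n, len(states)): row i is node i's time series."""
        out = np.empty((self.n, len(self.states)), dtype=np.int64)
        for t, s in enumerate(self.states):
            out[:, t] = decode_state(s, self.n)
        return out


def _resolve(net_or_L) -> tuple[TransitionMatrix, tuple[str, ...]]:
    if isinstance(net_or_L, BooleanNetwork):
        return transition_matrix_direct(net_or_L), net_or_L.nodes
    if isinstance(net_or_L, TransitionMatrix):
        names = tuple(f"x{i}" for i in range(1, net_or_L.n + 1))
        return net_or_L, names
    raise TypeError(f"expected BooleanNetwork or TransitionMatrix, got {type(net_or_L)}")


def _find_phases(states: Sequence[int]
                 ) -> tuple[tuple[int, ...], tuple[int, ...], int] | None:
    seen: dict[int, int] = {}
    for t, s in enumerate(states):
        if s in seen:
            t1 = seen[s]
            return tuple(states[:t1]), tuple(states[t1:t]), t - t1
        seen[s] = t
    return None


def simulate(net_or_L: BooleanNetwork | TransitionMatrix,
             initial: int | Sequence[int],
             steps: int | None = None) -> Trajectory:
    """Iterate the successor map from an initial state.

    ``initial`` is either a 1-based integrated-state index or an ordered
    0/1 node tuple.  The default ``steps`` of 2·2ⁿ + 1 guarantees the
    attractor is entered and traversed, so the phase annotation is always
    available; shorter runs may leave it as ``None``.
    """
    L, names = _resolve(net_or_L)
    n = L.n
    if isinstance(initial, (tuple, list)):
        from .stp import encode_state
        if len(initial) != n:
            raise ValueError(f"expected {n} bits, got {len(initial)}")
        start = encode_state(initial).index
    else:
        start = int(initial)
        if not 1 <= start <= L.num_states:
            raise ValueError(
                f"initial state index {start} out of range [1, {L.num_states}]")
    if steps is None:
        steps = 2 * L.num_states + 1
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    states = [start]
    for _ in range(steps):
        states.append(L.successor_of(states[-1]))
    phases = _find_phases(states)
    if phases is None:
        transient = cycle = period = None
    else:
        transient, cycle, period = phases
    return Trajectory(n=n, states=tuple(states), node_names=names,
                      transient=transient, cycle=cycle, period=period)


def decompose_phases(traj: Trajectory) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Split a trajectory into its transient prefix and periodic cycle.

    Raises :class:`~stpbn.errors.TrajectoryError` when the trajectory is
    too short to revisit a state (2ⁿ + 1 recorded transitions always
    suffice).
    """
    if traj.transient is not None and traj.cycle is not None:
        return traj.transient, traj.cycle
    phases = _find_phases(traj.states)
    if phases is None:
        raise TrajectoryError(
            f"trajectory of {len(traj.states)} states never revisits a state; "
            f"simulate at least 2^{traj.n} steps")
    return phases[0], phases[1]


def pulse_table(traj: Trajectory,
                node_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-node 0/1 time series as a DataFrame (one row per time step).

    Columns are the node names (high expression = 1); the index is the
    discrete time step.  CSV-serializable via ``DataFrame.to_csv``.
    """
    names = tuple(node_names) if node_names is not None else traj.node_names
    if len(names) != traj.n:
        raise ValueError(f"expected {traj.n} node names, got {len(names)}")
    data = traj.per_node_series().T
    frame = pd.DataFrame(data, columns=list(names))
    frame.index.name = "step"
    return frame
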