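"""Synchronous Boolean dynamics and exhaustive attractor enumeration.

States are integers: bit ``i`` of a state holds the value of node
``net.node_names[i]``.  With clamped nodes the engine enumerates only the
free-node subspace; attractor states always carry the clamp bits at their
clamped values.

The exhaustive search follows the block strategy: the full successor mapping
over the free-state space is materialized once with bit-parallel expression
evaluation, trajectories are fast-forwarded by iterated pointer jumping
(``J = J[J]`` squares the step count), and the surviving representative
states are resolved to canonical cycles with a vectorized Floyd walk.  The
result is exact — every initial state is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BooleanNetwork, NetworkError
from .expr import compile_expr

__all__ = [
    "Attractor",
    "Landscape",
    "CompiledNetwork",
    "step",
    "trajectory_to_attractor",
    "exhaustive_attractors",
    "attractors_of_states",
]

DEFAULT_FREE_NODE_CAP = 30
_BLOCK_BITS = 20  # successor map is built in blocks of 2**_BLOCK_BITS states


@dataclass(frozen=True)
class Attractor:
    """A cyclic state sequence, canonically rotated (smallest state first)."""

    states: tuple[int, ...]
    basin_size: int | None = None

    def __post_init__(self):
        if not self.states:
            raise ValueError("attractor needs at least one state")
        mn = min(range(len(self.states)), key=lambda i: self.states[i])
        if mn != 0:
            rotated = self.states[mn:] + self.states[:mn]
            object.__setattr__(self, "states", rotated)

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_cyclic(self) -> bool:
        return self.period > 1

    @property
    def key(self) -> int:
        """Canonical identity: the smallest state on the cycle."""
        return self.states[0]


@dataclass(frozen=True)
class Landscape:
    """Exhaustive attractor landscape over the free-state space."""

    net: BooleanNetwork
    attractors: tuple[Attractor, ...]
    free_node_count: int

    @property
    def total_states(self) -> int:
        return 1 << self.free_node_count

    @property
    def n_cyclic(self) -> int:
        return sum(1 for a in self.attractors if a.is_cyclic)

    def basin_total(self) -> int:
        return sum(a.basin_size for a in self.attractors)

    def to_dict(self) -> dict:
        """Structured dump (JSON-ready).  Bit order: bit i of each state
        integer holds node_names[i]."""
        return {
            "node_names": list(self.net.node_names),
            "clamps": dict(self.net.clamps),
            "free_node_count": self.free_node_count,
            "total_states": self.total_states,
            "attractors": [
                {"states": list(a.states), "period": a.period,
                 "basin_size": a.basin_size}
                for a in self.attractors],
        }

    def to_table(self):
        """Long-format table: one row per attractor state."""
        import pandas as pd
        rows = []
        names = self.net.node_names
        for aid, att in enumerate(self.attractors):
            for k, s in enumerate(att.states):
                row = {"attractor": aid, "period": att.period,
                       "basin_size": att.basin_size, "phase": k,
                       "state": s}
                row.update({n: (s >> i) & 1 for i, n in enumerate(names)})
                rows.append(row)
        return pd.DataFrame(rows)


class CompiledNetwork:
    """Bit-parallel evaluator for a network, reused across engine calls."""

    def __init__(self, net: BooleanNetwork):
        self.net = net
        names = net.node_names
        self.n = len(names)
        index = {name: i for i, name in enumerate(names)}
        self.funcs = [compile_expr(net.functions[name], index)
                      for name in names]
        self.clamp_idx = np.array(
            [index[n] for n in net.clamps], dtype=np.int64)
        self.clamp_vals = np.array(
            [net.clamps[n] for n in net.clamps], dtype=np.int64)
        self.free_idx = np.array(
            [i for i, n in enumerate(names) if n not in net.clamps],
            dtype=np.int64)
        self.n_free = len(self.free_idx)
        self.clamp_mask = int(sum(1 << int(i) for i in self.clamp_idx))
        self.clamp_bits = int(sum(int(v) << int(i) for i, v in
                                  zip(self.clamp_idx, self.clamp_vals)))
        self._state_dtype = np.int64

    # -- full-state batch operations -------------------------------------

    def apply_clamp_bits(self, states: np.ndarray) -> np.ndarray:
        if not len(self.clamp_idx):
            return states
        return (states & ~self.clamp_mask) | self.clamp_bits

    def step_batch(self, states: np.ndarray) -> np.ndarray:
        """One synchronous step on an array of full-state integers."""
        states = np.asarray(states, dtype=np.int64)
        env = [((states >> i) & 1).astype(bool) for i in range(self.n)]
        out = np.zeros(states.shape, dtype=np.int64)
        for i, f in enumerate(self.funcs):
            bit = f(env)
            if isinstance(bit, (bool, np.bool_)):
                if bit:
                    out |= 1 << i
            else:
                out |= bit.astype(np.int64) << i
        return self.apply_clamp_bits(out)

    # -- free-index space -------------------------------------------------

    def expand_free(self, free: np.ndarray) -> np.ndarray:
        """Free-space indices -> full-state integers (clamp bits set)."""
        free = np.asarray(free, dtype=np.int64)
        full = np.zeros(free.shape, dtype=np.int64)
        for j, i in enumerate(self.free_idx):
            full |= ((free >> j) & 1) << int(i)
        return full | self.clamp_bits

    def compress_free(self, full: np.ndarray) -> np.ndarray:
        """Full-state integers -> free-space indices."""
        full = np.asarray(full, dtype=np.int64)
        free = np.zeros(full.shape, dtype=np.int64)
        for j, i in enumerate(self.free_idx):
            free |= ((full >> int(i)) & 1) << j
        return free

    def free_successor_block(self, free_lo: int, free_hi: int,
                             out_dtype) -> np.ndarray:
        """Successor (in free-index space) of free states ``lo..hi-1``."""
        idx = np.arange(free_lo, free_hi, dtype=np.int64)
        env: list = [None] * self.n
        for j, i in enumerate(self.free_idx):
            env[int(i)] = ((idx >> j) & 1).astype(bool)
        for i, v in zip(self.clamp_idx, self.clamp_vals):
            env[int(i)] = np.bool_(v)  # numpy bool: `~` stays boolean
        succ = np.zeros(idx.shape, dtype=out_dtype)
        for j, i in enumerate(self.free_idx):
            bit = self.funcs[int(i)](env)
            if isinstance(bit, (bool, np.bool_)):
                if bit:
                    succ |= out_dtype(1 << j)
            else:
                succ |= bit.astype(out_dtype) << out_dtype(j)
        return succ


def _compiled(net) -> CompiledNetwork:
    return net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)


def step(net: BooleanNetwork | CompiledNetwork, state: int) -> int:
    """Synchronous update of a single full-state integer."""
    cn = _compiled(net)
    return int(cn.step_batch(np.array([state]))[0])


def trajectory_to_attractor(net: BooleanNetwork | CompiledNetwork,
                            state: int) -> tuple[Attractor, int]:
    """Follow the trajectory from ``state`` until it enters its cycle.

    Returns the canonical attractor and the transient length (synchronous
    steps from ``state`` to the first in-cycle state).
    """
    cn = _compiled(net)
    state = int(cn.apply_clamp_bits(np.array([state]))[0])
    seen: dict[int, int] = {}
    trail: list[int] = []
    s = state
    while s not in seen:
        seen[s] = len(trail)
        trail.append(s)
        s = step(cn, s)
    start = seen[s]
    cycle = tuple(trail[start:])
    return Attractor(cycle), start


def _floyd_cycle_states(cn: CompiledNetwork,
                        starts: np.ndarray) -> np.ndarray:
    """For each full-state in ``starts`` return one state on its cycle.

    Vectorized Floyd: advance tortoise by one step and hare by two until
    they meet; the meeting state lies on the trajectory's cycle.
    """
    tort = starts.astype(np.int64, copy=True)
    hare = cn.step_batch(tort)
    active = tort != hare
    guard = 0
    limit = (1 << min(cn.n_free, 62)) + 2
    while active.any():
        idx = np.nonzero(active)[0]
        t = cn.step_batch(tort[idx])
        h = cn.step_batch(cn.step_batch(hare[idx]))
        tort[idx] = t
        hare[idx] = h
        active[idx] = t != h
        guard += 1
        if guard > limit:  # pragma: no cover - safety net
            raise RuntimeError("cycle detection failed to terminate")
    return tort


def _canonical_cycle_min(cn: CompiledNetwork,
                         on_cycle: np.ndarray) -> np.ndarray:
    """Smallest state of the cycle through each given on-cycle state."""
    cur = cn.step_batch(on_cycle)
    best = np.minimum(on_cycle, cur)
    active = cur != on_cycle
    guard = 0
    limit = (1 << min(cn.n_free, 62)) + 2
    while active.any():
        idx = np.nonzero(active)[0]
        nxt = cn.step_batch(cur[idx])
        cur[idx] = nxt
        best[idx] = np.minimum(best[idx], nxt)
        active[idx] = nxt != on_cycle[idx]
        guard += 1
        if guard > limit:  # pragma: no cover - safety net
            raise RuntimeError("cycle walk failed to terminate")
    return best


def _walk_cycle(cn: CompiledNetwork, start: int) -> tuple[int, ...]:
    """Collect the full cycle through an on-cycle ``start`` state."""
    states = [start]
    s = step(cn, start)
    while s != start:
        states.append(s)
        s = step(cn, s)
    return tuple(states)


def attractors_of_states(net: BooleanNetwork | CompiledNetwork,
                         states) -> list[Attractor]:
    """Resolve the attractor reached from each of many initial states.

    Basin sizes are not computed (``basin_size=None``); duplicate cycles
    share one :class:`Attractor` instance.
    """
    cn = _compiled(net)
    arr = cn.apply_clamp_bits(np.asarray(states, dtype=np.int64))
    if arr.size == 0:
        return []
    on_cycle = _floyd_cycle_states(cn, arr)
    mins = _canonical_cycle_min(cn, on_cycle)
    cache: dict[int, Attractor] = {}
    out = []
    for m in mins:
        m = int(m)
        if m not in cache:
            cache[m] = Attractor(_walk_cycle(cn, m))
        out.append(cache[m])
    return out


def exhaustive_attractors(net: BooleanNetwork | CompiledNetwork, *,
                          free_node_cap: int = DEFAULT_FREE_NODE_CAP,
                          block_bits: int = _BLOCK_BITS,
                          max_jump_rounds: int | None = None) -> Landscape:
    """Enumerate every attractor and exact basin sizes over all
    ``2**free_node_count`` initial states.

    Deterministic: attractors are sorted by their smallest state encoding.
    """
    cn = _compiled(net)
    nf = cn.n_free
    if nf > free_node_cap:
        raise NetworkError(
            f"free-node count {nf} exceeds cap {free_node_cap}; "
            "clamp more nodes or raise free_node_cap explicitly")

    total = 1 << nf
    dtype = np.int32 if nf <= 30 else np.int64

    # 1. successor mapping in free-index space, built in blocks
    succ = np.empty(total, dtype=dtype)
    bsz = 1 << min(block_bits, nf)
    for lo in range(0, total, bsz):
        hi = min(lo + bsz, total)
        succ[lo:hi] = cn.free_successor_block(lo, hi, dtype)

    # 2. in-place pointer jumping with path compression: each round
    #    replaces J[s] by J[J[s]] chunk by chunk.  Because chunks already
    #    rewritten in this round may be read again, an entry can jump
    #    further than 2**round steps — harmless, since any forward state on
    #    the trajectory is an equally valid representative.  Rounds stop
    #    once a sample of trajectories stops coalescing; correctness does
    #    not depend on reaching the cycles (step 4 walks forward from
    #    wherever the jumps landed).
    if max_jump_rounds is None:
        max_jump_rounds = max(2 * nf, 4)
    J = succ
    del succ
    stride = max(1, total >> 16)
    prev_unique = -1
    stable = 0
    for _ in range(max_jump_rounds):
        for lo in range(0, total, bsz):
            hi = min(lo + bsz, total)
            J[lo:hi] = J[J[lo:hi]]
        sample_unique = len(np.unique(J[::stride]))
        if sample_unique == prev_unique:
            stable += 1
            if stable >= 2:
                break
        else:
            stable = 0
            prev_unique = sample_unique

    # 3. representative free-states and multiplicities via in-place sort +
    #    run-length encoding (avoids np.unique's full-size copy)
    J.sort()
    rep_chunks = [np.unique(J[lo:min(lo + bsz, total)])
                  for lo in range(0, total, bsz)]
    reps = np.unique(np.concatenate(rep_chunks))
    del rep_chunks
    counts = (np.searchsorted(J, reps, side="right")
              - np.searchsorted(J, reps, side="left"))
    del J

    # 4. resolve each representative to its canonical attractor
    full_reps = cn.expand_free(reps.astype(np.int64))
    atts = attractors_of_states(cn, full_reps)

    # 5. aggregate basin mass per attractor
    basin: dict[int, int] = {}
    att_by_key: dict[int, Attractor] = {}
    for att, cnt in zip(atts, counts):
        att_by_key[att.key] = att
        basin[att.key] = basin.get(att.key, 0) + int(cnt)

    final = tuple(
        Attractor(att_by_key[key].states, basin_size=basin[key])
        for key in sorted(att_by_key))
    return Landscape(net=cn.net, attractors=final, free_node_count=nf)
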