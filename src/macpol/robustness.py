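"""Robustness statistics: Derrida curves with regime classification and
per-rule sensitivity.

The Derrida procedure samples pairs of states at a controlled initial
Hamming distance, advances each by one synchronous step, and records the
mean normalized distance afterwards.  Pair sampling is stratified over all
initial distances 1..N so the curve covers the whole [0, 1] axis.

Rule sensitivity is the probability that flipping one uniformly chosen bit
of a random full state changes a node's update function output.  By default
the flipped bit ranges over all N nodes (so a constant rule scores 0 and a
copy-of-one-input rule scores 1/N); ``inputs_only=True`` restricts flips to
the rule's own input variables, the convention of common Boolean-network
toolkits (a copy rule then scores 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import CompiledNetwork
from .network import BooleanNetwork

__all__ = [
    "DerridaCurve",
    "SensitivityProfile",
    "derrida_curve",
    "classify_regime",
    "rule_sensitivity",
    "network_sensitivity",
]


@dataclass(frozen=True)
class DerridaCurve:
    #: (h_t, mean_h_t1, n_pairs) per initial-distance bin; h in [0, 1]
    points: tuple[tuple[float, float, int], ...]
    seed: int
    n_nodes: int

    def as_arrays(self):
        arr = np.array([(h, m) for h, m, _ in self.points])
        return arr[:, 0], arr[:, 1]

    def initial_slope(self) -> float:
        """Slope estimate at the origin: mean h(t+1) at distance 1 over 1/N."""
        for h, m, _ in self.points:
            if h > 0:
                return m / h
        raise ValueError("curve has no positive-distance bin")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.points, columns=["h_t", "mean_h_t1",
                                                  "n_pairs"])


@dataclass(frozen=True)
class SensitivityProfile:
    per_node: dict[str, float]
    n_samples: int
    seed: int

    @property
    def network_mean(self) -> float:
        return float(np.mean(list(self.per_node.values())))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            {"node": list(self.per_node), "sensitivity":
             list(self.per_node.values())})


def _random_states(rng: np.random.Generator, n_nodes: int,
                   size: int) -> np.ndarray:
    # draw bits column-wise to stay independent of node count word width
    out = np.zeros(size, dtype=np.int64)
    for i in range(n_nodes):
        out |= rng.integers(0, 2, size=size, dtype=np.int64) << i
    return out


def derrida_curve(net: BooleanNetwork | CompiledNetwork,
                  n_pairs: int = 10_000, seed: int = 0) -> DerridaCurve:
    """Mean one-step normalized Hamming distance per initial distance.

    ``n_pairs`` pairs are split as evenly as possible over the initial
    distances d = 1..N; each pair is a uniform random state plus a copy with
    d distinct random bits flipped.  The exact point (0, 0) is always
    included.
    """
    cn = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)
    n = cn.n
    rng = np.random.default_rng(seed)
    per_bin = np.full(n, n_pairs // n, dtype=int)
    per_bin[: n_pairs % n] += 1

    points = [(0.0, 0.0, 0)]
    for d, m in enumerate(per_bin, start=1):
        if m == 0:
            continue
        x1 = _random_states(rng, n, m)
        flip = np.zeros(m, dtype=np.int64)
        for j in range(m):
            bits = rng.choice(n, size=d, replace=False)
            flip[j] = int(np.bitwise_or.reduce(1 << bits.astype(np.int64)))
        x2 = x1 ^ flip
        y1 = cn.step_batch(x1)
        y2 = cn.step_batch(x2)
        diff = y1 ^ y2
        hamming = np.zeros(m, dtype=np.int64)
        for i in range(n):
            hamming += (diff >> i) & 1
        points.append((d / n, float(hamming.mean() / n), int(m)))
    return DerridaCurve(points=tuple(points), seed=seed, n_nodes=n)


def classify_regime(curve: DerridaCurve, alpha: float = 0.05) -> str:
    """Classify dynamics as ``ordered``, ``critical`` or ``chaotic``.

    Chi-squared goodness-of-fit of the observed mean distances against the
    identity line (expected = h_t), restricted to the bins before the first
    crossing of the identity line (excluding the trivial origin).  No
    significant deviation -> critical; a significant deficit -> ordered; a
    significant excess -> chaotic.
    """
    from scipy import stats

    obs, exp = [], []
    for h, m, npairs in curve.points:
        if h == 0.0:
            continue
        obs.append(m)
        exp.append(h)
        if len(obs) > 1 and m <= h:
            break  # first intersection with the identity line
    obs_a = np.asarray(obs)
    exp_a = np.asarray(exp)
    if not obs_a.any():
        return "ordered"
    # scale to a common total so the test compares shape, as in a
    # goodness-of-fit on binned frequencies
    scale = obs_a.sum() / exp_a.sum()
    stat, p = stats.chisquare(obs_a, exp_a * scale)
    if p >= alpha:
        return "critical"
    return "chaotic" if obs_a.sum() > exp_a.sum() else "ordered"


def rule_sensitivity(net: BooleanNetwork | CompiledNetwork, node: str,
                     n_samples: int = 50_000, seed: int = 0,
                     inputs_only: bool = False) -> float:
    """Fraction of random states whose one-bit flip changes ``node``'s rule
    output."""
    cn = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)
    n = cn.n
    idx = cn.net.node_names.index(node)
    f = cn.funcs[idx]
    rng = np.random.default_rng(seed)

    if inputs_only:
        from .expr import expr_variables
        pool = sorted(cn.net.index(v)
                      for v in expr_variables(cn.net.functions[node]))
        if not pool:
            return 0.0
        pool = np.array(pool)
    else:
        pool = np.arange(n)

    x = _random_states(rng, n, n_samples)
    flips = rng.choice(pool, size=n_samples)
    x2 = x ^ (np.int64(1) << flips.astype(np.int64))

    def evaluate(states):
        env = [((states >> i) & 1).astype(bool) for i in range(n)]
        val = f(env)
        if isinstance(val, (bool, np.bool_)):
            return np.full(states.shape, bool(val))
        return val

    return float(np.mean(evaluate(x) != evaluate(x2)))


def network_sensitivity(net: BooleanNetwork | CompiledNetwork,
                        n_samples: int = 50_000, seed: int = 0,
                        inputs_only: bool = False) -> SensitivityProfile:
    """Per-node rule sensitivity plus the network mean."""
    cn = net if isinstance(net, CompiledNetwork) else CompiledNetwork(net)
    rng = np.random.default_rng(seed)
    per_node = {}
    for node in cn.net.node_names:
        sub_seed = int(rng.integers(0, 2**32))
        per_node[node] = rule_sensitivity(cn, node, n_samples=n_samples,
                                          seed=sub_seed,
                                          inputs_only=inputs_only)
    return SensitivityProfile(per_node=per_node, n_samples=n_samples,
                              seed=seed)
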