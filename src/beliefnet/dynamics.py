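"""Glauber belief dynamics and the exact Boltzmann configuration distribution.

A single-node update proposes a new grid value for one belief uniformly at
random and accepts it with the heat-bath probability

    P(accept) = 1 / (1 + exp(beta * dE))

where dE is the change in the configuration dissonance H(b).  With the
default ``node_sum`` energy convention, H(b) = sum_i H_i, so flipping node i
changes the configuration energy by exactly twice the node-level change
dH_i (every pairwise term involving i appears in both H_i and H_j).  The
chain is then in detailed balance with the Boltzmann law
P(b) proportional to exp(-beta * H(b)), which :func:`boltzmann_exact`
enumerates on small grids.  The ``pairwise`` convention counts each pair
once (dE = dH_i), which is the same family of stationary laws at twice the
interdependence.

At beta = 0 every proposal is accepted with probability exactly 1/2 and the
node marginals are uniform on the grid: beliefs drift randomly with no gain
in consistency.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .dissonance import NODE_SUM, network_dissonance

__all__ = [
    "DynamicsConfig",
    "ExactDistribution",
    "node_dissonance",
    "delta_H",
    "acceptance_probability",
    "glauber_step",
    "simulate_chain",
    "sample_state_counts",
    "boltzmann_exact",
    "total_variation",
]

DISTANCE = "distance"
PRODUCT = "product"
PAIRWISE = "pairwise"

_ENERGY_FACTOR = {NODE_SUM: 2.0, PAIRWISE: 1.0}


@dataclass
class DynamicsConfig:
    """Parameters of the single-node update chain.

    beta is the network interdependence (inverse-temperature analogue);
    proposal_grid the ordered belief states in [-1, 1]; sweeps the number of
    full passes over the nodes.
    """

    beta: float
    proposal_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(-1.0, 1.0, 7)
    )
    sweeps: int = 100
    seed: int = 0
    energy_convention: str = NODE_SUM
    schedule: str = "sequential"  # or "random"

    def __post_init__(self) -> None:
        self.proposal_grid = np.asarray(self.proposal_grid, dtype=float)
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        g = self.proposal_grid
        if g.size < 2 or np.any(np.diff(g) <= 0) or g.min() < -1 or g.max() > 1:
            raise ValueError("proposal grid must be strictly increasing within [-1, 1]")
        if self.energy_convention not in _ENERGY_FACTOR:
            raise ValueError(f"unknown energy convention {self.energy_convention!r}")


def node_dissonance(b, omega, i: int, convention: str = DISTANCE) -> float:
    """Node-level dissonance H_i under the distance or Ising-product form."""
    b = np.asarray(b, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if convention == DISTANCE:
        return float(np.sum(omega[i] * np.abs(b[i] - b)))
    if convention == PRODUCT:
        return float(-np.sum(omega[i] * b[i] * b))  # omega[i, i] == 0
    raise ValueError(f"unknown convention {convention!r}")


def delta_H(b, omega, i: int, b_new: float, convention: str = DISTANCE) -> float:
    """Change in node i's dissonance when b_i moves to ``b_new`` (O(K) local)."""
    b = np.asarray(b, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if not -1.0 - 1e-12 <= b_new <= 1.0 + 1e-12:
        raise ValueError("b_new must lie in [-1, 1]")
    if convention == DISTANCE:
        return float(np.sum(omega[i] * (np.abs(b_new - b) - np.abs(b[i] - b))))
    if convention == PRODUCT:
        return float(-np.sum(omega[i] * (b_new - b[i]) * b))
    raise ValueError(f"unknown convention {convention!r}")


def acceptance_probability(beta: float, delta_energy: float) -> float:
    """Heat-bath acceptance 1 / (1 + exp(beta * dE)); exactly 1/2 at beta or dE = 0."""
    x = beta * delta_energy
    if x >= 0:
        return 1.0 / (1.0 + math.exp(min(x, 700.0)))
    return 1.0 - 1.0 / (1.0 + math.exp(max(-x, -700.0)))


def glauber_step(
    b: np.ndarray,
    omega: np.ndarray,
    config: DynamicsConfig,
    i: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One single-node update: uniform grid proposal, heat-bath acceptance.

    Returns the (possibly unchanged) belief vector; the input is not
    modified.  The energy change is the configuration-level dE (under
    ``node_sum`` that is 2 x the node-level dH_i).
    """
    b = np.asarray(b, dtype=float).copy()
    g = config.proposal_grid
    candidates = g[g != b[i]]
    if candidates.size == 0:
        return b
    b_new = candidates[rng.integers(candidates.size)]
    de = _ENERGY_FACTOR[config.energy_convention] * delta_H(b, omega, i, b_new)
    if rng.random() < acceptance_probability(config.beta, de):
        b[i] = b_new
    return b


def _sweep_matrix(
    B: np.ndarray,
    omega: np.ndarray,
    grid: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    energy_convention: str = NODE_SUM,
) -> None:
    """One in-place Glauber sweep over all nodes, vectorized across persons.

    Current values need not lie on the grid (e.g. after an intervention
    shift); proposals always come from the grid.
    """
    n, k = B.shape
    factor = _ENERGY_FACTOR[energy_convention]
    for i in range(k):
        cur = B[:, i]
        # uniform proposal from grid values != current; off-grid values
        # (possible after an intervention shift) propose over the full grid
        r = rng.integers(0, grid.size - 1, size=n)
        full = rng.integers(0, grid.size, size=n)
        pos = np.clip(np.searchsorted(grid, cur), 0, grid.size - 1)
        on_grid = np.isclose(grid[pos], cur)
        prop_idx = np.where(on_grid, r + (r >= pos), full)
        bp = grid[prop_idx]
        w = omega[i]
        dh = (np.abs(bp[:, None] - B) - np.abs(cur[:, None] - B)) @ w
        acc = rng.random(n) < 1.0 / (1.0 + np.exp(np.clip(factor * beta * dh, -700, 700)))
        B[acc, i] = bp[acc]


def simulate_chain(
    b0, omega, config: DynamicsConfig
) -> np.ndarray:
    """Run the chain and return snapshots: (sweeps + 1) x K, row 0 = b0.

    Within a sweep nodes update in fixed (or seeded random) order; the whole
    trajectory is reproducible from the config seed.
    """
    b0 = np.asarray(b0, dtype=float)
    omega = np.asarray(omega, dtype=float)
    k = b0.size
    rng = np.random.default_rng(config.seed)
    traj = np.empty((config.sweeps + 1, k))
    traj[0] = b0
    b = b0.copy()
    for s in range(config.sweeps):
        order = (
            range(k)
            if config.schedule == "sequential"
            else rng.permutation(k)
        )
        for i in order:
            b = glauber_step(b, omega, config, i, rng)
        traj[s + 1] = b
    return traj


def sample_state_counts(
    omega,
    config: DynamicsConfig,
    n_sweeps: int,
    burn_in: int = 0,
    b0=None,
) -> np.ndarray:
    """Visit counts over grid^K configurations, one count per post-burn-in sweep.

    A memory-light fast path for long chains: maintains the mixed-radix
    state index incrementally instead of storing the trajectory.  State
    ordering matches :func:`boltzmann_exact` (node 0 most significant).
    """
    omega = np.asarray(omega, dtype=float)
    grid = config.proposal_grid
    g, k = grid.size, omega.shape[0]
    rng = np.random.default_rng(config.seed)
    if b0 is None:
        idx = rng.integers(0, g, size=k)
    else:
        idx = np.array([int(np.argmin(np.abs(grid - v))) for v in np.asarray(b0)])
    b = [float(grid[t]) for t in idx]
    idx = [int(t) for t in idx]
    w_rows = [list(map(float, omega[i])) for i in range(k)]
    grid_l = list(map(float, grid))
    place = [g ** (k - 1 - i) for i in range(k)]
    code = sum(idx[i] * place[i] for i in range(k))
    factor_beta = _ENERGY_FACTOR[config.energy_convention] * config.beta

    counts = np.zeros(g**k, dtype=np.int64)
    total = burn_in + n_sweeps
    n_updates = total * k
    props = rng.integers(0, g - 1, size=n_updates)
    unifs = rng.random(n_updates)
    exp = math.exp
    u = 0
    for s in range(total):
        for i in range(k):
            cur_idx = idx[i]
            p = props[u]
            if p >= cur_idx:
                p += 1
            bp = grid_l[p]
            bi = b[i]
            row = w_rows[i]
            dh = 0.0
            for j in range(k):
                if j != i:
                    bj = b[j]
                    dh += row[j] * (abs(bp - bj) - abs(bi - bj))
            x = factor_beta * dh
            if x > 700.0:
                x = 700.0
            elif x < -700.0:
                x = -700.0
            if unifs[u] < 1.0 / (1.0 + exp(x)):
                b[i] = bp
                code += (p - cur_idx) * place[i]
                idx[i] = p
            u += 1
        if s >= burn_in:
            counts[code] += 1
    return counts


@dataclass
class ExactDistribution:
    """Enumerated Boltzmann distribution over grid^K belief configurations."""

    grid: np.ndarray
    beta: float
    convention: str  # energy convention for H
    energies: np.ndarray  # H(b) per configuration
    probabilities: np.ndarray
    Z: float

    @property
    def n_configs(self) -> int:
        return self.probabilities.size

    def configurations(self) -> np.ndarray:
        k = round(math.log(self.n_configs, self.grid.size))
        return np.array(list(itertools.product(self.grid, repeat=k)))

    def expected_H(self) -> float:
        return float(np.dot(self.probabilities, self.energies))

    def node_marginal(self, i: int, K: int) -> np.ndarray:
        p = self.probabilities.reshape((self.grid.size,) * K)
        axes = tuple(a for a in range(K) if a != i)
        return p.sum(axis=axes)

    def to_json(self, path) -> None:
        payload = {
            "grid": self.grid.tolist(),
            "beta": self.beta,
            "convention": self.convention,
            "probabilities": self.probabilities.tolist(),
            "Z": self.Z,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def boltzmann_exact(omega, config: DynamicsConfig) -> ExactDistribution:
    """Enumerate P(b) = exp(-beta H(b)) / Z over all grid^K configurations.

    H(b) uses the config's energy convention (``node_sum`` by default, the
    sum of all node-specific dissonances).  Configuration order is
    lexicographic in grid indices with node 0 most significant, matching
    :func:`sample_state_counts`.
    """
    omega = np.asarray(omega, dtype=float)
    k = omega.shape[0]
    g = config.proposal_grid.size
    if g**k > 10**6:
        raise ValueError(f"state space too large: {g}^{k} configurations")
    configs = np.array(list(itertools.product(config.proposal_grid, repeat=k)))
    diffs = np.abs(configs[:, :, None] - configs[:, None, :])
    pairwise = 0.5 * np.einsum("cij,ij->c", diffs, omega)
    H = _ENERGY_FACTOR[config.energy_convention] * pairwise
    w = np.exp(-config.beta * H)  # H is bounded by K^2 max|omega|; no overflow risk
    Z = float(w.sum())
    probs = w / Z
    return ExactDistribution(
        grid=config.proposal_grid.copy(),
        beta=config.beta,
        convention=config.energy_convention,
        energies=H,
        probabilities=probs,
        Z=Z,
    )


def total_variation(p, q) -> float:
    """Total-variation distance between two distributions on the same support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return 0.5 * float(np.abs(p / p.sum() - q / q.sum()).sum())
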