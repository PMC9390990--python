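"""Ground-truth belief networks and synthetic longitudinal Likert panels.

The generator emulates the structure of a longitudinal belief survey: a
between-person topic/group design, ~20 beliefs per topic split into a moral
and a social cluster, four measurement occasions (W1, W2a, W2b, W3) with an
intervention between W2a and W2b, group-level ties constant over time, and
wave-varying interdependence.  Two sampling routes are provided:

* :func:`simulate_panel_ggm` draws each wave from the model-implied Gaussian
  Sigma_t = Delta_t (I - Omega)^-1 Delta_t plus an additive person effect.
* :func:`simulate_panel_dynamics` evolves each person's belief vector by
  Glauber single-node updates between waves, so belief *change* carries the
  dissonance-reduction signal the downstream statistics test for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .panel import BeliefPanel, CONTINUOUS, RAW, RESCALED, WAVES, panel_from_arrays
from .preprocess import likert_from_rescaled

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "simulate_panel_ggm",
    "simulate_panel_dynamics",
    "default_grid",
]

#: Wave-level interdependence multipliers: sharp rise after first measurement,
#: roughly constant across the intervention, partial decay at follow-up.
DEFAULT_PROFILE = (1.0, 1.45, 1.55, 1.35)

MAX_SHRINK_ITER = 50


def default_grid(levels: int = 7) -> np.ndarray:
    """Evenly spaced belief states in [-1, 1] (7 levels mirror a 1..7 Likert)."""
    return np.linspace(-1.0, 1.0, levels)


@dataclass
class GroundTruth:
    """Generating parameters of a group-level belief network.

    omega is the symmetric tie (partial-correlation) matrix with zero
    diagonal; delta_by_wave holds the per-wave positive scaling vectors whose
    inverse mean is the wave's interdependence; mu_by_wave the per-wave
    intercepts; person_sd the SD of the scalar additive person effect.
    """

    omega: np.ndarray
    delta_by_wave: list[np.ndarray]
    mu_by_wave: list[np.ndarray]
    person_sd: float
    cluster_labels: list[str]
    seed: int

    @property
    def n_beliefs(self) -> int:
        return self.omega.shape[0]

    @property
    def waves(self) -> list[str]:
        return list(WAVES[: len(self.delta_by_wave)])

    def sigma(self, t: int) -> np.ndarray:
        """Model-implied covariance Delta_t (I - Omega)^-1 Delta_t."""
        d = np.diag(self.delta_by_wave[t])
        core = np.linalg.inv(np.eye(self.n_beliefs) - self.omega)
        return d @ core @ d

    def validate(self) -> "GroundTruth":
        k = self.n_beliefs
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        if np.any(np.diag(self.omega) != 0):
            raise ValueError("omega must have an exactly zero diagonal")
        if np.linalg.eigvalsh(np.eye(k) - self.omega).min() <= 0:
            raise ValueError("(I - omega) must be positive definite")
        for d in self.delta_by_wave:
            if np.any(np.asarray(d) <= 0):
                raise ValueError("delta entries must be strictly positive")
        if len(self.cluster_labels) != k:
            raise ValueError("one cluster label per belief required")
        return self

    def to_json(self, path) -> None:
        payload = {
            "omega": self.omega.tolist(),
            "delta_by_wave": [d.tolist() for d in self.delta_by_wave],
            "mu_by_wave": [m.tolist() for m in self.mu_by_wave],
            "person_sd": self.person_sd,
            "cluster_labels": self.cluster_labels,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            omega=np.asarray(payload["omega"], dtype=float),
            delta_by_wave=[np.asarray(d, dtype=float) for d in payload["delta_by_wave"]],
            mu_by_wave=[np.asarray(m, dtype=float) for m in payload["mu_by_wave"]],
            person_sd=float(payload["person_sd"]),
            cluster_labels=list(payload["cluster_labels"]),
            seed=int(payload["seed"]),
        ).validate()


def make_ground_truth(
    K: int = 20,
    sparsity: float = 0.5,
    within_cluster_bias: float = 3.0,
    tie_scale: float = 0.3,
    waves: int = 4,
    interdependence_profile=DEFAULT_PROFILE,
    seed: int = 0,
    *,
    tie_min: float = 0.05,
    negative_fraction: float = 0.15,
    base_delta: tuple[float, float] = (0.35, 0.45),
    person_sd: float = 0.3,
    mu: float = 0.0,
) -> GroundTruth:
    """Draw a sparse two-cluster belief network with wave-varying scaling.

    Ties are present with a higher probability within the moral and social
    clusters than between them (``within_cluster_bias`` is the within/between
    probability ratio); tie magnitudes are uniform on [tie_min, tie_scale]
    and mostly positive.  delta_by_wave scales inversely with the
    interdependence profile, so interdependence 1/mean(delta) follows the
    profile.  (I - omega) positive definiteness is repaired, if necessary, by
    uniform shrinkage of omega (factor 0.95, at most 50 iterations).
    """
    if K < 2:
        raise ValueError("K >= 2 required")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    profile = np.asarray(interdependence_profile, dtype=float)
    if profile.size != waves:
        raise ValueError("interdependence_profile must have one entry per wave")
    if np.any(profile <= 0):
        raise ValueError("interdependence_profile entries must be positive")

    rng = np.random.default_rng(seed)
    half = K // 2
    labels = ["moral"] * half + ["social"] * (K - half)

    iu, ju = np.triu_indices(K, k=1)
    within = np.array([labels[a] == labels[b] for a, b in zip(iu, ju)])
    f_w = within.mean()
    density = 1.0 - sparsity
    p_between = density / ((1 - f_w) + within_cluster_bias * f_w)
    p_within = min(1.0, within_cluster_bias * p_between)
    p_between = min(1.0, p_between)
    present = rng.random(iu.size) < np.where(within, p_within, p_between)

    mags = rng.uniform(tie_min, tie_scale, size=iu.size)
    signs = np.where(rng.random(iu.size) < negative_fraction, -1.0, 1.0)
    vals = np.where(present, mags * signs, 0.0)

    omega = np.zeros((K, K))
    omega[iu, ju] = vals
    omega += omega.T

    for _ in range(MAX_SHRINK_ITER):
        if np.linalg.eigvalsh(np.eye(K) - omega).min() > 1e-6:
            break
        omega *= 0.95
    else:
        raise ValueError("positive-definiteness repair failed after bounded shrinkage")

    base = rng.uniform(base_delta[0], base_delta[1], size=K)
    delta_by_wave = [base / profile[t] for t in range(waves)]
    mu_by_wave = [np.full(K, float(mu)) for _ in range(waves)]

    return GroundTruth(
        omega=omega,
        delta_by_wave=delta_by_wave,
        mu_by_wave=mu_by_wave,
        person_sd=float(person_sd),
        cluster_labels=labels,
        seed=int(seed),
    ).validate()


def _belief_names(gt: GroundTruth) -> list[str]:
    counts: dict[str, int] = {}
    names = []
    for lab in gt.cluster_labels:
        counts[lab] = counts.get(lab, 0) + 1
        names.append(f"{lab[0]}{counts[lab]:02d}")
    return names


def _group_assignment(n: int, groups, rng: np.random.Generator) -> np.ndarray:
    if groups is None:
        groups = ["all"]
    reps = np.array(list(groups) * (n // len(groups) + 1))[:n]
    rng.shuffle(reps)
    return reps


def simulate_panel_ggm(
    gt: GroundTruth,
    n: int,
    seed: int = 0,
    *,
    topic: str = "topic1",
    groups=None,
    dialect: str = RAW,
) -> BeliefPanel:
    """Sample a panel wave-by-wave from the model-implied Gaussian.

    Each wave t draws persons independently from N(mu_t + a_p, Sigma_t) with
    Sigma_t = Delta_t (I - Omega)^-1 Delta_t and a scalar person effect
    a_p ~ N(0, person_sd^2) shared across waves and beliefs.  Dialect
    ``raw`` maps to the 1..7 Likert grid (affine map then round/clip),
    ``rescaled`` clips to [-1, 1], ``continuous`` returns the draws as-is.
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    gt.validate()
    rng = np.random.default_rng(seed)
    k = gt.n_beliefs
    person_ids = np.arange(n)
    person_eff = rng.normal(0.0, gt.person_sd, size=n)
    core = np.linalg.inv(np.eye(k) - gt.omega)
    # single Cholesky of the Omega core; per-wave scaling applied outside
    chol_core = np.linalg.cholesky(core)

    values_by_wave: dict[str, np.ndarray] = {}
    for t, wave in enumerate(gt.waves):
        z = rng.standard_normal((n, k))
        draws = z @ chol_core.T * gt.delta_by_wave[t][None, :]
        draws += gt.mu_by_wave[t][None, :] + person_eff[:, None]
        values_by_wave[wave] = draws

    groups_arr = _group_assignment(n, groups, rng)
    if dialect == RAW:
        values_by_wave = {
            w: likert_from_rescaled(v) for w, v in values_by_wave.items()
        }
    elif dialect == RESCALED:
        values_by_wave = {w: np.clip(v, -1.0, 1.0) for w, v in values_by_wave.items()}
    elif dialect != CONTINUOUS:
        raise ValueError(f"unknown dialect {dialect!r}")

    return panel_from_arrays(
        values_by_wave, person_ids, _belief_names(gt), topic, groups_arr, dialect
    ).validate()


def simulate_panel_dynamics(
    gt: GroundTruth,
    n: int,
    beta_by_wave,
    sweeps_between_waves: int,
    intervention: tuple[str, list[int], float] | None = None,
    seed: int = 0,
    *,
    grid: np.ndarray | None = None,
    topic: str = "topic1",
    groups=None,
    dialect: str = RESCALED,
    energy_convention: str = "node_sum",
) -> BeliefPanel:
    """Evolve persons' belief vectors by Glauber sweeps between waves.

    Persons start uniformly at random on the proposal grid.  Between wave
    t-1 and wave t each person receives ``sweeps_between_waves`` full sweeps
    of single-node updates at interdependence ``beta_by_wave[t]`` (the
    destination wave's beta).  ``sweeps_between_waves`` may be a single int
    or one count per transition (measurement occasions are unevenly spaced:
    the two wave-2 measurements bracket the intervention minutes apart,
    the others are days apart).  ``intervention=(wave, node_indices, shift)``
    adds ``shift`` to the listed beliefs immediately after that wave's
    snapshot, clipped to [-1, 1]; there is no external-field term in the
    dissonance itself.
    """
    from .dynamics import _sweep_matrix  # local import to avoid cycle

    gt.validate()
    beta = np.asarray(beta_by_wave, dtype=float)
    waves = gt.waves
    if beta.size != len(waves):
        raise ValueError("beta_by_wave must have one entry per wave")
    if np.any(beta < 0):
        raise ValueError("beta_by_wave must be >= 0")
    if np.isscalar(sweeps_between_waves):
        sweeps_seq = [int(sweeps_between_waves)] * (len(waves) - 1)
    else:
        sweeps_seq = [int(s) for s in sweeps_between_waves]
        if len(sweeps_seq) != len(waves) - 1:
            raise ValueError("need one sweep count per wave transition")
    if any(s < 0 for s in sweeps_seq):
        raise ValueError("sweeps_between_waves must be >= 0")
    if intervention is not None and intervention[0] not in waves:
        raise ValueError(f"unknown wave label in intervention: {intervention[0]!r}")

    if grid is None:
        grid = default_grid(7)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    k = gt.n_beliefs
    b = grid[rng.integers(0, grid.size, size=(n, k))]

    values_by_wave: dict[str, np.ndarray] = {}
    for t, wave in enumerate(waves):
        if t > 0:
            for _ in range(sweeps_seq[t - 1]):
                _sweep_matrix(
                    b, gt.omega, grid, float(beta[t]), rng, energy_convention
                )
        values_by_wave[wave] = b.copy()
        if intervention is not None and wave == intervention[0]:
            _, nodes, shift = intervention
            b[:, list(nodes)] = np.clip(b[:, list(nodes)] + shift, -1.0, 1.0)

    groups_arr = _group_assignment(n, groups, rng)
    if dialect == RAW:
        values_by_wave = {
            w: likert_from_rescaled(v) for w, v in values_by_wave.items()
        }
    elif dialect not in (RESCALED, CONTINUOUS):
        raise ValueError(f"unknown dialect {dialect!r}")

    return panel_from_arrays(
        values_by_wave, np.arange(n), _belief_names(gt), topic, groups_arr, dialect
    ).validate()
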