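"""Multigroup Gaussian graphical model of belief networks.

The covariance at each measurement occasion t is parameterized as

    Sigma_t = Delta_t (I - Omega_t)^-1 Delta_t

where Omega_t is the symmetric zero-diagonal matrix of partial correlations
(the network ties) and Delta_t is a positive diagonal scaling matrix.  The
wave-level interdependence beta_t is the inverse mean of the scaling values
delta_{i,t}: small scaling values inflate the marginal correlations implied
by the same ties, which is read as stronger coupling between beliefs.

Fitting maximizes the stacked multivariate-Gaussian likelihood over
(Omega_t, Delta_t, mu_t) with optional cross-wave equality constraints on
each block and an optional zero mask on ties.  Specifications are compared
by BIC; sparsification uses a prune step-up search (zero the weakest tie
while BIC improves, then re-free zeroed ties while BIC improves).

Numerical notes: the likelihood is written in terms of the stored sample
moments with the unbiased (n-1) covariance, so the unconstrained per-wave
maximum coincides exactly with the closed-form precision decomposition of
the sample covariance; mu is profiled out analytically (GLS mean under the
equality constraint); delta is optimized on the log scale; positive
definiteness of (I - Omega) acts as a natural log-barrier, with an eigvalue
penalty taking over if a line-search iterate leaves the cone.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .preprocess import WaveMatrix

__all__ = [
    "ConstraintSpec",
    "WaveMoments",
    "NetworkModel",
    "FitError",
    "sample_moments",
    "omega_delta_from_precision",
    "model_implied_sigma",
    "fit_spec",
    "prune_stepup",
    "select_spec",
    "interdependence",
]

LOG2PI = float(np.log(2.0 * np.pi))


class FitError(RuntimeError):
    """Raised when a model fit fails (infeasible start or non-convergence)."""


@dataclass(frozen=True)
class ConstraintSpec:
    """Cross-wave equality constraints plus the sparse/dense toggle.

    The three equality flags span the 2^3 = 8 specification grid; ``sparse``
    marks whether the tie matrix is additionally pruned.
    """

    omega_equal: bool = False
    mu_equal: bool = False
    delta_equal: bool = False
    sparse: bool = False

    def label(self) -> str:
        parts = [
            "omega=eq" if self.omega_equal else "omega=free",
            "mu=eq" if self.mu_equal else "mu=free",
            "delta=eq" if self.delta_equal else "delta=free",
            "sparse" if self.sparse else "dense",
        ]
        return ",".join(parts)


@dataclass
class WaveMoments:
    """Per-wave sample means, unbiased covariances, and counts."""

    waves: list[str]
    means: list[np.ndarray]
    covs: list[np.ndarray]
    ns: list[int]
    belief_ids: list[str]

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def n_beliefs(self) -> int:
        return len(self.belief_ids)

    @property
    def n_total(self) -> int:
        return int(sum(self.ns))


@dataclass
class NetworkModel:
    """Fitted multigroup GGM."""

    spec: ConstraintSpec
    waves: list[str]
    belief_ids: list[str]
    omega_by_wave: list[np.ndarray]
    delta_by_wave: list[np.ndarray]
    mu_by_wave: list[np.ndarray]
    zero_mask: frozenset[tuple[int, int]]
    loglik: float
    n_params: int
    bic: float
    converged: bool = True
    _theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def beta_by_wave(self) -> list[float]:
        return [1.0 / float(np.mean(d)) for d in self.delta_by_wave]

    def omega(self, wave: str | int = 0) -> np.ndarray:
        if isinstance(wave, str):
            wave = self.waves.index(wave)
        return self.omega_by_wave[wave]

    def sigma(self, t: int) -> np.ndarray:
        return model_implied_sigma(self.omega_by_wave[t], self.delta_by_wave[t])

    def edge_list(self) -> pd.DataFrame:
        """Nonzero ties of the first wave's network (undirected, i < j)."""
        om = self.omega_by_wave[0]
        rows = [
            (self.belief_ids[i], self.belief_ids[j], om[i, j])
            for i, j in zip(*np.triu_indices_from(om, k=1))
            if om[i, j] != 0.0
        ]
        return pd.DataFrame(rows, columns=["belief_i", "belief_j", "omega"])

    def to_json(self, path) -> None:
        payload = {
            "spec": {
                "omega_equal": self.spec.omega_equal,
                "mu_equal": self.spec.mu_equal,
                "delta_equal": self.spec.delta_equal,
                "sparse": self.spec.sparse,
            },
            "waves": self.waves,
            "belief_ids": self.belief_ids,
            "omega_by_wave": [o.tolist() for o in self.omega_by_wave],
            "delta_by_wave": [d.tolist() for d in self.delta_by_wave],
            "mu_by_wave": [m.tolist() for m in self.mu_by_wave],
            "zero_mask": sorted(self.zero_mask),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "beta_by_wave": self.beta_by_wave,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# moments and closed forms
# ---------------------------------------------------------------------------

def sample_moments(matrices: list[WaveMatrix]) -> WaveMoments:
    """Unbiased per-wave means and covariances from wave matrices."""
    if not matrices:
        raise ValueError("at least one wave required")
    belief_ids = list(matrices[0].frame.columns)
    waves, means, covs, ns = [], [], [], []
    for wm in matrices:
        if list(wm.frame.columns) != belief_ids:
            raise ValueError("inconsistent belief ordering across waves")
        x = wm.values
        n, k = x.shape
        if n <= k:
            raise ValueError(f"wave {wm.wave}: need n > K ({n} <= {k})")
        cov = np.cov(x, rowvar=False, ddof=1)
        if np.linalg.matrix_rank(cov) < k:
            warnings.warn(f"wave {wm.wave}: rank-deficient sample covariance")
        waves.append(wm.wave)
        means.append(x.mean(axis=0))
        covs.append(np.atleast_2d(cov))
        ns.append(n)
    return WaveMoments(waves, means, covs, ns, belief_ids)


def omega_delta_from_precision(precision: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose an SPD precision matrix into ties and scaling values.

    omega_ij = -K_ij / sqrt(K_ii K_jj) (the partial correlation) and
    delta_i = K_ii^(-1/2); Sigma = Delta (I - Omega)^-1 Delta inverts the
    input exactly.
    """
    precision = np.asarray(precision, dtype=float)
    if np.linalg.eigvalsh(precision).min() <= 0:
        raise ValueError("precision matrix must be symmetric positive definite")
    delta = 1.0 / np.sqrt(np.diag(precision))
    omega = -precision * np.outer(delta, delta)
    np.fill_diagonal(omega, 0.0)
    return omega, delta


def model_implied_sigma(omega: np.ndarray, delta: np.ndarray) -> np.ndarray:
    k = omega.shape[0]
    core = np.linalg.inv(np.eye(k) - omega)
    return core * np.outer(delta, delta)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

@dataclass
class _Packing:
    """Layout of the free-parameter vector for one specification."""

    K: int
    T: int
    omega_equal: bool
    delta_equal: bool
    free_pairs: list[tuple[int, int]]

    @property
    def n_omega_blocks(self) -> int:
        return 1 if self.omega_equal else self.T

    @property
    def n_delta_blocks(self) -> int:
        return 1 if self.delta_equal else self.T

    @property
    def size(self) -> int:
        return (
            len(self.free_pairs) * self.n_omega_blocks
            + self.K * self.n_delta_blocks
        )

    def unpack(self, theta: np.ndarray):
        m = len(self.free_pairs)
        omegas, pos = [], 0
        for _ in range(self.n_omega_blocks):
            om = np.zeros((self.K, self.K))
            for (i, j), v in zip(self.free_pairs, theta[pos : pos + m]):
                om[i, j] = om[j, i] = v
            omegas.append(om)
            pos += m
        logdeltas = []
        for _ in range(self.n_delta_blocks):
            logdeltas.append(theta[pos : pos + self.K].copy())
            pos += self.K
        if self.omega_equal:
            omegas = omegas * self.T
        if self.delta_equal:
            logdeltas = logdeltas * self.T
        return omegas, logdeltas

    def pack(self, omegas: list[np.ndarray], deltas: list[np.ndarray]) -> np.ndarray:
        theta = []
        blocks = 1 if self.omega_equal else self.T
        for b in range(blocks):
            theta.extend(omegas[b][i, j] for i, j in self.free_pairs)
        blocks = 1 if self.delta_equal else self.T
        for b in range(blocks):
            theta.extend(np.log(deltas[b]))
        return np.asarray(theta, dtype=float)


def _profiled_mu(moments: WaveMoments, mu_equal: bool, precisions: list[np.ndarray]):
    if not mu_equal:
        return [m.copy() for m in moments.means]
    lhs = sum(n * K for n, K in zip(moments.ns, precisions))
    rhs = sum(n * K @ m for n, K, m in zip(moments.ns, precisions, moments.means))
    mu = np.linalg.solve(lhs, rhs)
    return [mu.copy() for _ in moments.waves]


def _objective(theta, moments: WaveMoments, packing: _Packing, mu_equal: bool):
    K, T = packing.K, packing.T
    omegas, logdeltas = packing.unpack(theta)
    eye = np.eye(K)

    # feasibility + cholesky per distinct omega block
    feasible = True
    block_ids = [0] * T if packing.omega_equal else list(range(T))
    chol_cache: dict[int, np.ndarray | None] = {}
    for b in set(block_ids):
        a = eye - omegas[b if not packing.omega_equal else 0]
        try:
            chol_cache[b] = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            chol_cache[b] = None
            feasible = False

    if not feasible:
        # eigenvalue penalty pushing back toward the PD cone
        pen, grad = 1e7, np.zeros_like(theta)
        m = len(packing.free_pairs)
        for b in set(block_ids):
            if chol_cache[b] is not None:
                continue
            a = eye - omegas[b if not packing.omega_equal else 0]
            vals, vecs = np.linalg.eigh(a)
            lam, v = vals[0], vecs[:, 0]
            pen += 1e9 * (1e-6 - lam)
            gblock = np.array([2.0 * v[i] * v[j] for i, j in packing.free_pairs])
            off = 0 if packing.omega_equal else b * m
            grad[off : off + m] += 1e9 * gblock
        return pen, grad

    deltas = [np.exp(ld) for ld in logdeltas]
    precisions = []
    for t in range(T):
        a = eye - omegas[t]
        inv_d = 1.0 / deltas[t]
        precisions.append(a * np.outer(inv_d, inv_d))

    mus = _profiled_mu(moments, mu_equal, precisions)

    f = 0.0
    grad = np.zeros_like(theta)
    m = len(packing.free_pairs)
    n_ob = packing.n_omega_blocks
    for t in range(T):
        n = moments.ns[t]
        d = moments.means[t] - mus[t]
        M = moments.covs[t] + np.outer(d, d)
        L = chol_cache[0 if packing.omega_equal else t]
        logdet_a = 2.0 * np.sum(np.log(np.diag(L)))
        logdet_k = logdet_a - 2.0 * np.sum(logdeltas[t])
        Kmat = precisions[t]
        sigma = np.linalg.inv(Kmat)
        f += 0.5 * n * (K * LOG2PI - logdet_k + np.sum(Kmat * M))
        G = 0.5 * n * (M - sigma)
        # omega gradient
        dd = deltas[t]
        gom = np.array(
            [-2.0 * G[i, j] / (dd[i] * dd[j]) for i, j in packing.free_pairs]
        )
        off = 0 if packing.omega_equal else t * m
        grad[off : off + m] += gom
        # log-delta gradient
        gld = -2.0 * np.sum(G * Kmat, axis=1)
        doff = m * n_ob + (0 if packing.delta_equal else t * K)
        grad[doff : doff + K] += gld
    return f, grad


def _initial_values(moments: WaveMoments, zero_mask, packing: _Packing):
    """Feasible start from the per-wave closed-form decompositions."""
    K = moments.n_beliefs
    omegas, deltas = [], []
    for cov in moments.covs:
        c = np.asarray(cov, dtype=float)
        # ridge if near-singular
        jitter = 0.0
        while True:
            try:
                prec = np.linalg.inv(c + jitter * np.eye(K))
                om, de = omega_delta_from_precision(prec)
                break
            except (np.linalg.LinAlgError, ValueError):
                jitter = max(1e-8, jitter * 10 or 1e-8)
                if jitter > 1.0:
                    raise FitError("could not invert sample covariance")
        omegas.append(om)
        deltas.append(de)
    if packing.omega_equal:
        om = np.mean(omegas, axis=0)
        omegas = [om] * packing.T
    if packing.delta_equal:
        de = np.mean(deltas, axis=0)
        deltas = [de] * packing.T
    for om in omegas:
        for i, j in zero_mask:
            om[i, j] = om[j, i] = 0.0
    # shrink each omega block until feasible
    out = []
    for om in omegas:
        om = om.copy()
        for _ in range(100):
            if np.linalg.eigvalsh(np.eye(K) - om).min() > 1e-5:
                break
            om *= 0.9
        out.append(om)
    return packing.pack(out, deltas)


def _count_params(packing: _Packing, mu_equal: bool) -> int:
    K, T = packing.K, packing.T
    n_omega = len(packing.free_pairs) * packing.n_omega_blocks
    n_delta = K * packing.n_delta_blocks
    n_mu = K * (1 if mu_equal else T)
    return n_omega + n_delta + n_mu


def fit_spec(
    moments: WaveMoments,
    spec: ConstraintSpec,
    zero_mask=None,
    *,
    init: np.ndarray | None = None,
    maxiter: int = 5000,
) -> NetworkModel:
    """Maximum-likelihood fit of one constraint specification.

    ``zero_mask`` is a set of (i, j) tie index pairs fixed at zero (shared
    across waves).  BIC = -2 loglik + n_params * log(total observations).
    """
    K, T = moments.n_beliefs, moments.n_waves
    mask = frozenset(
        (min(i, j), max(i, j)) for i, j in (zero_mask or ())
    )
    for i, j in mask:
        if not (0 <= i < j < K):
            raise ValueError(f"invalid tie index pair in zero mask: {(i, j)}")
    free_pairs = [
        (i, j) for i, j in itertools.combinations(range(K), 2) if (i, j) not in mask
    ]
    packing = _Packing(K, T, spec.omega_equal, spec.delta_equal, free_pairs)

    theta0 = init if init is not None else _initial_values(moments, mask, packing)
    res = minimize(
        _objective,
        theta0,
        args=(moments, packing, spec.mu_equal),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    converged = bool(res.success) or res.status == 1  # status 1: maxiter
    if not np.isfinite(res.fun) or res.fun >= 1e7:
        raise FitError(f"fit infeasible for spec {spec.label()}")
    if not converged:
        warnings.warn(
            f"fit did not fully converge for spec {spec.label()}: {res.message}"
        )

    omegas, logdeltas = packing.unpack(res.x)
    deltas = [np.exp(ld) for ld in logdeltas]
    eye = np.eye(K)
    precisions = [
        (eye - omegas[t]) * np.outer(1.0 / deltas[t], 1.0 / deltas[t])
        for t in range(T)
    ]
    mus = _profiled_mu(moments, spec.mu_equal, precisions)
    loglik = -float(res.fun)
    n_params = _count_params(packing, spec.mu_equal)
    bic = -2.0 * loglik + n_params * np.log(moments.n_total)
    return NetworkModel(
        spec=spec,
        waves=list(moments.waves),
        belief_ids=list(moments.belief_ids),
        omega_by_wave=[om.copy() for om in omegas],
        delta_by_wave=[de.copy() for de in deltas],
        mu_by_wave=mus,
        zero_mask=mask,
        loglik=loglik,
        n_params=n_params,
        bic=float(bic),
        converged=converged,
        _theta=res.x.copy(),
    )


# ---------------------------------------------------------------------------
# sparsification and model selection
# ---------------------------------------------------------------------------

def _tie_magnitude(model: NetworkModel, pair) -> float:
    i, j = pair
    return float(np.mean([abs(om[i, j]) for om in model.omega_by_wave]))


def _warm_start(model: NetworkModel, new_mask, moments, spec) -> np.ndarray:
    """Re-pack the fitted parameters under a modified zero mask."""
    K, T = moments.n_beliefs, moments.n_waves
    free_pairs = [
        (i, j)
        for i, j in itertools.combinations(range(K), 2)
        if (i, j) not in new_mask
    ]
    packing = _Packing(K, T, spec.omega_equal, spec.delta_equal, free_pairs)
    omegas = [om.copy() for om in model.omega_by_wave]
    for om in omegas:
        for i, j in new_mask:
            om[i, j] = om[j, i] = 0.0
    return packing.pack(omegas, model.delta_by_wave)


def prune_stepup(
    moments: WaveMoments, spec: ConstraintSpec, model: NetworkModel
) -> NetworkModel:
    """Sparsify a fitted model: prune weakest ties, then re-free while BIC drops.

    Backward phase: repeatedly fix the smallest-magnitude free tie to zero
    (ties broken by row/column order), refit, and keep the pruned model iff
    its BIC decreases; stop at the first non-improvement.  Step-up phase:
    repeatedly re-free the zeroed tie whose release most improves BIC, while
    an improvement exists.
    """
    current = model
    # backward
    while True:
        free = sorted(
            set(itertools.combinations(range(moments.n_beliefs), 2))
            - current.zero_mask
        )
        if not free:
            break
        pair = min(free, key=lambda p: (_tie_magnitude(current, p), p))
        mask = current.zero_mask | {pair}
        cand = fit_spec(
            moments, spec, mask, init=_warm_start(current, mask, moments, spec)
        )
        if cand.bic < current.bic:
            current = cand
        else:
            break
    # step-up
    while current.zero_mask:
        best = None
        for pair in sorted(current.zero_mask):
            mask = current.zero_mask - {pair}
            cand = fit_spec(
                moments, spec, mask, init=_warm_start(current, mask, moments, spec)
            )
            if best is None or cand.bic < best.bic:
                best = cand
        if best is not None and best.bic < current.bic:
            current = best
        else:
            break
    return replace(current, spec=replace(spec, sparse=True))


def select_spec(moments: WaveMoments) -> tuple[NetworkModel, pd.DataFrame]:
    """Fit the full specification grid and return the BIC winner.

    All 8 equality-constraint combinations are fitted dense, then each is
    sparsified by prune step-up, giving 16 candidates.  Failures of single
    members are recorded in the comparison table rather than raised, unless
    every fit fails.
    """
    if moments.n_waves < 2:
        raise ValueError("select_spec requires at least two waves")
    rows, models = [], []
    for om_eq, mu_eq, de_eq in itertools.product([False, True], repeat=3):
        for sparse in (False, True):
            spec = ConstraintSpec(om_eq, mu_eq, de_eq, sparse)
            try:
                if not sparse:
                    model = fit_spec(moments, spec)
                    dense_model = model
                else:
                    model = prune_stepup(
                        moments, replace(spec, sparse=False), dense_model
                    )
                models.append(model)
                rows.append(
                    {
                        "omega_equal": om_eq,
                        "mu_equal": mu_eq,
                        "delta_equal": de_eq,
                        "sparse": sparse,
                        "n_params": model.n_params,
                        "loglik": model.loglik,
                        "bic": model.bic,
                        "converged": model.converged,
                        "error": "",
                    }
                )
            except FitError as exc:  # pragma: no cover - defensive
                rows.append(
                    {
                        "omega_equal": om_eq,
                        "mu_equal": mu_eq,
                        "delta_equal": de_eq,
                        "sparse": sparse,
                        "n_params": np.nan,
                        "loglik": np.nan,
                        "bic": np.nan,
                        "converged": False,
                        "error": str(exc),
                    }
                )
    if not models:
        raise FitError("all specification fits failed")
    table = pd.DataFrame(rows)
    best = min(models, key=lambda m: m.bic)
    return best, table


def interdependence(
    model: NetworkModel, wave: str | int, convention: str = "inverse_mean"
) -> float:
    """Wave-level interdependence beta from the scaling values.

    ``inverse_mean`` (the reported convention) returns 1 / mean(delta);
    ``mean_inverse`` returns mean(1 / delta).
    """
    if isinstance(wave, str):
        wave = model.waves.index(wave)
    delta = model.delta_by_wave[wave]
    if convention == "inverse_mean":
        return 1.0 / float(np.mean(delta))
    if convention == "mean_inverse":
        return float(np.mean(1.0 / delta))
    raise ValueError(f"unknown convention {convention!r}")
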