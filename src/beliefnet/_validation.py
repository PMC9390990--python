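"""Self-contained oracle suite behind ``beliefnet validate``.

Each check recomputes a quantity two independent ways (closed form vs.
implementation, enumeration vs. simulation) and reports pass/fail; the CLI
exits non-zero if any check fails.
"""

from __future__ import annotations

import numpy as np

from .dissonance import NODE_SUM, network_dissonance
from .dynamics import (
    DynamicsConfig,
    boltzmann_exact,
    sample_state_counts,
    total_variation,
)
from .inference_stats import EffectRecord, meta_random_effects
from .network_estimation import (
    ConstraintSpec,
    fit_spec,
    model_implied_sigma,
    omega_delta_from_precision,
    sample_moments,
)
from .preprocess import residualize, rescale_beliefs
from .synthetic_data import make_ground_truth, simulate_panel_ggm


def _check_roundtrip(rng) -> tuple[bool, str]:
    a = rng.standard_normal((6, 6))
    prec = a @ a.T + 6 * np.eye(6)
    omega, delta = omega_delta_from_precision(prec)
    err = np.abs(model_implied_sigma(omega, delta) - np.linalg.inv(prec)).max()
    return err < 1e-10, f"max reconstruction error {err:.2e}"

def _check_boltzmann(rng) -> tuple[bool, str]:
    omega = np.array([[0.0, 0.5], [0.5, 0.0]])
    cfg = DynamicsConfig(beta=1.0, proposal_grid=np.array([-1.0, 1.0]))
    dist = boltzmann_exact(omega, cfg)
    expect = 1.0 / (2.0 + 2.0 * np.exp(-2.0))
    err = abs(dist.probabilities.max() - expect)
    return err < 1e-12, f"aligned-config probability error {err:.2e}"

def _check_chain(rng, quick: bool) -> tuple[bool, str]:
    gt = make_ground_truth(K=3, sparsity=0.0, tie_scale=0.4, waves=1,
                           interdependence_profile=[1.0], seed=3)
    cfg = DynamicsConfig(
        beta=1.0, proposal_grid=np.linspace(-1, 1, 3),
        seed=int(rng.integers(2**31)),
    )
    sweeps = 20_000 if quick else 200_000
    counts = sample_state_counts(gt.omega, cfg, n_sweeps=sweeps, burn_in=2_000)
    exact = boltzmann_exact(gt.omega, cfg)
    tv = total_variation(counts, exact.probabilities)
    bound = 0.05 if quick else 0.02
    return tv < bound, f"TV(chain, exact) = {tv:.4f} (bound {bound})"

def _check_meta(rng) -> tuple[bool, str]:
    effects = [
        EffectRecord("a", "t", 0.30, 50),
        EffectRecord("b", "t", 0.10, 80),
        EffectRecord("c", "t", 0.25, 40),
    ]
    res = meta_random_effects(effects)
    # independent hand computation of the DerSimonian-Laird algebra
    y = np.arctanh([0.30, 0.10, 0.25])
    v = 1.0 / (np.array([50, 80, 40]) - 3)
    w = 1.0 / v
    yw = (w * y).sum() / w.sum()
    q = (w * (y - yw) ** 2).sum()
    tau2 = max(0.0, (q - 2) / (w.sum() - (w**2).sum() / w.sum()))
    ws = 1.0 / (v + tau2)
    pooled = np.tanh((ws * y).sum() / ws.sum())
    err = max(abs(res.pooled - pooled), abs(res.Q - q), abs(res.tau2 - tau2))
    return err < 1e-12, f"DL mismatch {err:.2e}"

def _check_dissonance(rng) -> tuple[bool, str]:
    k = 6
    omega = rng.uniform(-0.3, 0.3, (k, k))
    omega = (omega + omega.T) / 2
    np.fill_diagonal(omega, 0.0)
    b = rng.uniform(-1, 1, k)
    brute = sum(
        omega[i, j] * abs(b[i] - b[j]) for i in range(k) for j in range(k) if i != j
    )
    err = abs(network_dissonance(b, omega, NODE_SUM) - brute)
    return err < 1e-12, f"enumeration mismatch {err:.2e}"

def _check_recovery(rng, quick: bool) -> tuple[bool, str]:
    n = 400 if quick else 1500
    gt = make_ground_truth(K=5, sparsity=0.4, waves=2,
                           interdependence_profile=[1.0, 1.3], seed=11)
    panel = simulate_panel_ggm(gt, n, seed=int(rng.integers(2**31)),
                               dialect="continuous")
    moments = sample_moments(residualize(panel))
    model = fit_spec(moments, ConstraintSpec(omega_equal=True))
    mae = np.abs(model.omega_by_wave[0] - gt.omega)[np.triu_indices(5, 1)].mean()
    bound = 0.08 if quick else 0.04
    return mae < bound, f"mean |omega_hat - omega| = {mae:.4f} (bound {bound})"


def run_validation(quick: bool = False, seed: int = 0) -> list[tuple[str, bool, str]]:
    rng = np.random.default_rng(seed)
    checks = [
        ("ggm_roundtrip", _check_roundtrip(rng)),
        ("boltzmann_enumeration", _check_boltzmann(rng)),
        ("chain_vs_enumeration", _check_chain(rng, quick)),
        ("meta_analysis_algebra", _check_meta(rng)),
        ("dissonance_enumeration", _check_dissonance(rng)),
        ("omega_recovery", _check_recovery(rng, quick)),
    ]
    return [(name, ok, detail) for name, (ok, detail) in checks]
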