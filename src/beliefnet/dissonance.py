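"""Network dissonance: tie-weighted inconsistency of a belief configuration.

The belief-specific dissonance of node i is

    H_i = sum_{j != i} omega_ij * |b_i - b_j|

and the configuration-level dissonance aggregates the pairwise terms either
once per pair (``pairwise_once``, the person-level score) or as the sum of
all node dissonances (``node_sum`` = 2 x pairwise_once, the energy entering
the Boltzmann configuration distribution).  The unweighted variant replaces
every tie by 1, recovering the classic structure-free dissonance measure.

Dissonance is computed on recorded (non-residualized) beliefs on the [-1, 1]
scale; it is translation invariant and positively homogeneous in the
beliefs, so downstream correlations are unaffected by the Likert-to-[-1, 1]
rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_estimation import NetworkModel
from .panel import BeliefPanel, RAW, PanelError

__all__ = [
    "DissonanceScores",
    "belief_dissonance",
    "network_dissonance",
    "dissonance_matrix",
    "dissonance_panel",
]

PAIRWISE_ONCE = "pairwise_once"
NODE_SUM = "node_sum"
WEIGHTED = "weighted"
UNWEIGHTED = "unweighted"


@dataclass
class DissonanceScores:
    """Per (person, wave) total and per-belief dissonances for one topic."""

    per_belief: pd.DataFrame  # person_id, wave, belief_id, H_i
    totals: pd.DataFrame  # person_id, wave, H_total
    variant: str
    aggregation: str = PAIRWISE_ONCE
    topic: str | None = None

    def totals_at(self, wave: str) -> pd.Series:
        sub = self.totals[self.totals["wave"] == wave]
        if sub.empty:
            raise ValueError(f"wave {wave!r} not present in scores")
        return sub.set_index("person_id")["H_total"].sort_index()

    def per_belief_at(self, wave: str) -> pd.DataFrame:
        """Persons x beliefs matrix of H_i at one wave."""
        sub = self.per_belief[self.per_belief["wave"] == wave]
        if sub.empty:
            raise ValueError(f"wave {wave!r} not present in scores")
        return (
            sub.pivot(index="person_id", columns="belief_id", values="H_i")
            .sort_index(axis=0)
            .sort_index(axis=1)
        )


def _check_args(b: np.ndarray, omega: np.ndarray) -> None:
    if omega.shape[0] != omega.shape[1] or omega.shape[0] != b.shape[-1]:
        raise ValueError("belief vector and tie matrix sizes disagree")


def belief_dissonance(b, omega, i: int) -> float:
    """H_i = sum_{j != i} omega_ij |b_i - b_j| (may be negative with negative ties)."""
    b = np.asarray(b, dtype=float)
    omega = np.asarray(omega, dtype=float)
    _check_args(b, omega)
    if not 0 <= i < b.size:
        raise IndexError(f"belief index {i} out of range")
    return float(np.sum(omega[i] * np.abs(b[i] - b)))


def network_dissonance(b, omega, aggregation: str = PAIRWISE_ONCE) -> float:
    """Configuration-level dissonance H(b) under the chosen aggregation."""
    b = np.asarray(b, dtype=float)
    omega = np.asarray(omega, dtype=float)
    _check_args(b, omega)
    pairwise = 0.5 * float(np.sum(omega * np.abs(b[:, None] - b[None, :])))
    if aggregation == PAIRWISE_ONCE:
        return pairwise
    if aggregation == NODE_SUM:
        return 2.0 * pairwise
    raise ValueError(f"unknown aggregation {aggregation!r}")


def dissonance_matrix(B: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Per-belief dissonances H_i for a persons x beliefs matrix."""
    B = np.asarray(B, dtype=float)
    omega = np.asarray(omega, dtype=float)
    _check_args(B, omega)
    diffs = np.abs(B[:, :, None] - B[:, None, :])  # persons x i x j
    return np.einsum("pij,ij->pi", diffs, omega)


def dissonance_panel(
    panel: BeliefPanel,
    model: NetworkModel | np.ndarray,
    variant: str = WEIGHTED,
    aggregation: str = PAIRWISE_ONCE,
) -> DissonanceScores:
    """Dissonance scores per person and wave from recorded beliefs.

    ``model`` may be a fitted :class:`NetworkModel` (its first-wave tie
    matrix is used; under the selected equal-ties specification it is
    constant across waves) or a raw tie matrix.  The unweighted variant
    replaces every off-diagonal tie by 1.
    """
    if panel.dialect == RAW:
        raise PanelError("dissonance expects rescaled beliefs; rescale first")
    panel.validate()
    if len(panel.topics) != 1:
        raise PanelError("dissonance_panel expects a single-topic panel")
    belief_ids = panel.belief_ids()
    if isinstance(model, NetworkModel):
        if list(model.belief_ids) != belief_ids:
            raise ValueError("panel and model belief sets disagree")
        omega = model.omega_by_wave[0]
    else:
        omega = np.asarray(model, dtype=float)
        if omega.shape[0] != len(belief_ids):
            raise ValueError("panel and tie-matrix belief sets disagree")
    if variant == UNWEIGHTED:
        omega = np.ones_like(omega)
        np.fill_diagonal(omega, 0.0)
    elif variant != WEIGHTED:
        raise ValueError(f"unknown variant {variant!r}")

    per_belief_frames, total_frames = [], []
    for wave in panel.waves:
        mat = panel.pivot(wave)
        H = dissonance_matrix(mat.to_numpy(dtype=float), omega)
        per_belief_frames.append(
            pd.DataFrame(
                {
                    "person_id": np.repeat(mat.index.to_numpy(), len(belief_ids)),
                    "wave": wave,
                    "belief_id": np.tile(belief_ids, len(mat)),
                    "H_i": H.ravel(),
                }
            )
        )
        factor = 0.5 if aggregation == PAIRWISE_ONCE else 1.0
        total_frames.append(
            pd.DataFrame(
                {
                    "person_id": mat.index.to_numpy(),
                    "wave": wave,
                    "H_total": factor * H.sum(axis=1),
                }
            )
        )
    return DissonanceScores(
        per_belief=pd.concat(per_belief_frames, ignore_index=True),
        totals=pd.concat(total_frames, ignore_index=True),
        variant=variant,
        aggregation=aggregation,
        topic=panel.topics[0],
    )
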