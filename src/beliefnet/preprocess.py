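"""Rescaling and fixed-effects residualization ahead of network estimation.

Likert responses (1..7) are mapped affinely onto the model's belief scale
[-1, 1].  Before the Gaussian graphical model is fitted, each belief is
regressed on person indicators (and optionally wave indicators) to remove
stable between-person differences; the residuals, split by wave, are what
the network likelihood sees.  Network dissonance, by contrast, is computed
downstream on the recorded (non-residualized) rescaled values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import BeliefPanel, CONTINUOUS, PanelError, RAW, RESCALED

__all__ = [
    "WaveMatrix",
    "rescale_beliefs",
    "likert_from_rescaled",
    "residualize",
    "wave_matrices",
]

PERSON_ONLY = "person_only"
PERSON_AND_WAVE = "person_and_wave"


@dataclass
class WaveMatrix:
    """Persons x beliefs matrix of continuous values at one wave."""

    wave: str
    frame: pd.DataFrame  # index: person_id, columns: belief_id

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="person_id")

    @classmethod
    def from_csv(cls, path, wave: str) -> "WaveMatrix":
        return cls(wave, pd.read_csv(path, index_col="person_id"))


def rescale_beliefs(panel: BeliefPanel) -> BeliefPanel:
    """Map raw Likert values onto [-1, 1] via value' = (value - 4) / 3."""
    if panel.dialect != RAW:
        raise PanelError("rescale_beliefs expects a raw-dialect panel")
    panel.validate()
    out = panel.data.copy()
    out["value"] = (out["value"] - 4.0) / 3.0
    return BeliefPanel(out, dialect=RESCALED)


def likert_from_rescaled(values: np.ndarray) -> np.ndarray:
    """Inverse map [-1, 1] -> {1..7}: affine, round half away from zero, clip.

    Exact inverse of :func:`rescale_beliefs` on the Likert grid.
    """
    x = 4.0 + 3.0 * np.asarray(values, dtype=float)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(rounded, 1, 7)


def wave_matrices(panel: BeliefPanel) -> list[WaveMatrix]:
    """Split a single-topic panel into per-wave persons x beliefs matrices."""
    if len(panel.topics) != 1:
        raise PanelError("wave_matrices expects a single-topic panel")
    return [WaveMatrix(w, panel.pivot(w)) for w in panel.waves]


def residualize(panel: BeliefPanel, mode: str = PERSON_ONLY) -> list[WaveMatrix]:
    """Partial person (and optionally wave) fixed effects out of each belief.

    For every belief the stacked observations (all persons, all waves) are
    regressed on person indicator variables -- equivalently, demeaned per
    person across waves.  In ``person_and_wave`` mode wave indicators are
    added; for the complete (balanced) panels this package requires, the
    two-way fit reduces to x - person_mean - wave_mean + grand_mean.

    Returns residual matrices split by wave, with consistent person and
    belief ordering.  In ``person_only`` mode the per-person mean residual
    is exactly zero for every belief, and wave-level means are preserved up
    to a common constant, which keeps per-wave intercepts estimable.
    """
    if panel.dialect == RAW:
        raise PanelError("residualize expects rescaled (or continuous) values")
    if mode not in (PERSON_ONLY, PERSON_AND_WAVE):
        raise ValueError(f"unknown residualization mode {mode!r}")
    panel.validate()
    if len(panel.topics) != 1:
        raise PanelError("residualize expects a single-topic panel")
    if len(panel.waves) < 2:
        raise PanelError("residualization needs at least two waves per person")

    mats = {w: panel.pivot(w) for w in panel.waves}
    stack = np.stack([mats[w].to_numpy(dtype=float) for w in panel.waves])  # T,N,K
    person_mean = stack.mean(axis=0, keepdims=True)
    resid = stack - person_mean
    if mode == PERSON_AND_WAVE:
        wave_mean = stack.mean(axis=1, keepdims=True)
        grand = stack.mean(axis=(0, 1), keepdims=True)
        resid = stack - person_mean - wave_mean + grand

    out = []
    for t, w in enumerate(panel.waves):
        frame = pd.DataFrame(
            resid[t], index=mats[w].index, columns=mats[w].columns
        )
        out.append(WaveMatrix(w, frame))
    return out
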