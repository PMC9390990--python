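"""Long-format longitudinal belief panels.

A :class:`BeliefPanel` holds one record per (person, wave, belief): the
person's response to one belief item at one measurement occasion, together
with the person's topic (which study arm they belong to) and experimental
group.  Responses come in three dialects:

``raw``
    Likert integers in {1..7} as administered in a survey.
``rescaled``
    The model's belief scale, values in [-1, 1].
``continuous``
    Unbounded continuous values (pre-rounding Gaussian draws or fixed-effect
    residuals); used internally for estimation diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAVES: tuple[str, ...] = ("W1", "W2a", "W2b", "W3")

RAW = "raw"
RESCALED = "rescaled"
CONTINUOUS = "continuous"
DIALECTS = (RAW, RESCALED, CONTINUOUS)

COLUMNS = ["person_id", "wave", "topic", "group", "belief_id", "value"]


class PanelError(ValueError):
    """Raised when a panel violates the complete-cases contract."""


@dataclass
class BeliefPanel:
    """Complete-cases long-format belief panel.

    Parameters
    ----------
    data
        DataFrame with columns ``person_id, wave, topic, group, belief_id,
        value``.  Every person must be observed on every belief of their
        topic at every wave (the analyses assume complete cases).
    dialect
        One of ``"raw"``, ``"rescaled"``, ``"continuous"``.
    """

    data: pd.DataFrame
    dialect: str = RAW

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelError(f"panel missing columns: {missing}")
        self.data = self.data[COLUMNS].copy()

    # -- structure ---------------------------------------------------------
    @property
    def waves(self) -> list[str]:
        present = set(self.data["wave"].unique())
        return [w for w in WAVES if w in present]

    @property
    def topics(self) -> list[str]:
        return sorted(self.data["topic"].unique())

    def belief_ids(self, topic: str | None = None) -> list[str]:
        df = self.data if topic is None else self.data[self.data["topic"] == topic]
        return sorted(df["belief_id"].unique())

    def persons(self, topic: str | None = None) -> list:
        df = self.data if topic is None else self.data[self.data["topic"] == topic]
        return sorted(df["person_id"].unique())

    def person_meta(self) -> pd.DataFrame:
        """One row per person with their topic and group."""
        meta = self.data[["person_id", "topic", "group"]].drop_duplicates()
        if meta["person_id"].duplicated().any():
            raise PanelError("a person is assigned to more than one topic/group")
        return meta.set_index("person_id")

    def for_topic(self, topic: str) -> "BeliefPanel":
        sub = self.data[self.data["topic"] == topic]
        if sub.empty:
            raise PanelError(f"unknown topic {topic!r}")
        return BeliefPanel(sub.reset_index(drop=True), dialect=self.dialect)

    def pivot(self, wave: str, topic: str | None = None) -> pd.DataFrame:
        """Persons x beliefs matrix of responses at one wave."""
        df = self.data if topic is None else self.data[self.data["topic"] == topic]
        df = df[df["wave"] == wave]
        if df.empty:
            raise PanelError(f"wave {wave!r} not present")
        mat = df.pivot(index="person_id", columns="belief_id", values="value")
        return mat.sort_index(axis=0).sort_index(axis=1)

    # -- validation --------------------------------------------------------
    def validate(self) -> "BeliefPanel":
        """Check panel invariants; raise :class:`PanelError` on violation."""
        if self.dialect not in DIALECTS:
            raise PanelError(f"unknown dialect {self.dialect!r}")
        bad_waves = set(self.data["wave"]) - set(WAVES)
        if bad_waves:
            raise PanelError(f"unknown wave labels: {sorted(bad_waves)}")
        if self.data["value"].isna().any():
            raise PanelError("panel contains missing values")
        keys = self.data[["person_id", "wave", "topic", "belief_id"]]
        if keys.duplicated().any():
            raise PanelError("duplicate (person, wave, belief) records")
        # complete grid per topic: persons x waves x beliefs
        for topic in self.topics:
            sub = self.data[self.data["topic"] == topic]
            n_p = sub["person_id"].nunique()
            n_w = sub["wave"].nunique()
            n_b = sub["belief_id"].nunique()
            if len(sub) != n_p * n_w * n_b:
                raise PanelError(
                    f"incomplete cases for topic {topic!r}: "
                    f"{len(sub)} records != {n_p} persons x {n_w} waves x {n_b} beliefs"
                )
        v = self.data["value"].to_numpy()
        if self.dialect == RAW:
            if not np.array_equal(v, np.round(v)) or v.min() < 1 or v.max() > 7:
                raise PanelError("raw dialect requires integers in 1..7")
        elif self.dialect == RESCALED:
            if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
                raise PanelError("rescaled dialect requires values in [-1, 1]")
        return self

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dialect: str = RAW) -> "BeliefPanel":
        return cls(pd.read_csv(path), dialect=dialect).validate()


def panel_from_arrays(
    values_by_wave: dict[str, np.ndarray],
    person_ids,
    belief_ids,
    topic: str,
    groups,
    dialect: str,
) -> BeliefPanel:
    """Assemble a single-topic panel from per-wave persons x beliefs arrays."""
    frames = []
    person_ids = np.asarray(person_ids)
    groups = np.asarray(groups)
    belief_ids = list(belief_ids)
    for wave, mat in values_by_wave.items():
        mat = np.asarray(mat)
        n, k = mat.shape
        frames.append(
            pd.DataFrame(
                {
                    "person_id": np.repeat(person_ids, k),
                    "wave": wave,
                    "topic": topic,
                    "group": np.repeat(groups, k),
                    "belief_id": np.tile(belief_ids, n),
                    "value": mat.ravel(),
                }
            )
        )
    return BeliefPanel(pd.concat(frames, ignore_index=True), dialect=dialect)


def concat_panels(panels: list[BeliefPanel]) -> BeliefPanel:
    dialects = {p.dialect for p in panels}
    if len(dialects) != 1:
        raise PanelError("cannot concatenate panels with mixed dialects")
    return BeliefPanel(
        pd.concat([p.data for p in panels], ignore_index=True), dialect=dialects.pop()
    )
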