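"""Statistical layer: change scores, correlations, and meta-analysis.

Per-group Pearson (or repeated-measures) correlations between dissonance and
subsequent belief change are pooled with a Fisher-z random-effects
meta-analysis (DerSimonian-Laird between-effect variance), with heterogeneity
Q and indicator-coded moderators tested by a Wald-type omnibus QM.
Dissonance reduction is pooled as standardized mean change d.  Weighted and
unweighted dissonance models are compared with the Meng-Rosenthal-Rubin test
for overlapping dependent correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dissonance import DissonanceScores
from .panel import BeliefPanel, PanelError, RAW, RESCALED

__all__ = [
    "EffectRecord",
    "MetaResult",
    "change_scores",
    "correlate_by_group",
    "multilevel_correlation",
    "meta_random_effects",
    "meta_moderators",
    "standardized_mean_change",
    "compare_dependent_correlations",
    "direction_summary",
]

FISHER_Z_R = "fisher_z_r"
STD_MEAN_CHANGE = "std_mean_change"


@dataclass
class EffectRecord:
    """One group-level effect entering a meta-analysis."""

    group: str
    topic: str
    effect: float
    n: int
    effect_type: str = FISHER_Z_R
    variance: float | None = None  # on the analysis (transformed) scale

    def __post_init__(self) -> None:
        if self.effect_type == FISHER_Z_R:
            if not abs(self.effect) < 1:
                raise ValueError("|r| < 1 required for a correlation effect")
            if self.n <= 3:
                raise ValueError("n >= 4 required for a correlation effect")


@dataclass
class MetaResult:
    """Pooled random-effects estimate with heterogeneity and moderators."""

    pooled: float  # back-transformed scale (r or d)
    pooled_transformed: float
    se: float
    p: float
    ci: tuple[float, float]
    tau2: float
    Q: float
    df: int
    p_Q: float
    k: int
    effect_type: str
    moderators: pd.DataFrame | None = None
    QM: float | None = None
    QM_df: int | None = None
    p_QM: float | None = None

    def to_dict(self) -> dict:
        out = {
            "pooled": self.pooled,
            "pooled_transformed": self.pooled_transformed,
            "se": self.se,
            "p": self.p,
            "ci": list(self.ci),
            "tau2": self.tau2,
            "Q": self.Q,
            "df": self.df,
            "p_Q": self.p_Q,
            "k": self.k,
            "effect_type": self.effect_type,
        }
        if self.moderators is not None:
            out["moderators"] = self.moderators.to_dict(orient="records")
            out["QM"] = self.QM
            out["QM_df"] = self.QM_df
            out["p_QM"] = self.p_QM
        return out


# ---------------------------------------------------------------------------
# change scores and correlations
# ---------------------------------------------------------------------------

def change_scores(
    panel: BeliefPanel, wave_a: str, wave_b: str, level: str = "average"
) -> pd.DataFrame:
    """Signed and absolute belief change between two waves.

    ``average`` level: per person, change in the mean over beliefs (the
    overall attitude), where opposite-signed belief changes cancel.
    ``belief`` level: per (person, belief) change.
    """
    if panel.dialect == RAW:
        raise PanelError("change_scores expects rescaled values")
    for w in (wave_a, wave_b):
        if w not in panel.waves:
            raise PanelError(f"wave {w!r} missing from panel")
    if len(panel.topics) != 1:
        raise PanelError("change_scores expects a single-topic panel")
    a = panel.pivot(wave_a)
    b = panel.pivot(wave_b)
    diff = b - a
    if level == "average":
        signed = diff.mean(axis=1)
        out = pd.DataFrame(
            {"person_id": signed.index, "signed": signed.values}
        )
        out["absolute"] = out["signed"].abs()
        return out.reset_index(drop=True)
    if level == "belief":
        long = diff.stack().rename("signed").reset_index()
        long.columns = ["person_id", "belief_id", "signed"]
        long["absolute"] = long["signed"].abs()
        return long
    raise ValueError(f"unknown level {level!r}")


def multilevel_correlation(x: pd.DataFrame, y: pd.DataFrame) -> float:
    """Repeated-measures correlation: Pearson r of within-person-centered values.

    ``x`` and ``y`` are persons x beliefs frames with identical indexes.
    Removing person means strips stable between-person differences, so each
    person contributes only the covariation across their own beliefs.
    Persons without within-person variance in x or y are excluded.
    """
    if not x.index.equals(y.index) or x.shape != y.shape:
        raise ValueError("x and y must be aligned persons x beliefs frames")
    if x.shape[1] < 2:
        raise ValueError("at least two beliefs per person required")
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    keep = (xv.std(axis=1) > 0) & (yv.std(axis=1) > 0)
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} person(s) with no within-person variance"
        )
    if not keep.any():
        raise ValueError("no person has within-person variance in both variables")
    xv, yv = xv[keep], yv[keep]
    xc = (xv - xv.mean(axis=1, keepdims=True)).ravel()
    yc = (yv - yv.mean(axis=1, keepdims=True)).ravel()
    return float(np.corrcoef(xc, yc)[0, 1])


def correlate_by_group(
    scores: DissonanceScores,
    change: pd.DataFrame,
    meta: pd.DataFrame,
    wave: str,
    level: str = "average",
    min_n: int = 4,
) -> list[EffectRecord]:
    """Per (group, topic) correlation between dissonance at ``wave`` and change.

    ``meta`` maps person_id -> (topic, group) (see ``BeliefPanel.person_meta``).
    ``average`` level correlates H_total with absolute average change;
    ``belief`` level computes the repeated-measures correlation of per-belief
    H_i with per-belief absolute change.  Groups with fewer than ``min_n``
    persons are dropped with a warning.
    """
    records: list[EffectRecord] = []
    for (topic, group), sub in meta.groupby(["topic", "group"], sort=True):
        persons = sub.index.intersection(change["person_id"].unique())
        if level == "average":
            h = scores.totals_at(wave).reindex(persons)
            c = change.set_index("person_id")["absolute"].reindex(persons)
            ok = h.notna() & c.notna()
            n = int(ok.sum())
            if n < min_n:
                warnings.warn(f"group {group!r}/{topic!r} dropped (n={n} < {min_n})")
                continue
            r = float(np.corrcoef(h[ok], c[ok])[0, 1])
        elif level == "belief":
            h = scores.per_belief_at(wave).reindex(persons).dropna()
            c = (
                change.pivot(index="person_id", columns="belief_id", values="absolute")
                .reindex(h.index)
                .sort_index(axis=1)
            )
            n = len(h)
            if n < min_n:
                warnings.warn(f"group {group!r}/{topic!r} dropped (n={n} < {min_n})")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = multilevel_correlation(h, c)
        else:
            raise ValueError(f"unknown level {level!r}")
        # degenerate perfect correlations are nudged inside the open interval
        # so they remain Fisher-z poolable
        r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        records.append(EffectRecord(group=str(group), topic=str(topic), effect=r, n=n))
    return records


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def _transform(effects: list[EffectRecord], effect_type: str):
    """Effects and sampling variances on the pooling scale."""
    y, v = [], []
    for e in effects:
        if effect_type == FISHER_Z_R:
            y.append(np.arctanh(e.effect))
            v.append(1.0 / (e.n - 3))
        elif effect_type == STD_MEAN_CHANGE:
            y.append(e.effect)
            v.append(
                e.variance
                if e.variance is not None
                else 1.0 / e.n + e.effect**2 / (2.0 * e.n)
            )
        else:
            raise ValueError(f"unknown effect type {effect_type!r}")
    return np.asarray(y), np.asarray(v)


def _back(value: float, effect_type: str) -> float:
    return float(np.tanh(value)) if effect_type == FISHER_Z_R else float(value)


def meta_random_effects(
    effects: list[EffectRecord], effect_type: str = FISHER_Z_R
) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    Correlations are pooled on the Fisher-z scale with variance 1/(n-3) and
    the pooled estimate back-transformed with tanh; standardized mean
    changes are pooled directly.  Q uses fixed-effect weights with df = k-1;
    tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)).
    """
    if not effects:
        raise ValueError("at least one effect required")
    y, v = _transform(effects, effect_type)
    k = y.size
    w = 1.0 / v
    yw = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - yw) ** 2))
    df = k - 1
    if df > 0:
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - df) / c)
        p_Q = float(stats.chi2.sf(Q, df))
    else:
        tau2, p_Q = 0.0, 1.0
    wstar = 1.0 / (v + tau2)
    pooled_t = float(np.sum(wstar * y) / np.sum(wstar))
    se = float(np.sqrt(1.0 / np.sum(wstar)))
    z = pooled_t / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci_t = (pooled_t - 1.959963984540054 * se, pooled_t + 1.959963984540054 * se)
    return MetaResult(
        pooled=_back(pooled_t, effect_type),
        pooled_transformed=pooled_t,
        se=se,
        p=p,
        ci=(_back(ci_t[0], effect_type), _back(ci_t[1], effect_type)),
        tau2=float(tau2),
        Q=Q,
        df=df,
        p_Q=p_Q,
        k=k,
        effect_type=effect_type,
    )


def meta_moderators(
    effects: list[EffectRecord],
    moderators: pd.DataFrame,
    effect_type: str = FISHER_Z_R,
) -> MetaResult:
    """Mixed-effects meta-regression with method-of-moments tau2.

    ``moderators`` holds one row per effect (indicator-coded covariates such
    as topic and experimental-vs-control); an intercept is prepended.  QM is
    the Wald chi-square omnibus test of all moderator coefficients.
    """
    y, v = _transform(effects, effect_type)
    k = y.size
    X = np.column_stack([np.ones(k), moderators.to_numpy(dtype=float)])
    p_dim = X.shape[1]
    if np.linalg.matrix_rank(X) < p_dim:
        raise ValueError("moderator design matrix is rank deficient")
    if k <= p_dim:
        raise ValueError("more coefficients than effects")

    # fixed-effect WLS residual heterogeneity
    W = np.diag(1.0 / v)
    XtW = X.T @ W
    beta_fe = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta_fe
    Q_E = float(resid @ W @ resid)
    # method-of-moments tau2 for meta-regression (DL generalization)
    P_tr = np.trace(np.linalg.solve(XtW @ X, X.T @ np.diag(1.0 / v**2) @ X))
    c = np.sum(1.0 / v) - P_tr
    tau2 = max(0.0, (Q_E - (k - p_dim)) / c)

    Wstar = np.diag(1.0 / (v + tau2))
    XtWs = X.T @ Wstar
    cov = np.linalg.inv(XtWs @ X)
    beta = cov @ (XtWs @ y)
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))

    bmod = beta[1:]
    covmod = cov[1:, 1:]
    QM = float(bmod @ np.linalg.solve(covmod, bmod))
    QM_df = p_dim - 1
    p_QM = float(stats.chi2.sf(QM, QM_df))

    coef_table = pd.DataFrame(
        {
            "term": ["intercept"] + list(moderators.columns),
            "b": beta,
            "se": se,
            "z": zvals,
            "p": pvals,
        }
    )
    pooled_t = float(beta[0])
    return MetaResult(
        pooled=_back(pooled_t, effect_type),
        pooled_transformed=pooled_t,
        se=float(se[0]),
        p=float(pvals[0]),
        ci=(
            _back(pooled_t - 1.959963984540054 * se[0], effect_type),
            _back(pooled_t + 1.959963984540054 * se[0], effect_type),
        ),
        tau2=float(tau2),
        Q=Q_E,
        df=k - p_dim,
        p_Q=float(stats.chi2.sf(Q_E, k - p_dim)),
        k=k,
        effect_type=effect_type,
        moderators=coef_table,
        QM=QM,
        QM_df=QM_df,
        p_QM=p_QM,
    )


def standardized_mean_change(pre, post) -> tuple[float, float]:
    """Paired standardized mean change d = mean(pre - post) / sd(pre - post).

    Positive d means the quantity decreased.  Sampling variance
    1/n + d^2 / (2n).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be paired 1-d vectors")
    n = pre.size
    if n < 4:
        raise ValueError("n >= 4 required")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: d undefined")
    d = float(diff.mean() / sd)
    return d, 1.0 / n + d**2 / (2.0 * n)


def compare_dependent_correlations(
    r_wx: float, r_wy: float, r_xy: float, n: int
) -> tuple[float, float]:
    """Meng-Rosenthal-Rubin z test for two overlapping dependent correlations.

    r_wx and r_wy share the common variable w (here: belief change), and
    r_xy is the correlation between the two predictors (weighted and
    unweighted dissonance).  Returns (z, two-sided p).
    """
    for r in (r_wx, r_wy, r_xy):
        if not abs(r) < 1:
            raise ValueError("|r| < 1 required")
    if n < 10:
        raise ValueError("n >= 10 required")
    corr = np.array([[1, r_wx, r_wy], [r_wx, 1, r_xy], [r_wy, r_xy, 1]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")
    rbar2 = (r_wx**2 + r_wy**2) / 2.0
    f = min(1.0, (1.0 - r_xy) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (np.arctanh(r_wx) - np.arctanh(r_wy)) * np.sqrt(
        (n - 3) / (2.0 * (1.0 - r_xy) * h)
    )
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# direction of change
# ---------------------------------------------------------------------------

def direction_summary(panel: BeliefPanel, topic: str) -> dict:
    """Proportions of positive vs negative average change and initial strata.

    Per person the mean signed change in the belief average across
    consecutive waves classifies them as moving toward acceptance (positive)
    or skepticism (negative); persons with exactly zero mean change are
    counted separately.  Initial strata use the raw 1..7 mean at the first
    wave with cutoffs 3.5 and 4.5 (negative / neutral / positive).
    """
    sub = panel.for_topic(topic)
    if len(sub.waves) < 2:
        raise PanelError("direction_summary needs at least two waves")
    if sub.dialect == RAW:
        raw_first = sub.pivot(sub.waves[0]).mean(axis=1)
        values = {w: (sub.pivot(w) - 4.0) / 3.0 for w in sub.waves}
    elif sub.dialect == RESCALED:
        values = {w: sub.pivot(w) for w in sub.waves}
        raw_first = 4.0 + 3.0 * values[sub.waves[0]].mean(axis=1)
    else:
        raise PanelError("direction_summary expects raw or rescaled dialect")

    waves = sub.waves
    deltas = [
        (values[waves[t + 1]] - values[waves[t]]).mean(axis=1)
        for t in range(len(waves) - 1)
    ]
    mean_change = pd.concat(deltas, axis=1).mean(axis=1)
    n_pos = int((mean_change > 0).sum())
    n_neg = int((mean_change < 0).sum())
    n_zero = int((mean_change == 0).sum())
    n_changers = n_pos + n_neg

    m = raw_first.to_numpy(dtype=float)
    labels = np.select([m < 3.5, m > 4.5], ["negative", "positive"], default="neutral")
    strata_counts = pd.Series(labels).value_counts().to_dict()
    return {
        "topic": topic,
        "n": int(len(mean_change)),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "n_zero": n_zero,
        "prop_positive": n_pos / n_changers if n_changers else float("nan"),
        "prop_negative": n_neg / n_changers if n_changers else float("nan"),
        "strata_counts": {str(k): int(cnt) for k, cnt in strata_counts.items()},
    }
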