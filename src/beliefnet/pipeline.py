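"""End-to-end orchestration: generate -> preprocess -> estimate -> dissonance
-> analyze, with a manifest of every artifact written.

The pipeline reproduces the analysis order of a longitudinal belief-change
study: estimate the group-level belief network per topic, score each
person's network dissonance at every wave, test whether dissonance predicts
subsequent absolute belief change (per-group correlations pooled by
Fisher-z random-effects meta-analysis with topic and condition moderators),
test whether dissonance decreases across the intervention (standardized
mean change meta-analysis), compare weighted against unweighted dissonance,
and summarize the direction of change by initial-belief strata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dissonance import UNWEIGHTED, WEIGHTED, dissonance_panel
from .inference_stats import (
    FISHER_Z_R,
    STD_MEAN_CHANGE,
    EffectRecord,
    change_scores,
    compare_dependent_correlations,
    correlate_by_group,
    direction_summary,
    meta_moderators,
    meta_random_effects,
    multilevel_correlation,
    standardized_mean_change,
)
from .network_estimation import (
    ConstraintSpec,
    fit_spec,
    prune_stepup,
    sample_moments,
    select_spec,
)
from .panel import RAW, WAVES, BeliefPanel, PanelError, concat_panels
from .preprocess import PERSON_ONLY, rescale_beliefs, residualize
from .synthetic_data import (
    DEFAULT_PROFILE,
    make_ground_truth,
    simulate_panel_dynamics,
    simulate_panel_ggm,
)

log = logging.getLogger("beliefnet.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class TopicConfig:
    name: str
    n: int = 300
    n_beliefs: int = 20
    groups: list[str] = field(default_factory=lambda: ["control", "g1", "g2"])


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "beliefnet_run"
    # input
    input_kind: str = "synthetic"  # or "csv"
    panel_path: str | None = None
    panel_dialect: str = RAW
    generator: str = "dynamics"  # or "ggm"
    topics: list[TopicConfig] = field(
        default_factory=lambda: [
            TopicConfig("gm_food", 549, 20, ["control", "g1", "g2", "g3", "g4", "g5"]),
            TopicConfig("vaccines", 430, 20, ["control", "g1", "g2", "g3", "g4"]),
        ]
    )
    sparsity: float = 0.5
    beta_by_wave: list[float] = field(default_factory=lambda: [0.6, 0.9, 1.0, 0.8])
    sweeps_between_waves: list[int] = field(default_factory=lambda: [2, 1, 2])
    intervention_shift: float = 0.2
    # analysis
    residualize_mode: str = PERSON_ONLY
    spec_search: str = "winning"  # or "full"
    dissonance_wave: str = "W2a"
    change_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("W2a", "W2b"), ("W2b", "W3")]
    )
    control_group: str = "control"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        topics = [TopicConfig(**t) for t in raw.pop("topics", [])] or None
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        unknown = set(raw) - set(cls.__dataclass_fields__) - {"topics"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if topics:
            cfg.topics = topics
        cfg.change_pairs = [tuple(p) for p in cfg.change_pairs]
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> "PipelineConfig":
        if self.input_kind not in ("synthetic", "csv"):
            raise ConfigError(f"unknown input kind {self.input_kind!r}")
        if self.input_kind == "csv" and not self.panel_path:
            raise ConfigError("csv input requires panel_path")
        if self.generator not in ("dynamics", "ggm"):
            raise ConfigError(f"unknown generator {self.generator!r}")
        if self.spec_search not in ("winning", "full"):
            raise ConfigError(f"unknown spec_search {self.spec_search!r}")
        referenced = {self.dissonance_wave}
        referenced.update(w for pair in self.change_pairs for w in pair)
        bad = referenced - set(WAVES)
        if bad:
            raise ConfigError(f"config references unknown waves: {sorted(bad)}")
        return self


def _subseed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _build_panel(cfg: PipelineConfig) -> tuple[BeliefPanel, dict]:
    """Generate (or load) the study panel; returns panel + ground-truth map."""
    if cfg.input_kind == "csv":
        panel = BeliefPanel.from_csv(cfg.panel_path, dialect=cfg.panel_dialect)
        return panel, {}
    truths, parts = {}, []
    for ti, topic in enumerate(cfg.topics):
        gt = make_ground_truth(
            K=topic.n_beliefs,
            sparsity=cfg.sparsity,
            seed=_subseed(cfg.seed, 1, ti),
        )
        truths[topic.name] = gt
        n_groups = len(topic.groups)
        sizes = [topic.n // n_groups] * n_groups
        for i in range(topic.n - sum(sizes)):
            sizes[i] += 1
        for gi, (group, size) in enumerate(zip(topic.groups, sizes)):
            seed = _subseed(cfg.seed, 2, ti, gi)
            if cfg.generator == "dynamics":
                half = topic.n_beliefs // 2
                intervention = (
                    None
                    if group == cfg.control_group
                    else ("W2a", list(range(half, topic.n_beliefs)), cfg.intervention_shift)
                )
                sub = simulate_panel_dynamics(
                    gt,
                    size,
                    beta_by_wave=cfg.beta_by_wave,
                    sweeps_between_waves=cfg.sweeps_between_waves,
                    intervention=intervention,
                    seed=seed,
                    topic=topic.name,
                    groups=[group],
                    dialect="raw",
                )
            else:
                sub = simulate_panel_ggm(
                    gt, size, seed=seed, topic=topic.name, groups=[group], dialect="raw"
                )
            sub.data["person_id"] = (
                f"{topic.name}:{group}:" + sub.data["person_id"].astype(str)
            )
            parts.append(sub)
    return concat_panels(parts).validate(), truths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to outdir)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts[name] = _sha256(path)

    def _stage(name: str):
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = _stage("input")
        panel, truths = _build_panel(config)
        _write("panel.csv", panel.to_csv)
        for tname, gt in truths.items():
            _write(f"ground_truth_{tname}.json", gt.to_json)
        timings["input"] = time.perf_counter() - t0

        t0 = _stage("preprocess")
        rescaled = rescale_beliefs(panel) if panel.dialect == RAW else panel
        timings["preprocess"] = time.perf_counter() - t0

        t0 = _stage("estimate")
        models = {}
        for tname in rescaled.topics:
            tp = rescaled.for_topic(tname)
            mats = residualize(tp, mode=config.residualize_mode)
            moments = sample_moments(mats)
            if config.spec_search == "full":
                model, table = select_spec(moments)
            else:
                # the typical winning specification: sparse, equal ties,
                # equal intercepts, free scaling
                spec = ConstraintSpec(omega_equal=True, mu_equal=True, delta_equal=False)
                dense = fit_spec(moments, spec)
                model = prune_stepup(moments, spec, dense)
                table = pd.DataFrame(
                    [
                        {
                            "omega_equal": True,
                            "mu_equal": True,
                            "delta_equal": False,
                            "sparse": s,
                            "n_params": m.n_params,
                            "loglik": m.loglik,
                            "bic": m.bic,
                            "converged": m.converged,
                            "error": "",
                        }
                        for s, m in [(False, dense), (True, model)]
                    ]
                )
            models[tname] = model
            _write(f"model_{tname}.json", model.to_json)
            _write(
                f"edges_{tname}.csv",
                lambda p, m=model: m.edge_list().to_csv(p, index=False),
            )
            _write(
                f"spec_comparison_{tname}.csv",
                lambda p, t=table: t.to_csv(p, index=False),
            )
        timings["estimate"] = time.perf_counter() - t0

        t0 = _stage("dissonance")
        scores = {}
        for tname in rescaled.topics:
            tp = rescaled.for_topic(tname)
            for variant in (WEIGHTED, UNWEIGHTED):
                sc = dissonance_panel(tp, models[tname], variant=variant)
                scores[(tname, variant)] = sc
                _write(
                    f"dissonance_{tname}_{variant}.csv",
                    lambda p, s=sc: s.per_belief.to_csv(p, index=False),
                )
                _write(
                    f"dissonance_totals_{tname}_{variant}.csv",
                    lambda p, s=sc: s.totals.to_csv(p, index=False),
                )
        timings["dissonance"] = time.perf_counter() - t0

        t0 = _stage("analyze")
        meta_map = rescaled.person_meta()
        analysis: dict = {}
        effects_rows = []
        for wave_a, wave_b in config.change_pairs:
            pair_key = f"{wave_a}_to_{wave_b}"
            analysis[pair_key] = {}
            for level in ("average", "belief"):
                effects: list[EffectRecord] = []
                for tname in rescaled.topics:
                    tp = rescaled.for_topic(tname)
                    change = change_scores(tp, wave_a, wave_b, level=level)
                    effects.extend(
                        correlate_by_group(
                            scores[(tname, WEIGHTED)],
                            change,
                            meta_map.loc[meta_map["topic"] == tname],
                            wave=wave_a,
                            level=level,
                        )
                    )
                if not effects:
                    continue
                pooled = meta_random_effects(effects, FISHER_Z_R)
                entry = {"meta": pooled.to_dict()}
                if len(effects) >= 4:
                    mods = pd.DataFrame(
                        {
                            "topic_is_second": [
                                float(e.topic == rescaled.topics[-1]) for e in effects
                            ],
                            "experimental": [
                                float(e.group != config.control_group) for e in effects
                            ],
                        }
                    )
                    try:
                        entry["moderated"] = meta_moderators(
                            effects, mods, FISHER_Z_R
                        ).to_dict()
                    except ValueError as exc:
                        entry["moderated"] = {"error": str(exc)}
                analysis[pair_key][level] = entry
                effects_rows.extend(
                    {
                        "pair": pair_key,
                        "level": level,
                        "group": e.group,
                        "topic": e.topic,
                        "effect": e.effect,
                        "n": e.n,
                        "type": e.effect_type,
                    }
                    for e in effects
                )
        _write(
            "effects.csv",
            lambda p: pd.DataFrame(effects_rows).to_csv(p, index=False),
        )

        # dissonance reduction: standardized mean change of H across pairs
        reduction = {}
        for wave_a, wave_b in config.change_pairs:
            effects = []
            for tname in rescaled.topics:
                sc = scores[(tname, WEIGHTED)]
                tm = meta_map.loc[meta_map["topic"] == tname]
                for group, sub in tm.groupby("group"):
                    pre = sc.totals_at(wave_a).reindex(sub.index).dropna()
                    post = sc.totals_at(wave_b).reindex(pre.index)
                    try:
                        d, var = standardized_mean_change(pre.to_numpy(), post.to_numpy())
                    except ValueError:
                        continue
                    effects.append(
                        EffectRecord(
                            group=str(group),
                            topic=tname,
                            effect=d,
                            n=len(pre),
                            effect_type=STD_MEAN_CHANGE,
                            variance=var,
                        )
                    )
            if effects:
                reduction[f"{wave_a}_to_{wave_b}"] = meta_random_effects(
                    effects, STD_MEAN_CHANGE
                ).to_dict()
        analysis["dissonance_reduction"] = reduction

        # weighted vs unweighted model comparison (pooled over persons)
        comparison = {}
        for wave_a, wave_b in config.change_pairs:
            for level in ("average", "belief"):
                rs = _pooled_comparison(
                    rescaled, scores, wave_a, wave_b, level
                )
                if rs is not None:
                    comparison[f"{wave_a}_to_{wave_b}:{level}"] = rs
        analysis["model_comparison"] = comparison

        analysis["direction"] = {
            t: direction_summary(rescaled, t) for t in rescaled.topics
        }
        _write(
            "analysis.json",
            lambda p: Path(p).write_text(json.dumps(analysis, indent=1)),
        )
        timings["analyze"] = time.perf_counter() - t0
    except Exception as exc:
        log.error("pipeline stage failed: %s", exc)
        raise

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _pooled_comparison(rescaled, scores, wave_a, wave_b, level):
    """Meng test of weighted vs unweighted dissonance over pooled persons."""
    hw_all, hu_all, ch_all = [], [], []
    for tname in rescaled.topics:
        tp = rescaled.for_topic(tname)
        change = change_scores(tp, wave_a, wave_b, level=level)
        if level == "average":
            hw = scores[(tname, WEIGHTED)].totals_at(wave_a)
            hu = scores[(tname, UNWEIGHTED)].totals_at(wave_a)
            ch = change.set_index("person_id")["absolute"].reindex(hw.index)
            hw_all.append(hw.to_numpy())
            hu_all.append(hu.to_numpy())
            ch_all.append(ch.to_numpy())
        else:
            hw = scores[(tname, WEIGHTED)].per_belief_at(wave_a)
            hu = scores[(tname, UNWEIGHTED)].per_belief_at(wave_a)
            cm = (
                change.pivot(index="person_id", columns="belief_id", values="absolute")
                .reindex(hw.index)
                .sort_index(axis=1)
            )
            # within-person centering, then pool the centered values
            for arrs, mat in ((hw_all, hw), (hu_all, hu), (ch_all, cm)):
                v = mat.to_numpy(dtype=float)
                arrs.append((v - v.mean(axis=1, keepdims=True)).ravel())
    hw = np.concatenate(hw_all)
    hu = np.concatenate(hu_all)
    ch = np.concatenate(ch_all)
    n = len(set(rescaled.data["person_id"])) if level == "belief" else hw.size
    if np.std(hw) == 0 or np.std(hu) == 0 or np.std(ch) == 0:
        return None
    r_wx = float(np.corrcoef(ch, hw)[0, 1])
    r_wy = float(np.corrcoef(ch, hu)[0, 1])
    r_xy = float(np.corrcoef(hw, hu)[0, 1])
    try:
        z, p = compare_dependent_correlations(r_wx, r_wy, r_xy, n)
    except ValueError:
        z, p = float("nan"), float("nan")
    return {
        "r_weighted": r_wx,
        "r_unweighted": r_wy,
        "r_between": r_xy,
        "n": int(n),
        "z": z,
        "p": p,
    }
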