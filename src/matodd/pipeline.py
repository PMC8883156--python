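"""End-to-end orchestration: stimuli -> responses -> d' -> features -> regression.

Every stage reads and writes files; a manifest of content hashes and the
resolved configuration make any run reproducible from (config, code).  All
randomness descends from a single master seed through stable per-artifact
hashes.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import io as mio
from . import regression as reg
from . import stimuli as stim
from .psychophysics import (
    OddityDesign,
    ResponseRecord,
    TaskCondition,
    aggregate,
    cross_environment_regression,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "make_link", "default_conditions", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    master_seed: int = 0
    dimensions: tuple[str, ...] = stim.DIMENSIONS
    objects: tuple[int, ...] = (1, 2, 3, 4, 5)
    illuminations: tuple[int, ...] = (1, 2, 3)
    #: difficulties per dimension; None means the full grid minus the anchor
    difficulties: dict[str, tuple[float, ...]] | None = None
    image_size: int = 128
    n_crowd_observers: int = 100
    n_lab_observers: int = 20
    lab_repetitions: int = 10
    link_gain: float = 3.0
    crowd_attenuation: float = 0.8
    lapse: float = 0.02
    feature_variant: str = "ps_color"
    n_resamples: int = 200
    support: int = reg.DEFAULT_SUPPORT
    n_sim: int = 200_000
    out_dir: str = "matodd_out"

    def validate(self) -> None:
        for d in self.dimensions:
            if d not in stim.DIMENSIONS:
                raise ValueError(f"unknown dimension {d!r}")
        if "GP" in self.dimensions and 1 not in self.illuminations:
            raise ValueError(
                "GP (glossy vs painted) exists only under illumination "
                "condition 1, which this config does not include"
            )
        if self.feature_variant not in feat.VARIANTS:
            raise ValueError(f"unknown feature variant {self.feature_variant!r}")
        if self.difficulties:
            for dim, vals in self.difficulties.items():
                for v in vals:
                    stim.MaterialSpec(dim, v)  # grid check

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dimensions"] = list(self.dimensions)
        d["objects"] = list(self.objects)
        d["illuminations"] = list(self.illuminations)
        if self.difficulties is not None:
            d["difficulties"] = {k: list(v) for k, v in self.difficulties.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("dimensions", "objects", "illuminations"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("difficulties"):
            d["difficulties"] = {k: tuple(v) for k, v in d["difficulties"].items()}
        return cls(**d)


def _grid_difficulties(dimension: str) -> tuple[float, ...]:
    grid = stim.PARAMETER_GRIDS[dimension]
    if dimension == "GP":
        return grid
    anchor = stim.ANCHORS[dimension]
    return tuple(v for v in grid if abs(v - anchor) > 1e-9)


def default_conditions(config: PipelineConfig) -> list[TaskCondition]:
    """Expand the config into the full list of task conditions.

    GP is restricted to illumination condition 1 (matching the stimulus
    design: histogram-matched painted objects are only constructed under a
    single illumination).
    """
    conds = []
    for dim in config.dimensions:
        if config.difficulties and dim in config.difficulties:
            diffs = config.difficulties[dim]
        else:
            diffs = _grid_difficulties(dim)
        for ill in config.illuminations:
            if dim == "GP" and ill != 1:
                continue
            for obj in config.objects:
                for v in diffs:
                    conds.append(TaskCondition(dim, obj, ill, float(v)))
    return conds


def make_link(dimension: str, gain: float):
    """Ground-truth mapping from stimulus parameter distance to d'.

    Distances are normalized by the dimension's maximum distance from the
    anchor, so a full-grid step yields d' = gain on every dimension.  OT
    distances are taken on a log scale, matching its geometric parameter
    grid.  link(0) = 0 and the map is monotone nondecreasing.
    """
    if dimension == "GP":
        return lambda delta: gain * (1.0 if delta > 0 else 0.0)
    if dimension == "OT":
        return _ot_link(gain)
    grid = np.array(stim.PARAMETER_GRIDS[dimension], dtype=float)
    anchor = stim.ANCHORS[dimension]
    dmax = float(np.max(np.abs(grid - anchor)))
    return lambda delta: gain * min(abs(delta) / dmax, 1.0)


def _ot_link(gain: float):
    grid = np.array(stim.PARAMETER_GRIDS["OT"], dtype=float)
    anchor = 1.0
    dmax = float(np.max(np.abs(np.log(grid) - np.log(anchor))))

    def link(delta: float) -> float:
        if delta <= 0:
            return 0.0
        value = max(anchor - delta, float(grid.min()))
        return gain * min(abs(np.log(value) - np.log(anchor)) / dmax, 1.0)

    return link


def links_for(config: PipelineConfig, environment: str) -> dict[str, object]:
    gain = config.link_gain
    if environment == "crowd":
        gain *= config.crowd_attenuation
    out = {}
    for dim in config.dimensions:
        out[dim] = _ot_link(gain) if dim == "OT" else make_link(dim, gain)
    return out


# ---------------------------------------------------------------------------
# stages

def generate_stimuli(config: PipelineConfig, out: Path) -> list[Path]:
    """Render every stimulus image of the configured corpus to PNG."""
    paths = []
    for cond in default_conditions(config):
        for img, scene, value in _condition_images(cond, config):
            p = mio.stimulus_path(
                out, cond.dimension, cond.illumination, cond.object_id,
                value, scene.pose_deg,
            )
            if not p.exists():
                mio.save_png(img, p)
            paths.append(p)
    return paths


def _condition_scenes(cond: TaskCondition) -> list[stim.SceneSpec]:
    geom = stim.OBJECTS[cond.object_id]
    if cond.illumination == 1:
        return [stim.SceneSpec(geom, 1, p) for p in stim.POSES_DEG]
    return [
        stim.SceneSpec(geom, pid, 0)
        for pid in stim.proxies_for_condition(cond.illumination)
    ]


def _condition_images(cond: TaskCondition, config: PipelineConfig):
    """The stimulus set of one condition: target and non-target renders
    across the condition's pose/illumination combinations."""
    size = config.image_size
    for scene in _condition_scenes(cond):
        if cond.dimension == "GP":
            yield (
                stim.render_object(
                    scene, stim.MaterialSpec("GP", cond.difficulty), size
                ),
                scene,
                cond.difficulty,
            )
            seed = stim.derive_seed(
                config.master_seed, "gp", cond.label(), scene.pose_deg,
                scene.illumination_id,
            )
            yield (
                stim.make_inconsistent_highlights(
                    scene, cond.difficulty, seed=seed, size=size
                ),
                scene,
                -cond.difficulty,  # painted variant tagged by sign in filenames
            )
        else:
            anchor = stim.ANCHORS[cond.dimension]
            for value in (cond.difficulty, anchor):
                yield (
                    stim.render_object(
                        scene, stim.MaterialSpec(cond.dimension, value), size
                    ),
                    scene,
                    value,
                )


def simulate_observers(
    config: PipelineConfig, environment: str
) -> list[ResponseRecord]:
    """Synthetic response tables for one environment.

    Crowd: ``n_crowd_observers`` observers, one judgment per condition.
    Lab: ``n_lab_observers`` observers, ``lab_repetitions`` judgments per
    condition.  Crowd sensitivity is attenuated by ``crowd_attenuation``.
    """
    links = links_for(config, environment)
    if environment == "lab":
        n_obs, n_rep = config.n_lab_observers, config.lab_repetitions
    else:
        n_obs, n_rep = config.n_crowd_observers, 1
    records = []
    for cond in default_conditions(config):
        link = links[cond.dimension]
        for obs in range(n_obs):
            for rep in range(n_rep):
                seed = stim.derive_seed(
                    config.master_seed, environment, cond.label(), obs, rep
                )
                records.append(
                    stim.simulate_observer(
                        cond,
                        link,
                        lapse=config.lapse,
                        seed=seed,
                        observer_id=f"{environment}_{obs:04d}",
                        environment=environment,
                    )
                )
    return records


def estimate_dprime(
    records: list[ResponseRecord], config: PipelineConfig, environment: str
) -> pd.DataFrame:
    mode = "per_observer" if environment == "lab" else "pooled"
    estimates = aggregate(
        records, mode=mode, n_sim=config.n_sim, seed=config.master_seed
    )
    rows = []
    for cond, est in estimates.items():
        rows.append(
            {
                "condition": cond.label(),
                "task": cond.dimension,
                "object": cond.object_id,
                "illumination": cond.illumination,
                "difficulty": cond.difficulty,
                "pc": est.pc,
                "n_trials": est.n_trials,
                "chance": est.chance,
                "d_prime": est.d_prime,
                "sem": est.sem if est.sem is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("condition").sort_index()


def extract_condition_features(config: PipelineConfig) -> pd.DataFrame:
    """Per-condition, per-image feature vectors for the configured variant."""
    # white per illumination condition: average over its proxies
    white_by_cond = {}
    for ill in config.illuminations:
        pids = stim.proxies_for_condition(ill)
        white_by_cond[ill] = np.mean(
            [stim.white_point(pid) for pid in pids], axis=0
        )
    rows = []
    index = []
    for cond in default_conditions(config):
        wp = white_by_cond[cond.illumination]
        for i, (img, scene, value) in enumerate(_condition_images(cond, config)):
            fv = feat.extract_features(img, wp, config.feature_variant)
            rows.append(fv.as_series())
            index.append((cond.label(), i))
    df = pd.DataFrame(rows)
    df.index = pd.MultiIndex.from_tuples(index, names=["condition", "image"])
    return df


def condition_distances(features_df: pd.DataFrame) -> pd.DataFrame:
    """Per-feature distance rows (one per condition) from per-image features."""
    flat = features_df.reset_index(level="image", drop=True)
    z = feat.zscore_columns(flat)
    rows = {}
    for cond, grp in z.groupby(level=0):
        rows[cond] = feat.per_feature_distances(grp)
    return pd.DataFrame(rows).T.sort_index()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and write a manifest of artifact hashes."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "artifacts": {}}

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0):
        manifest["stages"][name] = round(time.time() - t0, 3)
        logger.info("stage %s finished in %.1fs", name, manifest["stages"][name])

    try:
        t0 = stage("generate_stimuli")
        stim_dir = out / "stimuli"
        generate_stimuli(config, stim_dir)
        done("generate_stimuli", t0)

        t0 = stage("simulate_observers")
        lab_records = simulate_observers(config, "lab")
        crowd_records = simulate_observers(config, "crowd")
        mio.write_responses(lab_records, out / "responses_lab.csv")
        mio.write_responses(crowd_records, out / "responses_crowd.csv")
        done("simulate_observers", t0)

        t0 = stage("estimate_dprime")
        lab_est = estimate_dprime(lab_records, config, "lab")
        crowd_est = estimate_dprime(crowd_records, config, "crowd")
        lab_est.to_csv(out / "dprime_lab.csv")
        crowd_est.to_csv(out / "dprime_crowd.csv")
        common = lab_est.index.intersection(crowd_est.index)
        line = cross_environment_regression(
            lab_est.loc[common, "d_prime"].to_numpy(),
            crowd_est.loc[common, "d_prime"].to_numpy(),
        )
        mio.write_json(
            {
                "slope": line.slope,
                "intercept": line.intercept,
                "r_squared": line.r_squared,
                "n_conditions": int(len(common)),
            },
            out / "environment_regression.json",
        )
        done("estimate_dprime", t0)

        t0 = stage("extract_features")
        feats = extract_condition_features(config)
        feats.to_csv(out / "features.csv")
        dists = condition_distances(feats)
        dists.to_csv(out / "feature_distances.csv")
        done("extract_features", t0)

        t0 = stage("regress")
        dataset = reg.assemble_dataset(
            dists,
            lab_est.loc[dists.index, "d_prime"],
            lab_est.loc[dists.index, "task"],
        )
        result = reg.resample_evaluate(
            dataset,
            condition_name=config.feature_variant,
            n_resamples=config.n_resamples,
            seed=config.master_seed,
            support=min(config.support, dists.shape[1] - 1),
        )
        mio.write_json(
            {
                "condition": result.condition_name,
                "median_mse": result.median_mse,
                "median_r2": result.median_r2,
                "support": result.support,
                "per_task_mse": result.per_task_mse.to_dict(orient="records"),
            },
            out / "regression.json",
        )
        done("regress", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.suffix in (".csv", ".json", ".png"):
            manifest["artifacts"][str(p.relative_to(out))] = mio.file_sha256(p)
    mio.write_json(manifest, out / "manifest.json")
    return manifest
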