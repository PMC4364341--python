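"""End-to-end orchestration: simulate -> T2 map -> texture -> functional
summary -> histology scoring -> group statistics, under one YAML config
with a single global seed and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

import myotex
from myotex import biomechanics, group_stats, histo_scoring, synthetic_data
from myotex.synthetic_data import (
    CohortSpec,
    GROUPS,
    MuscleSpec,
    PhantomSpec,
    generate_cohort,
    generate_histo_counts,
    generate_phantom,
    treated_means_from_rescue,
)
from myotex.t2_mapping import fit_t2
from myotex.texture_analysis import TextureConfig, muscle_features, weighted_composite

__all__ = ["ConfigError", "RunConfig", "default_config", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised with the complete list of configuration problems."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in self.errors))


@dataclass
class RunConfig:
    seed: int
    phantom: PhantomSpec
    lesion_fraction_by_group: dict[str, float]
    n_imaging_per_group: int
    cohort: CohortSpec
    texture: TextureConfig
    histo_untreated_means: pd.DataFrame
    histo_rescue_percent: pd.DataFrame
    histo_dispersion: float
    histo_significant: pd.DataFrame | None
    comparisons: list[tuple[str, str]]
    adjust: bool
    raw: dict = field(repr=False, default_factory=dict)


def default_config() -> dict:
    """A small, fast demo configuration exercising every stage."""
    return {
        "seed": 0,
        "phantom": {
            "grid_shape": [24, 24, 24],
            "voxel_size": [1.0, 1.0, 1.0],
            "muscles": [
                {"label": 1, "name": "muscle_a", "volume_fraction": 0.16, "baseline_t2": 43.0},
                {"label": 2, "name": "muscle_b", "volume_fraction": 0.16, "baseline_t2": 39.0},
            ],
            "lesion_t2_shift": 30.0,
            "lesion_patch_radius": 2,
            "echo_times": [float(t) for t in range(10, 101, 10)],
            "s0": 1000.0,
            "noise_sd": 5.0,
        },
        "imaging": {
            "n_per_group": 3,
            "lesion_fraction_by_group": {"WT": 0.0, "WT+NBD": 0.0, "GRMD": 0.2, "GRMD+NBD": 0.1},
        },
        "cohort": {
            "n_per_group": {"WT": 8, "WT+NBD": 3, "GRMD": 10, "GRMD+NBD": 6},
            "variables": {
                "body_mass": {
                    "WT": [17.80, 0.44], "WT+NBD": [21.10, 3.15],
                    "GRMD": [13.40, 2.20], "GRMD+NBD": [12.70, 2.81],
                },
                "extension_force_per_kg": {
                    "WT": [2.61, 0.49], "WT+NBD": [2.00, 0.22],
                    "GRMD": [1.56, 0.92], "GRMD+NBD": [2.70, 0.65],
                },
                "flexion_force_per_kg": {
                    "WT": [1.30, 0.13], "WT+NBD": [1.24, 0.19],
                    "GRMD": [0.62, 0.18], "GRMD+NBD": [0.55, 0.13],
                },
                "ecd_1_30": {
                    "WT": [17.86, 5.20], "WT+NBD": [23.25, 17.4],
                    "GRMD": [54.30, 14.73], "GRMD+NBD": [54.48, 13.64],
                },
                "cs_circumference": {
                    "WT": [2.09, 0.40], "WT+NBD": [2.30, 0.49],
                    "GRMD": [4.03, 1.04], "GRMD+NBD": [3.67, 0.65],
                },
            },
        },
        # fixed-range binning keeps the gray-level scale common across groups;
        # per-ROI min-max would rescale a lesion-free noisy ROI into maximal
        # salt-and-pepper texture and invert the group contrast
        "texture": {"n_levels": 16, "n_slices": 5, "binning": "fixed_range",
                    "fixed_range": [30.0, 90.0]},
        "histo": {
            "untreated_means": {
                m: {k: 100.0 for k in histo_scoring.MARKERS} for m in histo_scoring.MUSCLES
            },
            "rescue_percent": {
                "cranial_sartorius": {"inflammation": 34, "necrotic_foci": 25,
                                      "igg_myofibers": 22, "regeneration": 43},
                "lateral_gastrocnemius": {"inflammation": 40, "necrotic_foci": 34,
                                          "igg_myofibers": 35, "regeneration": 35},
                "vastus_lateralis": {"inflammation": 31, "necrotic_foci": 35,
                                     "igg_myofibers": 32, "regeneration": 44},
                "diaphragm": {"inflammation": 37, "necrotic_foci": 37,
                              "igg_myofibers": 32, "regeneration": 41},
            },
            "nonsignificant_cells": [["cranial_sartorius", "necrotic_foci"],
                                     ["cranial_sartorius", "igg_myofibers"]],
            "dispersion": 0.0,
        },
        "stats": {
            "comparisons": [["GRMD", "GRMD+NBD"], ["WT", "WT+NBD"]],
            "adjust": True,
        },
    }


_TOP_KEYS = {"seed", "phantom", "imaging", "cohort", "texture", "histo", "stats"}
_PHANTOM_KEYS = {"grid_shape", "voxel_size", "muscles", "lesion_fraction", "lesion_t2_shift",
                 "lesion_patch_radius", "echo_times", "s0", "noise_sd"}
_IMAGING_KEYS = {"n_per_group", "lesion_fraction_by_group"}
_COHORT_KEYS = {"n_per_group", "variables"}
_TEXTURE_KEYS = {"n_levels", "binning", "fixed_range", "n_slices", "slab_axis"}
_HISTO_KEYS = {"untreated_means", "rescue_percent", "treated_means", "nonsignificant_cells",
               "dispersion"}
_STATS_KEYS = {"comparisons", "adjust"}


def _check_keys(section: Mapping, allowed: set, where: str, errors: list[str]) -> None:
    for k in section:
        if k not in allowed:
            errors.append(f"{where}: unknown key {k!r}")


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and cross-validate a run configuration.

    Accepts a YAML path or an already-parsed mapping. All problems are
    collected and raised together as :class:`ConfigError`, not
    first-error-only; unknown keys are rejected.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    errors: list[str] = []
    _check_keys(raw, _TOP_KEYS, "top level", errors)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0

    # phantom
    phantom_cfg = raw.get("phantom", {}) or {}
    _check_keys(phantom_cfg, _PHANTOM_KEYS, "phantom", errors)
    phantom = None
    try:
        muscles = [MuscleSpec(**m) for m in phantom_cfg.get("muscles", default_config()["phantom"]["muscles"])]
        phantom = PhantomSpec(
            grid_shape=tuple(phantom_cfg.get("grid_shape", (24, 24, 24))),
            voxel_size=tuple(phantom_cfg.get("voxel_size", (1.0, 1.0, 1.0))),
            muscles=muscles,
            lesion_fraction=float(phantom_cfg.get("lesion_fraction", 0.0)),
            lesion_t2_shift=float(phantom_cfg.get("lesion_t2_shift", 30.0)),
            lesion_patch_radius=int(phantom_cfg.get("lesion_patch_radius", 2)),
            echo_times=tuple(phantom_cfg.get("echo_times", tuple(np.arange(10.0, 101.0, 10.0)))),
            s0=float(phantom_cfg.get("s0", 1000.0)),
            noise_sd=float(phantom_cfg.get("noise_sd", 0.0)),
            seed=seed,
        )
    except (TypeError, ValueError) as e:
        errors.append(f"phantom: {e}")

    imaging_cfg = raw.get("imaging", {}) or {}
    _check_keys(imaging_cfg, _IMAGING_KEYS, "imaging", errors)
    n_imaging = imaging_cfg.get("n_per_group", 3)
    if not isinstance(n_imaging, int) or n_imaging < 1:
        errors.append("imaging.n_per_group: must be a positive integer")
        n_imaging = 1
    lf_by_group = dict(imaging_cfg.get("lesion_fraction_by_group", {g: 0.0 for g in GROUPS}))
    for g, f in lf_by_group.items():
        if g not in GROUPS:
            errors.append(f"imaging.lesion_fraction_by_group: unknown group {g!r}")
        elif not 0.0 <= float(f) <= 1.0:
            errors.append(f"imaging.lesion_fraction_by_group[{g!r}]: must be in [0, 1]")

    # cohort
    cohort_cfg = raw.get("cohort", {}) or {}
    _check_keys(cohort_cfg, _COHORT_KEYS, "cohort", errors)
    cohort = None
    try:
        variables = {
            var: {g: (float(ms[0]), float(ms[1])) for g, ms in per_group.items()}
            for var, per_group in (cohort_cfg.get("variables", {}) or {}).items()
        }
        cohort = CohortSpec(
            n_per_group=dict(cohort_cfg.get("n_per_group", {"WT": 8, "WT+NBD": 3, "GRMD": 10, "GRMD+NBD": 6})),
            variables=variables,
            seed=seed,
        )
    except (TypeError, ValueError, IndexError) as e:
        errors.append(f"cohort: {e}")

    # texture
    texture_cfg = raw.get("texture", {}) or {}
    _check_keys(texture_cfg, _TEXTURE_KEYS, "texture", errors)
    texture = None
    try:
        texture = TextureConfig(
            n_levels=int(texture_cfg.get("n_levels", 16)),
            binning=texture_cfg.get("binning", "roi_minmax"),
            fixed_range=tuple(texture_cfg["fixed_range"]) if texture_cfg.get("fixed_range") else None,
            n_slices=texture_cfg.get("n_slices", 5),
            slab_axis=int(texture_cfg.get("slab_axis", 2)),
        )
    except (TypeError, ValueError) as e:
        errors.append(f"texture: {e}")

    # histo
    histo_cfg = raw.get("histo", {}) or {}
    _check_keys(histo_cfg, _HISTO_KEYS, "histo", errors)
    untreated = rescue = treated = significant = None
    try:
        untreated = pd.DataFrame(histo_cfg["untreated_means"]).T.astype(float) \
            if "untreated_means" in histo_cfg else pd.DataFrame(default_config()["histo"]["untreated_means"]).T.astype(float)
        if (untreated.to_numpy() <= 0).any():
            errors.append("histo.untreated_means: all cells must be > 0")
        if "treated_means" in histo_cfg and "rescue_percent" in histo_cfg:
            errors.append("histo: give either treated_means or rescue_percent, not both")
        if "treated_means" in histo_cfg:
            treated = pd.DataFrame(histo_cfg["treated_means"]).T.astype(float)
            treated = treated.loc[untreated.index, untreated.columns]
            rescue = 100.0 * (untreated - treated) / untreated
        else:
            rp = histo_cfg.get("rescue_percent", default_config()["histo"]["rescue_percent"])
            rescue = pd.DataFrame(rp).T.astype(float).loc[untreated.index, untreated.columns]
        significant = pd.DataFrame(True, index=untreated.index, columns=untreated.columns)
        for muscle, marker in histo_cfg.get("nonsignificant_cells", []):
            if muscle not in significant.index or marker not in significant.columns:
                errors.append(f"histo.nonsignificant_cells: unknown cell ({muscle!r}, {marker!r})")
            else:
                significant.loc[muscle, marker] = False
    except (KeyError, TypeError, ValueError) as e:
        errors.append(f"histo: {e}")
    dispersion = histo_cfg.get("dispersion", 0.0)
    if not isinstance(dispersion, (int, float)) or dispersion < 0:
        errors.append("histo.dispersion: must be a nonnegative number")
        dispersion = 0.0

    # stats
    stats_cfg = raw.get("stats", {}) or {}
    _check_keys(stats_cfg, _STATS_KEYS, "stats", errors)
    comparisons = []
    for pair in stats_cfg.get("comparisons", [["GRMD", "GRMD+NBD"], ["WT", "WT+NBD"]]):
        if len(pair) != 2 or any(g not in GROUPS for g in pair):
            errors.append(f"stats.comparisons: invalid pair {pair!r}")
        else:
            comparisons.append((str(pair[0]), str(pair[1])))
    adjust = bool(stats_cfg.get("adjust", True))

    if errors:
        raise ConfigError(errors)
    assert phantom is not None and cohort is not None and texture is not None
    return RunConfig(
        seed=seed,
        phantom=phantom,
        lesion_fraction_by_group=lf_by_group,
        n_imaging_per_group=n_imaging,
        cohort=cohort,
        texture=texture,
        histo_untreated_means=untreated,
        histo_rescue_percent=rescue,
        histo_dispersion=float(dispersion),
        histo_significant=significant,
        comparisons=comparisons,
        adjust=adjust,
        raw=raw,
    )


def _stage_seed(seed: int, name: str) -> int:
    return (int(seed) * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run every stage and emit the report bundle.

    Outputs: ``cohort.csv``, ``functional_summary.csv`` and
    ``functional_stats.csv`` (endpoint layout), ``imaging_features.csv``,
    ``imaging_summary.csv`` and ``imaging_stats.csv`` (muscle x feature
    layout), ``histo_rescue.csv`` and ``histo_summary.json`` (rescue
    layout), plus ``manifest.json``. Identical config and seed give a
    byte-identical bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- cohort / functional endpoints -----------------------------------
    stage = "cohort"
    try:
        cohort = generate_cohort(config.cohort)
        paths["cohort"] = out / "cohort.csv"
        _write_csv(cohort, paths["cohort"])
        summary = biomechanics.group_summary(cohort)
        paths["functional_summary"] = out / "functional_summary.csv"
        _write_csv(summary, paths["functional_summary"])

        endpoints = [c for c in cohort.columns if c not in ("animal_id", "group")]
        stat_frames = []
        for g1, g2 in config.comparisons:
            try:
                res = group_stats.compare_groups(
                    cohort, endpoints, (g1, g2), adjust=config.adjust
                )
            except ValueError:
                continue  # e.g. zero-dispersion demo data: nothing testable
            res.insert(0, "comparison", f"{g1} vs {g2}")
            stat_frames.append(res)
        paths["functional_stats"] = out / "functional_stats.csv"
        if stat_frames:
            _write_csv(pd.concat(stat_frames, ignore_index=True), paths["functional_stats"])
        else:
            cols = ["comparison", "endpoint", "mean1", "sd1", "n1", "mean2", "sd2", "n2",
                    "mean_difference", "t", "df", "p", "p_adjusted", "flag"]
            _write_csv(pd.DataFrame(columns=cols), paths["functional_stats"])
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # --- imaging ----------------------------------------------------------
    stage = "imaging"
    try:
        feature_rows = []
        for group in GROUPS:
            lf = float(config.lesion_fraction_by_group.get(group, 0.0))
            for i in range(config.n_imaging_per_group):
                spec = PhantomSpec(
                    grid_shape=config.phantom.grid_shape,
                    voxel_size=config.phantom.voxel_size,
                    muscles=config.phantom.muscles,
                    lesion_fraction=lf,
                    lesion_t2_shift=config.phantom.lesion_t2_shift,
                    lesion_patch_radius=config.phantom.lesion_patch_radius,
                    echo_times=config.phantom.echo_times,
                    s0=config.phantom.s0,
                    noise_sd=config.phantom.noise_sd,
                    seed=_stage_seed(config.seed, f"imaging.{group}.{i}"),
                )
                vol, lmap = generate_phantom(spec)
                t2map = fit_t2(vol, mask=lmap.labels > 0)
                feats = muscle_features(
                    t2map, lmap, config.texture, animal_id=f"{group}-img{i + 1:02d}", group=group
                )
                for feature in ("mean_t2", "sli", "hi", "entropy"):
                    feats[f"composite_{feature}"] = weighted_composite(feats, feature)
                feature_rows.append(feats)
        features = pd.concat(feature_rows, ignore_index=True)
        paths["imaging_features"] = out / "imaging_features.csv"
        _write_csv(features, paths["imaging_features"])

        img_summary = (
            features.groupby(["group", "muscle"], sort=False)
            .agg(
                n=("animal_id", "nunique"),
                t2_mean=("mean_t2", "mean"), t2_sd=("mean_t2", "std"),
                sli_mean=("sli", "mean"), sli_sd=("sli", "std"),
                hi_mean=("hi", "mean"), hi_sd=("hi", "std"),
            )
            .reset_index()
        )
        paths["imaging_summary"] = out / "imaging_summary.csv"
        _write_csv(img_summary, paths["imaging_summary"])

        per_animal = features.drop_duplicates("animal_id")[
            ["animal_id", "group", "composite_mean_t2", "composite_sli", "composite_hi"]
        ]
        img_stats = []
        for g1, g2 in config.comparisons:
            if (
                (per_animal["group"] == g1).sum() >= 2
                and (per_animal["group"] == g2).sum() >= 2
            ):
                res = group_stats.compare_groups(
                    per_animal,
                    ["composite_mean_t2", "composite_sli", "composite_hi"],
                    (g1, g2),
                    adjust=config.adjust,
                )
                res.insert(0, "comparison", f"{g1} vs {g2}")
                img_stats.append(res)
        if img_stats:
            paths["imaging_stats"] = out / "imaging_stats.csv"
            _write_csv(pd.concat(img_stats, ignore_index=True), paths["imaging_stats"])
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # --- histology --------------------------------------------------------
    stage = "histo"
    try:
        treated_means = treated_means_from_rescue(
            config.histo_untreated_means, config.histo_rescue_percent
        )
        u_draw, t_draw = generate_histo_counts(
            config.histo_untreated_means,
            treated_means,
            dispersion=config.histo_dispersion,
            seed=_stage_seed(config.seed, "histo"),
        )
        table = histo_scoring.rescue_table(u_draw, t_draw, significant=config.histo_significant)
        rescue_out = table.rescue.round(6).reset_index(names="muscle")
        paths["histo_rescue"] = out / "histo_rescue.csv"
        _write_csv(rescue_out, paths["histo_rescue"])
        paths["histo_summary"] = out / "histo_summary.json"
        paths["histo_summary"].write_text(
            json.dumps(
                {"marker_averages": table.marker_averages, "composite": table.composite},
                indent=2,
                sort_keys=True,
            )
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # --- manifest ---------------------------------------------------------
    config_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "seed": config.seed,
        "config_sha256": config_hash,
        "myotex_version": myotex.__version__,
        "outputs": {k: p.name for k, p in sorted(paths.items())},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
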