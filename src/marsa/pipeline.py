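"""Configuration-driven orchestration of the full synthetic experiment.

``run_pipeline`` executes every stage end to end: synthetic ground truth and
two-modality behavioral cohorts, multiple-arrangement re-estimation of each
subject's RDM, fixed- and random-effects RSA between modalities, synthetic
brain volumes with planted regions, searchlight RDM fields, per-subject
cross-validated NNLS reweighting (visual, linguistic, joint), variance
partitioning, and group statistics — then writes TSV/NIfTI artifacts, a JSON
report, and a run manifest with artifact checksums.

All randomness derives from one global seed: a fixed-order seed sequence
fans out into independent per-stage streams, so two runs with the same
config produce bitwise-identical data artifacts.
"""
from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import InvalidArgumentError, MarsaError
from .group_stats import group_map
from .io import save_map_nifti, save_patterns_nifti, write_rdm_tsv, write_stack
from .ma import run_ma_session
from .rdm import (
    RDMStack,
    devectorize,
    fixed_effects_rsa,
    random_effects_rsa,
    within_modality_consistency,
)
from .reweight import field_reweight, make_folds
from .searchlight import VoxelMask, build_index, field_rdms
from .synthetic import (
    RegionSpec,
    TwoModalitySpec,
    ball_region,
    make_ground_truth,
    simulate_brain,
    simulate_two_modalities,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "RunManifest"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "n_items": 30,
        "n_dims": 3,
        "n_categories": 4,
        "cat_separation": 2.0,
        "within_sd": 1.0,
        "n_subjects": 12,
        "shared_w": 1.0,
        "unique_visual_w": 0.3,
        "unique_linguistic_w": 0.3,
        "noise_sd": 0.1,
        "brain": {
            "n_subjects": 8,
            "mask_shape": [10, 10, 10],
            "noise_sd": 0.5,
            "regions": [
                {"center": [3, 3, 3], "radius": 2.0, "source": "shared", "amplitude": 1.0},
                {
                    "center": [7, 7, 7],
                    "radius": 2.0,
                    "source": "unique_linguistic",
                    "amplitude": 1.0,
                },
            ],
        },
    },
    "ma": {
        "enabled": True,
        "subset_size": 8,
        "evidence_threshold": 0.5,
        "max_trials": 10,
        "placement_noise": 0.05,
        "arena_radius": 1.0,
    },
    "searchlight": {"radius": 2.0, "min_voxels": 10},
    "reweight": {"train_frac": 0.7, "n_folds": 10},
    "rsa": {"n_perm": 500},
    "stats": {"q": 0.05, "sidedness": "one"},
    "io": {"write_nifti": True},
}


@dataclass
class RunManifest:
    """Record of one pipeline run: resolved config, artifacts, timings."""

    config: dict
    artifacts: dict = field(default_factory=dict)  # relative path -> sha256
    timings: dict = field(default_factory=dict)  # stage -> seconds
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "artifacts": self.artifacts,
                    "timings": self.timings,
                    "warnings": self.warnings,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _merge_defaults(raw: dict, defaults: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in raw.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise InvalidArgumentError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise InvalidArgumentError(f"{here} must be a mapping")
            out[key] = _merge_defaults(value, defaults[key], here)
        else:
            out[key] = value
    return out


def validate_config(raw) -> dict:
    """Parse YAML/JSON text (or accept a dict), reject unknown keys, fill defaults."""
    if raw is None:
        raw = {}
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise InvalidArgumentError("config must be a mapping")
    raw = copy.deepcopy(raw)
    # regions are a free-form list: validate separately, then splice
    regions = None
    syn = raw.get("synthetic", {})
    if isinstance(syn, dict) and isinstance(syn.get("brain"), dict):
        regions = syn["brain"].pop("regions", None)
    cfg = _merge_defaults(raw, DEFAULT_CONFIG)
    if regions is not None:
        for i, r in enumerate(regions):
            extra = set(r) - {"center", "radius", "source", "amplitude"}
            if extra:
                raise InvalidArgumentError(
                    f"unknown keys {sorted(extra)} in synthetic.brain.regions[{i}]"
                )
        cfg["synthetic"]["brain"]["regions"] = regions
    if cfg["searchlight"]["radius"] < 1:
        raise InvalidArgumentError("searchlight.radius must be >= 1")
    if not (0 < cfg["reweight"]["train_frac"] < 1):
        raise InvalidArgumentError("reweight.train_frac must be in (0, 1)")
    if cfg["stats"]["sidedness"] not in ("one", "two"):
        raise InvalidArgumentError("stats.sidedness must be 'one' or 'two'")
    for name, region in enumerate(cfg["synthetic"]["brain"]["regions"]):
        if region["source"] not in ("shared", "unique_visual", "unique_linguistic"):
            raise InvalidArgumentError(
                f"synthetic.brain.regions[{name}].source must name a planted source"
            )
    return cfg


def load_config(path) -> dict:
    return validate_config(Path(path).read_text())


def _stage_seeds(global_seed: int, names: list[str]) -> dict:
    children = np.random.SeedSequence(global_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full synthetic experiment and write all artifacts.

    Any stage failure aborts with the stage name attached; a partial
    manifest (stages completed so far) is still written.
    """
    cfg = validate_config(config) if not _is_resolved(config) else config
    if seed is not None:
        cfg = copy.deepcopy(cfg)
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(
        cfg["seed"], ["ground_truth", "modalities", "ma", "brain", "folds", "rsa_perm"]
    )
    manifest = RunManifest(config=cfg)
    stage = "setup"
    t0 = time.perf_counter()

    def tick(name):
        nonlocal stage, t0
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        stage, t0 = name, time.perf_counter()

    def register(relpath):
        data = (out / relpath).read_bytes()
        manifest.artifacts[str(relpath)] = hashlib.sha256(data).hexdigest()

    try:
        # --- synthetic ground truth and behavioral cohorts -----------------
        tick("synthetic")
        syn = cfg["synthetic"]
        gt = make_ground_truth(
            syn["n_items"],
            syn["n_dims"],
            syn["n_categories"],
            syn["cat_separation"],
            seed=seeds["ground_truth"],
            within_sd=syn["within_sd"],
        )
        spec = TwoModalitySpec(
            shared_w=syn["shared_w"],
            unique_visual_w=syn["unique_visual_w"],
            unique_linguistic_w=syn["unique_linguistic_w"],
            noise_sd=syn["noise_sd"],
            seed=seeds["modalities"],
        )
        visual, linguistic, sources = simulate_two_modalities(gt, spec, syn["n_subjects"])
        write_rdm_tsv(gt.true_rdm, out / "ground_truth_rdm.tsv")
        register("ground_truth_rdm.tsv")

        # --- MA re-estimation of each subject RDM ---------------------------
        tick("ma_estimation")
        ma = cfg["ma"]
        if ma["enabled"]:
            ma_rng = np.random.default_rng(seeds["ma"])

            def reestimate(stack: RDMStack) -> RDMStack:
                mats = []
                for vec in stack.vectors:
                    _, est = run_ma_session(
                        devectorize(vec, stack.n_items),
                        subset_size=min(ma["subset_size"], stack.n_items),
                        evidence_threshold=ma["evidence_threshold"],
                        max_trials=ma["max_trials"],
                        placement_noise=ma["placement_noise"],
                        seed=int(ma_rng.integers(2**31)),
                        arena_radius=ma["arena_radius"],
                    )
                    mats.append(est)
                return RDMStack.from_matrices(mats, labels=stack.labels)

            visual, linguistic = reestimate(visual), reestimate(linguistic)
        write_stack(visual, out / "rdms_visual")
        write_stack(linguistic, out / "rdms_linguistic")
        for d in ("rdms_visual", "rdms_linguistic"):
            for f in sorted((out / d).iterdir()):
                register(Path(d) / f.name)

        # --- behavioral RSA -------------------------------------------------
        tick("rsa")
        fe = fixed_effects_rsa(visual, linguistic)
        re_stat, re_p = random_effects_rsa(
            visual, linguistic, n_perm=cfg["rsa"]["n_perm"], seed=seeds["rsa_perm"]
        )
        rsa_table = {
            "fixed_effects_spearman": fe,
            "random_effects_spearman": re_stat,
            "random_effects_p": re_p,
            "within_visual_consistency": within_modality_consistency(visual),
            "within_linguistic_consistency": within_modality_consistency(linguistic),
        }

        # --- synthetic brains and searchlight fields ------------------------
        tick("brain")
        brain_cfg = syn["brain"]
        shape = tuple(brain_cfg["mask_shape"])
        source_names = [r["source"] for r in brain_cfg["regions"]]
        source_mats = [sources[name] for name in source_names]
        regions = [
            RegionSpec(
                voxels=ball_region(r["center"], r["radius"], shape),
                source=i,
                amplitude=r.get("amplitude", 1.0),
            )
            for i, r in enumerate(brain_cfg["regions"])
        ]
        brains = simulate_brain(
            source_mats,
            shape,
            regions,
            brain_cfg["noise_sd"],
            brain_cfg["n_subjects"],
            seed=seeds["brain"],
            n_items=syn["n_items"],
        )
        mask = VoxelMask(np.ones(shape, dtype=bool))
        index = build_index(
            mask, cfg["searchlight"]["radius"], cfg["searchlight"]["min_voxels"]
        )

        # --- per-subject reweighting and variance partitioning --------------
        tick("reweight")
        plan = make_folds(
            syn["n_items"],
            cfg["reweight"]["train_frac"],
            cfg["reweight"]["n_folds"],
            seed=seeds["folds"],
        )
        joint = RDMStack(
            n_items=syn["n_items"],
            vectors=np.vstack([visual.vectors, linguistic.vectors]),
            labels=[f"vis:{l}" for l in visual.labels]
            + [f"lin:{l}" for l in linguistic.labels],
        )
        maps = {"visual": [], "linguistic": [], "joint": []}
        unique_maps = {"unique_visual": [], "unique_linguistic": []}
        keep = None
        for brain in brains:
            fld = field_rdms(brain.patterns, index, policy="lenient")
            if fld.skipped:
                manifest.warnings.append(f"skipped degenerate centers: {fld.skipped}")
            vis_map, _ = field_reweight(visual, fld, plan)
            lin_map, _ = field_reweight(linguistic, fld, plan)
            joint_map, _ = field_reweight(joint, fld, plan)
            finite = np.isfinite(vis_map) & np.isfinite(lin_map) & np.isfinite(joint_map)
            keep = finite if keep is None else (keep & finite)
            maps["visual"].append(vis_map)
            maps["linguistic"].append(lin_map)
            maps["joint"].append(joint_map)
            unique_maps["unique_linguistic"].append(joint_map**2 - vis_map**2)
            unique_maps["unique_visual"].append(joint_map**2 - lin_map**2)
        centers = index.centers[keep]
        for d in (maps, unique_maps):
            for k in d:
                d[k] = [m[keep] for m in d[k]]

        # --- group statistics ------------------------------------------------
        tick("group_stats")
        q = cfg["stats"]["q"]
        group = {name: group_map(maps[name], centers, q) for name in maps}
        group.update({name: group_map(unique_maps[name], centers, q) for name in unique_maps})
        if cfg["io"]["write_nifti"]:
            save_patterns_nifti(
                brains[0].patterns, mask.inside, out / "brain_sub00.nii", out / "mask.nii"
            )
            register("brain_sub00.nii")
            register("mask.nii")
            for name, gm in group.items():
                for layer, values in (
                    ("mean", gm.mean_map),
                    ("t", gm.t_map),
                    ("p", gm.p_map),
                    ("fdrmask", gm.fdr_mask.astype(float)),
                ):
                    rel = f"map_{name}_{layer}.nii"
                    save_map_nifti(values, centers, shape, out / rel)
                    register(rel)

        # --- report -----------------------------------------------------------
        tick("report")
        unique_summary = {
            name: {
                "mean": float(np.mean(np.column_stack(unique_maps[name]))),
                "peak": float(np.max(group[name].mean_map)),
                "n_fdr_significant": int(group[name].fdr_mask.sum()),
            }
            for name in unique_maps
        }
        ordering = sorted(unique_summary, key=lambda k: -unique_summary[k]["mean"])
        report = {
            "rsa": rsa_table,
            "searchlight": {
                name: {
                    "peak_mean_r": float(np.max(group[name].mean_map)),
                    "n_fdr_significant": int(group[name].fdr_mask.sum()),
                    "n_centers": int(centers.shape[0]),
                }
                for name in maps
            },
            "variance_partition": {
                "summary": unique_summary,
                "ordering_by_mean_unique_r2": ordering,
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        register("report.json")
        tick("done")
    except MarsaError as err:
        manifest.warnings.append(f"aborted in stage '{stage}': {err}")
        manifest.write(out / "manifest.partial.json")
        raise MarsaError(f"pipeline failed in stage '{stage}': {err}") from err
    manifest.write(out / "manifest.json")
    return manifest


def _is_resolved(config) -> bool:
    return isinstance(config, dict) and set(config) == set(DEFAULT_CONFIG)
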