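"""End-to-end orchestration: simulate -> classify -> extract -> analyze.

A run is driven by one config mapping (YAML/JSON-able) and a master seed;
per-stage seeds are derived hierarchically with ``numpy.random.SeedSequence``
so any stage is reproducible in isolation and the whole run is byte-stable:
same config + seed gives identical output files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .clustering import remove_outliers
from .simulate import SimDesign, simulate_cohort, simulate_phantom
from .specificity import inter_feature_matrices, run_specificity
from .stats import TERMS, compare_saf_lr, fit_all_bundles, fit_ticv_model, percent_change_table
from .tractometry import assign_streamlines, filter_by_length

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "phantom_demo": True,
        "regression": True,
        "percent_change": True,
        "compare": True,
        "correlations": True,
        "specificity": True,
    },
    "cohort": {
        "n_participants": 616,
        "pathways": ["AF", "CST", "CC", "OR", "ILF", "UF", "SLF", "CG"],
        "noise_sd": 1.0,
        "coupling_assoc": 0.6,
        "coupling_nonassoc": 0.2,
        "contamination_rate": 0.0,
    },
    "phantom": {
        "n_pathways": 3,
        "fibers_per_bundle": 30,
        "n_distractors": 10,
        "n_outliers": 2,
    },
    "thresholds": {
        "min_length_mm": 5.0,
        "max_length_mm": 40.0,
        "outlier_alpha": 0.6,
        "fdr_alpha": 0.05,
        "bisquare_c": 4.685,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "ufiber_run") -> Path:
    """Execute the enabled stages and write a report directory.

    Outputs: cohort and feature TSVs, effect-matrix TSVs per coefficient,
    SAF-vs-LR comparison, percent-change table, per-pathway correlation
    matrices, specificity tables, an optional phantom-classification demo,
    and a run manifest (config hash + seed).  On stage failure the partial
    outputs are kept and the manifest records the failure before the error
    propagates with a nonzero exit from the CLI.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    alpha = config["thresholds"]["fdr_alpha"]
    tuning_c = config["thresholds"]["bisquare_c"]
    stages = config["stages"]
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "completed": [],
        "failed": None,
        "counts": {},
    }

    def _finish(stage: str) -> None:
        manifest["completed"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        design = SimDesign(seed=_stage_seed(seed, "cohort"), **config["cohort"])
        cohort, features, _ = simulate_cohort(design)
        io.write_table(cohort, out / "cohort.tsv")
        io.write_table(features, out / "features.tsv")
        ticv = fit_ticv_model(cohort, tuning_c=tuning_c)
        io.write_table(ticv.to_frame("value").reset_index(names="coefficient"), out / "ticv_model.tsv")
        _finish("simulate_cohort")

        if stages.get("phantom_demo"):
            phantom = simulate_phantom(
                seed=_stage_seed(seed, "phantom"), **config["phantom"]
            )
            io.write_phantom(phantom, out / "phantom")
            kept = filter_by_length(
                phantom.tractogram,
                config["thresholds"]["min_length_mm"],
                config["thresholds"]["max_length_mm"],
            )
            bundles = assign_streamlines(phantom.tractogram, phantom.lr_masks)
            for bundle in bundles.values():
                bundle.streamline_indices &= kept
                members = sorted(bundle.streamline_indices)
                if len(members) >= 2:
                    local_kept = remove_outliers(
                        [phantom.tractogram.streamlines[i] for i in members],
                        outlier_alpha=config["thresholds"]["outlier_alpha"],
                    )
                    bundle.post_filter_indices = {members[i] for i in local_kept}
            io.write_assignment(bundles, out / "phantom" / "assignment.json")
            manifest["counts"]["phantom_streamlines"] = len(phantom.tractogram)
            manifest["counts"]["phantom_in_length_band"] = len(kept)
            manifest["counts"]["phantom_assigned"] = sum(
                len(b.streamline_indices) for b in bundles.values()
            )
            manifest["counts"]["phantom_post_filter"] = sum(
                len(b.post_filter_indices or ()) for b in bundles.values()
            )
            _finish("phantom_demo")

        results = None
        if stages.get("regression"):
            results = fit_all_bundles(features, cohort, alpha=alpha, tuning_c=tuning_c)
            io.write_table(results, out / "regression_results.tsv")
            for term in TERMS:
                if term == "intercept":
                    continue
                panel = results[results["term"] == term].pivot(
                    index=["tier", "pathway"], columns="feature", values="beta"
                )
                panel.to_csv(out / f"effect_matrix_{term}.tsv", sep="\t")
            manifest["counts"]["regression_cells_failed"] = int(
                results["failed"].sum() // len(TERMS)
            )
            _finish("regression")

        if stages.get("percent_change"):
            pct = percent_change_table(features, cohort, tuning_c=tuning_c)
            io.write_table(pct, out / "percent_change_per_year.tsv")
            _finish("percent_change")

        if stages.get("compare") and results is not None:
            for term in ("age", "sex", "interaction"):
                comp = compare_saf_lr(results, term=term, alpha=alpha)
                io.write_table(comp, out / f"saf_vs_lr_{term}.tsv")
            _finish("compare")

        if stages.get("correlations"):
            corr_dir = out / "correlations"
            corr_dir.mkdir(exist_ok=True)
            for pathway in design.pathways:
                mats = inter_feature_matrices(features, cohort, pathway, alpha=alpha)
                for name in ("saf_saf", "lr_lr", "saf_lr"):
                    getattr(mats, name).to_csv(
                        corr_dir / f"{pathway}_{name}.tsv", sep="\t"
                    )
            _finish("correlations")

        if stages.get("specificity"):
            spec = run_specificity(features, cohort, alpha=alpha)
            io.write_table(spec, out / "specificity.tsv")
            manifest["counts"]["specificity_significant"] = int(
                spec["significant"].sum()
            )
            _finish("specificity")
    except Exception as exc:
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    return out
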