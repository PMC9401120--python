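"""End-to-end study orchestration.

Runs the full analysis analogue under one YAML/dict config: load or simulate
repertoires -> copy-number fractioning -> per-sample indices -> fraction-wise
group comparison -> dissimilarity-based classification -> distribution of a
supplied clonotype set over fractions. Emits a diff-able results bundle of
TSV and JSON files plus a run manifest (config echo, seeds, package version).
"""
from __future__ import annotations

import dataclasses
import glob as globmod
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import dissimilarity_matrix, kmedoids, loo_classify, mds_embed
from .fractioning import (
    LOG2_SCHEME,
    TRIPARTITION_SCHEME,
    custom_sub_repertoire,
    distribute_clonotype_set,
    split_by_scheme,
    sub_repertoire,
)
from .group_stats import compare_cohorts, index_per_fraction, pairwise_jaccard
from .io import preprocess, write_repertoire
from .synthetic import EffectConfig, SyntheticCohortConfig, generate_cohort
from .types import Repertoire

logger = logging.getLogger(__name__)

SCHEMES = {"log2": LOG2_SCHEME, "tripartition": TRIPARTITION_SCHEME}


def _log_stage(sample_id: str, stage: str, n_in: int, n_out: int, t0: float) -> None:
    logger.info(
        "sample=%s stage=%s n_in=%d n_out=%d elapsed=%.3fs",
        sample_id, stage, n_in, n_out, time.time() - t0,
    )


def config_from_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def build_synthetic_config(d: dict) -> SyntheticCohortConfig:
    d = dict(d)
    if "effect" in d and isinstance(d["effect"], dict):
        d["effect"] = EffectConfig(**d["effect"])
    return SyntheticCohortConfig(**d)


def load_cohort(config: dict, seed: int) -> tuple[list[Repertoire], list[str]]:
    """Load repertoires from input globs or simulate them."""
    if "simulate" in config:
        sim = dict(config["simulate"])
        sim.setdefault("seed", seed)
        cohort = generate_cohort(build_synthetic_config(sim))
        return cohort.repertoires, cohort.labels
    reps: list[Repertoire] = []
    labels: list[str] = []
    dialect = config.get("dialect", "simple-tsv")
    downsample_to = config.get("downsample_to")
    label_map = {}
    if "labels_file" in config:
        lab = pd.read_csv(config["labels_file"], sep="\t")
        label_map = dict(zip(lab["sample_id"].astype(str), lab["label"].astype(str)))
    for pattern_label, pattern in (("control", config.get("control_glob")),
                                   ("immunized", config.get("treated_glob"))):
        if not pattern:
            continue
        paths = sorted(globmod.glob(pattern))
        if not paths:
            raise FileNotFoundError(f"no files match {pattern}")
        for p in paths:
            t0 = time.time()
            rep = preprocess(p, dialect, downsample_to, seed, group_label=pattern_label)
            _log_stage(rep.sample_id, "preprocess", -1, len(rep), t0)
            reps.append(rep)
            labels.append(label_map.get(rep.sample_id, pattern_label))
    if not reps:
        raise ValueError("config must provide 'simulate' or input globs")
    return reps, labels


def run_study(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Run every configured stage; returns the summary dict written as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    reps, labels = load_cohort(config, seed)
    controls = [r for r, l in zip(reps, labels) if l == "control"]
    treated = [r for r, l in zip(reps, labels) if l != "control"]
    scheme_name = config.get("scheme", "log2")
    scheme = SCHEMES[scheme_name]
    indices = config.get("indices", ["rhi_vj", "rhi_ld", "cdi"])
    summary: dict = {"n_samples": len(reps), "stages": []}

    # per-sample index tables
    rows = []
    for rep in reps:
        t0 = time.time()
        for idx in indices:
            for f, iv in enumerate(index_per_fraction(rep, idx, scheme), start=1):
                rows.append(
                    {"sample_id": rep.sample_id, "group": rep.group_label,
                     "index": idx, "fraction": f,
                     "value": iv.value if iv.defined else np.nan, "n": iv.n_items}
                )
        _log_stage(rep.sample_id, "indices", len(rep), len(indices) * len(scheme), t0)
    pd.DataFrame(rows).to_csv(out / "per_sample_indices.tsv", sep="\t", index=False)
    summary["stages"].append("indices")

    # fraction-wise comparison (p-value heatmap table)
    if len(controls) >= 2 and len(treated) >= 2:
        alternative = config.get("alternative", "less")
        frames = []
        for idx in indices:
            cmp = compare_cohorts(controls, treated, idx, scheme, alternative)
            frames.append(cmp.to_frame())
        heat = pd.concat(frames, ignore_index=True)
        heat.to_csv(out / "pvalue_heatmap.tsv", sep="\t", index=False)
        summary["n_significant_cells"] = int(
            (heat["p_holm"].to_numpy() < 0.05).sum()
        )
        summary["stages"].append("compare")
        pairwise_jaccard(reps, labels).to_csv(
            out / "pairwise_jaccard.tsv", sep="\t", index=False
        )
        summary["stages"].append("jaccard")

    # classification
    cls_cfg = config.get("classification", {"sub": "top", "criterion": "vj"})
    if cls_cfg and len(reps) >= 4:
        sub_kind = cls_cfg.get("sub", "top")
        excluded = set(cls_cfg.get("exclude_groups", []))
        kept = [(r, l) for r, l in zip(reps, labels)
                if r.timepoint not in excluded and r.group_label not in excluded]
        if sub_kind.startswith("custom:"):
            parts = sub_kind.split(":")
            cn_min, cn_max = float(parts[1]), float(parts[2]) if len(parts) > 2 else float("inf")
            subs = [custom_sub_repertoire(r, cn_min, cn_max) for r, _ in kept]
        else:
            subs = [sub_repertoire(r, sub_kind) for r, _ in kept]
        sub_labels = ["control" if l == "control" else "immunized" for _, l in kept]
        nonempty = [i for i, s in enumerate(subs) if len(s) > 0]
        subs = [subs[i] for i in nonempty]
        sub_labels = [sub_labels[i] for i in nonempty]
        m = dissimilarity_matrix(subs, cls_cfg.get("criterion", "vj"),
                                 weighted=cls_cfg.get("weighted", False))
        pd.DataFrame(m.values, index=m.sample_ids, columns=m.sample_ids).to_csv(
            out / "dissimilarity_matrix.tsv", sep="\t"
        )
        assignments, medoids = kmedoids(m, 2, seed=seed)
        coords = mds_embed(m, 2)
        pd.DataFrame(
            {"sample_id": m.sample_ids, "cluster": assignments,
             "mds_x": coords[:, 0], "mds_y": coords[:, 1], "label": sub_labels}
        ).to_csv(out / "clusters_mds.tsv", sep="\t", index=False)
        cls = loo_classify(m, sub_labels)
        (out / "classification.json").write_text(json.dumps(
            {"confusion": cls.confusion.tolist(), "accuracy": cls.accuracy,
             "fisher_p": cls.fisher_p, "predicted": cls.predicted_labels,
             "medoid_ids": [m.sample_ids[i] for i in medoids]}, indent=2))
        summary["loo_accuracy"] = cls.accuracy
        summary["fisher_p"] = cls.fisher_p
        summary["stages"].append("classify")

    # distribution of a supplied clonotype set over fractions
    if "clonotype_set" in config:
        aa_set = [s.strip() for s in Path(config["clonotype_set"]).read_text().split()]
        rows = []
        for rep in reps:
            counts = distribute_clonotype_set(rep, aa_set, scheme)
            for f, c in enumerate(counts, start=1):
                rows.append({"sample_id": rep.sample_id, "group": rep.group_label,
                             "fraction": f, "n_set_members": int(c)})
        pd.DataFrame(rows).to_csv(out / "set_distribution.tsv", sep="\t", index=False)
        summary["stages"].append("distribute")

    manifest = {
        "repfrac_version": __version__,
        "seed": seed,
        "config": config,
        "elapsed_s": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def write_cohort(cohort, out_dir: str | Path, dialect: str = "simple-tsv") -> None:
    """Write one clonotype table per animal, a labels TSV and a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rep in cohort.repertoires:
        write_repertoire(rep, out / f"{rep.sample_id}.tsv", dialect)
    pd.DataFrame(
        {"sample_id": [r.sample_id for r in cohort.repertoires],
         "label": cohort.labels,
         "timepoint": [r.timepoint for r in cohort.repertoires]}
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2))
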