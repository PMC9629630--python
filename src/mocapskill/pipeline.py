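"""End-to-end orchestration: simulate -> metrics -> stats -> classify.

One YAML config governs every stage; a run manifest records the config
snapshot, seeds and SHA-256 hashes of every artifact so a rerun with an
identical manifest reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd
import yaml

from .classify import compare_models, run_discrimination
from .io import RunConfig, read_cohort, write_cohort
from .metrics import compute_features
from .simulate import SyntheticCohortConfig, generate_cohort
from .stats import pca_fit, robust_z_normalize, screen_metrics

log = logging.getLogger("mocapskill")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def load_pipeline_config(path) -> tuple[SyntheticCohortConfig, RunConfig]:
    """Config YAML with two sections: ``simulate`` and ``analysis``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"simulate", "analysis"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    sim_raw = raw.get("simulate", {}) or {}
    ana_raw = raw.get("analysis", {}) or {}
    sim_fields = {f.name for f in dataclasses.fields(SyntheticCohortConfig)}
    bad = set(sim_raw) - sim_fields
    if bad:
        raise ValueError(f"unknown simulate fields: {sorted(bad)}")
    for key in ("workspace",):
        if key in sim_raw:
            sim_raw[key] = tuple(tuple(pair) for pair in sim_raw[key])
    for f in dataclasses.fields(SyntheticCohortConfig):
        if f.name.endswith(("_rate", "_mm", "_s", "_deg_s", "_per_min", "time_scale")):
            if f.name in sim_raw and isinstance(sim_raw[f.name], (list, tuple)):
                sim_raw[f.name] = tuple(sim_raw[f.name])
    return SyntheticCohortConfig(**sim_raw), RunConfig.from_dict(ana_raw)


def default_pipeline_config_dict() -> dict:
    return {
        "simulate": dataclasses.asdict(SyntheticCohortConfig()),
        "analysis": RunConfig().to_dict(),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    sim_config: SyntheticCohortConfig,
    run_config: RunConfig,
    out_dir,
    seed: int | None = None,
    cohort_dir=None,
) -> dict:
    """Execute all stages and return the run manifest (also written to disk).

    If ``seed`` is given it overrides both the simulator seed and the CV
    base seed.  If ``cohort_dir`` points at an existing cohort, simulation
    is skipped and the cohort is imported instead.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        sim_config = dataclasses.replace(sim_config, seed=int(seed))
        run_config = dataclasses.replace(run_config, base_seed=int(seed))
    manifest: dict = {
        "config": {
            "simulate": dataclasses.asdict(sim_config),
            "analysis": run_config.to_dict(),
        },
        "seeds": {"simulate": sim_config.seed, "cv_base": run_config.base_seed},
        "stages": {},
        "artifacts": {},
    }

    def _stage(name):
        log.info("stage %s: starting", name)
        t0 = time.time()

        def done(**outputs):
            dt = time.time() - t0
            log.info("stage %s: done in %.1fs", name, dt)
            manifest["stages"][name] = {"wall_time_s": round(dt, 2)}
            for key, path in outputs.items():
                manifest["artifacts"][key] = {
                    "path": str(path),
                    "sha256": _sha256(Path(path)),
                }

        return done

    # --- simulate / import ------------------------------------------------
    done = _stage("simulate")
    try:
        if cohort_dir is not None:
            cohort = read_cohort(cohort_dir)
        else:
            cohort = generate_cohort(sim_config)
            write_cohort(cohort, out / "cohort")
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc
    labels_path = out / "labels.csv"
    cohort.labels_frame().to_csv(labels_path, index=False)
    done(labels=labels_path)

    # --- metrics ----------------------------------------------------------
    done = _stage("metrics")
    try:
        features = compute_features(cohort, run_config)
    except Exception as exc:
        raise StageError("metrics", str(exc)) from exc
    features_path = out / "features.csv"
    features.to_csv(features_path)
    done(features=features_path)

    # --- stats ------------------------------------------------------------
    done = _stage("stats")
    try:
        clean = features.dropna_rows()
        normalized, _ = robust_z_normalize(clean.values)
        screening = screen_metrics(
            clean.values, clean.labels3, alpha=run_config.alpha, holm=run_config.holm
        )
        retained = screening.retained
        outputs = {}
        screening_path = out / "screening.csv"
        screening.table.to_csv(screening_path)
        outputs["screening"] = screening_path
        if len(retained) >= 2:
            pca = pca_fit(normalized[retained])
            loadings_path = out / "pca_loadings.csv"
            scores_path = out / "pca_scores.csv"
            pca.loadings.to_csv(loadings_path)
            pca.scores.to_csv(scores_path)
            evr_path = out / "pca_explained_variance.csv"
            pd.Series(
                pca.explained_variance_ratio,
                index=pca.loadings.columns,
                name="explained_variance_ratio",
            ).to_csv(evr_path)
            outputs.update(
                pca_loadings=loadings_path, pca_scores=scores_path, pca_evr=evr_path
            )
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc
    done(**outputs)

    # --- classify ---------------------------------------------------------
    done = _stage("classify")
    outputs = {}
    try:
        summary: dict = {}
        for scheme in ("three_group", "two_group"):
            results = run_discrimination(features, scheme, run_config)
            comparison = compare_models(results)
            acc = pd.DataFrame({k: r.accuracies for k, r in results.items()})
            acc_path = out / f"accuracies_{scheme}.csv"
            acc.to_csv(acc_path, index_label="repetition")
            table_path = out / f"comparison_{scheme}.csv"
            comparison.to_table().to_csv(table_path, index=False)
            outputs[f"accuracies_{scheme}"] = acc_path
            outputs[f"comparison_{scheme}"] = table_path
            summary[scheme] = {
                "median_accuracy": {k: r.median for k, r in results.items()},
                "iqr": {k: list(r.iqr) for k, r in results.items()},
                "friedman_p": comparison.friedman_p,
                "pairwise_p": {
                    f"{a}_vs_{b}": res.p for (a, b), res in comparison.pairwise.items()
                },
            }
        summary_path = out / "summary.json"
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
        outputs["summary"] = summary_path
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    done(**outputs)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(results_dir) -> str:
    """Markdown summary of a completed run: screening counts, top PCA
    loadings per component, and the median (IQR) accuracy comparison."""
    results_dir = Path(results_dir)
    screening_path = results_dir / "screening.csv"
    summary_path = results_dir / "summary.json"
    if not screening_path.exists() or not summary_path.exists():
        raise FileNotFoundError(f"incomplete results directory: {results_dir}")
    screening = pd.read_csv(screening_path, index_col=0)
    with open(summary_path, "r", encoding="utf-8") as fh:
        summary = json.load(fh)

    lines = ["# Skill-credentialing run report", ""]
    n_total = len(screening)
    n_kept = int(screening["retained"].sum())
    lines += [
        "## Metric screening",
        "",
        f"{n_kept} of {n_total} metrics show significant three-group "
        "differences (Kruskal-Wallis) and enter the PCA.",
        "",
    ]

    loadings_path = results_dir / "pca_loadings.csv"
    if loadings_path.exists():
        loadings = pd.read_csv(loadings_path, index_col=0)
        lines += ["## Top PCA loadings", ""]
        for comp in loadings.columns[: min(5, loadings.shape[1])]:
            top = loadings[comp].abs().sort_values(ascending=False).head(5)
            items = ", ".join(
                f"{name} ({loadings.loc[name, comp]:+.2f})" for name in top.index
            )
            lines.append(f"- {comp}: {items}")
        lines.append("")

    lines += ["## Classifier comparison", ""]
    for scheme, block in summary.items():
        lines.append(f"### {scheme.replace('_', ' ')}")
        lines.append("")
        for kind, med in block["median_accuracy"].items():
            lo, hi = block["iqr"][kind]
            lines.append(f"- {kind}: median accuracy {med:.4f} (IQR {lo:.4f}-{hi:.4f})")
        lines.append(f"- Friedman p = {block['friedman_p']:.4g}")
        for pair, p in block["pairwise_p"].items():
            lines.append(f"- {pair.replace('_', ' ')}: p = {p:.4g}")
        lines.append("")
    return "\n".join(lines)


def setup_logging(log_file=None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
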