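"""End-to-end workflow: parse -> regions/classes -> scales -> rank correlations
-> per-class evaluation -> bootstrap comparisons -> meta-predictor -> report
bundle.

The run is driven by a single :class:`RunConfig` (constructible from YAML) and
writes a directory of TSV tables plus a JSON manifest.  All randomness derives
from one run seed through a ``numpy`` seed sequence, so stages are individually
reproducible and a rerun with the same config and inputs is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._aa import AA_ORDER
from .composition import CompositionScale, build_pools, compute_scale
from .evaluation import (
    MetaRouting,
    assemble_meta,
    bootstrap_compare,
    evaluate,
    evaluate_by_class,
)
from .io import (
    AnnotatedProtein,
    PredictionTrack,
    PropensityScale,
    builtin_scale,
    load_dataset,
    read_predictions,
    read_scale,
    write_predictions,
    write_scale,
)
from .regions import IDPClass, classify_idps, region_summary
from .scales import bias_performance_correlation, scale_matrix
from .synthetic import generate_predictions, generate_reference, preset

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("idrbias")

_CATEGORY_SAMPLES = (
    ("caid", "disorder"),
    ("fully_disordered", "fully_disordered_idrs"),
    ("short", "short_idrs"),
    ("long", "long_idrs"),
    ("binding", "binding_idrs"),
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (either real inputs or a preset)."""

    output_dir: str
    seed: int = 0
    # data: either a synthetic preset name...
    synthetic_preset: str | None = None
    # ...or real input paths
    reference: str | None = None
    binding: str | None = None
    predictions: list[str] = field(default_factory=list)
    external_scale: str | None = "builtin:disprot_propensity"
    # statistics
    n_resamples: int = 10_000
    alpha: float = 0.05
    bootstrap_iterations: int = 100
    bootstrap_fraction: float = 0.5
    bootstrap_metrics: list[str] = field(default_factory=lambda: ["auc"])
    # meta-predictor routing: class value -> predictor name, or "auto"
    routing: dict[str, str] | str = "auto"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        has_real = self.reference is not None
        if self.synthetic_preset is None and not has_real:
            raise ValueError("config needs either a synthetic preset or a reference path")
        if self.synthetic_preset is not None and has_real:
            raise ValueError("give either a synthetic preset or real inputs, not both")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _load_external_scale(spec: str | None) -> PropensityScale | None:
    if spec is None:
        return None
    if spec.startswith("builtin:"):
        return builtin_scale(spec.split(":", 1)[1])
    return read_scale(spec)


def _prediction_selectors(track: PredictionTrack, threshold: float = 0.5):
    """Putative-disorder / putative-order residue selectors from one track."""

    def putative_disorder(p: AnnotatedProtein) -> np.ndarray:
        c = track.calls.get(p.id)
        return (c == 1) if c is not None else (track.scores[p.id] >= threshold)

    def putative_order(p: AnnotatedProtein) -> np.ndarray:
        return ~putative_disorder(p)

    return putative_disorder, putative_order


def _scale_table(scale: CompositionScale) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "aa": list(AA_ORDER),
            "enrichment": [scale.values[a] for a in AA_ORDER],
            "p_value": [scale.p_values[a] for a in AA_ORDER],
            "call": [scale.calls[a].value for a in AA_ORDER],
        }
    )


def _auto_routing(per_class: pd.DataFrame) -> MetaRouting:
    """Route each class to the predictor with the best AUC on it."""
    overall = per_class[per_class.subset == "all"].set_index("predictor").auc
    default = str(overall.idxmax())
    mapping: dict[IDPClass, str] = {}
    for cls in IDPClass:
        if cls is IDPClass.UNASSIGNED:
            continue
        rows = per_class[(per_class.subset == cls.value) & per_class.auc.notna()]
        mapping[cls] = str(rows.set_index("predictor").auc.idxmax()) if len(rows) else default
    return MetaRouting(mapping, default)


def _routing_from_config(cfg: RunConfig, per_class: pd.DataFrame) -> MetaRouting:
    if cfg.routing == "auto":
        return _auto_routing(per_class)
    by_value = {c.value: c for c in IDPClass}
    mapping = {}
    default = None
    for key, name in dict(cfg.routing).items():
        if key in ("default", IDPClass.UNASSIGNED.value):
            default = name
        elif key in by_value:
            mapping[by_value[key]] = name
        else:
            raise ValueError(f"routing refers to unknown class {key!r}")
    if default is None:
        raise ValueError("routing needs a 'default' entry")
    return MetaRouting(mapping, default)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow and write the report bundle.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "scales").mkdir(exist_ok=True)
    t0 = time.time()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
    }

    # --- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if config.synthetic_preset:
            syn = preset(config.synthetic_preset)
            rng = np.random.default_rng(seeds[0])
            proteins, truth = generate_reference(syn, seed=rng)
            tracks = [
                generate_predictions(proteins, prof, truth.classes, seed=rng)
                for prof in syn.predictor_profiles
            ]
            truth.proteins.to_csv(outdir / "ground_truth_proteins.tsv", sep="\t", index=False)
            truth.regions.to_csv(outdir / "ground_truth_regions.tsv", sep="\t", index=False)
        else:
            proteins = load_dataset(config.reference, config.binding)
            tracks = [read_predictions(p, reference=proteins) for p in config.predictions]
        external = _load_external_scale(config.external_scale)

        # --- stage: regions and classes -----------------------------------
        stage = "regions"
        summary = region_summary(proteins)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        classes = classify_idps(proteins)
        pd.DataFrame(
            [{"protein_id": pid, "class": cls.value} for pid, cls in classes.items()]
        ).to_csv(outdir / "classes.tsv", sep="\t", index=False)
        log.info("regions: %d proteins, stage at %.1fs", len(proteins), time.time() - t0)

        # --- stage: composition scales ------------------------------------
        stage = "scales"
        scale_rng = np.random.default_rng(seeds[1])
        scales: list[PropensityScale] = []
        for label, selector in _CATEGORY_SAMPLES:
            try:
                sample, background = build_pools(proteins, selector, "nondisordered")
            except ValueError as exc:
                log.warning("skipping scale %s: %s", label, exc)
                continue
            sc = compute_scale(
                sample, background,
                n_resamples=config.n_resamples, alpha=config.alpha,
                seed=scale_rng, name=label,
            )
            _scale_table(sc).to_csv(outdir / "scales" / f"{label}.tsv", sep="\t", index=False)
            scales.append(sc)
        predictor_scales: dict[str, CompositionScale] = {}
        for track in tracks:
            put_dis, put_ord = _prediction_selectors(track)
            sample, background = build_pools(proteins, put_dis, put_ord)
            sc = compute_scale(
                sample, background,
                n_resamples=config.n_resamples, alpha=config.alpha,
                seed=scale_rng, name=f"pred_{track.name}",
            )
            _scale_table(sc).to_csv(
                outdir / "scales" / f"pred_{track.name}.tsv", sep="\t", index=False
            )
            predictor_scales[track.name] = sc
        log.info("scales: %d computed, stage at %.1fs", len(scales) + len(predictor_scales),
                 time.time() - t0)

        # --- stage: rank correlations -------------------------------------
        stage = "rank correlations"
        all_scales = list(scales) + list(predictor_scales.values())
        if external is not None:
            all_scales.append(external)
        matrix = scale_matrix(all_scales)
        matrix.to_long().to_csv(outdir / "kcc.tsv", sep="\t", index=False)

        # --- stage: per-class evaluation ----------------------------------
        stage = "evaluation"
        per_class = evaluate_by_class(tracks, proteins, classes)
        per_class.to_csv(outdir / "per_class_metrics.tsv", sep="\t", index=False)

        # accuracy vs scale agreement (needs >= 3 predictors)
        pcc = None
        native = next((s for s in scales if s.name == "caid"), None)
        if native is not None and len(tracks) >= 3:
            aucs = {
                r.predictor: r.auc
                for r in per_class[per_class.subset == "all"].itertuples()
            }
            kccs = {
                name: matrix.value("caid", f"pred_{name}") for name in predictor_scales
            }
            pcc = bias_performance_correlation(aucs, kccs)
        manifest["bias_performance_pcc"] = pcc

        # --- stage: meta-predictor ----------------------------------------
        stage = "meta"
        routing = _routing_from_config(config, per_class)
        meta = assemble_meta(tracks, routing, classes, proteins)
        write_predictions(meta, outdir / "meta_pred.txt", proteins=proteins)
        manifest["routing"] = {
            **{c.value: n for c, n in routing.mapping.items()},
            "default": routing.default,
        }

        rows = [vars(evaluate(meta, proteins))]
        rows += [vars(evaluate(t, proteins)) for t in tracks]
        meta_eval = pd.DataFrame(rows).sort_values("auc", ascending=False)

        # --- stage: bootstrap comparisons ---------------------------------
        stage = "bootstrap"
        boot_rng = np.random.default_rng(seeds[2])
        boot_rows = []
        for track in tracks:
            for metric in config.bootstrap_metrics:
                cmp = bootstrap_compare(
                    meta, track, proteins,
                    metric=metric,
                    n_iter=config.bootstrap_iterations,
                    fraction=config.bootstrap_fraction,
                    seed=boot_rng,
                )
                boot_rows.append(
                    {
                        "method_a": cmp.method_a, "method_b": cmp.method_b,
                        "metric": metric,
                        "mean_a": float(cmp.values_a.mean()),
                        "mean_b": float(cmp.values_b.mean()),
                        "normality_p": cmp.normality_p,
                        "test": cmp.test_used.value,
                        "p_value": cmp.p_value,
                    }
                )
        bootstrap_df = pd.DataFrame(boot_rows)
        bootstrap_df.to_csv(outdir / "bootstrap.tsv", sep="\t", index=False)
        pvals = bootstrap_df[bootstrap_df.metric == "auc"].set_index("method_b").p_value
        meta_eval["p_vs_meta"] = [
            None if r.predictor == meta.name else float(pvals.get(r.predictor, float("nan")))
            for r in meta_eval.itertuples()
        ]
        meta_eval.to_csv(outdir / "meta_eval.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    manifest["n_proteins"] = len(proteins)
    manifest["tables"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*.tsv")
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
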