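"""End-to-end orchestration: simulate → curate → annotate → train →
evaluate → explain.

This is the integration surface the command-line interface and the smoke
workflow share. Every step is the corresponding module's public API; the
pipeline only wires artifacts together and writes reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from prp.curation import (
    CurationConfig,
    LabeledVariantSet,
    build_test_set,
    build_training_set,
    records_from_vcf,
)
from prp.evaluation import compare_tools, evaluate, score_distribution
from prp.features import FEATURE_NAMES, assemble_features, build_npf_table
from prp.interpretation import explain, export_explanations, global_importance
from prp.resources import load_bundle
from prp.simulate import (
    SimulationConfig,
    load_dates,
    simulate_clinvar_vcf,
    simulate_reference,
    simulate_resources,
)
from prp.training import classify, default_spec, fit_final, predict, tune
from prp.variants import GenomicVariant, call_coding_effect

logger = logging.getLogger(__name__)


def train_plant() -> list:
    """Planted training-source composition (mirrors the curation filters)."""
    return [
        dict(n=120, sig="Pathogenic", status="criteria_provided,_multiple_submitters,_no_conflicts", af="rare", year=2021),
        dict(n=40, sig="Likely_pathogenic", status="reviewed_by_expert_panel", af="rare", year=2021),
        dict(n=90, sig="Benign", status="criteria_provided,_multiple_submitters,_no_conflicts", af="common", year=2021),
        dict(n=30, sig="Likely_benign", status="practice_guideline", af="common", year=2021),
        dict(n=60, sig="Likely_benign", status="criteria_provided,_single_submitter", af="rare", year=2021),
        dict(n=10, sig="Uncertain_significance", status="criteria_provided,_multiple_submitters,_no_conflicts", af="rare", year=2021),
    ]


def test_plant() -> list:
    return [
        dict(n=50, sig="Pathogenic", status="criteria_provided,_multiple_submitters,_no_conflicts", af="rare", year=2023),
        dict(n=50, sig="Benign", status="criteria_provided,_multiple_submitters,_no_conflicts", af="common", year=2023),
    ]


def _manifest_consequences(manifest: dict) -> dict:
    out = {}
    for key_str, (cons, gene) in manifest["consequences"].items():
        chrom, pos, ref, alt = key_str.split("|")
        out[(chrom, int(pos), ref, alt)] = (cons, gene)
    return out


def _pathogenic_positions(*manifests) -> set:
    positions = set()
    for manifest in manifests:
        for cell in manifest["cells"]:
            if "pathogenic" not in cell["sig"].lower():
                continue
            if "conflicting" in cell["sig"].lower():
                continue
            for chrom, pos, _, _ in cell["keys"]:
                positions.add((chrom, int(pos)))
    return positions


def write_af_tables(records, out_dir, seed: int) -> dict:
    """gnomAD-style AF tables (v4 = asserted AF, v2 = jittered copy)."""
    rng = np.random.default_rng(seed + 4)
    out_dir = Path(out_dir)
    paths = {"af_v2": out_dir / "af_v2.tsv", "af_v4": out_dir / "af_v4.tsv"}
    with open(paths["af_v4"], "w") as f4, open(paths["af_v2"], "w") as f2:
        for rec in records:
            if rec.af is None:
                continue
            chrom, pos, ref, alt = rec.key
            f4.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{rec.af:.6e}\n")
            v2 = min(1.0, rec.af * float(rng.uniform(0.8, 1.25)))
            f2.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{v2:.6e}\n")
    return {k: str(v) for k, v in paths.items()}


def annotate_set(
    labeled: LabeledVariantSet, reference, bundle, npf_table
) -> tuple:
    """Feature matrix (canonical columns), labels, AFs and keys for a set."""
    rows, labels, afs, keys = [], [], [], []
    for lr in labeled.records:
        chrom, pos, ref, alt = lr.record.key
        variant = GenomicVariant(chrom, pos, ref, alt)
        tx = reference.transcripts[lr.record.gene]
        effect = call_coding_effect(variant, tx, reference.genome)
        rows.append(
            assemble_features(variant, effect, tx, bundle, npf_table=npf_table)
        )
        labels.append(1 if lr.label == "TP" else 0)
        afs.append(lr.record.af)
        keys.append(lr.record.key)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES), dtype=float)
    return df, np.array(labels), afs, keys


def _synthetic_tool_scores(labels: np.ndarray, seed: int) -> pd.DataFrame:
    """Two comparator columns: a noisy oracle and pure noise."""
    rng = np.random.default_rng(seed + 5)
    n = len(labels)
    noisy = np.clip(labels * 0.7 + rng.normal(0.15, 0.18, n), 0, 1)
    noise = rng.uniform(0, 1, n)
    return pd.DataFrame({"noisy_oracle": noisy, "pure_noise": noise})


@dataclass
class PipelineResult:
    training_set: LabeledVariantSet
    test_set: LabeledVariantSet
    tune_result: object
    model: object
    test_report: object
    af_strata: list
    tool_reports: dict
    distribution: dict
    importance: object
    attributions: list
    artifacts: dict = field(default_factory=dict)


def run_pipeline(
    out_dir,
    seed: int = 0,
    n_trials: int = 10,
    cv_folds: int = 10,
    augment_size: int = 3000,
    algorithm: str = "gbt_xgb_style",
    sim_config: SimulationConfig = None,
) -> PipelineResult:
    """Run the whole pipeline on synthetic inputs in ``out_dir``.

    The augmentation size follows the protocol default (3,000) and clamps
    to the eligible single-submitter rare-benign pool at toy scale.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = sim_config or SimulationConfig(seed=seed)

    # 1. simulate
    reference = simulate_reference(config)
    train_manifest = simulate_clinvar_vcf(
        config, reference, out_dir, plant=train_plant(), filename="clinvar_train.vcf"
    )
    test_cfg = SimulationConfig(seed=seed + 1000, n_genes=config.n_genes,
                                cds_length_range=config.cds_length_range)
    test_manifest = simulate_clinvar_vcf(
        test_cfg, reference, out_dir, plant=test_plant(), filename="clinvar_test.vcf"
    )
    bundle_cfg = simulate_resources(
        config,
        reference,
        out_dir,
        pathogenic_positions=_pathogenic_positions(train_manifest, test_manifest),
    )

    # 2. curate
    cur_config = CurationConfig(seed=seed, augment_size=augment_size)
    train_records = records_from_vcf(
        train_manifest["vcf"],
        _manifest_consequences(train_manifest),
        dates=load_dates(train_manifest["dates"]),
    )
    test_records = records_from_vcf(
        test_manifest["vcf"],
        _manifest_consequences(test_manifest),
        dates=load_dates(test_manifest["dates"]),
    )
    training_set = build_training_set(train_records, cur_config)
    test_set = build_test_set(test_records, training_set, config=cur_config)

    # 3. annotate
    bundle_cfg.update(
        write_af_tables(train_records + test_records, out_dir, seed)
    )
    bundle = load_bundle(bundle_cfg)
    npf_table = build_npf_table(bundle.proteome)
    X_train, y_train, _, _ = annotate_set(training_set, reference, bundle, npf_table)
    X_test, y_test, af_test, test_keys = annotate_set(
        test_set, reference, bundle, npf_table
    )
    X_train.to_csv(out_dir / "train_features.tsv", sep="\t", index=False)
    X_test.to_csv(out_dir / "test_features.tsv", sep="\t", index=False)

    # 4. train
    spec = default_spec(algorithm, seed=seed, scale="desk")
    tune_result = tune(
        spec, X_train, y_train, n_trials=n_trials, seed=seed, k=cv_folds
    )
    model = fit_final(spec, tune_result.best_params, X_train, y_train)
    model.save(out_dir / "model.prp")

    # 5. evaluate
    scores = predict(model, X_test)
    report, strata = evaluate(
        scores, y_test, threshold=model.threshold, af_values=af_test
    )
    tools = _synthetic_tool_scores(y_test, seed)
    tool_reports = compare_tools(
        tools, {"noisy_oracle": 0.5, "pure_noise": 0.5}, y_test
    )
    distribution = score_distribution(scores, y_test, threshold=model.threshold)

    # 6. explain
    attributions = explain(model, X_test, keys=test_keys, seed=seed)
    importance = global_importance(model, X_train, seed=seed)

    artifacts = {
        "evaluation": out_dir / "evaluation.json",
        "importance": out_dir / "importance.tsv",
        "waterfall": out_dir / "waterfall.tsv",
        "decision": out_dir / "decision.tsv",
        "predictions": out_dir / "predictions.tsv",
    }
    with open(artifacts["evaluation"], "w") as fh:
        json.dump(
            {
                "overall": report.as_dict(),
                "af_strata": [
                    {"bin": list(s.af_bin), "n": s.n, **s.report.as_dict()}
                    for s in strata
                ],
                "tools": {t: r.as_dict() for t, r in tool_reports.items()},
                "cv_auc": tune_result.best_auc,
                "best_params": tune_result.best_params,
            },
            fh,
            indent=1,
        )
    export_explanations(attributions, "bar").to_csv(
        artifacts["importance"], sep="\t", index=False
    )
    export_explanations(attributions[:2], "waterfall").to_csv(
        artifacts["waterfall"], sep="\t", index=False
    )
    export_explanations(attributions[:2], "decision").to_csv(
        artifacts["decision"], sep="\t", index=False
    )
    pd.DataFrame(
        {
            "key": ["|".join(map(str, k)) for k in test_keys],
            "score": scores,
            "label": y_test,
            "predicted": classify(scores, model.threshold),
        }
    ).to_csv(artifacts["predictions"], sep="\t", index=False)

    return PipelineResult(
        training_set=training_set,
        test_set=test_set,
        tune_result=tune_result,
        model=model,
        test_report=report,
        af_strata=strata,
        tool_reports=tool_reports,
        distribution=distribution,
        importance=importance,
        attributions=attributions,
        artifacts={k: str(v) for k, v in artifacts.items()},
    )
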