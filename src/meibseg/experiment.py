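"""The six-condition cross-device experiment.

Two models are trained on the internal-device style — one on raw phantoms,
one on CLAHE-preprocessed phantoms — and evaluated on up to six testing
conditions: internal, internal+CLAHE, external, external+HS, external+CLAHE
and external+HS+CLAHE.  The histogram-specification template is the average
histogram of the internal-style image pool.  Non-CLAHE conditions are scored
by the raw-trained model and CLAHE conditions by the CLAHE-trained model
(configurable).  Outputs are per-image metric/loss-rate CSVs, per-condition
aggregates, pairwise Mann–Whitney comparisons, the average-histogram gap and
the t-SNE separation score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augmentation import AugmentConfig, augment_pair
from .evaluation import (aggregate_metrics, compare_groups, domain_embedding,
                         loss_rate_rmse, mg_loss_rate, region_metrics,
                         LossRateRecord)
from .model import NetworkConfig, build_network, predict_mask
from .preprocessing import CLAHEParams, average_histogram, clahe, specify_histogram
from .synthetic import builtin_style, generate_dataset
from .training import TrainConfig, train

log = logging.getLogger("meibseg")

ALL_CONDITIONS = ("internal", "internal+clahe", "external", "external+hs",
                  "external+clahe", "external+hs+clahe")

__all__ = ["ExperimentConfig", "run_experiment", "ALL_CONDITIONS"]


@dataclass
class ExperimentConfig:
    internal_style: str = "deviceA"
    external_style: str = "deviceB"
    conditions: tuple = ALL_CONDITIONS
    n_train: int = 60
    n_val: int = 10
    n_test_internal: int = 20
    n_test_external: int = 20
    augment: bool = False
    seed: int = 0
    clahe_params: CLAHEParams = field(default_factory=CLAHEParams)
    model: NetworkConfig = field(default_factory=lambda: NetworkConfig(
        width_scale=0.25, input_size=96))
    training: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=20, batch_size=8, input_size=96))
    clahe_model_for_clahe_conditions: bool = True
    out_dir: str = "runs/experiment"

    def __post_init__(self):
        unknown = set(self.conditions) - set(ALL_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if not self.conditions:
            raise ValueError("at least one condition is required")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "model" in raw:
            for key in ("encoder_blocks", "msp_dilations"):
                if key in raw["model"]:
                    raw["model"][key] = tuple(raw["model"][key])
            raw["model"] = NetworkConfig(**raw["model"])
        if "training" in raw:
            raw["training"] = TrainConfig(**raw["training"])
        if "clahe_params" in raw:
            raw["clahe_params"] = CLAHEParams(**raw["clahe_params"])
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)


def _apply_clahe(items, params):
    out = []
    for it in items:
        new = type(it)(image=clahe(it.image, params), mask=it.mask,
                       style_name=it.style_name,
                       true_loss_rate=it.true_loss_rate,
                       image_id=it.image_id)
        out.append(new)
    return out


def _apply_hs(items, template):
    out = []
    for it in items:
        matched, _ = specify_histogram(it.image, template)
        out.append(type(it)(image=matched, mask=it.mask,
                            style_name=it.style_name,
                            true_loss_rate=it.true_loss_rate,
                            image_id=it.image_id))
    return out


def _evaluate_condition(net, items, condition):
    metric_rows, rate_records = [], []
    for it in items:
        pred = predict_mask(net, it.image)
        for region in (1, 2):
            rec = region_metrics(pred, it.mask, region, image_id=it.image_id)
            metric_rows.append({"image_id": it.image_id, "condition": condition,
                                "region": "eyelid" if region == 1 else "MG",
                                "dsc": rec.dsc, "recall": rec.recall,
                                "precision": rec.precision,
                                "defined": rec.defined})
        try:
            pred_rate = mg_loss_rate(pred)
        except ValueError:
            pred_rate = 1.0  # nothing segmented: treat as total loss
        rate_records.append(LossRateRecord(it.image_id, pred_rate,
                                           mg_loss_rate(it.mask)))
    return metric_rows, rate_records


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full cross-device protocol; returns the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)


def _run(config: ExperimentConfig, out: Path) -> dict:
    style_int = builtin_style(config.internal_style)
    style_ext = builtin_style(config.external_style)
    seed = config.seed
    log.info("generating datasets (seed=%d)", seed)
    train_set = generate_dataset(config.n_train, None, style_int, seed)
    val_set = generate_dataset(config.n_val, None, style_int, seed + 1)
    test_int = generate_dataset(config.n_test_internal, None, style_int, seed + 2)
    test_ext = generate_dataset(config.n_test_external, None, style_ext, seed + 3)

    if config.augment:
        augmented = []
        for i, it in enumerate(train_set):
            augmented.extend(augment_pair(it, AugmentConfig(seed=seed + i)))
        train_set = train_set + augmented

    # HS template from the internal-style pool (training + internal test)
    template = average_histogram([it.image for it in train_set + test_int],
                                 source_set=config.internal_style)
    template.save(out / "template.csv")

    needed_raw = any(not c.endswith("clahe") for c in config.conditions)
    needed_clahe = any(c.endswith("clahe") for c in config.conditions)
    if not config.clahe_model_for_clahe_conditions:
        needed_raw, needed_clahe = True, False

    models = {}
    if needed_raw:
        log.info("training raw model")
        net = build_network(config.model)
        net, hist = train(net, train_set, val_set, config.training)
        models["raw"] = net
        pd.DataFrame(hist.to_rows()).to_csv(out / "history_raw.csv", index=False)
    if needed_clahe:
        log.info("training CLAHE model")
        net = build_network(config.model)
        net, hist = train(net, _apply_clahe(train_set, config.clahe_params),
                          _apply_clahe(val_set, config.clahe_params),
                          config.training)
        models["clahe"] = net
        pd.DataFrame(hist.to_rows()).to_csv(out / "history_clahe.csv",
                                            index=False)

    def condition_inputs(condition):
        base = test_int if condition.startswith("internal") else test_ext
        items = base
        if "+hs" in condition:
            items = _apply_hs(items, template)
        if condition.endswith("clahe"):
            items = _apply_clahe(items, config.clahe_params)
        return items

    def condition_model(condition):
        if condition.endswith("clahe") and config.clahe_model_for_clahe_conditions:
            return models["clahe"]
        return models.get("raw") or models["clahe"]

    all_metrics, rmse_rows, rate_rows = [], [], []
    per_condition_mg_dsc = {}
    for condition in config.conditions:
        log.info("evaluating condition %s", condition)
        items = condition_inputs(condition)
        metric_rows, rate_records = _evaluate_condition(
            condition_model(condition), items, condition)
        all_metrics.extend(metric_rows)
        rmse_rows.append({"condition": condition,
                          "rmse": loss_rate_rmse(rate_records)})
        for r in rate_records:
            rate_rows.append({"image_id": r.image_id, "condition": condition,
                              "predicted_rate": r.predicted_rate,
                              "true_rate": r.true_rate,
                              "predicted_grade": r.predicted_grade,
                              "true_grade": r.true_grade})
        per_condition_mg_dsc[condition] = [
            m["dsc"] for m in metric_rows
            if m["region"] == "MG" and m["defined"]]

    metrics_df = pd.DataFrame(all_metrics)
    metrics_df.to_csv(out / "metrics.csv", index=False)
    pd.DataFrame(rate_rows).to_csv(out / "loss_rates.csv", index=False)
    pd.DataFrame(rmse_rows).to_csv(out / "rmse.csv", index=False)

    agg_rows = []
    for condition in config.conditions:
        for region in ("MG", "eyelid"):
            sub = metrics_df[(metrics_df.condition == condition)
                             & (metrics_df.region == region)]
            recs = [type("R", (), dict(dsc=r.dsc, recall=r.recall,
                                       precision=r.precision,
                                       defined=r.defined))()
                    for r in sub.itertuples()]
            agg = aggregate_metrics(recs)
            agg.update({"condition": condition, "region": region})
            agg_rows.append(agg)
    pd.DataFrame(agg_rows).to_csv(out / "metrics_summary.csv", index=False)

    comparisons = []
    for c1, c2 in [("external", "external+hs"), ("external", "external+clahe"),
                   ("internal", "internal+clahe")]:
        if c1 in per_condition_mg_dsc and c2 in per_condition_mg_dsc:
            a, b = per_condition_mg_dsc[c1], per_condition_mg_dsc[c2]
            if len(a) >= 2 and len(b) >= 2:
                res = compare_groups(a, b, metric="MG DSC", group_a=c1,
                                     group_b=c2)
                comparisons.append({"metric": res.metric, "a": c1, "b": c2,
                                    "U": res.u_statistic, "p": res.p_value,
                                    "significant": res.significant})
    if comparisons:
        pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)

    from .synthetic import style_histogram_gap
    hist_gap = style_histogram_gap(test_int, test_ext)
    _, _, tsne_sep = domain_embedding(test_int, test_ext, seed=seed)

    report = {
        "version": __version__,
        "seed": seed,
        "conditions": list(config.conditions),
        "histogram_gap": hist_gap,
        "tsne_separation": tsne_sep,
        "mean_mg_dsc": {c: float(np.mean(v)) if v else float("nan")
                        for c, v in per_condition_mg_dsc.items()},
        "rmse": {r["condition"]: r["rmse"] for r in rmse_rows},
        "config": json.loads(json.dumps(asdict(config), default=str)),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
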