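"""Configuration-driven orchestration of the full study workflow.

Stages: data (simulate or load) -> feature selection -> encoding ->
model training (unimodal branches, bimodal network, benchmarks) ->
evaluation (0.5 and Youden cut-offs) -> survival analysis. A manifest
with the config hash, fanned-out stage seeds and package versions plus
all numeric artifacts are written to the output directory; rerunning the
same config reproduces the metrics byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import io as cio
from . import models as mdl
from . import network as net
from . import survival as surv
from . import synthetic as syn

__all__ = ["ConfigError", "StageError", "PipelineConfig", "run_pipeline",
           "report_summary"]

log = logging.getLogger(__name__)

STAGES = ("data", "features", "encode", "train", "evaluate", "survival")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass(frozen=True)
class PipelineConfig:
    simulate: syn.SimConfig | None = None
    paths: dict | None = None  # expression/clinical/survival/splits/interactome
    literature_genes: tuple[str, ...] = syn.LITERATURE_BIOMARKERS
    n_background_edges: int = 150
    k: int = 30
    r_threshold: float = 0.6
    alpha: float = 0.01
    micro_widths: tuple[int, ...] = (40, 40, 40, 40)
    clinical_widths: tuple[int, ...] = (18, 18, 18, 18)
    post_widths: tuple[int, ...] = (32, 32)
    l2_penalty: float = 1e-4
    learning_rate: float = 0.006
    max_epochs: int = 100
    batch_size: int = 20
    patience: int = 30
    benchmarks: tuple[str, ...] = ("rf",)
    reclassify: bool = True
    seed: int = 0

    def validate(self) -> None:
        if (self.simulate is None) == (self.paths is None):
            raise ConfigError("exactly one of 'simulate' and 'paths' "
                              "must be configured")
        for b in self.benchmarks:
            if b not in mdl.BENCHMARK_KINDS:
                raise ConfigError(f"unknown benchmark {b!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        try:
            sim = d.pop("simulate", None)
            if sim is not None:
                sim = syn.SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in sim.items()})
            kwargs = {}
            for f in dataclasses.fields(cls):
                if f.name in ("simulate",):
                    continue
                if f.name in d:
                    v = d.pop(f.name)
                    kwargs[f.name] = tuple(v) if isinstance(v, list) else v
            if d.keys() - {"paths"}:
                raise ConfigError(f"unknown config keys: {sorted(d)}")
            cfg = cls(simulate=sim, **kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("pipeline config must be a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seed(base: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence([int(base), stage]).generate_state(1)[0]
               % 2**31)


def _load_or_simulate(config: PipelineConfig):
    """Stage 1: return (bundle, interactome)."""
    if config.simulate is not None:
        sim = replace(config.simulate, seed=_stage_seed(config.seed, 0))
        bundle = syn.assemble_cohort(sim)
        inter = syn.simulate_interactome(
            list(bundle.expression.index), bundle.truth,
            n_background_edges=config.n_background_edges,
            seed=_stage_seed(config.seed, 1))
        return bundle, inter
    p = config.paths
    for key in ("expression", "clinical", "survival", "interactome"):
        if key not in p:
            raise ConfigError(f"paths.{key} missing")
    bundle = cio.load_cohort(p["expression"], p["clinical"], p["survival"],
                             p.get("splits"))
    if bundle.splits is None:
        rng = np.random.default_rng(_stage_seed(config.seed, 0))
        bundle.splits = syn._assign_splits(bundle.sample_ids,
                                           (0.5, 0.166, 0.334), rng)
    return bundle, cio.read_interactome(p["interactome"])


def _encode(bundle, panel, out):
    labels = surv.five_year_label(bundle.survival)
    dead = pd.Series(labels.dead.astype(int), index=bundle.survival.index)
    usable = pd.Series(labels.usable, index=bundle.survival.index)
    train_ids = bundle.split_ids("train")
    expr_block = cio.encode_expression(bundle.expression, panel.combined,
                                       train_ids)
    clin_block = cio.encode_clinical(bundle.clinical, train_ids)
    sets = {}
    for split in ("train", "validation", "test"):
        ids = [s for s in bundle.split_ids(split) if usable[s]]
        sets[split] = {
            "ids": ids,
            "Xm": expr_block.matrix_for(ids),
            "Xc": clin_block.matrix_for(ids),
            "y": dead.loc[ids].to_numpy(),
        }
    out["n_usable"] = {k: len(v["ids"]) for k, v in sets.items()}
    return sets, expr_block, clin_block


def _train_models(config, sets, expr_block, clin_block):
    tseed = _stage_seed(config.seed, 3)
    tspec = mdl.TrainSpec(learning_rate=config.learning_rate,
                          max_epochs=config.max_epochs,
                          batch_size=config.batch_size,
                          early_stop_patience=config.patience, seed=tseed)
    tr, va = sets["train"], sets["validation"]
    micro_spec = mdl.BranchSpec(tr["Xm"].shape[1], config.micro_widths,
                                l2_penalty=config.l2_penalty, seed=tseed)
    clin_spec = mdl.BranchSpec(tr["Xc"].shape[1], config.clinical_widths,
                               l2_penalty=config.l2_penalty, seed=tseed + 1)
    micro = mdl.train_unimodal(micro_spec, tr["Xm"], tr["y"], va["Xm"],
                               va["y"], tspec, kind="micro")
    clin = mdl.train_unimodal(clin_spec, tr["Xc"], tr["y"], va["Xc"],
                              va["y"], tspec, kind="clinical")
    bspec = mdl.BimodalSpec(micro_spec, clin_spec, config.post_widths,
                            l2_penalty=config.l2_penalty, seed=tseed + 2)
    bimodal = mdl.train_bimodal(micro, clin, tr["Xm"], tr["Xc"], tr["y"],
                                va["Xm"], va["Xc"], va["y"], bspec, tspec)
    trained = {"micro": micro, "clinical": clin, "bimodal": bimodal}
    for kind in config.benchmarks:
        Xtr = np.hstack([tr["Xm"], tr["Xc"]])
        trained[f"{kind}_combined"] = mdl.train_benchmark(
            kind, Xtr, tr["y"], seed=_stage_seed(config.seed, 4))
    return trained


def _model_inputs(name, model, split):
    if name == "micro":
        return split["Xm"]
    if name == "clinical":
        return split["Xc"]
    if name == "bimodal":
        return (split["Xm"], split["Xc"])
    return np.hstack([split["Xm"], split["Xc"]])


def _evaluate(config, trained, sets, out_dir):
    metrics = {}
    cutoffs = {}
    for name, model in trained.items():
        val_scores = mdl.predict_risk(model, _model_inputs(name, model,
                                                           sets["validation"]))
        test_scores = mdl.predict_risk(model, _model_inputs(name, model,
                                                            sets["test"]))
        roc = ev.roc_and_auc(test_scores, sets["test"]["y"])
        _write_roc(out_dir / "roc" / f"{name}.tsv", roc)
        entry = {"test_auc": roc.auc, "cutoffs": {}}
        use = {"0.5": 0.5}
        if config.reclassify:
            val_roc = ev.roc_and_auc(val_scores, sets["validation"]["y"])
            yj = ev.youden_cutoff(val_roc)
            entry["youden_cutoff"] = yj.cutoff
            entry["youden_j"] = yj.youden_j
            use["youden"] = yj.cutoff
        for label, cut in use.items():
            pred = ev.classify_at(test_scores, cut)
            rep = ev.classification_metrics(pred, sets["test"]["y"])
            entry["cutoffs"][label] = {"cutoff": cut, **rep.as_dict()}
        metrics[name] = entry
        cutoffs[name] = use
    return metrics, cutoffs


def _survival_analysis(trained, cutoffs, bundle, expr_block, clin_block,
                       out_dir):
    """Risk stratification on the full test split (censored included)."""
    test_ids = bundle.split_ids("test")
    surv_tbl = bundle.survival.loc[test_ids]
    split = {"Xm": expr_block.matrix_for(test_ids),
             "Xc": clin_block.matrix_for(test_ids)}
    results = {}
    for name, model in trained.items():
        scores = mdl.predict_risk(model, _model_inputs(name, model, split))
        results[name] = {}
        for label, cut in cutoffs[name].items():
            rg = surv.risk_group_survival(scores, cut, surv_tbl)
            if rg.degenerate:
                results[name][label] = {"degenerate": True,
                                        "n_high": rg.n_high, "n_low": rg.n_low}
                continue
            results[name][label] = {
                "degenerate": False, "n_high": rg.n_high, "n_low": rg.n_low,
                "hr": rg.cox.hr, "ci_low": rg.cox.ci_low,
                "ci_high": rg.cox.ci_high, "cox_p": rg.cox.p_value,
                "logrank_p": rg.logrank.p_value,
                "logrank_statistic": rg.logrank.statistic,
            }
            _write_km(out_dir / "km" / f"{name}_{label.replace('.', '')}.tsv",
                      rg)
    return results


def _write_roc(path: Path, roc: ev.ROCResult):
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"threshold": roc.thresholds, "tpr": roc.tpr,
                  "fpr": roc.fpr}).to_csv(path, sep="\t", index=False)


def _write_km(path: Path, rg: surv.RiskGroupResult):
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for grp, km in (("high", rg.km_high), ("low", rg.km_low)):
        frames.append(pd.DataFrame({"group": grp, "time_months": km.times,
                                    "survival": km.survival,
                                    "at_risk": km.at_risk,
                                    "events": km.events}))
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def _json_dump(obj, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)!r}")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages; returns the metrics report (also written as
    metrics.json). Any stage failure raises StageError naming the stage;
    artifacts written before the failure are retained."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    timings = {}
    stage = "data"
    t0 = time.time()
    try:
        bundle, interactome = _load_or_simulate(config)
        report["n_samples"] = len(bundle.sample_ids)
        report["split_sizes"] = {s: len(bundle.split_ids(s))
                                 for s in ("train", "validation", "test")}
        timings[stage] = time.time() - t0

        stage = "features"
        t0 = time.time()
        sel = net.run_feature_selection(bundle, interactome,
                                        config.literature_genes,
                                        k=config.k,
                                        r_threshold=config.r_threshold,
                                        alpha=config.alpha)
        panel = sel.panel
        report["panel"] = {"literature": list(panel.literature_genes),
                           "novel": list(panel.novel_genes),
                           "size": len(panel)}
        for anchor, prv in sel.prv_tables.items():
            p = out / "prv" / f"{anchor}.tsv"
            p.parent.mkdir(parents=True, exist_ok=True)
            prv.table.to_csv(p, sep="\t")
        _json_dump(report["panel"], out / "panel.json")
        timings[stage] = time.time() - t0

        stage = "encode"
        t0 = time.time()
        sets, expr_block, clin_block = _encode(bundle, panel, report)
        timings[stage] = time.time() - t0

        stage = "train"
        t0 = time.time()
        trained = _train_models(config, sets, expr_block, clin_block)
        timings[stage] = time.time() - t0

        stage = "evaluate"
        t0 = time.time()
        metrics, cutoffs = _evaluate(config, trained, sets, out)
        report["models"] = metrics
        timings[stage] = time.time() - t0

        stage = "survival"
        t0 = time.time()
        report["survival"] = _survival_analysis(trained, cutoffs, bundle,
                                                expr_block, clin_block, out)
        timings[stage] = time.time() - t0
    except (ConfigError,) as exc:
        raise
    except Exception as exc:
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    _json_dump(report, out / "metrics.json")
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=_jsonable)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, i)
                        for i, s in enumerate(STAGES)},
        "stages": list(STAGES),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "versions": _versions(),
    }
    _json_dump(manifest, out / "manifest.json")
    return report


def _versions() -> dict:
    import lifelines
    import sklearn
    from importlib.metadata import version as _v
    try:
        own = _v("prognet")
    except Exception:
        own = "unknown"
    return {"prognet": own, "numpy": np.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
            "lifelines": lifelines.__version__}


def report_summary(run_dir) -> tuple[str, dict]:
    """Tabulate a completed run: AUC/accuracy/precision/recall/F1 per
    model x cutoff and HR/CI per stratification. Returns (text, dict);
    both carry identical numbers."""
    path = Path(run_dir) / "metrics.json"
    if not path.exists():
        raise cio.DataError(f"missing artifact: {path}")
    report = json.loads(path.read_text())
    rows = []
    for name, entry in sorted(report.get("models", {}).items()):
        for label, m in sorted(entry["cutoffs"].items()):
            rows.append({"model": name, "cutoff_rule": label,
                         "cutoff": m["cutoff"], "auc": entry["test_auc"],
                         "accuracy": m["accuracy"],
                         "precision": m["precision"], "recall": m["recall"],
                         "f1": m["f1"]})
    srows = []
    for name, entry in sorted(report.get("survival", {}).items()):
        for label, m in sorted(entry.items()):
            if m.get("degenerate"):
                srows.append({"model": name, "cutoff_rule": label,
                              "degenerate": True})
            else:
                srows.append({"model": name, "cutoff_rule": label,
                              "hr": m["hr"], "ci_low": m["ci_low"],
                              "ci_high": m["ci_high"],
                              "logrank_p": m["logrank_p"]})
    lines = ["model         cutoff   AUC     acc     prec    recall  F1"]
    for r in rows:
        lines.append(f"{r['model']:<13} {r['cutoff_rule']:<8} "
                     f"{r['auc']:.4f}  {r['accuracy']:.4f}  "
                     f"{r['precision']:.4f}  {r['recall']:.4f}  {r['f1']:.4f}")
    lines.append("")
    lines.append("model         cutoff   HR      95% CI            logrank p")
    for r in srows:
        if r.get("degenerate"):
            lines.append(f"{r['model']:<13} {r['cutoff_rule']:<8} degenerate")
        else:
            lines.append(f"{r['model']:<13} {r['cutoff_rule']:<8} "
                         f"{r['hr']:.3f}  [{r['ci_low']:.3f}, "
                         f"{r['ci_high']:.3f}]  {r['logrank_p']:.4g}")
    return "\n".join(lines), {"classification": rows, "survival": srows}
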