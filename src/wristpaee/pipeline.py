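"""End-to-end study replica: simulate → non-wear → split → fit → evaluate → associate.

One :class:`~wristpaee.config.RunConfig` drives the full sequence with
fixed seeds; every stage writes its table under the configured output
directory and the run manifest records paths, seeds and headline
metrics. Stage seeds are derived from the master seed by hashing the
stage name, so any stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import evaluation as ev
from . import models as mod
from . import nonwear as nw
from . import synthetic as syn
from .config import RunConfig, save_config

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name XOR master."""
    return (zlib.crc32(stage.encode()) ^ master_seed) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _detect_nonwear(epochs: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Re-detect wear flags from signal content (not the generator's truth).

    Combined sensor: zero trunk movement with invalid heart rate for
    >90 min. Wrist: the epoch-level proxy rule (runs of exactly zero
    wrist movement of at least the minimum duration), since raw waveform
    data is not simulated at cohort scale.
    """
    epoch_length = config.generator.epoch_length
    out = epochs.copy()
    out["wear_wrist"] = nw.wrist_nonwear_epoch_proxy(out, config.nonwear, epoch_length)
    flags = []
    for _, grp in out.groupby("participant_id", sort=False):
        segs = nw.detect_combined_nonwear(
            grp["trunk_acc_ms2"], grp["hr_valid"], grp["epoch_start"],
            epoch_length, config.nonwear)
        flagged = nw.flag_epochs(
            grp.assign(wear_combined=True), segs, epoch_length)
        flags.append(flagged["wear_combined"].to_numpy())
    out["wear_combined"] = np.concatenate(flags)
    return out


def _nonwear_segment_table(epochs: pd.DataFrame, epoch_length: int) -> pd.DataFrame:
    """Non-worn segments per participant and sensor, from epoch flags."""
    rows = []
    for pid, grp in epochs.groupby("participant_id", sort=False):
        starts = pd.to_datetime(grp["epoch_start"]).to_numpy()
        for sensor, col in (("wrist", "wear_wrist"), ("combined", "wear_combined")):
            worn = grp[col].to_numpy(dtype=bool)
            for i0, i1, val in nw._runs(~worn):
                if val:
                    rows.append({
                        "participant_id": pid, "sensor": sensor,
                        "start": starts[i0],
                        "end": starts[i1 - 1] + np.timedelta64(epoch_length, "s"),
                        "worn": False})
    return pd.DataFrame(rows, columns=["participant_id", "sensor",
                                       "start", "end", "worn"])


def _evaluate_models(models, test_epochs):
    """Per-model epoch-level evaluation for one outcome."""
    rows = {}
    crit_col = mod.OUTCOME_COLUMNS[next(iter(models.values())).spec.outcome]
    for k, m in models.items():
        pred = mod.predict(m, test_epochs)
        df = pd.DataFrame({"pred": pred,
                           "crit": test_epochs[crit_col].to_numpy(),
                           "pid": test_epochs["participant_id"].to_numpy()}).dropna()
        r2b, r2w = ev.variance_decomposition(df["pred"], df["crit"], df["pid"])
        rows[k] = {"model": k, "outcome": m.spec.outcome,
                   "metric": m.spec.metric, "form": m.spec.form,
                   "r2_between": r2b, "r2_within": r2w,
                   "rmse": ev.rmse(df["pred"], df["crit"])}
    return pd.DataFrame(rows.values())


def run_pipeline(config: RunConfig | None = None,
                 output_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns the manifest dictionary.

    On stage failure a :class:`StageError` propagates after the partial
    manifest (with the failing stage named) is written.
    """
    config = config or RunConfig()
    out_dir = Path(output_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"seeds": {"generator": config.generator.seed,
                                "split": config.split.seed},
                      "outputs": {}, "metrics": {}, "stages": []}

    def emit(name: str, frame: pd.DataFrame) -> Path:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest["outputs"][name] = str(path)
        return path

    def fail(stage: str, err: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if isinstance(err, StageError):
            return err
        return StageError(stage, str(err))

    try:
        stage = "simulate"
        cohort, epochs = syn.generate_dataset(config.generator)
        emit("cohort", cohort)
        emit("epochs", epochs.assign(
            epoch_start=pd.to_datetime(epochs["epoch_start"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S")))
        manifest["stages"].append(stage)

        stage = "nonwear"
        detected = _detect_nonwear(epochs, config)
        emit("wear_segments", _nonwear_segment_table(
            detected, config.generator.epoch_length))
        analysis_epochs = nw.apply_exclusions(detected)
        manifest["metrics"]["n_epochs_total"] = int(len(epochs))
        manifest["metrics"]["n_epochs_analysed"] = int(len(analysis_epochs))
        by_sex = analysis_epochs.merge(cohort[["participant_id", "sex"]],
                                       on="participant_id")
        manifest["metrics"].update({
            "mean_paee_jminkg": float(analysis_epochs["paee_jminkg"].mean()),
            "mean_enmo_mg": float(analysis_epochs["enmo_mg"].mean()),
            "mean_hpfvm_mg": float(analysis_epochs["hpfvm_mg"].mean()),
            "mean_trunk_acc_ms2": float(analysis_epochs["trunk_acc_ms2"].mean()),
            "mean_paee_men_jminkg": float(
                by_sex.loc[by_sex["sex"] == "male", "paee_jminkg"].mean()),
            "mean_paee_women_jminkg": float(
                by_sex.loc[by_sex["sex"] == "female", "paee_jminkg"].mean())})
        manifest["stages"].append(stage)

        stage = "split"
        split = mod.split_participants(cohort, config.split.train_fraction,
                                       config.split.seed)
        train = analysis_epochs[analysis_epochs["participant_id"].isin(
            split.train_ids)]
        test = analysis_epochs[analysis_epochs["participant_id"].isin(
            split.test_ids)]
        emit("split", split.frame())
        manifest["stages"].append(stage)

        stage = "fit"
        paee_models = mod.fit_all_models(train, outcome="paee")
        trunk_models = mod.fit_all_models(train, outcome="trunk_acc")
        emit("models_paee", mod.models_to_frame(paee_models))
        emit("models_trunk", mod.models_to_frame(trunk_models))
        manifest["stages"].append(stage)

        stage = "evaluate"
        if len(split.test_ids) == 0:
            raise StageError(stage, "train_fraction leaves no test participants; "
                                    "evaluation cannot run")
        eval_paee = _evaluate_models(paee_models, test)
        eval_trunk = _evaluate_models(trunk_models, test)
        emit("evaluation_models", pd.concat([eval_paee, eval_trunk],
                                            ignore_index=True))
        keys = sorted(paee_models)
        best = mod.select_best([paee_models[k] for k in keys],
                               eval_paee.set_index("model")["rmse"].loc[keys],
                               eval_trunk.set_index("model")["rmse"].loc[keys])
        best_num = next(k for k in keys if paee_models[k] is best)
        report = ev.evaluate_predictions(
            test, mod.predict(best, test), cohort=cohort)
        emit("evaluation_best", report.summary_frame().assign(model=best_num))
        emit("stratified_bias", report.stratified)
        emit("bias_trends", report.trends.reset_index(names="term"))
        manifest["metrics"].update({
            "best_model": best_num,
            "r2_between": report.r2_between, "r2_within": report.r2_within,
            "rmse": report.rmse, "rmse_mets": float(ev.to_mets(report.rmse)),
            "mean_bias": report.mean_bias,
            "loa_lower": report.loa_lower, "loa_upper": report.loa_upper})
        manifest["stages"].append(stage)

        stage = "associate"
        results = {"criterion": assoc.fit_bmi_association(
            cohort, assoc.participant_paee(test), "criterion")}
        for k, m in paee_models.items():
            pred = test.assign(pred=mod.predict(m, test))
            pred.loc[test["paee_jminkg"].isna(), "pred"] = np.nan
            means = assoc.participant_paee(pred, "pred")
            results[f"model{k}"] = assoc.fit_bmi_association(
                cohort, means, f"model{k}")
        comparison = assoc.compare_sources(results)
        emit("association", comparison)
        manifest["metrics"]["bmi_beta_criterion"] = results["criterion"].beta
        manifest["metrics"]["bmi_beta_best_model"] = results[f"model{best_num}"].beta
        manifest["stages"].append(stage)
    except StageError as err:
        raise fail(err.stage, err) from err
    except Exception as err:  # noqa: BLE001 - stage name is the useful context
        raise fail(stage, err) from err

    save_config(config, out_dir / "config.yaml")
    manifest["outputs"]["config"] = str(out_dir / "config.yaml")
    manifest["checksums"] = {k: _sha256(Path(p))
                             for k, p in manifest["outputs"].items()}
    manifest["runtime_s"] = round(time.time() - t0, 1)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(out_dir / "manifest.json")
    return manifest
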