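"""End-to-end orchestration: synthesize → preprocess → univariate screen →
combination search → stage distances → treatment response, from a single
config with one root seed and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import classify, cohort, combo, preprocess, stage
from ._rng import subseed
from .stats import two_sample_t

__all__ = ["RunConfig", "run_pipeline", "univariate_screen", "load_config"]

log = logging.getLogger("breathvoc")


@dataclass
class RunConfig:
    """One run: data source, preprocessing thresholds, classifier/search
    settings, stage toggles, output directory and the root seed."""

    outdir: str = "breathvoc_run"
    seed: int = 0
    # data source: either a directory with voc_table/meta/blanks CSVs, or synthesis
    input_dir: str | None = None
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    # preprocessing
    min_prevalence: float = 0.05
    train_frac: float = 152 / 208
    # classifier / search
    classifier: dict = field(default_factory=dict)  # ClassifierConfig overrides
    search: dict = field(default_factory=dict)  # SearchPlan overrides (pool defaults to top screen hits)
    pool_size: int = 10
    # stage toggles
    stages: tuple[str, ...] = ("synth", "preprocess", "screen", "search", "stage", "response")
    response_marker: str | None = None
    response_cutoff: float | None = None
    log_level: str = "INFO"

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run config."""
    import yaml

    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in doc:
        doc["stages"] = tuple(doc["stages"])
    return RunConfig(**doc)


def univariate_screen(log2_df: pd.DataFrame, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-VOC Welch t test, case (HCC) vs control, on log2 values.

    No multiplicity adjustment is applied (none is used in the headline
    screen); the Benjamini–Hochberg column ``fdr_bh`` is an optional
    extension, clearly separate from the unadjusted p.
    """
    pos = np.asarray(groups) == "hcc"
    rows = []
    for c in log2_df.columns:
        x = log2_df.loc[pos, c].to_numpy()
        y = log2_df.loc[~pos, c].to_numpy()
        res = two_sample_t(x, y, welch=True)
        rows.append({
            "voc": c, "t": res.statistic, "p": res.pvalue,
            "mean_case": res.summaries["group_x"]["mean"],
            "mean_control": res.summaries["group_y"]["mean"],
            "n_case": res.n[0], "n_control": res.n[1],
        })
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    out["fdr_bh"] = sps.false_discovery_control(out["p"], method="bh")
    return out


def _write_json(path: Path, doc) -> None:
    path.write_text(json.dumps(doc, indent=2, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run report.

    Writes stage outputs under ``config.outdir`` plus ``manifest.json``
    (seed, config hash, per-output SHA-256 of numeric CSVs) and a
    human-readable ``summary.txt``. A stage failure raises after writing a
    FAILED marker naming the stage; earlier outputs are retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    summary_lines: list[str] = [f"breathvoc run (seed={config.seed}, hash={report['config_hash']})"]
    current = "setup"
    try:
        # ---- synth / load -------------------------------------------------
        current = "synth"
        if config.input_dir is not None:
            raw = preprocess.read_voc_table(Path(config.input_dir) / "voc_table.csv")
            meta = preprocess.read_meta(Path(config.input_dir) / "meta.csv")
            blanks = preprocess.read_blanks(Path(config.input_dir) / "blanks.csv")
            summary_lines.append(f"loaded {len(raw)} samples from {config.input_dir}")
        else:
            synth_cfg = cohort.default_config(
                **{**config.synth, "seed": subseed(config.seed, "synth")})
            coh = cohort.generate_cohort(synth_cfg)
            raw, meta, blanks = coh.voc_table, coh.meta, coh.blanks
            if "synth" in config.stages:
                cohort.write_cohort(coh, outdir / "cohort")
                report["stages"]["synth"] = {"n_samples": int(len(raw)),
                                             "n_voc": int(raw.shape[1])}
                summary_lines.append(f"synthesized {len(raw)} samples x {raw.shape[1]} VOCs")
        if set(config.stages) <= {"synth"}:
            _finish(outdir, report, summary_lines)
            return report

        # ---- preprocess ---------------------------------------------------
        current = "preprocess"
        meta_idx = meta.set_index("sample_id")
        table = preprocess.VOCTable.from_raw(raw, blanks, meta_idx.loc[raw.index, "day"])
        table = preprocess.prevalence_filter(table, config.min_prevalence)
        if "preprocess" in config.stages:
            table.write(outdir / "processed", min_prevalence=config.min_prevalence)
        # Pre-treatment samples only for case/control analyses.
        pre_ids = meta_idx.index[(meta_idx["timepoint"].astype(str) != "post")]
        pre_ids = [i for i in table.sample_ids if i in set(pre_ids)]
        pre_table = table.select_samples(pre_ids)
        pre_meta = meta_idx.loc[pre_ids]
        (train_tab, train_meta), (test_tab, test_meta), comp = preprocess.split_train_test(
            pre_table, pre_meta.reset_index(), train_frac=config.train_frac,
            seed=subseed(config.seed, "split"))
        report["stages"]["preprocess"] = {
            "n_voc_kept": int(pre_table.raw.shape[1]), "split": comp}
        summary_lines.append(
            f"prevalence filter kept {pre_table.raw.shape[1]} VOCs; "
            f"split train n={comp['train']['n']} / test n={comp['test']['n']}")

        # ---- univariate screen -------------------------------------------
        current = "screen"
        screen = univariate_screen(
            pre_table.log2, np.where(pre_meta["group"] == "hcc", "hcc", "control"))
        if "screen" in config.stages:
            screen.to_csv(outdir / "univariate_screen.csv", index=False)
            n_sig = int(screen["significant"].sum())
            report["stages"]["screen"] = {"n_significant": n_sig}
            summary_lines.append(
                f"univariate screen: {n_sig}/{len(screen)} VOCs with p < 0.05")

        # ---- combination search ------------------------------------------
        clf_cfg = classify.ClassifierConfig(
            **{**config.classifier, "seed": subseed(config.seed, "classify")})
        subgroups = np.where(train_meta["group"] == "hcc", "case",
                             train_meta["group"]).astype(str)
        y_train = np.asarray(train_meta["group"])
        best_vocs = None
        if "search" in config.stages:
            current = "search"
            pool = tuple(screen.sort_values("p")["voc"].head(config.pool_size))
            plan = combo.SearchPlan(
                **{"pool": pool, "k": (1, min(6, len(pool))), "strategy": "greedy",
                   "classifier": clf_cfg, "seed": subseed(config.seed, "search"),
                   **config.search})
            results = combo.search_combinations(
                train_tab.log2, y_train, plan, smote_subgroups=subgroups)
            tables = combo.top10_tables(results)
            freq = combo.voc_frequency(tables)
            pd.DataFrame([r.to_record() for r in results]).to_csv(
                outdir / "combo_results.csv", index=False)
            _write_json(outdir / "combo_report.json", {
                "top10": {k: [r.to_record() for r in v] for k, v in tables.items()},
                "frequency": {k: v.to_dict() for k, v in freq.items()},
            })
            best = tables["accuracy"][0]
            best_vocs = list(best.vocs)
            report["stages"]["search"] = {"best_vocs": best_vocs,
                                          **best.metrics.as_dict()}
            summary_lines.append(
                f"best combination ({len(best_vocs)} VOCs): {', '.join(best_vocs)} — "
                f"LOO accuracy {best.metrics.accuracy:.3f}, "
                f"sensitivity {best.metrics.sensitivity:.3f}, "
                f"specificity {best.metrics.specificity:.3f}")

        # ---- stage distances ---------------------------------------------
        if "stage" in config.stages:
            current = "stage"
            vocs = best_vocs or list(train_tab.log2.columns[: config.pool_size])
            model = classify.fit_classifier(
                train_tab.log2[vocs], y_train, clf_cfg, positive_label="hcc")
            hcc_mask = (train_meta["group"] == "hcc").to_numpy()
            summ = stage.stage_distances(
                model, train_tab.log2[vocs].to_numpy()[hcc_mask],
                train_meta["bclc_stage"].to_numpy()[hcc_mask])
            summ.table.to_csv(outdir / "stage_distances.csv")
            report["stages"]["stage"] = {
                "means": summ.means.to_dict(), "spearman_rho": summ.spearman_rho}
            summary_lines.append(
                "stage mean distances: "
                + ", ".join(f"{s}={m:.3f}" for s, m in summ.means.items())
                + f" (Spearman rho {summ.spearman_rho:.2f})")

        # ---- treatment response ------------------------------------------
        if "response" in config.stages:
            current = "response"
            compounds = ([config.response_marker] if config.response_marker
                         else list(table.corrected.columns[:2]))
            deltas = stage.paired_deltas(table.corrected, meta, compounds)
            if len(deltas) and deltas["patient"].nunique() >= 2:
                resp = stage.response_analysis(deltas, cutoff=config.response_cutoff)
                deltas.to_csv(outdir / "response_deltas.csv", index=False)
                _write_json(outdir / "response_report.json", resp)
                report["stages"]["response"] = {
                    "n_patients": resp["n_patients"],
                    "responder_share_pct": resp["responder_share_pct"]}
                summary_lines.append(
                    f"response: {resp['n_responders']}/{resp['n_patients']} responders "
                    f"({resp['responder_share_pct']:.1f}%)")
            else:
                summary_lines.append("response: no paired samples, skipped")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    _finish(outdir, report, summary_lines)
    return report


def _finish(outdir: Path, report: dict, summary_lines: list[str]) -> None:
    hashes = {}
    for p in sorted(outdir.rglob("*.csv")):
        hashes[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    report["output_hashes"] = hashes
    _write_json(outdir / "manifest.json", report)
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
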