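"""End-to-end orchestration: simulate/ingest → cohort → analyses → report.

A single YAML (or dict) config drives every stage; one top-level seed fans
out to per-stage seeds by fixed offsets so a run is reproducible from one
knob.  Rerunning with the same config and seed reproduces every stage
output byte-for-byte (``report.json`` additionally carries wall-clock
timings and is the one file that may differ between reruns).

Outputs written to the run directory: ``sim.tsv``/``truth.json`` (when
simulating), ``ingest_report.json``, ``cohort.tsv``, ``exclusions.json``,
``summary.json``, ``qr_all.tsv``, ``qr_sustained.tsv``,
``profile_<concept>.tsv``, ``food_changes.tsv``, ``auc.json`` and
``report.json``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from querysignal.ingest import IngestError, LogSpan, read_query_log
from querysignal.lexicon import load_lexicon, packaged_lexicon_path
from querysignal.cohort import CohortConfig, build_cohort, cohort_summary, write_cohort
from querysignal.signal import WindowSpec, query_ratio_table, rank_concepts, temporal_profile
from querysignal.recipes import load_recipe_map, rank_food_changes
from querysignal.classify import build_feature_matrix, evaluate_auc
from querysignal.simulate import SimConfig, generate_logs

__all__ = ["RunReport", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger("querysignal")

_SEED_MOD = 2**31
_STAGE_SEED_OFFSETS = {"simulate": 0, "classify_anchor": 1009, "classify_folds": 2003}


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    seed: int
    config: dict
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, n_out: int, seconds: float, **extra) -> None:
        self.stages.append(
            {"stage": name, "n_in": n_in, "n_out": n_out, "seconds": round(seconds, 3), **extra}
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"seed": self.seed, "config": self.config, "stages": self.stages}, indent=1),
            encoding="utf-8",
        )


def load_pipeline_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + _STAGE_SEED_OFFSETS[stage]) % _SEED_MOD


def _parse_date(v) -> date:
    return v if isinstance(v, date) else date.fromisoformat(str(v))


def _qr_to_frame(results, cohort_label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "concept": [r.concept_id for r in results],
            "n_before": [r.n_before for r in results],
            "n_after": [r.n_after for r in results],
            "qr": [round(r.qr, 6) if r.qr is not None else "" for r in results],
            "cohort": cohort_label,
        }
    )


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> RunReport:
    """Run every configured stage and write outputs to the run directory.

    ``config`` is a dict or a YAML path.  Top-level keys: ``seed``,
    ``outdir``, ``simulate`` (SimConfig fields) or ``log`` + ``span``,
    ``cohort``, ``lexicons``, ``recipe_map``, ``analysis``, ``classify``.
    Missing input files raise :class:`IngestError` naming the stage.
    """
    if not isinstance(config, dict):
        config = load_pipeline_config(config)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    outdir = Path(outdir or cfg.get("outdir", "querysignal_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=seed, config=cfg)

    # --- stage: obtain a log -------------------------------------------------
    t = time.perf_counter()
    if "simulate" in cfg:
        sim_cfg = SimConfig.from_dict({**cfg["simulate"], "seed": _stage_seed(seed, "simulate")})
        log_path = outdir / "sim.tsv"
        df_sim, _truth = generate_logs(sim_cfg, log_path, outdir / "truth.json")
        span = sim_cfg.span
        report.add_stage("simulate", 0, len(df_sim), time.perf_counter() - t)
        logger.info("simulate: %d records", len(df_sim))
    elif "log" in cfg:
        log_path = Path(cfg["log"])
        if not log_path.exists():
            raise IngestError(f"stage ingest: missing input file {log_path}")
        span_cfg = cfg.get("span", {})
        span = LogSpan(
            _parse_date(span_cfg.get("start", "2017-01-01")),
            _parse_date(span_cfg.get("end", "2017-10-31")),
        )
        report.add_stage("obtain_log", 0, 0, time.perf_counter() - t)
    else:
        raise ValueError("config must contain either a 'simulate' section or a 'log' path")

    t = time.perf_counter()
    records, ingest_report = read_query_log(log_path, span)
    (outdir / "ingest_report.json").write_text(
        json.dumps(ingest_report.as_dict(), indent=1), encoding="utf-8"
    )
    report.add_stage(
        "ingest", ingest_report.n_lines, len(records), time.perf_counter() - t,
        rejected=ingest_report.n_rejected,
    )
    logger.info("ingest: %d/%d records accepted", len(records), ingest_report.n_lines)

    # --- stage: cohort -------------------------------------------------------
    t = time.perf_counter()
    ccfg_in = cfg.get("cohort", {})
    if "simulate" in cfg:
        default_ccfg = sim_cfg.cohort_config()
    else:
        default_ccfg = CohortConfig()
    ccfg = CohortConfig(
        index_start=_parse_date(ccfg_in.get("index_start", default_ccfg.index_start)),
        index_end=_parse_date(ccfg_in.get("index_end", default_ccfg.index_end)),
        washout_months=int(ccfg_in.get("washout_months", default_ccfg.washout_months)),
        history_cutoff=_parse_date(ccfg_in.get("history_cutoff", default_ccfg.history_cutoff)),
        window_days=int(ccfg_in.get("window_days", default_ccfg.window_days)),
    )
    members, exclusions = build_cohort(records, ccfg)
    write_cohort(members, outdir / "cohort.tsv")
    (outdir / "exclusions.json").write_text(
        json.dumps(exclusions.as_dict(), indent=1), encoding="utf-8"
    )
    summary = cohort_summary(members)
    (outdir / "summary.json").write_text(
        json.dumps(summary.as_dict(), indent=1), encoding="utf-8"
    )
    report.add_stage("cohort", len(records), len(members), time.perf_counter() - t,
                     exclusions=exclusions.as_dict())
    logger.info("cohort: %d members", len(members))

    # --- stage: lexicons -----------------------------------------------------
    lex_cfg = cfg.get("lexicons", {})
    sym_path = lex_cfg.get("symptoms") or packaged_lexicon_path("symptoms.tsv")
    cond_path = lex_cfg.get("conditions") or packaged_lexicon_path("conditions.tsv")
    for p in (sym_path, cond_path):
        if not Path(p).exists():
            raise IngestError(f"stage lexicon: missing input file {p}")
    sym_lex = load_lexicon(sym_path, "symptom")
    cond_lex = load_lexicon(cond_path, "condition")

    # --- stage: query ratios -------------------------------------------------
    t = time.perf_counter()
    acfg = cfg.get("analysis", {})
    window = WindowSpec(int(acfg.get("window_days", ccfg.window_days)))
    min_support = int(acfg.get("min_support", 10))
    top_k = int(acfg.get("top_k", 10))
    denominator = acfg.get("denominator", "after")
    sustained = [m for m in members if m.interest == "sustained"]
    frames = []
    for label, group in (("all", members), ("sustained", sustained)):
        for lex in (sym_lex, cond_lex):
            res = query_ratio_table(
                group, records, lex, window, min_support=min_support,
                denominator=denominator, span=span,
            )
            frames.append((label, rank_concepts(res, top_k)))
    qr_all = pd.concat(
        [_qr_to_frame(r, lbl) for lbl, r in frames if lbl == "all"], ignore_index=True
    )
    qr_sus = pd.concat(
        [_qr_to_frame(r, lbl) for lbl, r in frames if lbl == "sustained"], ignore_index=True
    )
    qr_all.to_csv(outdir / "qr_all.tsv", sep="\t", index=False)
    qr_sus.to_csv(outdir / "qr_sustained.tsv", sep="\t", index=False)
    report.add_stage("query_ratio", len(members), len(qr_all) + len(qr_sus), time.perf_counter() - t)

    # --- stage: temporal profiles -------------------------------------------
    t = time.perf_counter()
    n_prof = 0
    for concept in acfg.get("profile_concepts", []):
        lex = sym_lex if concept in sym_lex else cond_lex
        prof = temporal_profile(
            members, records, lex, concept, int(acfg.get("profile_range_days", 30))
        )
        out = prof.table.copy()
        out["ratio"] = out["ratio"].round(6)
        out.to_csv(outdir / f"profile_{concept.replace(' ', '_')}.tsv", sep="\t", index=False)
        n_prof += 1
    report.add_stage("profiles", len(members), n_prof, time.perf_counter() - t)

    # --- stage: dietary shifts ----------------------------------------------
    t = time.perf_counter()
    rm_path = cfg.get("recipe_map") or packaged_lexicon_path("recipes.tsv")
    if not Path(rm_path).exists():
        raise IngestError(f"stage recipes: missing input file {rm_path}")
    recipe_map = load_recipe_map(rm_path)
    changes = rank_food_changes(
        members, records, recipe_map, window, min_support=min_support, top_k=top_k, span=span
    )
    rows = []
    for direction, items in (
        ("increased", changes.foods_increased),
        ("decreased", changes.foods_decreased),
        ("increased", changes.ingredients_increased),
        ("decreased", changes.ingredients_decreased),
    ):
        for r in items:
            rows.append(
                {
                    "item_kind": r.item_kind,
                    "direction": direction,
                    "item": r.item_id,
                    "n_before": r.n_before,
                    "n_after": r.n_after,
                    "change_score": round(r.change_score, 6),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "food_changes.tsv", sep="\t", index=False)
    report.add_stage("recipes", len(members), len(rows), time.perf_counter() - t)

    # --- stage: classification ----------------------------------------------
    t = time.perf_counter()
    kcfg = cfg.get("classify", {})
    auc_out: dict = {"enabled": bool(kcfg.get("enabled", True))}
    if kcfg.get("enabled", True) and members:
        member_ids = {m.user_id for m in members}
        others = [u for u in records["user_id"].unique() if u not in member_ids]
        ratio = int(kcfg.get("comparison_ratio", 5))
        comparison = others[: ratio * len(members)]
        if comparison:
            fm = build_feature_matrix(
                members, comparison, records, sym_lex, cond_lex,
                seed=_stage_seed(seed, "classify_anchor"),
            )
            auc_out["n_target"] = len(members)
            auc_out["n_comparison"] = len(comparison)
            for spec in (kcfg.get("models") or ["linear_regression", "random_forest"]):
                res = evaluate_auc(
                    fm,
                    model_spec=spec,
                    n_trees=int(kcfg.get("trees", 50)),
                    folds=int(kcfg.get("folds", 10)),
                    seed=_stage_seed(seed, "classify_folds"),
                )
                auc_out[spec] = {
                    "mean_auc": round(res.mean_auc, 6),
                    "fold_aucs": [round(a, 6) for a in res.fold_aucs],
                }
        else:
            auc_out["skipped"] = "no comparison users available"
    (outdir / "auc.json").write_text(json.dumps(auc_out, indent=1), encoding="utf-8")
    report.add_stage("classify", len(members), 1, time.perf_counter() - t)

    report.write(outdir / "report.json")
    return report
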