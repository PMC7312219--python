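"""End-to-end orchestration: epochs -> features -> subset search -> reports.

A :class:`RunConfig` names exactly one input source (the synthetic
generator or an EDF recording plus an interval CSV), the feature method,
the selector and its budgets.  :func:`run_pipeline` computes the feature
table once (cached as CSV in the output directory), runs the selector
and writes ``pareto.csv``, ``history.csv``, ``classifier_usage.csv``, a
run log and a resolved-config snapshot sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edfio, moo, synth
from .evaluate import PortfolioSpec, evaluate_subset
from .features import FeatureTable, build_feature_table

__all__ = ["RunConfig", "run_pipeline", "compare_selectors"]

logger = logging.getLogger("eegselect")

SELECTORS = ("nsga2", "nsga3", "backward", "all_channels")


@dataclass
class RunConfig:
    """Everything needed to reproduce one channel-selection run."""

    outdir: str
    synth: synth.SynthConfig | None = None
    edf_path: str | None = None
    intervals_path: str | None = None
    method: str = "dwt"
    selector: str = "nsga2"
    ga: moo.GAConfig = field(default_factory=moo.GAConfig)
    portfolio: PortfolioSpec = field(default_factory=PortfolioSpec)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        sources = (self.synth is not None) + (self.edf_path is not None)
        if sources != 1:
            raise ValueError("exactly one input source (synth | edf_path) required")
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")
        if self.method not in ("emd", "dwt"):
            raise ValueError("method must be 'emd' or 'dwt'")

    def snapshot(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (frozenset, set, tuple)):
                return sorted(obj) if isinstance(obj, (frozenset, set)) else list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def source_key(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.snapshot().items() if k in ("synth", "edf_path", "intervals_path", "method")},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_epochs(config: RunConfig):
    if config.synth is not None:
        return synth.generate_epochs(config.synth)
    rec = edfio.load_recording(config.edf_path)
    if rec.fs > 128 and rec.fs % 128 == 0:
        rec = edfio.Recording(
            rec.channel_labels, 128.0,
            np.vstack([edfio.downsample(s, rec.fs, 128.0) for s in rec.signals]),
        )
    intervals = edfio.read_intervals(config.intervals_path)
    return edfio.epoch_and_label(rec, intervals, seed=config.seed)


def _feature_table(config: RunConfig, outdir: Path) -> FeatureTable:
    cache = outdir / f"features_{config.method}_{config.source_key()}.csv"
    if cache.exists():
        logger.info("feature cache hit: %s", cache)
        return FeatureTable.from_csv(cache, config.method)
    epochs = _load_epochs(config)
    table = build_feature_table(epochs, config.method)
    table.to_csv(cache)
    logger.info("feature table %s cached to %s", table.matrix.shape, cache)
    return table


def _make_evaluator(table: FeatureTable, config: RunConfig):
    def evaluator(subset):
        score = evaluate_subset(
            table, subset, portfolio=config.portfolio, k=config.cv_folds, seed=config.seed
        )
        logger.debug(
            "eval mask=%s winner=%s acc=%.4f folds=%d",
            "".join("1" if c in subset else "0" for c in range(table.n_channels)),
            score.classifier_id, score.accuracy, score.n_folds,
        )
        return score

    return evaluator


def _pareto_frame(entries, channel_labels) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append({
            "n_channels": e.no,
            "accuracy": e.acc,
            "sensitivity": e.sensitivity,
            "specificity": e.specificity,
            "classifier": e.classifier_id,
            "channel_labels": "|".join(channel_labels[c] for c in e.subset),
            "generation_found": e.generation_found,
        })
    return pd.DataFrame(rows)


def _usage_frame(winner_lists) -> pd.DataFrame:
    counts: dict[str, int] = {}
    total = 0
    for winners in winner_lists:
        for cid in winners:
            fam = cid.split("(")[0] if cid else "unknown"
            counts[fam] = counts.get(fam, 0) + 1
            total += 1
    rows = [
        {"classifier": fam, "wins": n, "percent": 100.0 * n / total if total else 0.0}
        for fam, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute one configured run; returns the Pareto table written to
    ``pareto.csv``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.DEBUG)
    try:
        (outdir / "config.json").write_text(json.dumps(config.snapshot(), indent=2))
        table = _feature_table(config, outdir)
        evaluator = _make_evaluator(table, config)
        c = table.n_channels

        history_rows: list[dict] = []
        winner_lists: list[list[str]] = []
        if config.selector in ("nsga2", "nsga3"):
            archive, history = moo.run_nsga(config.selector, c, evaluator, config.ga)
            entries = archive.entries
            for h in history:
                history_rows.append({
                    "generation": h["generation"],
                    "evaluations": h["evaluations"],
                    "best_per_no": json.dumps(h["best_per_no"]),
                })
                winner_lists.append(h["winners"])
        elif config.selector == "backward":
            path = moo.backward_elimination(c, evaluator)
            entries = sorted(path, key=lambda e: e.no)
            winner_lists.append([e.classifier_id for e in path])
        else:  # all_channels
            score = evaluator(tuple(range(c)))
            entries = [moo.ArchiveEntry(
                subset=tuple(range(c)), acc=score.accuracy, no=c,
                classifier_id=score.classifier_id,
                sensitivity=score.sensitivity, specificity=score.specificity,
            )]
            winner_lists.append([score.classifier_id])

        pareto = _pareto_frame(entries, table.channel_labels)
        pareto.to_csv(outdir / "pareto.csv", index=False)
        pd.DataFrame(history_rows).to_csv(outdir / "history.csv", index=False)
        _usage_frame(winner_lists).to_csv(outdir / "classifier_usage.csv", index=False)
        logger.info("selector=%s wrote %d pareto entries", config.selector, len(pareto))
        return pareto
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def compare_selectors(config: RunConfig, nsga_variant: str = "nsga2") -> pd.DataFrame:
    """Backward-elimination path vs NSGA archive, aligned by channel
    count; missing combinations stay blank."""
    outdir = Path(config.outdir)
    be_cfg = dataclasses.replace(config, selector="backward", outdir=str(outdir / "backward"))
    ga_cfg = dataclasses.replace(config, selector=nsga_variant, outdir=str(outdir / nsga_variant))
    be = run_pipeline(be_cfg)
    ga = run_pipeline(ga_cfg)
    merged = pd.merge(
        be[["n_channels", "accuracy"]].rename(columns={"accuracy": "backward"}),
        ga[["n_channels", "accuracy"]].rename(columns={"accuracy": nsga_variant}),
        on="n_channels", how="outer",
    ).sort_values("n_channels").reset_index(drop=True)
    outdir.mkdir(parents=True, exist_ok=True)
    merged.to_csv(outdir / "comparison.csv", index=False)
    return merged
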