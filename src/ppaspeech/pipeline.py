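"""End-to-end orchestration: extract -> prepare -> model grid -> longitudinal.

A run is a pure function of its :class:`RunConfig` (paths + statistical
parameters + seeds): outputs land in a run directory as tidy CSVs next to a
config snapshot and a log.  The packaged demo simulates a four-group cohort
at the published group sizes and pushes it through every stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    GMV_BLOCK,
    PATIENT_GROUPS,
    STANDARD_LANGUAGE_BLOCK,
    generate_cohorts,
    generate_longitudinal,
    load_default_deltas,
    load_default_profiles,
)
from .features import FEATURE_NAMES, feature_table
from .longitudinal import trend_table
from .sfs import run_model_grid
from .stats import select_candidates
from .transcript import read_lexicon, read_transcript

logger = logging.getLogger("ppaspeech")

__all__ = ["RunConfig", "run_pipeline", "demo_config"]


@dataclass
class RunConfig:
    output_dir: str
    # exactly one input mode: simulation, or real transcripts + subjects
    simulate: bool = True
    n_per_group: dict[str, int] | None = None
    transcripts_dir: str | None = None
    lexicon_path: str | None = None
    subjects_csv: str | None = None
    # statistics
    alpha: float = 0.05
    r_threshold: float = 0.8
    max_k: int = 6
    ridge_strength: float = 1.0
    folds: int = 10
    bonferroni: str = "n_groups"
    seed: int = 0
    # stage toggles
    run_prepare: bool = True
    run_sfs: bool = True
    run_longitudinal: bool = True

    def validate(self) -> None:
        real = [self.transcripts_dir, self.subjects_csv]
        if self.simulate and any(real):
            raise ValueError("config must use simulation or real inputs, not both")
        if not self.simulate:
            if not (self.transcripts_dir and self.lexicon_path and self.subjects_csv):
                raise ValueError(
                    "real-input mode needs transcripts_dir, lexicon_path and subjects_csv"
                )
            for p in (self.transcripts_dir, self.lexicon_path, self.subjects_csv):
                if not Path(p).exists():
                    raise FileNotFoundError(p)


def demo_config(output_dir: str, seed: int = 1) -> RunConfig:
    """The packaged demo: simulated four-group cohort at published sizes."""
    return RunConfig(output_dir=output_dir, simulate=True, seed=seed)


def _build_table(cfg: RunConfig) -> pd.DataFrame:
    if cfg.simulate:
        return generate_cohorts(
            cfg.seed, n_per_group=cfg.n_per_group, include_auxiliary=True
        )
    lex = read_lexicon(cfg.lexicon_path)
    transcripts = [
        read_transcript(p) for p in sorted(Path(cfg.transcripts_dir).glob("*.json"))
    ]
    feats = feature_table(transcripts, lex).reset_index()
    subjects = pd.read_csv(cfg.subjects_csv)
    return feats.merge(subjects, on="subject_id", how="inner")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every enabled stage; returns the run directory.

    Outputs: ``features.csv``, ``candidates.csv``, ``sfs_models.csv``,
    ``mcnemar.csv``, ``longitudinal.csv``, ``run_config.yaml``, ``run.log``.
    Stage failures abort with the stage name; completed outputs stay on disk.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    snapshot = dataclasses.asdict(cfg)
    snapshot["ppaspeech_version"] = __version__
    (out / "run_config.yaml").write_text(yaml.safe_dump(snapshot, sort_keys=True))

    stage = "extract"
    try:
        t0 = time.perf_counter()
        table = _build_table(cfg)
        table.to_csv(out / "features.csv", index=False)
        logger.info("stage=extract n=%d dt=%.1fs", len(table), time.perf_counter() - t0)

        speech_vars = [v for v in FEATURE_NAMES if v in table.columns]
        # generated cohorts carry the per-word noun rate used by the profiles
        if "noun_rate_word" in table.columns and "noun_rate_word" not in speech_vars:
            speech_vars.append("noun_rate_word")
        gmv_vars = [v for v in GMV_BLOCK if v in table.columns]
        lang_vars = [v for v in STANDARD_LANGUAGE_BLOCK if v in table.columns]

        speech_keep, gmv_keep = speech_vars, gmv_vars
        if cfg.run_prepare:
            stage = "prepare"
            t0 = time.perf_counter()
            rows = []
            keep: dict[str, list[str]] = {}
            for block, variables in (("speech", speech_vars), ("gmv", gmv_vars)):
                if not variables:
                    keep[block] = []
                    continue
                cand = select_candidates(
                    table,
                    variables,
                    alpha=cfg.alpha,
                    r_threshold=cfg.r_threshold,
                    bonferroni=cfg.bonferroni,
                )
                keep[block] = cand.retained
                rows += [
                    {"block": block, "variable": v, "status": "retained", "reason": "",
                     "outliers_flagged": cand.outlier_audit.get(v, 0)}
                    for v in cand.retained
                ]
                rows += [
                    {"block": block, "variable": v, "status": "dropped", "reason": r,
                     "outliers_flagged": cand.outlier_audit.get(v, 0)}
                    for v, r in cand.dropped.items()
                ]
            pd.DataFrame(rows).to_csv(out / "candidates.csv", index=False)
            speech_keep, gmv_keep = keep["speech"], keep["gmv"]
            logger.info(
                "stage=prepare speech=%d gmv=%d dt=%.1fs",
                len(speech_keep), len(gmv_keep), time.perf_counter() - t0,
            )

        if cfg.run_sfs:
            stage = "sfs"
            t0 = time.perf_counter()
            blocks = {"speech": speech_keep}
            if lang_vars:
                blocks["standard_language"] = lang_vars
            if gmv_keep:
                blocks["gmv"] = gmv_keep
            grid = run_model_grid(
                table,
                blocks,
                max_k=cfg.max_k,
                ridge_strength=cfg.ridge_strength,
                folds=cfg.folds,
                seed=cfg.seed,
            )
            grid.summary().to_csv(out / "sfs_models.csv", index=False)
            grid.comparisons.to_csv(out / "mcnemar.csv", index=False)
            logger.info(
                "stage=sfs models=%d dt=%.1fs",
                len(grid.models), time.perf_counter() - t0,
            )

        if cfg.run_longitudinal:
            stage = "longitudinal"
            t0 = time.perf_counter()
            deltas = load_default_deltas()
            if cfg.simulate:
                profiles = load_default_profiles()
                base = table[table["group"].isin(PATIENT_GROUPS)]
                keep_rows = []
                for g in PATIENT_GROUPS:
                    sub = base[base["group"] == g]
                    n_fu = min(deltas.n_followup.get(g, len(sub)), len(sub))
                    keep_rows.append(sub.iloc[:n_fu])
                baseline = pd.concat(keep_rows, ignore_index=True)
                bounds = {
                    v: (s.min, s.max)
                    for v, s in profiles["nfvPPA"].variables.items()
                }
                follow = generate_longitudinal(
                    baseline, deltas, cfg.seed + 1, bounds=bounds
                )
                records = pd.concat([baseline, follow], ignore_index=True)
            else:
                records = table[table["visit"].isin([0, 1])]
            long_vars = [
                v for v in deltas.deltas["nfvPPA"] if v in records.columns
            ]
            tt = trend_table(records, long_vars, groups=list(PATIENT_GROUPS))
            tt.to_csv(out / "longitudinal.csv", index=False)
            logger.info(
                "stage=longitudinal vars=%d dt=%.1fs",
                len(long_vars), time.perf_counter() - t0,
            )
    except Exception:
        logger.exception("stage=%s failed", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}") from None
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
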