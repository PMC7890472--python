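"""End-to-end orchestration: simulate → preprocess+score → analyze.

A run is described by a :class:`RunConfig` (YAML on disk); unknown keys are
rejected.  ``run_pipeline`` executes the stages deterministically from the
config's seed and writes ``scores.csv``, ``judgements.csv``, ``report.json``
and a plain-text log into the output directory.  The report embeds the
package version and a hash of the canonical config, so a run can be
reproduced from its own artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coordination import HAND_MODES, score_table
from .dtw_engine import StepPattern, rj_step_pattern
from .errors import ConfigError, StatsError
from .sensor_io import write_session
from .stats import (
    ContingencyTable,
    bonferroni_alpha,
    chi_squared,
    code_judgements,
    fit_difficulty_model,
    fit_suspicion_model,
    mixed_anova_3x3,
)
from .synthetic_dyads import CouplingSpec, simulate_study

logger = logging.getLogger("dyadwarp.pipeline")

_CONFIG_FIELDS = {
    "seed": 0,
    "design": "exp1",
    "n_dyads": 43,
    "duration_s": 30.0,
    "kappa_by_task": None,
    "judgement_accuracy_by_task": None,
    "valid_range": (-500.0, 500.0),
    "target_rate_hz": 5.0,
    "zscore_scale": 1000,
    "max_empty_bin_fraction": 0.10,
    "pattern": "rj6c",
    "hand_mode": "same_label",
    "analyses": ("difficulty", "suspicion", "judgements"),
    "out_dir": "dyadwarp_run",
}

_VALID_ANALYSES = ("difficulty", "suspicion", "judgements", "anova")


@dataclasses.dataclass
class RunConfig:
    """Schema-validated pipeline configuration."""

    seed: int = 0
    design: str = "exp1"
    n_dyads: int = 43
    duration_s: float = 30.0
    kappa_by_task: Optional[dict] = None
    judgement_accuracy_by_task: Optional[dict] = None
    valid_range: tuple = (-500.0, 500.0)
    target_rate_hz: float = 5.0
    zscore_scale: int = 1000
    max_empty_bin_fraction: float = 0.10
    pattern: str = "rj6c"
    hand_mode: str = "same_label"
    analyses: tuple = ("difficulty", "suspicion", "judgements")
    out_dir: str = "dyadwarp_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(_CONFIG_FIELDS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**{k: d[k] for k in d})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.design not in ("exp1", "exp2"):
            raise ConfigError(f"design must be 'exp1' or 'exp2', got {self.design!r}")
        if self.hand_mode not in HAND_MODES:
            raise ConfigError(f"unknown hand_mode {self.hand_mode!r}")
        if self.n_dyads < 2:
            raise ConfigError("n_dyads must be >= 2")
        for a in self.analyses:
            if a not in _VALID_ANALYSES:
                raise ConfigError(f"unknown analysis {a!r}; valid: {_VALID_ANALYSES}")
        parse_pattern(self.pattern)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["valid_range"] = list(self.valid_range)
        d["analyses"] = list(self.analyses)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def parse_pattern(spec: str) -> StepPattern:
    """Parse a step-pattern id like ``rj6c`` or ``rj2d-s``."""
    s = spec.lower()
    if not s.startswith("rj") or len(s) < 4:
        raise ConfigError(f"cannot parse step pattern {spec!r}; expected e.g. 'rj6c'")
    smoothed = s.endswith("-s")
    core = s[2:-2] if smoothed else s[2:]
    try:
        ptype = int(core[:-1])
    except ValueError:
        raise ConfigError(f"cannot parse step pattern {spec!r}") from None
    return rj_step_pattern(ptype, core[-1], smoothed)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    for key in ("valid_range", "analyses"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig.from_dict(raw)


def judgement_analyses(judgements: pd.DataFrame) -> dict:
    """Detection-accuracy contingency analyses from a judgements table."""
    j = judgements.copy()
    j["coded"] = code_judgements(j)
    out = {}
    lies = j[j["veracity"] == "lie"]
    lie_tasks = sorted(lies["task"].unique())
    if len(lie_tasks) >= 2:
        counts = tuple(
            (
                int(((lies["task"] == t) & (lies["coded"] == "correct")).sum()),
                int(((lies["task"] == t) & (lies["coded"] == "incorrect")).sum()),
            )
            for t in lie_tasks
        )
        try:
            res = chi_squared(ContingencyTable(row_labels=tuple(lie_tasks), counts=counts))
        except StatsError as exc:
            logger.warning("lies-by-task chi-squared skipped: %s", exc)
        else:
            out["lies_by_task"] = {
                "formula": "pearson_chi2_no_correction",
                "rows": lie_tasks,
                "chi2": res.chi2, "df": res.df, "p": res.p, "phi": res.effect, "n": res.n,
            }
    counts_tvl = tuple(
        (
            int(((j["veracity"] == v) & (j["coded"] == "correct")).sum()),
            int(((j["veracity"] == v) & (j["coded"] == "incorrect")).sum()),
        )
        for v in ("truth", "lie")
    )
    if all(sum(row) for row in counts_tvl):
        try:
            res = chi_squared(ContingencyTable(row_labels=("truth", "lie"), counts=counts_tvl))
        except StatsError as exc:
            logger.warning("truths-vs-lies chi-squared skipped: %s", exc)
        else:
            out["truths_vs_lies"] = {
                "formula": "pearson_chi2_no_correction",
                "chi2": res.chi2, "df": res.df, "p": res.p, "phi": res.effect, "n": res.n,
            }
    return out


def _model_report(fit) -> dict:
    rep = {
        "formula": "mixedlm_random_intercept_reml",
        "F": fit.F, "df_num": fit.df_num, "df_den": fit.df_den, "p": fit.p,
        "slope": fit.slope, "slope_se": fit.slope_se, "slope_t": fit.slope_t,
        "slope_df": fit.slope_df, "slope_p": fit.slope_p,
        "effect_r": fit.effect_r,
        "random_intercept_var": fit.random_intercept_var,
        "residual_var": fit.residual_var,
        "singular": fit.singular,
        "n_obs": fit.n_obs, "n_dyads": fit.n_groups,
    }
    if fit.contrasts:
        rep["contrasts"] = [
            {
                "pair": list(c.pair), "t": c.t, "df": c.df, "p": c.p,
                "cohens_d": c.d, "bonferroni_alpha": c.corrected_alpha,
            }
            for c in fit.contrasts
        ]
    return rep


def analyze(
    scores: pd.DataFrame,
    judgements: Optional[pd.DataFrame] = None,
    analyses=("difficulty", "suspicion", "judgements"),
) -> dict:
    """Run the selected statistical analyses and return a report dict."""
    report: dict = {}
    if "difficulty" in analyses:
        report["difficulty_model"] = _model_report(fit_difficulty_model(scores))
    if "suspicion" in analyses and judgements is not None:
        joined = scores.merge(
            judgements[["dyad_id", "task", "suspicion"]], on=["dyad_id", "task"]
        )
        try:
            report["suspicion_model"] = _model_report(fit_suspicion_model(joined))
        except StatsError as exc:
            logger.warning("suspicion model skipped: %s", exc)
    if "anova" in analyses:
        try:
            aov = mixed_anova_3x3(scores)
            report["mixed_anova"] = {
                "formula": "mixed_design_anova_partial_eta_sq",
                "table": aov.to_dict(orient="records"),
            }
        except StatsError as exc:
            logger.warning("mixed ANOVA skipped: %s", exc)
    if "judgements" in analyses and judgements is not None:
        report["judgements"] = judgement_analyses(judgements)
        report["bonferroni"] = {
            "formula": "family_alpha_over_k",
            "alpha_k3": bonferroni_alpha(0.05, 3),
            "alpha_k2": bonferroni_alpha(0.05, 2),
        }
    return report


def run_pipeline(config: RunConfig, write_sessions: bool = False) -> dict:
    """Execute simulate → score → analyze; returns the report dict.

    Deterministic given (config, seed).  Artifacts are written under
    ``config.out_dir``; with ``write_sessions`` the raw session CSVs are
    emitted as well.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dyadwarp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("run start: config hash %s", config.config_hash)
        spec = CouplingSpec(duration_s=config.duration_s)
        sessions, judgements, truth = simulate_study(
            n_dyads=config.n_dyads,
            design=config.design,
            kappa_by_task=config.kappa_by_task,
            judgement_accuracy_by_task=config.judgement_accuracy_by_task,
            seed=config.seed,
            spec=spec,
        )
        if write_sessions:
            for s in sessions:
                write_session(s, out_dir / "sessions" / s.dyad_id)
            truth.kappa.to_csv(out_dir / "ground_truth_kappa.csv", index=False)
        pattern = parse_pattern(config.pattern)
        scores = score_table(
            sessions,
            pattern=pattern,
            hand_mode=config.hand_mode,
            valid_range=tuple(config.valid_range),
        )
        float_cols = scores.select_dtypes("number").columns
        scores[float_cols] = scores[float_cols].round(6)
        scores.to_csv(out_dir / "scores.csv", index=False)
        judgements.to_csv(out_dir / "judgements.csv", index=False)
        analyses = tuple(config.analyses)
        if config.design == "exp2" and "anova" not in analyses:
            analyses = analyses + ("anova",)
        report = {
            "package": "dyadwarp",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "inputs": {"scores": "scores.csv", "judgements": "judgements.csv"},
            "results": analyze(scores, judgements, analyses),
        }
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("run complete")
        return report
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
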