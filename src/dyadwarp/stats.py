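"""Statistical layer: judgement coding, contingency analyses, mixed models.

Covers the study's analyses of coordination scores and veracity judgements:

* coding 7-point truthfulness ratings into correct/incorrect detections
  (5–7 correct for truths, 1–3 correct for lies, 4 always incorrect);
* Pearson χ² contingency analyses (no continuity correction) with the
  Φ / Cramér's V effect size ``sqrt(χ² / (n · min(r−1, c−1)))``;
* linear mixed-effects models of coordination with a per-dyad random
  intercept: an omnibus test over task levels, a linear-trend test over the
  empirically ordered difficulty coding (easy lie < truth < difficult lie <
  very difficult lie, coded 1–4), pairwise paired-t contrasts with a
  Bonferroni-corrected α, and a model with a continuous predictor
  (interviewer suspicion);
* the 3 (attention instruction) × 3 (task) mixed-design ANOVA with partial
  η² effect sizes.

Denominator degrees of freedom for the mixed-model Wald F use the
containment rule ``n_obs − n_dyads − rank(X)``; the effect size r for a
trend test is ``sqrt(t² / (t² + df))``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import StatsError

logger = logging.getLogger("dyadwarp.stats")

__all__ = [
    "JudgementRecord",
    "ContingencyTable",
    "DifficultyCoding",
    "ChiSquareResult",
    "ContrastResult",
    "MixedModelFit",
    "code_judgement",
    "code_judgements",
    "chi_squared",
    "bonferroni_alpha",
    "fit_difficulty_model",
    "fit_suspicion_model",
    "mixed_anova_3x3",
]


@dataclass(frozen=True)
class JudgementRecord:
    """One interviewer veracity judgement on the 7-point truthfulness scale."""

    dyad_id: str
    task: str
    veracity: str  # "truth" or "lie"
    rating: int    # 1 ("not at all" truthful) .. 7 ("very much")

    def __post_init__(self) -> None:
        if self.veracity not in ("truth", "lie"):
            raise StatsError(f"veracity must be 'truth' or 'lie', got {self.veracity!r}")
        if not 1 <= int(self.rating) <= 7:
            raise StatsError(f"rating must be in 1..7, got {self.rating}")


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of correct/incorrect detections by group."""

    row_labels: Tuple[str, ...]
    counts: Tuple[Tuple[int, ...], ...]
    col_labels: Tuple[str, ...] = ("correct", "incorrect")

    @property
    def n(self) -> int:
        return int(np.sum(self.counts))

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] != len(self.row_labels) or arr.shape[1] != len(self.col_labels):
            raise StatsError("counts shape does not match labels")
        if np.any(arr < 0):
            raise StatsError("negative cell count")


@dataclass(frozen=True)
class DifficultyCoding:
    """Ordered task levels with strictly increasing numeric codes.

    The order is the one fixed by the difficulty manipulation check:
    the easy (concealment) lie is experienced as easier than the truth.
    """

    levels: Tuple[str, ...] = ("easy_lie", "truth", "difficult_lie", "very_difficult_lie")
    codes: Tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.codes):
            raise StatsError("levels and codes differ in length")
        if not all(a < b for a, b in zip(self.codes, self.codes[1:])):
            raise StatsError("codes must be strictly increasing")

    def code(self, task: str) -> float:
        try:
            return self.codes[self.levels.index(task)]
        except ValueError:
            raise StatsError(f"task {task!r} not in difficulty coding") from None


def code_judgement(rec: JudgementRecord) -> str:
    """'correct' iff rating 5–7 for a truth or 1–3 for a lie; 4 is incorrect."""
    r = int(rec.rating)
    if rec.veracity == "truth":
        return "correct" if r >= 5 else "incorrect"
    return "correct" if r <= 3 else "incorrect"


def code_judgements(df: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`code_judgement` over a judgements table."""
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            code_judgement(
                JudgementRecord(
                    dyad_id=str(getattr(rec, "dyad_id", "")),
                    task=str(getattr(rec, "task", "")),
                    veracity=rec.veracity,
                    rating=rec.rating,
                )
            )
        )
    return pd.Series(out, index=df.index, name="coded")


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    effect: float  # Phi / Cramér's V
    n: int


def chi_squared(table: ContingencyTable) -> ChiSquareResult:
    """Pearson χ² without continuity correction, with Φ / Cramér's V.

    The effect size is non-negative by definition; any direction must be
    read off the table itself.
    """
    arr = np.asarray(table.counts, dtype=float)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise StatsError("zero marginal in contingency table")
    chi2, p, df, expected = sps.chi2_contingency(arr, correction=False)
    if np.any(expected <= 0):
        raise StatsError("expected count of zero")
    n = table.n
    k = min(arr.shape[0] - 1, arr.shape[1] - 1)
    effect = float(np.sqrt(chi2 / (n * k)))
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p), effect=effect, n=n)


def bonferroni_alpha(family_alpha: float, k: int) -> float:
    """Bonferroni-corrected per-test α, reported rounded to 3 decimals."""
    if k < 1:
        raise StatsError("k must be >= 1")
    if not 0.0 < family_alpha < 1.0:
        raise StatsError("family_alpha must be in (0, 1)")
    return round(family_alpha / k, 3)


@dataclass(frozen=True)
class ContrastResult:
    pair: Tuple[str, str]
    t: float
    df: int
    p: float
    d: float            # Cohen's d = mean(diff) / SD(diff)
    corrected_alpha: float
    n_pairs: int


@dataclass
class MixedModelFit:
    """Random-intercept mixed model of coordination.

    ``F``/``df_num``/``df_den`` is the omnibus Wald test over the fixed
    predictor(s); ``slope`` the linear-trend (or continuous-predictor)
    estimate with ``effect_r = sqrt(t²/(t²+df))`` from the trend t-test.
    """

    fixed_effects: Dict[str, float]
    random_intercept_var: float
    residual_var: float
    F: float
    df_num: int
    df_den: int
    p: float
    slope: float
    slope_se: float
    slope_t: float
    slope_df: int
    slope_p: float
    effect_r: float
    contrasts: List[ContrastResult] = field(default_factory=list)
    singular: bool = False
    n_obs: int = 0
    n_groups: int = 0


def _fit_mixedlm(endog, exog, groups):
    """REML random-intercept fit; returns (result, singular_flag)."""
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM(endog, exog, groups=groups)
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:
            raise StatsError(f"mixed model could not be fitted: {exc}") from exc
        for w in caught:
            if "singular" in str(w.message).lower() or "converge" in str(w.message).lower():
                singular = True
    if float(np.squeeze(res.cov_re)) < 1e-10:
        singular = True
    return res, singular


def _wald_F(res, idx: Sequence[int], df_den: int) -> Tuple[float, int, float]:
    beta = np.asarray(res.fe_params)[list(idx)]
    V = np.asarray(res.cov_params())[np.ix_(list(idx), list(idx))]
    q = len(idx)
    F = float(beta @ np.linalg.solve(V, beta) / q)
    p = float(sps.f.sf(F, q, df_den))
    return F, q, p


def _paired_contrasts(
    data: pd.DataFrame,
    pairs: Sequence[Tuple[str, str]],
    dv: str,
    family_alpha: float = 0.05,
) -> List[ContrastResult]:
    alpha = bonferroni_alpha(family_alpha, len(pairs)) if pairs else family_alpha
    out = []
    wide = data.pivot_table(index="dyad_id", columns="task", values=dv)
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            continue
        diff = (wide[a] - wide[b]).dropna().to_numpy()
        if diff.size < 2:
            continue
        sd = diff.std(ddof=1)
        t = float(diff.mean() / (sd / np.sqrt(diff.size)))
        df = diff.size - 1
        p = float(2 * sps.t.sf(abs(t), df))
        d = float(diff.mean() / sd)
        out.append(
            ContrastResult(
                pair=(a, b), t=t, df=df, p=p, d=d, corrected_alpha=alpha, n_pairs=diff.size
            )
        )
    return out


def _prepare_scores(scores: pd.DataFrame, dv: str) -> pd.DataFrame:
    data = scores[["dyad_id", "task", dv]].dropna().copy()
    if data.empty:
        raise StatsError("empty score table")
    counts = data.groupby("dyad_id")["task"].nunique()
    if (counts >= 2).sum() < 2:
        raise StatsError("need >= 2 tasks per dyad for >= 2 dyads")
    return data


def fit_difficulty_model(
    scores: pd.DataFrame,
    coding: DifficultyCoding = DifficultyCoding(),
    dv: str = "aggregate",
    contrast_pairs: Optional[Sequence[Tuple[str, str]]] = None,
    family_alpha: float = 0.05,
) -> MixedModelFit:
    """Mixed model of coordination on task difficulty (random dyad intercept).

    Reports the omnibus Wald F over the task levels, the linear-trend
    estimate over the numeric difficulty coding, and paired-t contrasts
    (default: each lie against the truth) with Bonferroni-corrected α.
    """
    data = _prepare_scores(scores, dv)
    tasks = [t for t in coding.levels if t in set(data["task"])]
    if len(tasks) < 2:
        raise StatsError("fewer than two task levels present")
    if data[dv].nunique() == 1:
        # degenerate: constant outcome carries no effect at all
        n, g = len(data), data["dyad_id"].nunique()
        return MixedModelFit(
            fixed_effects={"intercept": float(data[dv].iloc[0])},
            random_intercept_var=0.0,
            residual_var=0.0,
            F=0.0, df_num=len(tasks) - 1, df_den=max(n - g - len(tasks), 1), p=1.0,
            slope=0.0, slope_se=0.0, slope_t=0.0,
            slope_df=max(n - g - 2, 1), slope_p=1.0, effect_r=0.0,
            contrasts=[], singular=True, n_obs=n, n_groups=g,
        )
    y = data[dv].to_numpy(dtype=float)
    groups = data["dyad_id"].to_numpy()
    n, g = len(data), data["dyad_id"].nunique()

    # omnibus over task levels (treatment dummies against the first level)
    dummies = np.column_stack(
        [(data["task"] == t).to_numpy(dtype=float) for t in tasks[1:]]
    )
    X_om = np.column_stack([np.ones(n), dummies])
    res_om, sing1 = _fit_mixedlm(y, X_om, groups)
    df_den_om = n - g - X_om.shape[1]
    if df_den_om <= 0:
        raise StatsError("not enough observations for the omnibus test")
    F, q, pF = _wald_F(res_om, range(1, X_om.shape[1]), df_den_om)

    # linear trend over the difficulty coding
    code = data["task"].map(coding.code).to_numpy(dtype=float)
    X_tr = np.column_stack([np.ones(n), code])
    res_tr, sing2 = _fit_mixedlm(y, X_tr, groups)
    slope = float(res_tr.fe_params[1])
    se = float(np.sqrt(np.asarray(res_tr.cov_params())[1, 1]))
    df_tr = n - g - 2
    t = slope / se
    p_tr = float(2 * sps.t.sf(abs(t), df_tr))
    r = float(np.sqrt(t * t / (t * t + df_tr)))

    if contrast_pairs is None:
        contrast_pairs = [(t_, "truth") for t_ in tasks if t_ != "truth"]
    contrasts = _paired_contrasts(data, contrast_pairs, dv, family_alpha)

    fixed = {"intercept": float(res_om.fe_params[0])}
    for t_, b in zip(tasks[1:], res_om.fe_params[1:]):
        fixed[t_] = float(b)
    return MixedModelFit(
        fixed_effects=fixed,
        random_intercept_var=float(np.squeeze(res_om.cov_re)),
        residual_var=float(res_om.scale),
        F=F,
        df_num=q,
        df_den=df_den_om,
        p=pF,
        slope=slope,
        slope_se=se,
        slope_t=float(t),
        slope_df=df_tr,
        slope_p=p_tr,
        effect_r=r,
        contrasts=contrasts,
        singular=sing1 or sing2,
        n_obs=n,
        n_groups=g,
    )


def fit_suspicion_model(
    scores: pd.DataFrame,
    predictor: str = "suspicion",
    dv: str = "aggregate",
) -> MixedModelFit:
    """Mixed model of coordination on a continuous predictor (suspicion)."""
    cols = ["dyad_id", "task", dv, predictor]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise StatsError(f"missing column(s) {missing} in joined score table")
    data = scores[cols].dropna().copy()
    if data.empty:
        raise StatsError("empty join of scores and ratings")
    y = data[dv].to_numpy(dtype=float)
    x = data[predictor].to_numpy(dtype=float)
    groups = data["dyad_id"].to_numpy()
    n, g = len(data), data["dyad_id"].nunique()
    X = np.column_stack([np.ones(n), x])
    res, singular = _fit_mixedlm(y, X, groups)
    df_den = n - g - 2
    if df_den <= 0:
        raise StatsError("not enough observations")
    slope = float(res.fe_params[1])
    se = float(np.sqrt(np.asarray(res.cov_params())[1, 1]))
    t = slope / se
    p = float(2 * sps.t.sf(abs(t), df_den))
    r = float(np.sqrt(t * t / (t * t + df_den)))
    return MixedModelFit(
        fixed_effects={"intercept": float(res.fe_params[0]), predictor: slope},
        random_intercept_var=float(np.squeeze(res.cov_re)),
        residual_var=float(res.scale),
        F=float(t * t),
        df_num=1,
        df_den=df_den,
        p=p,
        slope=slope,
        slope_se=se,
        slope_t=float(t),
        slope_df=df_den,
        slope_p=p,
        effect_r=r,
        singular=singular,
        n_obs=n,
        n_groups=g,
    )


def mixed_anova_3x3(
    scores: pd.DataFrame,
    dv: str = "aggregate",
    within: str = "task",
    between: str = "attention_instruction",
    subject: str = "dyad_id",
) -> pd.DataFrame:
    """Mixed-design ANOVA (between: instruction, within: task).

    Classical decomposition with partial η² = SS_effect/(SS_effect+SS_error).
    Dyads missing a task level are removed listwise with a warning.  Returns
    a table with rows for the between effect, the within effect and their
    interaction.
    """
    data = scores[[subject, within, between, dv]].dropna().copy()
    if data.empty:
        raise StatsError("empty score table")
    n_levels = data[within].nunique()
    complete = data.groupby(subject)[within].nunique() == n_levels
    dropped = complete.index[~complete]
    if len(dropped):
        logger.warning(
            "mixed ANOVA: listwise deletion of %d dyad(s) missing a task level", len(dropped)
        )
        data = data[data[subject].isin(complete.index[complete])]
    if data[subject].nunique() < 3 or data[between].nunique() < 2:
        raise StatsError("too few complete dyads or between-groups for the ANOVA")
    if data[dv].nunique() == 1:
        b, w = data[between].nunique(), data[within].nunique()
        ns = data[subject].nunique()
        rows = [
            ("instruction", b - 1, ns - b),
            ("task", w - 1, (ns - b) * (w - 1)),
            ("interaction", (b - 1) * (w - 1), (ns - b) * (w - 1)),
        ]
        return pd.DataFrame(
            [
                {"effect": e, "F": 0.0, "df_num": d1, "df_den": d2, "p": 1.0, "np2": 0.0}
                for e, d1, d2 in rows
            ]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=data, dv=dv, within=within, between=between, subject=subject
        )
    out = aov.rename(
        columns={"Source": "effect", "DF1": "df_num", "DF2": "df_den",
                 "p_unc": "p", "p-unc": "p"}
    )[["effect", "F", "df_num", "df_den", "p", "np2"]]
    out["effect"] = out["effect"].replace(
        {between: "instruction", within: "task", "Interaction": "interaction"}
    )
    return out.reset_index(drop=True)
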