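"""Downstream analyses: incremental value of the metabolic score over BMI,
composite cognitive scores, and regressions of cognition on latent scores.

The model comparison asks whether the metabolic latent score explains
variance in total gray matter volume beyond age, sex and BMI: Model 1
regresses head-size-adjusted total GMV on age + sex + BMI, Model 2 adds the
metabolic score, and the two are compared with the nested-model F-test
F = ((RSS1 - RSS2)/1) / (RSS2/(N - k2 - 1)).

Cognitive composites follow the CERAD convention of averaging standardized
test components per domain:

    executive  = [z(animal fluency) + z(S-words) - z((TMT_B - TMT_A)/TMT_A)] / 3
    memory     = [z(learned) + z(recalled) + z(recognized)] / 3
    processing = -z(TMT_A)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "NestedModelComparison",
    "CompositeScores",
    "total_gmv",
    "compare_models",
    "composite_scores",
    "cognition_regressions",
]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def total_gmv(
    raw_voxel_matrix: np.ndarray,
    voxel_volume_mm3: float,
    tiv: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-subject total in-mask GMV (ml), optionally TIV-adjusted.

    The total is the sum of the unstandardized masked voxel values times the
    voxel volume; head-size adjustment residualizes the total on TIV
    (intercept included), with the grand mean added back so the adjusted
    values stay on the ml scale.
    """
    raw = np.asarray(raw_voxel_matrix, dtype=float)
    if (raw < -1e-6).any():
        import warnings

        warnings.warn("negative voxel values present in GMV matrix", stacklevel=2)
    totals_ml = raw.sum(axis=1) * voxel_volume_mm3 / 1000.0
    out = {"total_ml": totals_ml}
    if tiv is not None:
        design = np.column_stack([np.ones(len(totals_ml)), np.asarray(tiv, float)])
        beta, *_ = np.linalg.lstsq(design, totals_ml, rcond=None)
        out["total_ml_adj"] = totals_ml - design @ beta + totals_ml.mean()
    return out


@dataclass
class NestedModelComparison:
    model1: pd.DataFrame  # term, beta_std, t, p
    model2: pd.DataFrame
    adj_r2_model1: float
    adj_r2_model2: float
    rss1: float
    rss2: float
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int


def _standardized_ols(y: np.ndarray, terms: dict[str, np.ndarray]) -> tuple[pd.DataFrame, float, float]:
    """OLS with z-scored outcome and continuous predictors; binary 0/1
    predictors enter as-is. Returns (coef table, adjusted R^2, RSS of the
    unstandardized fit)."""
    yz = _zscore(y)
    cols = {}
    for name, vals in terms.items():
        vals = np.asarray(vals, dtype=float)
        is_binary = set(np.unique(vals)) <= {0.0, 1.0}
        cols[name] = vals if is_binary else _zscore(vals)
    design = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(yz, design).fit()
    table = pd.DataFrame(
        {
            "term": list(terms),
            "beta_std": [fit.params[t] for t in terms],
            "t": [fit.tvalues[t] for t in terms],
            "p": [fit.pvalues[t] for t in terms],
        }
    )
    # RSS on the raw outcome scale for the F comparison
    design_raw = sm.add_constant(
        pd.DataFrame({k: np.asarray(v, float) for k, v in terms.items()})
    )
    fit_raw = sm.OLS(np.asarray(y, float), design_raw).fit()
    return table, float(fit.rsquared_adj), float(fit_raw.ssr)


def compare_models(
    total_gmv_adj: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    bmi: np.ndarray,
    metabolic_score: np.ndarray,
) -> NestedModelComparison:
    """Nested comparison: (age, sex, BMI) vs (age, sex, BMI, metabolic score)."""
    y = np.asarray(total_gmv_adj, dtype=float)
    n = len(y)
    if np.isnan(y).any():
        raise ValueError("missing values in outcome")
    corr_bm = np.corrcoef(bmi, metabolic_score)[0, 1]
    if abs(corr_bm) > 0.999:
        import warnings

        warnings.warn(
            "BMI and metabolic score nearly collinear; comparison ill-conditioned",
            stacklevel=2,
        )
    t1, r2a1, rss1 = _standardized_ols(y, {"age": age, "sex": sex, "bmi": bmi})
    t2, r2a2, rss2 = _standardized_ols(
        y, {"age": age, "sex": sex, "bmi": bmi, "metabolic_score": metabolic_score}
    )
    k2 = 4
    df_den = n - k2 - 1
    f_stat = ((rss1 - rss2) / 1.0) / (rss2 / df_den)
    p = float(stats.f.sf(f_stat, 1, df_den))
    return NestedModelComparison(
        model1=t1,
        model2=t2,
        adj_r2_model1=r2a1,
        adj_r2_model2=r2a2,
        rss1=rss1,
        rss2=rss2,
        f_statistic=float(f_stat),
        p_value=p,
        df_num=1,
        df_den=df_den,
    )


@dataclass
class CompositeScores:
    executive: np.ndarray
    memory: np.ndarray
    processing_speed: np.ndarray
    components: pd.DataFrame

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "executive": self.executive,
                "memory": self.memory,
                "processing_speed": self.processing_speed,
            }
        )


def composite_scores(table: pd.DataFrame) -> CompositeScores:
    """Per-domain composite z-scores from the raw test scores.

    All z-scores are computed over the analysis sample passed in. The /3 in
    the executive and memory formulas divides the whole three-term sum, so
    each composite is the mean of its standardized components.
    """
    required = [
        "animal_fluency", "s_words", "tmt_a", "tmt_b",
        "word_list_learned", "word_list_recalled", "word_list_recognized",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(f"missing cognitive columns: {missing}")
    tmt_a = table["tmt_a"].to_numpy(dtype=float)
    tmt_b = table["tmt_b"].to_numpy(dtype=float)
    if (tmt_a <= 0).any():
        raise ValueError("TMT part A must be positive")
    z = {
        "animal_fluency": _zscore(table["animal_fluency"]),
        "s_words": _zscore(table["s_words"]),
        "tmt_ratio": _zscore((tmt_b - tmt_a) / tmt_a),
        "tmt_a": _zscore(tmt_a),
        "learned": _zscore(table["word_list_learned"]),
        "recalled": _zscore(table["word_list_recalled"]),
        "recognized": _zscore(table["word_list_recognized"]),
    }
    executive = (z["animal_fluency"] + z["s_words"] - z["tmt_ratio"]) / 3.0
    memory = (z["learned"] + z["recalled"] + z["recognized"]) / 3.0
    processing = -z["tmt_a"]
    return CompositeScores(
        executive=executive,
        memory=memory,
        processing_speed=processing,
        components=pd.DataFrame(z),
    )


def cognition_regressions(
    composites: CompositeScores,
    metabolic_score: np.ndarray,
    brain_score: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-domain OLS of each composite on both latent scores jointly.

    Returns one row per (domain, predictor) with standardized beta, t, p.
    Optional covariates (e.g. age, sex) can be added; default none, since
    the latent scores are already confound-residualized upstream.
    """
    ms = np.asarray(metabolic_score, dtype=float)
    bs = np.asarray(brain_score, dtype=float)
    if len(ms) < 10:
        raise ValueError("need at least 10 complete cases")
    rows = []
    for domain, y in (
        ("executive", composites.executive),
        ("memory", composites.memory),
        ("processing_speed", composites.processing_speed),
    ):
        terms = {"metabolic_score": ms, "brain_score": bs}
        if covariates:
            terms.update(covariates)
        table, _, _ = _standardized_ols(np.asarray(y, float), terms)
        table.insert(0, "domain", domain)
        rows.append(table)
    return pd.concat(rows, ignore_index=True)
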