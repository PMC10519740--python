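"""Questionnaire scoring, classification cut-offs and covariate adjustment.

Implements the scoring rules for the questionnaires used throughout the
pipeline: the Insomnia Severity Index (ISI), the SDQ emotional-symptoms
(anxiety) subscale, the Children's Anxiety Sensitivity Index (CASI), the
Short Mood and Feelings Questionnaire (SMFQ) and the Psychotic-Like
Symptoms Questionnaire (PLSQ), plus GCSE mean grade as a precomputed
numeric.  Also provides the insomnia cut-off (ISI total > 8), the
short-sleep cut-off (< 7 h/night), Cronbach's alpha, and the
residualize-and-standardize transform applied to polygenic scores and to
phenotypes before twin-model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ScaleDefinition",
    "SCALES",
    "score_scale",
    "classify_insomnia",
    "classify_sleep_duration",
    "cronbach_alpha",
    "residualize_standardize",
    "ScaleValidationError",
]

SHORT = "short"
NORMAL_LONG = "normal_long"

#: ISI totals strictly greater than this value indicate risk of insomnia.
ISI_CUTOFF = 8

#: Nightly sleep below this many hours counts as short sleep for adolescents.
SHORT_SLEEP_HOURS = 7.0


class ScaleValidationError(ValueError):
    """Raised when item responses violate a scale's response bounds."""


@dataclass(frozen=True)
class ScaleDefinition:
    """Static description of a summed questionnaire scale.

    Parameters
    ----------
    name : str
        Identifier used in column names and error messages.
    n_items : int
        Number of items in the scale.
    item_min, item_max : int
        Bounds on a single item response.  For scales with heterogeneous
        item ranges (PLSQ) these are the loosest bounds.
    total_min, total_max : int
        Theoretical range of the total score.
    min_responses : int
        Minimum number of answered items required to compute a total.
        Defaults to 1; the shipped definitions require complete responses
        for every scale except the PLSQ, whose documented rule is at
        least five responses.
    """

    name: str
    n_items: int
    item_min: int
    item_max: int
    total_min: int
    total_max: int
    min_responses: int = 1

    def __post_init__(self) -> None:
        if not (self.total_min <= self.total_max):
            raise ValueError(f"{self.name}: total_min > total_max")
        if not (1 <= self.min_responses <= self.n_items):
            raise ValueError(f"{self.name}: min_responses must be in [1, n_items]")


SCALES: dict[str, ScaleDefinition] = {
    "isi": ScaleDefinition("isi", n_items=7, item_min=0, item_max=4,
                           total_min=0, total_max=28, min_responses=7),
    "anxiety": ScaleDefinition("anxiety", n_items=5, item_min=0, item_max=2,
                               total_min=0, total_max=10, min_responses=5),
    "anxiety_sensitivity": ScaleDefinition("anxiety_sensitivity", n_items=18,
                                           item_min=0, item_max=2,
                                           total_min=0, total_max=36,
                                           min_responses=18),
    "depression": ScaleDefinition("depression", n_items=13, item_min=0, item_max=2,
                                  total_min=0, total_max=26, min_responses=13),
    # PLSQ items have heterogeneous response formats; the theoretical total
    # range (0-91) is narrower than n_items * item_max.
    "psychotic": ScaleDefinition("psychotic", n_items=29, item_min=0, item_max=4,
                                 total_min=0, total_max=91, min_responses=5),
}


def score_scale(items, scale: ScaleDefinition) -> float:
    """Total score for one respondent, prorating partial responses.

    ``items`` is a sequence of length ``scale.n_items``; missing responses
    are NaN/None.  Returns NaN when fewer than ``scale.min_responses``
    items were answered.  Complete responses return the plain sum; partial
    responses at or above the minimum are prorated as
    ``mean(answered) * n_items`` and clamped to the theoretical range.
    """
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in items], dtype=float
    )
    if arr.shape != (scale.n_items,):
        raise ScaleValidationError(
            f"{scale.name}: expected {scale.n_items} items, got {arr.size}"
        )
    answered = ~np.isnan(arr)
    bad = answered & ((arr < scale.item_min) | (arr > scale.item_max))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ScaleValidationError(
            f"{scale.name}: item {idx} value {arr[idx]} outside "
            f"[{scale.item_min}, {scale.item_max}]"
        )
    n_ans = int(answered.sum())
    if n_ans < scale.min_responses:
        return float("nan")
    if n_ans == scale.n_items:
        return float(arr.sum())
    total = float(arr[answered].mean() * scale.n_items)
    return float(min(max(total, scale.total_min), scale.total_max))


def classify_insomnia(isi_total: float) -> bool:
    """True when the ISI total exceeds the risk cut-off (total > 8)."""
    if not (SCALES["isi"].total_min <= isi_total <= SCALES["isi"].total_max):
        raise ScaleValidationError(f"ISI total {isi_total} outside [0, 28]")
    return isi_total > ISI_CUTOFF


def classify_sleep_duration(hours: float) -> str:
    """'short' for under 7 h/night, 'normal_long' for 7 h or more."""
    if hours < 0:
        raise ScaleValidationError(f"negative sleep hours: {hours}")
    return SHORT if hours < SHORT_SLEEP_HOURS else NORMAL_LONG


def cronbach_alpha(item_matrix) -> float:
    """Internal-consistency alpha = (k/(k-1)) * (1 - sum(var_i)/var_total).

    Complete-case: rows with any missing item are dropped.  Requires at
    least two items and three complete rows; raises ``ValueError`` when
    the total-score variance is zero (alpha undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 items")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 3:
        raise ValueError("need >= 3 complete rows")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def residualize_standardize(values, covariates=None) -> np.ndarray:
    """OLS-residualize ``values`` on ``covariates`` and z-standardize.

    Mirrors the adjustment contract used for polygenic scores (regress
    out nuisance covariates, then scale to mean 0, SD 1) and for
    phenotypes before twin-model fitting (age and sex regressed out).
    Missing values (in ``values`` or any covariate) propagate as NaN;
    the regression and the standardization use complete cases only.

    Raises ``ValueError`` naming the offending columns when the design
    matrix (with intercept) is rank-deficient, and when the residuals
    have zero variance.
    """
    y = np.asarray(values, dtype=float)
    if covariates is None:
        X = np.empty((y.size, 0))
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if X.shape[0] != y.size:
        raise ValueError("values and covariates have different lengths")

    ok = ~np.isnan(y)
    if X.shape[1]:
        ok &= ~np.isnan(X).any(axis=1)
    if ok.sum() < X.shape[1] + 2:
        raise ValueError("too few complete cases")

    Xc = X[ok]
    # constant columns duplicate the intercept and carry no information
    keep = [j for j in range(Xc.shape[1]) if np.ptp(Xc[:, j]) > 0]
    design = sm.add_constant(Xc[:, keep], has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns by checking rank contribution
        collinear = []
        for j in range(1, design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(keep[j - 1])
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {collinear}")

    resid = sm.OLS(y[ok], design).fit().resid
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd <= 1e-10 * max(np.std(y[ok]), 1.0):
        raise ValueError("residuals have zero variance; standardization undefined")

    out = np.full(y.size, np.nan)
    out[ok] = (resid - resid.mean()) / sd
    return out


def score_individuals(df: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-individual score table from a pair-per-row cohort frame.

    Stacks twin 1 / twin 2 columns (suffixes ``1``/``2``) into one row per
    individual, attaches insomnia and sleep-duration classifications, and
    keeps pair-level columns (zygosity, age, polygenic scores).
    """
    rows = []
    trait_cols = ["isi", "anx", "anxsens", "dep", "gcse", "psyc"]
    for twin in (1, 2):
        sub = pd.DataFrame({
            "pair_id": df["pair_id"],
            "twin": twin,
            "zyg": df["zyg"],
            "age": df["age"],
            "sex": df[f"sex{twin}"],
            "sleep_hours": df[f"hours{twin}"],
        })
        for c in trait_cols:
            col = f"{c}{twin}"
            sub[c] = df[col] if col in df else np.nan
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    out["sleep_label"] = [
        classify_sleep_duration(h) if np.isfinite(h) else None
        for h in out["sleep_hours"]
    ]
    out["insomnia_flag"] = [
        classify_insomnia(t) if np.isfinite(t) else None for t in out["isi"]
    ]
    return out.sort_values(["pair_id", "twin"]).reset_index(drop=True)
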