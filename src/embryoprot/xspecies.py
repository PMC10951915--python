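"""Cross-species developmental stage correspondence.

Ortholog-matched, sum-to-one stage profiles from two species are compared at
every pair of stages under Pearson, Spearman, or cosine similarity, giving a
stage-by-stage similarity matrix.  The best-matching partner stage per row
traces the inferred developmental correspondence; one minus the best
similarity per stage is the divergence curve.  The hourglass statistic
operationalizes the visual pattern of such curves:

    H = mean divergence(mid) - mean( mean divergence(early),
                                     mean divergence(late) )

H > 0 means divergence peaks at mid-development (inverse hourglass, the
pattern reported for chordate proteomes at gastrulation/neurulation); H < 0
means a mid-developmental conservation bottleneck (classic hourglass).
Significance comes from permuting the early/mid/late class labels across
stages; curves whose statistic is not significant are labeled flat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import ProfileSet
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from .io import ExpressionMatrix
from .orthology import OrthologMap

logger = logging.getLogger(__name__)

METRICS = ("pearson", "spearman", "cosine")
STAGE_CLASSES = ("early", "mid", "late")

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERMUTATIONS = 1000


@dataclass
class StageSimilarityMatrix:
    """All-pairs stage similarity between two ordered stage series.

    Rows are species-A stages, columns species-B stages; undefined entries
    (zero-variance stage vectors under rank/linear correlation) are NaN.
    """

    values: pd.DataFrame
    metric: str
    n_orthologs: int

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise InvalidParameterError(f"unknown metric {self.metric!r}")


@dataclass
class DivergenceCurve:
    """Per species-A stage: best-matching partner stage and 1 - similarity."""

    values: pd.DataFrame  # columns: best_match_stage, best_similarity, divergence
    metric: str


@dataclass
class HourglassResult:
    """Shape classification of a divergence curve.

    ``direction`` is the sign-implied shape (inverse_hourglass when the
    statistic is positive, hourglass when negative); ``label`` additionally
    requires permutation significance and falls back to flat otherwise.
    """

    label: str
    direction: str
    statistic: float
    p_value: float
    n_permutations: int


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every stage column onto the common (mean-sorted) distribution.

    Each column's values are replaced by the across-column mean of the sorted
    values at the corresponding rank; a group of k ties within a column gets
    the mean of the k reference values its ranks span.  Entities with missing
    values are dropped first with a logged count; a single-column matrix is
    returned unchanged with a warning.
    """
    df = matrix.values.dropna(axis=0)
    n_dropped = len(matrix.values) - len(df)
    if n_dropped:
        logger.info("quantile_normalize: dropped %d entities with missing values",
                    n_dropped)
    if df.shape[1] < 2:
        logger.warning("quantile_normalize: single column; returned unchanged")
        return ExpressionMatrix(df, modality=matrix.modality,
                                species=matrix.species)
    X = df.to_numpy(dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)

    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranked = col[order]
        assigned = np.empty_like(ranked)
        i = 0
        while i < len(ranked):
            k = i
            while k + 1 < len(ranked) and ranked[k + 1] == ranked[i]:
                k += 1
            assigned[i:k + 1] = reference[i:k + 1].mean()
            i = k + 1
        out[order, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns),
        modality=matrix.modality, species=matrix.species,
    )


def _similarity(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return math.nan
        return float(stats.pearsonr(x, y).statistic)
    if metric == "spearman":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return math.nan
        return float(stats.spearmanr(x, y).statistic)
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return math.nan
        return float(x @ y / (nx * ny))
    raise InvalidParameterError(f"unknown metric {metric!r}")


def stage_similarity(
    profiles_a: ProfileSet,
    profiles_b: ProfileSet,
    omap: OrthologMap,
    metric: str = "pearson",
    min_orthologs: int = 10,
) -> StageSimilarityMatrix:
    """Similarity between every species-A stage and every species-B stage.

    Entry (s, t) compares the vector of species-A ortholog values at stage s
    with the species-B values at stage t, over all mapped pairs present and
    non-missing in both.  Spearman uses average ranks for ties.
    """
    if metric not in METRICS:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    pairs = [
        (a, b) for a, b in zip(omap.pairs["id_a"], omap.pairs["id_b"])
        if a in profiles_a.values.index and b in profiles_b.values.index
    ]
    if len(pairs) < min_orthologs:
        raise InsufficientDataError(
            f"only {len(pairs)} mapped ortholog(s) with profiles; "
            f"need >= {min_orthologs}"
        )
    A = profiles_a.values.loc[[a for a, _ in pairs]].to_numpy(dtype=float)
    B = profiles_b.values.loc[[b for _, b in pairs]].to_numpy(dtype=float)
    stages_a = profiles_a.stage_labels
    stages_b = profiles_b.stage_labels

    sim = np.full((len(stages_a), len(stages_b)), np.nan)
    for i in range(len(stages_a)):
        for j in range(len(stages_b)):
            x, y = A[:, i], B[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3:
                sim[i, j] = _similarity(x[ok], y[ok], metric)
    return StageSimilarityMatrix(
        values=pd.DataFrame(sim, index=stages_a, columns=stages_b),
        metric=metric,
        n_orthologs=len(pairs),
    )


def best_match_trace(sim: StageSimilarityMatrix) -> pd.DataFrame:
    """Best-matching species-B stage per species-A stage.

    Ties are broken toward the earlier species-B stage and logged.  Returns a
    DataFrame with columns best_match_stage, best_similarity indexed by
    species-A stage.
    """
    rows = []
    for stage, row in sim.values.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            raise InvalidInputError(
                f"stage {stage!r} has no defined similarity to any partner stage"
            )
        best = np.nanmax(vals)
        hits = np.flatnonzero(vals == best)
        if len(hits) > 1:
            logger.info(
                "stage %s: %d partner stages tie at similarity %.6g; "
                "kept the earliest", stage, len(hits), best,
            )
        rows.append((stage, sim.values.columns[hits[0]], float(best)))
    return pd.DataFrame(
        rows, columns=["stage", "best_match_stage", "best_similarity"],
    ).set_index("stage")


def divergence_curve(sim: StageSimilarityMatrix) -> DivergenceCurve:
    """Per species-A stage, divergence = 1 - best similarity over B stages.

    For Pearson/Spearman this can exceed 1 (similarity can be negative); the
    value is reported as-is rather than clamped.
    """
    trace = best_match_trace(sim)
    out = trace.copy()
    out["divergence"] = 1.0 - out["best_similarity"]
    return DivergenceCurve(values=out, metric=sim.metric)


def hourglass_classify(
    curve: DivergenceCurve,
    classes: dict[str, str],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> HourglassResult:
    """Classify a divergence curve as hourglass / inverse hourglass / flat.

    The statistic contrasts mean mid-stage divergence against the average of
    the early and late means.  The null distribution permutes the class
    labels across stages (two-sided on |H|, with the add-one correction);
    curves that do not reach ``alpha`` are labeled flat, otherwise the label
    follows the sign of the statistic.
    """
    div = curve.values["divergence"]
    stages = list(div.index)
    if len(stages) < 3:
        raise InvalidParameterError("need >= 3 stages to classify a curve")
    missing = [s for s in stages if s not in classes]
    if missing:
        raise InvalidParameterError(f"stages without a class: {missing}")
    labels = np.array([classes[s] for s in stages])
    for cls in STAGE_CLASSES:
        if not np.any(labels == cls):
            raise InvalidParameterError(f"stage class {cls!r} is empty")
    vals = div.to_numpy(dtype=float)

    def _stat(lbl: np.ndarray) -> float:
        mid = vals[lbl == "mid"].mean()
        early = vals[lbl == "early"].mean()
        late = vals[lbl == "late"].mean()
        return mid - 0.5 * (early + late)

    h_obs = _stat(labels)
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_permutations):
        n_extreme += abs(_stat(rng.permutation(labels))) >= abs(h_obs)
    p_value = (1 + n_extreme) / (n_permutations + 1)

    direction = "inverse_hourglass" if h_obs > 0 else (
        "hourglass" if h_obs < 0 else "flat"
    )
    label = direction if (p_value < alpha and h_obs != 0) else "flat"
    return HourglassResult(
        label=label,
        direction=direction,
        statistic=float(h_obs),
        p_value=float(p_value),
        n_permutations=n_permutations,
    )


def shared_expression_fraction(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    omap: OrthologMap,
    classes_a: dict[str, str],
    classes_b: dict[str, str],
) -> pd.Series:
    """Fraction of orthologs expressed in both species, per stage class.

    ``expr_a``/``expr_b`` are boolean expressed calls (gene x stage).  An
    ortholog counts as expressed in a class when it is expressed at one or
    more stages of that class; the fraction is over all mapped orthologs.
    """
    out = {}
    for cls in STAGE_CLASSES:
        stages_a = [s for s in expr_a.columns if classes_a.get(s) == cls]
        stages_b = [s for s in expr_b.columns if classes_b.get(s) == cls]
        if not stages_a or not stages_b:
            raise InvalidParameterError(
                f"stage class {cls!r} is empty in one species"
            )
        n_common = 0
        n_total = 0
        for a, b in zip(omap.pairs["id_a"], omap.pairs["id_b"]):
            n_total += 1
            in_a = a in expr_a.index and bool(expr_a.loc[a, stages_a].any())
            in_b = b in expr_b.index and bool(expr_b.loc[b, stages_b].any())
            if in_a and in_b:
                n_common += 1
        if n_total == 0:
            raise InsufficientDataError("empty ortholog map")
        out[cls] = n_common / n_total
    return pd.Series(out, name="shared_expression_fraction")
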