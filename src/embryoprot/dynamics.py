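"""Within-species temporal profile analytics.

Relative abundance time courses (multiplexed proteomics or TPM matrices over
an ordered stage series) are median-normalized across stages, scaled so each
entity's profile sums to one, clustered by k-means with many random restarts,
and compared between RNA and protein by per-gene correlation over the shared
stages.  Stage-transition ranking orders entities by the magnitude of their
log2 change between consecutive stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from .io import ExpressionMatrix
from .orthology import OrthologMap

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("raw", "median_normalized", "sum_to_one", "log2")

DEFAULT_K_WITHIN = 8       # within-species profile clusters
DEFAULT_K_COCLUSTER = 5    # cross-species ortholog co-clusters
DEFAULT_RESTARTS = 100


@dataclass
class ProfileSet:
    """Per-entity profiles over an ordered stage series with a normalization tag."""

    values: pd.DataFrame
    normalization: str = "raw"
    species: str = ""

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise InvalidParameterError(
                f"unknown normalization {self.normalization!r}"
            )
        if self.normalization == "sum_to_one":
            sums = self.values.sum(axis=1, skipna=True)
            if not np.allclose(sums.to_numpy(), 1.0, atol=1e-9):
                raise InvalidInputError("sum_to_one profiles must sum to 1")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterModel:
    """k-means result: assignments, centroids, and the best total within-SS."""

    k: int
    assignments: pd.Series      # entity -> cluster id (0-based, size-ordered)
    centroids: pd.DataFrame     # one row per cluster
    total_within_ss: float
    n_restarts: int
    seed: int

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each stage column so its median equals the grand median.

    The grand median is the median over all non-missing values of the input.
    """
    df = matrix.values
    col_medians = df.median(axis=0, skipna=True)
    zero_cols = col_medians[~(col_medians > 0)]
    if len(zero_cols):
        raise InvalidInputError(
            f"stage {zero_cols.index[0]!r} has a non-positive median; "
            "cannot median-normalize"
        )
    grand = float(np.nanmedian(df.to_numpy(dtype=float)))
    factors = grand / col_medians
    return ExpressionMatrix(
        df * factors, modality=matrix.modality, species=matrix.species,
    )


def sum_to_one(matrix: ExpressionMatrix | ProfileSet) -> ProfileSet:
    """Scale each entity's profile to sum to 1 over its non-missing stages.

    Entities whose profile is entirely zero (or missing) are dropped with a
    logged count.  Idempotent: applying it twice gives the same profiles.
    """
    df = matrix.values
    species = getattr(matrix, "species", "")
    sums = df.sum(axis=1, skipna=True)
    keep = sums > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("sum_to_one: dropped %d all-zero profile(s)", n_dropped)
    out = df[keep].div(sums[keep], axis=0)
    return ProfileSet(out, normalization="sum_to_one", species=species)


def rna_protein_correlation(
    rna: ProfileSet,
    protein: ProfileSet,
    pairing: dict[str, str] | None = None,
    min_stages: int = 3,
    method: str = "pearson",
) -> tuple[pd.DataFrame, float]:
    """Per-gene correlation between RNA and protein dynamics.

    ``pairing`` maps RNA ids to protein ids; by default entities are paired by
    identical id.  Correlations use the stages shared by both sets (by label)
    and the non-missing positions of each pair; pairs with fewer than
    ``min_stages`` usable stages or zero variance on either side are excluded
    with a logged count.  Returns the per-pair records and the median r.
    """
    shared_stages = [s for s in rna.stage_labels if s in set(protein.stage_labels)]
    if len(shared_stages) < min_stages:
        raise InsufficientDataError(
            f"only {len(shared_stages)} shared stage(s); need >= {min_stages}"
        )
    if pairing is None:
        pairing = {i: i for i in rna.entity_ids if i in protein.values.index}

    records = []
    n_excluded = 0
    r_vals = rna.values[shared_stages]
    p_vals = protein.values[shared_stages]
    for rna_id, prot_id in pairing.items():
        if rna_id not in r_vals.index or prot_id not in p_vals.index:
            n_excluded += 1
            continue
        x = r_vals.loc[rna_id].to_numpy(dtype=float)
        y = p_vals.loc[prot_id].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_stages:
            n_excluded += 1
            continue
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            n_excluded += 1  # zero variance: r undefined
            continue
        if method == "pearson":
            r = float(stats.pearsonr(xs, ys).statistic)
        elif method == "spearman":
            r = float(stats.spearmanr(xs, ys).statistic)
        elif method == "cosine":
            r = float(xs @ ys / (np.linalg.norm(xs) * np.linalg.norm(ys)))
        else:
            raise InvalidParameterError(f"unknown method {method!r}")
        records.append((rna_id, prot_id, r, int(ok.sum())))
    if n_excluded:
        logger.info("rna_protein_correlation: excluded %d pair(s)", n_excluded)
    df = pd.DataFrame(records, columns=["rna_id", "protein_id", "r", "n_stages_used"])
    if df.empty:
        raise InsufficientDataError("no usable RNA-protein pairs")
    return df, float(df["r"].median())


def kmeans_profiles(
    profiles: ProfileSet,
    k: int,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> ClusterModel:
    """Euclidean k-means on complete profiles, best of ``n_restarts`` starts.

    Entities with any missing stage are excluded (and counted) before
    clustering.  Each restart initializes centroids from k randomly chosen
    entities; the restart with the lowest total within-cluster sum of squares
    wins.  Cluster ids are relabeled by descending cluster size (ties broken
    by the first-occurring member entity), so the labeling is deterministic
    for a given seed.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    df = profiles.values
    complete = df.dropna(axis=0)
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("kmeans_profiles: excluded %d incomplete profile(s)", n_dropped)
    if k > len(complete):
        raise InvalidParameterError(
            f"k={k} exceeds the {len(complete)} complete profiles"
        )
    X = complete.to_numpy(dtype=float)
    km = KMeans(
        n_clusters=k, init="random", n_init=n_restarts,
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
        algorithm="lloyd",
    ).fit(X)
    raw_labels = km.labels_

    # relabel by descending size; break ties by first-occurring entity
    order_key = {}
    for lbl in range(k):
        members = np.flatnonzero(raw_labels == lbl)
        first = int(members[0]) if members.size else len(complete)
        order_key[lbl] = (-members.size, first)
    ranked = sorted(range(k), key=lambda lbl: order_key[lbl])
    remap = {old: new for new, old in enumerate(ranked)}
    labels = np.array([remap[l] for l in raw_labels])
    centroids = pd.DataFrame(
        km.cluster_centers_[ranked], columns=complete.columns,
        index=pd.RangeIndex(k, name="cluster"),
    )
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=complete.index, name="cluster"),
        centroids=centroids,
        total_within_ss=float(km.inertia_),
        n_restarts=n_restarts,
        seed=seed,
    )


def co_cluster_orthologs(
    profiles_a: ProfileSet,
    profiles_b: ProfileSet,
    omap: OrthologMap,
    k: int = DEFAULT_K_COCLUSTER,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> ClusterModel:
    """Cluster ortholog pairs on the concatenation of their two profiles.

    Both profile sets must be sum-to-one normalized so the two species
    contribute comparably.  Pairs missing in either set are excluded with a
    logged count; the cluster assignment is indexed by the species-A id.
    """
    if len(omap) == 0:
        raise InvalidParameterError("empty ortholog map")
    for ps, name in ((profiles_a, "A"), (profiles_b, "B")):
        if ps.normalization != "sum_to_one":
            raise InvalidParameterError(
                f"species-{name} profiles must be sum_to_one normalized"
            )
    rows = []
    index = []
    n_missing = 0
    for a, b in zip(omap.pairs["id_a"], omap.pairs["id_b"]):
        if a not in profiles_a.values.index or b not in profiles_b.values.index:
            n_missing += 1
            continue
        rows.append(
            np.concatenate([
                profiles_a.values.loc[a].to_numpy(dtype=float),
                profiles_b.values.loc[b].to_numpy(dtype=float),
            ])
        )
        index.append(a)
    if n_missing:
        logger.info("co_cluster_orthologs: %d pair(s) missing a profile", n_missing)
    if not rows:
        raise InsufficientDataError("no ortholog pair has profiles in both sets")
    cols = (
        [f"A:{s}" for s in profiles_a.stage_labels]
        + [f"B:{s}" for s in profiles_b.stage_labels]
    )
    concat = ProfileSet(
        pd.DataFrame(rows, index=index, columns=cols), normalization="raw",
    )
    return kmeans_profiles(concat, k=k, n_restarts=n_restarts, seed=seed)


def fold_change(
    matrix: ExpressionMatrix | ProfileSet,
    numerator_stage: str,
    denominator_stage: str,
    pseudo: float = 0.0,
) -> pd.DataFrame:
    """Per-entity fold change (and log2) between two stages.

    The canonical use is larva over unfertilized egg, i.e. the relative
    abundance at hatching compared to the maternal starting point.
    """
    df = matrix.values
    for stage in (numerator_stage, denominator_stage):
        if stage not in df.columns:
            raise InvalidParameterError(f"unknown stage label {stage!r}")
    num = df[numerator_stage] + pseudo
    den = df[denominator_stage] + pseudo
    keep = (den > 0) & num.notna() & den.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fold_change: excluded %d entities with zero denominator",
                    n_dropped)
    fc = num[keep] / den[keep]
    return pd.DataFrame({"FC": fc, "log2FC": np.log2(fc)})


def stage_transition_ranking(
    profiles: ProfileSet | ExpressionMatrix,
    top_n: int | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Rank entities by |log2 ratio| across each consecutive stage pair.

    A pseudocount of half the smallest positive value in the matrix guards
    log ratios on zero-containing profiles.  Ties are broken by entity id.
    """
    df = profiles.values
    stages = list(df.columns)
    if len(stages) < 2:
        raise InvalidParameterError("need >= 2 stages to rank transitions")
    vals = df.to_numpy(dtype=float)
    positive = vals[np.isfinite(vals) & (vals > 0)]
    if positive.size == 0:
        raise InvalidParameterError("matrix has no positive values")
    eps = positive.min() * 0.5

    out: dict[tuple[str, str], pd.DataFrame] = {}
    for s, t in zip(stages, stages[1:]):
        ratio = np.log2((df[t] + eps) / (df[s] + eps))
        tbl = pd.DataFrame({
            "entity_id": df.index,
            "log2_ratio": ratio.to_numpy(),
            "abs_log2_ratio": np.abs(ratio.to_numpy()),
        })
        tbl = tbl.sort_values(
            ["abs_log2_ratio", "entity_id"], ascending=[False, True],
            kind="stable",
        ).reset_index(drop=True)
        if top_n is not None:
            tbl = tbl.head(top_n)
        out[(s, t)] = tbl
    return out


def aggregate_isoform_tpm(
    tx_matrix: ExpressionMatrix,
    tx_to_gene: dict[str, str],
) -> ExpressionMatrix:
    """Gene-level TPM as the per-stage sum of each gene's transcript TPMs."""
    if tx_matrix.modality != "rna_tpm":
        raise InvalidParameterError("expected an rna_tpm matrix")
    unmapped = [t for t in tx_matrix.entity_ids if t not in tx_to_gene]
    if unmapped:
        raise InvalidInputError(f"unmapped transcripts: {sorted(unmapped)[:10]}")
    genes = tx_matrix.values.index.to_series().map(tx_to_gene)
    agg = tx_matrix.values.groupby(genes, sort=True).sum(min_count=1)
    agg.index.name = "entity_id"
    return ExpressionMatrix(agg, modality="rna_tpm", species=tx_matrix.species)


def expressed_flags(
    tpm_matrix: ExpressionMatrix,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Boolean expressed call per (gene, stage): TPM >= threshold (inclusive).

    Missing values are not expressed.
    """
    if tpm_matrix.modality != "rna_tpm":
        raise InvalidParameterError("expected an rna_tpm matrix")
    df = tpm_matrix.values
    return (df >= threshold) & df.notna()
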