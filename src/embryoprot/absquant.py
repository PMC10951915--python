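"""Absolute protein concentration estimation from spike-in standards.

A staggered set of standards of known amounts is spiked into the lysate; the
measured MS1 signal is related to amount by a power law, i.e. a line in
log10-log10 space.  That line is fitted robustly with the Theil-Sen estimator
(slope = median of all pairwise slopes; intercept = median residual), signals
are inverted through the curve, and the resulting concentrations are rescaled
by one global factor so their molar sum matches the configured total protein
concentration of the egg (default 2 mM).  A low-concentration cutoff is then
applied.  Complex stoichiometry is assessed by comparing each detected
complex's log10-concentration distribution against the remaining proteome
(ANOVA followed by Tukey HSD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
)
from .io import AnnotationList, ComplexCatalog, ExpressionMatrix, SpikeInTable

logger = logging.getLogger(__name__)

#: Total molar protein concentration of the egg used for global scaling (nM).
DEFAULT_TOTAL_NM = 2e6  # 2 mM

#: Default low-concentration cutoff (nM); 0.01 uM as printed in the protocol.
DEFAULT_CUTOFF_NM = 10.0


@dataclass
class StandardCurve:
    """Robust log10-log10 fit of measured signal against known amount."""

    slope: float
    intercept: float
    n_points_used: int
    n_excluded_zero_signal: int = 0
    fit_space: str = "log10-log10"

    def signal_to_amount(self, signal: np.ndarray) -> np.ndarray:
        """Invert the curve: amount = 10 ** ((log10 signal - b) / m)."""
        if self.slope == 0:
            raise DegenerateFitError("standard curve slope is zero")
        return 10.0 ** ((np.log10(signal) - self.intercept) / self.slope)


@dataclass
class ConcentrationTable:
    """Estimated per-entity concentrations in nM with optional annotations."""

    concentrations: pd.Series  # entity_id -> nM
    is_tf: pd.Series | None = None
    is_sm: pd.Series | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.concentrations.to_numpy() <= 0).any():
            raise InvalidParameterError("concentrations must be > 0")

    def __len__(self) -> int:
        return len(self.concentrations)

    def to_frame(self) -> pd.DataFrame:
        df = self.concentrations.rename("concentration_nM").to_frame()
        if self.is_tf is not None:
            df["is_TF"] = self.is_tf.reindex(df.index, fill_value=False)
        if self.is_sm is not None:
            df["is_SM"] = self.is_sm.reindex(df.index, fill_value=False)
        return df


@dataclass
class StoichiometryResult:
    """Per-complex comparison against the whole-proteome distribution.

    ``p_value`` is the dispersion (variance-ratio) test of the subunits'
    log10-concentration scatter against the background; ``tukey_p`` is the
    Tukey-HSD-adjusted mean-location contrast of the complex against the
    background group.
    """

    per_complex: pd.DataFrame  # complex_id, n_detected_subunits, p_value, tukey_p
    anova_f: float | None = None
    anova_p: float | None = None
    subunit_values: dict[str, pd.Series] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.per_complex)

    def flagged(self, alpha: float = 0.01) -> pd.DataFrame:
        return self.per_complex[self.per_complex["p_value"] < alpha]


def fit_standard_curve(spikeins: SpikeInTable) -> StandardCurve:
    """Theil-Sen fit in (x = log10 known amount, y = log10 signal).

    Standards with zero signal (undetected) are excluded and counted.  The
    slope is the median of pairwise slopes over distinct-x pairs and the
    intercept is the median of ``y - slope * x``.
    """
    df = spikeins.standards
    usable = df[df["measured_signal"] > 0]
    n_zero = len(df) - len(usable)
    if len(usable) < 2:
        raise InsufficientDataError(
            f"need >= 2 standards with positive signal, have {len(usable)}"
        )
    x = np.log10(usable["known_amount"].to_numpy(dtype=float))
    y = np.log10(usable["measured_signal"].to_numpy(dtype=float))
    if np.unique(x).size < 2:
        raise DegenerateFitError("all standard amounts identical; slope undefined")
    # method="joint" gives intercept = median(y - slope * x)
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        n_points_used=len(usable),
        n_excluded_zero_signal=n_zero,
    )


def estimate_concentrations(
    curve: StandardCurve,
    signals: ExpressionMatrix,
    total_concentration_nM: float = DEFAULT_TOTAL_NM,
    cutoff_nM: float = DEFAULT_CUTOFF_NM,
    isoform_map: dict[str, str] | None = None,
    annotations: list[AnnotationList] | None = None,
) -> ConcentrationTable:
    """Convert single-stage MS1 signals to absolute concentrations.

    Per entity the raw concentration is the curve inversion of its signal;
    isoforms are collapsed to genes by summing signal before conversion when
    ``isoform_map`` is given.  All raw concentrations are rescaled by one
    global factor so their molar sum equals ``total_concentration_nM``;
    entities below ``cutoff_nM`` are removed after scaling.  The monotone
    transform preserves the concentration ordering of entities.
    """
    if curve.slope == 0:
        raise DegenerateFitError("standard curve slope is zero")
    if signals.n_stages != 1:
        raise InvalidParameterError(
            f"expected a single-stage signal matrix, got {signals.n_stages} stages"
        )
    if total_concentration_nM <= 0 or cutoff_nM < 0:
        raise InvalidParameterError("total must be > 0 and cutoff >= 0")

    col = signals.values.iloc[:, 0]
    usable = col[(col > 0) & col.notna()]
    n_dropped = len(col) - len(usable)
    if n_dropped:
        logger.info("dropped %d entities with zero/missing signal", n_dropped)
    if usable.empty:
        raise InsufficientDataError("no entities with positive signal")

    if isoform_map is not None:
        genes = usable.index.to_series().map(isoform_map)
        if genes.isna().any():
            missing = list(usable.index[genes.isna()])[:10]
            raise InvalidParameterError(f"isoforms without gene mapping: {missing}")
        usable = usable.groupby(genes).sum()

    raw = pd.Series(
        curve.signal_to_amount(usable.to_numpy(dtype=float)), index=usable.index,
    )
    factor = total_concentration_nM / raw.sum()
    scaled = raw * factor
    kept = scaled[scaled >= cutoff_nM]
    n_cut = len(scaled) - len(kept)
    if kept.empty:
        logger.warning("cutoff %.3g nM removed every entity", cutoff_nM)
        return ConcentrationTable(
            concentrations=pd.Series(dtype=float),
            provenance={"curve": curve, "scaling_factor": factor,
                        "n_below_cutoff": n_cut, "n_dropped_signal": n_dropped},
        )

    is_tf = is_sm = None
    if annotations:
        for ann in annotations:
            flags = pd.Series(kept.index.isin(ann.entity_ids), index=kept.index)
            if ann.category == "TF":
                is_tf = flags
            elif ann.category == "SM":
                is_sm = flags
    return ConcentrationTable(
        concentrations=kept,
        is_tf=is_tf,
        is_sm=is_sm,
        provenance={
            "curve": curve,
            "scaling_factor": factor,
            "n_below_cutoff": n_cut,
            "n_dropped_signal": n_dropped,
        },
    )


def median_concentration(
    table: ConcentrationTable,
    subset: AnnotationList | None = None,
) -> float:
    """Median concentration (nM), optionally over an annotated subset."""
    conc = table.concentrations
    if subset is not None:
        present = conc.index.intersection(subset.entity_ids)
        n_absent = len(subset.entity_ids) - len(present)
        if n_absent:
            logger.info(
                "%d %s id(s) absent from the concentration table",
                n_absent, subset.category,
            )
        conc = conc.loc[present]
    if conc.empty:
        raise InsufficientDataError("no entities to take a median over")
    return float(conc.median())


def complex_stoichiometry_test(
    table: ConcentrationTable,
    catalog: ComplexCatalog,
    alpha: float = 0.01,
    min_subunits: int = 3,
) -> StoichiometryResult:
    """Test whether complex subunits are tighter than the whole proteome.

    Complexes with at least ``min_subunits`` detected subunits form groups;
    all proteins outside every qualifying complex form the background group.
    Two complementary comparisons of log10 concentrations are computed:

    * ``p_value`` — a one-sided variance-ratio test of each complex's
      subunit dispersion against the background dispersion (small p means
      the subunits are significantly tighter, i.e. stoichiometric).  A
      mean-location contrast cannot detect tightness for complexes whose
      abundance sits near the proteome median, so this is the primary
      per-complex significance.
    * ``tukey_p`` — group ANOVA followed by Tukey HSD of each complex's
      mean against the background group, which flags complexes whose
      abundance level differs from the bulk proteome.
    """
    conc = table.concentrations
    qualifying: dict[str, pd.Series] = {}
    for cid in catalog.complexes:
        detected = conc.index.intersection(catalog.members(cid))
        if len(detected) >= min_subunits:
            qualifying[cid] = conc.loc[detected]
    if not qualifying:
        return StoichiometryResult(
            per_complex=pd.DataFrame(
                columns=["complex_id", "n_detected_subunits", "p_value", "tukey_p"]
            )
        )

    in_complex = set().union(*(s.index for s in qualifying.values()))
    background = conc.drop(index=list(in_complex))
    if background.empty:
        raise InsufficientDataError("no background proteins outside complexes")

    groups = [np.log10(background.to_numpy())]
    labels = ["__background__"] * len(background)
    for cid, vals in qualifying.items():
        groups.append(np.log10(vals.to_numpy()))
        labels.extend([cid] * len(vals))
    f_stat, anova_p = stats.f_oneway(*groups)

    values = np.concatenate(groups)
    tukey = pairwise_tukeyhsd(values, np.asarray(labels), alpha=alpha)
    res = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0],
    )
    # keep only each complex's comparison against the background group
    mask = (res["group1"] == "__background__") | (res["group2"] == "__background__")
    res = res[mask].copy()
    res["complex_id"] = res.apply(
        lambda r: r["group2"] if r["group1"] == "__background__" else r["group1"],
        axis=1,
    )
    tukey_p = dict(zip(res["complex_id"], res["p-adj"].astype(float)))

    # dispersion test: complex variance vs background variance (lower tail)
    bg_log = np.log10(background.to_numpy())
    bg_var = float(np.var(bg_log, ddof=1))
    bg_df = len(bg_log) - 1
    rows = []
    for cid, vals in qualifying.items():
        log_vals = np.log10(vals.to_numpy())
        ratio = float(np.var(log_vals, ddof=1)) / bg_var
        p_disp = float(stats.f.cdf(ratio, len(log_vals) - 1, bg_df))
        rows.append((cid, len(vals), p_disp, tukey_p[cid]))
    per_complex = pd.DataFrame(
        rows, columns=["complex_id", "n_detected_subunits", "p_value", "tukey_p"],
    ).sort_values("complex_id", kind="stable").reset_index(drop=True)
    return StoichiometryResult(
        per_complex=per_complex,
        anova_f=float(f_stat),
        anova_p=float(anova_p),
        subunit_values={c: np.log10(v) for c, v in qualifying.items()},
    )


def cumulative_abundance(values: pd.Series | np.ndarray) -> pd.DataFrame:
    """Cumulative percent of total abundance against descending rank."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.any(arr < 0):
        raise InvalidParameterError("values must be non-empty and non-negative")
    total = arr.sum()
    if total <= 0:
        raise InvalidParameterError("values sum to zero; curve undefined")
    ordered = np.sort(arr)[::-1]
    cum_pct = np.cumsum(ordered) / total * 100.0
    return pd.DataFrame({
        "rank": np.arange(1, arr.size + 1),
        "cumulative_percent": cum_pct,
    })
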