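"""Synthetic data generators with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and seed (one
``numpy.random.default_rng`` stream per call, no global state), so outputs are
bit-reproducible.  Abundance noise is log-normal (Gaussian in log10 space),
matching the multiplicative error of MS signal.  Latent temporal programs are
smooth positive curves (cubic spline through a few random control points over
normalized stage time) so that stage autocorrelation resembles real
developmental series rather than white noise.

Cross-species decorrelation is injected by mixing each ortholog's partner
profile with an independent program; the mixing weight follows a quadratic in
normalized stage index whose sign is set by the requested shape:

* ``inverse_hourglass`` — maximal decorrelation at mid stages,
* ``hourglass``        — maximal decorrelation at early/late stages,
* ``flat``             — uniform decorrelation across stages.

At ``effect_size = 0`` all three shapes degenerate to identical, fully
conserved programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .absquant import ConcentrationTable
from .errors import InvalidInputError, InvalidParameterError
from .io import (
    ComplexCatalog,
    ExpressionMatrix,
    HitTable,
    SequenceSet,
    SpikeInTable,
    BLAST_COLUMNS,
)
from .orthology import OrthologMap

SHAPES = ("hourglass", "inverse_hourglass", "flat")

#: Residues used for random protein sequences (canonical alphabet).
_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Center of the log10 nM concentration distribution; the bulk of an egg
#: proteome sits around tens of nM.
_LOG10_CONC_CENTER = np.log10(22.0)


@dataclass
class SimTruth:
    """Ground truth recorded by a generator for parameter-recovery tests."""

    seed: int
    true_concentrations: pd.Series | None = None  # entity -> nM, strictly > 0
    curve_slope: float | None = None
    curve_intercept: float | None = None
    conservation_labels: pd.Series | None = None  # ortholog id_a -> label
    shape_label: str | None = None
    snp_positions: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_concentrations is not None:
            if (self.true_concentrations.to_numpy() <= 0).any():
                raise InvalidInputError("true concentrations must be > 0")


# ---------------------------------------------------------------------------
# Spike-in experiment
# ---------------------------------------------------------------------------

def gen_spikein_experiment(
    n_standards: int,
    n_sample_proteins: int,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    dynamic_range_orders: float = 8.0,
    seed: int = 0,
) -> tuple[SpikeInTable, ExpressionMatrix, SimTruth]:
    """Simulate a spike-in standard curve plus a single-stage egg proteome.

    Standards have known amounts log-spaced over ``dynamic_range_orders``
    orders of magnitude (like a staggered commercial standard set); their
    measured signal obeys ``log10(signal) = slope * log10(amount) + intercept
    + Normal(0, noise_sd)``.  Sample-protein true concentrations are drawn
    log-uniform over the same dynamic range and converted to signals by the
    same law.
    """
    if n_standards < 3:
        raise InvalidParameterError("n_standards must be >= 3")
    if n_sample_proteins < 1:
        raise InvalidParameterError("n_sample_proteins must be >= 1")
    if slope == 0:
        raise InvalidParameterError("slope must be nonzero")
    if dynamic_range_orders <= 0:
        raise InvalidParameterError("dynamic_range_orders must be > 0")
    rng = np.random.default_rng(seed)

    log_amounts = np.linspace(0.0, dynamic_range_orders, n_standards)
    log_signals = (
        slope * log_amounts + intercept + rng.normal(0.0, noise_sd, n_standards)
    )
    standards = pd.DataFrame({
        "standard_id": [f"UPS{i + 1:03d}" for i in range(n_standards)],
        "known_amount": 10.0 ** log_amounts,
        "measured_signal": 10.0 ** log_signals,
    })

    log_conc = rng.uniform(0.0, dynamic_range_orders, n_sample_proteins)
    log_sig = (
        slope * log_conc + intercept
        + rng.normal(0.0, noise_sd, n_sample_proteins)
    )
    ids = [f"P{i + 1:05d}" for i in range(n_sample_proteins)]
    signals = ExpressionMatrix(
        pd.DataFrame({"unfE": 10.0 ** log_sig}, index=pd.Index(ids, name="entity_id")),
        modality="protein_relative",
        species="synthetic",
    )
    truth = SimTruth(
        seed=seed,
        true_concentrations=pd.Series(10.0 ** log_conc, index=ids, name="nM"),
        curve_slope=slope,
        curve_intercept=intercept,
    )
    return SpikeInTable(standards), signals, truth


# ---------------------------------------------------------------------------
# Two-species developmental time series
# ---------------------------------------------------------------------------

def _latent_programs(rng: np.random.Generator, n: int, times: np.ndarray,
                     n_knots: int = 6, amplitude: float = 1.0) -> np.ndarray:
    """Smooth positive profiles: 10**(amplitude * cubic spline), n x stages."""
    knots = np.linspace(0.0, 1.0, n_knots)
    control = rng.normal(0.0, 1.0, size=(n, n_knots))
    spline = CubicSpline(knots, control, axis=1)
    return 10.0 ** (amplitude * spline(times))


def _mixing_weight(
    shape: str, times: np.ndarray, effect_size: float, mid_width: float = 0.25,
) -> np.ndarray:
    """Stage-dependent mixing weight: a clipped quadratic bump.

    ``b(u) = max(0, 1 - ((u - 0.5) / mid_width)**2)`` peaks at mid-development
    and vanishes outside ``0.5 +/- mid_width``, so decorrelation is confined
    to the mid window rather than bleeding into early/late stages.  The
    inverse-hourglass shape uses ``b`` directly, the hourglass shape its
    complement, and flat a constant at half height.
    """
    bump = np.maximum(0.0, 1.0 - ((times - 0.5) / mid_width) ** 2)
    if shape == "inverse_hourglass":
        q = bump
    elif shape == "hourglass":
        q = 1.0 - bump
    elif shape == "flat":
        q = np.full_like(times, 0.5)
    else:
        raise InvalidParameterError(
            f"unknown shape {shape!r}; expected one of {SHAPES}"
        )
    return np.clip(effect_size * q, 0.0, 1.0)


def gen_two_species_timeseries(
    n_orthologs: int,
    n_stages_a: int = 8,
    n_stages_b: int = 8,
    shape: Literal["hourglass", "inverse_hourglass", "flat"] = "flat",
    effect_size: float = 0.0,
    noise_sd: float = 0.0,
    divergent_fraction: float = 1.0,
    mid_width: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologMap, SimTruth]:
    """Two ortholog-matched stage series sharing a latent temporal program.

    Species A carries the shared program directly; species B mixes the shared
    program with an independent one, with a stage-dependent mixing weight
    determined by ``shape`` and ``effect_size`` (see module docstring).
    ``divergent_fraction`` of the orthologs (the first ones, labeled
    ``divergent`` in the returned truth) receive the mixing; the rest stay
    fully conserved.  Multiplicative log-normal noise of width ``noise_sd``
    (log10 units) is applied to both matrices.
    """
    if shape not in SHAPES:
        raise InvalidParameterError(
            f"unknown shape {shape!r}; expected one of {SHAPES}"
        )
    if n_stages_a < 4 or n_stages_b < 4:
        raise InvalidParameterError("both species need >= 4 stages")
    if n_orthologs < 2:
        raise InvalidParameterError("n_orthologs must be >= 2")
    if effect_size < 0:
        raise InvalidParameterError("effect_size must be >= 0")
    if not 0.0 <= divergent_fraction <= 1.0:
        raise InvalidParameterError("divergent_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    times_a = np.linspace(0.0, 1.0, n_stages_a)
    times_b = np.linspace(0.0, 1.0, n_stages_b)
    # one spline per ortholog, evaluated on both species' stage grids
    knots = np.linspace(0.0, 1.0, 6)
    shared_ctrl = rng.normal(0.0, 1.0, size=(n_orthologs, 6))
    indep_ctrl = rng.normal(0.0, 1.0, size=(n_orthologs, 6))
    shared = CubicSpline(knots, shared_ctrl, axis=1)
    indep = CubicSpline(knots, indep_ctrl, axis=1)

    profiles_a = 10.0 ** shared(times_a)
    w_stage = _mixing_weight(shape, times_b, effect_size, mid_width)
    n_divergent = int(round(divergent_fraction * n_orthologs))
    w = np.zeros((n_orthologs, n_stages_b))
    w[:n_divergent, :] = w_stage
    profiles_b = (1.0 - w) * 10.0 ** shared(times_b) + w * 10.0 ** indep(times_b)

    if noise_sd > 0:
        profiles_a = profiles_a * 10.0 ** rng.normal(0, noise_sd, profiles_a.shape)
        profiles_b = profiles_b * 10.0 ** rng.normal(0, noise_sd, profiles_b.shape)

    ids_a = [f"cio{i + 1:05d}" for i in range(n_orthologs)]
    ids_b = [f"xen{i + 1:05d}" for i in range(n_orthologs)]
    stages_a = [f"A{i + 1}" for i in range(n_stages_a)]
    stages_b = [f"B{i + 1}" for i in range(n_stages_b)]
    mat_a = ExpressionMatrix(
        pd.DataFrame(profiles_a, index=pd.Index(ids_a, name="entity_id"),
                     columns=stages_a),
        modality="protein_relative", species="species_a",
    )
    mat_b = ExpressionMatrix(
        pd.DataFrame(profiles_b, index=pd.Index(ids_b, name="entity_id"),
                     columns=stages_b),
        modality="protein_relative", species="species_b",
    )
    omap = OrthologMap.from_pairs(list(zip(ids_a, ids_b)))
    per_ortholog_divergent = (w.mean(axis=1) > 0) & (effect_size > 0)
    labels = pd.Series(
        np.where(per_ortholog_divergent, "divergent", "conserved"), index=ids_a,
    )
    truth = SimTruth(
        seed=seed, shape_label=shape if effect_size > 0 else "flat",
        conservation_labels=labels,
    )
    return mat_a, mat_b, omap, truth


def stage_classes_by_thirds(stage_labels: list[str]) -> dict[str, str]:
    """Early/mid/late split of an ordered stage series into near-equal thirds."""
    n = len(stage_labels)
    if n < 3:
        raise InvalidParameterError("need >= 3 stages to form three classes")
    cut1, cut2 = round(n / 3), round(2 * n / 3)
    out: dict[str, str] = {}
    for i, s in enumerate(stage_labels):
        out[s] = "early" if i < cut1 else ("mid" if i < cut2 else "late")
    return out


# ---------------------------------------------------------------------------
# SNP-bearing sequence batches
# ---------------------------------------------------------------------------

def gen_fasta_with_snps(
    n_sequences: int,
    mean_length: int,
    snp_rate: float,
    seed: int = 0,
) -> tuple[SequenceSet, SequenceSet, SimTruth]:
    """Two sequence batches differing by independent single-residue changes.

    Batch 2 substitutes each residue of batch 1 independently with probability
    ``snp_rate`` (to a uniformly chosen different residue), emulating protein
    sequence polymorphisms between animal batches.  Identifiers are identical
    in both batches.
    """
    if n_sequences < 1:
        raise InvalidParameterError("n_sequences must be >= 1")
    if mean_length < 1:
        raise InvalidParameterError("mean_length must be >= 1")
    if not 0.0 <= snp_rate < 0.1:
        raise InvalidParameterError("snp_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)

    batch1: dict[str, str] = {}
    batch2: dict[str, str] = {}
    snp_positions: dict[str, list[int]] = {}
    lengths = np.maximum(1, rng.poisson(mean_length, n_sequences))
    for i, length in enumerate(lengths):
        seq_id = f"seq{i + 1:05d}"
        residues = _RESIDUES[rng.integers(0, len(_RESIDUES), length)]
        mutated = residues.copy()
        hits = np.flatnonzero(rng.random(length) < snp_rate)
        for pos in hits:
            choices = _RESIDUES[_RESIDUES != residues[pos]]
            mutated[pos] = choices[rng.integers(0, len(choices))]
        batch1[seq_id] = "".join(residues)
        batch2[seq_id] = "".join(mutated)
        snp_positions[seq_id] = [int(p) for p in hits]
    truth = SimTruth(seed=seed, snp_positions=snp_positions)
    return SequenceSet(batch1), SequenceSet(batch2), truth


# ---------------------------------------------------------------------------
# Reciprocal hit tables
# ---------------------------------------------------------------------------

def _hit_row(q: str, s: str, evalue: float, bits: float,
             rng: np.random.Generator) -> tuple:
    alen = int(rng.integers(80, 400))
    pid = float(rng.uniform(30, 99))
    return (q, s, round(pid, 2), alen, int(alen * (100 - pid) / 100),
            int(rng.integers(0, 5)), 1, alen, 1, alen, evalue, bits)


def gen_hit_tables(
    omap: OrthologMap,
    n_decoys: int = 0,
    seed: int = 0,
) -> tuple[HitTable, HitTable]:
    """Reciprocal hit tables in which each true pair is the best hit both ways.

    Decoy hits (``n_decoys`` per direction, random query/wrong subject) carry
    strictly worse e-values and strictly lower bit scores than every true hit,
    so reciprocal-best-hit resolution recovers the input map exactly.
    """
    # OrthologMap construction already enforces one-to-one-ness
    rng = np.random.default_rng(seed)
    ids_a = list(omap.pairs["id_a"])
    ids_b = list(omap.pairs["id_b"])
    n = len(ids_a)

    rows_ab, rows_ba = [], []
    for a, b in zip(ids_a, ids_b):
        ev = 10.0 ** rng.uniform(-180.0, -50.0)
        bits = float(rng.uniform(400, 1200))
        rows_ab.append(_hit_row(a, b, ev, round(bits, 1), rng))
        ev2 = 10.0 ** rng.uniform(-180.0, -50.0)
        bits2 = float(rng.uniform(400, 1200))
        rows_ba.append(_hit_row(b, a, ev2, round(bits2, 1), rng))

    if n_decoys > 0 and n >= 2:
        for rows, queries, subjects in (
            (rows_ab, ids_a, ids_b), (rows_ba, ids_b, ids_a),
        ):
            for _ in range(n_decoys):
                qi = int(rng.integers(0, n))
                sj = int(rng.integers(0, n - 1))
                if sj >= qi:
                    sj += 1  # wrong partner by construction
                ev = 10.0 ** rng.uniform(-40.0, -3.0)
                bits = round(float(rng.uniform(40, 300)), 1)
                rows.append(_hit_row(queries[qi], subjects[sj], ev, bits, rng))

    def _table(rows: list[tuple]) -> HitTable:
        return HitTable(pd.DataFrame(rows, columns=list(BLAST_COLUMNS)))

    return _table(rows_ab), _table(rows_ba)


# ---------------------------------------------------------------------------
# Complex stoichiometry dataset
# ---------------------------------------------------------------------------

def gen_complex_dataset(
    n_complexes: int,
    subunits_per_complex: int = 5,
    within_sd: float = 0.1,
    global_sd: float = 1.0,
    n_background: int = 500,
    seed: int = 0,
) -> tuple[ConcentrationTable, ComplexCatalog, SimTruth]:
    """Egg-like concentration table with stoichiometrically tight complexes.

    Each complex has a complex-specific mean log10 concentration drawn from
    the global distribution; its subunits scatter around that mean with sd
    ``within_sd`` (log10).  Background proteins scatter with sd ``global_sd``.
    """
    if n_complexes < 0 or subunits_per_complex < 2:
        raise InvalidParameterError(
            "need n_complexes >= 0 and subunits_per_complex >= 2"
        )
    if not within_sd < global_sd:
        raise InvalidParameterError("require within_sd < global_sd")
    rng = np.random.default_rng(seed)

    ids: list[str] = []
    log_conc: list[float] = []
    complexes: dict[str, tuple[str, list[str]]] = {}
    for c in range(n_complexes):
        cid = f"CPX{c + 1:03d}"
        center = rng.normal(_LOG10_CONC_CENTER, global_sd)
        members = []
        for s in range(subunits_per_complex):
            pid = f"{cid}_S{s + 1}"
            members.append(pid)
            ids.append(pid)
            log_conc.append(center + rng.normal(0.0, within_sd))
        complexes[cid] = (f"complex {c + 1}", members)
    for i in range(n_background):
        ids.append(f"BG{i + 1:05d}")
        log_conc.append(rng.normal(_LOG10_CONC_CENTER, global_sd))

    conc = pd.Series(10.0 ** np.asarray(log_conc), index=ids, name="concentration_nM")
    table = ConcentrationTable(concentrations=conc)
    truth = SimTruth(seed=seed, true_concentrations=conc.copy())
    return table, ComplexCatalog(complexes), truth
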