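"""Readers, writers, and validated in-memory containers for external formats.

All tabular formats are plain TSV; sequences are FASTA; alignment hits use the
12-column tabular dialect emitted by ``blastp -outfmt 6``.  Readers validate
strictly and raise :class:`~embryoprot.errors.FormatError` rather than coercing
silently; recoverable irregularities (duplicate annotation ids) are logged as
warnings.  Expression values are serialized in linear space with 10 significant
digits so that every writer/reader pair round-trips losslessly at working
precision; missing values are written as ``NA`` and are distinct from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

MODALITIES = ("protein_relative", "protein_absolute_nM", "rna_tpm")
ANNOTATION_CATEGORIES = ("TF", "SM", "kinase", "phosphatase")

#: Canonical amino acids plus X (unknown) and U (selenocysteine).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XU")

#: The eight sampled Ciona stages, unfertilized egg through hatching tadpole.
CIONA_STAGES = (
    "unfE", "fertE", "cell-16", "iniG", "latN", "midTII", "latTII", "larva",
)

#: Default early/mid/late split of the Ciona series: the mid-developmental
#: window covers gastrulation and neurulation.
CIONA_STAGE_CLASSES = {
    "unfE": "early", "fertE": "early", "cell-16": "early",
    "iniG": "mid", "latN": "mid",
    "midTII": "late", "latTII": "late", "larva": "late",
}

_FLOAT_FMT = "%.10g"

BLAST_COLUMNS = (
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Non-negative abundances for entities across an ordered stage series.

    ``values`` is a DataFrame indexed by unique entity ids with one column per
    stage, in developmental order (column order is meaningful and never
    sorted).  Missing measurements are NaN and are distinct from zero.
    """

    values: pd.DataFrame
    modality: str
    species: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise FormatError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate entity id {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate stage label {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            r, c = np.argwhere(np.nan_to_num(vals, nan=0.0) < 0)[0]
            raise FormatError(
                f"negative value at entity {idx[r]!r}, stage {cols[c]!r}"
            )
        self.values = self.values.astype(float)

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_entities(self) -> int:
        return len(self.values.index)

    @property
    def n_stages(self) -> int:
        return len(self.values.columns)


def read_expression_tsv(path: str | Path, modality: str, species: str = "") -> ExpressionMatrix:
    """Read an entities x stages TSV with a header row and id first column."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, header=0,
            na_values=["NA"], keep_default_na=False, dtype=str,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no stage columns found")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    df.index = df.index.astype(str)
    try:
        return ExpressionMatrix(df, modality=modality, species=species)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(
        Path(path), sep="\t", na_rep="NA", float_format=_FLOAT_FMT,
        index_label="entity_id",
    )


# ---------------------------------------------------------------------------
# FASTA sequence sets
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Ordered mapping of unique sequence ids to amino-acid sequences."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __contains__(self, key: str) -> bool:
        return key in self.sequences

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)


def _validate_protein_sequence(seq_id: str, seq: str) -> str:
    seq = seq.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise FormatError(f"empty sequence for id {seq_id!r}")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise FormatError(
            f"invalid residue {seq[pos]!r} at position {pos} in sequence {seq_id!r}"
        )
    return seq


def read_fasta(path: str | Path) -> SequenceSet:
    """Read protein FASTA; ids are the first whitespace token of each header."""
    path = Path(path)
    sequences: dict[str, str] = {}
    seq_id: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if seq_id is None:
            return
        sequences[seq_id] = _validate_protein_sequence(seq_id, "".join(chunks))

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                token = line[1:].split()[0] if line[1:].split() else ""
                if not token:
                    raise FormatError(f"{path}: empty FASTA header")
                if token in sequences:
                    raise FormatError(f"{path}: duplicate FASTA id {token!r}")
                seq_id, chunks = token, []
            else:
                if seq_id is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line)
        _flush()
    if not sequences:
        raise FormatError(f"{path}: no sequences found")
    return SequenceSet(sequences)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    with open(Path(path), "w") as handle:
        for seq_id, seq in seqs.sequences.items():
            handle.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular hit tables
# ---------------------------------------------------------------------------

@dataclass
class HitTable:
    """Alignment hits in file order (12-column tabular dialect)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(BLAST_COLUMNS) - set(self.records.columns)
        if missing:
            raise FormatError(f"hit table missing columns {sorted(missing)}")
        ev = self.records["e_value"].to_numpy(dtype=float)
        if np.any(ev < 0):
            raise FormatError("negative e-value in hit table")
        if not np.all(np.isfinite(self.records["bit_score"].to_numpy(dtype=float))):
            raise FormatError("non-finite bit score in hit table")

    def __len__(self) -> int:
        return len(self.records)


def read_blast_tab(path: str | Path) -> HitTable:
    """Parse headerless 12-column tab-separated alignment output."""
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=list(BLAST_COLUMNS))
    for col in ("percent_identity", "e_value", "bit_score"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("alignment_length", "mismatches", "gap_opens",
                "q_start", "q_end", "s_start", "s_end"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    return HitTable(df.reset_index(drop=True))


def write_blast_tab(hits: HitTable, path: str | Path) -> None:
    hits.records[list(BLAST_COLUMNS)].to_csv(
        Path(path), sep="\t", header=False, index=False, float_format="%.6g",
    )


# ---------------------------------------------------------------------------
# Complex catalog and annotation lists
# ---------------------------------------------------------------------------

@dataclass
class ComplexCatalog:
    """Protein-complex membership: complex id -> (name, member entity ids)."""

    complexes: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, (name, members) in self.complexes.items():
            if len(members) < 2:
                raise FormatError(
                    f"complex {cid!r} has {len(members)} member(s); need >= 2"
                )
            if any(not m for m in members):
                raise FormatError(f"complex {cid!r} has an empty member id")

    def __len__(self) -> int:
        return len(self.complexes)

    def members(self, complex_id: str) -> list[str]:
        return self.complexes[complex_id][1]


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Read a TSV of complex_id, complex_name, ';'-separated members."""
    path = Path(path)
    complexes: dict[str, tuple[str, list[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns (id, name, members)"
                )
            cid, name, member_field = fields
            if cid in complexes:
                raise FormatError(f"{path}:{lineno}: duplicate complex id {cid!r}")
            members = [m for m in member_field.split(";") if m]
            complexes[cid] = (name, members)
    try:
        return ComplexCatalog(complexes)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(Path(path), "w") as handle:
        for cid, (name, members) in catalog.complexes.items():
            handle.write(f"{cid}\t{name}\t{';'.join(members)}\n")


@dataclass
class AnnotationList:
    """A functional category (TF, SM, kinase, phosphatase) and its entity ids."""

    category: str
    entity_ids: list[str]

    def __post_init__(self) -> None:
        if self.category not in ANNOTATION_CATEGORIES:
            raise FormatError(
                f"unknown annotation category {self.category!r}; "
                f"expected one of {ANNOTATION_CATEGORIES}"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise FormatError(f"duplicate ids in {self.category} annotation list")

    def __len__(self) -> int:
        return len(self.entity_ids)


def read_annotation_list(path: str | Path, category: str) -> AnnotationList:
    """Read one entity id per line; duplicates are dropped with a warning."""
    path = Path(path)
    seen: dict[str, None] = {}
    n_dups = 0
    with open(path) as handle:
        for line in handle:
            token = line.strip()
            if not token:
                continue
            if token in seen:
                n_dups += 1
            else:
                seen[token] = None
    if n_dups:
        logger.warning(
            "%s: dropped %d duplicate id(s) in %s annotation list",
            path, n_dups, category,
        )
    return AnnotationList(category=category, entity_ids=list(seen))


def write_annotation_list(annotation: AnnotationList, path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in annotation.entity_ids))


# ---------------------------------------------------------------------------
# Spike-in standards
# ---------------------------------------------------------------------------

@dataclass
class SpikeInTable:
    """Known-amount standards and their measured MS1 signals.

    ``known_amount`` is in the unit recorded in ``amount_unit`` (default fmol,
    matching commercial dynamic-range standard sets); ``measured_signal`` is an
    MS1 area in arbitrary units.  A zero signal means the standard was not
    detected and is excluded from curve fitting.
    """

    standards: pd.DataFrame  # columns: standard_id, known_amount, measured_signal
    amount_unit: str = "fmol"

    def __post_init__(self) -> None:
        required = {"standard_id", "known_amount", "measured_signal"}
        missing = required - set(self.standards.columns)
        if missing:
            raise FormatError(f"spike-in table missing columns {sorted(missing)}")
        if (self.standards["known_amount"].to_numpy(dtype=float) <= 0).any():
            raise FormatError("spike-in known_amount must be > 0")
        if (self.standards["measured_signal"].to_numpy(dtype=float) < 0).any():
            raise FormatError("spike-in measured_signal must be >= 0")

    def __len__(self) -> int:
        return len(self.standards)


def read_spikein_tsv(path: str | Path, amount_unit: str = "fmol") -> SpikeInTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={"standard_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty spike-in file") from exc
    try:
        return SpikeInTable(df, amount_unit=amount_unit)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spikein_tsv(table: SpikeInTable, path: str | Path) -> None:
    table.standards.to_csv(
        Path(path), sep="\t", index=False, float_format=_FLOAT_FMT,
    )
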