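"""Rule-based in-silico proteolysis and cross-database peptide comparison.

Trypsin cleaves C-terminal to K or R except when the next residue is proline;
LysC cleaves C-terminal to K including before proline.  With ``m`` allowed
missed cleavages, every union of up to ``m + 1`` consecutive fully-cleaved
fragments is emitted; length filters are applied last.  Digestion is
position-faithful: with no missed cleavages and no length filter the peptides
of a protein concatenate back to the protein.

The SNP-robustness analysis digests two sequence databases sharing
identifiers (e.g. assembled from two animal batches) and reports the fraction
of peptides identical between them.  Fractions are over the union of distinct
peptide strings (set semantics), since single-residue polymorphisms make a
peptide either shared or wholly unique; a count-weighted mode is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from .io import AMINO_ACIDS, SequenceSet

#: Cleavage-site patterns: the site is C-terminal to the matched residue.
_CLEAVAGE_RULES = {
    "trypsin": re.compile(r"[KR](?!P)"),
    "lysC": re.compile(r"K"),
}

PROTEASES = tuple(_CLEAVAGE_RULES)


@dataclass
class PeptideSet:
    """Distinct peptides of a digested database with per-peptide parents."""

    source_id: str
    protease: str
    missed_cleavages: int
    peptides: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def peptide_strings(self) -> set[str]:
        return set(self.peptides)


def digest(
    sequence: str,
    protease: str = "trypsin",
    missed_cleavages: int = 0,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[str]:
    """Cleave one sequence; peptides are returned in N-to-C order.

    Peptides from ``m`` missed cleavages follow the fully-cleaved peptides,
    grouped by miss count and ordered by position within each group.
    """
    if not sequence:
        raise InvalidParameterError("sequence must be non-empty")
    if protease not in _CLEAVAGE_RULES:
        raise InvalidParameterError(
            f"unknown protease {protease!r}; expected one of {PROTEASES}"
        )
    if missed_cleavages < 0 or min_len < 1:
        raise InvalidParameterError("missed_cleavages >= 0 and min_len >= 1")
    sequence = sequence.upper()
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        pos = next(i for i, c in enumerate(sequence) if c in bad)
        raise InvalidInputError(
            f"invalid residue {sequence[pos]!r} at position {pos}"
        )

    cut_after = [m.start() for m in _CLEAVAGE_RULES[protease].finditer(sequence)]
    bounds = [0] + [i + 1 for i in cut_after if i + 1 < len(sequence)] + [len(sequence)]
    fragments = [sequence[a:b] for a, b in zip(bounds, bounds[1:])]

    peptides: list[str] = []
    for miss in range(missed_cleavages + 1):
        for start in range(len(fragments) - miss):
            pep = "".join(fragments[start:start + miss + 1])
            if len(pep) < min_len:
                continue
            if max_len is not None and len(pep) > max_len:
                continue
            peptides.append(pep)
    return peptides


def digest_set(
    seqs: SequenceSet,
    protease: str = "trypsin",
    missed_cleavages: int = 0,
    min_len: int = 1,
    max_len: int | None = None,
    source_id: str = "",
) -> PeptideSet:
    """Digest every sequence of a database into one peptide set."""
    peptides: dict[str, set[str]] = {}
    for seq_id, seq in seqs.sequences.items():
        for pep in digest(seq, protease, missed_cleavages, min_len, max_len):
            peptides.setdefault(pep, set()).add(seq_id)
    return PeptideSet(
        source_id=source_id,
        protease=protease,
        missed_cleavages=missed_cleavages,
        peptides=peptides,
    )


def peptide_set_overlap(
    set_a: PeptideSet,
    set_b: PeptideSet,
    count_weighted: bool = False,
) -> tuple[float, float, float]:
    """(shared, unique-to-A, unique-to-B) fractions over the peptide union.

    The three fractions sum to 1.  ``count_weighted`` weights each peptide by
    its number of parent proteins instead of counting distinct strings.
    """
    if (set_a.protease, set_a.missed_cleavages) != (
        set_b.protease, set_b.missed_cleavages
    ):
        raise InvalidInputError(
            "peptide sets were produced with different protease settings"
        )
    a, b = set_a.peptide_strings, set_b.peptide_strings
    union = a | b
    if not union:
        raise InsufficientDataError("both peptide sets are empty")

    def _weight(pep: str) -> float:
        if not count_weighted:
            return 1.0
        return float(
            len(set_a.peptides.get(pep, ())) + len(set_b.peptides.get(pep, ()))
        )

    total = sum(_weight(p) for p in union)
    shared = sum(_weight(p) for p in a & b) / total
    unique_a = sum(_weight(p) for p in a - b) / total
    unique_b = sum(_weight(p) for p in b - a) / total
    return shared, unique_a, unique_b


def snp_robustness_report(
    batch1: SequenceSet,
    batch2: SequenceSet,
    protease: str = "trypsin",
    missed_cleavages: int = 0,
) -> dict:
    """Digest the id-shared sequences of two databases and compare peptides.

    Returns counts of shared identifiers and per-batch peptides plus the
    shared/unique fractions (percent) over the peptide union.
    """
    shared_ids = [i for i in batch1.sequences if i in batch2.sequences]
    if not shared_ids:
        raise InsufficientDataError("no shared identifiers between batches")
    sub1 = SequenceSet({i: batch1[i] for i in shared_ids})
    sub2 = SequenceSet({i: batch2[i] for i in shared_ids})
    pep1 = digest_set(sub1, protease, missed_cleavages, source_id="batch1")
    pep2 = digest_set(sub2, protease, missed_cleavages, source_id="batch2")
    shared, ua, ub = peptide_set_overlap(pep1, pep2)
    return {
        "n_shared_ids": len(shared_ids),
        "n_peptides_batch1": len(pep1),
        "n_peptides_batch2": len(pep2),
        "protease": protease,
        "missed_cleavages": missed_cleavages,
        "shared_fraction_pct": 100.0 * shared,
        "unique_batch1_pct": 100.0 * ua,
        "unique_batch2_pct": 100.0 * ub,
    }
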