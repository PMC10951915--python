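"""Reciprocal-best-hit (RBH) resolution of one-to-one cross-species orthologs.

The module consumes precomputed alignment hit tables (12-column tabular
dialect) rather than invoking an aligner, which keeps ortholog resolution
deterministic and download-free.  The selection criteria mirror a standard
reciprocal BLASTP protocol: hits above the e-value threshold are discarded,
the best subject per query is the one with (1) the lowest e-value and (2) the
highest bit score, and a pair is kept only when it is best in both directions.
Remaining ties are broken by file order, and every such event is logged.

For users with real proteomes the matching aligner invocation is::

    blastp -query a.fasta -db b -outfmt 6 -evalue 0.01 \\
        -max_target_seqs 1 -matrix BLOSUM45 > a_vs_b.tsv

(and the reverse); per-query best-hit selection in this module replicates the
effect of ``-max_target_seqs 1`` logically, so results do not depend on the
aligner's internal reporting quirks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import InvalidInputError
from .io import HitTable

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 0.01

ORTHOLOG_COLUMNS = (
    "id_a", "id_b", "evalue_ab", "bits_ab", "evalue_ba", "bits_ba",
)


@dataclass
class OrthologMap:
    """One-to-one cross-species pairs with per-direction hit provenance.

    ``pairs`` has columns id_a, id_b and, when produced by RBH resolution,
    the e-values and bit scores supporting each direction.  Each id appears
    in at most one pair.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        if "id_a" not in self.pairs.columns or "id_b" not in self.pairs.columns:
            raise InvalidInputError("ortholog map needs id_a and id_b columns")
        for col in ("id_a", "id_b"):
            if self.pairs[col].duplicated().any():
                dup = self.pairs[col][self.pairs[col].duplicated()].iloc[0]
                raise InvalidInputError(
                    f"id {dup!r} appears in more than one ortholog pair ({col})"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["id_a"], self.pairs["id_b"]))

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, str] | list[tuple[str, str]]) -> "OrthologMap":
        items = list(pairs.items()) if isinstance(pairs, Mapping) else list(pairs)
        df = pd.DataFrame(items, columns=["id_a", "id_b"])
        return cls(df)


def read_ortholog_tsv(path: str | Path) -> OrthologMap:
    df = pd.read_csv(Path(path), sep="\t", header=0, dtype={"id_a": str, "id_b": str})
    return OrthologMap(df)


def write_ortholog_tsv(omap: OrthologMap, path: str | Path) -> None:
    omap.pairs.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def best_hits(hits: HitTable, evalue_max: float = DEFAULT_EVALUE_MAX) -> pd.DataFrame:
    """Best subject per query: lowest e-value, then highest bit score.

    Hits with e-value above ``evalue_max`` are discarded first.  Queries whose
    hits are all discarded are absent from the result.  Ties remaining after
    both criteria are broken by file order (first hit wins) and logged.

    Returns a DataFrame indexed by query_id with columns subject_id, e_value,
    bit_score.
    """
    df = hits.records
    df = df[df["e_value"] <= evalue_max]
    if df.empty:
        return pd.DataFrame(
            columns=["subject_id", "e_value", "bit_score"]
        ).rename_axis("query_id")

    # stable sort keeps file order as the final tie-break
    ranked = df.reset_index(drop=True).sort_values(
        ["query_id", "e_value", "bit_score"],
        ascending=[True, True, False],
        kind="stable",
    )
    best = ranked.drop_duplicates("query_id", keep="first")

    # detect and log genuine (e-value, bit-score) ties that fell to file order
    key = ranked.set_index("query_id")[["e_value", "bit_score"]]
    dup_mask = key.index.duplicated(keep=False)
    if dup_mask.any():
        grouped = ranked.groupby("query_id", sort=False)
        for qid, grp in grouped:
            if len(grp) > 1:
                top = grp.iloc[0]
                tied = grp[
                    (grp["e_value"] == top["e_value"])
                    & (grp["bit_score"] == top["bit_score"])
                ]
                if len(tied) > 1:
                    logger.info(
                        "query %s: %d equally good hits; kept first in file order",
                        qid, len(tied),
                    )
    return best.set_index("query_id")[["subject_id", "e_value", "bit_score"]]


def reciprocal_best_hits(
    hits_ab: HitTable,
    hits_ba: HitTable,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> OrthologMap:
    """Keep pair (a, b) iff a's best hit is b and b's best hit is a.

    The result is one-to-one by construction and sorted by id_a for
    deterministic output.
    """
    best_ab = best_hits(hits_ab, evalue_max)
    best_ba = best_hits(hits_ba, evalue_max)
    rows = []
    for a, rec in best_ab.iterrows():
        b = rec["subject_id"]
        if b in best_ba.index and best_ba.loc[b, "subject_id"] == a:
            back = best_ba.loc[b]
            rows.append(
                (a, b, rec["e_value"], rec["bit_score"],
                 back["e_value"], back["bit_score"])
            )
    df = pd.DataFrame(rows, columns=list(ORTHOLOG_COLUMNS))
    df = df.sort_values("id_a", kind="stable").reset_index(drop=True)
    return OrthologMap(df)


def collapse_to_gene_level(
    omap: OrthologMap,
    isoform_to_gene_a: Mapping[str, str],
    isoform_to_gene_b: Mapping[str, str],
) -> OrthologMap:
    """Project protein-level pairs onto genes, enforcing one-to-one-ness.

    Gene pairs supported by several protein pairs collapse to one pair; a gene
    matched to two or more distinct partner genes is dropped entirely (with a
    log record) so the output stays one-to-one.
    """
    missing_a = [i for i in omap.pairs["id_a"] if i not in isoform_to_gene_a]
    missing_b = [i for i in omap.pairs["id_b"] if i not in isoform_to_gene_b]
    if missing_a or missing_b:
        raise InvalidInputError(
            f"unmapped protein ids: {sorted(missing_a + missing_b)[:10]}"
        )
    genes = pd.DataFrame({
        "gene_a": [isoform_to_gene_a[i] for i in omap.pairs["id_a"]],
        "gene_b": [isoform_to_gene_b[i] for i in omap.pairs["id_b"]],
    }).drop_duplicates()

    conflict_a = set(genes.loc[genes["gene_a"].duplicated(keep=False), "gene_a"])
    conflict_b = set(genes.loc[genes["gene_b"].duplicated(keep=False), "gene_b"])
    keep = ~(genes["gene_a"].isin(conflict_a) | genes["gene_b"].isin(conflict_b))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d gene pair(s) with conflicting partners to keep the "
            "map one-to-one", n_dropped,
        )
    out = genes[keep].rename(columns={"gene_a": "id_a", "gene_b": "id_b"})
    out = out.sort_values("id_a", kind="stable").reset_index(drop=True)
    return OrthologMap(out)
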