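"""Best-hit taxonomic assignment with gyrB/parE gene labelling.

Each OTU representative is compared to every marker record under global
(end-to-end) alignment with unit costs; percent identity is
matches / alignment-length x 100. The best hit provides taxonomy and gene
label; when several equally good hits disagree, the taxonomy is truncated to
their lowest common rank (multi-affiliation) and disagreeing gene labels
yield the label ``ambiguous``. Identity below 80% demotes the taxonomy to
phylum: with intra-species marker identity around 94-95%, weaker hits are
not rank-reliable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from gyrbench.amplicon_pipeline import OTUTable
from gyrbench.refdb import RANKS, MarkerRecord

__all__ = [
    "Assignment",
    "global_identity",
    "assign",
    "assign_all",
    "paralog_ratios",
    "LOW_IDENTITY_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Below this percent identity, assignments are demoted to phylum rank.
LOW_IDENTITY_THRESHOLD = 80.0

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class Assignment:
    """Best-hit assignment of one OTU."""

    otu_id: str
    identity: float  # percent, 0..100
    gene: str  # gyrB | parE | 16S | ambiguous
    taxonomy: tuple[str, ...]  # truncated at the deepest unambiguous rank
    hits: tuple[str, ...]  # marker_ids of the tied best hits

    @property
    def rank(self) -> str:
        return RANKS[len(self.taxonomy) - 1] if self.taxonomy else "unassigned"


def global_identity(a: str, b: str) -> float:
    """Percent identity under global alignment: matches / columns x 100."""
    res = edlib.align(a, b, mode="NW", task="path")
    alen = sum(int(n) for n, _ in _CIG_RE.findall(res["cigar"]))
    return 100.0 * (alen - res["editDistance"]) / alen


def _best_hits(rep: str, db: Sequence[MarkerRecord]) -> tuple[float, list[MarkerRecord]]:
    # rank hits by (edit distance, alignment length) as exact integers; the
    # percent identity of the winners is computed once afterwards
    best_key: tuple[int, int] | None = None
    best: list[MarkerRecord] = []
    for rec in db:
        res = edlib.align(rep, rec.sequence, mode="NW", task="path")
        alen = sum(int(n) for n, _ in _CIG_RE.findall(res["cigar"]))
        key = (res["editDistance"], -alen)
        if best_key is None or key < best_key:
            best_key, best = key, [rec]
        elif key == best_key:
            best.append(rec)
    assert best_key is not None
    dist, neg_alen = best_key
    identity = 100.0 * (-neg_alen - dist) / -neg_alen
    best.sort(key=lambda r: r.marker_id)
    return identity, best


def _lca(taxonomies: Sequence[tuple[str, ...]], max_depth: int = 7) -> tuple[str, ...]:
    depth = 0
    for level in range(max_depth):
        names = {t[level] if level < len(t) else "" for t in taxonomies}
        if len(names) == 1 and "" not in names:
            depth = level + 1
        else:
            break
    return taxonomies[0][:depth]


def assign(otu_id: str, representative: str, db: Sequence[MarkerRecord]) -> Assignment:
    """Assign one OTU representative against the marker database.

    Ties are resolved by lexicographic marker_id, making the result invariant
    to database order.
    """
    if not db:
        raise ValueError("empty marker database")
    identity, hits = _best_hits(representative, db)
    taxonomy = _lca([h.taxonomy for h in hits])
    genes = {h.gene for h in hits}
    gene = hits[0].gene if len(genes) == 1 else "ambiguous"
    if gene == "ambiguous":
        logger.info("OTU %s: best hits disagree on gene label (%s)", otu_id, sorted(genes))
    if identity < LOW_IDENTITY_THRESHOLD:
        taxonomy = taxonomy[:2]
    return Assignment(
        otu_id=otu_id,
        identity=identity,
        gene=gene,
        taxonomy=taxonomy,
        hits=tuple(h.marker_id for h in hits),
    )


def assign_all(table: OTUTable, db: Sequence[MarkerRecord]) -> pd.DataFrame:
    """Assign every OTU of a table; returns a tidy frame (one row per OTU).

    Columns: otu_id, identity, gene, rank, then one column per taxonomy rank
    (empty below the truncation point).
    """
    rows = []
    for otu_id, rep in table.representatives.items():
        a = assign(otu_id, rep, db)
        row = {"otu_id": a.otu_id, "identity": a.identity, "gene": a.gene, "rank": a.rank}
        for i, rank in enumerate(RANKS[:7]):
            row[rank] = a.taxonomy[i] if i < len(a.taxonomy) else ""
        row["hits"] = ",".join(a.hits)
        rows.append(row)
    return pd.DataFrame(rows)


def paralog_ratios(
    assignments: pd.DataFrame, table: OTUTable, rank: str = "species"
) -> pd.DataFrame:
    """Per-taxon gyrB read fraction, mean +/- SD across samples.

    For every taxon at ``rank``, the per-sample fraction
    gyrB / (gyrB + parE) is computed over samples where the taxon has > 0
    marker reads; taxa absent everywhere are excluded. OTUs with an
    ambiguous gene label are left out of both numerator and denominator.
    """
    if rank not in RANKS[:7]:
        raise ValueError(f"rank must be one of {RANKS[:7]}")
    sub = assignments[(assignments[rank] != "") & assignments["gene"].isin(["gyrB", "parE"])]
    rows = []
    for taxon, group in sub.groupby(rank):
        counts = table.df.loc[table.df.index.intersection(group["otu_id"])]
        by_gene = counts.groupby(
            group.set_index("otu_id")["gene"].reindex(counts.index)
        ).sum()
        gyrb = by_gene.loc["gyrB"] if "gyrB" in by_gene.index else pd.Series(0, index=table.df.columns)
        pare = by_gene.loc["parE"] if "parE" in by_gene.index else pd.Series(0, index=table.df.columns)
        denom = gyrb + pare
        present = denom > 0
        if not present.any():
            continue
        frac = (gyrb[present] / denom[present]).astype(float)
        rows.append(
            {
                "taxon": taxon,
                "rank": rank,
                "n_samples": int(present.sum()),
                "mean_gyrb_fraction": float(frac.mean()),
                "sd_gyrb_fraction": float(frac.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)
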