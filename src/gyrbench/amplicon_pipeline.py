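"""Per-sample reads to a filtered OTU table.

Stages: exact dereplication, swarm-style single-linkage clustering at edit
distance d (default 3), simplified de-novo chimera removal, and a
whole-dataset low-abundance filter (keep OTUs seen more than 10 times).

Clustering semantics: OTUs are the connected components of the graph joining
unique sequences at Levenshtein distance <= d. Small inputs are clustered by
brute force over all pairs; large inputs go through an exact pigeonhole
candidate filter (d+1 positional chunks: two equal-length sequences differing
by <= d substitutions share at least one chunk) with every candidate pair
verified by banded edit distance, and all-pairs verification across length
buckets differing by <= d. Union-find accumulates components; a pair already
connected is skipped, which cannot change the final components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "Dereplicate",
    "OTU",
    "OTUTable",
    "dereplicate",
    "edit_distance",
    "swarm_cluster",
    "remove_chimeras",
    "abundance_filter",
    "build_otu_table",
    "cluster_reads",
]

logger = logging.getLogger(__name__)

#: Inputs up to this many unique sequences are clustered by brute force.
_BRUTE_FORCE_LIMIT = 600


def edit_distance(a: str, b: str, k: int | None = None) -> int:
    """Levenshtein distance; -1 when a bound ``k`` is given and exceeded."""
    return edlib.align(a, b, mode="NW", task="distance", k=-1 if k is None else k)[
        "editDistance"
    ]


@dataclass
class Dereplicate:
    """Unique sequences with per-sample counts, ordered by decreasing total."""

    samples: tuple[str, ...]
    sequences: tuple[str, ...]
    counts: np.ndarray  # (n_sequences, n_samples) int

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class OTU:
    """A cluster of unique sequences with aggregated per-sample counts."""

    otu_id: str
    representative: str
    members: tuple[str, ...]
    counts: np.ndarray  # per sample

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class OTUTable:
    """OTUs x samples count matrix with representative sequences."""

    df: pd.DataFrame  # index: otu ids, columns: samples
    representatives: dict[str, str]
    d: int
    removed: pd.DataFrame | None = None  # log of filtered-out OTUs

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def totals(self) -> pd.Series:
        return self.df.sum(axis=1)


def dereplicate(reads_by_sample: Mapping[str, Sequence[str]]) -> Dereplicate:
    """Exact-string dereplication across samples; counts are conserved."""
    samples = tuple(reads_by_sample)
    index: dict[str, np.ndarray] = {}
    for j, sample in enumerate(samples):
        for read in reads_by_sample[sample]:
            row = index.get(read)
            if row is None:
                row = np.zeros(len(samples), dtype=np.int64)
                index[read] = row
            row[j] += 1
    # decreasing total count, ties broken lexicographically
    order = sorted(index, key=lambda s: (-int(index[s].sum()), s))
    counts = (
        np.vstack([index[s] for s in order])
        if order
        else np.zeros((0, len(samples)), dtype=np.int64)
    )
    return Dereplicate(samples, tuple(order), counts)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _verify_pairs(
    pairs: Iterable[tuple[int, int]],
    seqs: Sequence[str],
    d: int,
    uf: _UnionFind,
) -> None:
    for i, j in pairs:
        if uf.find(i) == uf.find(j):
            continue
        if edit_distance(seqs[i], seqs[j], k=d) != -1:
            uf.union(i, j)


def _chunk_bounds(length: int, k: int) -> list[int]:
    return [round(i * length / k) for i in range(k + 1)]


def _cluster_components(seqs: Sequence[str], d: int) -> _UnionFind:
    n = len(seqs)
    uf = _UnionFind(n)
    if d == 0:
        return uf  # dereplicated input: every sequence is its own component
    if n <= _BRUTE_FORCE_LIMIT:
        _verify_pairs(((i, j) for i in range(n) for j in range(i + 1, n)), seqs, d, uf)
        return uf

    # length buckets
    by_length: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_length.setdefault(len(s), []).append(i)

    # pigeonhole within equal-length buckets: d+1 positional chunks
    for length, idxs in by_length.items():
        bounds = _chunk_bounds(length, d + 1)
        buckets: dict[tuple[int, str], list[int]] = {}
        for i in idxs:
            s = seqs[i]
            for c in range(d + 1):
                buckets.setdefault((c, s[bounds[c] : bounds[c + 1]]), []).append(i)
        for members in buckets.values():
            if len(members) < 2:
                continue
            # star against the most abundant member (input is ordered by
            # abundance, so the smallest index), then remaining cross-
            # component pairs
            center = members[0]
            _verify_pairs(((center, i) for i in members[1:]), seqs, d, uf)
            groups: dict[int, list[int]] = {}
            for i in members:
                groups.setdefault(uf.find(i), []).append(i)
            if len(groups) > 1:
                roots = sorted(groups)
                for a in range(len(roots)):
                    for b in range(a + 1, len(roots)):
                        _verify_pairs(
                            (
                                (i, j)
                                for i in groups[roots[a]]
                                for j in groups[roots[b]]
                            ),
                            seqs,
                            d,
                            uf,
                        )

    # cross-length pairs (only chimeras/indel mode produce these): all pairs
    lengths = sorted(by_length)
    for a_idx, la in enumerate(lengths):
        for lb in lengths[a_idx + 1 :]:
            if lb - la > d:
                break
            _verify_pairs(
                ((i, j) for i in by_length[la] for j in by_length[lb]), seqs, d, uf
            )
    return uf


def swarm_cluster(derep: Dereplicate, d: int = 3) -> list[OTU]:
    """Single-linkage clustering of unique sequences at edit distance <= d.

    Representative = highest-total member, ties broken lexicographically.
    OTU ids are assigned in decreasing total-count order (``Cluster_1`` is
    the most abundant), ties again lexicographic on the representative.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    seqs = derep.sequences
    uf = _cluster_components(seqs, d)
    groups: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        groups.setdefault(uf.find(i), []).append(i)

    totals = derep.totals
    otus: list[OTU] = []
    for members in groups.values():
        rep_idx = min(members, key=lambda i: (-int(totals[i]), seqs[i]))
        counts = derep.counts[members].sum(axis=0)
        otus.append(
            OTU(
                otu_id="",
                representative=seqs[rep_idx],
                members=tuple(seqs[i] for i in sorted(members)),
                counts=counts,
            )
        )
    otus.sort(key=lambda o: (-o.total, o.representative))
    for rank, otu in enumerate(otus, 1):
        otu.otu_id = f"Cluster_{rank}"
    return otus


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def remove_chimeras(
    otus: Sequence[OTU], d: int = 3, abundance_skew: float = 2.0
) -> tuple[list[OTU], list[OTU]]:
    """Simplified de-novo chimera removal on OTU representatives.

    An OTU is flagged chimeric when its representative splits at some
    breakpoint into a prefix exactly matching one more-abundant parent
    representative and a suffix exactly matching another (both parents at
    least ``abundance_skew`` times its total), and it is not within ``d``
    edits of any single parent. Returns ``(kept, flagged)``.

    This is a deliberate simplification of reference chimera detectors
    (exact two-parent crossover only); it can be disabled upstream.
    """
    ordered = sorted(otus, key=lambda o: o.total)
    kept: list[OTU] = []
    flagged: list[OTU] = []
    for otu in ordered:
        parents = [p for p in otus if p.total >= abundance_skew * otu.total and p is not otu]
        if _is_chimera(otu, parents, d):
            flagged.append(otu)
        else:
            kept.append(otu)
    kept.sort(key=lambda o: (-o.total, o.representative))
    return kept, flagged


def _is_chimera(otu: OTU, parents: Sequence[OTU], d: int) -> bool:
    rep = otu.representative
    n = len(rep)
    if n < 2 or not parents:
        return False
    for p in parents:  # within d of a single parent: a neighbor, not a chimera
        if edit_distance(rep, p.representative, k=d) != -1:
            return False
    prefixes = {id(p): _common_prefix(rep, p.representative) for p in parents}
    suffixes = {id(p): _common_suffix(rep, p.representative) for p in parents}
    for pa in parents:
        lcp = prefixes[id(pa)]
        if lcp < 1:
            continue
        for pb in parents:
            if pb is pa:
                continue
            lcs = suffixes[id(pb)]
            # need a breakpoint k with 1 <= k <= lcp and n - k <= lcs
            if lcs >= 1 and lcp + lcs >= n:
                return True
    return False


def build_otu_table(otus: Sequence[OTU], samples: Sequence[str], d: int = 3) -> OTUTable:
    df = pd.DataFrame(
        {otu.otu_id: otu.counts for otu in otus}, index=list(samples)
    ).T.astype(int)
    reps = {otu.otu_id: otu.representative for otu in otus}
    return OTUTable(df=df, representatives=reps, d=d)


def abundance_filter(table: OTUTable, min_total: int = 11) -> OTUTable:
    """Keep OTUs whose whole-dataset total is >= ``min_total`` (default 11,
    i.e. 'more than 10 times in the whole dataset'); dropped OTUs are logged
    on the returned table."""
    totals = table.totals()
    keep = totals[totals >= min_total].index
    drop = totals[totals < min_total]
    if len(keep) == 0:
        logger.warning("abundance_filter: no OTU passes min_total=%d", min_total)
    removed = table.df.loc[drop.index].copy()
    filtered = OTUTable(
        df=table.df.loc[keep].copy(),
        representatives={k: table.representatives[k] for k in keep},
        d=table.d,
        removed=removed,
    )
    return filtered


def cluster_reads(
    reads_by_sample: Mapping[str, Sequence[str]],
    d: int = 3,
    min_total: int = 11,
    detect_chimeras: bool = True,
) -> tuple[OTUTable, dict[str, int]]:
    """Full pipeline: dereplicate, cluster, de-chimera, abundance-filter.

    Returns the filtered table and a conservation ledger with reads in /
    kept / chimera-removed / filter-removed counts.
    """
    derep = dereplicate(reads_by_sample)
    otus = swarm_cluster(derep, d=d)
    if detect_chimeras:
        otus, flagged = remove_chimeras(otus, d=d)
    else:
        flagged = []
    table = build_otu_table(otus, derep.samples, d=d)
    filtered = abundance_filter(table, min_total=min_total)
    ledger = {
        "reads_in": derep.total_reads,
        "reads_kept": int(filtered.df.to_numpy().sum()),
        "chimera_removed": int(sum(o.total for o in flagged)),
        "filter_removed": int(filtered.removed.to_numpy().sum()) if filtered.removed is not None else 0,
    }
    return filtered, ledger
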