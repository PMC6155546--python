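"""Truth-vs-observed comparison for mock-community runs.

Generalizes the quality-control logic of mock-community benchmarking:
composition recovery per taxonomic rank, richness recovery, paralog-ratio
recovery, and strain-cluster resolution. Observed quantities come from the
post-QC pipeline output (chimera- and abundance-filtered, assigned reads);
expected quantities trace back to the mock specification and its truth
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from gyrbench.amplicon_pipeline import OTUTable, edit_distance, _UnionFind
from gyrbench.refdb import MarkerRecord, RANKS
from gyrbench.synthetic_data import MockSpec, TruthTable
from gyrbench.diversity import merge_by_rank

__all__ = [
    "composition_recovery",
    "richness_recovery",
    "paralog_recovery",
    "strain_resolution",
    "expected_cluster_count",
    "evaluate_run",
]

_RANK_COL = {"phylum": "phylum", "species": "species"}


def composition_recovery(
    truth: TruthTable,
    assignments: pd.DataFrame,
    table: OTUTable,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Expected vs observed read fractions per taxon and sample.

    Observed fraction = assigned reads of the taxon / all assigned reads in
    the sample (post-QC denominators); expected fraction from the truth
    table's true read counts. Taxa absent from both sides yield no row.
    """
    if rank not in _RANK_COL:
        raise ValueError("composition recovery supports ranks 'phylum' and 'species'")
    observed_tbl = merge_by_rank(table, assignments, rank)
    obs_frac = observed_tbl / observed_tbl.sum(axis=0)

    rows = []
    for sample in table.samples:
        truth_sub = truth.reads[truth.reads["sample"] == sample]
        exp = truth_sub.groupby(_RANK_COL[rank])["count"].sum()
        exp_frac = exp / exp.sum()
        taxa = sorted(set(exp_frac.index) | set(obs_frac.index[obs_frac[sample] > 0]))
        for taxon in taxa:
            e = float(exp_frac.get(taxon, 0.0))
            o = float(obs_frac[sample].get(taxon, 0.0))
            if e == 0.0 and o == 0.0:
                continue
            rows.append(
                {
                    "sample": sample,
                    "rank": rank,
                    "taxon": taxon,
                    "expected": e,
                    "observed": o,
                    "abs_difference": abs(e - o),
                }
            )
    return pd.DataFrame(rows)


def richness_recovery(
    truth: TruthTable,
    assignments: pd.DataFrame,
    table: OTUTable,
    rank: str = "species",
) -> pd.DataFrame:
    """Expected vs observed taxon richness per sample.

    Expected = distinct taxa with nonzero true reads; observed = distinct
    taxa at the rank among assigned OTUs with nonzero counts.
    """
    rank_col = {"species": "species", "genus": "genus", "phylum": "phylum"}[rank]
    truth_reads = truth.reads.copy()
    if rank == "genus":  # derive genus from the species binomial
        truth_reads["genus"] = truth_reads["species"].str.split().str[0]
    observed_tbl = merge_by_rank(table, assignments, rank)
    rows = []
    for sample in table.samples:
        sub = truth_reads[(truth_reads["sample"] == sample) & (truth_reads["count"] > 0)]
        expected = sub[rank_col].nunique()
        observed = int((observed_tbl[sample] > 0).sum()) if sample in observed_tbl else 0
        rows.append(
            {"sample": sample, "rank": rank, "expected": expected, "observed": observed}
        )
    return pd.DataFrame(rows)


def paralog_recovery(
    spec: MockSpec, ratios: pd.DataFrame
) -> pd.DataFrame:
    """Expected vs observed per-species gyrB read fraction.

    Expected = 1 - parE_fraction (exactly 1.0 for Proteobacteria).
    ``ratios`` is the output of :func:`gyrbench.taxonomy.paralog_ratios` at
    species rank.
    """
    rows = []
    obs = ratios.set_index("taxon")
    for species in spec.species:
        if species not in obs.index:
            continue
        expected = 1.0 - spec.parE_fraction.get(species, 0.0)
        rows.append(
            {
                "species": species,
                "expected_gyrb_fraction": expected,
                "observed_gyrb_fraction": float(obs.loc[species, "mean_gyrb_fraction"]),
                "sd": float(obs.loc[species, "sd_gyrb_fraction"]),
                "n_samples": int(obs.loc[species, "n_samples"]),
            }
        )
    return pd.DataFrame(rows)


def expected_cluster_count(refs: Sequence[MarkerRecord], d: int = 3) -> int:
    """Number of OTUs an error-free run should produce: connected components
    of the reference amplicons at edit distance <= d (brute force)."""
    n = len(refs)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if edit_distance(refs[i].sequence, refs[j].sequence, k=d) != -1:
                uf.union(i, j)
    return len({uf.find(i) for i in range(n)})


def strain_resolution(
    truth: TruthTable,
    table: OTUTable,
    assignments: pd.DataFrame,
    species: str,
    gene: str | None = "gyrB",
    refs: Sequence[MarkerRecord] | None = None,
) -> pd.DataFrame:
    """Within-species OTU structure: each OTU's share of the species' reads.

    Restricted to OTUs assigned to ``species`` (and to ``gene``-labelled
    OTUs unless ``gene`` is None); fractions are of the species' total reads
    within that gene restriction. When ``refs`` is given, each OTU is
    cross-referenced to the truth strains whose reference amplicon is
    nearest to its representative (ties listed jointly).
    """
    sel = assignments[assignments["species"] == species]
    if gene is not None:
        sel = sel[sel["gene"] == gene]
    otu_ids = [o for o in sel["otu_id"] if o in table.df.index]
    if not otu_ids:
        return pd.DataFrame(
            columns=["otu_id", "reads", "fraction", "strains"]
        )
    counts = table.df.loc[otu_ids].sum(axis=1)
    total = float(counts.sum())
    rows = []
    for otu_id in otu_ids:
        strains = ""
        if refs is not None:
            rep = table.representatives[otu_id]
            cand = [
                r for r in refs if r.species == species and (gene is None or r.gene == gene)
            ]
            if cand:
                dists = {r.strain: edit_distance(rep, r.sequence) for r in cand}
                dmin = min(dists.values())
                strains = ",".join(sorted(s for s, v in dists.items() if v == dmin))
        rows.append(
            {
                "otu_id": otu_id,
                "reads": float(counts[otu_id]),
                "fraction": float(counts[otu_id]) / total,
                "strains": strains,
            }
        )
    out = pd.DataFrame(rows).sort_values("fraction", ascending=False, ignore_index=True)
    return out


def evaluate_run(
    spec: MockSpec,
    truth: TruthTable,
    table: OTUTable,
    assignments: pd.DataFrame,
    ratios: pd.DataFrame,
    refs: Sequence[MarkerRecord] | None = None,
) -> pd.DataFrame:
    """Full recovery report, one tidy frame with a ``section`` column."""
    sections = []
    for rank in ("phylum", "species"):
        comp = composition_recovery(truth, assignments, table, rank)
        comp.insert(0, "section", f"composition_{rank}")
        sections.append(comp)
    for rank in ("species", "genus"):
        rich = richness_recovery(truth, assignments, table, rank)
        rich.insert(0, "section", f"richness_{rank}")
        sections.append(rich)
    par = paralog_recovery(spec, ratios)
    par.insert(0, "section", "paralog_ratio")
    sections.append(par)
    if refs is not None:
        for species in spec.species:
            res = strain_resolution(truth, table, assignments, species, refs=refs)
            if not res.empty:
                res.insert(0, "section", "strain_resolution")
                res.insert(1, "species", species)
                sections.append(res)
    return pd.concat(sections, ignore_index=True)
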