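"""Mock-community simulation with parE co-amplification and qPCR truth.

The generator emulates the quality-control mock communities used to benchmark
gyrB against 16S rDNA amplicon sequencing of meat/seafood spoilage
microbiota:

* the four bundled presets MC1-MC4 encode the published mock compositions
  exactly (phylum split x within-phylum percentages x per-strain splits);
* gyrB primers co-amplify the parE paralog within Firmicutes at a
  species-dependent fraction, and never within Proteobacteria;
* reads copy their reference with i.i.d. substitution errors (an indel mode
  is available) and an optional fraction of two-parent chimeras;
* matched qPCR threshold cycles follow the two published calibration curves
  (16S probes and housekeeping-gene probes) with Gaussian Ct noise.

All randomness flows from a single seed through named substreams, so a fixed
seed yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gyrbench.insilico_pcr import IUPAC, PrimerPair, PRIMER_PRESETS, reverse_complement
from gyrbench.refdb import GenomeRecord, MarkerRecord

__all__ = [
    "CalibrationCurve",
    "CURVE_16S",
    "CURVE_HOUSEKEEPING",
    "Member",
    "MockSpec",
    "TruthTable",
    "UnrealizablePlanError",
    "STRAIN_TAXONOMY",
    "PARE_FRACTIONS",
    "DEFAULT_DIVERGENCE_PLAN",
    "MOCK_PRESETS",
    "mock_preset",
    "make_reference_set",
    "simulate_reads",
    "simulate_qpcr",
    "make_genome_records",
    "QuantPanel",
    "make_quant_panel",
    "PANEL_SPECIES",
]


# ---------------------------------------------------------------------------
# qPCR calibration


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear Ct calibration: Ct = intercept + slope * ln(CFU.g^-1)."""

    name: str
    intercept: float  # Ct at 1 CFU.g^-1
    slope: float  # Ct per ln(CFU.g^-1), < 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("calibration slope must be negative")


#: Calibration for 16S rRNA-based qPCR probes.
CURVE_16S = CalibrationCurve("16S", 39.43, -1.52)
#: Calibration for housekeeping-gene qPCR probes.
CURVE_HOUSEKEEPING = CalibrationCurve("housekeeping", 40.98, -1.44)

_CURVES = {c.name: c for c in (CURVE_16S, CURVE_HOUSEKEEPING)}


# ---------------------------------------------------------------------------
# Mock community composition


@dataclass(frozen=True)
class Member:
    """One strain of a mock community with its final community fraction."""

    strain_id: str
    taxonomy: tuple[str, ...]  # 8 ranks, strain last
    proportion: float

    @property
    def species(self) -> str:
        return self.taxonomy[6]

    @property
    def phylum(self) -> str:
        return self.taxonomy[1]


class UnrealizablePlanError(ValueError):
    """A strain divergence plan admits no star realization."""


@dataclass(frozen=True)
class MockSpec:
    """A mock community: strain proportions, parE fractions, error model."""

    name: str
    members: tuple[Member, ...]
    parE_fraction: Mapping[str, float]  # species -> fraction of reads from parE
    depth: int = 50_000
    error_rate: float = 1e-3  # substitutions per base
    indel_rate: float = 0.0  # insertions+deletions per base (optional mode)
    chimera_rate: float = 0.0  # fraction of reads that are two-parent chimeras
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(m.proportion for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"member proportions sum to {total}, expected 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for m in self.members:
            p = self.parE_fraction.get(m.species, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"parE fraction for {m.species} out of [0, 1]")
            if m.phylum != "Firmicutes" and p > 0:
                raise ValueError(
                    f"parE co-amplification is restricted to Firmicutes; "
                    f"{m.species} ({m.phylum}) has fraction {p}"
                )

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for m in self.members:
            if m.species not in out:
                out.append(m.species)
        return out

    def species_proportions(self) -> dict[str, float]:
        agg: dict[str, float] = {}
        for m in self.members:
            agg[m.species] = agg.get(m.species, 0.0) + m.proportion
        return agg

    def sample_names(self) -> list[str]:
        return [f"{self.name}_s{i + 1}" for i in range(self.n_samples)]


def _tax(phylum: str, cls: str, order: str, family: str, genus: str, species: str, strain: str) -> tuple[str, ...]:
    return ("Bacteria", phylum, cls, order, family, genus, species, strain)


def _firm(family: str, genus: str, species: str, strain: str, order: str = "Lactobacillales", cls: str = "Bacilli"):
    return _tax("Firmicutes", cls, order, family, genus, species, strain)


def _gamma(order: str, family: str, genus: str, species: str, strain: str):
    return _tax("Proteobacteria", "Gammaproteobacteria", order, family, genus, species, strain)


#: Taxonomy of every strain used in the bundled mock communities.
STRAIN_TAXONOMY: dict[str, tuple[str, ...]] = {
    # Firmicutes
    "CMTALT10": _firm("Lactobacillaceae", "Lactobacillus", "Lactobacillus algidus", "CMTALT10"),
    "23K": _firm("Lactobacillaceae", "Lactobacillus", "Lactobacillus sakei", "23K"),
    "DSM20017": _firm("Lactobacillaceae", "Lactobacillus", "Lactobacillus sakei", "DSM20017"),
    "DSM15831": _firm("Lactobacillaceae", "Lactobacillus", "Lactobacillus sakei", "DSM15831"),
    "CMTALT02": _firm("Streptococcaceae", "Lactococcus", "Lactococcus piscium", "CMTALT02"),
    "160x8": _firm("Listeriaceae", "Brochothrix", "Brochothrix thermosphacta", "160x8", order="Bacillales"),
    "cH814": _firm("Listeriaceae", "Brochothrix", "Brochothrix thermosphacta", "cH814", order="Bacillales"),
    "ATCC11509": _firm("Listeriaceae", "Brochothrix", "Brochothrix thermosphacta", "ATCC11509", order="Bacillales"),
    "MFPA43A14-05": _firm("Carnobacteriaceae", "Carnobacterium", "Carnobacterium divergens", "MFPA43A14-05"),
    "DSM20342": _firm("Carnobacteriaceae", "Carnobacterium", "Carnobacterium maltaromaticum", "DSM20342"),
    "MFPA44A14-01": _firm("Leuconostocaceae", "Leuconostoc", "Leuconostoc gelidum", "MFPA44A14-01"),
    "DSM5578": _firm("Leuconostocaceae", "Leuconostoc", "Leuconostoc gelidum", "DSM5578"),
    "MFPC16A28-05": _firm("Leuconostocaceae", "Weissella", "Weissella viridescens", "MFPC16A28-05"),
    # Proteobacteria
    "ATCC4973": _gamma("Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", "Pseudomonas fragi", "ATCC4973"),
    "MFPA15A12-05": _gamma("Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", "Pseudomonas lundensis", "MFPA15A12-05"),
    "MFPB42A12-09": _gamma("Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", "Pseudomonas lundensis", "MFPB42A12-09"),
    "PCAi-D2.2": _gamma("Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", "Pseudomonas lundensis", "PCAi-D2.2"),
    "MFPA43A14-04": _gamma("Pseudomonadales", "Moraxellaceae", "Acinetobacter", "Acinetobacter guillouiae", "MFPA43A14-04"),
    "CIP105612": _gamma("Vibrionales", "Vibrionaceae", "Photobacterium", "Photobacterium phosphoreum", "CIP105612"),
    "MFPA44A14-05": _gamma("Enterobacterales", "Yersiniaceae", "Serratia", "Serratia proteamaculans", "MFPA44A14-05"),
    "1C2F": _gamma("Enterobacterales", "Yersiniaceae", "Serratia", "Serratia proteamaculans", "1C2F"),
    "CIP103236": _gamma("Enterobacterales", "Yersiniaceae", "Serratia", "Serratia proteamaculans", "CIP103236"),
    "CIP57.31": _gamma("Enterobacterales", "Hafniaceae", "Hafnia", "Hafnia alvei", "CIP57.31"),
    "MFPA43A14-03": _gamma("Enterobacterales", "Morganellaceae", "Morganella", "Morganella psychrotolerans", "MFPA43A14-03"),
}

#: Default parE read fractions per species. Proteobacteria never co-amplify
#: parE; within Firmicutes the fraction is species-dependent.
PARE_FRACTIONS: dict[str, float] = {
    "Lactobacillus algidus": 0.80,
    "Lactobacillus sakei": 0.30,
    "Lactococcus piscium": 0.40,
    "Brochothrix thermosphacta": 0.80,
    "Carnobacterium divergens": 0.80,
    "Carnobacterium maltaromaticum": 0.85,
    "Leuconostoc gelidum": 0.75,
    "Weissella viridescens": 0.70,
}

# within-phylum strain splits (fractions of the phylum, sum to 1 per phylum)
_INTER_FIRMICUTES = {
    "CMTALT10": 0.05,
    "23K": 0.35,
    "CMTALT02": 0.10,
    "160x8": 0.05,
    "MFPA43A14-05": 0.10,
    "DSM20342": 0.10,
    "MFPA44A14-01": 0.05,
    "MFPC16A28-05": 0.20,
}
_INTER_PROTEOBACTERIA = {
    "ATCC4973": 0.20,
    "MFPA15A12-05": 0.15,
    "MFPA43A14-04": 0.05,
    "CIP105612": 0.25,
    "MFPA44A14-05": 0.10,
    "CIP57.31": 0.05,
    "MFPA43A14-03": 0.20,
}
_INTRA_FIRMICUTES = {
    "23K": 0.20,
    "DSM20017": 0.20,
    "DSM15831": 0.20,
    "160x8": 0.10,
    "cH814": 0.05,
    "ATCC11509": 0.05,
    "MFPA44A14-01": 0.15,
    "DSM5578": 0.05,
}
_INTRA_PROTEOBACTERIA = {
    "MFPA15A12-05": 0.20,
    "MFPB42A12-09": 0.10,
    "PCAi-D2.2": 0.10,
    "MFPA44A14-05": 0.20,
    "1C2F": 0.20,
    "CIP103236": 0.20,
}

#: Phylum split and within-phylum strain tables per preset.
MOCK_PRESETS: dict[str, tuple[float, dict[str, float], dict[str, float]]] = {
    # (Firmicutes fraction, Firmicutes strains, Proteobacteria strains)
    "MC1": (0.99, _INTER_FIRMICUTES, _INTER_PROTEOBACTERIA),
    "MC2": (0.50, _INTER_FIRMICUTES, _INTER_PROTEOBACTERIA),
    "MC3": (0.01, _INTER_FIRMICUTES, _INTER_PROTEOBACTERIA),
    "MC4": (0.65, _INTRA_FIRMICUTES, _INTRA_PROTEOBACTERIA),
}

#: Planned pairwise edit distances between intra-species strain amplicons.
#: The L. sakei plan makes 23K and DSM15831 co-cluster at swarm d=3 while
#: DSM20017 stays a separate cluster; B. thermosphacta is clonal.
DEFAULT_DIVERGENCE_PLAN: dict[str, dict[frozenset[str], int]] = {
    "Lactobacillus sakei": {
        frozenset({"23K", "DSM15831"}): 2,
        frozenset({"23K", "DSM20017"}): 8,
        frozenset({"DSM15831", "DSM20017"}): 8,
    },
    "Brochothrix thermosphacta": {
        frozenset({"160x8", "cH814"}): 0,
        frozenset({"160x8", "ATCC11509"}): 0,
        frozenset({"cH814", "ATCC11509"}): 0,
    },
    "Pseudomonas lundensis": {
        frozenset({"MFPA15A12-05", "MFPB42A12-09"}): 2,
        frozenset({"MFPA15A12-05", "PCAi-D2.2"}): 2,
        frozenset({"MFPB42A12-09", "PCAi-D2.2"}): 2,
    },
    "Serratia proteamaculans": {
        frozenset({"MFPA44A14-05", "1C2F"}): 2,
        frozenset({"MFPA44A14-05", "CIP103236"}): 2,
        frozenset({"1C2F", "CIP103236"}): 2,
    },
    "Leuconostoc gelidum": {
        frozenset({"MFPA44A14-01", "DSM5578"}): 12,
    },
}


def mock_preset(name: str, **overrides) -> MockSpec:
    """Build a bundled mock community (MC1-MC4).

    Keyword overrides are forwarded to :class:`MockSpec` (``depth``,
    ``error_rate``, ``chimera_rate``, ``n_samples``, ``seed``...).
    """
    if name not in MOCK_PRESETS:
        raise KeyError(f"unknown mock preset {name!r}; available: {sorted(MOCK_PRESETS)}")
    firm_frac, firm, prot = MOCK_PRESETS[name]
    members = []
    for table, phylum_frac in ((firm, firm_frac), (prot, 1.0 - firm_frac)):
        for strain_id, within in table.items():
            members.append(
                Member(strain_id, STRAIN_TAXONOMY[strain_id], phylum_frac * within)
            )
    return MockSpec(name=name, members=tuple(members), parE_fraction=dict(PARE_FRACTIONS), **overrides)


# ---------------------------------------------------------------------------
# Reference sequence construction

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BYTE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_IDX[_b] = _i


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASE_BYTES[rng.integers(0, 4, size=length)]


def _mutate(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each given position with a uniformly-chosen different base."""
    out = arr.copy()
    if len(positions) == 0:
        return out
    idx = _BYTE_TO_IDX[out[positions]]
    shift = rng.integers(1, 4, size=len(positions))
    out[positions] = _BASE_BYTES[(idx + shift) % 4]
    return out


def _mutate_fraction(arr: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    k = int(round(fraction * len(arr)))
    pos = rng.choice(len(arr), size=k, replace=False)
    return _mutate(arr, pos, rng)


def _star_weights(strains: Sequence[str], plan: Mapping[frozenset[str], int]) -> dict[str, int]:
    """Decompose planned pairwise distances into per-strain star weights.

    A plan is realizable here when distances admit an additive star
    d(i, j) = x_i + x_j with nonnegative integer x; substitutions at disjoint
    position sets then realize it exactly.
    """

    def d(a: str, b: str) -> int:
        key = frozenset({a, b})
        if key not in plan:
            raise UnrealizablePlanError(f"no planned distance for strain pair {a}, {b}")
        return plan[key]

    if len(strains) == 1:
        return {strains[0]: 0}
    if len(strains) == 2:
        a, b = strains
        return {a: 0, b: d(a, b)}
    weights: dict[str, int] = {}
    for i, s in enumerate(strains):
        j, k = [t for t in strains if t != s][:2]
        num = d(s, j) + d(s, k) - d(j, k)
        if num < 0 or num % 2:
            raise UnrealizablePlanError(
                f"plan for strains {list(strains)} is not an additive integer star"
            )
        weights[s] = num // 2
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            if weights[a] + weights[b] != d(a, b):
                raise UnrealizablePlanError(
                    f"planned distance {d(a, b)} for ({a}, {b}) inconsistent with star"
                )
    return weights


def _edit_distance(a: str, b: str, k: int | None = None) -> int:
    import edlib

    res = edlib.align(a, b, mode="NW", task="distance", k=-1 if k is None else k)
    return res["editDistance"]


def make_reference_set(
    spec: MockSpec,
    divergence_plan: Mapping[str, Mapping[frozenset[str], int]] | None = None,
    length: int = 280,
    seed: int | None = None,
    min_species_distance: int = 7,
    min_paralog_divergence: float = 0.20,
) -> list[MarkerRecord]:
    """Generate gyrB (and, within Firmicutes, parE) reference amplicons.

    One gyrB amplicon is emitted per strain; species with a positive parE
    fraction additionally get one parE amplicon per strain. Intra-species
    strain sequences realize the planned pairwise edit distances through
    substitutions at disjoint positions; species backbones diverge along a
    two-phylum hierarchy, and parE backbones branch off the Firmicutes gyrB
    ancestor far enough to keep every parE >= ``min_paralog_divergence`` of
    the length away from every gyrB.

    The realized set is verified (inter-species pairs >= ``min_species_distance``
    edits for the same gene; gyrB-parE pairs >= the paralog floor) and a
    violation raises ``RuntimeError``.
    """
    plan = DEFAULT_DIVERGENCE_PLAN if divergence_plan is None else divergence_plan
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    root = _random_seq(length, rng)
    anc = {
        "Firmicutes": _mutate_fraction(root, 0.05, rng),
        "Proteobacteria": _mutate_fraction(root, 0.30, rng),
    }
    pare_anc = _mutate_fraction(anc["Firmicutes"], 0.25, rng)

    by_species: dict[str, list[Member]] = {}
    for m in spec.members:
        by_species.setdefault(m.species, []).append(m)

    records: list[MarkerRecord] = []
    for species, members in by_species.items():
        phylum = members[0].phylum
        strains = [m.strain_id for m in members]
        weights = _star_weights(strains, plan.get(species, {}))
        genes = [("gyrB", _mutate_fraction(anc[phylum], 0.10, rng))]
        if spec.parE_fraction.get(species, 0.0) > 0:
            genes.append(("parE", _mutate_fraction(pare_anc, 0.10, rng)))
        for gene, base in genes:
            total = sum(weights.values())
            if total > length:
                raise UnrealizablePlanError(
                    f"plan for {species} needs {total} sites, amplicon length is {length}"
                )
            pool = rng.choice(length, size=total, replace=False)
            offset = 0
            for member in members:
                w = weights[member.strain_id]
                pos = pool[offset : offset + w]
                offset += w
                seq = _mutate(base, pos, rng)
                records.append(
                    MarkerRecord(
                        marker_id=f"{member.strain_id}_{gene}",
                        taxonomy=member.taxonomy,
                        gene=gene,
                        sequence=seq.tobytes().decode(),
                    )
                )

    _verify_reference_set(records, min_species_distance, min_paralog_divergence, length)
    return records


def _verify_reference_set(
    records: Sequence[MarkerRecord],
    min_species_distance: int,
    min_paralog_divergence: float,
    length: int,
) -> None:
    floor = int(math.ceil(min_paralog_divergence * length))
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            if a.gene != b.gene:
                if _edit_distance(a.sequence, b.sequence, k=floor) != -1 and not (
                    _edit_distance(a.sequence, b.sequence) >= floor
                ):
                    raise RuntimeError(
                        f"paralog divergence violated: {a.marker_id} vs {b.marker_id}"
                    )
            elif a.species != b.species:
                d = _edit_distance(a.sequence, b.sequence, k=min_species_distance)
                if d != -1 and d < min_species_distance:
                    raise RuntimeError(
                        f"inter-species distance violated: {a.marker_id} vs {b.marker_id} ({d})"
                    )


# ---------------------------------------------------------------------------
# Read and qPCR simulation


@dataclass
class TruthTable:
    """Ground truth of a simulated run.

    ``reads``: per (sample, strain, gene) true read counts (sum = depth per
    sample). ``loads``: per (sample, species) CFU.g^-1; ``totals``: total
    bacterial load Q per sample. ``chimeras``: chimeric reads emitted on top
    of the true counts.
    """

    reads: pd.DataFrame
    loads: pd.DataFrame
    totals: pd.DataFrame
    chimeras: dict[str, int] = field(default_factory=dict)

    def phylum_fractions(self, sample: str) -> pd.Series:
        sub = self.reads[self.reads["sample"] == sample]
        frac = sub.groupby("phylum")["count"].sum()
        return frac / frac.sum()

    def species_fractions(self, sample: str) -> pd.Series:
        sub = self.reads[self.reads["sample"] == sample]
        frac = sub.groupby("species")["count"].sum()
        return frac / frac.sum()


def _apply_substitutions(
    template: np.ndarray, count: int, error_rate: float, rng: np.random.Generator
) -> list[str]:
    """Copy ``template`` ``count`` times with i.i.d. substitution errors."""
    L = len(template)
    block = np.tile(template, (count, 1))
    if error_rate > 0:
        mask = rng.random((count, L)) < error_rate
        rows, cols = np.nonzero(mask)
        if len(rows):
            idx = _BYTE_TO_IDX[block[rows, cols]]
            shift = rng.integers(1, 4, size=len(rows))
            block[rows, cols] = _BASE_BYTES[(idx + shift) % 4]
    return [row.tobytes().decode() for row in block]


def _apply_indels(seq: str, rng: np.random.Generator, indel_rate: float) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < indel_rate / 2:  # deletion
            continue
        out.append(ch)
        if r > 1 - indel_rate / 2:  # insertion after the base
            out.append("ACGT"[rng.integers(0, 4)])
    return "".join(out)


def simulate_reads(
    spec: MockSpec,
    refs: Sequence[MarkerRecord],
    seed: int | None = None,
) -> tuple[dict[str, list[str]], TruthTable]:
    """Draw amplicon reads for every sample of a mock community.

    Read counts per (strain, gene) class are multinomial with probability
    proportional to the strain proportion times the species parE split; each
    read copies its reference with substitution errors at ``spec.error_rate``
    (plus optional indels), and ``spec.chimera_rate`` of the depth is emitted
    additionally as two-parent chimeras with a uniform breakpoint. Matched
    per-sample total loads and per-species CFU are drawn for the qPCR side.

    Returns ``(reads_by_sample, truth)``; deterministic for a fixed seed.
    """
    if not refs:
        raise ValueError("empty reference set")
    base_seed = spec.seed if seed is None else seed
    ref_by_key = {(r.strain, r.gene): r for r in refs}

    classes: list[tuple[Member, str, MarkerRecord, float]] = []
    for member in spec.members:
        p = spec.parE_fraction.get(member.species, 0.0)
        for gene, weight in (("gyrB", 1.0 - p), ("parE", p)):
            if weight <= 0:
                continue
            ref = ref_by_key.get((member.strain_id, gene))
            if ref is None:
                raise ValueError(
                    f"reference set lacks {gene} amplicon for strain {member.strain_id}"
                )
            classes.append((member, gene, ref, member.proportion * weight))
    probs = np.array([c[3] for c in classes])
    probs = probs / probs.sum()
    templates = [
        np.frombuffer(c[2].sequence.encode(), dtype=np.uint8) for c in classes
    ]

    reads_by_sample: dict[str, list[str]] = {}
    truth_rows: list[dict] = []
    load_rows: list[dict] = []
    total_rows: list[dict] = []
    chimeras: dict[str, int] = {}
    species_prop = spec.species_proportions()

    for s_idx, sample in enumerate(spec.sample_names()):
        rng = np.random.default_rng([base_seed, 7, s_idx])
        counts = rng.multinomial(spec.depth, probs)
        reads: list[str] = []
        for k, ((member, gene, _ref, _w), count) in enumerate(zip(classes, counts)):
            if count:
                reads.extend(_apply_substitutions(templates[k], count, spec.error_rate, rng))
            truth_rows.append(
                {
                    "sample": sample,
                    "strain_id": member.strain_id,
                    "species": member.species,
                    "phylum": member.phylum,
                    "gene": gene,
                    "count": int(count),
                }
            )
        if spec.indel_rate > 0:
            reads = [_apply_indels(r, rng, spec.indel_rate) for r in reads]
        n_chim = int(rng.binomial(spec.depth, spec.chimera_rate)) if spec.chimera_rate else 0
        for _ in range(n_chim):
            i, j = rng.choice(len(refs), size=2, replace=False)
            a, b = refs[i].sequence, refs[j].sequence
            bp = int(rng.integers(1, min(len(a), len(b))))
            reads.append(a[:bp] + b[bp:])
        chimeras[sample] = n_chim
        reads_by_sample[sample] = reads

        total_load = float(10 ** (8.0 + 0.3 * rng.standard_normal()))
        total_rows.append({"sample": sample, "cfu": total_load})
        for species, prop in species_prop.items():
            load_rows.append({"sample": sample, "species": species, "cfu": total_load * prop})

    truth = TruthTable(
        reads=pd.DataFrame(truth_rows),
        loads=pd.DataFrame(load_rows),
        totals=pd.DataFrame(total_rows),
        chimeras=chimeras,
    )
    return reads_by_sample, truth


def simulate_qpcr(
    truth: TruthTable,
    noise_sd: float = 0.15,
    seed: int = 0,
    species_curve: CalibrationCurve = CURVE_HOUSEKEEPING,
    total_curve: CalibrationCurve = CURVE_16S,
    species: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Simulate qPCR threshold cycles from the truth's CFU loads.

    Species-specific probes follow the housekeeping calibration; the
    all-bacteria probe (reported under species ``all_bacteria``) follows the
    16S calibration. Ct = intercept + slope * ln(CFU) + N(0, noise_sd); exact
    at ``noise_sd=0``.
    """
    rng = np.random.default_rng([seed, 11])
    rows: list[dict] = []
    wanted = None if species is None else set(species)
    for _, rec in truth.loads.iterrows():
        if wanted is not None and rec["species"] not in wanted:
            continue
        rows.append(
            {
                "species": rec["species"],
                "sample": rec["sample"],
                "Ct": _ct(rec["cfu"], species_curve, noise_sd, rng),
                "curve": species_curve.name,
            }
        )
    for _, rec in truth.totals.iterrows():
        rows.append(
            {
                "species": "all_bacteria",
                "sample": rec["sample"],
                "Ct": _ct(rec["cfu"], total_curve, noise_sd, rng),
                "curve": total_curve.name,
            }
        )
    return pd.DataFrame(rows)


def _ct(cfu: float, curve: CalibrationCurve, noise_sd: float, rng: np.random.Generator) -> float:
    if cfu <= 0:
        raise ValueError(f"CFU must be > 0, got {cfu}")
    ct = curve.intercept + curve.slope * math.log(cfu)
    if noise_sd > 0:
        ct += noise_sd * rng.standard_normal()
    return float(ct)


# ---------------------------------------------------------------------------
# Synthetic annotated genomes (for exercising the database builder)


def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC[c])[rng.integers(0, len(IUPAC[c]))] for c in primer)


def make_genome_records(
    refs: Sequence[MarkerRecord],
    primers: PrimerPair | None = None,
    seed: int = 0,
    flank: int = 50,
) -> list[GenomeRecord]:
    """Embed reference amplicons in synthetic annotated genome records.

    Each strain becomes one genome record whose gyrB/parE genes consist of a
    random flank, a concrete realization of the forward primer site, the
    amplicon insert, the plus-strand reverse primer site, and a trailing
    flank - so in-silico PCR over these genomes recovers the original
    reference set.
    """
    primers = PRIMER_PRESETS["gyrB"] if primers is None else primers
    rng = np.random.default_rng([seed, 13])
    by_strain: dict[str, list[MarkerRecord]] = {}
    for r in refs:
        by_strain.setdefault(r.strain or r.marker_id, []).append(r)
    genomes: list[GenomeRecord] = []
    for strain, markers in by_strain.items():
        genes = []
        for m in markers:
            fsite = _realize_primer(primers.forward, rng)
            rsite = reverse_complement(_realize_primer(primers.reverse, rng))
            left = _random_seq(flank, rng).tobytes().decode()
            right = _random_seq(flank, rng).tobytes().decode()
            genes.append((m.gene, left + fsite + m.sequence + rsite + right))
        genomes.append(GenomeRecord(strain, markers[0].taxonomy, tuple(genes)))
    return genomes


# ---------------------------------------------------------------------------
# qPCR quantification panel


#: The 13-species quantification panel: (species, phylum, amplification bias
#: in log10 units). Two species carry strong biases - one over-amplified, one
#: under-amplified - mirroring the over/underestimation structure seen in
#: real food-sample quantification; the rest are close to unbiased.
PANEL_SPECIES: tuple[tuple[str, str, float], ...] = (
    ("Lactobacillus algidus", "Firmicutes", 1.3),
    ("Lactobacillus sakei", "Firmicutes", 0.0),
    ("Lactococcus piscium", "Firmicutes", 0.0),
    ("Brochothrix thermosphacta", "Firmicutes", -1.2),
    ("Carnobacterium divergens", "Firmicutes", 0.0),
    ("Leuconostoc gelidum", "Firmicutes", 0.0),
    ("Weissella viridescens", "Firmicutes", 0.0),
    ("Pseudomonas fragi", "Proteobacteria", 0.0),
    ("Acinetobacter guillouiae", "Proteobacteria", 0.0),
    ("Photobacterium phosphoreum", "Proteobacteria", 0.0),
    ("Serratia proteamaculans", "Proteobacteria", 0.0),
    ("Hafnia alvei", "Proteobacteria", -0.4),
    ("Morganella psychrotolerans", "Proteobacteria", 0.0),
)


@dataclass
class QuantPanel:
    """A synthetic multi-sample quantification panel.

    ``reads``: per (species, sample) raw read counts; ``qpcr``: Ct table
    including ``all_bacteria`` rows; ``meta``: species, phylum and the
    generating amplification bias (log10); ``depth``: reads per sample.
    """

    reads: pd.DataFrame
    qpcr: pd.DataFrame
    meta: pd.DataFrame
    depth: int


def make_quant_panel(
    n_samples: int = 20,
    depth: int = 50_000,
    read_sigma: float = 0.3,
    ct_noise_sd: float = 0.15,
    bias_wobble_sd: float = 0.1,
    seed: int = 0,
) -> QuantPanel:
    """Simulate the 13-species qPCR/read-count panel.

    Per sample, species loads are drawn log-uniform over 1e4-1e9 CFU.g^-1;
    read counts are multinomial with weights load x 10^(bias + noise), where
    the per-observation noise is N(0, ``read_sigma``) in log10 units;
    species Ct values follow the housekeeping calibration and the
    all-bacteria Ct the 16S calibration, both with Gaussian Ct noise.
    """
    rng = np.random.default_rng([seed, 17])
    species = [s for s, _, _ in PANEL_SPECIES]
    phyla = {s: p for s, p, _ in PANEL_SPECIES}
    bias = {
        s: b + (bias_wobble_sd * rng.standard_normal() if b == 0.0 else 0.0)
        for s, _, b in PANEL_SPECIES
    }

    read_rows, qpcr_rows = [], []
    for i in range(n_samples):
        sample = f"panel_s{i + 1:02d}"
        log_load = rng.uniform(4.0, 9.0, size=len(species))
        loads = 10.0 ** log_load
        weights = loads * 10.0 ** (
            np.array([bias[s] for s in species]) + read_sigma * rng.standard_normal(len(species))
        )
        counts = rng.multinomial(depth, weights / weights.sum())
        for sp, load, nr in zip(species, loads, counts):
            read_rows.append({"species": sp, "sample": sample, "nr": int(nr)})
            qpcr_rows.append(
                {
                    "species": sp,
                    "sample": sample,
                    "Ct": _ct(load, CURVE_HOUSEKEEPING, ct_noise_sd, rng),
                    "curve": CURVE_HOUSEKEEPING.name,
                }
            )
        qpcr_rows.append(
            {
                "species": "all_bacteria",
                "sample": sample,
                "Ct": _ct(float(loads.sum()), CURVE_16S, ct_noise_sd, rng),
                "curve": CURVE_16S.name,
            }
        )
    meta = pd.DataFrame(
        {"species": species, "phylum": [phyla[s] for s in species], "bias": [bias[s] for s in species]}
    )
    return QuantPanel(pd.DataFrame(read_rows), pd.DataFrame(qpcr_rows), meta, depth)
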