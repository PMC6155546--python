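"""End-to-end orchestration: simulate -> build-db -> cluster -> assign ->
quantify -> diversity -> phylo -> evaluate.

A :class:`RunConfig` (single key-value config; CLI flags override) drives
:func:`run_all`, which executes every stage in order, writes plot-ready
tables into the output directory, and records a manifest (parameter values,
package version, SHA-256 checksums of every output). All randomness derives
from the single master seed through named substreams, so re-running with the
same config yields byte-identical tabular outputs. A stage failure leaves a
``FAILED`` marker beside any partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

import gyrbench
from gyrbench.amplicon_pipeline import OTUTable, cluster_reads
from gyrbench.diversity import (
    bray_curtis_matrix,
    composition_table,
    median_depth_normalize,
    merge_by_rank,
    pcoa,
    rarefaction_curve,
    richness,
)
from gyrbench.evaluation import evaluate_run
from gyrbench.insilico_pcr import PRIMER_PRESETS, PrimerPair
from gyrbench.phylo import build_marker_tree
from gyrbench.quantify import build_quant_records, fit_quant_model, species_deviation
from gyrbench.refdb import build_database, write_marker_fasta, write_marker_tsv
from gyrbench.synthetic_data import (
    MOCK_PRESETS,
    MockSpec,
    mock_preset,
    make_genome_records,
    make_reference_set,
    simulate_qpcr,
    simulate_reads,
)
from gyrbench.taxonomy import assign_all, paralog_ratios

__all__ = ["RunConfig", "RunResult", "run_all", "write_reads_fasta", "read_reads_dir"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one synthetic benchmark run."""

    preset: str = "MC1"
    depth: int = 50_000
    error_rate: float = 1e-3
    chimera_rate: float = 0.0
    indel_rate: float = 0.0
    n_samples: int = 1
    d: int = 3
    min_total: int = 11
    seed: int = 0
    primer_preset: str = "gyrB"
    amplicon_length: int = 280
    qpcr_noise_sd: float = 0.15
    qpcr_path: str | None = None  # external Ct table instead of simulation
    out_dir: str = "gyrbench_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.preset not in MOCK_PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {sorted(MOCK_PRESETS)}"
            )
        if self.primer_preset not in PRIMER_PRESETS:
            raise ValueError(f"unknown primer preset {self.primer_preset!r}")
        if self.qpcr_path is not None and not Path(self.qpcr_path).exists():
            raise FileNotFoundError(f"qPCR table not found: {self.qpcr_path}")

    def mock_spec(self) -> MockSpec:
        return mock_preset(
            self.preset,
            depth=self.depth,
            error_rate=self.error_rate,
            chimera_rate=self.chimera_rate,
            indel_rate=self.indel_rate,
            n_samples=self.n_samples,
            seed=self.seed,
        )


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    refs: list
    db: list
    truth: object
    table: OTUTable
    assignments: pd.DataFrame
    ratios: pd.DataFrame
    quant: pd.DataFrame
    fits: pd.DataFrame
    deviations: pd.DataFrame
    report: pd.DataFrame
    manifest: dict


def write_reads_fasta(reads_by_sample: Mapping[str, Sequence[str]], out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, reads in reads_by_sample.items():
        path = out / f"{sample}.fasta"
        with open(path, "w") as fh:
            for i, read in enumerate(reads, 1):
                fh.write(f">{sample}_read{i}\n{read}\n")
        paths.append(path)
    return paths


def read_reads_dir(reads_dir: str | Path) -> dict[str, list[str]]:
    from Bio import SeqIO

    reads: dict[str, list[str]] = {}
    for path in sorted(Path(reads_dir).glob("*.fasta")):
        reads[path.stem] = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
    if not reads:
        raise FileNotFoundError(f"no .fasta files under {reads_dir}")
    return reads


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def quantify_run(
    table: OTUTable, assignments: pd.DataFrame, qpcr: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Species-level quantification of a clustered, assigned run.

    Counts are merged to species over both gene labels (parE reads count
    toward their species), normalized to the median sequencing depth (Nt),
    joined with qPCR loads, and fitted per phylum stratum. Returns
    (quant records, fit summary, per-species deviations).
    """
    norm = median_depth_normalize(table)
    by_species = merge_by_rank(norm, assignments, "species")
    nt_by_sample = {s: float(norm.df[s].sum()) for s in norm.samples}
    reads = (
        by_species.stack()
        .rename_axis(["species", "sample"])
        .reset_index(name="nr")
    )
    phylum_by_species = (
        assignments[assignments["species"] != ""]
        .drop_duplicates("species")
        .set_index("species")["phylum"]
        .to_dict()
    )
    quant = build_quant_records(reads, qpcr, nt_by_sample, phylum_by_species)
    fits_rows, dev_frames = [], []
    for stratum, group in quant.groupby("stratum"):
        try:
            fit = fit_quant_model(group, stratum=stratum)
        except ValueError as exc:
            logger.warning("quantify: %s", exc)
            continue
        fits_rows.append(
            {
                "stratum": stratum,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "n": int(len(fit.residuals)),
            }
        )
        dev = species_deviation(fit, group)
        dev.insert(0, "stratum", stratum)
        dev_frames.append(dev)
    fits = pd.DataFrame(fits_rows)
    deviations = (
        pd.concat(dev_frames, ignore_index=True) if dev_frames else pd.DataFrame()
    )
    return quant, fits, deviations


def run_all(config: RunConfig) -> RunResult:
    """Execute the full synthetic benchmark and write all outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        result = _run_stages(config, out)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return result


def _run_stages(config: RunConfig, out: Path) -> RunResult:
    spec = config.mock_spec()
    primers = PRIMER_PRESETS[config.primer_preset]

    refs = make_reference_set(spec, length=config.amplicon_length)
    genomes = make_genome_records(refs, primers, seed=spec.seed)
    db = build_database(genomes, primers, gene_names=("gyrB", "parE"))
    write_marker_fasta(db, out / "db.fasta")
    write_marker_tsv(db, out / "db.tsv")

    reads, truth = simulate_reads(spec, refs)
    write_reads_fasta(reads, out / "reads")
    _write_tsv(truth.reads, out / "truth_reads.tsv")
    _write_tsv(truth.loads, out / "truth_loads.tsv")
    _write_tsv(truth.totals, out / "truth_totals.tsv")

    if config.qpcr_path is not None:
        qpcr = pd.read_csv(config.qpcr_path, sep="\t")
    else:
        qpcr = simulate_qpcr(truth, noise_sd=config.qpcr_noise_sd, seed=spec.seed)
    _write_tsv(qpcr, out / "qpcr.tsv")

    table, ledger = cluster_reads(reads, d=config.d, min_total=config.min_total)
    _write_tsv(table.df, out / "otu_table.tsv", index=True)
    with open(out / "representatives.fasta", "w") as fh:
        for otu_id, rep in table.representatives.items():
            fh.write(f">{otu_id}\n{rep}\n")

    assignments = assign_all(table, db)
    _write_tsv(assignments, out / "assignments.tsv")
    ratios = paralog_ratios(assignments, table, rank="species")
    _write_tsv(ratios, out / "paralog_ratios.tsv")

    quant, fits, deviations = quantify_run(table, assignments, qpcr)
    _write_tsv(quant, out / "quant.tsv")
    _write_tsv(fits, out / "quant_fits.tsv")
    _write_tsv(deviations, out / "quant_deviations.tsv")

    div_dir = out / "diversity"
    div_dir.mkdir(exist_ok=True)
    rich = pd.DataFrame(
        {
            "otu": richness(table),
            "species": richness(table, "species", assignments),
            "genus": richness(table, "genus", assignments),
        }
    ).rename_axis("sample")
    _write_tsv(rich, div_dir / "richness.tsv", index=True)
    _write_tsv(rarefaction_curve(table), div_dir / "rarefaction.tsv")
    for rank in ("phylum", "genus"):
        _write_tsv(
            composition_table(table, assignments, rank),
            div_dir / f"composition_{rank}.tsv",
            index=True,
        )
    norm = median_depth_normalize(table)
    genus_tbl = merge_by_rank(norm, assignments, "genus")
    if len(table.samples) >= 2:
        dm = bray_curtis_matrix(genus_tbl)
        _write_tsv(dm, div_dir / "bray_curtis.tsv", index=True)
        ord_ = pcoa(dm)
        coords = ord_.coordinates.copy()
        coords.columns = [
            f"{ax} ({100 * p:.1f}%)"
            for ax, p in zip(coords.columns, ord_.proportion_explained)
        ]
        _write_tsv(coords.rename_axis("sample"), div_dir / "pcoa.tsv", index=True)

    tree = build_marker_tree(db)
    tree.write(str(out / "marker_tree.nwk"))

    report = evaluate_run(spec, truth, table, assignments, ratios, refs=refs)
    _write_tsv(report, out / "report.tsv")

    manifest = {
        "package": "gyrbench",
        "version": gyrbench.__version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "read_ledger": ledger,
        "files": {},
    }
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(
        config=config,
        refs=refs,
        db=db,
        truth=truth,
        table=table,
        assignments=assignments,
        ratios=ratios,
        quant=quant,
        fits=fits,
        deviations=deviations,
        report=report,
        manifest=manifest,
    )
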