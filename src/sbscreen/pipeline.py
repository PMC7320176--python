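"""End-to-end orchestration from a single YAML configuration.

The configuration has per-stage sections (``simulate``, ``readproc``,
``cis``, ``classify``) plus a top-level ``seed`` and ``outdir``. Unknown keys
anywhere are rejected with the offending key name. Every stochastic stage
derives its own deterministic sub-seed from the top-level seed, so an
identical configuration reproduces byte-identical outputs. The run report
embeds all parameters, seeds and per-stage record counts, making it
sufficient to re-run the pipeline exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import io as sio
from .cis import gene_cis_scan, recurrence_filter
from .classify import classify_genes
from .errors import ConfigError, DataError
from .genes import GeneCatalog
from .readproc import AdapterConfig, process_reads, Reference
from .simulate import (
    CatalogConfig,
    DriverSpec,
    ReadConfig,
    ScreenConfig,
    make_gene_catalog,
    random_genome,
    simulate_screen,
    emit_reads,
)

_TOP_KEYS = {"seed", "outdir", "simulate", "readproc", "cis", "classify"}
_SIM_KEYS = {"chrom_lengths", "n_genes", "gene_length", "n_exons",
             "n_tumours", "background_rate", "donor_chrom", "hopping_factor",
             "drivers", "with_sequence", "reads"}
_READ_KEYS = {"read_length", "flank_length", "reads_per_site", "error_rate",
              "contaminant_fraction"}
_READPROC_KEYS = {"fastq", "reference", "mismatch_tolerance", "max_mismatches"}
_CIS_KEYS = {"alpha", "theta", "exclude_donor", "upstream", "genome_length"}
_CLASSIFY_KEYS = {"alpha", "window_frac", "cluster_threshold", "min_insertions"}


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with path.open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    if "seed" not in cfg:
        raise ConfigError("top-level 'seed' is required")
    return cfg


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: Mapping[str, Any], outdir: str | Path | None = None) -> dict:
    """Execute the configured stages in dependency order; returns the report.

    With a ``simulate`` section, a genome/catalog/screen/reads are generated;
    otherwise ``readproc.fastq`` + ``readproc.reference`` (or a pre-mapped
    insertion TSV) must exist. All outputs and the JSON report are written
    under ``outdir``.
    """
    _check_keys(config, _TOP_KEYS, "top level")
    seed = config.get("seed")
    if seed is None:
        raise ConfigError("top-level 'seed' is required")
    outdir = Path(outdir or config.get("outdir", "sbscreen_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    s_catalog, s_screen, s_reads = _subseeds(seed, 3)
    report: dict[str, Any] = {"seed": int(seed), "outdir": str(outdir),
                              "stages": {}}

    catalog: GeneCatalog | None = None
    insertions = None
    truth = None

    sim = config.get("simulate")
    if sim:
        _check_keys(sim, _SIM_KEYS, "simulate")
        chroms = {str(c): int(n) for c, n in sim["chrom_lengths"].items()}
        cat_cfg = CatalogConfig(
            chrom_lengths=chroms,
            n_genes=int(sim.get("n_genes", 20)),
            gene_length=int(sim.get("gene_length", 10_000)),
            n_exons=int(sim.get("n_exons", 10)),
            seed=s_catalog,
        )
        catalog = make_gene_catalog(cat_cfg)
        catalog.to_tsv(outdir / "catalog.tsv")
        drivers = [
            DriverSpec(
                gene_id=d["gene_id"],
                driver_class=d["class"],
                penetrance=d.get("penetrance", 0.2),
                hotspot=tuple(d["hotspot"]) if d.get("hotspot") else None,
                sense_prob=float(d.get("sense_prob", 0.5)),
            )
            for d in sim.get("drivers", [])
        ]
        with_seq = bool(sim.get("with_sequence", False))
        genome = random_genome(chroms, seed=s_catalog + 1) if with_seq else None
        screen_cfg = ScreenConfig(
            n_tumours={(str(s), str(c)): int(n)
                       for s, groups in sim["n_tumours"].items()
                       for c, n in groups.items()},
            background_rate=float(sim.get("background_rate", 50.0)),
            donor_chrom=sim.get("donor_chrom"),
            hopping_factor=float(sim.get("hopping_factor", 3.0)),
            drivers=drivers,
            seed=s_screen,
        )
        insertions, truth = simulate_screen(catalog, screen_cfg, genome=genome)
        sio.write_insertions(insertions, outdir / "insertions_truth.tsv")
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        report["stages"]["simulate"] = {
            "seed_catalog": s_catalog, "seed_screen": s_screen,
            "n_genes": len(catalog), "n_insertions": int(len(insertions)),
            "n_tumours": int(insertions["tumour_id"].nunique()) if len(insertions) else 0,
            "n_driver_insertions": int(len(truth)),
        }
        if genome is not None:
            sio.write_fasta(genome, outdir / "genome.fa")
            read_section = sim.get("reads", {})
            _check_keys(read_section, _READ_KEYS, "simulate.reads")
            read_cfg = ReadConfig(seed=s_reads, **{
                k: read_section[k] for k in read_section})
            reads = emit_reads(insertions, genome, read_cfg)
            sio.write_fastq(reads, outdir / "reads.fastq")
            report["stages"]["emit_reads"] = {
                "seed": s_reads, "n_reads": len(reads),
                "error_rate": read_cfg.error_rate,
                "contaminant_fraction": read_cfg.contaminant_fraction,
            }
            # feed the sequencing path downstream instead of the truth table
            rp = config.get("readproc", {})
            _check_keys(rp, _READPROC_KEYS, "readproc")
            adapter_cfg = AdapterConfig(
                mismatch_tolerance=float(rp.get("mismatch_tolerance", 0.10)),
                max_mismatches=int(rp.get("max_mismatches", 3)),
            )
            insertions, tally = process_reads(reads, Reference(genome), adapter_cfg)
            sio.write_insertions(insertions, outdir / "insertions.tsv")
            sio.write_bed(insertions, outdir / "insertions.bed")
            report["stages"]["readproc"] = {
                "input_reads": len(reads), **{k: int(v) for k, v in tally.items()}}
        else:
            sio.write_insertions(insertions, outdir / "insertions.tsv")
    else:
        rp = config.get("readproc")
        if not rp:
            raise ConfigError("either a simulate or a readproc section is required")
        _check_keys(rp, _READPROC_KEYS, "readproc")
        fastq = rp.get("fastq")
        ref_path = rp.get("reference")
        if not fastq or not ref_path:
            raise ConfigError("readproc needs 'fastq' and 'reference' paths")
        reads = sio.read_fastq(fastq)
        genome = sio.read_fasta(ref_path)
        adapter_cfg = AdapterConfig(
            mismatch_tolerance=float(rp.get("mismatch_tolerance", 0.10)),
            max_mismatches=int(rp.get("max_mismatches", 3)),
        )
        insertions, tally = process_reads(reads, Reference(genome), adapter_cfg)
        sio.write_insertions(insertions, outdir / "insertions.tsv")
        report["stages"]["readproc"] = {
            "input_reads": len(reads), **{k: int(v) for k, v in tally.items()}}

    cis_cfg = config.get("cis", {})
    _check_keys(cis_cfg, _CIS_KEYS, "cis")
    if catalog is None:
        raise ConfigError("CIS stage requires a catalog (simulate section)")
    scan = gene_cis_scan(
        insertions, catalog,
        alpha=float(cis_cfg.get("alpha", 0.05)),
        upstream=int(cis_cfg.get("upstream", 3000)),
        exclude_donor=bool(cis_cfg.get("exclude_donor", False)),
        genome_length=cis_cfg.get("genome_length"),
    )
    scan.to_csv(outdir / "cis_genes.tsv", sep="\t", index=False)
    candidates = recurrence_filter(scan, theta=float(cis_cfg.get("theta", 0.05)))
    report["stages"]["cis"] = {
        "alpha": float(cis_cfg.get("alpha", 0.05)),
        "theta": float(cis_cfg.get("theta", 0.05)),
        "significant_genes": int(len(scan)),
        "candidate_genes": len(candidates),
        "candidates": candidates.genes,
    }

    cl_cfg = config.get("classify", {})
    _check_keys(cl_cfg, _CLASSIFY_KEYS, "classify")
    calls = classify_genes(
        candidates, insertions, catalog,
        alpha=float(cl_cfg.get("alpha", 0.05)),
        window_frac=float(cl_cfg.get("window_frac", 0.2)),
        cluster_threshold=float(cl_cfg.get("cluster_threshold", 0.5)),
        min_insertions=int(cl_cfg.get("min_insertions", 5)),
    )
    calls.to_csv(outdir / "driver_calls.tsv", sep="\t", index=False)
    report["stages"]["classify"] = {
        "calls": {row.gene_id: row.driver_class
                  for row in calls.itertuples(index=False)},
    }

    with (outdir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
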