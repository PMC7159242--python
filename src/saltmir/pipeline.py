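"""End-to-end pipeline orchestration: config validation and staged runs.

A run directory receives one TSV/GFF3/FASTA artifact per stage plus a
manifest recording the seed and every threshold, so a run is
self-describing and byte-reproducible given the same config and seed
(timestamps are kept out of result tables).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conserved, discovery, preprocess, quant, synthetic, targets
from .preprocess import ContaminantIndex, LibraryStats
from .synthetic import LIBRARIES


@dataclass
class SimulateParams:
    n_chrom: int = 1
    chrom_len: int = 50_000
    gc: float = 0.43
    n_hairpins: int = 10
    depth: int = 100_000
    contaminant_fraction: float = 0.25
    adapter: str = synthetic.DEFAULT_ADAPTER
    error_rate: float = 0.0
    n_catalog_decoys: int = 50
    n_transcripts: int = 8
    transcript_length: int = 400


@dataclass
class ThresholdParams:
    min_overlap: int = 8
    mean_q: float = 20.0
    min_trim_len: int = 15
    min_len: int = 16
    max_len: int = 35
    mono_frac: float = 0.8
    dinuc_frac: float = 0.8
    max_mismatch_known: int = 2
    min_count_novel: int = 10
    max_loci: int = 20
    min_precursor_length: int = 60
    max_loops: int = 1
    max_duplex_mismatches: int = 6
    max_mfe: float = -15.0
    min_mfei: float = 0.64
    min_au: float = 20.0
    max_au: float = 85.0
    target_cutoff: float = 3.0

    def hairpin_thresholds(self) -> discovery.Thresholds:
        return discovery.Thresholds(
            min_precursor_length=self.min_precursor_length,
            max_loops=self.max_loops,
            max_duplex_mismatches=self.max_duplex_mismatches,
            max_mfe=self.max_mfe,
            min_mfei=self.min_mfei,
            min_au=self.min_au,
            max_au=self.max_au,
        )


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: Path = Path("results/run")
    simulate: SimulateParams | None = field(default_factory=SimulateParams)
    paths: dict[str, object] = field(default_factory=dict)
    thresholds: ThresholdParams = field(default_factory=ThresholdParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = raw.get("simulate", "default")
        if isinstance(sim, dict):
            simulate = SimulateParams(**sim)
        elif sim == "default" or sim is True:
            simulate = SimulateParams()
        else:  # explicit null / false disables simulation
            simulate = None
        return cls(
            seed=int(raw.get("seed", 1)),
            out_dir=Path(raw.get("out_dir", "results/run")),
            simulate=simulate,
            paths={k: v for k, v in (raw.get("paths") or {}).items()},
            thresholds=ThresholdParams(**(raw.get("thresholds") or {})),
        )


_THRESHOLD_RANGES = {
    "min_overlap": (4, 30),
    "mean_q": (0, 41),
    "min_trim_len": (10, 35),
    "min_len": (14, 25),
    "max_len": (25, 50),
    "mono_frac": (0.5, 1.0),
    "dinuc_frac": (0.5, 1.0),
    "max_mismatch_known": (0, 4),
    "min_count_novel": (1, 1000),
    "max_loci": (1, 1000),
    "min_precursor_length": (40, 300),
    "max_loops": (1, 5),
    "max_duplex_mismatches": (0, 10),
    "max_mfe": (-100.0, 0.0),
    "min_mfei": (0.0, 5.0),
    "min_au": (0.0, 100.0),
    "max_au": (0.0, 100.0),
    "target_cutoff": (0.0, 10.0),
}


def validate_config(config: PipelineConfig) -> list[str]:
    """All validation errors, collected (not fail-fast)."""
    errors: list[str] = []
    defaults = ThresholdParams()
    for name, (lo, hi) in _THRESHOLD_RANGES.items():
        v = getattr(config.thresholds, name)
        if not lo <= v <= hi:
            errors.append(f"threshold {name}={v} outside [{lo}, {hi}]")
    if config.simulate is None:
        required = ["genome", "catalog", "ncrna_db", "transcripts"]
        for key in required:
            if key not in config.paths:
                errors.append(f"missing required path: {key}")
        fq = config.paths.get("fastq")
        if not isinstance(fq, dict) or set(fq) != set(LIBRARIES):
            errors.append(f"paths.fastq must map the libraries {LIBRARIES}")
        for key, val in (config.paths or {}).items():
            vals = val.values() if isinstance(val, dict) else [val]
            for p in vals:
                if isinstance(p, str) and not Path(p).exists():
                    errors.append(f"path does not exist: {key}: {p}")
    else:
        sim = config.simulate
        if not 0 < sim.gc < 1:
            errors.append(f"simulate.gc={sim.gc} outside (0,1)")
        if not 0 <= sim.contaminant_fraction < 1:
            errors.append("simulate.contaminant_fraction outside [0,1)")
        if sim.depth < 1000:
            errors.append("simulate.depth must be >= 1000")
    return errors


class StageFailure(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage} failed: {message}")
        self.stage = stage


def write_manifest(config: PipelineConfig, out: Path) -> None:
    manifest = {
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "simulate": dataclasses.asdict(config.simulate) if config.simulate else None,
        "paths": {k: str(v) for k, v in config.paths.items() if not isinstance(v, dict)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def stage_simulate(config: PipelineConfig) -> dict:
    """Generate genome, truth, contaminants, catalog, transcriptome and the
    four FASTQ libraries under <out_dir>/sim."""
    sim = config.simulate
    out = Path(config.out_dir) / "sim"
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = synthetic.generate_genome(
        sim.n_chrom, sim.chrom_len, sim.gc, sim.n_hairpins, config.seed
    )
    truth.contaminant_fraction = sim.contaminant_fraction
    truth.adapter = sim.adapter
    ncrna = synthetic.make_ncrna_db(config.seed)
    catalog = synthetic.make_catalog(config.seed, n_decoys=sim.n_catalog_decoys)
    transcripts, planted_sites = synthetic.make_transcriptome(
        truth.planted_loci, config.seed, sim.n_transcripts, sim.transcript_length
    )
    fastq, planted_counts = synthetic.simulate_reads(
        truth, sim.depth, config.seed, out_dir=out,
        ncrna_db=ncrna, genome=genome, error_rate=sim.error_rate,
    )
    genome_path = synthetic.write_genome(genome, out / "genome.fasta")
    truth.genome_path = genome_path
    truth.to_tsv(out / "truth.tsv")
    truth.to_gff3(out / "truth.gff3")
    synthetic.write_fasta(ncrna, out / "ncrna.fasta")
    synthetic.write_fasta(catalog, out / "catalog.fasta")
    synthetic.write_fasta(transcripts, out / "transcripts.fasta")
    pd.DataFrame(planted_sites).to_csv(out / "planted_sites.tsv", sep="\t", index=False)
    return {
        "genome": genome, "truth": truth, "ncrna": ncrna, "catalog": catalog,
        "transcripts": transcripts, "planted_sites": planted_sites,
        "fastq": fastq, "planted_counts": planted_counts,
        "paths": {
            "genome": genome_path,
            "ncrna_db": out / "ncrna.fasta",
            "catalog": out / "catalog.fasta",
            "transcripts": out / "transcripts.fasta",
            "fastq": fastq,
        },
    }


def stage_preprocess(config: PipelineConfig, fastq: dict[str, Path],
                     ncrna_db: Path, adapter: str, out: Path) -> dict:
    t = config.thresholds
    contaminants = ContaminantIndex.from_fasta(ncrna_db, min_len=t.min_len, max_len=t.max_len)
    counts, stats = {}, {}
    for lib in LIBRARIES:
        counts[lib], stats[lib] = preprocess.process_library(
            fastq[lib], adapter, contaminants, library=lib,
            min_overlap=t.min_overlap, mean_q=t.mean_q,
            min_trim_len=t.min_trim_len, min_len=t.min_len, max_len=t.max_len,
            mono_frac=t.mono_frac, dinuc_frac=t.dinuc_frac,
        )
    usable = {lib: stats[lib].usable_reads for lib in LIBRARIES}
    tags = preprocess.collapse(counts, usable)
    report = preprocess.qc_report(stats)
    hist = preprocess.length_histogram(tags, t.min_len, t.max_len)
    out.mkdir(parents=True, exist_ok=True)
    tags.to_csv(out / "tags.tsv", sep="\t", index=False, float_format="%.6g")
    report.to_csv(out / "library_stats.tsv", sep="\t")
    hist.to_csv(out / "length_histogram.tsv", sep="\t", index=False)
    return {"tags": tags, "stats": stats, "report": report, "histogram": hist}


def stage_conserved(config: PipelineConfig, tags: pd.DataFrame,
                    catalog_path: Path, out: Path) -> dict:
    catalog = preprocess.read_fasta(catalog_path)
    annotations = conserved.match_known(
        tags, catalog, max_mismatch=config.thresholds.max_mismatch_known
    )
    table = conserved.annotations_table(annotations)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "conserved.tsv", sep="\t", index=False, float_format="%.6g")
    return {"annotations": annotations, "table": table}


def stage_novel(config: PipelineConfig, tags: pd.DataFrame,
                annotated: set[str], genome: dict[str, str], out: Path) -> dict:
    t = config.thresholds
    sel = tags[
        (tags["total_count"] >= t.min_count_novel)
        & ~tags["sequence"].isin(annotated)
    ]
    hits = discovery.map_tags(list(sel["sequence"]), genome, max_loci=t.max_loci)
    best = discovery.discover_novel(hits, genome, t.hairpin_thresholds())
    rows = []
    rpm_cols = [c for c in tags.columns if c.startswith("rpm_")]
    by_seq = sel.set_index("sequence")
    for i, (tag, cand) in enumerate(sorted(best.items())):
        if cand is None:
            continue
        row = {
            "name": f"can-miR{i + 1:04d}", "sequence": tag,
            "max_rpm": float(by_seq.loc[tag, rpm_cols].max()),
            "length": len(tag), "star": cand.star_seq or "NO",
            "duplex_mismatches": cand.duplex_mismatches,
            "precursor_length": cand.pl,
            "au_pct": round(cand.au_pct, 1), "mfe": round(cand.mfe, 2),
            "mfei": round(cand.mfei, 2), "arm": cand.arm,
            "chrom": cand.chrom, "precursor_start": cand.precursor_start,
            "precursor_end": cand.precursor_end, "strand": cand.strand,
            "all_pass": cand.all_pass,
        }
        row.update({f"pass_{k}": v for k, v in cand.verdict.items()})
        rows.append((row, cand))
    table = pd.DataFrame([r for r, _ in rows])
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "novel_candidates.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out / "novel_loci.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for row, cand in rows:
            if not row["all_pass"]:
                continue
            fh.write(
                f"{cand.chrom}\tsaltmir\tmiRNA_primary_transcript\t"
                f"{cand.precursor_start + 1}\t{cand.precursor_end}\t.\t"
                f"{cand.strand}\t.\tID={row['name']};mature_seq={row['sequence']}\n"
            )
    with open(out / "novel_precursors.fasta", "w") as fh:
        for row, cand in rows:
            if row["all_pass"]:
                fh.write(f">{row['name']}\n{cand.precursor_seq}\n")
    with open(out / "novel_structures.txt", "w") as fh:
        for row, cand in rows:
            if row["all_pass"]:
                fh.write(f">{row['name']}\n{cand.precursor_seq}\n{cand.structure} ({cand.mfe:.2f})\n")
    return {"table": table, "candidates": dict(best)}


def stage_targets(config: PipelineConfig, mirnas: list[tuple[str, str]],
                  transcripts_path: Path, out: Path) -> pd.DataFrame:
    transcripts = preprocess.read_fasta(transcripts_path)
    rows = []
    for name, seq in mirnas:
        for h in targets.scan_transcriptome(
            name, seq, transcripts, cutoff=config.thresholds.target_cutoff
        ):
            rows.append({
                "mirna": h.mirna_name, "transcript": h.transcript_id,
                "start": h.t_start, "end": h.t_end,
                "expectation": h.expectation,
                "cleavage": h.cleavage if isinstance(h.cleavage, int)
                else f"{h.cleavage[0]}-{h.cleavage[1]}",
                "alignment_mirna_3to5": h.alignment[0],
                "alignment_pairing": h.alignment[1],
                "alignment_target_5to3": h.alignment[2],
            })
    table = pd.DataFrame(rows)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "targets.tsv", sep="\t", index=False, float_format="%.6g")
    return table


def stage_quantify(config: PipelineConfig, out: Path,
                   qpcr: pd.DataFrame | None = None,
                   densitometry: pd.DataFrame | None = None,
                   luciferase: pd.DataFrame | None = None) -> dict:
    """Quantify the measurement tables (synthetic defaults when not given)."""
    seed = config.seed
    if qpcr is None:
        qpcr = quant.simulate_qpcr_table({"LAO": 0.4, "Myb": 1.6}, seed=seed)
    if densitometry is None:
        densitometry = quant.simulate_densitometry_table(
            {"miR159a": 0.5, "miR167f": 0.6}, seed=seed
        )
    if luciferase is None:
        luciferase = quant.simulate_luciferase_table(
            {"LAO": 0.5, "MCO": 0.6, "Myb": 0.55}, seed=seed
        )
    rel = quant.qpcr_relative_expression(qpcr)
    dens = quant.densitometry_table(densitometry)
    luc = pd.DataFrame([
        quant.luciferase_compare(luciferase, p) for p in luciferase["pair"].unique()
    ])
    out.mkdir(parents=True, exist_ok=True)
    rel.to_csv(out / "qpcr_relative_expression.tsv", sep="\t", index=False, float_format="%.6g")
    dens.to_csv(out / "densitometry_folds.tsv", sep="\t", index=False, float_format="%.6g")
    luc.to_csv(out / "luciferase_comparison.tsv", sep="\t", index=False, float_format="%.6g")
    return {"qpcr": rel, "densitometry": dens, "luciferase": luc}


def run_all(config: PipelineConfig) -> dict:
    """Execute simulate (when configured) -> preprocess -> conserved ->
    novel -> targets -> quantify; returns the in-memory stage results."""
    errors = validate_config(config)
    if errors:
        raise ValueError("config invalid: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(config, out)
    results: dict = {}

    try:
        if config.simulate is not None:
            sim = stage_simulate(config)
            results["simulate"] = sim
            fastq = sim["paths"]["fastq"]
            ncrna_db = sim["paths"]["ncrna_db"]
            catalog_path = sim["paths"]["catalog"]
            transcripts_path = sim["paths"]["transcripts"]
            genome = sim["genome"]
            adapter = config.simulate.adapter
        else:
            fastq = {lib: Path(p) for lib, p in config.paths["fastq"].items()}
            ncrna_db = Path(config.paths["ncrna_db"])
            catalog_path = Path(config.paths["catalog"])
            transcripts_path = Path(config.paths["transcripts"])
            genome = dict(preprocess.read_fasta(config.paths["genome"]))
            adapter = config.paths.get("adapter", synthetic.DEFAULT_ADAPTER)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("simulate", str(exc)) from exc

    try:
        pre = stage_preprocess(config, fastq, ncrna_db, adapter, out / "preprocess")
        results["preprocess"] = pre
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("preprocess", str(exc)) from exc

    try:
        cons = stage_conserved(config, pre["tags"], catalog_path, out / "conserved")
        results["conserved"] = cons
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("conserved", str(exc)) from exc

    try:
        annotated = {a.tag for a in cons["annotations"]}
        nov = stage_novel(config, pre["tags"], annotated, genome, out / "novel")
        results["novel"] = nov
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("novel", str(exc)) from exc

    try:
        table = nov["table"]
        mirnas = []
        if len(table):
            called = table[table["all_pass"]]
            mirnas = list(zip(called["name"], called["sequence"]))
        results["targets"] = stage_targets(
            config, mirnas, transcripts_path, out / "targets"
        )
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("targets", str(exc)) from exc

    try:
        results["quantify"] = stage_quantify(config, out / "quantify")
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("quantify", str(exc)) from exc

    return results
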