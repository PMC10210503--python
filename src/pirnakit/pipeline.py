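"""End-to-end pipeline: simulate -> trim -> map -> annotate -> metrics ->
qpcr -> repression -> report.

Every stage reads and writes plain-text artifacts (FASTA/FASTQ/TSV/bedGraph/
JSON) under one output directory.  A manifest records parameters and input
checksums per stage; re-running with unchanged inputs skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import (
    aligner,
    library_annotation,
    pirna_metrics,
    qpcr_stats,
    repression_assay,
    sequence_io,
    synthetic_data,
)
from .aligner import ReferenceSet
from .pirna_metrics import ConversionSeries
from .repression_assay import EggChamberCount
from .sequence_io import TrimmedRead

log = logging.getLogger("pirnakit")

STAGES = ("simulate", "trim", "map", "annotate", "metrics", "qpcr", "repression", "report")


@dataclass
class RunConfig:
    """Parameters for one pipeline run."""

    outdir: str = "pirnakit_run"
    seed: int = 0
    adapter: str = sequence_io.DEFAULT_ADAPTER
    min_len: int = 18
    max_len: int = 30
    max_mm: int = 0
    unique_only: bool = True
    normalization_mode: str = "genome_minus_misc"
    pirna_window: tuple[int, int] = (23, 29)
    overlap_K: int = 25
    generations: tuple[int, ...] = (1, 2, 3, 4)
    lineages: tuple[str, ...] = ("paternal", "maternal")
    depth_scale: float = 0.05  # fraction of full library depth to simulate
    regions: tuple[str, ...] = ("PlArB", "T3", "white")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in data.items()})
        for key in ("pirna_window", "generations", "lineages", "regions"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def sim_config(self) -> synthetic_data.SimulationConfig:
        return synthetic_data.SimulationConfig(seed=self.seed, adapter=self.adapter).scaled(
            self.depth_scale
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-stage record of parameters, input checksums and outputs."""

    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_cached(self, stage: str, inputs: Sequence[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        current = {str(p): _sha256(p) for p in inputs if p.exists()}
        if rec["inputs"] != current:
            return False
        return all(Path(p).exists() for p in rec["outputs"])

    def record(self, stage: str, inputs: Sequence[Path], outputs: Sequence[Path]) -> None:
        self.data["stages"][stage] = {
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": [str(p) for p in outputs],
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _lib_tag(lineage: str, generation: int) -> str:
    return f"{lineage}_G{generation}"


def _load_refs(outdir: Path) -> ReferenceSet:
    entries = sequence_io.read_fasta(outdir / "references.fa")
    roles = json.loads((outdir / "region_roles.json").read_text())
    return ReferenceSet.from_fasta(entries, roles)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    sim = cfg.sim_config()
    refs, bed = synthetic_data.make_references(sim)
    outputs = []
    fa = outdir / "references.fa"
    sequence_io.write_fasta({r.name: r.seq for r in refs}, fa)
    roles = outdir / "region_roles.json"
    roles.write_text(json.dumps({r.name: r.role for r in refs}, indent=2))
    bed_path = outdir / "subregions.bed"
    with open(bed_path, "wt") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        for _, row in bed.iterrows():
            fh.write(f"{row.region}\t{row.start}\t{row.end}\t{row['name']}\n")
    outputs += [fa, roles, bed_path]

    for lineage in cfg.lineages:
        for g in cfg.generations:
            reads, truth, _ = synthetic_data.simulate_library(sim, g, lineage)
            tag = _lib_tag(lineage, g)
            fq = outdir / f"library_{tag}.fastq"
            sequence_io.write_fastq(reads, fq)
            truth_path = outdir / f"truth_{tag}.tsv"
            sequence_io.write_table(truth, truth_path, comment=f"seed={cfg.seed}")
            outputs += [fq, truth_path]

    chambers: list[EggChamberCount] = []
    for lineage in cfg.lineages:
        for g in cfg.generations:
            chambers += synthetic_data.simulate_egg_chambers(sim, g, lineage)
    ec_path = outdir / "egg_chambers.tsv"
    sequence_io.write_table(
        [
            {
                "lineage": c.lineage,
                "generation": c.generation,
                "subline": c.subline,
                "n_total": c.n_total,
                "n_repressed": c.n_repressed,
            }
            for c in chambers
        ],
        ec_path,
        comment=f"seed={cfg.seed}",
    )
    outputs.append(ec_path)

    rt, chip = synthetic_data.simulate_qpcr(sim)
    rt_path = outdir / "rt_qpcr.tsv"
    sequence_io.write_table(
        [
            {"sample_id": s.sample_id, "gene": s.gene, "replicate": i + 1, "sq": v}
            for s in rt
            for i, v in enumerate(s.sq)
        ],
        rt_path,
        comment=f"seed={cfg.seed}",
    )
    chip_path = outdir / "chip_qpcr.tsv"
    sequence_io.write_table(
        [
            {
                "sample_id": s.sample_id,
                "region": s.target_region,
                "mean_ct_chip": s.mean_ct_chip,
                "mean_ct_input": s.mean_ct_input,
                "mean_ct_ns": s.mean_ct_ns,
                "input_fraction": s.input_fraction,
            }
            for s in chip
        ],
        chip_path,
        comment=f"seed={cfg.seed}",
    )
    outputs += [rt_path, chip_path]
    return outputs


def stage_trim(cfg: RunConfig, outdir: Path) -> list[Path]:
    outputs = []
    for lineage in cfg.lineages:
        for g in cfg.generations:
            tag = _lib_tag(lineage, g)
            fq = outdir / f"library_{tag}.fastq"
            if not fq.exists():
                raise FileNotFoundError(f"stage trim: missing input {fq}")
            truth = sequence_io.read_table(outdir / f"truth_{tag}.tsv")
            mult = dict(zip(truth["read_id"], truth["multiplicity"]))
            kept_rows = []
            rejected = {"empty": 0, "no_adapter": 0, "too_short": 0, "too_long": 0}
            for read in sequence_io.read_fastq(fq):
                out = sequence_io.trim_adapter(read, cfg.adapter, cfg.min_len, cfg.max_len)
                if isinstance(out, TrimmedRead):
                    kept_rows.append(
                        {
                            "read_id": out.id,
                            "seq": out.seq,
                            "multiplicity": int(mult.get(out.id, 1)),
                        }
                    )
                else:
                    rejected[out.reason] += 1
            path = outdir / f"trimmed_{tag}.tsv"
            sequence_io.write_table(kept_rows, path, comment=f"seed={cfg.seed}")
            outputs.append(path)
            log.info("trim %s: kept %d species, rejected %s", tag, len(kept_rows), rejected)
    summary = outdir / "trim_summary.tsv"
    # rejects of the last library stand for the run; all libraries share the adapter
    sequence_io.write_table(
        [{"reason": k, "count": v} for k, v in rejected.items()], summary
    )
    outputs.append(summary)
    return outputs


def _load_trimmed(path: Path) -> tuple[list[TrimmedRead], list[int]]:
    df = sequence_io.read_table(path)
    reads = [TrimmedRead(id=str(r.read_id), seq=str(r.seq)) for r in df.itertuples()]
    return reads, [int(m) for m in df["multiplicity"]]


def stage_map(cfg: RunConfig, outdir: Path) -> list[Path]:
    refs = _load_refs(outdir)
    outputs = []
    for lineage in cfg.lineages:
        for g in cfg.generations:
            tag = _lib_tag(lineage, g)
            reads, mult = _load_trimmed(outdir / f"trimmed_{tag}.tsv")
            result = aligner.map_library(
                reads, refs, max_mm=cfg.max_mm, unique_only=cfg.unique_only,
                multiplicities=mult,
            )
            frame = aligner.hits_to_frame(result.hits)
            frame["first_nt"] = [h.first_nt for h in result.hits]
            path = outdir / f"hits_{tag}.tsv"
            sequence_io.write_table(frame, path, comment=f"seed={cfg.seed}")
            outputs.append(path)
            log.info(
                "map %s: %d hits (%d unique, %d multi, %d unmapped species)",
                tag, len(result.hits), result.n_unique, result.n_multi, result.n_unmapped,
            )
    return outputs


def stage_annotate(cfg: RunConfig, outdir: Path) -> list[Path]:
    refs = _load_refs(outdir)
    outputs = []
    for lineage in cfg.lineages:
        for g in cfg.generations:
            tag = _lib_tag(lineage, g)
            reads, mult = _load_trimmed(outdir / f"trimmed_{tag}.tsv")
            ann = library_annotation.annotate_library(reads, refs, multiplicities=mult)
            path = outdir / f"annotation_{tag}.tsv"
            sequence_io.write_table(ann.to_frame(), path, comment=f"seed={cfg.seed}")
            outputs.append(path)
    return outputs


def _load_annotation(path: Path) -> library_annotation.LibraryAnnotation:
    df = sequence_io.read_table(path).set_index("category")["count"]
    return library_annotation.LibraryAnnotation(
        total_reads=int(df["total"]),
        genome=int(df["genome"]),
        miscRNA=int(df["miscRNA"]),
        tRNA=int(df["tRNA"]),
        miRNA=int(df["miRNA"]),
        unmatched=int(df["unmatched"]),
    )


def _load_hits(path: Path) -> list[aligner.AlignmentHit]:
    df = sequence_io.read_table(path)
    return [
        aligner.AlignmentHit(
            region=str(r.region),
            start=int(r.start),
            strand=str(r.strand),
            read_id=str(r.read_id),
            length=int(r.end) - int(r.start),
            mismatches=int(r.mismatches),
            multiplicity=int(r.multiplicity),
            first_nt=str(r.first_nt),
        )
        for r in df.itertuples()
    ]


def stage_metrics(cfg: RunConfig, outdir: Path) -> list[Path]:
    refs = _load_refs(outdir)
    outputs = []
    series: dict[tuple[str, str], ConversionSeries] = {}
    region_rows = []
    for lineage in cfg.lineages:
        for g in cfg.generations:
            tag = _lib_tag(lineage, g)
            hits = _load_hits(outdir / f"hits_{tag}.tsv")
            ann = _load_annotation(outdir / f"annotation_{tag}.tsv")
            for region in cfg.regions:
                L = len(refs[region].seq)
                dens = pirna_metrics.density_per_kb(
                    hits, ann, region, refs[region].length_kb,
                    window=cfg.pirna_window, mode=cfg.normalization_mode,
                )
                prof = pirna_metrics.coverage_profile(
                    hits, ann, region, L, window=cfg.pirna_window,
                    mode=cfg.normalization_mode,
                )
                ratio = pirna_metrics.sirna_pirna_ratio(
                    hits, ann, region, pirna_window=cfg.pirna_window,
                    mode=cfg.normalization_mode,
                )
                cov_path = outdir / f"coverage_{tag}_{region}.bedgraph"
                sequence_io.write_coverage(prof, cov_path)
                outputs.append(cov_path)
                if prof.total > 0:
                    sense_fraction, cls = pirna_metrics.strand_asymmetry(prof)
                    try:
                        sig = pirna_metrics.overlap_signature(prof, K=cfg.overlap_K)
                        z10 = None if sig.degenerate else sig.z(10)
                        sig_path = outdir / f"signature_{tag}_{region}.tsv"
                        sequence_io.write_table(
                            sig.to_frame(), sig_path, allow_nan=True,
                            comment=f"seed={cfg.seed}",
                        )
                        outputs.append(sig_path)
                    except ValueError:
                        z10 = None  # single-stranded coverage
                else:
                    sense_fraction, cls, z10 = np.nan, "no_coverage", None
                sd = pirna_metrics.size_distribution(
                    hits, ann, region, cfg.min_len, cfg.max_len,
                    mode=cfg.normalization_mode,
                )
                sd_path = outdir / f"sizedist_{tag}_{region}.tsv"
                sequence_io.write_table(sd.to_frame(), sd_path, comment=f"seed={cfg.seed}")
                outputs.append(sd_path)
                region_rows.append(
                    {
                        "lineage": lineage,
                        "generation": g,
                        "region": region,
                        "density_per_kb": dens.density,
                        "one_u_fraction": np.nan if dens.one_u_fraction is None
                        else dens.one_u_fraction,
                        "sense_fraction": sense_fraction,
                        "strand_class": cls,
                        "z10": np.nan if z10 is None else z10,
                        "sirna_pirna_ratio": np.nan if ratio is None else ratio,
                    }
                )
                key = (lineage, region)
                series.setdefault(key, ConversionSeries(lineage, region)).add(
                    g, dens, ratio
                )
    metrics_path = outdir / "region_metrics.tsv"
    sequence_io.write_table(
        pd.DataFrame(region_rows), metrics_path, allow_nan=True,
        comment=f"seed={cfg.seed}",
    )
    outputs.append(metrics_path)

    conv_rows = []
    for (lineage, region), s in series.items():
        gens = s.generations
        row = {
            "lineage": lineage,
            "region": region,
            "g_first": gens[0],
            "g_last": gens[-1],
            "ratio_last_over_first": np.nan,
            "fitted_conversion_rate": np.nan,
        }
        if s.densities[gens[0]].density > 0:
            row["ratio_last_over_first"] = round(
                pirna_metrics.generation_ratio(s, gens[0], gens[-1]), 2
            )
        if lineage == "paternal" and len(gens) >= 2:
            row["fitted_conversion_rate"] = pirna_metrics.fit_conversion_rate(s)
        conv_rows.append(row)
    conv_path = outdir / "conversion_series.tsv"
    sequence_io.write_table(
        pd.DataFrame(conv_rows), conv_path, allow_nan=True, comment=f"seed={cfg.seed}"
    )
    outputs.append(conv_path)
    return outputs


def load_rt_samples(path: Path) -> list[qpcr_stats.RtQpcrSample]:
    df = sequence_io.read_table(path)
    out = []
    for (sid, gene), grp in df.groupby(["sample_id", "gene"], sort=True):
        sq = tuple(grp.sort_values("replicate")["sq"])
        out.append(qpcr_stats.RtQpcrSample(sample_id=str(sid), gene=str(gene), sq=sq))
    return out


def load_chip_samples(path: Path) -> list[qpcr_stats.ChipSample]:
    df = sequence_io.read_table(path)
    return [
        qpcr_stats.ChipSample(
            sample_id=str(r.sample_id),
            target_region=str(r.region),
            mean_ct_chip=float(r.mean_ct_chip),
            mean_ct_input=float(r.mean_ct_input),
            mean_ct_ns=float(r.mean_ct_ns),
            input_fraction=float(r.input_fraction),
        )
        for r in df.itertuples()
    ]


def stage_qpcr(cfg: RunConfig, outdir: Path) -> list[Path]:
    rt = load_rt_samples(outdir / "rt_qpcr.tsv")
    by_sample: dict[str, dict[str, qpcr_stats.RtQpcrSample]] = {}
    for s in rt:
        by_sample.setdefault(s.sample_id, {})[s.gene] = s
    genes = sorted({s.gene for s in rt} - {qpcr_stats.REFERENCE_GENE})
    rt_rows = []
    for gene in genes:
        ratios = [
            qpcr_stats.rt_ratio(d[gene], d[qpcr_stats.REFERENCE_GENE])
            for d in by_sample.values()
            if gene in d and qpcr_stats.REFERENCE_GENE in d
        ]
        mean, sd = qpcr_stats.rt_group_summary(ratios)
        rt_rows.append({"gene": gene, "n": len(ratios), "mean_ratio": mean, "sd": sd})
    rt_out = outdir / "rt_summary.tsv"
    sequence_io.write_table(pd.DataFrame(rt_rows), rt_out, allow_nan=True)

    chip = load_chip_samples(outdir / "chip_qpcr.tsv")
    per_region: dict[str, list[float]] = {}
    for s in chip:
        per_region.setdefault(s.target_region, []).append(qpcr_stats.fold_enrichment(s))
    mean_fe = {r: float(np.mean(v)) for r, v in per_region.items()}
    rel = qpcr_stats.normalize_to_region(mean_fe, qpcr_stats.CONTROL_REGION)
    chip_rows = [
        {
            "region": r,
            "n": len(per_region[r]),
            "mean_fold_enrichment": mean_fe[r],
            "relative_to_control": rel[r],
        }
        for r in sorted(per_region)
    ]
    chip_out = outdir / "chip_summary.tsv"
    sequence_io.write_table(pd.DataFrame(chip_rows), chip_out)
    return [rt_out, chip_out]


def stage_repression(cfg: RunConfig, outdir: Path) -> list[Path]:
    df = sequence_io.read_table(outdir / "egg_chambers.tsv")
    outputs = []
    frames = []
    for lineage, grp in df.groupby("lineage"):
        counts = [
            EggChamberCount(
                lineage=str(r.lineage),
                generation=int(r.generation),
                subline=str(r.subline),
                n_total=int(r.n_total),
                n_repressed=int(r.n_repressed),
            )
            for r in grp.itertuples()
        ]
        summary = repression_assay.subline_summary(counts)
        summary.insert(0, "lineage", lineage)
        frames.append(summary)
    path = outdir / "repression_summary.tsv"
    sequence_io.write_table(pd.concat(frames, ignore_index=True), path, allow_nan=True)
    outputs.append(path)
    return outputs


def stage_report(cfg: RunConfig, outdir: Path) -> list[Path]:
    report = {
        "seed": cfg.seed,
        "parameters": {
            "adapter": cfg.adapter,
            "length_window": [cfg.min_len, cfg.max_len],
            "pirna_window": list(cfg.pirna_window),
            "max_mm": cfg.max_mm,
            "normalization_mode": cfg.normalization_mode,
            "overlap_K": cfg.overlap_K,
            "depth_scale": cfg.depth_scale,
        },
        "tables": {
            name: str(outdir / name)
            for name in (
                "region_metrics.tsv",
                "conversion_series.tsv",
                "rt_summary.tsv",
                "chip_summary.tsv",
                "repression_summary.tsv",
            )
        },
    }
    conv = sequence_io.read_table(outdir / "conversion_series.tsv")
    report["conversion_series"] = conv.to_dict(orient="records")
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return [path]


_STAGE_FUNCS: dict[str, Callable[[RunConfig, Path], list[Path]]] = {
    "simulate": stage_simulate,
    "trim": stage_trim,
    "map": stage_map,
    "annotate": stage_annotate,
    "metrics": stage_metrics,
    "qpcr": stage_qpcr,
    "repression": stage_repression,
    "report": stage_report,
}

_STAGE_INPUTS: dict[str, Callable[[RunConfig, Path], list[Path]]] = {
    "simulate": lambda cfg, d: [],
    "trim": lambda cfg, d: sorted(d.glob("library_*.fastq")),
    "map": lambda cfg, d: sorted(d.glob("trimmed_*.tsv")) + [d / "references.fa"],
    "annotate": lambda cfg, d: sorted(d.glob("trimmed_*.tsv")) + [d / "references.fa"],
    "metrics": lambda cfg, d: sorted(d.glob("hits_*.tsv"))
    + sorted(d.glob("annotation_*.tsv")),
    "qpcr": lambda cfg, d: [d / "rt_qpcr.tsv", d / "chip_qpcr.tsv"],
    "repression": lambda cfg, d: [d / "egg_chambers.tsv"],
    "report": lambda cfg, d: [d / "conversion_series.tsv"],
}


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict[str, str]:
    """Run all stages, skipping those whose inputs and outputs are unchanged.

    Returns a stage -> status ('ran' | 'cached') mapping.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir / "manifest.json")
    status: dict[str, str] = {}
    for stage in STAGES:
        inputs = _STAGE_INPUTS[stage](cfg, outdir)
        missing = [p for p in inputs if not p.exists()]
        if missing and stage != "simulate":
            raise FileNotFoundError(f"stage {stage!r}: missing input {missing[0]}")
        if not force and manifest.stage_cached(stage, inputs):
            status[stage] = "cached"
            log.info("stage %s: cached", stage)
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, inputs, outputs)
        status[stage] = "ran"
        log.info("stage %s: %.2fs, %d outputs", stage, time.perf_counter() - t0, len(outputs))
    return status
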