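"""End-to-end orchestration: QC -> ROH -> inbreeding -> islands -> annotation.

Each population (breed) in the input is analysed independently after a joint
QC pass: allele frequencies, the adaptive window size ``L``, the scan
threshold ``t`` and the island incidence threshold are all
population-specific.  Every stage's table is written as TSV into a
per-population subdirectory, together with a run manifest recording package
version, parameters and input checksums; reruns on identical inputs are
byte-identical (the manifest carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import features_in_islands, qtl_enrichment, read_gene_annotation, read_qtl_database
from .datatypes import GenotypeDataset, RohscapeError
from .genotype_io import apply_qc, read_plink
from .inbreeding import InbreedingEstimator, write_inbreeding
from .islands import IslandCaller
from .roh import ROHDetector, write_segments
from .structure import IBSMDS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    input_prefix: str
    output_dir: str
    input_format: str | None = None
    sample_call_rate: float = 0.9
    snp_call_rate: float = 0.95
    autosomes: list[str] | None = None
    alpha: float = 0.05
    n_out: int = 2
    mean_het: float | None = None
    window_snps: int | None = None
    scan_threshold: float | None = None
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 150_000
    island_quantile: float = 0.999
    island_min_incidence: float = 0.30
    island_merge_gap_bp: int = 1_000_000
    flank_bp: int = 500_000
    gene_annotation: str | None = None
    qtl_database: str | None = None
    run_mds: bool = True
    mds_components: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("gene_annotation", "qtl_database"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cfg: PipelineConfig, dataset: GenotypeDataset | None = None
) -> dict:
    """Run every stage; returns the manifest dictionary.

    ``dataset`` may be passed directly (e.g. a simulated population) to skip
    file reading.  Any stage failure is re-raised wrapped with the stage name.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package": "rohscape",
        "version": __version__,
        "parameters": dataclasses.asdict(cfg),
        "inputs": {},
        "populations": {},
    }

    stage = "read"
    try:
        if dataset is None:
            dataset = read_plink(cfg.input_prefix, cfg.input_format)
            for ext in ("ped", "map", "bed", "bim", "fam"):
                p = Path(cfg.input_prefix).with_suffix("." + ext)
                if p.exists():
                    manifest["inputs"][p.name] = _sha256(p)

        stage = "qc"
        dataset = apply_qc(
            dataset,
            sample_call_rate=cfg.sample_call_rate,
            snp_call_rate=cfg.snp_call_rate,
            autosomes=cfg.autosomes,
        )

        genes = qtls = None
        if cfg.gene_annotation is not None:
            stage = "annotation-load"
            genes = read_gene_annotation(cfg.gene_annotation)
            manifest["inputs"][Path(cfg.gene_annotation).name] = _sha256(Path(cfg.gene_annotation))
        if cfg.qtl_database is not None:
            stage = "annotation-load"
            qtls = read_qtl_database(cfg.qtl_database)
            manifest["inputs"][Path(cfg.qtl_database).name] = _sha256(Path(cfg.qtl_database))

        for pop, sub in dataset.split_by_population():
            pdir = outdir / pop
            pdir.mkdir(exist_ok=True)
            pinfo: dict = {"n_samples": sub.n_samples, "n_markers": sub.n_markers}

            stage = f"{pop}:detect"
            det = ROHDetector(
                alpha=cfg.alpha, n_out=cfg.n_out, mean_het=cfg.mean_het,
                window_snps=cfg.window_snps, scan_threshold=cfg.scan_threshold,
                min_length_bp=cfg.min_length_bp, max_gap_bp=cfg.max_gap_bp,
                min_density_bp_per_snp=cfg.min_density_bp_per_snp,
            ).fit(sub)
            write_segments(det.segments_, pdir / "segments.tsv")
            pinfo.update(
                mean_het=round(det.mean_het_, 6), window_snps=det.window_snps_,
                scan_threshold=det.scan_threshold_, n_segments=len(det.segments_),
            )

            stage = f"{pop}:inbreeding"
            inb = InbreedingEstimator().fit(sub, segments=det.segments_)
            write_inbreeding(inb.records_, pdir / "inbreeding.tsv")
            pinfo["f_hom_f_roh_correlation"] = (
                None if pd.isna(inb.correlation_) else round(float(inb.correlation_), 6)
            )
            pinfo["l_auto_bp"] = int(inb.span_.total_bp)

            stage = f"{pop}:islands"
            isl = IslandCaller(
                quantile=cfg.island_quantile,
                min_incidence=cfg.island_min_incidence,
                merge_gap_bp=cfg.island_merge_gap_bp,
            ).fit(sub, segments=det.segments_)
            isl.profile_[["chromosome", "position_bp", "snp_id", "carrier_count", "incidence"]].to_csv(
                pdir / "incidence.tsv", sep="\t", index=False, float_format="%.6g"
            )
            isl.islands_.to_csv(pdir / "islands.tsv", sep="\t", index=False, float_format="%.6g")
            with (pdir / "islands.bed").open("w") as fh:
                for r in isl.islands_.itertuples(index=False):
                    fh.write(f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\n")
            pinfo["n_islands"] = len(isl.islands_)
            pinfo["island_threshold"] = round(float(isl.threshold_), 6)

            if genes is not None or qtls is not None:
                stage = f"{pop}:annotate"
                if genes is not None:
                    ghits = features_in_islands(isl.islands_, genes, cfg.flank_bp)
                    ghits.to_csv(pdir / "island_genes.tsv", sep="\t", index=False)
                    pinfo["n_gene_hits"] = len(ghits)
                if qtls is not None:
                    qhits = features_in_islands(isl.islands_, qtls, cfg.flank_bp)
                    qhits.to_csv(pdir / "island_qtls.tsv", sep="\t", index=False)
                    enr = qtl_enrichment(qhits, qtls)
                    enr.to_csv(pdir / "qtl_enrichment.tsv", sep="\t", index=False,
                               float_format="%.6g")
                    pinfo["n_qtl_hits"] = int(qhits["qtl_id"].nunique()) if len(qhits) else 0
            else:
                logger.info("population %s: no annotation paths; annotation skipped", pop)
                pinfo["annotation"] = "skipped (no annotation paths configured)"

            if cfg.run_mds and sub.n_samples > cfg.mds_components:
                stage = f"{pop}:mds"
                mds = IBSMDS(n_components=cfg.mds_components).fit(sub)
                mds.coordinates_.to_csv(pdir / "mds.tsv", sep="\t", index=False,
                                        float_format="%.6g")
                pinfo["mds_explained"] = [round(float(x), 6)
                                          for x in mds.explained_variance_ratio_]

            manifest["populations"][pop] = pinfo
    except RohscapeError as exc:
        raise RohscapeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
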