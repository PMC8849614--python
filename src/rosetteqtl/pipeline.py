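"""Configuration and the end-to-end synthetic pipeline driver.

The pipeline chains the package's stages in workflow order: simulate
rosette masks and measure them (morphometry showcase), simulate a MAGIC
population with a planted QTL, compute phenotype statistics and the PCA
morphospace, reconstruct founder probabilities and scan every trait with
permutation thresholds, then call, filter and annotate QTL peaks.  Every
output file is hashed into a run manifest; a rerun with the same
configuration and seed reproduces the hashes bit for bit.

One global seed fans out to per-stage seeds through
``derive_seed(seed, stage)``, so stages are reproducible in isolation
and inserting a stage never perturbs the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rosetteqtl import io as rio
from rosetteqtl import phenostats, qtl_post, qtl_scan
from rosetteqtl.magicsim import QTLPlan, simulate_founders, simulate_magic_population, simulate_phenotypes
from rosetteqtl.morphometry import DESCRIPTOR_NAMES, measure_rosette
from rosetteqtl.rosette import generate_rosette_mask, random_rosette_specs

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

log = logging.getLogger("rosetteqtl")

STAGES = ("rosettes", "magic", "phenotypes", "phenostats", "scan", "peaks")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=(int(seed), idx))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    # rosette showcase
    n_rosettes: int = 6
    image_size_px: int = 512
    # MAGIC population
    n_founders: int = 19
    n_markers_per_chrom: tuple[int, ...] = (60, 60, 60)
    n_lines: int = 200
    expected_breakpoints_per_chrom: float = 3.0
    genotyping_error: float = 0.01
    genes_per_chrom: int = 40
    # phenotypes
    das_list: tuple[int, ...] = (35, 36)
    n_replicates: int = 3
    qtl_trait: str = "Compactness"
    qtl_marker: str | None = None  # default: middle marker of chromosome 1
    qtl_variance_fraction: float = 0.2
    line_variance: float = 0.3
    noise_variance: float = 0.7
    # scan
    alpha: float = 0.05
    n_perm: int = 500
    hmm_error: float = 0.01
    mosaic_density: float = 3.0
    include_pcs: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.n_lines < 30:
            raise ValueError("n_lines must be >= 30 for a meaningful scan")
        if self.qtl_trait not in DESCRIPTOR_NAMES:
            raise ValueError(f"qtl_trait must be one of {DESCRIPTOR_NAMES}")
        if not self.das_list:
            raise ValueError("das_list must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_markers_per_chrom", "das_list"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- stage 1: rosette masks + morphometry -----------------------------
    seed = derive_seed(config.seed, "rosettes")
    log.info("stage rosettes: %d masks at %d px", config.n_rosettes, config.image_size_px)
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    rows = []
    for i, spec in enumerate(
        random_rosette_specs(config.n_rosettes, seed=seed, image_size_px=config.image_size_px)
    ):
        mask, _ = generate_rosette_mask(spec)
        rio.write_mask(mask, mask_dir / f"rosette_{i + 1}.png")
        vec = measure_rosette(mask)
        rows.append({"line": f"S{i + 1}", "replicate": 1, "das": config.das_list[0], **vec.as_dict()})
    rosette_csv = out / "rosette_descriptors.csv"
    pd.DataFrame(rows).to_csv(rosette_csv, index=False)
    outputs["rosette_descriptors"] = rosette_csv

    # --- stage 2: MAGIC genotypes + gene annotation -----------------------
    seed = derive_seed(config.seed, "magic")
    log.info("stage magic: %d lines, %s markers", config.n_lines, config.n_markers_per_chrom)
    panel = simulate_founders(
        config.n_founders, config.n_markers_per_chrom, seed=seed
    )
    pop = simulate_magic_population(
        panel,
        config.n_lines,
        config.expected_breakpoints_per_chrom,
        error_rate=config.genotyping_error,
        seed=seed + 1,
    )
    outputs.update(rio.write_genotypes(pop, out / "geno"))
    genes = _synthetic_genes(panel, config.genes_per_chrom)
    gff_path = out / "genes.gff3"
    rio.write_gff3(genes, gff_path)
    outputs["genes"] = gff_path

    # --- stage 3: phenotypes with a planted QTL ---------------------------
    seed = derive_seed(config.seed, "phenotypes")
    marker = config.qtl_marker
    if marker is None:
        sl = panel.chrom_slices()[panel.chromosomes()[0]]
        marker = panel.markers["marker"].iloc[(sl.start + sl.stop) // 2]
    rng = np.random.default_rng(seed)
    effects = rng.normal(0.0, 1.0, size=config.n_founders)
    tables = []
    truth_info = {"causal_marker": str(marker), "qtl_trait": config.qtl_trait}
    for d_i, das in enumerate(config.das_list):
        merged = None
        for t_i, trait in enumerate(DESCRIPTOR_NAMES):
            plan = QTLPlan(
                causal_marker=marker,
                founder_effects=effects if trait == config.qtl_trait else np.zeros(config.n_founders),
                line_variance=config.line_variance,
                noise_variance=config.noise_variance,
                n_replicates=config.n_replicates,
                qtl_variance_fraction=(
                    config.qtl_variance_fraction if trait == config.qtl_trait else None
                ),
                trait=trait,
                das=das,
            )
            tab, realized = simulate_phenotypes(pop, plan, seed=seed + 31 * d_i + t_i)
            if trait == config.qtl_trait:
                truth_info[f"realized_qtl_fraction_das{das}"] = realized["qtl_fraction"]
            merged = tab if merged is None else merged.merge(
                tab, on=["line", "replicate", "das"]
            )
        tables.append(merged)
    pheno = pd.concat(tables, ignore_index=True)
    pheno_csv = out / "phenotypes.csv"
    rio.write_phenotype_table(pheno, pheno_csv)
    outputs["phenotypes"] = pheno_csv

    # --- stage 4: phenotype statistics ------------------------------------
    log.info("stage phenostats")
    averaged = phenostats.average_replicates(pheno)
    averaged_csv = out / "averaged.csv"
    averaged.to_csv(averaged_csv, index=False)
    outputs["averaged"] = averaged_csv
    for das in config.das_list:
        corr = phenostats.correlations_by_das(averaged, das)
        p = out / f"correlations_{das}.csv"
        corr.to_csv(p)
        outputs[f"correlations_{das}"] = p
    herit = phenostats.heritability_table(pheno)
    herit_csv = out / "heritability.csv"
    herit.to_csv(herit_csv, index=False)
    outputs["heritability"] = herit_csv
    model = phenostats.build_morphospace(averaged)
    model.loadings.to_csv(out / "pca_loadings.csv", index_label="descriptor")
    model.scores.to_csv(out / "pca_scores.csv", index=False)
    outputs["pca_loadings"] = out / "pca_loadings.csv"
    outputs["pca_scores"] = out / "pca_scores.csv"

    # --- stage 5: founder probabilities + scans ---------------------------
    seed = derive_seed(config.seed, "scan")
    log.info("stage scan: HMM + %d traits x %d DAS", 9, len(config.das_list))
    probs = qtl_scan.infer_founder_probabilities(
        pop, error_rate=config.hmm_error, mosaic_density=config.mosaic_density
    )
    designs = qtl_scan.MarkerDesigns(probs)
    traits = list(DESCRIPTOR_NAMES)
    pc_scores = model.scores if config.include_pcs else None
    if config.include_pcs:
        traits += model.component_names
    scans: list[qtl_scan.ScanResult] = []
    thr_rows = []
    scan_dir = out / "scans"
    scan_dir.mkdir(exist_ok=True)
    for das in config.das_list:
        sub = averaged[averaged["das"] == das].set_index("line")
        pcs = (
            pc_scores[pc_scores["das"] == das].set_index("line")
            if pc_scores is not None
            else None
        )
        for t_i, trait in enumerate(traits):
            source = sub if trait in DESCRIPTOR_NAMES else pcs
            y = source.reindex(probs.line_names)[trait].to_numpy(dtype=float)
            scan = qtl_scan.scan_trait(probs, y, trait=trait, das=das)
            thr = qtl_scan.permutation_threshold(
                designs,
                y,
                alpha=config.alpha,
                n_perm=config.n_perm,
                seed=seed + 101 * t_i + das,
            )
            table = scan.table.copy()
            for k, name in enumerate(probs.panel.founder_names):
                table[f"eff_{name}"] = scan.effects[name].to_numpy()
            p = scan_dir / f"scan_{trait}_{das}.csv"
            table.to_csv(p, index=False)
            outputs[f"scan_{trait}_{das}"] = p
            thr_rows.append(
                {
                    "trait": trait,
                    "das": das,
                    "alpha": config.alpha,
                    "n_perm": config.n_perm,
                    "logP_threshold": thr.logp_threshold,
                }
            )
            scan._threshold = thr  # carried to the peak stage
            scans.append(scan)
    thresholds = pd.DataFrame(thr_rows)
    thr_csv = out / "thresholds.csv"
    thresholds.to_csv(thr_csv, index=False)
    outputs["thresholds"] = thr_csv

    # --- stage 6: peaks, redundancy filter, tables, nearest genes ---------
    log.info("stage peaks")
    records = []
    for scan in scans:
        records.extend(qtl_post.call_qtl_peaks(scan, scan._threshold))
    kept = qtl_post.filter_redundant_qtls(records)
    gene_records = qtl_post.read_gff3_genes(gff_path)
    qtls = qtl_post.annotate_records(kept, gene_records)
    qtl_csv = out / "qtls.csv"
    qtls.to_csv(qtl_csv, index=False)
    outputs["qtls"] = qtl_csv
    tables = qtl_post.tabulate_qtls(kept)
    for key, df in tables.items():
        p = out / f"tables_{key}.csv"
        df.to_csv(p, index_label=key)
        outputs[f"tables_{key}"] = p

    manifest = {
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: derive_seed(config.seed, s) for s in STAGES},
        "qtl_truth": truth_info,
        "n_qtls_raw": len(records),
        "n_qtls_filtered": len(kept),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("pipeline done: %d raw QTLs, %d after redundancy filter", len(records), len(kept))
    return manifest


def _synthetic_genes(panel, genes_per_chrom: int) -> pd.DataFrame:
    """Evenly tiled synthetic gene models spanning each chromosome."""
    rows = []
    for chrom, sl in panel.chrom_slices().items():
        lo = int(panel.markers["pos_bp"].iloc[sl.start])
        hi = int(panel.markers["pos_bp"].iloc[sl.stop - 1])
        span = max(hi - lo, 1)
        step = span // max(genes_per_chrom, 1)
        length = max(step // 2, 1)
        for g in range(genes_per_chrom):
            start = lo + g * step
            rows.append(
                {
                    "gene_id": f"{chrom}G{g + 1:03d}",
                    "chrom": chrom,
                    "start_bp": start,
                    "end_bp": start + length,
                    "annotation": "synthetic gene model",
                }
            )
    return pd.DataFrame(rows)
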