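"""File formats: masks (PNG + JSON sidecar), phenotype CSVs, genotype CSVs.

All tabular interchange is plain CSV.  Phenotype tables are long format
with identifier columns line, replicate, das followed by one numeric
column per descriptor; masks are 8-bit single-channel images with
foreground 255 and a JSON sidecar holding the mm-per-pixel scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from rosetteqtl.magicsim import FounderPanel, MagicGenotypes
from rosetteqtl.morphometry import RosetteMask

__all__ = [
    "write_mask",
    "read_mask",
    "read_phenotype_table",
    "write_phenotype_table",
    "write_genotypes",
    "read_genotypes",
    "write_gff3",
]

REQUIRED_ID_COLUMNS = ("line", "replicate", "das")


def write_mask(mask: RosetteMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit PNG/TIFF plus a JSON scale sidecar."""
    path = Path(path)
    img = Image.fromarray((mask.foreground * 255).astype(np.uint8), mode="L")
    img.save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"mm_per_px": mask.mm_per_px, "source_id": mask.source_id})
    )


def read_mask(path: str | Path, mm_per_px: float | None = None) -> RosetteMask:
    """Read a mask image; the scale comes from the sidecar unless given."""
    path = Path(path)
    source_id = path.stem
    if mm_per_px is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no mm_per_px given and no sidecar {sidecar.name}"
            )
        meta = json.loads(sidecar.read_text())
        mm_per_px = float(meta["mm_per_px"])
        source_id = meta.get("source_id", source_id)
    pixels = np.asarray(Image.open(path).convert("L"))
    return RosetteMask(pixels=pixels > 127, mm_per_px=mm_per_px, source_id=source_id)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format phenotype CSV.

    Raises with the offending column or row number on missing identifier
    columns or non-numeric descriptor cells.
    """
    table = pd.read_csv(path)
    for col in REQUIRED_ID_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    value_cols = [c for c in table.columns if c not in REQUIRED_ID_COLUMNS]
    if not value_cols:
        raise ValueError("phenotype table has no descriptor columns")
    for col in value_cols:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value in column {col!r} at row {row + 2} "
                f"(including header): {table[col].iloc[row]!r}"
            )
        table[col] = coerced
    table["replicate"] = table["replicate"].astype(int)
    table["das"] = table["das"].astype(int)
    table["line"] = table["line"].astype(str)
    return table


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_genotypes(pop: MagicGenotypes, out_dir: str | Path) -> dict[str, Path]:
    """Write founders.csv, rils.csv and (if present) truth.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = pop.panel
    founders = panel.markers.copy()
    for i, name in enumerate(panel.founder_names):
        founders[name] = panel.alleles[i]
    f_path = out_dir / "founders.csv"
    founders.to_csv(f_path, index=False)
    rils = pd.DataFrame(
        pop.calls.T, index=panel.markers["marker"], columns=pop.line_names
    )
    r_path = out_dir / "rils.csv"
    rils.to_csv(r_path, index_label="marker")
    paths = {"founders": f_path, "rils": r_path}
    if pop.mosaic is not None:
        t_path = out_dir / "truth.csv"
        pop.mosaic.to_csv(t_path, index=False)
        paths["truth"] = t_path
    return paths


def read_genotypes(geno_dir: str | Path) -> MagicGenotypes:
    """Read founders.csv + rils.csv back into a genotype object."""
    geno_dir = Path(geno_dir)
    founders = pd.read_csv(geno_dir / "founders.csv")
    map_cols = ["marker", "chrom", "pos_bp", "pos_cM"]
    founder_names = [c for c in founders.columns if c not in map_cols]
    panel = FounderPanel(
        markers=founders[map_cols].copy(),
        alleles=founders[founder_names].to_numpy(dtype=np.int8).T,
        founder_names=founder_names,
    )
    rils = pd.read_csv(geno_dir / "rils.csv").set_index("marker")
    rils = rils.reindex(panel.markers["marker"])
    calls = rils.to_numpy(dtype=np.int8).T
    return MagicGenotypes(
        panel=panel, calls=calls, line_names=list(rils.columns)
    )


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a minimal GFF3 gene annotation.

    ``genes`` needs columns gene_id, chrom, start_bp, end_bp and
    optionally annotation; coordinates are 1-based inclusive.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            note = str(g.get("annotation", "")).replace(";", ",")
            attrs = f"ID={g['gene_id']}"
            if note:
                attrs += f";Note={note}"
            fh.write(
                f"{g['chrom']}\trosetteqtl\tgene\t{int(g['start_bp'])}\t"
                f"{int(g['end_bp'])}\t.\t+\t.\t{attrs}\n"
            )
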