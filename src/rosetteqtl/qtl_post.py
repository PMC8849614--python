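"""QTL post-processing: peaks, redundancy filtering, tables, nearest genes.

A QTL is a maximal run of contiguous markers (within one chromosome)
whose logP meets the genome-wide threshold; its location is the peak
marker with the largest logP inside the run (ties break to the lowest
position).  Because the same locus is often significant on several days
and descriptors, records are de-duplicated by walking days in ascending
order and, within a day, descriptors in their canonical order followed
by PC1..PC9, keeping a record only if its peak marker has not been kept
before.  Counts per day, per variable and per chromosome (with
cumulative sums) summarise the filtered list, and each kept QTL is
annotated with the closest gene from a GFF3 annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rosetteqtl.morphometry import DESCRIPTOR_NAMES

__all__ = [
    "QTLRecord",
    "GeneRecord",
    "TRAIT_ORDER",
    "call_qtl_peaks",
    "filter_redundant_qtls",
    "tabulate_qtls",
    "nearest_gene",
    "read_gff3_genes",
    "annotate_records",
]

#: Canonical trait order used by the redundancy filter: the nine shape
#: descriptors in table order, then the principal components.
TRAIT_ORDER = tuple(DESCRIPTOR_NAMES) + tuple(f"PC{i}" for i in range(1, 10))


@dataclass
class QTLRecord:
    """One called QTL: trait x DAS x peak marker with its interval."""

    trait: str
    das: int
    chrom: str
    start_bp: int
    end_bp: int
    peak_marker: str
    peak_pos_bp: int
    peak_logp: float
    variance_explained: float
    threshold: float
    founder_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start_bp <= self.peak_pos_bp <= self.end_bp:
            raise ValueError("interval must contain the peak marker")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene, 1-based inclusive coordinates (GFF3)."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("gene start must be <= end")

    def distance_to(self, pos_bp: int) -> int:
        if self.start_bp <= pos_bp <= self.end_bp:
            return 0
        return min(abs(pos_bp - self.start_bp), abs(pos_bp - self.end_bp))


def call_qtl_peaks(scan, threshold) -> list[QTLRecord]:
    """Call QTLs as maximal threshold-passing marker runs per chromosome.

    ``scan`` is a ScanResult; ``threshold`` a Threshold object or float.
    Runs never bridge sub-threshold markers; the peak is the run's
    largest logP, ties resolved to the lowest position.
    """
    thr = threshold.logp_threshold if hasattr(threshold, "logp_threshold") else float(threshold)
    table = scan.table
    records: list[QTLRecord] = []
    for chrom, grp in table.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp").reset_index(drop=True)
        passing = (grp["logP"] >= thr).to_numpy()
        if not passing.any():
            continue
        edges = np.diff(np.concatenate([[0], passing.astype(int), [0]]))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        for a, b in zip(starts, stops):
            run = grp.iloc[a:b]
            peak = run.sort_values(["logP", "pos_bp"], ascending=[False, True]).iloc[0]
            effects = {}
            if peak["marker"] in scan.effects.index:
                effects = scan.effects.loc[peak["marker"]].dropna().to_dict()
            records.append(
                QTLRecord(
                    trait=scan.trait,
                    das=scan.das if scan.das is not None else 0,
                    chrom=str(chrom),
                    start_bp=int(run["pos_bp"].iloc[0]),
                    end_bp=int(run["pos_bp"].iloc[-1]),
                    peak_marker=str(peak["marker"]),
                    peak_pos_bp=int(peak["pos_bp"]),
                    peak_logp=float(peak["logP"]),
                    variance_explained=float(peak["var_explained"]),
                    threshold=thr,
                    founder_effects=effects,
                )
            )
    return records


def _trait_rank(trait: str) -> int:
    try:
        return TRAIT_ORDER.index(trait)
    except ValueError:
        raise ValueError(f"unknown trait label {trait!r}") from None


def filter_redundant_qtls(
    records: list[QTLRecord], window_bp: int = 0
) -> list[QTLRecord]:
    """Keep the first report of each locus, walking days then descriptors.

    Records are visited in ascending DAS and, within a day, in canonical
    trait order (descriptors then PCs).  A record is kept iff no earlier
    kept record has the same peak marker (or, with ``window_bp`` > 0, a
    peak within that distance on the same chromosome).  Output is sorted
    by day then trait; filtering is idempotent.
    """
    ordered = sorted(records, key=lambda r: (r.das, _trait_rank(r.trait), r.chrom, r.peak_pos_bp))
    kept: list[QTLRecord] = []
    for rec in ordered:
        duplicate = False
        for prev in kept:
            if window_bp <= 0:
                if prev.peak_marker == rec.peak_marker:
                    duplicate = True
                    break
            elif prev.chrom == rec.chrom and abs(prev.peak_pos_bp - rec.peak_pos_bp) <= window_bp:
                duplicate = True
                break
        if not duplicate:
            kept.append(rec)
    return kept


def tabulate_qtls(
    records: list[QTLRecord],
) -> dict[str, pd.DataFrame]:
    """Per-day, per-variable and per-chromosome QTL counts.

    Each table carries a cumulative sum; the three grand totals are equal
    (every record contributes to exactly one cell of each table).
    """
    def counts(keys, order=None):
        ser = pd.Series(keys, dtype=object).value_counts()
        if order is not None:
            ser = ser.reindex([k for k in order if k in ser.index])
        else:
            ser = ser.sort_index()
        df = pd.DataFrame({"n_qtls": ser.astype(int)})
        df["cumulative"] = df["n_qtls"].cumsum()
        return df

    by_day = counts([r.das for r in records])
    by_var = counts([r.trait for r in records], order=TRAIT_ORDER)
    by_chrom = counts([r.chrom for r in records])
    return {"day": by_day, "variable": by_var, "chromosome": by_chrom}


def nearest_gene(
    chrom: str, pos_bp: int, genes: list[GeneRecord]
) -> GeneRecord | None:
    """The gene closest to a marker position (0 if the marker is inside).

    Ties break to the lower start coordinate; returns None when the
    marker's chromosome carries no annotated gene.
    """
    candidates = [g for g in genes if g.chrom == chrom]
    if not candidates:
        return None
    return min(candidates, key=lambda g: (g.distance_to(pos_bp), g.start_bp))


def read_gff3_genes(path) -> list[GeneRecord]:
    """Read gene features (1-based inclusive) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        note = feat.attributes.get("Note", feat.attributes.get("description", [""]))
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=feat.seqid,
                start_bp=feat.start,
                end_bp=feat.end,
                annotation=note[0] if note else "",
            )
        )
    return genes


def annotate_records(
    records: list[QTLRecord], genes: list[GeneRecord]
) -> pd.DataFrame:
    """One row per QTL with its nearest gene (or 'no annotation')."""
    rows = []
    for r in records:
        g = nearest_gene(r.chrom, r.peak_pos_bp, genes)
        rows.append(
            {
                "trait": r.trait,
                "das": r.das,
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "peak_marker": r.peak_marker,
                "peak_pos_bp": r.peak_pos_bp,
                "peak_logP": r.peak_logp,
                "var_explained": r.variance_explained,
                "threshold": r.threshold,
                "nearest_gene": g.gene_id if g else "no annotation",
                "gene_distance_bp": g.distance_to(r.peak_pos_bp) if g else -1,
                "gene_annotation": g.annotation if g else "",
            }
        )
    return pd.DataFrame(rows)
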