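"""Simulator for a multiparent (MAGIC-like) mapping population.

A MAGIC population is founded by inter-crossing many accessions (19 for
the Arabidopsis population this package targets) followed by generations
of selfing, so each recombinant inbred line (RIL) genome is a fine mosaic
of founder haplotypes.  The simulator does not replay the crossing funnel
generation by generation; it draws an equivalent Markov mosaic along each
chromosome with a configurable expected breakpoint count, which is all
the downstream haplotype-reconstruction and QTL machinery consumes.

Three layers are generated, each deterministic in (inputs, seed):

1. a founder panel — biallelic SNP alleles for each founder on a marker
   map (:func:`simulate_founders`);
2. line mosaics and genotypes — Poisson breakpoints, uniform founder per
   segment, SNP calls read off the founder alleles with a symmetric
   genotyping error (:func:`simulate_magic_population`);
3. replicated phenotypes with a planted QTL — founder effects at a causal
   marker plus line and replicate noise (:func:`simulate_phenotypes`),
   the forward model matched to the variance-decomposition model used
   for heritability estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FounderPanel",
    "MagicGenotypes",
    "QTLPlan",
    "simulate_founders",
    "simulate_magic_population",
    "simulate_phenotypes",
]

DEFAULT_N_FOUNDERS = 19


class SimulationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class FounderPanel:
    """Founder SNP alleles on a marker map.

    ``markers`` has columns marker, chrom, pos_bp, pos_cM (sorted by
    chromosome then position, strictly increasing within chromosome);
    ``alleles`` is (n_founders, n_markers) over {0, 1}.
    """

    markers: pd.DataFrame
    alleles: np.ndarray
    founder_names: list[str]

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "pos_bp", "pos_cM"}
        if not required.issubset(self.markers.columns):
            raise SimulationError(f"marker map needs columns {sorted(required)}")
        if self.alleles.shape != (len(self.founder_names), len(self.markers)):
            raise SimulationError("alleles shape does not match map/founders")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos_cM"].is_monotonic_increasing or grp["pos_cM"].duplicated().any():
                raise SimulationError("positions must be strictly increasing per chromosome")

    @property
    def n_founders(self) -> int:
        return len(self.founder_names)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        out = {}
        chroms = self.markers["chrom"].to_numpy()
        for c in self.chromosomes():
            idx = np.flatnonzero(chroms == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out


@dataclass
class MagicGenotypes:
    """Observed SNP calls of the RILs plus (for simulations) the truth.

    ``calls`` is (n_lines, n_markers) with values 0/1 and -1 for missing.
    ``founder_truth`` carries the simulator's founder-of-origin indicator
    for every (line, marker) cell, used only to validate reconstruction.
    """

    panel: FounderPanel
    calls: np.ndarray
    line_names: list[str]
    founder_truth: np.ndarray | None = None
    mosaic: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.line_names), self.panel.n_markers):
            raise SimulationError("calls shape does not match lines/markers")


@dataclass
class QTLPlan:
    """A planted QTL plus the variance components of the phenotype model.

    ``founder_effects`` (trait units, one per founder) act at
    ``causal_marker``.  If ``qtl_variance_fraction`` is set, the effects
    are rescaled so the QTL explains that fraction of the total
    phenotypic variance realised in the simulated lines.  ``line_variance``
    is the residual genetic (among-line) variance not due to the QTL;
    ``noise_variance`` is the replicate-level environmental variance.
    """

    causal_marker: str
    founder_effects: np.ndarray
    line_variance: float = 0.0
    noise_variance: float = 1.0
    n_replicates: int = 3
    qtl_variance_fraction: float | None = None
    mean: float = 0.0
    trait: str = "trait"
    das: int = 35

    def __post_init__(self) -> None:
        self.founder_effects = np.asarray(self.founder_effects, dtype=float)
        if self.line_variance < 0 or self.noise_variance < 0:
            raise SimulationError("variance components must be non-negative")
        if self.qtl_variance_fraction is not None and not (
            0 <= self.qtl_variance_fraction < 1
        ):
            raise SimulationError("qtl_variance_fraction must be in [0, 1)")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")


def simulate_founders(
    n_founders: int = DEFAULT_N_FOUNDERS,
    n_markers_per_chrom: tuple[int, ...] = (100, 100, 100, 100, 100),
    maf_range: tuple[float, float] = (0.2, 0.5),
    seed: int = 0,
    cm_spacing: float = 1.0,
    bp_per_cm: int = 250_000,
) -> FounderPanel:
    """Draw a biallelic founder panel on an equally spaced cM map.

    Each marker's minor-allele frequency across founders is uniform in
    ``maf_range``; founder alleles are independent Bernoulli draws.
    Marker ids are ``<chrom>_m<idx>``; physical positions scale the cM map
    by ``bp_per_cm``.
    """
    if n_founders < 2:
        raise SimulationError("need at least 2 founders")
    lo, hi = maf_range
    if not (0 < lo <= hi < 1):
        raise SimulationError("maf_range must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for ci, n_mark in enumerate(n_markers_per_chrom, start=1):
        chrom = f"Chr{ci}"
        for m in range(n_mark):
            pos_cm = m * cm_spacing
            rows.append(
                (f"{chrom}_m{m}", chrom, int(pos_cm * bp_per_cm) + 1, pos_cm)
            )
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "pos_cM"])
    freqs = rng.uniform(lo, hi, size=len(markers))
    alleles = (rng.random((n_founders, len(markers))) < freqs).astype(np.int8)
    names = [f"F{i + 1}" for i in range(n_founders)]
    return FounderPanel(markers=markers, alleles=alleles, founder_names=names)


def simulate_magic_population(
    panel: FounderPanel,
    n_lines: int,
    expected_breakpoints_per_chrom: float = 3.0,
    error_rate: float = 0.01,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> MagicGenotypes:
    """Simulate RIL mosaics and their SNP calls from a founder panel.

    Per line and chromosome the number of breakpoints is Poisson with the
    given mean, breakpoint positions are uniform over the chromosome's cM
    span and each segment's founder is uniform over the panel.  SNP calls
    copy the segment founder's allele, flipped with probability
    ``error_rate`` and masked to missing (-1) with ``missing_rate``.
    """
    if panel.n_markers == 0:
        raise SimulationError("empty founder panel")
    if n_lines < 1:
        raise SimulationError("n_lines must be >= 1")
    if expected_breakpoints_per_chrom < 0:
        raise SimulationError("breakpoint rate must be >= 0")
    rng = np.random.default_rng(seed)
    n_mark = panel.n_markers
    truth = np.empty((n_lines, n_mark), dtype=np.int16)
    seg_rows = []
    slices = panel.chrom_slices()
    pos = panel.markers["pos_cM"].to_numpy()
    line_names = [f"L{i + 1}" for i in range(n_lines)]
    for li in range(n_lines):
        for chrom, sl in slices.items():
            p = pos[sl]
            lo, hi = float(p[0]), float(p[-1])
            n_bp = rng.poisson(expected_breakpoints_per_chrom)
            cuts = np.sort(rng.uniform(lo, hi, size=n_bp))
            bounds = np.concatenate([[lo], cuts, [hi + 1e-9]])
            founders = rng.integers(0, panel.n_founders, size=len(bounds) - 1)
            seg_idx = np.clip(np.searchsorted(cuts, p, side="right"), 0, len(founders) - 1)
            truth[li, sl] = founders[seg_idx]
            for s in range(len(founders)):
                seg_rows.append(
                    (line_names[li], chrom, bounds[s], bounds[s + 1], int(founders[s]) + 1)
                )
    # vectorized founder lookup: alleles[founder, marker]
    calls = panel.alleles[truth, np.arange(n_mark)[None, :]].astype(np.int8)
    if error_rate > 0:
        flips = rng.random(calls.shape) < error_rate
        calls = np.where(flips, 1 - calls, calls)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, -1, calls)
    mosaic = pd.DataFrame(
        seg_rows, columns=["line", "chrom", "start_cM", "end_cM", "founder"]
    )
    return MagicGenotypes(
        panel=panel,
        calls=calls,
        line_names=line_names,
        founder_truth=truth,
        mosaic=mosaic,
    )


def simulate_phenotypes(
    population: MagicGenotypes, plan: QTLPlan, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Forward-simulate replicated phenotypes with a planted QTL.

    The phenotype of replicate j of line i is
    ``mean + effect[founder_i at causal marker] + b_i + e_ij`` with
    ``b_i ~ N(0, line_variance)`` and ``e_ij ~ N(0, noise_variance)`` —
    the same one-way random-effects law assumed by the heritability
    estimator, plus the founder-effect QTL term.

    Returns a long-format table (line, replicate, das, <trait>) and the
    realised variance decomposition (fractions of total variance).
    """
    if population.founder_truth is None:
        raise SimulationError("population lacks founder truth; cannot place QTL")
    markers = population.panel.markers["marker"].to_numpy()
    hits = np.flatnonzero(markers == plan.causal_marker)
    if len(hits) == 0:
        raise SimulationError(f"causal marker {plan.causal_marker!r} not in panel")
    if len(plan.founder_effects) != population.panel.n_founders:
        raise SimulationError("founder_effects length != n_founders")
    rng = np.random.default_rng(seed)
    founder_at_qtl = population.founder_truth[:, hits[0]]
    effects = plan.founder_effects.copy()
    genetic = effects[founder_at_qtl]
    var_qtl = float(np.var(genetic))
    if plan.qtl_variance_fraction is not None:
        q = plan.qtl_variance_fraction
        rest = plan.line_variance + plan.noise_variance
        if q == 0 or var_qtl == 0:
            effects[:] = 0.0
        else:
            if rest == 0:
                raise SimulationError(
                    "cannot target a variance fraction < 1 with zero residual variance"
                )
            effects *= np.sqrt(q * rest / ((1.0 - q) * var_qtl))
        genetic = effects[founder_at_qtl]
        var_qtl = float(np.var(genetic))
    n_lines = len(population.line_names)
    line_eff = rng.normal(0.0, np.sqrt(plan.line_variance), size=n_lines)
    rows = []
    values = np.empty((n_lines, plan.n_replicates))
    for j in range(plan.n_replicates):
        noise = rng.normal(0.0, np.sqrt(plan.noise_variance), size=n_lines)
        values[:, j] = plan.mean + genetic + line_eff + noise
    for i, line in enumerate(population.line_names):
        for j in range(plan.n_replicates):
            rows.append((line, j + 1, plan.das, values[i, j]))
    table = pd.DataFrame(rows, columns=["line", "replicate", "das", plan.trait])
    total = var_qtl + plan.line_variance + plan.noise_variance
    realized = {
        "var_qtl": var_qtl,
        "var_line": plan.line_variance,
        "var_noise": plan.noise_variance,
        "qtl_fraction": var_qtl / total if total > 0 else 0.0,
    }
    return table, realized
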