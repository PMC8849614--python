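"""Founder-haplotype reconstruction and multiparent QTL scanning.

Reconstruction: each RIL genome is modelled per chromosome as a hidden
Markov chain over the 19 founder states.  Emissions compare the line's
SNP call with each founder's allele (1 - epsilon on match, epsilon on
mismatch, uninformative on missing); transitions between adjacent
markers allow a founder switch with probability given by the Haldane map
function on the inter-marker distance, scaled so the expected number of
switches per chromosome matches a configurable mosaic density.  The
forward-backward posterior gives, per line and marker, a probability
vector over founders (identity-by-descent probabilities).

Scan: at every marker the phenotype is regressed on the founder
probability columns (the intercept lies in their span since each row
sums to one; rank deficiency is resolved by pseudo-inverse).  The
founder term is tested with an F-test (numerator df = rank - 1), and
-log10 p is reported together with the model R^2 (variance explained)
and founder-effect estimates shrunk toward their common mean with
founder-specific precision (an empirical-Bayes random-effects summary).
Genome-wide significance comes from a permutation test: the phenotype is
permuted across lines, the maximum -log10 p per permutation is recorded,
and the threshold is the empirical (1 - alpha) quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rosetteqtl.magicsim import FounderPanel, MagicGenotypes

__all__ = [
    "FounderProbabilities",
    "ScanResult",
    "Threshold",
    "infer_founder_probabilities",
    "MarkerDesigns",
    "scan_trait",
    "permutation_threshold",
    "founder_effect_summary",
]

DEFAULT_ERROR_RATE = 0.01
DEFAULT_MOSAIC_DENSITY = 3.0  # expected founder switches per chromosome
MAX_MISSING_FRACTION = 0.2


@dataclass
class FounderProbabilities:
    """Posterior founder-of-origin probabilities per line and marker."""

    panel: FounderPanel
    probs: np.ndarray  # (n_lines, n_markers, n_founders)
    line_names: list[str]

    def __post_init__(self) -> None:
        expected = (len(self.line_names), self.panel.n_markers, self.panel.n_founders)
        if self.probs.shape != expected:
            raise ValueError(f"probs shape {self.probs.shape} != {expected}")

    @property
    def n_lines(self) -> int:
        return len(self.line_names)


@dataclass
class ScanResult:
    """Per-marker association statistics for one trait."""

    trait: str
    das: int | None
    table: pd.DataFrame  # marker, chrom, pos_bp, pos_cM, logP, var_explained
    effects: pd.DataFrame = field(repr=False)  # markers x founders (shrunk)
    effect_sds: pd.DataFrame = field(repr=False)

    @property
    def max_logp(self) -> float:
        return float(self.table["logP"].max())


@dataclass
class Threshold:
    """Permutation-based genome-wide significance threshold."""

    alpha: float
    n_permutations: int
    logp_threshold: float
    seed: int
    max_logp_distribution: np.ndarray = field(default=None, repr=False)


def _haldane_switch_probs(panel: FounderPanel, mosaic_density: float) -> np.ndarray:
    """Per-interval founder-switch probability, 0 at chromosome starts.

    Inter-marker cM distances are scaled so the expected number of
    switches along each chromosome equals ``mosaic_density``, then mapped
    through Haldane's function r = (1 - exp(-2d))/2.
    """
    pos = panel.markers["pos_cM"].to_numpy(dtype=float)
    r = np.zeros(panel.n_markers)
    for _, sl in panel.chrom_slices().items():
        p = pos[sl]
        span = p[-1] - p[0]
        if span <= 0:
            continue
        d_morgan = np.diff(p) * mosaic_density / span
        r[sl.start + 1 : sl.stop] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    return r


def infer_founder_probabilities(
    genotypes: MagicGenotypes,
    error_rate: float = DEFAULT_ERROR_RATE,
    mosaic_density: float = DEFAULT_MOSAIC_DENSITY,
) -> FounderProbabilities:
    """Forward-backward founder posterior for every retained line.

    Lines with more than 20% missing calls are dropped with a warning.
    Posterior rows sum to one; with unambiguous emissions the posterior
    concentrates on the true founder, with completely uninformative
    markers it is uniform.
    """
    panel = genotypes.panel
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    calls = genotypes.calls
    missing_frac = (calls < 0).mean(axis=1)
    keep = missing_frac <= MAX_MISSING_FRACTION
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} lines with >20% missing calls",
            stacklevel=2,
        )
    keep_idx = np.flatnonzero(keep)
    n_lines = len(keep_idx)
    K = panel.n_founders
    r = _haldane_switch_probs(panel, mosaic_density)
    slices = panel.chrom_slices()
    alleles = panel.alleles  # (K, M)
    probs = np.empty((n_lines, panel.n_markers, K))
    for out_i, li in enumerate(keep_idx):
        c = calls[li]
        # emission likelihoods (M, K)
        match = alleles.T == c[:, None]
        emit = np.where(match, 1.0 - error_rate, error_rate)
        emit[c < 0] = 1.0
        for _, sl in slices.items():
            e = emit[sl]
            rr = r[sl.start : sl.stop]
            m = e.shape[0]
            fwd = np.empty((m, K))
            bwd = np.empty((m, K))
            f = e[0] / K
            fwd[0] = f / f.sum()
            for t in range(1, m):
                stay = 1.0 - rr[t]
                switch = rr[t] / (K - 1)
                pred = (stay - switch) * fwd[t - 1] + switch
                f = pred * e[t]
                fwd[t] = f / f.sum()
            b = np.ones(K)
            bwd[m - 1] = b
            for t in range(m - 2, -1, -1):
                stay = 1.0 - rr[t + 1]
                switch = rr[t + 1] / (K - 1)
                v = bwd[t + 1] * e[t + 1]
                b = (stay - switch) * v + switch * v.sum()
                bwd[t] = b / b.sum()
            post = fwd * bwd
            post /= post.sum(axis=1, keepdims=True)
            probs[out_i, sl.start : sl.stop] = post
    return FounderProbabilities(
        panel=panel,
        probs=probs,
        line_names=[genotypes.line_names[i] for i in keep_idx],
    )


class MarkerDesigns:
    """Precomputed per-marker regression bases for fast repeated scans.

    For each marker the founder-probability design (whose column span
    contains the intercept) is reduced to an orthonormal basis by SVD;
    F-statistics for any phenotype — or batch of permuted phenotypes —
    then cost one matrix product per marker.
    """

    def __init__(self, probs: FounderProbabilities):
        self.panel = probs.panel
        self.line_names = probs.line_names
        n, m, k = probs.probs.shape
        self.n_lines = n
        self.bases: list[np.ndarray] = []
        self.ranks = np.empty(m, dtype=int)
        self.pinvs: list[np.ndarray] = []
        for j in range(m):
            x = probs.probs[:, j, :]
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            r = int((s > s[0] * 1e-9).sum()) if s[0] > 0 else 0
            self.bases.append(u[:, :r])
            self.ranks[j] = r
            self.pinvs.append(vt[:r].T @ (u[:, :r] / s[:r]).T)

    def logp_r2(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """-log10 p and R^2 per marker for phenotype columns ``y``.

        ``y`` may be 1-D (one trait) or (n_lines, k) for a batch; returns
        arrays of shape (n_markers,) or (n_markers, k).
        """
        y2d = np.atleast_2d(y.T).T.astype(float)
        n, k = y2d.shape
        tss = ((y2d - y2d.mean(axis=0)) ** 2).sum(axis=0)
        m = len(self.bases)
        logp = np.zeros((m, k))
        r2 = np.zeros((m, k))
        for j, q in enumerate(self.bases):
            r = self.ranks[j]
            df1 = r - 1
            df2 = n - r
            if df1 < 1 or df2 < 1:
                continue
            qty = q.T @ y2d
            rss = np.maximum(
                (y2d**2).sum(axis=0) - (qty**2).sum(axis=0), 1e-300
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                fstat = ((tss - rss) / df1) / (rss / df2)
                fstat = np.where(tss > 0, np.maximum(fstat, 0.0), 0.0)
                pval = stats.f.sf(fstat, df1, df2)
                logp[j] = -np.log10(np.maximum(pval, 1e-300))
                r2[j] = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        if y.ndim == 1:
            return logp[:, 0], r2[:, 0]
        return logp, r2


def _shrunk_effects(
    x: np.ndarray, pinv: np.ndarray, y: np.ndarray, rank: int
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes founder means at one marker.

    Raw least-squares founder means (pseudo-inverse solution) are shrunk
    toward their probability-mass-weighted average with weights from the
    ratio of between-founder to sampling variance; founders carrying
    little probability mass get strong shrinkage and wide uncertainty.
    """
    n = len(y)
    raw = pinv @ y
    resid = y - x @ raw
    df = max(n - rank, 1)
    sigma2 = float(resid @ resid) / df
    mass = x.sum(axis=0)
    s2 = sigma2 / np.maximum(mass, 1e-9)
    wmean = float(np.sum(mass * raw) / mass.sum())
    tau2 = max(0.0, float(np.average((raw - wmean) ** 2, weights=mass)) - s2.mean())
    lam = tau2 / (tau2 + s2)
    eff = wmean + lam * (raw - wmean)
    sd = np.sqrt(lam * s2)
    return eff, sd


def scan_trait(
    probs: FounderProbabilities | MarkerDesigns,
    phenotype: np.ndarray | pd.Series,
    trait: str = "trait",
    das: int | None = None,
    with_effects: bool = True,
) -> ScanResult:
    """Genome scan of one phenotype over all markers.

    ``phenotype`` must be ordered like the probability object's lines.
    A constant phenotype yields logP = 0 everywhere with a warning.
    """
    designs = probs if isinstance(probs, MarkerDesigns) else MarkerDesigns(probs)
    raw_probs = None if isinstance(probs, MarkerDesigns) else probs.probs
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != designs.n_lines:
        raise ValueError("phenotype length does not match lines")
    if np.ptp(y) == 0:
        warnings.warn("constant phenotype: logP set to 0 genome-wide", stacklevel=2)
    logp, r2 = designs.logp_r2(y)
    table = designs.panel.markers.copy()
    table["logP"] = logp
    table["var_explained"] = r2
    founders = designs.panel.founder_names
    markers = table["marker"].tolist()
    if with_effects and raw_probs is not None:
        eff = np.empty((len(markers), len(founders)))
        sds = np.empty_like(eff)
        for j in range(len(markers)):
            eff[j], sds[j] = _shrunk_effects(
                raw_probs[:, j, :], designs.pinvs[j], y, designs.ranks[j]
            )
        effects = pd.DataFrame(eff, index=markers, columns=founders)
        effect_sds = pd.DataFrame(sds, index=markers, columns=founders)
    else:
        effects = pd.DataFrame(index=markers, columns=founders, dtype=float)
        effect_sds = effects.copy()
    return ScanResult(
        trait=trait, das=das, table=table, effects=effects, effect_sds=effect_sds
    )


def permutation_threshold(
    probs: FounderProbabilities | MarkerDesigns,
    phenotype: np.ndarray | pd.Series,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
    batch: int = 100,
) -> Threshold:
    """Genome-wide logP threshold from phenotype permutations.

    The phenotype vector is permuted across lines ``n_perm`` times, the
    genome-wide maximum logP recorded for each permutation, and the
    threshold taken as the empirical (1 - alpha) quantile with linear
    (type-7) interpolation.  Deterministic given ``seed``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    designs = probs if isinstance(probs, MarkerDesigns) else MarkerDesigns(probs)
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    maxes = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.column_stack([rng.permutation(y) for _ in range(b)])
        logp, _ = designs.logp_r2(perms)
        maxes[done : done + b] = logp.max(axis=0)
        done += b
    thr = float(np.quantile(maxes, 1.0 - alpha))
    return Threshold(
        alpha=alpha,
        n_permutations=n_perm,
        logp_threshold=thr,
        seed=seed,
        max_logp_distribution=maxes,
    )


def founder_effect_summary(scan: ScanResult, marker: str) -> pd.DataFrame:
    """Founder-effect estimates and normal-approximation intervals."""
    if marker not in scan.effects.index:
        raise KeyError(f"marker {marker!r} not in scan")
    eff = scan.effects.loc[marker]
    sd = scan.effect_sds.loc[marker]
    return pd.DataFrame(
        {
            "founder": eff.index,
            "effect": eff.to_numpy(),
            "sd": sd.to_numpy(),
            "lower": eff.to_numpy() - 1.96 * sd.to_numpy(),
            "upper": eff.to_numpy() + 1.96 * sd.to_numpy(),
        }
    )
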