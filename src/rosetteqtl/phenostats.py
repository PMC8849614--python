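"""Phenotype statistics: averaging, correlations, heritability, morphospace.

Replicate values of each line are averaged per day after sowing (DAS) and
all downstream analyses use the line means.  Broad-sense heritability is
estimated per descriptor and DAS from the one-way random-effects model

    P_ij = mu + R_i + e_ij,   R_i ~ N(0, Vg),  e_ij ~ N(0, Ve),

fitted by restricted maximum likelihood (profile likelihood in the
variance ratio), with H^2 = Vg / (Vg + Ve).  The morphospace is the PCA
of the correlation matrix of the nine descriptors over line-averaged
rows pooled across DAS; all nine components are retained so between-line
distances are preserved up to the per-descriptor standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from rosetteqtl.morphometry import DESCRIPTOR_NAMES

__all__ = [
    "average_replicates",
    "correlations_by_das",
    "heritability",
    "HeritabilityEstimate",
    "MorphospaceModel",
    "build_morphospace",
    "project_morphospace",
]

ID_COLUMNS = ("line", "replicate", "das")


def _descriptor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate values per (line, das).

    Missing replicate values are ignored in the mean; the number of
    replicates contributing to each cell is recorded in ``n_replicates``
    (the maximum across descriptors of that row).  Rows where every
    replicate of every descriptor is missing are dropped with a warning.
    """
    value_cols = _descriptor_columns(table)
    if not value_cols:
        raise ValueError("phenotype table has no descriptor columns")
    grouped = table.groupby(["line", "das"], sort=True)
    means = grouped[value_cols].mean()
    counts = grouped[value_cols].count().max(axis=1)
    out = means.reset_index()
    out["n_replicates"] = counts.to_numpy()
    empty = out[value_cols].isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} (line, das) cells with no data",
            stacklevel=2,
        )
        out = out[~empty].reset_index(drop=True)
    return out


def correlations_by_das(averaged: pd.DataFrame, das: int) -> pd.DataFrame:
    """Pairwise Pearson correlations of descriptor means at one DAS.

    Zero-variance descriptors yield missing entries (reported as NaN).
    Requires at least 3 lines at that DAS.
    """
    rows = averaged[averaged["das"] == das]
    if len(rows) < 3:
        raise ValueError(f"need >= 3 lines at das {das}, have {len(rows)}")
    cols = [c for c in _descriptor_columns(rows) if c != "n_replicates"]
    return rows[cols].corr(method="pearson", min_periods=3)


@dataclass
class HeritabilityEstimate:
    """REML variance components and broad-sense heritability for one trait."""

    descriptor: str
    das: int
    vg: float
    ve: float

    @property
    def h2(self) -> float:
        total = self.vg + self.ve
        return self.vg / total if total > 0 else 0.0


def _oneway_reml(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML fit of the one-way random-intercept model.

    Profiles the likelihood in the variance ratio lambda = Vg/Ve; the
    residual variance has a closed form given lambda.  Returns (Vg, Ve)
    with Vg truncated at zero.
    """
    uniq, inv = np.unique(groups, return_inverse=True)
    n_i = np.bincount(inv).astype(float)
    s1 = np.bincount(inv, weights=values)
    s2 = np.bincount(inv, weights=values**2)
    N = float(len(values))
    if len(uniq) < 2:
        return 0.0, float(np.var(values, ddof=1)) if N > 1 else 0.0

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = 1.0 + n_i * lam
        w = n_i / denom
        sw = w.sum()
        q = float(np.sum(s2 - lam / denom * s1**2) - (np.sum(s1 / denom)) ** 2 / sw)
        q = max(q, 1e-300)
        return (N - 1.0) * np.log(q) + float(np.sum(np.log(denom))) + np.log(sw)

    res = minimize_scalar(neg2_reml, bounds=(-30.0, 30.0), method="bounded")
    lam = float(np.exp(res.x))
    if neg2_reml(-30.0) <= res.fun:  # boundary solution: no line variance
        lam = 0.0
    denom = 1.0 + n_i * lam
    w = n_i / denom
    q = float(np.sum(s2 - lam / denom * s1**2) - (np.sum(s1 / denom)) ** 2 / w.sum())
    ve = max(q / (N - 1.0), 0.0)
    return lam * ve, ve


def heritability(
    table: pd.DataFrame, descriptor: str, das: int
) -> HeritabilityEstimate:
    """Estimate broad-sense heritability of one descriptor at one DAS.

    Degenerate inputs (all observations equal) give Vg = 0, H^2 = 0.
    """
    rows = table[(table["das"] == das)][["line", descriptor]].dropna()
    if rows["line"].nunique() < 2:
        raise ValueError("need >= 2 lines with data")
    values = rows[descriptor].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        return HeritabilityEstimate(descriptor, das, 0.0, 0.0)
    vg, ve = _oneway_reml(values, rows["line"].to_numpy())
    return HeritabilityEstimate(descriptor, das, vg, ve)


def heritability_table(table: pd.DataFrame) -> pd.DataFrame:
    """H^2 for every descriptor x DAS combination present in the table."""
    out = []
    for das in sorted(table["das"].unique()):
        for desc in _descriptor_columns(table):
            est = heritability(table, desc, das)
            out.append((desc, das, est.vg, est.ve, est.h2))
    return pd.DataFrame(out, columns=["descriptor", "das", "Vg", "Ve", "H2"])


@dataclass
class MorphospaceModel:
    """Correlation-matrix PCA of the descriptor space.

    Stores the standardization (per-descriptor mean and SD pooled over
    all line-averaged rows), the orthonormal loadings, eigenvalues and
    variance fractions, and the scores of the training rows.
    """

    descriptors: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: pd.DataFrame  # descriptors x components
    eigenvalues: np.ndarray
    scores: pd.DataFrame  # line, das, PC1..PCk

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def component_names(self) -> list[str]:
        return list(self.loadings.columns)


def build_morphospace(
    averaged: pd.DataFrame, descriptors: list[str] | None = None
) -> MorphospaceModel:
    """Fit the all-components correlation-matrix PCA on line-averaged rows.

    Rows are pooled over all DAS; each descriptor is standardized by its
    pooled mean and SD, the correlation matrix is eigendecomposed, and
    all components are retained.  Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    if descriptors is None:
        descriptors = [
            c
            for c in averaged.columns
            if c in DESCRIPTOR_NAMES or (c not in ID_COLUMNS and c != "n_replicates")
        ]
    if len(averaged) < 10:
        raise ValueError("need >= 10 rows to build the morphospace")
    data = averaged[descriptors].to_numpy(dtype=float)
    if np.isnan(data).any():
        raise ValueError("missing descriptor values; complete rows required")
    means = data.mean(axis=0)
    sds = data.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if len(zero):
        raise ValueError(f"zero-variance descriptor: {descriptors[zero[0]]}")
    z = (data - means) / sds
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # reproducible sign: dominant loading positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(len(descriptors))]
    loadings = pd.DataFrame(eigvec, index=descriptors, columns=comp_names)
    scores = pd.DataFrame(z @ eigvec, columns=comp_names)
    scores.insert(0, "das", averaged["das"].to_numpy())
    scores.insert(0, "line", averaged["line"].to_numpy())
    return MorphospaceModel(
        descriptors=list(descriptors),
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=eigval,
        scores=scores,
    )


def project_morphospace(
    model: MorphospaceModel, rows: pd.DataFrame
) -> pd.DataFrame:
    """Project new line-averaged rows into a fitted morphospace.

    Uses the model's stored standardization; the transform is orthogonal,
    so Euclidean distances between standardized rows are preserved.
    """
    missing = [d for d in model.descriptors if d not in rows.columns]
    if missing:
        raise ValueError(f"missing descriptor columns: {missing}")
    z = (rows[model.descriptors].to_numpy(dtype=float) - model.means) / model.sds
    scores = pd.DataFrame(
        z @ model.loadings.to_numpy(), columns=model.component_names
    )
    for col in ("das", "line"):
        if col in rows.columns:
            scores.insert(0, col, rows[col].to_numpy())
    return scores
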