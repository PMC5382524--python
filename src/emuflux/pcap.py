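"""Principal component analysis of proteomics with production overlay (PCAP).

Given a strains-by-proteins abundance matrix and a bioproduct titer per
strain, PCA locates the directions of coordinated proteome variation; the
component most correlated with production then ranks proteins as
engineering targets — the loading magnitude says how strongly a protein
moves along the production axis, its sign (relative to the correlation
sign) whether to increase or decrease it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import ValidationError

__all__ = ["OmicsMatrix", "PCAPResult", "TargetRanking", "pcap_analyze", "rank_targets"]


@dataclass
class OmicsMatrix:
    """Rows = strains/conditions, columns = proteins, plus production titers."""

    data: pd.DataFrame
    production: pd.Series

    def __post_init__(self) -> None:
        if isinstance(self.data, np.ndarray):
            self.data = pd.DataFrame(self.data)
        if not isinstance(self.production, pd.Series):
            self.production = pd.Series(np.asarray(self.production), index=self.data.index)
        if len(self.production) != len(self.data):
            raise ValidationError("production length must equal the number of rows")
        if self.data.isna().any().any():
            raise ValidationError("omics matrix contains missing entries; impute first")

    @property
    def n_strains(self) -> int:
        return len(self.data)

    @property
    def proteins(self) -> list:
        return list(self.data.columns)


@dataclass
class PCAPResult:
    """PCA scores/loadings with the production vector bound to the scores."""

    scores: np.ndarray  # strains x k
    loadings: np.ndarray  # proteins x k
    explained_variance: np.ndarray  # k fractions, nonincreasing
    proteins: list
    strains: list
    production: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.strains, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.proteins, columns=cols)

    def score_production_correlations(self) -> np.ndarray:
        prod = self.production - self.production.mean()
        if np.allclose(prod, 0):
            raise ValidationError("production has zero variance")
        out = []
        for j in range(self.scores.shape[1]):
            s = self.scores[:, j]
            denom = np.linalg.norm(s) * np.linalg.norm(prod)
            out.append(float(s @ prod / denom) if denom > 0 else 0.0)
        return np.array(out)


def pcap_analyze(matrix: OmicsMatrix, k: int = 2, scale: bool = True, log: bool = False) -> PCAPResult:
    """PCA of the (column-centered, optionally unit-variance) omics matrix.

    Requires at least 3 strains and ``k <= min(n_strains - 1, n_proteins)``.
    Sign convention: each loading vector's largest-magnitude entry is made
    positive, so results are deterministic across runs and libraries.
    """
    X = matrix.data.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValidationError("PCAP requires at least 3 strains/conditions")
    if not 1 <= k <= min(n - 1, p):
        raise ValidationError(f"k={k} out of range for a {n}x{p} matrix")
    if log:
        if np.any(X <= 0):
            raise ValidationError("log transform requires strictly positive abundances")
        X = np.log(X)
    means = X.mean(axis=0)
    Xc = X - means
    col_sd = Xc.std(axis=0, ddof=1)
    if np.all(col_sd == 0):
        raise ValidationError("degenerate omics matrix: no protein varies")
    scales = np.ones(p)
    if scale:
        scales = np.where(col_sd > 0, col_sd, 1.0)
        Xc = Xc / scales

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xc)
    loadings = pca.components_.T  # proteins x k, orthonormal columns

    # deterministic sign: dominant loading entry positive
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    return PCAPResult(
        scores=scores,
        loadings=loadings,
        explained_variance=pca.explained_variance_ratio_,
        proteins=matrix.proteins,
        strains=list(matrix.data.index),
        production=matrix.production.to_numpy(dtype=float),
        column_means=means,
        column_scales=scales,
    )


@dataclass
class TargetRanking:
    """Proteins ordered by |loading| on the production-correlated component."""

    component: int  # 0-based index of the component used
    correlation: float  # correlation of that component's scores with production
    proteins: list  # ordered, strongest first
    loadings: np.ndarray  # loading of each listed protein, same order
    recommendations: list = field(default_factory=list)  # "increase"/"decrease"

    def top(self, n: int) -> list:
        return self.proteins[:n]


def rank_targets(result: PCAPResult, component: int | None = None) -> TargetRanking:
    """Rank proteins as engineering targets for higher production.

    Uses the principal component whose scores correlate most strongly (in
    magnitude) with production unless ``component`` is given explicitly.
    A protein whose loading carries the same sign as the correlation should
    be increased to push production up; opposite sign, decreased.
    """
    corrs = result.score_production_correlations()
    if component is None:
        component = int(np.argmax(np.abs(corrs)))
    if not 0 <= component < result.scores.shape[1]:
        raise ValidationError(f"component {component} out of range")
    corr = corrs[component]
    load = result.loadings[:, component]
    order = np.argsort(-np.abs(load))
    proteins = [result.proteins[i] for i in order]
    ordered = load[order]
    direction = np.sign(corr) if corr != 0 else 1.0
    recommendations = ["increase" if l * direction > 0 else "decrease" for l in ordered]
    return TargetRanking(
        component=component,
        correlation=float(corr),
        proteins=proteins,
        loadings=ordered,
        recommendations=recommendations,
    )
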