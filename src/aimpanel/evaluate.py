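"""Quantitative panel evaluation against the complete SNP set.

A reduced panel is judged by refitting the admixture model on the panel's
SNPs alone (same K, tolerance, restart and seed policy as the reference
fit, so differences reflect the panel rather than optimizer noise),
aligning the fitted components to the reference to undo label switching,
and measuring the per-individual Euclidean distance between the two
ancestry vectors. Panels are then compared by a one-way ANOVA over the
per-individual distances followed by Tukey's HSD post hoc test.

Statistical caveat, kept faithful to common practice rather than "fixed":
the distance vectors of different panels share individuals, so the ANOVA
independence assumption is violated; p-values are descriptive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .admixture import AdmixtureFit, align_components, fit_admixture
from .genotype_io import GenotypeMatrix
from .panels import Panel, subset_genotypes
from .scoring import normalize_genotypes

#: Distances below this count as "zero" (individuals recovered exactly).
ZERO_TOLERANCE = 1e-3


@dataclass
class DistanceReport:
    """Per-individual Q-distance between a panel fit and the reference fit."""

    panel_name: str
    individual_ids: list[str]
    distances: np.ndarray
    alignment: tuple[int, ...]

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    @property
    def n_zero(self) -> int:
        return int((self.distances <= ZERO_TOLERANCE).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "panel": self.panel_name,
                "individual_id": self.individual_ids,
                "distance": self.distances,
            }
        )

    def write(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class ComparisonTable:
    """ANOVA + Tukey HSD over the per-individual distances of several panels."""

    panel_names: list[str]
    anova_f: float
    anova_p: float
    pairs: pd.DataFrame  # columns: panel_a, panel_b, mean_diff, p_adj

    def pair_p(self, a: str, b: str) -> float:
        """Tukey-adjusted p for one pair, symmetric in argument order."""
        hit = self.pairs[
            ((self.pairs.panel_a == a) & (self.pairs.panel_b == b))
            | ((self.pairs.panel_a == b) & (self.pairs.panel_b == a))
        ]
        if hit.empty:
            raise KeyError(f"no such panel pair: {a!r}, {b!r}")
        return float(hit["p_adj"].iloc[0])

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#anova_f={self.anova_f:.6g}\n#anova_p={self.anova_p:.6g}\n")
            self.pairs.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def q_distances(q_ref: np.ndarray, q_panel: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean distance between two aligned Q matrices."""
    return np.sqrt(((np.asarray(q_ref) - np.asarray(q_panel)) ** 2).sum(axis=1))


def evaluate_panel(
    G_full: GenotypeMatrix,
    panel: Panel,
    K: int,
    seed: int = 0,
    reference: AdmixtureFit | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 3,
    return_fit: bool = False,
):
    """Distance report for one panel against the full-set reference fit.

    The reference fit is computed on ``G_full`` with the identical seed
    and optimizer settings if not supplied. The panel fit's components are
    aligned to the reference by optimal assignment before distances are
    taken, so label switching never inflates them.
    """
    if len(panel) < K:
        raise ValueError(f"panel of {len(panel)} SNPs cannot support K={K} clusters")
    if reference is None:
        reference = fit_admixture(G_full, K, seed=seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts)
    if reference.K != K:
        raise ValueError("reference fit has a different K")
    G_sub = subset_genotypes(G_full, panel)
    panel_fit = fit_admixture(G_sub, K, seed=seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts)
    alignment = align_components(reference.Q, panel_fit.Q)
    aligned = alignment.apply(panel_fit.Q.proportions)
    report = DistanceReport(
        panel_name=panel.name,
        individual_ids=list(G_full.individual_ids),
        distances=q_distances(reference.Q.proportions, aligned),
        alignment=alignment.permutation,
    )
    return (report, panel_fit) if return_fit else report


def compare_panels(reports: list[DistanceReport]) -> ComparisonTable:
    """One-way ANOVA + all-pairs Tukey HSD over per-individual distances."""
    if len(reports) < 2:
        raise ValueError("need at least two distance reports to compare")
    ids0 = reports[0].individual_ids
    for rep in reports[1:]:
        if rep.individual_ids != ids0:
            raise ValueError("distance reports cover different individual sets")
    groups = [rep.distances for rep in reports]
    names = [rep.panel_name for rep in reports]
    f_stat, p_val = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            rows.append(
                {
                    "panel_a": names[a],
                    "panel_b": names[b],
                    "mean_diff": float(groups[a].mean() - groups[b].mean()),
                    "p_adj": float(tukey.pvalue[a, b]),
                }
            )
    return ComparisonTable(
        panel_names=names,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        pairs=pd.DataFrame(rows),
    )


@dataclass
class PCAProjection:
    """Per-individual PC coordinates with variance-explained fractions."""

    individual_ids: list[str]
    coordinates: np.ndarray          # n x n_components, column c = PC c+1
    variance_explained: np.ndarray   # fraction per returned component

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"PC{c + 1}": self.coordinates[:, c] for c in range(self.coordinates.shape[1])}
        return pd.DataFrame({"individual_id": self.individual_ids, **cols})


def project_pca(G: GenotypeMatrix, n_components: int = 2) -> PCAProjection:
    """Principal-component coordinates of the individuals.

    Uses the same genotype normalisation as the SNP-weight scoring, so
    coordinates and weights come from one spectral decomposition:
    coordinates are U * S of the normalised matrix and the variance
    explained by each component is its eigenvalue's share of the computed
    spectrum. Deterministic up to a global sign per component.
    """
    n, m = G.n_individuals, G.n_snps
    if n < 2:
        raise ValueError("PCA requires >=2 individuals")
    if not 1 <= n_components <= min(n - 1, m):
        raise ValueError(f"n_components must be in 1..{min(n - 1, m)}")
    X = normalize_genotypes(G)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    eigvals = s**2
    var_frac = eigvals[:n_components] / eigvals.sum()
    return PCAProjection(
        individual_ids=list(G.individual_ids),
        coordinates=coords,
        variance_explained=var_frac,
    )
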