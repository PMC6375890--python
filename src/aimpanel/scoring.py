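"""Per-SNP ancestry-informativeness scores and top-N panel extraction.

Four scoring schemes are provided, all rankable per SNP:

``informativeness``
    Rosenberg's informativeness-for-assignment *I*: an entropy decomposition
    of allele frequencies across K predefined populations (natural log,
    ``0 ln 0 := 0``). Bounded by ``0 <= I <= ln K``; zero iff all
    populations share identical frequencies.
``fst``
    Weir & Cockerham's (1984) per-locus method-of-moments estimator
    theta-hat = a / (a + b + c), computed from observed allele frequencies
    and heterozygote proportions. Negative estimates are kept by default
    (they carry ranking information); an optional clamp to 0 is offered.
``pca_weight``
    SNP loadings of a chosen principal component of the genotype matrix,
    normalised the smartpca way: columns centred, scaled by
    sqrt(p(1-p)) with p the small-sample-corrected allele frequency,
    missing cells mean-imputed. Ranking uses |loading| since the sign of a
    PC is arbitrary.
``k_variance``
    Column-to-column sample variance (denominator K-1) of each SNP's row
    of an admixture P matrix: SNPs whose cluster-specific frequencies
    disagree most across the K clusters.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PMatrix

METHODS = ("informativeness", "fst", "pca_weight", "k_variance")


@dataclass
class AlleleFrequencyTable:
    """Per-SNP, per-population biallelic frequencies.

    ``p_alt[j, i]`` is the alternate-allele frequency of SNP j in
    population i (NaN where the population has no non-missing call), and
    ``counts[j, i]`` the number of observed allele copies behind it.
    ``p_mean`` is the unweighted mean of ``p_alt`` over populations — the
    "mean frequency over all populations" entering the informativeness
    statistic, deliberately not the sample-size-weighted pooled frequency.
    """

    snp_ids: list[str]
    population_labels: list[str]
    p_alt: np.ndarray
    counts: np.ndarray
    chromosomes: list[str] = field(default_factory=list)
    positions: list[int] = field(default_factory=list)
    weighted_mean: bool = False

    @property
    def K(self) -> int:
        return len(self.population_labels)

    @property
    def p_mean(self) -> np.ndarray:
        """Mean alternate-allele frequency over populations, per SNP."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if self.weighted_mean:
                w = self.counts.astype(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    return np.nansum(np.nan_to_num(self.p_alt) * w, axis=1) / w.sum(axis=1)
            return np.nanmean(self.p_alt, axis=1)


@dataclass
class ScoreTable:
    """One score per SNP for a single method; NaN marks unscorable SNPs."""

    snp_ids: list[str]
    chromosomes: list[str]
    positions: list[int]
    method: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.snp_ids) == len(self.chromosomes) == len(self.positions) == self.scores.size):
            raise ValueError("ScoreTable fields must have equal length")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chromosome": self.chromosomes,
                "position": self.positions,
                "method": self.method,
                "score": self.scores,
            }
        )

    def write(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        method = str(df["method"].iloc[0]) if len(df) else "unknown"
        return cls(
            snp_ids=df["snp_id"].astype(str).tolist(),
            chromosomes=df["chromosome"].astype(str).tolist(),
            positions=df["position"].astype(int).tolist(),
            method=method,
            scores=df["score"].to_numpy(),
        )


@dataclass
class SelectionConfig:
    """Panel-extraction knobs: top-N size, K-variance threshold, PC index."""

    top_n: int = 10_000
    variance_threshold: float = 0.15
    pc_index: int = 1

    def __post_init__(self) -> None:
        if self.top_n <= 0:
            raise ValueError("top_n must be positive")
        if self.pc_index <= 0:
            raise ValueError("pc_index must be positive (1-based)")


def resolve_labels(G: GenotypeMatrix, labels=None) -> np.ndarray:
    """Population label per individual: explicit mapping/sequence or FIDs."""
    if labels is None:
        return np.asarray(G.family_ids, dtype=object)
    if isinstance(labels, dict):
        missing = [iid for iid in G.individual_ids if iid not in labels]
        if missing:
            raise ValueError(f"no population label for individuals: {missing}")
        return np.asarray([labels[iid] for iid in G.individual_ids], dtype=object)
    labels = np.asarray(labels, dtype=object)
    if labels.size != G.n_individuals:
        raise ValueError("label vector length does not match individuals")
    return labels


def compute_allele_freqs(
    G: GenotypeMatrix,
    labels=None,
    weighted_mean: bool = False,
) -> AlleleFrequencyTable:
    """Per-population alternate-allele frequencies from genotype counts.

    For population i at SNP j the frequency is (sum of genotypes) /
    (2 x non-missing individuals); a population with zero non-missing
    calls gets NaN there. SNPs missing in every individual are entirely
    NaN and flagged unscorable downstream.
    """
    lab = resolve_labels(G, labels)
    pops = sorted(set(lab.tolist()))
    gt = G.genotypes.astype(float)
    obs = G.genotypes != MISSING
    gt[~obs] = 0.0

    m, K = G.n_snps, len(pops)
    p_alt = np.full((m, K), np.nan)
    counts = np.zeros((m, K), dtype=int)
    for i, pop in enumerate(pops):
        rows = lab == pop
        n_obs = obs[rows].sum(axis=0)
        alt = gt[rows].sum(axis=0)
        counts[:, i] = 2 * n_obs
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt[:, i] = np.where(n_obs > 0, alt / (2 * n_obs), np.nan)
    return AlleleFrequencyTable(
        snp_ids=list(G.snp_ids),
        population_labels=[str(p) for p in pops],
        p_alt=p_alt,
        counts=counts,
        chromosomes=list(G.chromosomes),
        positions=list(G.positions),
        weighted_mean=weighted_mean,
    )


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * ln(x) with the 0 ln 0 := 0 convention."""
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    out[np.isnan(x)] = np.nan
    return out


def informativeness(freqs: AlleleFrequencyTable) -> ScoreTable:
    """Rosenberg informativeness-for-assignment per SNP.

    I = sum over the two alleles j of
    [ -p_j ln p_j + sum_i (p_ij / K) ln p_ij ],
    with p_j the unweighted mean of p_ij over the K populations.
    Any SNP with an undefined population frequency is NaN (unscorable),
    never silently dropped. Tiny negative values from floating-point
    cancellation are clipped to 0.
    """
    if freqs.K < 2:
        raise ValueError("informativeness requires K >= 2 populations")
    K = freqs.K
    total = np.zeros(len(freqs.snp_ids))
    p_mean = freqs.p_mean
    for allele_freq, mean_freq in ((freqs.p_alt, p_mean), (1.0 - freqs.p_alt, 1.0 - p_mean)):
        total += -_xlogx(mean_freq) + _xlogx(allele_freq).sum(axis=1) / K
    total = np.where(np.isnan(total), np.nan, np.maximum(total, 0.0))
    return ScoreTable(
        snp_ids=list(freqs.snp_ids),
        chromosomes=list(freqs.chromosomes) or [""] * len(freqs.snp_ids),
        positions=list(freqs.positions) or [0] * len(freqs.snp_ids),
        method="informativeness",
        scores=total,
    )


def _wc_components(G: GenotypeMatrix, labels=None):
    """Weir-Cockerham per-locus variance components (a, b, c) and validity mask."""
    lab = resolve_labels(G, labels)
    pops = sorted(set(lab.tolist()))
    r = len(pops)
    if r < 2:
        raise ValueError("F_ST requires >=2 populations")

    obs = G.genotypes != MISSING
    gt = G.genotypes.astype(float)
    gt[~obs] = 0.0
    het = (G.genotypes == 1).astype(float)

    m = G.n_snps
    n_i = np.zeros((r, m))   # sampled individuals per pop per SNP
    p_i = np.full((r, m), np.nan)
    h_i = np.zeros((r, m))   # observed heterozygote proportion
    for idx, pop in enumerate(pops):
        rows = lab == pop
        n_obs = obs[rows].sum(axis=0).astype(float)
        n_i[idx] = n_obs
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[idx] = np.where(n_obs > 0, gt[rows].sum(axis=0) / (2 * n_obs), np.nan)
            h_i[idx] = np.where(n_obs > 0, het[rows].sum(axis=0) / n_obs, 0.0)

    valid = (n_i > 0).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    return a, b, c, valid, (n_i, p_i)


def genome_fst(G: GenotypeMatrix, labels=None) -> float:
    """Multi-locus Weir-Cockerham theta-hat: sum(a) / sum(a + b + c).

    The ratio-of-sums ("weighted") combination across loci is the
    estimator whose expectation tracks the generating differentiation
    parameter; averaging the per-locus ratios instead is downward-biased
    and only suited to ranking.
    """
    a, b, c, valid, _ = _wc_components(G, labels)
    return float(a[valid].sum() / (a + b + c)[valid].sum())


def wc_fst(
    G: GenotypeMatrix,
    labels=None,
    clamp_negative: bool = False,
    estimator: str = "wc",
) -> ScoreTable:
    """Per-SNP fixation index F_ST across the labelled populations.

    The default is the Weir-Cockerham (1984) two-level theta-hat
    a / (a + b + c) from observed allele frequencies and heterozygote
    proportions (what PLINK 1.9 ``--fst`` reports per locus). SNPs where
    some population has no non-missing call, or where a + b + c = 0, are
    NaN. ``estimator="hudson"`` switches to the Hudson two-population
    estimator 1 - Hw/Hb.
    """
    a, b, c, valid, (n_i, p_i) = _wc_components(G, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "hudson":
            if n_i.shape[0] != 2:
                raise ValueError("Hudson estimator is defined for exactly 2 populations")
            p1, p2 = p_i[0], p_i[1]
            c1, c2 = 2 * n_i[0], 2 * n_i[1]  # sampled allele counts
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (c1 - 1) - p2 * (1 - p2) / (c2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            theta = np.where(den != 0, num / den, np.nan)
        elif estimator == "wc":
            denom = a + b + c
            theta = np.where(denom != 0, a / denom, np.nan)
        else:
            raise ValueError(f"unknown estimator: {estimator!r}")

    theta = np.where(valid, theta, np.nan)
    if clamp_negative:
        theta = np.where(np.isnan(theta), np.nan, np.maximum(theta, 0.0))
    return ScoreTable(
        snp_ids=list(G.snp_ids),
        chromosomes=list(G.chromosomes),
        positions=list(G.positions),
        method="fst",
        scores=theta,
    )


def normalize_genotypes(G: GenotypeMatrix) -> np.ndarray:
    """Centred, variance-standardised genotype matrix for PCA.

    Columns are centred by their observed mean and divided by
    sqrt(p(1-p)) with p = (1 + sum g) / (2 + 2 n_obs), the
    small-sample-corrected frequency of the smartpca normalisation;
    missing cells become 0 after centring (mean imputation).
    """
    obs = G.genotypes != MISSING
    gt = G.genotypes.astype(float)
    gt[~obs] = 0.0
    n_obs = obs.sum(axis=0).astype(float)
    if np.any(n_obs == 0):
        raise ValueError("normalize_genotypes: some SNPs have no non-missing calls")
    col_sum = gt.sum(axis=0)
    mean = col_sum / n_obs
    p_hat = (1.0 + col_sum) / (2.0 + 2.0 * n_obs)
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    X = (gt - mean) / scale
    X[~obs] = 0.0
    return X


def pca_snp_weights(G: GenotypeMatrix, pc_index: int = 1) -> ScoreTable:
    """SNP loadings for one principal component of the genotype matrix.

    Loadings are the right-singular vector of the normalised matrix for
    the requested (1-based) component. Monomorphic SNPs get weight exactly
    0. The returned score is the signed loading; ranking by ``top_n``
    should use its absolute value (handled there via ``method`` name).
    """
    n, m = G.n_individuals, G.n_snps
    if n < 2:
        raise ValueError("PCA requires >=2 individuals")
    max_pc = min(n - 1, m)
    if not 1 <= pc_index <= max_pc:
        raise ValueError(f"pc_index {pc_index} out of range 1..{max_pc}")
    X = normalize_genotypes(G)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    weights = vt[pc_index - 1]
    return ScoreTable(
        snp_ids=list(G.snp_ids),
        chromosomes=list(G.chromosomes),
        positions=list(G.positions),
        method="pca_weight",
        scores=weights,
    )


def k_variance(P: PMatrix, snp_meta: GenotypeMatrix | None = None, ddof: int = 1) -> ScoreTable:
    """Column-to-column sample variance of each SNP's P-matrix row."""
    if P.K < 2:
        raise ValueError("k_variance requires K >= 2 clusters")
    scores = P.frequencies.var(axis=1, ddof=ddof)
    if snp_meta is not None:
        idx = snp_meta.snp_index()
        chroms = [snp_meta.chromosomes[idx[s]] for s in P.snp_ids]
        poss = [snp_meta.positions[idx[s]] for s in P.snp_ids]
    else:
        chroms = [""] * len(P.snp_ids)
        poss = [0] * len(P.snp_ids)
    return ScoreTable(
        snp_ids=list(P.snp_ids),
        chromosomes=chroms,
        positions=poss,
        method="k_variance",
        scores=scores,
    )


def _ranking_frame(scores: ScoreTable) -> pd.DataFrame:
    df = scores.to_dataframe()
    rank_score = df["score"].abs() if scores.method == "pca_weight" else df["score"]
    df = df.assign(_rank_score=rank_score)
    df = df[df["_rank_score"].notna()]
    # Deterministic total order: score desc, then (chromosome, position, snp_id).
    return df.sort_values(
        by=["_rank_score", "chromosome", "position", "snp_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )


def top_n(scores: ScoreTable, cfg: SelectionConfig | int):
    """The top-N SNPs of a score table as a named :class:`~aimpanel.panels.Panel`.

    NaN-scored SNPs are excluded before ranking; ties at the selection
    boundary break by (chromosome, position, snp_id) so panels are
    bit-reproducible. For PCA weights the ranking criterion is |weight|.
    """
    from .panels import Panel  # local import to avoid a cycle

    n = cfg.top_n if isinstance(cfg, SelectionConfig) else int(cfg)
    ranked = _ranking_frame(scores)
    if n > len(ranked):
        raise ValueError(f"top_n={n} exceeds the {len(ranked)} scorable SNPs")
    chosen = ranked.head(n)["snp_id"].tolist()
    return Panel(
        name=f"{scores.method}_top{n}",
        snp_ids=chosen,
        provenance={"method": scores.method, "selection": "top_n", "top_n": n},
    )


def threshold_panel(scores: ScoreTable, threshold: float):
    """All SNPs whose score meets a threshold (the K-variance selection rule)."""
    from .panels import Panel

    ranked = _ranking_frame(scores)
    chosen = ranked[ranked["_rank_score"] >= threshold]["snp_id"].tolist()
    return Panel(
        name=f"{scores.method}_ge{threshold:g}",
        snp_ids=chosen,
        provenance={"method": scores.method, "selection": "threshold", "threshold": threshold},
    )
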