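"""Synthetic genotype cohorts with known admixture structure.

The generative model is the minimal standard one for F_ST-controlled
population differentiation:

* ancestral allele frequency per SNP: pi ~ Uniform(0.05, 0.95) (bounded
  away from fixation so most simulated SNPs stay polymorphic);
* population k's frequency: Balding-Nichols,
  p_k ~ Beta(pi (1-F_k)/F_k, (1-pi)(1-F_k)/F_k), so E[p_k] = pi and the
  differentiation of population k from the ancestral pool is F_k
  (F_k = 0 degenerates to p_k = pi exactly);
* individual i's ancestry q_i: per design group, either a fixed simplex
  row (one-hot rows model pure-bred individuals) or a Dirichlet draw;
* genotypes: g_il ~ Binomial(2, sum_k q_ik p_kl) — the same binomial
  admixture likelihood the inference module fits — with uniform random
  masking at ``missing_rate``.

No linkage disequilibrium is simulated: none of the scoring statistics or
the admixture model uses it. Every random draw flows from the single
``seed`` of the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PMatrix, QMatrix


@dataclass
class GroupSpec:
    """One design group: ``n`` individuals, ancestry fixed or Dirichlet-drawn."""

    n: int
    label: str
    q: list[float] | None = None      # fixed simplex row (e.g. one-hot = pure-bred)
    alpha: list[float] | None = None  # Dirichlet concentration, used when q is None

    def __post_init__(self) -> None:
        if (self.q is None) == (self.alpha is None):
            raise ValueError("exactly one of q or alpha must be given")
        if self.q is not None and abs(sum(self.q) - 1.0) > 1e-9:
            raise ValueError("fixed q row must sum to 1")


@dataclass
class SimulationConfig:
    """Stated world for one synthetic cohort."""

    K: int = 3
    groups: list[GroupSpec] = field(default_factory=list)
    m: int = 10_000
    F: list[float] | float = 0.2
    missing_rate: float = 0.0
    seed: int = 0
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        fs = self.f_vector()
        if np.any(fs < 0) or np.any(fs >= 1):
            raise ValueError("each F must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for g in self.groups:
            width = len(g.q if g.q is not None else g.alpha)
            if width != self.K:
                raise ValueError(f"group {g.label!r} design width {width} != K={self.K}")

    def f_vector(self) -> np.ndarray:
        f = np.asarray(self.F, dtype=float)
        return np.full(self.K, float(f)) if f.ndim == 0 else f

    @property
    def n(self) -> int:
        return sum(g.n for g in self.groups)


@dataclass
class SimulatedDataset:
    """A genotype matrix plus the truth that generated it."""

    genotypes: GenotypeMatrix
    true_Q: QMatrix
    true_P: PMatrix
    config: SimulationConfig


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one cohort under the Balding-Nichols admixture model."""
    if not config.groups:
        raise ValueError("config must define at least one design group")
    rng = np.random.default_rng(config.seed)
    K, m = config.K, config.m
    fs = config.f_vector()

    pi = rng.uniform(config.ancestral_low, config.ancestral_high, size=m)
    P = np.empty((m, K))
    for k in range(K):
        F = fs[k]
        if F == 0.0:
            P[:, k] = pi
        else:
            ratio = (1.0 - F) / F
            P[:, k] = rng.beta(pi * ratio, (1.0 - pi) * ratio)

    q_rows, family_ids, individual_ids = [], [], []
    counter = 0
    for group in config.groups:
        if group.q is not None:
            q_block = np.tile(np.asarray(group.q, dtype=float), (group.n, 1))
        else:
            q_block = rng.dirichlet(np.asarray(group.alpha, dtype=float), size=group.n)
        q_rows.append(q_block)
        for _ in range(group.n):
            family_ids.append(group.label)
            individual_ids.append(f"sim{counter:04d}")
            counter += 1
    Q = np.vstack(q_rows)

    f_il = Q @ P.T
    genotypes = rng.binomial(2, f_il).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    snp_ids = [f"snp{j:06d}" for j in range(m)]
    G = GenotypeMatrix(
        individual_ids=individual_ids,
        family_ids=family_ids,
        snp_ids=snp_ids,
        chromosomes=["1"] * m,
        positions=list(range(1, m + 1)),
        genotypes=genotypes,
        ref_alleles=["A"] * m,
        alt_alleles=["B"] * m,
    )
    return SimulatedDataset(
        genotypes=G,
        true_Q=QMatrix(individual_ids, Q),
        true_P=PMatrix(snp_ids, P),
        config=config,
    )


def gorilla_cohort(seed: int, m: int = 50_000, missing_rate: float = 0.0) -> SimulatedDataset:
    """A 31-individual, three-source cohort emulating a real gorilla resequencing cohort.

    Three source populations: one strongly diverged "eastern" source
    (F = 0.30; eastern and western gorillas are distinct species and are
    separable by almost any marker) and two weakly diverged western
    sources, "cameroon" and "congo" (F = 0.05 each), whose fine structure
    is what an AIMs panel must resolve. The design mirrors that cohort's composition: 3 pure eastern individuals, 6 pure Cameroonian, 2 pure
    Congolese, 19 admixed western individuals (Dirichlet with a small
    eastern concentration so a few carry trace eastern ancestry), and one
    outlier with minority third-source ancestry standing in for the single
    Cross River gorilla.
    """
    groups = [
        GroupSpec(n=3, label="eastern", q=[1.0, 0.0, 0.0]),
        GroupSpec(n=6, label="cameroon", q=[0.0, 1.0, 0.0]),
        GroupSpec(n=2, label="congo", q=[0.0, 0.0, 1.0]),
        GroupSpec(n=19, label="western_admixed", alpha=[0.05, 1.5, 1.5]),
        GroupSpec(n=1, label="outlier", q=[0.15, 0.70, 0.15]),
    ]
    config = SimulationConfig(
        K=3,
        groups=groups,
        m=m,
        F=[0.30, 0.05, 0.05],
        missing_rate=missing_rate,
        seed=seed,
    )
    return simulate(config)


def assignment_labels(dataset: SimulatedDataset) -> list[str]:
    """Population label per individual: the source with the largest true q.

    Mirrors assigning each genome a geographic family ID
    before scoring (labels came from prior biogeographic analysis, not
    from the genotypes being scored).
    """
    sources = ["eastern", "cameroon", "congo"][: dataset.true_Q.K]
    if dataset.true_Q.K > len(sources):
        sources = [f"pop{k}" for k in range(dataset.true_Q.K)]
    return [sources[int(k)] for k in dataset.true_Q.proportions.argmax(axis=1)]
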