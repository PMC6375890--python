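"""Candidate AIMs panels: consensus, random negative controls, re-ranking.

A :class:`Panel` is an ordered set of SNP ids with provenance (method,
parameters, seed) so every downstream table is traceable. The central
construction is the consensus rule: keep SNPs selected by at least
``min_methods`` of the per-method top-N panels, which balances out the
blind spots of any single scoring scheme. A size-matched uniformly random
panel serves as the negative control.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix
from .scoring import ScoreTable


@dataclass
class Panel:
    """A named, ordered SNP subset with provenance metadata."""

    name: str
    snp_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"panel {self.name!r} has duplicate SNP ids")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in set(self.snp_ids)

    def write(self, path: str | os.PathLike) -> None:
        """Text format: ``#key=value`` provenance header, one SNP id per line."""
        with open(path, "w") as fh:
            fh.write(f"#name={self.name}\n")
            for key in sorted(self.provenance):
                fh.write(f"#{key}={json.dumps(self.provenance[key], sort_keys=True)}\n")
            for sid in self.snp_ids:
                fh.write(f"{sid}\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "Panel":
        name = os.path.basename(str(path))
        provenance: dict = {}
        snp_ids: list[str] = []
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].partition("=")
                    if key == "name":
                        name = value
                    else:
                        try:
                            provenance[key] = json.loads(value)
                        except json.JSONDecodeError:
                            provenance[key] = value
                else:
                    snp_ids.append(line)
        return cls(name=name, snp_ids=snp_ids, provenance=provenance)


def consensus_panel(
    panels: list[Panel],
    min_methods: int,
    universe: GenotypeMatrix | None = None,
    name: str = "consensus",
) -> Panel:
    """SNPs selected by at least ``min_methods`` of the input panels.

    Each input panel counts once per SNP. Output order is (membership
    count descending, chromosome, position) when a genotype matrix is
    supplied for coordinates, else (count descending, snp_id); either way
    the order is deterministic and independent of panel input order.
    """
    if not panels:
        raise ValueError("consensus_panel needs at least one input panel")
    if not 1 <= min_methods <= len(panels):
        raise ValueError(f"min_methods must be in 1..{len(panels)}")
    counts: dict[str, int] = {}
    for panel in panels:
        for sid in set(panel.snp_ids):
            counts[sid] = counts.get(sid, 0) + 1
    members = [sid for sid, c in counts.items() if c >= min_methods]
    if universe is not None:
        idx = universe.snp_index()
        unknown = [s for s in members if s not in idx]
        if unknown:
            raise ValueError(f"consensus SNPs not in the supplied universe: {unknown[:5]}")
        members.sort(key=lambda s: (-counts[s], universe.chromosomes[idx[s]], universe.positions[idx[s]], s))
    else:
        members.sort(key=lambda s: (-counts[s], s))
    return Panel(
        name=name,
        snp_ids=members,
        provenance={
            "method": "consensus",
            "min_methods": min_methods,
            "inputs": sorted(p.name for p in panels),
        },
    )


def random_panel(G: GenotypeMatrix, size: int, seed: int, name: str = "random") -> Panel:
    """Uniform without-replacement SNP sample — the negative control."""
    if size > G.n_snps:
        raise ValueError(f"requested {size} SNPs but the matrix has {G.n_snps}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(G.n_snps, size=size, replace=False)
    return Panel(
        name=name,
        snp_ids=[G.snp_ids[i] for i in chosen],
        provenance={"method": "random", "size": size, "seed": seed},
    )


def rerank_panel(panel: Panel, scores: ScoreTable, size: int, name: str | None = None) -> Panel:
    """The ``size`` best panel members under a score (genotyping-subset stand-in).

    Ties break by (chromosome, position, snp_id) as everywhere else. A
    panel member without a finite score is an error, never dropped.
    """
    if size > len(panel):
        raise ValueError(f"size {size} exceeds panel of {len(panel)} SNPs")
    df = scores.to_dataframe().set_index("snp_id")
    missing = [s for s in panel.snp_ids if s not in df.index or not np.isfinite(df.loc[s, "score"])]
    if missing:
        raise ValueError(f"no usable {scores.method} score for panel members: {missing[:10]}")
    sub = df.loc[panel.snp_ids].reset_index()
    rank_score = sub["score"].abs() if scores.method == "pca_weight" else sub["score"]
    sub = sub.assign(_rank=rank_score).sort_values(
        by=["_rank", "chromosome", "position", "snp_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    chosen = sub.head(size)["snp_id"].tolist()
    return Panel(
        name=name or f"{panel.name}_rerank{size}",
        snp_ids=chosen,
        provenance={
            "method": "rerank",
            "parent": panel.name,
            "score": scores.method,
            "size": size,
        },
    )


def subset_genotypes(G: GenotypeMatrix, panel: Panel) -> GenotypeMatrix:
    """Restrict a genotype matrix to the panel's SNPs (source column order)."""
    if len(panel) == 0:
        raise ValueError("cannot subset to an empty panel")
    idx_map = G.snp_index()
    unknown = [s for s in panel.snp_ids if s not in idx_map]
    if unknown:
        raise ValueError(f"panel SNPs absent from the genotype matrix: {unknown[:10]}")
    keep = sorted(idx_map[s] for s in panel.snp_ids)
    return GenotypeMatrix(
        individual_ids=list(G.individual_ids),
        family_ids=list(G.family_ids),
        snp_ids=[G.snp_ids[j] for j in keep],
        chromosomes=[G.chromosomes[j] for j in keep],
        positions=[G.positions[j] for j in keep],
        genotypes=G.genotypes[:, keep].copy(),
        ref_alleles=[G.ref_alleles[j] for j in keep],
        alt_alleles=[G.alt_alleles[j] for j in keep],
    )
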