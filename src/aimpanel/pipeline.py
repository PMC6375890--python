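"""End-to-end workflow: score -> panels -> consensus + control -> evaluate.

One call (:func:`run_workflow`) runs the full AIMs workflow on any labelled
genotype matrix:

1. fit the reference admixture model (K clusters) on the complete SNP set;
2. score every SNP four ways (informativeness, Weir-Cockerham F_ST,
   |PC-1 loading|, K-variance of the fitted P matrix);
3. extract per-method panels — top-N for the first three, a variance
   threshold for the fourth (so its panel size is data-driven);
4. build the >=min_methods-of-4 consensus panel and a size-matched random
   negative control;
5. refit admixture on every panel, align to the reference, and report
   per-individual Euclidean Q distances plus an ANOVA/Tukey comparison.

Every output file is deterministic given the config (seeds included), so a
rerun reproduces the run byte for byte; a JSON manifest records all
parameters, seeds and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

from .admixture import AdmixtureFit, fit_admixture
from .evaluate import ComparisonTable, DistanceReport, compare_panels, evaluate_panel
from .genotype_io import GenotypeMatrix, read_plink_binary, read_plink_text, write_qp
from .panels import Panel, consensus_panel, random_panel
from .scoring import (
    ScoreTable,
    compute_allele_freqs,
    informativeness,
    k_variance,
    pca_snp_weights,
    threshold_panel,
    top_n,
    wc_fst,
)
from .simulate import gorilla_cohort

logger = logging.getLogger("aimpanel.pipeline")


@dataclass
class WorkflowConfig:
    """Flat parameter block for one workflow run."""

    # Input: either PLINK paths ...
    ped_path: str | None = None
    map_path: str | None = None
    bed_path: str | None = None
    bim_path: str | None = None
    fam_path: str | None = None
    label_file: str | None = None  # optional TSV: individual_id <tab> population
    # ... or a simulation preset.
    preset: str | None = None       # currently: "gorilla"
    preset_m: int = 50_000

    K: int = 3
    top_n: int = 10_000
    variance_threshold: float = 0.15
    min_methods: int = 3
    pc_index: int = 1
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 2000
    n_restarts: int = 3
    out_dir: str = "aimpanel_run"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WorkflowResult:
    """In-memory bundle of everything a run produced."""

    config: WorkflowConfig
    genotypes: GenotypeMatrix
    reference_fit: AdmixtureFit
    score_tables: dict[str, ScoreTable]
    panels: dict[str, Panel]
    fits: dict[str, AdmixtureFit]
    reports: dict[str, DistanceReport]
    comparison: ComparisonTable
    manifest: dict = field(default_factory=dict)


def _load_labels(path: str) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            iid, pop = line.split("\t")[:2]
            labels[iid] = pop
    return labels


def _load_input(cfg: WorkflowConfig) -> tuple[GenotypeMatrix, list[str] | dict[str, str] | None]:
    if cfg.preset is not None:
        if cfg.preset != "gorilla":
            raise ValueError(f"unknown preset {cfg.preset!r}")
        from .simulate import assignment_labels

        dataset = gorilla_cohort(seed=cfg.seed, m=cfg.preset_m)
        return dataset.genotypes, assignment_labels(dataset)
    if cfg.ped_path and cfg.map_path:
        G = read_plink_text(cfg.ped_path, cfg.map_path)
    elif cfg.bed_path and cfg.bim_path and cfg.fam_path:
        G = read_plink_binary(cfg.bed_path, cfg.bim_path, cfg.fam_path)
    else:
        raise ValueError("config must give a preset, a .ped/.map pair, or a .bed/.bim/.fam triple")
    labels = _load_labels(cfg.label_file) if cfg.label_file else None
    return G, labels


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, t0: float, **params) -> None:
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
                " ".join(f"{k}={v}" for k, v in params.items()))


def run_workflow(cfg: WorkflowConfig) -> WorkflowResult:
    """Run the full panel-discovery-and-validation workflow; write outputs."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    t0 = time.perf_counter()
    G, labels = _load_input(cfg)
    _stage("load", t0, n=G.n_individuals, m=G.n_snps)

    reference = fit_admixture(
        G, cfg.K, seed=cfg.seed, tol=cfg.tol, max_iter=cfg.max_iter, n_restarts=cfg.n_restarts
    )
    write_qp(reference.Q, reference.P, os.path.join(cfg.out_dir, "reference"))
    _stage("reference_fit", t0, loglik=f"{reference.log_likelihood:.2f}", iters=reference.n_iterations)

    freqs = compute_allele_freqs(G, labels)
    score_tables = {
        "informativeness": informativeness(freqs),
        "fst": wc_fst(G, labels),
        "pca_weight": pca_snp_weights(G, pc_index=cfg.pc_index),
        "k_variance": k_variance(reference.P, snp_meta=G),
    }
    for name, table in score_tables.items():
        table.write(os.path.join(cfg.out_dir, f"scores_{name}.tsv"))
    _stage("scoring", t0)

    method_panels = {
        "informativeness": top_n(score_tables["informativeness"], cfg.top_n),
        "fst": top_n(score_tables["fst"], cfg.top_n),
        "pca_weight": top_n(score_tables["pca_weight"], cfg.top_n),
        "k_variance": threshold_panel(score_tables["k_variance"], cfg.variance_threshold),
    }
    consensus = consensus_panel(
        list(method_panels.values()), min_methods=cfg.min_methods, universe=G, name="consensus"
    )
    if len(consensus) == 0:
        raise RuntimeError("consensus panel is empty; lower min_methods or top_n")
    control = random_panel(G, size=len(consensus), seed=cfg.seed, name="random")
    panels: dict[str, Panel] = {**method_panels, "consensus": consensus, "random": control}
    for name, panel in panels.items():
        panel.write(os.path.join(cfg.out_dir, f"panel_{name}.txt"))
    _stage("panels", t0, consensus_size=len(consensus))

    fits: dict[str, AdmixtureFit] = {}
    reports: dict[str, DistanceReport] = {}
    for name, panel in panels.items():
        report, fit = evaluate_panel(
            G, panel, cfg.K, seed=cfg.seed, reference=reference,
            tol=cfg.tol, max_iter=cfg.max_iter, n_restarts=cfg.n_restarts,
            return_fit=True,
        )
        reports[name] = report
        fits[name] = fit
        write_qp(fit.Q, fit.P, os.path.join(cfg.out_dir, f"fit_{name}"))
        report.write(os.path.join(cfg.out_dir, f"distances_{name}.tsv"))
        _stage("evaluate", t0, panel=name, size=len(panel), mean=f"{report.mean:.4f}")

    comparison = compare_panels(list(reports.values()))
    comparison.write(os.path.join(cfg.out_dir, "comparison.tsv"))

    manifest = {
        "config": cfg.to_dict(),
        "n_individuals": G.n_individuals,
        "n_snps": G.n_snps,
        "panel_sizes": {name: len(p) for name, p in panels.items()},
        "n_admixture_fits": 1 + len(panels),
        "mean_distances": {name: reports[name].mean for name in reports},
        "outputs": {},
    }
    for fname in sorted(os.listdir(cfg.out_dir)):
        if fname == "manifest.json":
            continue
        manifest["outputs"][fname] = _sha256(os.path.join(cfg.out_dir, fname))
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _stage("done", t0)

    return WorkflowResult(
        config=cfg,
        genotypes=G,
        reference_fit=reference,
        score_tables=score_tables,
        panels=panels,
        fits=fits,
        reports=reports,
        comparison=comparison,
        manifest=manifest,
    )
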