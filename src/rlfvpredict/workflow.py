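"""Config-driven orchestration of the simulation experiment grid.

One experiment = a synthetic genome + half-sib population + DRP phenotypes
(shared across all cells), crossed with QTN scenarios (SQTN/MQTN/LQTN),
variant-selection strategies and replicates. Each cell fits a one-GRM
(common panel only) or two-GRM (common panel + selected RLFV) GBLUP model
by REML on the training cohort, predicts GEBV for the validation cohort and
computes reliability and bias statistics.

Per-replicate seeds are a pure function of (master seed, scenario,
replicate index), so any cell can be recomputed independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, genetest, kinship, selection, simulate
from .reml import reml_fit, predict_gebv

SCENARIOS = simulate.SCENARIOS
STRATEGIES = (
    "k50_only", "all_genic", "mapped", "annotation_high", "annotation_medhigh",
    "random_matched", "true_qtn", "qtn_plus_random",
)
_QTN_STRATEGIES = {"true_qtn", "qtn_plus_random"}


class WorkflowError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Desk-scale defaults preserving the structure of a progeny-test design.

    29 autosomes with 20 genes each (15 RLFV per gene), a 150-SNP/chromosome
    common panel, and 100 sires with 19 daughters each (n = 2000 genotyped
    individuals, youngest 400 in validation). The DRP parameters default to
    a fertility-like trait: genetic variance 145, phenotypic variance 328.8
    (heritability 0.441) and mean DRP reliability 0.85.
    """

    seed: int = 1
    # genome
    n_chr: int = 29
    genes_per_chr: int = 20
    rlfv_per_gene: int = 15
    n_common_per_chr: int = 150
    intergenic_rlfv_per_chr: int = 10
    annotation_class_probs: dict = field(
        default_factory=lambda: {"high": 0.01, "medium": 0.02, "low": 0.97})
    # population
    n_sires: int = 100
    daughters_per_sire: int = 19
    # phenotype
    sigma2_g: float = 145.0
    total_variance: float = 328.8
    mean_r2_drp: float = 0.85
    n_validation: int = 400
    # experiment grid
    qtn_fraction: float = 0.10
    scenarios: tuple = SCENARIOS
    strategies: tuple = ("k50_only", "true_qtn", "qtn_plus_random", "mapped")
    replicates: int = 10
    alpha: float = 0.01
    mapping_kinship: str = "pedigree"   # or "grm"
    random_genes_per_chr: int = 10      # noise genes for qtn_plus_random
    maf_floor: float = 0.001
    maf_ceiling: float = 0.05

    def validate(self) -> None:
        bad = set(self.strategies) - set(STRATEGIES)
        if bad:
            raise WorkflowError(f"unknown strategies: {sorted(bad)}")
        bad = set(self.scenarios) - set(SCENARIOS)
        if bad:
            raise WorkflowError(f"unknown scenarios: {sorted(bad)}")
        if self.replicates < 1:
            raise WorkflowError("replicates must be >= 1")
        if self.mapping_kinship not in ("pedigree", "grm"):
            raise WorkflowError("mapping_kinship must be 'pedigree' or 'grm'")
        if not 0 < self.alpha < 1:
            raise WorkflowError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["strategies"] = list(self.strategies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("scenarios", "strategies"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def replicate_seed(master_seed: int, scenario: str, replicate: int) -> int:
    """Deterministic per-cell seed, pure in (master seed, scenario, replicate)."""
    ss = np.random.SeedSequence(master_seed,
                                spawn_key=(SCENARIOS.index(scenario), replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def _stage_seed(master_seed: int, stage: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(97, stage))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SharedData:
    """Inputs shared across every cell of one experiment."""

    config: ExperimentConfig
    genome: simulate.GenomeMap
    pedigree: simulate.Pedigree
    genotypes: simulate.GenotypeMatrix
    phenotypes: simulate.PhenotypeTable   # DRP only, no QTN overlay
    rlfv: selection.VariantSubset
    grm50: kinship.RelationshipMatrix
    a_matrix: kinship.RelationshipMatrix | None

    @property
    def train_idx(self) -> np.ndarray:
        return np.flatnonzero(self.phenotypes.mask("training"))

    @property
    def val_idx(self) -> np.ndarray:
        return np.flatnonzero(self.phenotypes.mask("validation"))


def build_shared(config: ExperimentConfig) -> SharedData:
    config.validate()
    genome = simulate.simulate_genome_map(
        config.n_chr, config.genes_per_chr, config.rlfv_per_gene,
        config.n_common_per_chr, config.annotation_class_probs,
        seed=_stage_seed(config.seed, 0),
        intergenic_rlfv_per_chr=config.intergenic_rlfv_per_chr)
    pedigree, genotypes = simulate.simulate_population(
        genome, config.n_sires, config.daughters_per_sire,
        seed=_stage_seed(config.seed, 1))
    phenotypes = simulate.simulate_drp(
        genotypes.dosages[:, genome.common_indices], config.sigma2_g,
        config.total_variance, config.mean_r2_drp,
        seed=_stage_seed(config.seed, 2), n_validation=config.n_validation,
        ids=genotypes.ids)
    rlfv = selection.filter_rlfv(
        simulate.GenotypeMatrix(ids=genotypes.ids,
                                dosages=genotypes.dosages[:, genome.rlfv_indices]),
        config.maf_floor, config.maf_ceiling)
    # re-express RLFV subset in genome-wide variant indices
    rlfv = selection.VariantSubset(
        label=rlfv.label, indices=genome.rlfv_indices[rlfv.indices],
        provenance=rlfv.provenance)
    grm50 = kinship.vanraden_grm(genotypes, genome.common_indices)
    a_matrix = (kinship.pedigree_a_matrix(pedigree)
                if config.mapping_kinship == "pedigree" else None)
    return SharedData(config=config, genome=genome, pedigree=pedigree,
                      genotypes=genotypes, phenotypes=phenotypes, rlfv=rlfv,
                      grm50=grm50, a_matrix=a_matrix)


def _random_noise_genes(shared: SharedData, qtn_genes: set, seed: int) -> list[str]:
    """Sample ``random_genes_per_chr`` non-causal genes per chromosome."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for chrom, pool in shared.genome.genes_by_chromosome().items():
        avail = [g for g in pool if g not in qtn_genes]
        k = min(shared.config.random_genes_per_chr, len(avail))
        if k:
            out.extend(rng.choice(avail, size=k, replace=False))
    return out


def _strategy_subset(shared: SharedData, strategy: str,
                     qtn: simulate.QtnSet | None, cell_seed: int,
                     y_composed: simulate.PhenotypeTable) -> tuple[np.ndarray | None, str]:
    """Variant indices for the second GRM, or None for the one-GRM model."""
    cfg = shared.config
    if strategy == "k50_only":
        return None, ""
    if strategy in _QTN_STRATEGIES and qtn is None:
        raise WorkflowError(f"strategy {strategy!r} requires a QTN scenario")
    if strategy == "true_qtn":
        return qtn.variant_indices, ""
    if strategy == "qtn_plus_random":
        noise_genes = _random_noise_genes(shared, set(qtn.gene_ids), cell_seed + 1)
        noise = selection.select_by_mapping(shared.rlfv, shared.genome, noise_genes)
        idx = np.union1d(qtn.variant_indices, noise.indices)
        return idx, f"{len(noise_genes)} noise genes"
    if strategy == "mapped":
        kin = shared.a_matrix if shared.a_matrix is not None else shared.grm50
        mapped_genes, _ = genetest.scan_genes(
            shared.genome, shared.genotypes, y_composed, kin, alpha=cfg.alpha)
        sub = selection.select_by_mapping(shared.rlfv, shared.genome, mapped_genes)
        return sub.indices, f"{len(mapped_genes)} mapped genes"
    if strategy == "all_genic":
        return selection.select_genic(shared.rlfv, shared.genome).indices, ""
    if strategy == "annotation_high":
        return selection.select_by_annotation(shared.rlfv, shared.genome, {"high"}).indices, ""
    if strategy == "annotation_medhigh":
        return selection.select_by_annotation(
            shared.rlfv, shared.genome, {"high", "medium"}).indices, ""
    if strategy == "random_matched":
        medhigh = selection.select_by_annotation(
            shared.rlfv, shared.genome, {"high", "medium"})
        genic = selection.select_genic(shared.rlfv, shared.genome)
        sub = selection.select_random_matched(genic, medhigh.count, seed=cell_seed + 2)
        return sub.indices, f"matched to {medhigh.count} med-high RLFV"
    raise WorkflowError(f"unknown strategy {strategy!r}")


def run_strategy_cell(
    config: ExperimentConfig,
    scenario: str,
    strategy: str,
    rep_seed: int,
    shared: SharedData | None = None,
    replicate: int = 0,
) -> evaluation.EvaluationResult:
    """Run one scenario x strategy cell at the given replicate seed."""
    if shared is None:
        shared = build_shared(config)
    qtn = simulate.simulate_qtn_scenario(
        shared.genome, shared.genotypes, scenario, config.qtn_fraction,
        config.sigma2_g, seed=rep_seed)
    pheno = simulate.compose_phenotype(shared.phenotypes, qtn)
    return _evaluate_strategy(shared, pheno, qtn, scenario, strategy,
                              rep_seed, replicate)


def _evaluate_strategy(shared: SharedData, pheno: simulate.PhenotypeTable,
                       qtn: simulate.QtnSet | None, scenario: str,
                       strategy: str, cell_seed: int,
                       replicate: int) -> evaluation.EvaluationResult:
    cfg = shared.config
    t_idx, v_idx = shared.train_idx, shared.val_idx
    y = pheno.table["y"].to_numpy()
    subset, note = _strategy_subset(shared, strategy, qtn, cell_seed, pheno)

    Ks = [shared.grm50.values]
    names = ["g_50k"]
    if subset is not None:
        if len(subset) == 0:
            subset = None
            note = (note + "; " if note else "") + "empty RLFV set, one-GRM model"
        else:
            grm2 = kinship.vanraden_grm(shared.genotypes, subset)
            Ks.append(grm2.values)
            names.append("g_rlfv")

    fit = reml_fit(y[t_idx], [K[np.ix_(t_idx, t_idx)] for K in Ks],
                   term_names=tuple(names))
    gebv = predict_gebv(fit, Ks, t_idx, v_idx, y[t_idx], ids=shared.genotypes.ids)

    val_tab = pheno.table.iloc[v_idx]
    mean_r2 = float(val_tab["r2_drp"].mean())
    rel = evaluation.reliability(gebv["total"].to_numpy(), y[v_idx], mean_r2)
    acc = float(np.sqrt(max(rel, 0.0)))
    se = evaluation.accuracy_se(rel, len(t_idx), float(np.sqrt(mean_r2)))
    slope = evaluation.bias_slope(gebv["total"].to_numpy(), y[v_idx])
    return evaluation.EvaluationResult(
        scenario=scenario, strategy=strategy, replicate=replicate,
        reliability=rel, accuracy=acc, accuracy_se=se, bias_slope=slope,
        n_training=len(t_idx), n_validation=len(v_idx), mean_r2_drp=mean_r2,
        variance_components=dict(fit.variances), converged=fit.converged,
        note=note)


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    cells: list
    failures: list
    table: pd.DataFrame     # one row per scenario x strategy x replicate
    summary: pd.DataFrame   # replicate mean +/- SE per scenario x strategy
    timings: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "results.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        meta = {"config": self.config.to_dict(),
                "config_hash": self.config.config_hash(),
                "failures": self.failures, "timings": self.timings}
        (out / "report.json").write_text(json.dumps(meta, indent=2))


def run_experiment(config: ExperimentConfig, out_dir=None,
                   progress: bool = False) -> ExperimentReport:
    """Iterate scenarios x strategies x replicates and aggregate."""
    config.validate()
    t0 = time.perf_counter()
    shared = build_shared(config)
    timings = {"shared_build_s": round(time.perf_counter() - t0, 2)}

    cells, failures = [], []
    for scenario in config.scenarios:
        for rep in range(config.replicates):
            rs = replicate_seed(config.seed, scenario, rep)
            qtn = simulate.simulate_qtn_scenario(
                shared.genome, shared.genotypes, scenario, config.qtn_fraction,
                config.sigma2_g, seed=rs)
            pheno = simulate.compose_phenotype(shared.phenotypes, qtn)
            for strategy in config.strategies:
                try:
                    res = _evaluate_strategy(shared, pheno, qtn, scenario,
                                             strategy, rs, rep)
                    cells.append(res)
                except Exception as exc:  # cell isolation: one failure != abort
                    failures.append({"scenario": scenario, "strategy": strategy,
                                     "replicate": rep, "error": str(exc)})
                if progress:
                    print(f"[{scenario} rep {rep}] {strategy} done", flush=True)
    timings["total_s"] = round(time.perf_counter() - t0, 2)

    table = pd.DataFrame([{
        "scenario": c.scenario, "strategy": c.strategy, "replicate": c.replicate,
        "reliability_pct": c.reliability_pct, "accuracy": c.accuracy,
        "accuracy_se": c.accuracy_se, "bias_slope": c.bias_slope,
        "n_training": c.n_training, "n_validation": c.n_validation,
        "mean_r2_drp": c.mean_r2_drp, "converged": c.converged, "note": c.note,
        **{f"var_{k}": v for k, v in c.variance_components.items()},
    } for c in cells])

    rows = []
    if len(table):
        for (scenario, strategy), grp in table.groupby(["scenario", "strategy"], sort=False):
            if len(grp) >= 2:
                rel_mean, rel_se = evaluation.replicate_summary(grp["reliability_pct"])
                b_mean, b_se = evaluation.replicate_summary(grp["bias_slope"])
            else:
                rel_mean, rel_se = float(grp["reliability_pct"].iloc[0]), np.nan
                b_mean, b_se = float(grp["bias_slope"].iloc[0]), np.nan
            rows.append({"scenario": scenario, "strategy": strategy,
                         "n_replicates": len(grp),
                         "reliability_pct_mean": rel_mean, "reliability_pct_se": rel_se,
                         "bias_slope_mean": b_mean, "bias_slope_se": b_se})
    summary = pd.DataFrame(rows)

    report = ExperimentReport(config=config, cells=cells, failures=failures,
                              table=table, summary=summary, timings=timings)
    if out_dir is not None:
        report.write(out_dir)
    return report
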