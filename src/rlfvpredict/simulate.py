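"""Synthetic genomes, half-sib populations and de-regressed-proof phenotypes.

This module generates every input the prediction pipeline consumes, emulating
the data structure of a progeny-tested dairy-cattle population:

* a gene map with rare and low-frequency variants (RLFV, minor allele
  frequency in [0.001, 0.05)) located inside genes, a common "50k"-style SNP
  panel (MAF >= 0.05), and per-variant annotation-impact classes;
* a two-generation half-sib pedigree (founder sires and dams, half-sib
  daughters) with linked gene-dropping of founder haplotypes;
* de-regressed proofs (DRP): a polygenic true breeding value built from the
  common panel plus individual noise controlled by a DRP reliability;
* causal-variant overlays (QTN scenarios) that spread a fixed amount of
  genetic variance over many, few or very few genes.

All randomness is driven by explicit integer seeds; a fixed seed yields
bit-identical output.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ANNOTATION_CLASSES = ("high", "medium", "low")
PANEL_COMMON = "common_50k"
PANEL_RLFV = "sequence_rlfv"
SCENARIOS = ("SQTN", "MQTN", "LQTN")

# physical layout constants (bp)
_GENE_BLOCK = 100_000     # one gene per block, rest of the block intergenic
_RLFV_SPACING = 100       # spacing of RLFV inside a gene


class SimulationError(ValueError):
    """Raised on invalid simulation parameters or degenerate draws."""


@dataclass(frozen=True)
class GenomeMap:
    """Variant-level map of a synthetic genome.

    ``variants`` has one row per variant, ordered by (chromosome, position),
    with columns ``chrom``, ``pos`` (1-based bp), ``gene`` (gene ID or NaN),
    ``target_maf``, ``annotation`` (high/medium/low/intergenic) and ``panel``
    (``common_50k`` or ``sequence_rlfv``).
    """

    variants: pd.DataFrame
    chromosomes: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.variants
        required = {"chrom", "pos", "gene", "target_maf", "annotation", "panel"}
        missing = required - set(v.columns)
        if missing:
            raise SimulationError(f"variant table missing columns: {sorted(missing)}")
        common = v["panel"] == PANEL_COMMON
        if (v.loc[common, "target_maf"] < 0.05).any():
            raise SimulationError("common-panel variants must have target MAF >= 0.05")
        rlfv = v.loc[v["panel"] == PANEL_RLFV, "target_maf"]
        if ((rlfv < 0.001) | (rlfv >= 0.05)).any():
            raise SimulationError("RLFV target MAF must lie in [0.001, 0.05)")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @functools.cached_property
    def genes(self) -> dict[str, np.ndarray]:
        """Gene ID -> position-ordered array of variant row indices."""
        genic = self.variants[self.variants["gene"].notna()]
        return {
            gene: np.asarray(grp.sort_values("pos").index)
            for gene, grp in genic.groupby("gene", sort=True)
        }

    @functools.cached_property
    def rlfv_indices(self) -> np.ndarray:
        return np.flatnonzero((self.variants["panel"] == PANEL_RLFV).to_numpy())

    @functools.cached_property
    def common_indices(self) -> np.ndarray:
        return np.flatnonzero((self.variants["panel"] == PANEL_COMMON).to_numpy())

    def genes_by_chromosome(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in self.chromosomes}
        genic = self.variants[self.variants["gene"].notna()]
        for (chrom, gene), _ in genic.groupby(["chrom", "gene"], sort=True):
            out[chrom].append(gene)
        return out


@dataclass(frozen=True)
class Pedigree:
    """Per-individual sire/dam links; parents precede offspring in generation."""

    table: pd.DataFrame  # columns: id, sire, dam, generation

    def __post_init__(self) -> None:
        t = self.table
        if t["id"].duplicated().any():
            raise SimulationError("duplicate individual IDs in pedigree")
        gen = dict(zip(t["id"], t["generation"]))
        for _, row in t.iterrows():
            for parent in (row["sire"], row["dam"]):
                if pd.isna(parent):
                    continue
                if parent == row["id"]:
                    raise SimulationError(f"{row['id']} listed as its own ancestor")
                if parent not in gen or gen[parent] >= row["generation"]:
                    raise SimulationError(
                        f"parent {parent} of {row['id']} not defined in an earlier generation"
                    )

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()


@dataclass(frozen=True)
class GenotypeMatrix:
    """Allele dosages (0/1/2 copies of the counted allele), individuals x variants."""

    ids: np.ndarray
    dosages: np.ndarray  # int8, shape (n, m)

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.ids):
            raise SimulationError("dosage matrix inconsistent with individual IDs")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise SimulationError("dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class PhenotypeTable:
    """DRP phenotypes with reliabilities, composed phenotype and cohort split."""

    table: pd.DataFrame  # id, drp, r2_drp, y, cohort, birth_order
    tbv: np.ndarray      # polygenic true breeding value (diagnostic)
    sigma2_g: float
    total_variance: float

    @property
    def h2_target(self) -> float:
        return self.sigma2_g / self.total_variance

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def mask(self, cohort: str) -> np.ndarray:
        return (self.table["cohort"] == cohort).to_numpy()


@dataclass(frozen=True)
class QtnSet:
    """A drawn set of causal rare variants and their scaled effects."""

    scenario: str
    gene_ids: tuple[str, ...]
    variant_indices: np.ndarray
    alpha: np.ndarray          # per-QTN allele-substitution effect, scaled
    tbv_q: np.ndarray          # per-individual causal breeding value, scaled
    fraction: float            # target fraction of sigma2_50k
    sigma2_50k: float
    realized_variance: float
    genes_per_chr_drawn: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        target = self.fraction * self.sigma2_50k
        if abs(self.realized_variance - target) > 1e-10 * max(target, 1.0):
            raise SimulationError("TBV_Q variance scaling is not exact")


def _validate_probs(probs: dict[str, float]) -> dict[str, float]:
    unknown = set(probs) - set(ANNOTATION_CLASSES)
    if unknown:
        raise SimulationError(f"unknown annotation classes: {sorted(unknown)}")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise SimulationError(f"annotation class probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise SimulationError("annotation class probabilities must be non-negative")
    return probs


def simulate_genome_map(
    n_chr: int,
    genes_per_chr: int,
    rlfv_per_gene: int,
    n_common_per_chr: int,
    annotation_class_probs: dict[str, float] | None = None,
    seed: int = 0,
    intergenic_rlfv_per_chr: int = 0,
) -> GenomeMap:
    """Lay out a genome of ``n_chr`` chromosomes with genic RLFV and a common panel.

    Each chromosome is a sequence of ``genes_per_chr`` blocks of 100 kb; the
    gene occupies the head of the block and its RLFV sit at fixed 100-bp
    spacing inside it. Common-panel SNPs (and optional intergenic RLFV) are
    placed in the intergenic remainder. RLFV target MAFs are log-uniform on
    [0.001, 0.05) -- rarer variants are more numerous, as in sequence data --
    and common-panel MAFs are uniform on [0.05, 0.5). Annotation-impact
    classes are drawn i.i.d. per genic RLFV.
    """
    if min(n_chr, genes_per_chr, rlfv_per_gene, n_common_per_chr) < 1:
        raise SimulationError("all genome-map counts must be >= 1")
    if intergenic_rlfv_per_chr < 0:
        raise SimulationError("intergenic_rlfv_per_chr must be >= 0")
    probs = _validate_probs(
        annotation_class_probs
        if annotation_class_probs is not None
        else {"high": 0.01, "medium": 0.02, "low": 0.97}
    )
    rng = np.random.default_rng(seed)
    class_labels = list(ANNOTATION_CLASSES)
    class_p = np.array([probs.get(c, 0.0) for c in class_labels])

    rows: list[tuple] = []
    for c in range(1, n_chr + 1):
        chrom = str(c)
        chr_len = genes_per_chr * _GENE_BLOCK
        gene_span = rlfv_per_gene * _RLFV_SPACING
        for g in range(genes_per_chr):
            gene_id = f"G{c:02d}_{g + 1:03d}"
            start = g * _GENE_BLOCK + 1
            mafs = np.exp(rng.uniform(np.log(0.001), np.log(0.05), size=rlfv_per_gene))
            mafs = np.minimum(mafs, np.nextafter(0.05, 0.0))
            classes = rng.choice(class_labels, size=rlfv_per_gene, p=class_p)
            for j in range(rlfv_per_gene):
                rows.append(
                    (chrom, start + j * _RLFV_SPACING, gene_id,
                     float(mafs[j]), str(classes[j]), PANEL_RLFV)
                )
        # common SNPs round-robin over the intergenic tails of the blocks
        for k in range(n_common_per_chr):
            block = k % genes_per_chr
            slot = k // genes_per_chr
            pos = block * _GENE_BLOCK + gene_span + 1000 + slot * 53 + 17
            if pos > chr_len:
                raise SimulationError("too many common SNPs for chromosome length")
            maf = float(rng.uniform(0.05, 0.5))
            rows.append((chrom, pos, np.nan, maf, "intergenic", PANEL_COMMON))
        for k in range(intergenic_rlfv_per_chr):
            block = k % genes_per_chr
            slot = k // genes_per_chr
            pos = block * _GENE_BLOCK + gene_span + 50_000 + slot * 53 + 29
            maf = float(np.exp(rng.uniform(np.log(0.001), np.log(0.05))))
            rows.append((chrom, pos, np.nan, min(maf, np.nextafter(0.05, 0.0)),
                         "intergenic", PANEL_RLFV))

    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "gene", "target_maf", "annotation", "panel"]
    )
    variants["chrom_order"] = variants["chrom"].astype(int)
    variants = (
        variants.sort_values(["chrom_order", "pos"], kind="mergesort")
        .drop(columns="chrom_order")
        .reset_index(drop=True)
    )
    if variants.duplicated(["chrom", "pos"]).any():
        raise SimulationError("variant position collision in layout")
    return GenomeMap(variants=variants, chromosomes=tuple(str(c) for c in range(1, n_chr + 1)))


def _gamete(haplotypes: np.ndarray, chrom_slices: list[slice],
            genetic_pos: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete from a (2, m) haplotype pair with crossovers.

    Recombination follows a Haldane (no-interference) model: crossover count
    per chromosome is Poisson in its genetic length, positions uniform.
    """
    out = np.empty(haplotypes.shape[1], dtype=np.int8)
    for sl, gpos in zip(chrom_slices, genetic_pos):
        length = gpos[-1] - gpos[0] if len(gpos) > 1 else 0.0
        n_x = rng.poisson(length)
        start = rng.integers(2)
        if n_x == 0:
            out[sl] = haplotypes[start, sl]
            continue
        xpos = np.sort(rng.uniform(gpos[0], gpos[-1], size=n_x))
        phase = (start + np.searchsorted(xpos, gpos, side="right")) % 2
        idx = np.arange(sl.start, sl.stop)
        out[sl] = haplotypes[phase, idx]
    return out


def simulate_population(
    genome_map: GenomeMap,
    n_sires: int,
    daughters_per_sire: int,
    seed: int = 0,
    cm_per_mb: float = 1.0,
) -> tuple[Pedigree, GenotypeMatrix]:
    """Simulate founder sires/dams and half-sib daughters by gene-dropping.

    Founder haplotypes are drawn per-locus Bernoulli(target MAF), i.e. in
    linkage equilibrium; within-family co-segregation of linked loci arises
    from transmitting recombined founder haplotypes. Each daughter has a
    unique founder dam, so paternal half-sib families are the only close
    relationships -- the structure typical of progeny-tested dairy sires.

    The genotype matrix contains sires followed by daughters (age order);
    dams appear in the pedigree only, mirroring real sire datasets where
    dams are not genotyped.
    """
    if genome_map.n_variants == 0:
        raise SimulationError("genome map is empty")
    if n_sires < 1 or daughters_per_sire < 0:
        raise SimulationError("need n_sires >= 1 and daughters_per_sire >= 0")
    rng = np.random.default_rng(seed)
    v = genome_map.variants
    m = genome_map.n_variants
    maf = v["target_maf"].to_numpy()

    chrom_slices: list[slice] = []
    genetic_pos: list[np.ndarray] = []
    morgans_per_bp = cm_per_mb * 1e-8
    for chrom in genome_map.chromosomes:
        idx = np.flatnonzero((v["chrom"] == chrom).to_numpy())
        chrom_slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
        genetic_pos.append(v["pos"].to_numpy()[idx] * morgans_per_bp)

    n_daughters = n_sires * daughters_per_sire
    sire_ids = [f"S{i + 1:04d}" for i in range(n_sires)]
    dam_ids = [f"M{i + 1:04d}" for i in range(n_daughters)]
    daughter_ids = [f"D{i + 1:04d}" for i in range(n_daughters)]

    sire_haps = (rng.random((n_sires, 2, m)) < maf).astype(np.int8)
    dam_haps = (rng.random((n_daughters, 2, m)) < maf).astype(np.int8)

    dosages = np.empty((n_sires + n_daughters, m), dtype=np.int8)
    dosages[:n_sires] = sire_haps.sum(axis=1)

    ped_rows = [(sid, None, None, 0) for sid in sire_ids]
    ped_rows += [(did, None, None, 0) for did in dam_ids]
    for d in range(n_daughters):
        sire = d // daughters_per_sire if daughters_per_sire else 0
        pat = _gamete(sire_haps[sire], chrom_slices, genetic_pos, rng)
        mat = _gamete(dam_haps[d], chrom_slices, genetic_pos, rng)
        dosages[n_sires + d] = pat + mat
        ped_rows.append((daughter_ids[d], sire_ids[sire], dam_ids[d], 1))

    ped = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "generation"])
    ids = np.array(sire_ids + daughter_ids)
    return Pedigree(table=ped), GenotypeMatrix(ids=ids, dosages=dosages)


def simulate_drp(
    genotypes_common: GenotypeMatrix | np.ndarray,
    sigma2_g: float,
    total_variance: float,
    mean_r2_drp: float,
    seed: int = 0,
    n_validation: int = 1000,
    ids: np.ndarray | None = None,
    r2_concentration: float = 200.0,
) -> PhenotypeTable:
    """Build de-regressed proofs from a polygenic signal on the common panel.

    The polygenic true breeding value is a linear combination of centred
    common-panel dosages with i.i.d. normal effects, rescaled so its sample
    variance equals ``sigma2_g`` exactly. Each individual's DRP is its TBV
    plus noise with variance ``sigma2_g * (1 - r2) / r2`` where the
    per-individual DRP reliability ``r2`` is Beta-distributed around
    ``mean_r2_drp``. ``total_variance`` is the phenotypic variance of the
    underlying trait (metadata used for heritability bookkeeping); the trait
    heritability is ``sigma2_g / total_variance``.

    The youngest ``n_validation`` individuals (largest birth-order rank, i.e.
    the last rows) form the validation cohort.
    """
    if not 0 < sigma2_g < total_variance:
        raise SimulationError("need 0 < sigma2_g < total_variance")
    if not 0 < mean_r2_drp <= 1:
        raise SimulationError("mean_r2_drp must be in (0, 1]")
    if isinstance(genotypes_common, GenotypeMatrix):
        dos = genotypes_common.dosages
        ids = genotypes_common.ids if ids is None else ids
    else:
        dos = np.asarray(genotypes_common)
    n, m = dos.shape
    if ids is None:
        ids = np.array([f"I{i + 1:04d}" for i in range(n)])
    if not 0 < n_validation < n:
        raise SimulationError("n_validation must be in (0, n)")

    rng = np.random.default_rng(seed)
    Z = dos.astype(np.float64) - dos.mean(axis=0, dtype=np.float64)
    beta = rng.standard_normal(m)
    tbv = Z @ beta
    sd = tbv.std(ddof=1)
    if sd == 0:
        raise SimulationError("common panel is monomorphic; polygenic TBV has no variance")
    tbv *= np.sqrt(sigma2_g) / sd

    if mean_r2_drp == 1.0:
        r2 = np.ones(n)
        noise = np.zeros(n)
    else:
        a = mean_r2_drp * r2_concentration
        b = (1.0 - mean_r2_drp) * r2_concentration
        r2 = np.clip(rng.beta(a, b, size=n), 0.05, 1.0)
        noise = rng.standard_normal(n) * np.sqrt(sigma2_g * (1.0 - r2) / r2)
    drp = tbv + noise

    birth_order = np.arange(n)
    cohort = np.where(birth_order >= n - n_validation, "validation", "training")
    table = pd.DataFrame(
        {"id": ids, "drp": drp, "r2_drp": r2, "y": drp.copy(),
         "cohort": cohort, "birth_order": birth_order}
    )
    return PhenotypeTable(table=table, tbv=tbv, sigma2_g=float(sigma2_g),
                          total_variance=float(total_variance))


def _draw_qtn_genes(genome_map: GenomeMap, scenario: str,
                    rng: np.random.Generator,
                    sqtn_range: tuple[int, int] = (7, 10),
                    lqtn_genes: int = 9) -> tuple[list[str], dict[str, int]]:
    by_chr = genome_map.genes_by_chromosome()
    per_chr_drawn: dict[str, int] = {}
    genes: list[str] = []
    if scenario == "LQTN":
        all_genes = sorted(genome_map.genes)
        if len(all_genes) < lqtn_genes:
            raise SimulationError("fewer genes available than requested")
        genes = list(rng.choice(all_genes, size=lqtn_genes, replace=False))
    else:
        for chrom in genome_map.chromosomes:
            pool = by_chr[chrom]
            k = 1 if scenario == "MQTN" else int(rng.integers(sqtn_range[0], sqtn_range[1] + 1))
            if len(pool) < k:
                raise SimulationError(f"chromosome {chrom} has {len(pool)} genes, need {k}")
            genes.extend(rng.choice(pool, size=k, replace=False))
            per_chr_drawn[chrom] = k
    return genes, per_chr_drawn


def simulate_qtn_scenario(
    genome_map: GenomeMap,
    genotypes: GenotypeMatrix,
    scenario: str,
    fraction: float,
    sigma2_50k: float,
    seed: int = 0,
    sqtn_range: tuple[int, int] = (7, 10),
    lqtn_genes: int = 9,
) -> QtnSet:
    """Draw causal genes per scenario and scale their joint variance exactly.

    SQTN draws seven to ten genes per chromosome (uniformly, per replicate),
    MQTN one gene per chromosome, LQTN nine genes genome-wide; every RLFV in
    a selected gene becomes a QTN. Allele-substitution effects are standard
    normal, then TBV_Q = M_Q @ alpha is rescaled so its sample variance is
    exactly ``fraction * sigma2_50k``.
    """
    if scenario not in SCENARIOS:
        raise SimulationError(f"unknown scenario {scenario!r}")
    if fraction <= 0:
        raise SimulationError("variance fraction must be > 0")
    rng = np.random.default_rng(seed)
    genes, per_chr = _draw_qtn_genes(genome_map, scenario, rng, sqtn_range, lqtn_genes)

    panel = genome_map.variants["panel"].to_numpy()
    qtn_idx = np.sort(np.concatenate([genome_map.genes[g] for g in genes]))
    qtn_idx = qtn_idx[panel[qtn_idx] == PANEL_RLFV]
    alpha = rng.standard_normal(len(qtn_idx))
    m_q = genotypes.dosages[:, qtn_idx].astype(np.float64)
    tbv_raw = m_q @ alpha
    sd = tbv_raw.std(ddof=1)
    if sd == 0:
        raise SimulationError("all selected genes are monomorphic; cannot scale TBV_Q")
    scale = np.sqrt(fraction * sigma2_50k) / sd
    tbv_q = tbv_raw * scale
    return QtnSet(
        scenario=scenario,
        gene_ids=tuple(genes),
        variant_indices=qtn_idx,
        alpha=alpha * scale,
        tbv_q=tbv_q,
        fraction=float(fraction),
        sigma2_50k=float(sigma2_50k),
        realized_variance=float(tbv_q.var(ddof=1)),
        genes_per_chr_drawn=per_chr,
    )


def compose_phenotype(phenotypes: PhenotypeTable, qtn_set: QtnSet) -> PhenotypeTable:
    """Overlay the causal-variant signal on the DRP: y = DRP + TBV_Q."""
    if len(qtn_set.tbv_q) != len(phenotypes.table):
        raise SimulationError("QTN set and phenotype table cover different individuals")
    table = phenotypes.table.copy()
    table["y"] = table["drp"].to_numpy() + qtn_set.tbv_q
    return replace(phenotypes, table=table)
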