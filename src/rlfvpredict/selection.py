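"""Selection of rare and low-frequency variant (RLFV) subsets.

Four strategies mirror common practice for enriching genomic prediction
models with sequence variants: all genic RLFV, annotation-impact classes,
genes flagged by rare-variant association mapping, and size-matched random
controls. Every strategy operates on (and returns a subset of) the output
of :func:`filter_rlfv`, so provenance composes.

MAF boundaries are floor-inclusive, ceiling-exclusive: a variant is an RLFV
when maf_floor <= MAF < maf_ceiling, with MAF computed from the observed
frequencies of the full genotyped sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinship import minor_allele_frequencies
from .simulate import GenomeMap, GenotypeMatrix


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class VariantSubset:
    label: str
    indices: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.size != np.unique(idx).size:
            raise SelectionError("variant indices must be unique")
        object.__setattr__(self, "indices", np.sort(idx).astype(np.int64))

    @property
    def count(self) -> int:
        return int(self.indices.size)


def min_minor_allele_copies(n_individuals: int, maf_floor: float) -> int:
    """Smallest minor-allele count that passes the MAF floor in n diploids."""
    return math.ceil(maf_floor * 2 * n_individuals)


def filter_rlfv(genotypes: GenotypeMatrix | np.ndarray,
                maf_floor: float = 0.001,
                maf_ceiling: float = 0.05) -> VariantSubset:
    """Keep variants with maf_floor <= observed MAF < maf_ceiling."""
    if not 0 <= maf_floor < maf_ceiling <= 0.5:
        raise SelectionError("need 0 <= maf_floor < maf_ceiling <= 0.5")
    maf = minor_allele_frequencies(genotypes)
    keep = np.flatnonzero((maf >= maf_floor) & (maf < maf_ceiling))
    if keep.size == 0:
        warnings.warn("MAF filter retained no variants", stacklevel=2)
    return VariantSubset(
        label="rlfv",
        indices=keep,
        provenance={"strategy": "maf_filter",
                    "maf_floor": maf_floor, "maf_ceiling": maf_ceiling},
    )


def select_genic(subset: VariantSubset, genome_map: GenomeMap) -> VariantSubset:
    """All RLFV located inside any gene (including non-coding genes)."""
    genic = genome_map.variants["gene"].notna().to_numpy()
    keep = subset.indices[genic[subset.indices]]
    if keep.size == 0:
        warnings.warn("no genic variants in subset", stacklevel=2)
    return VariantSubset(label="all_genic", indices=keep,
                         provenance={"strategy": "genic", "parent": subset.label})


def select_by_annotation(subset: VariantSubset, genome_map: GenomeMap,
                         classes) -> VariantSubset:
    """RLFV whose annotation-impact class is in ``classes`` (high, medium)."""
    classes = set(classes)
    if not classes:
        raise SelectionError("annotation class set is empty")
    unknown = classes - {"high", "medium"}
    if unknown:
        raise SelectionError(f"unknown annotation classes: {sorted(unknown)}")
    ann = genome_map.variants["annotation"].to_numpy()
    keep = subset.indices[np.isin(ann[subset.indices], list(classes))]
    label = "annotation_high" if classes == {"high"} else "annotation_medhigh"
    return VariantSubset(label=label, indices=keep,
                         provenance={"strategy": "annotation",
                                     "classes": sorted(classes),
                                     "parent": subset.label})


def select_by_mapping(subset: VariantSubset, genome_map: GenomeMap,
                      mapped_genes) -> VariantSubset:
    """All RLFV inside genes flagged by the gene-level association scan."""
    mapped = set(mapped_genes)
    gene = genome_map.variants["gene"].to_numpy()
    in_mapped = np.array([g in mapped for g in gene[subset.indices]])
    keep = subset.indices[in_mapped] if subset.count else subset.indices
    return VariantSubset(label="mapped", indices=keep,
                         provenance={"strategy": "mapping",
                                     "n_genes": len(mapped),
                                     "parent": subset.label})


def select_random_matched(subset: VariantSubset, target_count: int,
                          seed: int = 0) -> VariantSubset:
    """Uniform sample without replacement from the subset, matched in size."""
    if target_count < 0 or target_count > subset.count:
        raise SelectionError(
            f"target_count {target_count} outside [0, {subset.count}]")
    rng = np.random.default_rng(seed)
    keep = rng.choice(subset.indices, size=target_count, replace=False)
    return VariantSubset(label="random_matched", indices=keep,
                         provenance={"strategy": "random_matched",
                                     "target_count": target_count,
                                     "seed": seed, "parent": subset.label})
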