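"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF (one contig per chromosome, GT fields, ALT = the
counted allele) or as a PLINK-style dosage TSV (individuals x variants).
Gene maps are written as BED (0-based, half-open) with a companion variant
annotation TSV; phenotypes, pedigrees, relationship matrices and variant
subsets are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .selection import VariantSubset
from .simulate import GenomeMap, GenotypeMatrix, Pedigree, PhenotypeTable


def variant_ids(genome_map: GenomeMap) -> np.ndarray:
    v = genome_map.variants
    return (v["chrom"].astype(str) + ":" + v["pos"].astype(str)).to_numpy()


def write_vcf(genome_map: GenomeMap, genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF with unphased GT fields."""
    v = genome_map.variants
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene ID">\n')
        fh.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Impact class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genome_map.chromosomes:
            length = int(v.loc[v["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.ids) + "\n")
        dos = genotypes.dosages
        for j, row in enumerate(v.itertuples(index=False)):
            gene = row.gene if isinstance(row.gene, str) else "."
            info = f"GENE={gene};ANN={row.annotation}"
            gts = "\t".join(gt_strings[dos[:, j]])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.chrom}:{row.pos}\tA\tC\t.\tPASS\t{info}\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a VCF back into a variant table and dosages of the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        gts = np.asarray(var.genotypes, dtype=np.int64)[:, :2]
        dosage_cols.append(gts.sum(axis=1).astype(np.int8))
        rows.append((var.CHROM, var.POS, var.INFO.get("GENE"), var.INFO.get("ANN")))
    vcf.close()
    table = pd.DataFrame(rows, columns=["chrom", "pos", "gene", "annotation"])
    table["gene"] = table["gene"].replace(".", np.nan)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(ids), 0), np.int8)
    return table, GenotypeMatrix(ids=ids, dosages=dosages)


def write_genes_bed(genome_map: GenomeMap, path) -> None:
    """Gene intervals as BED: 0-based start, half-open end, gene ID as name."""
    records = []
    v = genome_map.variants
    for gene, idx in genome_map.genes.items():
        pos = v["pos"].to_numpy()[idx]
        chrom = v["chrom"].iloc[idx[0]]
        records.append((chrom, int(pos.min()) - 1, int(pos.max()), gene))
    bed = pd.DataFrame(records, columns=["chrom", "start", "end", "name"])
    bed = bed.sort_values(["chrom", "start"], key=lambda s: s.astype(str)).reset_index(drop=True)
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_variant_table(genome_map: GenomeMap, path) -> None:
    v = genome_map.variants.copy()
    v.insert(0, "variant_id", variant_ids(genome_map))
    v.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> GenomeMap:
    v = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    chroms = tuple(dict.fromkeys(v["chrom"]))
    return GenomeMap(variants=v.drop(columns=["variant_id"]), chromosomes=chroms)


def write_dosage_tsv(genome_map: GenomeMap, genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.dosages, index=genotypes.ids,
                      columns=variant_ids(genome_map))
    df.to_csv(path, sep="\t", index_label="id")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return GenotypeMatrix(ids=df.index.to_numpy().astype(str),
                          dosages=df.to_numpy(dtype=np.int8))


def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    phenotypes.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, sigma2_g: float = np.nan,
                    total_variance: float = np.nan) -> PhenotypeTable:
    table = pd.read_csv(path, sep="\t")
    return PhenotypeTable(table=table, tbv=np.full(len(table), np.nan),
                          sigma2_g=sigma2_g, total_variance=total_variance)


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree(path) -> Pedigree:
    t = pd.read_csv(path, sep="\t", na_values="NA")
    t["sire"] = t["sire"].where(t["sire"].notna(), None)
    t["dam"] = t["dam"].where(t["dam"].notna(), None)
    return Pedigree(table=t)


def write_grm(matrix: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_grm(path, kind: str = "genomic") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return RelationshipMatrix(ids=df.index.to_numpy().astype(str),
                              values=df.to_numpy(dtype=np.float64), kind=kind)


def write_subset(subset: VariantSubset, genome_map: GenomeMap, prefix) -> None:
    """Variant-ID list as TSV plus a JSON provenance sidecar."""
    prefix = Path(prefix)
    vids = variant_ids(genome_map)[subset.indices]
    pd.DataFrame({"variant_id": vids, "index": subset.indices}).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False)
    meta = {"label": subset.label, "count": subset.count,
            "provenance": subset.provenance}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_subset(prefix) -> VariantSubset:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return VariantSubset(label=meta["label"], indices=df["index"].to_numpy(),
                         provenance=meta["provenance"])
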