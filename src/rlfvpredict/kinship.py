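"""Genomic and pedigree relationship matrices.

The genomic relationship matrix (GRM) follows VanRaden's method 1,

    G = (X - 2p1')(X - 2p1')' / (2 * sum_j p_j (1 - p_j)),

where X holds allele dosages of the counted (second) allele and p the
observed allele frequencies of the analysed sample. The denominator scales G
to be comparable to the pedigree-based additive relationship matrix A, which
is built with the tabular (recursive) method assuming unrelated, non-inbred
founders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import GenotypeMatrix, Pedigree


class KinshipError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    """Dense symmetric additive relationship matrix with provenance."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # "genomic" or "pedigree"
    denominator: float | None = None   # 2 * sum p(1-p), genomic only
    freqs: np.ndarray | None = None    # allele frequencies, genomic only

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise KinshipError("relationship matrix shape inconsistent with IDs")
        if not np.allclose(v, v.T, atol=1e-10):
            raise KinshipError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids: np.ndarray) -> np.ndarray:
        """Return the submatrix for ``ids`` in the given order."""
        index = {i: k for k, i in enumerate(self.ids)}
        try:
            rows = np.array([index[i] for i in ids])
        except KeyError as exc:
            raise KinshipError(f"individual {exc.args[0]!r} not in relationship matrix") from exc
        return self.values[np.ix_(rows, rows)]


def _dosage_array(genotypes: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosages, genotypes.ids
    arr = np.asarray(genotypes)
    return arr, np.array([f"I{i + 1:04d}" for i in range(arr.shape[0])])


def allele_frequencies(genotypes: GenotypeMatrix | np.ndarray,
                       variant_subset: np.ndarray | None = None) -> np.ndarray:
    """Observed frequency of the counted allele: mean dosage / 2 per variant."""
    dos, _ = _dosage_array(genotypes)
    if variant_subset is not None:
        variant_subset = np.asarray(variant_subset)
        if variant_subset.size == 0:
            raise KinshipError("empty variant subset")
        dos = dos[:, variant_subset]
    if dos.shape[1] == 0:
        raise KinshipError("empty variant subset")
    return dos.mean(axis=0, dtype=np.float64) / 2.0


def minor_allele_frequencies(genotypes: GenotypeMatrix | np.ndarray,
                             variant_subset: np.ndarray | None = None) -> np.ndarray:
    p = allele_frequencies(genotypes, variant_subset)
    return np.minimum(p, 1.0 - p)


def vanraden_grm(
    genotypes: GenotypeMatrix | np.ndarray,
    variant_subset: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    stabilize: bool = True,
) -> RelationshipMatrix:
    """VanRaden method-1 GRM over a variant subset.

    Monomorphic variants have centred dosages identically zero and a zero
    heterozygosity term, so they drop out of both numerator and denominator.
    With ``stabilize`` a tiny diagonal jitter (1e-6) is added if the matrix
    fails a Cholesky probe, which can happen through round-off when the
    subset has fewer variants than individuals.
    """
    dos, ids = _dosage_array(genotypes)
    if variant_subset is not None:
        variant_subset = np.asarray(variant_subset)
        if variant_subset.size == 0:
            raise KinshipError("empty variant subset")
        dos = dos[:, variant_subset]
    X = dos.astype(np.float64)
    p = allele_frequencies(X) if freqs is None else np.asarray(freqs, dtype=np.float64)
    if p.shape[0] != X.shape[1]:
        raise KinshipError("frequency vector length does not match subset size")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise KinshipError("all variants in subset are monomorphic (zero denominator)")
    Z = X - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    if stabilize:
        n = G.shape[0]
        try:
            np.linalg.cholesky(G + 1e-8 * np.eye(n))
        except np.linalg.LinAlgError:
            G = G + 1e-6 * np.eye(n)
    return RelationshipMatrix(ids=ids, values=G, kind="genomic",
                              denominator=denom, freqs=p)


def pedigree_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method.

    Individuals are processed in generation order; for individual i with
    parents s and d, a_ij = (a_sj + a_dj) / 2 for all earlier j and
    a_ii = 1 + a_sd / 2. Unknown parents contribute zero.
    """
    t = pedigree.table.sort_values(["generation"], kind="mergesort").reset_index(drop=True)
    n = len(t)
    ids = t["id"].to_numpy()
    index = {i: k for k, i in enumerate(ids)}
    A = np.zeros((n, n))
    for i in range(n):
        sire, dam = t.at[i, "sire"], t.at[i, "dam"]
        si = index.get(sire) if sire is not None and not (isinstance(sire, float) and np.isnan(sire)) else None
        di = index.get(dam) if dam is not None and not (isinstance(dam, float) and np.isnan(dam)) else None
        if i > 0:
            row = np.zeros(i)
            if si is not None:
                row += 0.5 * A[si, :i]
            if di is not None:
                row += 0.5 * A[di, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    return RelationshipMatrix(ids=ids, values=A, kind="pedigree")
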