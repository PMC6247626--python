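"""Gene-level rare-variant association with a polygenic background.

A kernel (famSKAT-style) variance-component score test: under the null the
phenotype follows y = X gamma + u + e with u ~ N(0, A sigma2_a) for a
pedigree (or genomic) relationship matrix A. For a gene with dosage matrix
M (n x m), variant effects are modelled as random with a common variance
and no assumption on their direction; the score statistic is

    Q = r' M M' r,    r = V0^{-1} (y - X gamma_hat),

and under the null Q is distributed as a mixture sum_i lambda_i chi2_1 with
lambda_i the eigenvalues of M' P0 M, where P0 is the null REML projection.
Tail probabilities are computed by numerical inversion of the characteristic
function (Imhof's integral) with a Satterthwaite moment-matching fallback.

The null model is fitted once per trait and reused across genes, making a
genome scan O(genes) in back-solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.linalg import cho_factor, cho_solve

from .kinship import RelationshipMatrix
from .reml import FitResult, reml_fit
from .simulate import GenomeMap, GenotypeMatrix, PhenotypeTable, PANEL_RLFV


class GeneTestError(ValueError):
    pass


@dataclass
class NullModelFit:
    """Fitted polygenic-only null model with a cached covariance factorization."""

    gamma: np.ndarray
    sigma2_a: float
    sigma2_e: float
    X: np.ndarray
    resid_v: np.ndarray            # V0^{-1} (y - X gamma_hat)
    _cho: tuple                    # Cholesky of V0
    _XtVinvX_inv: np.ndarray
    _VinvX: np.ndarray
    reml: FitResult | None = None

    def apply_p0(self, B: np.ndarray) -> np.ndarray:
        """P0 @ B with P0 = V0^{-1} - V0^{-1} X (X'V0^{-1}X)^{-1} X'V0^{-1}."""
        VB = cho_solve(self._cho, B)
        return VB - self._VinvX @ (self._XtVinvX_inv @ (self._VinvX.T @ B))


@dataclass
class GeneTestResult:
    gene: str
    n_variants: int
    Q: float
    p: float
    status: str            # "ok" or "degenerate"
    method: str = "imhof"  # p-value route: "imhof" or "satterthwaite"


def fit_null_model(y, covariates, kinship, **reml_kwargs) -> NullModelFit:
    """REML fit of y = X gamma + u + e with u ~ N(0, A sigma2_a).

    ``covariates`` may be None (intercept only) or an n x p design matrix
    that must already contain the intercept column.
    """
    A = kinship.values if isinstance(kinship, RelationshipMatrix) else np.asarray(kinship)
    fit = reml_fit(y, [A], X=covariates, term_names=("polygenic",), **reml_kwargs)
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.ones((len(y), 1)) if covariates is None else np.asarray(covariates, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    s2a, s2e = fit.variances["polygenic"], fit.residual_variance
    V0 = s2a * A + s2e * np.eye(len(y))
    cho = cho_factor(V0, lower=True)
    VinvX = cho_solve(cho, X)
    XtVinvX_inv = np.linalg.inv(X.T @ VinvX)
    gamma = XtVinvX_inv @ (VinvX.T @ y)
    resid_v = cho_solve(cho, y - X @ gamma)
    return NullModelFit(gamma=gamma, sigma2_a=s2a, sigma2_e=s2e, X=X,
                        resid_v=resid_v, _cho=cho, _XtVinvX_inv=XtVinvX_inv,
                        _VinvX=VinvX, reml=fit)


def _imhof_sf(q: float, lam: np.ndarray) -> float | None:
    """P(sum lambda_i chi2_1 > q) by Imhof's characteristic-function integral."""

    def integrand(u: float) -> float:
        lu = lam * u
        theta = 0.5 * np.sum(np.arctan(lu)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p(lu * lu)))
        return np.sin(theta) / (u * rho)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=500)
    except Exception:
        return None
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-5 or p < -1e-6 or p > 1 + 1e-6:
        return None
    return float(min(max(p, 1e-300), 1.0))


def _satterthwaite_sf(q: float, lam: np.ndarray) -> float:
    """Scaled chi-square approximation matching the first two moments."""
    s1, s2 = np.sum(lam), np.sum(lam**2)
    scale = s2 / s1
    df = s1**2 / s2
    return float(stats.chi2.sf(q / scale, df))


def mixture_chi2_sf(q: float, lam: np.ndarray) -> tuple[float, str]:
    """Upper-tail probability of a positive mixture of chi2_1 variables."""
    lam = np.asarray(lam, dtype=np.float64)
    p = _imhof_sf(q, lam)
    if p is not None:
        return p, "imhof"
    return _satterthwaite_sf(q, lam), "satterthwaite"


def gene_score_test(null_fit: NullModelFit, gene_dosages: np.ndarray,
                    gene: str = "") -> GeneTestResult:
    """Variance-component score test of one gene's variant set."""
    M = np.asarray(gene_dosages, dtype=np.float64)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] != len(null_fit.resid_v):
        raise GeneTestError("gene dosage rows do not match null-model individuals")
    Q = float(np.sum((M.T @ null_fit.resid_v) ** 2))
    S = M.T @ null_fit.apply_p0(M)
    S = 0.5 * (S + S.T)
    lam = np.linalg.eigvalsh(S)
    lam = lam[lam > max(lam.max(initial=0.0) * 1e-10, 0.0)]
    if lam.size == 0:
        return GeneTestResult(gene=gene, n_variants=M.shape[1], Q=Q, p=1.0,
                              status="degenerate")
    p, method = mixture_chi2_sf(Q, lam)
    return GeneTestResult(gene=gene, n_variants=M.shape[1], Q=Q, p=p,
                          status="ok", method=method)


def scan_genes(
    genome_map: GenomeMap,
    genotypes: GenotypeMatrix,
    phenotypes_training: PhenotypeTable | np.ndarray,
    kinship,
    alpha: float = 0.01,
    covariates=None,
    training_ids: np.ndarray | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Scan every gene's RLFV set for association on the training cohort.

    Returns the genes with p strictly below ``alpha`` and the full results
    table sorted by p. ``kinship`` must cover the training individuals; when
    it is a labelled RelationshipMatrix it is aligned to them by ID.
    """
    if not 0 < alpha < 1:
        raise GeneTestError("alpha must be in (0, 1)")
    if isinstance(phenotypes_training, PhenotypeTable):
        mask = phenotypes_training.mask("training")
        y = phenotypes_training.table["y"].to_numpy()[mask]
        train_ids = phenotypes_training.ids[mask]
    else:
        y = np.asarray(phenotypes_training, dtype=np.float64)
        train_ids = training_ids
    if train_ids is None:
        raise GeneTestError("training individual IDs are required")
    geno_index = {i: k for k, i in enumerate(genotypes.ids)}
    rows = np.array([geno_index[i] for i in train_ids])

    A = kinship.align(train_ids) if isinstance(kinship, RelationshipMatrix) else np.asarray(kinship)
    null_fit = fit_null_model(y, covariates, A)

    panel = genome_map.variants["panel"].to_numpy()
    results = []
    any_polymorphic = False
    dosages = genotypes.dosages[rows]
    for gene, var_idx in genome_map.genes.items():
        rlfv = var_idx[panel[var_idx] == PANEL_RLFV]
        if rlfv.size == 0:
            continue
        res = gene_score_test(null_fit, dosages[:, rlfv], gene=gene)
        any_polymorphic |= res.status == "ok"
        results.append(res)
    if not results or not any_polymorphic:
        raise GeneTestError("no genes with polymorphic RLFV in the training sample")
    table = pd.DataFrame(
        [(r.gene, r.n_variants, r.Q, r.p, r.status, r.method) for r in results],
        columns=["gene", "n_variants", "Q", "p", "status", "method"],
    ).sort_values("p", kind="mergesort").reset_index(drop=True)
    mapped = table.loc[(table["p"] < alpha) & (table["status"] == "ok"), "gene"].tolist()
    return mapped, table
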