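"""Population structure: PCA on a genetic covariance matrix.

Genotypes are standardized per site (centered by 2p, scaled by
sqrt(2p(1-p))), missing values set to zero after centering (their
expectation under missing-at-random), and the individuals x individuals
covariance eigendecomposed. On a domestication panel the first component
is expected to order individuals along the wild -> feral -> domesticated
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeTable


@dataclass
class PCAResult:
    scores: np.ndarray        # individuals x components
    explained_pct: np.ndarray  # per component, non-increasing
    eigenvalues: np.ndarray    # descending
    eigenvectors: np.ndarray   # columns = components


def genetic_covariance(geno: GenotypeTable) -> np.ndarray:
    """Individuals x individuals covariance of standardized genotypes.

    Raises if any site is monomorphic among called genotypes (standardizing
    would divide by zero); filter on MAF first.
    """
    p = geno.allele_freq()
    mono = ~np.isfinite(p) | (p <= 0.0) | (p >= 1.0)
    if mono.any():
        raise ValueError(
            f"{int(mono.sum())} monomorphic site(s) present; apply a MAF "
            "filter before computing the genetic covariance"
        )
    x = geno.calls.astype(float)
    x[geno.calls == MISSING] = np.nan
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z = np.nan_to_num(z, nan=0.0)
    return (z @ z.T) / geno.n_sites


def pca(cov: np.ndarray) -> PCAResult:
    """Eigendecomposition of a genetic covariance matrix.

    Scores are eigenvectors scaled by sqrt(eigenvalue); the explained
    percentage of each component is its eigenvalue over the trace. For a
    deterministic sign convention, each component is flipped so that its
    largest-magnitude loading is positive.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    scale = max(np.abs(cov).max(), 1.0)
    if np.abs(cov - cov.T).max() > 1e-8 * scale:
        raise ValueError("covariance matrix is not symmetric")
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    for k in range(vec.shape[1]):
        j = int(np.argmax(np.abs(vec[:, k])))
        if vec[j, k] < 0:
            vec[:, k] = -vec[:, k]
    lam_clipped = np.clip(lam, 0.0, None)
    scores = vec * np.sqrt(lam_clipped)
    total = lam.sum()
    explained = 100.0 * lam / total if total > 0 else np.full_like(lam, np.nan)
    return PCAResult(
        scores=scores, explained_pct=explained, eigenvalues=lam, eigenvectors=vec
    )
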