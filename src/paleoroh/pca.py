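"""PC space from a reference genotype matrix, least-squares projection of
sparse samples, and eigenvalue-weighted PC distances.

Sites are standardized the classical way: centred by the mean dose and
scaled by ``sqrt(p (1 - p))`` where ``p`` is a shrunken allele frequency,
``(count + 1) / (2 n + 2)``, which avoids division by zero at near-fixed
sites.  Missing reference genotypes are mean-imputed before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .callset import MISSING, GenotypeTable


class PcaError(ValueError):
    pass


@dataclass
class PCSpace:
    """Fitted principal-component space of a reference panel."""

    site_keys: list  # (chrom, pos) of retained sites
    mean: np.ndarray  # per-site centering term
    scale: np.ndarray  # per-site scaling term
    loadings: np.ndarray  # (n_sites, k) orthonormal site loadings
    eigenvalues: np.ndarray  # (k,) nonincreasing
    samples: list
    coordinates: np.ndarray  # (n_samples, k) reference coordinates

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _standardize_matrix(gt: np.ndarray):
    """Mean-impute missing doses, centre, and scale by sqrt(p(1-p))."""
    g = gt.astype(float)
    g[gt == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(mean, inds[1])
    n = gt.shape[0]
    p = (g.sum(axis=0) + 1.0) / (2.0 * n + 2.0)
    scale = np.sqrt(p * (1.0 - p))
    return (g - mean) / scale, mean, scale


def fit_pca(reference: GenotypeTable, n_components: int = 10) -> PCSpace:
    """Eigendecompose the standardized reference genotype matrix.

    Monomorphic sites are dropped.  If fewer components are supportable
    than requested (at most ``n_samples - 1``), K is reduced with a warning.
    """
    if reference.n_samples < 2:
        raise PcaError("need at least two reference samples")
    gt = reference.gt.T.astype(np.int16)  # samples x sites
    observed = np.where(gt == MISSING, np.nan, gt.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        site_var = np.nanvar(observed, axis=0)
    poly = np.nan_to_num(site_var) > 0
    if not poly.any():
        raise PcaError("all sites are monomorphic")
    gt = gt[:, poly]
    keys = [k for k, keep in zip(reference.site_keys(), poly) if keep]

    x, mean, scale = _standardize_matrix(gt)
    max_k = min(reference.n_samples - 1, x.shape[1])
    if n_components > max_k:
        warnings.warn(
            f"reducing components from {n_components} to {max_k}", stacklevel=2
        )
        n_components = max_k

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = n_components
    loadings = vt[:k].T
    coordinates = u[:, :k] * s[:k]
    eigenvalues = (s[:k] ** 2) / (reference.n_samples - 1)
    return PCSpace(
        site_keys=keys,
        mean=mean,
        scale=scale,
        loadings=loadings,
        eigenvalues=eigenvalues,
        samples=list(reference.samples),
        coordinates=coordinates,
    )


def project(sample: GenotypeTable, space: PCSpace, sample_name: str | None = None) -> np.ndarray:
    """Least-squares projection of one (possibly sparse) sample.

    Standardizes the sample's non-missing genotypes at sites shared with
    the space and solves ``min_c || x - L c ||`` over the loadings
    restricted to those sites.
    """
    j = 0 if sample_name is None else sample.samples.index(sample_name)
    key_index = {k: i for i, k in enumerate(space.site_keys)}
    rows, cols = [], []
    for r, key in enumerate(sample.site_keys()):
        i = key_index.get(key)
        if i is not None and sample.gt[r, j] != MISSING:
            rows.append(r)
            cols.append(i)
    if not rows:
        raise PcaError("no shared non-missing sites between sample and PC space")
    x = (sample.gt[rows, j].astype(float) - space.mean[cols]) / space.scale[cols]
    loadings = space.loadings[cols]
    coords, *_ = np.linalg.lstsq(loadings, x, rcond=None)
    return coords


def weighted_pc_distance(a: np.ndarray, b: np.ndarray, space: PCSpace, k: int = 10) -> float:
    """Sum over the first K components of eigenvalue-share-weighted absolute
    coordinate differences: ``sum_k w_k |a_k - b_k|`` with
    ``w_k = eigval_k / sum_{j<=K} eigval_j``."""
    if k > space.n_components:
        raise PcaError(f"K={k} exceeds the {space.n_components} fitted components")
    if len(a) < k or len(b) < k:
        raise PcaError("coordinate vectors shorter than K")
    eig = space.eigenvalues[:k]
    weights = eig / eig.sum()
    return float(np.sum(weights * np.abs(np.asarray(a)[:k] - np.asarray(b)[:k])))
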