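"""Relationship kernels and their eigen-structure.

Three covariance structures drive the reaction-norm model:

* ``G`` — genomic relationship matrix from centered SNP dosages,
  ``G = X X' / trace(X X')`` (hybrids x hybrids, trace 1);
* ``Omega`` — environmental relationship matrix from centered *and scaled*
  environmental covariates, ``Omega = W W' / trace(W W')``
  (year-locations x year-locations, trace 1);
* ``K`` — record-level interaction kernel, the Hadamard product of the
  record-expanded kernels, ``K = (Z1 G Z1') o (Z2 Omega Z2')``.

``K`` is never needed in dense form: because a Hadamard product of two Gram
matrices is the Gram matrix of the column-wise Khatri-Rao product of their
factors, a basis for ``K`` follows directly from the eigenvectors of ``G``
and ``Omega`` (see :func:`hadamard_eigenbasis`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KernelSet", "PCResult", "genomic_relationship", "environmental_relationship",
    "hadamard_eigenbasis", "pca", "rotate_pcs", "build_kernel_set", "incidence",
]


class DegenerateKernelError(ValueError):
    """Raised when a kernel would be identically zero or 1x1."""


def _as_array(x):
    return x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)


def genomic_relationship(X) -> np.ndarray:
    """Genomic relationship matrix ``X X' / trace(X X')`` from dosages.

    Columns are centered internally, so raw 0/1/2 (imputed) dosages can be
    passed directly.  The result is symmetric PSD with trace exactly 1.
    """
    X = _as_array(X)
    Xc = X - X.mean(axis=0, keepdims=True)
    XX = Xc @ Xc.T
    tr = np.trace(XX)
    if tr <= 0:
        raise DegenerateKernelError("all SNP columns are constant; genomic kernel is zero")
    G = XX / tr
    return (G + G.T) / 2.0


def environmental_relationship(W, return_dropped: bool = False):
    """Environmental relationship ``W W' / trace(W W')`` from centered, scaled ECs.

    Columns are centered and scaled to unit (population) variance internally;
    zero-variance columns are dropped with a warning.
    """
    import warnings

    W = _as_array(W)
    if W.shape[0] < 2:
        raise DegenerateKernelError("need at least two year-locations for an EC kernel")
    mu = W.mean(axis=0, keepdims=True)
    sd = W.std(axis=0, keepdims=True)  # population (n) variance, pinned for reproducibility
    keep = sd[0] > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance EC column(s)")
    if not keep.any():
        raise DegenerateKernelError("all EC columns are constant")
    Ws = (W[:, keep] - mu[:, keep]) / sd[:, keep]
    WW = Ws @ Ws.T
    Om = WW / np.trace(WW)
    Om = (Om + Om.T) / 2.0
    return (Om, keep) if return_dropped else Om


def incidence(labels, levels) -> np.ndarray:
    """0/1 incidence matrix mapping records (rows) to ``levels`` (columns)."""
    levels = list(levels)
    pos = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for r, lab in enumerate(labels):
        Z[r, pos[lab]] = 1.0
    return Z


@dataclass
class PCResult:
    """Eigen-structure of a symmetric PSD kernel.

    ``scores = eigenvectors * sqrt(eigenvalues)`` (kernel-PCA convention), so
    ``scores @ scores.T`` reconstructs the kernel.  For EC-derived PCs,
    :func:`rotate_pcs` fills ``rotation_deg`` and ``rotated_scores``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray
    cumulative: np.ndarray
    rotation_deg: float | None = None
    rotated_scores: np.ndarray | None = None
    rotation_objective: float | None = None

    def project(self, cross_kernel_rows: np.ndarray, n_components: int) -> np.ndarray:
        """Out-of-sample PC scores from kernel rows against the training set.

        ``cross_kernel_rows[i, j] = k(new_i, train_j)``; the projection is
        ``K_cross U diag(lambda^-1/2)`` restricted to the top components.
        """
        lam = self.eigenvalues[:n_components]
        U = self.eigenvectors[:, :n_components]
        with np.errstate(divide="ignore"):
            inv = np.where(lam > 0, 1.0 / np.sqrt(np.maximum(lam, 1e-300)), 0.0)
        return cross_kernel_rows @ U * inv


def pca(kernel, tol: float = 1e-8) -> PCResult:
    """Eigendecomposition of a symmetric kernel, eigenvalues descending.

    Small negative eigenvalues (>= -tol) are clipped to zero; an asymmetric
    input raises ``ValueError``.
    """
    Km = _as_array(kernel)
    if Km.shape[0] != Km.shape[1] or not np.allclose(Km, Km.T, atol=1e-10):
        raise ValueError("pca expects a symmetric square kernel")
    vals, vecs = np.linalg.eigh(Km)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals.min(initial=0.0) < -tol:
        raise ValueError(f"kernel has eigenvalue {vals.min():.3g} below -tol")
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    cumulative = np.cumsum(vals) / total if total > 0 else np.zeros_like(vals)
    scores = vecs * np.sqrt(vals)
    return PCResult(vals, vecs, scores, cumulative)


def rotate_pcs(pc1, pc2, longitude, latitude, step_deg: float = 0.5):
    """Clockwise rotation of the top-two PC scores toward geography.

    Scans angles theta in [0, 360) degrees on a ``step_deg`` grid and picks the
    theta maximizing ``corr(rot1, longitude) + corr(rot2, latitude)``, where
    ``rot1 = pc1 cos(theta) + pc2 sin(theta)`` and
    ``rot2 = -pc1 sin(theta) + pc2 cos(theta)`` (clockwise convention).

    Returns ``(theta_deg, rotated_scores (n x 2), objective)``.
    """
    pc1, pc2 = np.asarray(pc1, float), np.asarray(pc2, float)
    lon, lat = np.asarray(longitude, float), np.asarray(latitude, float)
    if len(pc1) < 3:
        raise ValueError("need at least 3 points to rotate")
    if np.std(lon) == 0 or np.std(lat) == 0:
        raise ValueError("zero-variance coordinate")

    def _corr(a, b):
        sa = np.std(a)
        return 0.0 if sa == 0 else np.corrcoef(a, b)[0, 1]

    thetas = np.arange(0.0, 360.0, step_deg)
    best = (-np.inf, 0.0)
    for th in thetas:
        rad = np.deg2rad(th)
        r1 = pc1 * np.cos(rad) + pc2 * np.sin(rad)
        r2 = -pc1 * np.sin(rad) + pc2 * np.cos(rad)
        obj = _corr(r1, lon) + _corr(r2, lat)
        if obj > best[0]:
            best = (obj, th)
    obj, theta = best
    rad = np.deg2rad(theta)
    rotated = np.column_stack([
        pc1 * np.cos(rad) + pc2 * np.sin(rad),
        -pc1 * np.sin(rad) + pc2 * np.cos(rad),
    ])
    return theta, rotated, obj


def hadamard_eigenbasis(eig_g, eig_omega, Z1, Z2, tol: float = 1e-8,
                        retain_rel: float = 1e-10, max_rank: int | None = None):
    """Factor ``K = (Z1 G Z1') o (Z2 Omega Z2')`` as ``B diag(D) B'``.

    ``eig_g`` and ``eig_omega`` are ``(eigenvalues, eigenvectors)`` pairs of G
    and Omega with eigenvalues >= 0.  Candidate columns
    ``(Z1 u_i sqrt(lam_i)) o (Z2 v_j sqrt(del_j))`` over retained eigenpairs
    (relative eigenvalue > ``retain_rel``) span K exactly, because a Hadamard
    product of Gram matrices is the Gram matrix of the column-wise Khatri-Rao
    product.  An SVD of the candidate matrix yields orthonormal ``B`` and
    positive weights ``D``; K itself is never formed.

    Raises ``ValueError`` if the requested relative Frobenius tolerance cannot
    be met at the allowed rank (reporting the achieved residual).
    """
    lam, U = np.asarray(eig_g[0], float), np.asarray(eig_g[1], float)
    dlt, V = np.asarray(eig_omega[0], float), np.asarray(eig_omega[1], float)
    if lam.min(initial=0) < -1e-12 or dlt.min(initial=0) < -1e-12:
        raise ValueError("eigenvalues must be non-negative (clip before calling)")
    lam, dlt = np.clip(lam, 0, None), np.clip(dlt, 0, None)
    ig = lam > retain_rel * lam.max(initial=0)
    io = dlt > retain_rel * dlt.max(initial=0)
    A = Z1 @ (U[:, ig] * np.sqrt(lam[ig]))       # records x rG
    Bm = Z2 @ (V[:, io] * np.sqrt(dlt[io]))      # records x rOm
    n = A.shape[0]
    C = (A[:, :, None] * Bm[:, None, :]).reshape(n, -1)  # Khatri-Rao rows
    Q, s, _ = np.linalg.svd(C, full_matrices=False)
    s2 = s * s
    frob2 = np.sum(s2 * s2)  # ||K||_F^2 = sum of squared kernel eigenvalues
    if frob2 == 0:
        return np.zeros((n, 0)), np.zeros(0)
    keep = s2 > s2[0] * 1e-14
    if max_rank is not None:
        keep &= np.arange(len(s2)) < max_rank
    resid = np.sqrt(np.sum((s2[~keep]) ** 2) / frob2)
    if resid >= tol:
        raise ValueError(f"requested tol {tol:g} unattainable at rank "
                         f"{keep.sum()}; achieved relative residual {resid:.3g}")
    return Q[:, keep], s2[keep]


@dataclass
class KernelSet:
    """G, Omega, incidence maps and the (factored) interaction kernel.

    ``hybrids`` and ``year_locations`` give the level order of the kernel
    rows; ``Z1``/``Z2`` map records to those levels.  The interaction kernel
    is carried in factored form (``B``, ``D``) and only densified on demand.
    """

    G: np.ndarray
    omega: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    hybrids: list
    year_locations: list
    eig_g: tuple = field(default=None, repr=False)
    eig_omega: tuple = field(default=None, repr=False)
    _B: np.ndarray = field(default=None, repr=False)
    _D: np.ndarray = field(default=None, repr=False)

    def eigen_g(self):
        if self.eig_g is None:
            r = pca(self.G)
            self.eig_g = (r.eigenvalues, r.eigenvectors)
        return self.eig_g

    def eigen_omega(self):
        if self.eig_omega is None:
            r = pca(self.omega)
            self.eig_omega = (r.eigenvalues, r.eigenvectors)
        return self.eig_omega

    def interaction_basis(self, tol: float = 1e-8):
        """Factored interaction kernel ``(B, D)`` with ``K = B diag(D) B'``."""
        if self._B is None:
            self._B, self._D = hadamard_eigenbasis(
                self.eigen_g(), self.eigen_omega(), self.Z1, self.Z2, tol=tol
            )
        return self._B, self._D

    def dense_k(self) -> np.ndarray:
        """Explicit ``K = (Z1 G Z1') o (Z2 Omega Z2')`` (records x records)."""
        return (self.Z1 @ self.G @ self.Z1.T) * (self.Z2 @ self.omega @ self.Z2.T)


def build_kernel_set(records: pd.DataFrame, dosages, ec_matrix: pd.DataFrame) -> KernelSet:
    """Assemble a :class:`KernelSet` aligned to a plot-record table.

    ``dosages`` is the (imputed) hybrids x SNPs matrix; ``ec_matrix`` the
    year-location x EC matrix.  Kernel rows follow the order of the input
    matrices; records missing from either index raise ``KeyError``.
    """
    hybrids = list(dosages.index)
    yls = list(ec_matrix.index)
    missing_h = set(records["hybrid"]) - set(hybrids)
    missing_e = set(records["year_location"]) - set(yls)
    if missing_h or missing_e:
        raise KeyError(f"records reference unknown hybrids {sorted(missing_h)[:3]} "
                       f"or year-locations {sorted(missing_e)[:3]}")
    G = genomic_relationship(dosages)
    Om = environmental_relationship(ec_matrix)
    Z1 = incidence(records["hybrid"], hybrids)
    Z2 = incidence(records["year_location"], yls)
    return KernelSet(G=G, omega=Om, Z1=Z1, Z2=Z2, hybrids=hybrids, year_locations=yls)
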