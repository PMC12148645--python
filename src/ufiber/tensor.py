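"""Diffusion tensor estimation and scalar maps (FA, MD, AD, RD).

The tensor is fit by weighted log-linear least squares on
``ln S = ln S0 - b g' D g`` using only measurements with b <= 1500 s/mm^2
(the inner shell plus b=0 volumes); the outer b=3000 shell is deliberately
ignored, matching the convention that the Gaussian tensor model only holds
at moderate b-values.  One reweighting pass with weights equal to the
squared predicted signal recovers near nonlinear-LS accuracy.

Negative eigenvalues (possible in noisy fits) are clamped to zero before
scalar derivation so FA stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

B_MAX_TENSOR = 1500.0  # s/mm^2, upper shell excluded from the tensor fit


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion acquisition: b-values (s/mm^2) with unit gradient vectors."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if nz.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("bvecs must be unit vectors where b > 0")
        if not (bvals == 0).any():
            raise ValueError("scheme must contain at least one b=0 measurement")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size


def read_scheme(bval_path, bvec_path) -> AcquisitionScheme:
    """Read FSL-style bval/bvec text files (bvecs as 3 rows)."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def write_scheme(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


@dataclass
class TensorFit:
    """One voxel's tensor fit and derived scalars."""

    D: np.ndarray  # symmetric 3x3, mm^2/s
    lnS0: float
    eigenvalues: np.ndarray  # sorted descending, clamped >= 0
    eigenvectors: np.ndarray  # columns matching eigenvalues
    FA: float
    MD: float
    AD: float
    RD: float
    n_used: int
    n_excluded_nonpositive: int


def tensor_scalars(eigenvalues: np.ndarray) -> tuple[float, float, float, float]:
    """(FA, MD, AD, RD) from eigenvalues sorted in descending order.

    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||, the normalized dispersion
    of the eigenvalues; MD their mean; AD the largest; RD the mean of the
    two smaller ones.
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    if lam.size != 3:
        raise ValueError("expected exactly 3 eigenvalues")
    if not (lam[0] >= lam[1] >= lam[2]):
        raise ValueError("eigenvalues must be sorted in descending order")
    if lam[2] < 0:
        raise ValueError("eigenvalues must be non-negative (clamp first)")
    md = lam.mean()
    ad = lam[0]
    rd = (lam[1] + lam[2]) / 2.0
    norm = np.linalg.norm(lam)
    if norm == 0.0:
        fa = 0.0
    else:
        fa = float(np.sqrt(1.5) * np.linalg.norm(lam - md) / norm)
    return fa, float(md), float(ad), float(rd)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def _unpack_tensor(coef: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


class DiffusionTensorModel(BaseEstimator):
    """Weighted log-linear tensor fit for a fixed acquisition scheme.

    Parameters
    ----------
    scheme : AcquisitionScheme
        The full acquisition; measurements above ``b_max`` are dropped
        before fitting.
    b_max : float
        Shell cutoff (s/mm^2), default 1500.
    """

    def __init__(self, scheme: AcquisitionScheme, b_max: float = B_MAX_TENSOR):
        self.scheme = scheme
        self.b_max = b_max

    def fit(self, X: np.ndarray, y=None) -> "DiffusionTensorModel":
        """Fit one voxel's signal vector; see :func:`fit_tensor`."""
        self.fit_ = fit_tensor(np.asarray(X, dtype=float).ravel(), self.scheme, self.b_max)
        return self

    def predict(self) -> np.ndarray:
        """Predicted signals on the (restricted) scheme from the fitted tensor."""
        f = self.fit_
        keep = self.scheme.bvals <= self.b_max
        design = _design_matrix(self.scheme.bvals[keep], self.scheme.bvecs[keep])
        params = np.concatenate(
            [[f.lnS0], [f.D[0, 0], f.D[1, 1], f.D[2, 2], f.D[0, 1], f.D[0, 2], f.D[1, 2]]]
        )
        return np.exp(design @ params)


def fit_tensor(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    b_max: float = B_MAX_TENSOR,
) -> TensorFit:
    """Fit the diffusion tensor to one voxel's signals.

    Measurements with b > ``b_max`` or non-positive signal are excluded
    (the latter with a recorded count); at least 7 usable rows including a
    b=0 must remain and the direction set must span the 6 tensor degrees of
    freedom, otherwise a ``ValueError`` is raised.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if signals.size != len(scheme):
        raise ValueError("signal vector length does not match scheme")
    keep = scheme.bvals <= b_max
    sig = signals[keep]
    bvals = scheme.bvals[keep]
    bvecs = scheme.bvecs[keep]
    positive = sig > 0
    n_excluded = int((~positive).sum())
    sig, bvals, bvecs = sig[positive], bvals[positive], bvecs[positive]
    if sig.size < 7:
        raise ValueError(
            f"need >=7 positive measurements with b <= {b_max}, have {sig.size}"
        )
    if not (bvals == 0).any():
        raise ValueError("no b=0 measurement among usable rows")
    design = _design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("gradient scheme is rank-deficient for a tensor fit")
    log_sig = np.log(sig)
    # OLS pass, then one reweighting with w = predicted signal squared
    params, *_ = np.linalg.lstsq(design, log_sig, rcond=None)
    pred = np.exp(design @ params)
    w = pred**2
    sw = np.sqrt(w)
    params, *_ = np.linalg.lstsq(design * sw[:, None], log_sig * sw, rcond=None)

    D = _unpack_tensor(params[1:])
    lam, vec = np.linalg.eigh(D)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam_clamped = np.clip(lam, 0.0, None)
    fa, md, ad, rd = tensor_scalars(lam_clamped)
    return TensorFit(
        D=D,
        lnS0=float(params[0]),
        eigenvalues=lam_clamped,
        eigenvectors=vec,
        FA=fa,
        MD=md,
        AD=ad,
        RD=rd,
        n_used=int(sig.size),
        n_excluded_nonpositive=n_excluded,
    )
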