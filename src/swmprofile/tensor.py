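"""Single-shell diffusion tensor estimation by weighted least squares.

The tensor is fit to log-signals in two passes: ordinary least squares on
``ln S = ln S0 - b g' D g``, then one reweighted pass using the squared
predicted signals from the OLS pass as weights — the canonical WLS-DTI
estimator.  Multiple b=0 rows enter the design as ordinary rows (they are not
pre-averaged), and rows with non-positive signal are dropped per voxel before
the log transform.  FA and MD follow from the tensor eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import MetricVolume

#: lower-triangle storage order of the symmetric tensor
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class DiffusionProtocol:
    """Acquisition scheme: one b-value (s/mm^2) and gradient direction per row.

    Directions of b=0 rows are arbitrary; all diffusion-weighted directions
    must be unit length.  A solvable tensor fit needs at least one b=0 row
    and six non-collinear directions (full-rank design).
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (len(self.bvalues), 3):
            raise ValueError("directions must be (n_acquisitions, 3)")

    def __len__(self) -> int:
        return len(self.bvalues)

    def validate(self) -> None:
        if not np.any(self.bvalues == 0):
            raise ValueError("protocol needs at least one b=0 acquisition")
        dw = self.bvalues > 0
        norms = np.linalg.norm(self.directions[dw], axis=1)
        if dw.any() and np.max(np.abs(norms - 1.0)) >= 1e-6:
            raise ValueError("non-unit gradient directions")
        if np.linalg.matrix_rank(self.design_matrix()) < 7:
            raise ValueError("fewer than 6 non-collinear diffusion directions")

    def design_matrix(self) -> np.ndarray:
        """Rows map (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to ln S."""
        b = self.bvalues
        g = self.directions
        return np.column_stack(
            [
                np.ones_like(b),
                -b * g[:, 0] ** 2,
                -b * g[:, 1] ** 2,
                -b * g[:, 2] ** 2,
                -2.0 * b * g[:, 0] * g[:, 1],
                -2.0 * b * g[:, 0] * g[:, 2],
                -2.0 * b * g[:, 1] * g[:, 2],
            ]
        )


def load_protocol(bval_path: str | Path, bvec_path: str | Path) -> DiffusionProtocol:
    """Read FSL-style bval (one row) and bvec (three rows) text files."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DiffusionProtocol(bvalues=bvals, directions=bvecs)


@dataclass
class TensorField:
    """Per-voxel symmetric tensor (6 unique elements, mm^2/s) and ln S0."""

    lowtri: np.ndarray            # (..., 6) in TENSOR_ELEMENTS order
    log_s0: np.ndarray            # (...,)
    valid: np.ndarray             # (...,) bool; False = not fit
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def as_matrices(self) -> np.ndarray:
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.lowtri, -1, 0)
        out = np.empty(self.lowtri.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = xx
        out[..., 1, 1] = yy
        out[..., 2, 2] = zz
        out[..., 0, 1] = out[..., 1, 0] = xy
        out[..., 0, 2] = out[..., 2, 0] = xz
        out[..., 1, 2] = out[..., 2, 1] = yz
        return out

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.as_matrices())


def matrices_to_lowtri(mats: np.ndarray) -> np.ndarray:
    mats = np.asarray(mats, dtype=float)
    return np.stack(
        [
            mats[..., 0, 0],
            mats[..., 1, 1],
            mats[..., 2, 2],
            mats[..., 0, 1],
            mats[..., 0, 2],
            mats[..., 1, 2],
        ],
        axis=-1,
    )


def forward_signals(
    tensors: np.ndarray, protocol: DiffusionProtocol, s0: np.ndarray | float = 1.0
) -> np.ndarray:
    """Noise-free signals S(g, b) = S0 exp(-b g' D g) for (..., 3, 3) tensors."""
    lowtri = matrices_to_lowtri(tensors) if np.shape(tensors)[-1] == 3 else np.asarray(tensors)
    design = protocol.design_matrix()
    log_s = lowtri @ design[:, 1:].T
    return np.asarray(s0)[..., None] * np.exp(log_s) if np.ndim(s0) else s0 * np.exp(log_s)


def fit_tensor_wls(
    signals: np.ndarray,
    protocol: DiffusionProtocol,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> TensorField:
    """Two-pass weighted-least-squares tensor fit.

    ``signals`` has the acquisition axis last.  Per voxel, rows with signal
    <= 0 are dropped; voxels with fewer than 7 usable rows (or a rank-deficient
    row subset) are flagged invalid rather than fit.
    """
    protocol.validate()
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != len(protocol):
        raise ValueError("signal and protocol lengths differ")
    spatial = signals.shape[:-1]
    flat = signals.reshape(-1, len(protocol))
    if mask is None:
        mask_flat = np.ones(flat.shape[0], dtype=bool)
    else:
        mask_flat = np.asarray(mask, dtype=bool).reshape(-1)

    design = protocol.design_matrix()
    params = np.full((flat.shape[0], 7), np.nan)
    valid = np.zeros(flat.shape[0], dtype=bool)

    usable = flat > 0
    clean = mask_flat & usable.all(axis=1)
    if np.any(clean):
        params[clean] = _wls_batch(design, flat[clean])
        valid[clean] = True

    # voxels with some non-positive rows: fit individually on the usable subset
    for idx in np.nonzero(mask_flat & ~usable.all(axis=1))[0]:
        rows = usable[idx]
        if rows.sum() < 7:
            continue
        sub = design[rows]
        if np.linalg.matrix_rank(sub) < 7:
            continue
        params[idx] = _wls_batch(sub, flat[idx, rows][None, :])[0]
        valid[idx] = True

    return TensorField(
        lowtri=params[:, 1:].reshape(spatial + (6,)),
        log_s0=params[:, 0].reshape(spatial),
        valid=valid.reshape(spatial),
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
    )


def _wls_batch(design: np.ndarray, signals: np.ndarray) -> np.ndarray:
    """OLS pass then one reweighting with squared predicted signals."""
    log_s = np.log(signals)
    ols, *_ = np.linalg.lstsq(design, log_s.T, rcond=None)
    w = np.exp(2.0 * (ols.T @ design.T))          # squared predicted signals
    # weighted normal equations, batched over voxels
    dw = design[None, :, :] * w[:, :, None]       # (v, n, 7)
    lhs = np.einsum("vni,nj->vij", dw, design)
    rhs = np.einsum("vni,vn->vi", dw, log_s)
    return np.linalg.solve(lhs, rhs[..., None])[..., 0]


def tensor_to_fa_md(
    tensor: TensorField, participant_id: str | None = None
) -> tuple[MetricVolume, MetricVolume]:
    """Fractional anisotropy and mean diffusivity from tensor eigenvalues.

    MD = mean eigenvalue; FA = sqrt(1/2) * sqrt(sum of squared pairwise
    eigenvalue differences) / ||lambda||, clipped to [0, 1], defined as 0 for
    an all-zero tensor.  Invalid voxels propagate as NaN.
    """
    mats = tensor.as_matrices()
    evals = np.linalg.eigvalsh(np.where(np.isfinite(mats), mats, 0.0))
    md = evals.mean(axis=-1)
    l1, l2, l3 = evals[..., 2], evals[..., 1], evals[..., 0]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num) / np.sqrt(den)
    fa = np.where(den == 0, 0.0, fa)
    fa = np.clip(fa, 0.0, 1.0)
    invalid = ~tensor.valid
    fa = np.where(invalid, np.nan, fa)
    md = np.where(invalid, np.nan, md)
    shape3 = fa.shape if fa.ndim == 3 else fa.reshape(fa.shape + (1,) * (3 - fa.ndim)).shape
    return (
        MetricVolume(fa.reshape(shape3), tensor.affine, "FA", participant_id),
        MetricVolume(md.reshape(shape3), tensor.affine, "MD", participant_id),
    )
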