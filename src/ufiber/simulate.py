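"""Synthetic cohorts, geometric phantoms, and forward-model DWI signals.

Everything downstream of image processing is testable against known ground
truth generated here:

* :func:`simulate_cohort` draws a developmental cohort (ages uniform on
  5.6-21.9 years, sex Bernoulli with the 279/616 male fraction) and builds
  bundle-wise feature tables with a known linear age/sex/interaction/TICV
  structure, cross-feature correlations, latent SAF-LR coupling, and
  optional gross-outlier contamination.
* :func:`simulate_phantom` builds tube-shaped long-range bundle masks and
  U-shaped SAF streamlines with per-streamline truth labels, distractors
  and injected outliers, so classification, length filtering and outlier
  rejection can be scored exactly.
* :func:`simulate_dwi_signal` evaluates the single-tensor forward model
  ``S(b, g) = S0 exp(-b g' D g)`` on an acquisition scheme.

Latent coupling construction: every bundle value receives
``c * h`` from a participant-level factor ``h`` (shared across all
pathways) plus ``sqrt(a^2 - c^2) * g_p`` from a participant-by-pathway
factor shared by the SAF and LR tier of pathway ``p``.  The covariance
between an associated SAF-LR pair is then ``a^2`` and between
non-associated bundles ``c^2``, so ``a == c`` is an exactly exchangeable
null and ``a > c`` makes associated pairs strictly more correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import FEATURES, z_transform
from .tensor import AcquisitionScheme
from .tractometry import Mask, Tractogram, VolumeGrid

# study conditions: HCP-D-like developmental cohort
AGE_RANGE = (5.6, 21.9)
MALE_FRACTION = 279 / 616
DEFAULT_N_PARTICIPANTS = 616

# default per-feature ground-truth coefficients (b0, b_age, b_sex,
# b_agexsex, b_ticv) on the standardized feature scale, age in years.
# Signs follow the developmental pattern: diffusivities fall with age,
# FA/ICVF/ISOVF/ODI rise; males start with higher MD/RD and lower
# FA/ICVF; MD/RD fall faster (and ICVF rises faster) in males.
DEFAULT_BETAS = {
    "FA": (0.0, 0.04, -0.20, 0.00, 0.10),
    "MD": (0.0, -0.05, 0.25, -0.02, 0.10),
    "AD": (0.0, -0.03, 0.15, -0.01, 0.10),
    "RD": (0.0, -0.05, 0.25, -0.02, 0.10),
    "ICVF": (0.0, 0.06, -0.20, 0.02, 0.10),
    "ISOVF": (0.0, 0.03, 0.00, 0.00, 0.05),
    "ODI": (0.0, 0.03, 0.00, 0.00, 0.05),
}

# TICV sub-model: small negative age effect in females, diverging male
# trajectory through the age-by-sex interaction (SD/year units)
TICV_BETA_AGE = -0.04
TICV_BETA_AGE_SEX = 0.07


def default_feature_correlation() -> np.ndarray:
    """Single-factor 7x7 correlation among the features.

    Loadings follow the dominant empirical axis (myelination/packing):
    FA and ICVF load positively, the diffusivities negatively, giving the
    familiar FA-RD and MD-ICVF anticorrelations.  By construction
    ``v v' + diag(1 - v^2)`` is positive semi-definite with unit diagonal.
    """
    v = np.array([0.7, -0.7, -0.4, -0.8, 0.7, -0.3, -0.4])
    corr = np.outer(v, v)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class SimDesign:
    """Ground-truth generative design for a synthetic cohort.

    ``betas`` has shape (n_pathways, 2 tiers [SAF, LR], 7 features, 5
    coefficients); by default every pathway/tier uses the per-feature
    defaults with a small deterministic tier offset so SAF and LR effect
    sizes differ.
    """

    n_participants: int = DEFAULT_N_PARTICIPANTS
    age_range: tuple[float, float] = AGE_RANGE
    sex_proportion: float = MALE_FRACTION
    pathways: tuple[str, ...] = ("AF", "CST", "CC", "OR")
    betas: np.ndarray | None = None
    noise_sd: float = 1.0
    feature_correlation: np.ndarray = field(default_factory=default_feature_correlation)
    coupling_assoc: float = 0.0
    coupling_nonassoc: float = 0.0
    contamination_rate: float = 0.0
    ticv_noise_sd: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        self.feature_correlation = np.asarray(self.feature_correlation, dtype=float)
        if self.feature_correlation.shape != (len(FEATURES), len(FEATURES)):
            raise ValueError("feature_correlation must be 7x7")
        if not np.allclose(self.feature_correlation, self.feature_correlation.T):
            raise ValueError("feature_correlation must be symmetric")
        if not np.allclose(np.diag(self.feature_correlation), 1.0):
            raise ValueError("feature_correlation must have unit diagonal")
        if np.linalg.eigvalsh(self.feature_correlation).min() < -1e-10:
            raise ValueError("feature_correlation is not positive semi-definite")
        if not (0.0 <= self.coupling_nonassoc <= self.coupling_assoc < 1.0):
            raise ValueError(
                "require 0 <= coupling_nonassoc <= coupling_assoc < 1"
            )
        if not (0.0 <= self.contamination_rate < 0.5):
            raise ValueError("contamination_rate must be in [0, 0.5)")
        if self.betas is None:
            self.betas = self.default_beta_array()
        self.betas = np.asarray(self.betas, dtype=float)
        expected = (len(self.pathways), 2, len(FEATURES), 5)
        if self.betas.shape != expected:
            raise ValueError(f"betas must have shape {expected}, got {self.betas.shape}")

    def default_beta_array(self) -> np.ndarray:
        base = np.array([DEFAULT_BETAS[f] for f in FEATURES])  # (7, 5)
        out = np.zeros((len(self.pathways), 2, len(FEATURES), 5))
        for p in range(len(self.pathways)):
            for t in range(2):  # 0 = SAF, 1 = LR
                out[p, t] = base
                # LR tracts mature with larger FA/AD age slopes, smaller ODI
                if t == 1:
                    out[p, t, FEATURES.index("FA"), 1] += 0.02
                    out[p, t, FEATURES.index("AD"), 1] += 0.01
                    out[p, t, FEATURES.index("ODI"), 1] -= 0.02
        return out


def simulate_cohort(
    design: SimDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, SimDesign]:
    """Draw a cohort table and bundle-feature table from a :class:`SimDesign`.

    Returns ``(cohort, features, design)`` — the design is echoed so
    downstream recovery can be scored against it.  Fully reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_participants
    ids = [f"sub-{i:04d}" for i in range(n)]
    age = rng.uniform(*design.age_range, size=n)
    sex = (rng.random(n) < design.sex_proportion).astype(float)

    # TICV with its own small age and age-by-sex effects
    ticv_latent = (
        TICV_BETA_AGE * age
        + TICV_BETA_AGE_SEX * age * sex
        + design.ticv_noise_sd * rng.standard_normal(n)
    )
    ticv = 1450.0 + 130.0 * ticv_latent  # arbitrary volume units
    cohort = pd.DataFrame(
        {"participant_id": ids, "Age": age, "Sex": sex.astype(int), "TICV": ticv}
    )
    zticv = z_transform(ticv, name="TICV")

    design_matrix = np.column_stack([np.ones(n), age, sex, age * sex, zticv])

    a, c = design.coupling_assoc, design.coupling_nonassoc
    pair_loading = np.sqrt(max(a**2 - c**2, 0.0))
    h = rng.standard_normal(n)  # shared participant factor
    g = rng.standard_normal((n, len(design.pathways)))  # participant x pathway

    n_contam = int(np.floor(design.contamination_rate * n))
    contaminated = np.zeros(n, dtype=bool)
    if n_contam:
        contaminated[rng.choice(n, size=n_contam, replace=False)] = True
    noise_scale = np.where(contaminated, 10.0, 1.0)

    # correlated feature noise via the Cholesky-like PSD square root
    w, V = np.linalg.eigh(design.feature_correlation)
    sqrt_corr = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T

    records = []
    for p_idx, pathway in enumerate(design.pathways):
        latent = c * h + pair_loading * g[:, p_idx]
        for t_idx, tier in enumerate(("SAF", "LR")):
            mean = design_matrix @ design.betas[p_idx, t_idx].T  # (n, 7)
            eps = rng.standard_normal((n, len(FEATURES))) @ sqrt_corr.T
            values = (
                mean
                + latent[:, None]
                + design.noise_sd * noise_scale[:, None] * eps
            )
            for f_idx, feature in enumerate(FEATURES):
                records.append(
                    pd.DataFrame(
                        {
                            "participant_id": ids,
                            "pathway": pathway,
                            "tier": tier,
                            "feature": feature,
                            "value": values[:, f_idx],
                        }
                    )
                )
    features = pd.concat(records, ignore_index=True)
    return cohort, features, design


# ---------------------------------------------------------------------------
# geometric phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSet:
    """Phantom tractogram with masks and per-streamline ground truth."""

    grid: VolumeGrid
    lr_masks: dict[str, Mask]
    tractogram: Tractogram
    truth_labels: list[set[str]]
    outlier_flags: np.ndarray
    in_band: np.ndarray  # True when the intended length lies in [5, 40] mm
    lengths: np.ndarray  # intended (pre-jitter) arc lengths, mm


def _tube_mask(
    grid: VolumeGrid, x_center: float, z_center: float, radius: float, y_span: tuple[float, float]
) -> Mask:
    nx, ny, nz = grid.shape
    xs, ys, zs = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    dist2 = (xs - x_center) ** 2 + (zs - z_center) ** 2
    voxels = (dist2 <= radius**2) & (ys >= y_span[0]) & (ys <= y_span[1])
    return Mask(grid=grid, voxels=voxels)


def _u_arc(
    x: float, y0: float, z_top: float, length: float, n_points: int, jitter: float, rng
) -> np.ndarray:
    """U-shaped arc whose polyline length is exactly ``length``, apex at z_top.

    The radius is chord-corrected so the inscribed polyline (not the
    continuous semicircle) has the requested length, and positional jitter
    is a rigid translation (clipped at 3 sigma), which preserves length
    exactly — so generator-recorded lengths are what a length filter sees.
    """
    n_seg = n_points - 1
    radius = length / (2.0 * n_seg * np.sin(np.pi / (2.0 * n_seg)))
    center_z = z_top - radius
    theta = np.linspace(0.0, np.pi, n_points)
    pts = np.column_stack(
        [
            np.full(n_points, x),
            y0 + radius * np.cos(theta),
            center_z + radius * np.sin(theta),
        ]
    )
    if jitter > 0:
        shift = np.clip(rng.normal(0.0, jitter, size=3), -3 * jitter, 3 * jitter)
        pts = pts + shift
    return pts


def simulate_phantom(
    grid_dims: tuple[int, int, int] = (60, 48, 48),
    n_pathways: int = 3,
    fibers_per_bundle: int = 30,
    n_distractors: int = 10,
    n_outliers: int = 2,
    seed: int = 0,
    length_range: tuple[float, float] = (8.0, 30.0),
    n_short: int = 0,
    n_long: int = 0,
    tube_radius: float = 2.0,
    jitter: float = 0.2,
    allow_overlap: bool = False,
) -> PhantomSet:
    """Build tube masks, labelled U-fibers, distractors and outliers.

    Per pathway: a tube-shaped LR mask along the y axis, ``fibers_per_bundle``
    U-arcs crossing it near the apex (lengths drawn around a bundle-level
    mean inside ``length_range``), ``n_short``/``n_long`` extra arcs with
    lengths outside the 5-40 mm band, and ``n_outliers`` straight
    streamlines that pass through the mask but deviate grossly from the
    bundle shape (flagged).  Distractors intersect no mask.

    Truth labels are assigned by construction: arcs and outliers of pathway
    ``p`` carry label ``{p}``, distractors the empty set.  Geometry
    guarantees no streamline approaches another pathway's mask.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if min(grid_dims) < 20:
        raise ValueError("phantom grid must be at least 20 voxels per axis")
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_dims
    affine = np.eye(4)
    affine[:3, 3] = (-1.0, -1.0, -1.0)  # non-trivial origin, 1 mm voxels
    grid = VolumeGrid(shape=grid_dims, affine=affine)

    margin = 4.0
    spacing = (nx - 2 * margin) / n_pathways
    if not allow_overlap and spacing <= 2 * tube_radius + 2.0:
        raise ValueError(
            f"{n_pathways} non-overlapping tubes of radius {tube_radius} "
            f"do not fit a grid of width {nx}"
        )
    z_center = 0.65 * nz
    pathway_names = [f"bundle{p:02d}" for p in range(n_pathways)]
    x_centers = [margin + (p + 0.5) * spacing for p in range(n_pathways)]
    masks = {
        name: _tube_mask(grid, x, z_center, tube_radius, (3.0, ny - 4.0))
        for name, x in zip(pathway_names, x_centers)
    }
    if not allow_overlap:
        total = sum(m.n_voxels for m in masks.values())
        union = np.zeros(grid_dims, dtype=bool)
        for m in masks.values():
            union |= m.voxels
        if union.sum() != total:
            raise ValueError("generated masks overlap; increase grid size or spacing")

    world = lambda v: grid.voxel_to_world(v)[0]  # noqa: E731
    streamlines: list[np.ndarray] = []
    labels: list[set[str]] = []
    outlier_flags: list[bool] = []
    lengths: list[float] = []
    # apex on the tube axis: with translation jitter clipped at 3 sigma the
    # apex voxel's center stays within tube_radius of the axis, so every
    # arc is guaranteed to traverse its own mask
    z_top = z_center

    def add_arc(x: float, length: float, label: set[str]) -> None:
        radius = length / np.pi
        y_mid = ny / 2.0 + rng.normal(0.0, 2.0)
        y_mid = float(np.clip(y_mid, radius + 3.0, ny - 4.0 - radius))
        pts_vox = _u_arc(x, y_mid, z_top, length, 24, jitter, rng)
        streamlines.append(grid.voxel_to_world(pts_vox))
        labels.append(label)
        outlier_flags.append(False)
        lengths.append(length)

    for name, x in zip(pathway_names, x_centers):
        base_len = rng.uniform(*length_range)
        for _ in range(fibers_per_bundle):
            length = float(np.clip(rng.normal(base_len, 1.5), *length_range))
            add_arc(x, length, {name})
        for _ in range(n_short):
            add_arc(x, float(rng.uniform(2.5, 4.0)), {name})
        for _ in range(n_long):
            add_arc(x, float(rng.uniform(42.0, 56.0)), {name})

    # distractors: short polylines far below every tube
    for _ in range(n_distractors):
        x0 = rng.uniform(2.0, nx - 3.0)
        y0 = rng.uniform(3.0, ny - 4.0)
        z0 = rng.uniform(2.0, z_center - tube_radius - 4.0)
        direction = rng.normal(size=3)
        direction[2] = 0.0  # stay in the low-z slab
        direction /= max(np.linalg.norm(direction), 1e-9)
        length = rng.uniform(8.0, 20.0)
        t = np.linspace(0.0, length, 12)
        pts_vox = np.array([x0, y0, z0]) + t[:, None] * direction
        pts_vox = np.clip(pts_vox, 1.0, np.array(grid_dims) - 2.0)
        streamlines.append(grid.voxel_to_world(pts_vox))
        labels.append(set())
        outlier_flags.append(False)
        lengths.append(float(np.linalg.norm(pts_vox[-1] - pts_vox[0])))

    # outliers: straight lines through each tube, far from the U shape
    if n_outliers > 0:
        y_positions = 6.0 + 18.0 * np.arange(n_outliers)
        if y_positions[-1] > ny - 6.0:
            raise ValueError(
                f"cannot place {n_outliers} well-separated outliers in a "
                f"grid of depth {ny}"
            )
        for name, x in zip(pathway_names, x_centers):
            for y_out in y_positions:
                z0, z1 = z_center - 18.0, z_center + 17.0
                t = np.linspace(0.0, 1.0, 16)
                pts_vox = np.column_stack(
                    [
                        np.full(16, x),
                        np.full(16, y_out),
                        z0 + t * (z1 - z0),
                    ]
                )
                shift = np.clip(rng.normal(0.0, jitter, size=3), -3 * jitter, 3 * jitter)
                pts_vox = pts_vox + shift
                streamlines.append(grid.voxel_to_world(pts_vox))
                labels.append({name})
                outlier_flags.append(True)
                lengths.append(z1 - z0)

    lengths_arr = np.asarray(lengths)
    return PhantomSet(
        grid=grid,
        lr_masks=masks,
        tractogram=Tractogram(streamlines=streamlines, grid=grid),
        truth_labels=labels,
        outlier_flags=np.asarray(outlier_flags),
        in_band=(lengths_arr >= 5.0) & (lengths_arr <= 40.0),
        lengths=lengths_arr,
    )


# ---------------------------------------------------------------------------
# DWI forward model
# ---------------------------------------------------------------------------


def hcp_like_scheme(
    n_b0: int = 28, n_b1500: int = 93, n_b3000: int = 92, seed: int = 0
) -> AcquisitionScheme:
    """Two-shell scheme (b = 1500 and 3000 s/mm^2) with quasi-uniform
    directions from a seeded random draw, plus interleaved b=0 volumes."""
    rng = np.random.default_rng(seed)

    def sphere(n: int) -> np.ndarray:
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    bvals = np.concatenate(
        [np.zeros(n_b0), np.full(n_b1500, 1500.0), np.full(n_b3000, 3000.0)]
    )
    bvecs = np.vstack([np.zeros((n_b0, 3)), sphere(n_b1500), sphere(n_b3000)])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def simulate_dwi_signal(
    tensor: np.ndarray,
    S0: float,
    scheme: AcquisitionScheme,
    noise_sd: float = 0.0,
    seed: int = 0,
    rician: bool = False,
) -> np.ndarray:
    """Single-tensor signals ``S0 exp(-b g' D g)`` with optional noise.

    Gaussian noise is added to the magnitude by default; with
    ``rician=True`` independent Gaussian noise corrupts both quadrature
    channels and the magnitude is returned.
    """
    D = np.asarray(tensor, dtype=float)
    if D.shape != (3, 3) or not np.allclose(D, D.T):
        raise ValueError("tensor must be a symmetric 3x3 matrix")
    if np.linalg.eigvalsh(D).min() < 0:
        raise ValueError("tensor has a negative eigenvalue")
    b = scheme.bvals
    g = scheme.bvecs
    adc = np.einsum("ij,jk,ik->i", g, D, g)
    signal = S0 * np.exp(-b * adc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if rician:
            re = signal + rng.normal(0.0, noise_sd, size=signal.shape)
            im = rng.normal(0.0, noise_sd, size=signal.shape)
            signal = np.hypot(re, im)
        else:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return signal
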