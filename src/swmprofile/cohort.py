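"""Synthetic cohort generator with analytic ground truth.

Emulates the structure of a two-group (22 controls, 29 young-onset Alzheimer's
patients) cortical-profile diffusion MRI study: spherical GM/WM boundary
phantoms per hemisphere, five scalar metric volumes per participant (FA, MD,
NDI, ODI, TF), per-participant per-ROI cortical thickness, and a participant
table.  Because the boundary is a sphere, the signed depth of every voxel is
known in closed form, so sampled profiles can be checked against the
generating polynomial exactly.

The voxel value at world point ``x`` for participant ``i`` and metric ``m`` is

    f(m, roi(x), group_i, d(x)) + b0_im + b1_im * d(x) + noise,

clamped to the metric's valid range, where ``d(x) = 1 + R - ||x - centre||``
is the continuous model distance (0 at the GM sample point 1 mm above the
boundary, 3 at 2 mm below it), ``f`` is a quadratic depth polynomial plus the
configured case-group effect, and ``(b0, b1)`` are participant random
intercept/slope.  TF additionally falls off toward the pial side (d < 0) to
mimic CSF partial volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import METRICS
from .mesh import DEFAULT_RADIUS_MM, generate_mesh
from .tensor import DiffusionProtocol, forward_signals
from .volume import METRIC_RANGES, MetricVolume

GROUPS = ("control", "case")

#: unit scale of each metric; random-effect and noise SDs are specified on
#: the unit-interval scale and multiplied by this (MD lives near 1e-3 mm^2/s).
METRIC_SCALE = {"FA": 1.0, "MD": 1.0e-3, "NDI": 1.0, "ODI": 1.0, "TF": 1.0}

#: default control-group depth polynomials a0 + a1*d + a2*d^2 in model
#: distance d (0 = GM point, 3 = SWM/DWM point).  Chosen to follow the
#: observed trend directions (FA, NDI, TF rise and MD, ODI fall moving from
#: GM into white matter) at plausible magnitudes; configuration, not claims.
DEFAULT_PROFILE_COEFFS: dict[str, tuple[float, float, float]] = {
    "FA": (0.15, 0.07, 0.0),
    "MD": (1.00e-3, -0.06e-3, 0.0),
    "NDI": (0.35, 0.07, 0.0),
    "ODI": (0.45, -0.06, 0.0),
    "TF": (0.68, 0.06, 0.0),
}

# ---------------------------------------------------------------- study facts
#: recruited participants and the exclusion tallies of the source study
STUDY_RECRUITED = 69
STUDY_EXCLUSIONS = {
    "t1_motion": 1,
    "t1_processing_failure": 3,
    "dti_motion_or_processing": 7,
    "noddi_motion_or_processing": 7,
}


def apply_exclusions(
    recruited: int = STUDY_RECRUITED, exclusions: Mapping[str, int] | None = None
) -> int:
    """Number of participants left for analysis after the exclusion ledger."""
    if exclusions is None:
        exclusions = STUDY_EXCLUSIONS
    if any(v < 0 for v in exclusions.values()):
        raise ValueError("exclusion counts must be non-negative")
    analyzed = recruited - sum(exclusions.values())
    if analyzed < 0:
        raise ValueError("exclusions exceed recruited participants")
    return analyzed


# ---------------------------------------------------------------- config
@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    ``profile_coeffs[metric][group]`` are quadratic coefficients in model
    distance; ``effect_template[(metric, roi)]`` is the group difference added
    for cases, either a quadratic ``(c0, c1, c2)`` in model distance or a
    ``{depth_index: delta}`` mapping (piecewise linear in between, constant
    outside).  ``random_sd[group]`` are participant intercept/slope SDs on the
    unit-metric scale; ``noise_sd[metric]`` is the voxel noise SD.
    """

    n_control: int = 22
    n_case: int = 29
    roi_count: int = 15
    profile_coeffs: dict = field(default_factory=dict)
    effect_template: dict = field(default_factory=dict)
    random_sd: dict = field(
        default_factory=lambda: {"control": (0.02, 0.005), "case": (0.02, 0.005)}
    )
    noise_sd: dict = field(
        default_factory=lambda: {m: 0.02 * METRIC_SCALE[m] for m in METRICS}
    )
    thickness_mean_sd: dict = field(
        default_factory=lambda: {"control": (2.59, 0.08), "case": (2.49, 0.12)}
    )
    thickness_effect: float = 0.0    # metric units per mm of thickness deviation
    roi_offsets: dict = field(default_factory=dict)  # metric -> (roi_count,) array
    seed: int = 0
    vertices_per_hemi: int = 600
    radius_mm: float = DEFAULT_RADIUS_MM
    voxel_size_mm: float = 1.0
    margin_mm: float = 3.0
    tf_csf_slope: float = 0.25       # extra TF decline per mm toward the pial side
    tf_csf_onset: float = -1.5       # model distance where CSF decline begins (pial side)

    def __post_init__(self) -> None:
        coeffs = {}
        for m in METRICS:
            entry = self.profile_coeffs.get(m, DEFAULT_PROFILE_COEFFS[m])
            if isinstance(entry, Mapping):
                coeffs[m] = {
                    g: tuple(entry.get(g, entry.get("control", DEFAULT_PROFILE_COEFFS[m])))
                    for g in GROUPS
                }
            else:
                coeffs[m] = {g: tuple(entry) for g in GROUPS}
        self.profile_coeffs = coeffs
        self.validate()

    def validate(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 participants per group")
        if self.roi_count < 1:
            raise ValueError("roi_count must be >= 1")
        if self.vertices_per_hemi < self.roi_count:
            raise ValueError("need at least one vertex per ROI")
        for g in GROUPS:
            if any(s < 0 for s in self.random_sd[g]):
                raise ValueError("random-effect SDs must be >= 0")
            if self.thickness_mean_sd[g][1] < 0:
                raise ValueError("thickness SD must be >= 0")
        if any(s < 0 for s in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        for (m, roi) in self.effect_template:
            if m not in METRICS:
                raise KeyError(f"unknown metric {m!r} in effect_template")
            if not 0 <= roi < self.roi_count:
                raise KeyError(f"ROI {roi} outside 0..{self.roi_count - 1}")


def _effect_curve(effect, d: np.ndarray) -> np.ndarray:
    """Evaluate a group-difference template at continuous model distance."""
    d = np.asarray(d, dtype=float)
    if isinstance(effect, Mapping):
        grid = np.arange(4.0)
        vals = np.array([float(effect.get(k, 0.0)) for k in range(4)])
        return np.interp(d, grid, vals)
    c = tuple(effect) + (0.0,) * (3 - len(effect))
    return c[0] + c[1] * d + c[2] * d * d


def true_ame(config: CohortConfig, roi: int, metric: str, depth_index: int) -> float:
    """Population group contrast implied by the effect template at one cell."""
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}")
    if not 0 <= roi < config.roi_count:
        raise KeyError(f"ROI {roi} outside 0..{config.roi_count - 1}")
    if depth_index not in (0, 1, 2, 3):
        raise ValueError("depth_index must be in {0,1,2,3}")
    effect = config.effect_template.get((metric, roi))
    if effect is None:
        return 0.0
    return float(_effect_curve(effect, np.array([float(depth_index)]))[0])


def template_value(
    config: CohortConfig,
    metric: str,
    group: str,
    d: np.ndarray,
    roi: int | np.ndarray = 0,
) -> np.ndarray:
    """Noise-free population value f(metric, roi, group, d) at model distance d.

    This is the closed form the voxel generator realizes; sampling a noiseless
    participant's volume along the surface normals must reproduce it up to
    interpolation error.
    """
    d = np.asarray(d, dtype=float)
    a0, a1, a2 = config.profile_coeffs[metric][group]
    val = a0 + a1 * d + a2 * d * d
    if metric == "TF":
        # CSF partial volume: extra decline outward of the onset (near pial)
        val = val + config.tf_csf_slope * np.minimum(d - config.tf_csf_onset, 0.0)
    offs = config.roi_offsets.get(metric)
    if offs is not None:
        val = val + np.asarray(offs)[np.asarray(roi, dtype=int)]
    if group == "case":
        roi_arr = np.broadcast_to(np.asarray(roi, dtype=int), d.shape)
        for (m, r), effect in config.effect_template.items():
            if m != metric:
                continue
            sel = roi_arr == r
            if np.any(sel):
                val = np.where(sel, val + _effect_curve(effect, d), val)
    lo, hi = METRIC_RANGES[metric]
    return np.clip(val, lo, np.inf if hi is None else hi)


# ---------------------------------------------------------------- cohort
def _participant_ids(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_control + config.n_case):
        grp = "control" if i < config.n_control else "case"
        pid = f"ctl{i:03d}" if grp == "control" else f"pat{i:03d}"
        rows.append({"participant_id": pid, "group": int(grp == "case"), "group_label": grp, "index": i})
    return pd.DataFrame(rows)


def _stream(master_seed: int, *key: int) -> np.random.Generator:
    """Independent reproducible stream keyed by (participant, purpose, ...)."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


class CohortBundle:
    """Lazy cohort: meshes, tables, and per-(participant, metric) volumes.

    Volumes are deterministic functions of ``(config.seed, participant index,
    metric)`` and are generated on demand so a full cohort never has to be
    resident in memory at once.
    """

    def __init__(self, config: CohortConfig):
        self.config = config
        self.mesh_left, self.mesh_right = generate_mesh(
            config.vertices_per_hemi, config.roi_count, config.seed, radius=config.radius_mm
        )
        self.participants = _participant_ids(config)
        self._index = dict(zip(self.participants.participant_id, self.participants["index"]))
        self._group = dict(zip(self.participants.participant_id, self.participants.group_label))
        self.thickness = self._make_thickness()
        self._grid_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # ------------------------------------------------------------- thickness
    def _make_thickness(self) -> pd.DataFrame:
        rows = []
        for _, p in self.participants.iterrows():
            mean, sd = self.config.thickness_mean_sd[p.group_label]
            rng = _stream(self.config.seed, int(p["index"]), 0)
            vals = rng.normal(mean, sd, size=self.config.roi_count)
            for roi in range(self.config.roi_count):
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "roi": roi,
                        "thickness_mm": float(vals[roi]),
                    }
                )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ grid
    def _grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel grid covering both hemispheres: (affine, model distance, roi)."""
        if self._grid_cache is not None:
            return self._grid_cache
        cfg = self.config
        h = cfg.voxel_size_mm
        r, m = cfg.radius_mm, cfg.margin_mm
        cl, cr = self.mesh_left.center, self.mesh_right.center
        lo = np.minimum(cl, cr) - (r + m)
        hi = np.maximum(cl, cr) + (r + m)
        shape = np.ceil((hi - lo) / h).astype(int) + 1
        affine = np.eye(4)
        affine[:3, :3] *= h
        affine[:3, 3] = lo
        ii = [np.arange(n) * h + lo[k] for k, n in enumerate(shape)]
        X, Y, Z = np.meshgrid(*ii, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        left = pts[..., 0] < 0.5 * (cl[0] + cr[0])
        dist = np.empty(tuple(shape))
        roi = np.empty(tuple(shape), dtype=np.int16)
        for mesh, sel in ((self.mesh_left, left), (self.mesh_right, ~left)):
            p = pts[sel].reshape(-1, 3)
            rad = np.linalg.norm(p - mesh.center, axis=1)
            dist[sel] = 1.0 + (mesh.radius - rad)   # model distance d
            roi[sel] = mesh.roi_of_points(p)
        self._grid_cache = (affine, dist, roi)
        return self._grid_cache

    # --------------------------------------------------------------- volumes
    def metric_volume(self, participant_id: str, metric: str) -> MetricVolume:
        cfg = self.config
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        idx = self._index[participant_id]
        group = self._group[participant_id]
        affine, d, roi = self._grid()

        val = template_value(cfg, metric, group, d, roi)

        if cfg.thickness_effect != 0.0:
            thick = self.thickness.query("participant_id == @participant_id")
            tvec = thick.sort_values("roi").thickness_mm.to_numpy()
            ref = 0.5 * (cfg.thickness_mean_sd["control"][0] + cfg.thickness_mean_sd["case"][0])
            val = val + cfg.thickness_effect * (tvec[roi] - ref) * METRIC_SCALE[metric]

        m_i = METRICS.index(metric)
        b0, b1 = self.random_effects(participant_id)[metric]
        val = val + b0 + b1 * d

        sd = cfg.noise_sd[metric]
        if sd > 0:
            rng = _stream(cfg.seed, idx, 2 + m_i)
            val = val + sd * rng.standard_normal(val.shape)

        lo, hi = METRIC_RANGES[metric]
        val = np.clip(val, lo, np.inf if hi is None else hi)
        return MetricVolume(val, affine, metric, participant_id)

    def random_effects(self, participant_id: str) -> dict[str, tuple[float, float]]:
        """Participant random intercept/slope per metric (deterministic)."""
        cfg = self.config
        idx = self._index[participant_id]
        sd0, sd1 = cfg.random_sd[self._group[participant_id]]
        rng = _stream(cfg.seed, idx, 1)
        draws = rng.standard_normal((len(METRICS), 2))
        return {
            m: (draws[k, 0] * sd0 * METRIC_SCALE[m], draws[k, 1] * sd1 * METRIC_SCALE[m])
            for k, m in enumerate(METRICS)
        }

    def volumes(self, participant_id: str) -> dict[str, MetricVolume]:
        return {m: self.metric_volume(participant_id, m) for m in METRICS}


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Build the synthetic cohort bundle (meshes, tables, lazy volumes)."""
    return CohortBundle(config)


# ------------------------------------------------- regional-summary simulator
def simulate_long_table(
    config: CohortConfig,
    seed: int,
    residual_sd: Mapping[str, float] | None = None,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Simulate the modelling table directly at the regional-summary level.

    Realizes the same data-generating process as the voxel path — quadratic
    depth profile + configured case effect + participant random intercept and
    slope — with independent Gaussian residuals standing in for averaged voxel
    noise (default SD: ``noise_sd / 8``, the attenuation of roughly 64
    effective vertices per ROI).  Used for replicate-heavy statistical checks
    where regenerating voxel volumes adds nothing but interpolation error.
    """
    if residual_sd is None:
        residual_sd = {m: config.noise_sd[m] / 8.0 for m in metrics}
    rng = np.random.default_rng(seed)
    participants = _participant_ids(config)
    d = np.arange(4.0)
    n, M, R = len(participants), len(metrics), config.roi_count
    scales = np.array([METRIC_SCALE[m] for m in metrics])

    # population mean profiles per (group, metric, roi, depth)
    mu = {
        g: np.stack(
            [
                np.stack([template_value(config, m, g, d, r) for r in range(R)])
                for m in metrics
            ]
        )
        for g in GROUPS
    }

    is_case = participants.group.to_numpy()                      # (n,)
    sd_mat = np.array([config.random_sd[g] for g in GROUPS])     # (2 groups, 2)
    b = rng.standard_normal((n, M, 2)) * sd_mat[is_case][:, None, :] * scales[None, :, None]
    tstats = np.array([config.thickness_mean_sd[g] for g in GROUPS])
    thick = rng.normal(tstats[is_case, 0, None], tstats[is_case, 1, None], (n, R))
    eps = rng.standard_normal((n, M, R, 4)) * np.array(
        [residual_sd[m] for m in metrics]
    )[None, :, None, None]

    mu_all = np.stack([mu[g] for g in GROUPS])[is_case]          # (n, M, R, 4)
    y = mu_all + b[..., 0, None, None] + b[..., 1, None, None] * d + eps

    return pd.DataFrame(
        {
            "participant_id": np.repeat(participants.participant_id.to_numpy(), M * R * 4),
            "group": np.repeat(is_case, M * R * 4),
            "roi": np.tile(np.repeat(np.arange(R), 4), n * M),
            "metric": np.tile(np.repeat(np.array(metrics, dtype=object), R * 4), n),
            "d": np.tile(np.arange(4), n * M * R),
            "d2": np.tile(np.arange(4) ** 2, n * M * R),
            "y": y.ravel(),
            "thickness": np.tile(np.repeat(thick, 4, axis=1), (1, M)).ravel(),
        }
    )


# ------------------------------------------------------------- DWI simulator
def generate_dwi(
    tensor_spec: np.ndarray,
    protocol: DiffusionProtocol,
    snr: float = np.inf,
    seed: int = 0,
    s0: float = 1.0,
) -> np.ndarray:
    """Forward diffusion-weighted signals S = S0 exp(-b g' D g) plus noise.

    ``tensor_spec`` assigns a symmetric positive-definite 3x3 tensor per voxel
    (shape (..., 3, 3)).  Gaussian noise with SD ``s0 / snr`` is added unless
    ``snr`` is infinite.  Deterministic given ``seed``.
    """
    protocol.validate()
    tensors = np.asarray(tensor_spec, dtype=float)
    if tensors.shape[-2:] != (3, 3):
        raise ValueError("tensor_spec must have shape (..., 3, 3)")
    if not np.allclose(tensors, np.swapaxes(tensors, -1, -2), atol=1e-12):
        raise ValueError("tensors must be symmetric")
    sig = forward_signals(tensors, protocol, s0=s0)
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        sig = sig + (s0 / snr) * rng.standard_normal(sig.shape)
    return sig
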