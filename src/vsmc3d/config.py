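"""Pipeline configuration: every tunable of the segmentation workflow.

Defaults follow the method's published constants where they exist
(``lc0=30``, ``lc1=5`` pixels for the ray emitting-length bound, 30 %
stable-point ratio, 3–5 px stable-edge search window, 0.25 µm z-step);
the remaining knobs are the package's own choices and are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # --- voxel geometry -------------------------------------------------
    xy_pixel_um: float = 0.412   # 211 µm field / 512 px
    z_step_um: float = 0.25

    # --- per-slice preprocessing ---------------------------------------
    diffusion_iterations: int = 5
    diffusion_dt: float = 0.15
    canny_sigma: float = 1.5
    canny_low: float = 0.1       # fraction of stack dynamic range
    canny_high: float = 0.2
    spur_length: int = 5         # px; shorter dead-end branches are pruned
    min_segment_length: int = 3  # px; shorter chains are dropped
    contrast_normalize: bool = False  # optional per-slice flat-field stand-in

    # --- ray fan / edge blocking ---------------------------------------
    lc0: float = 30.0            # emitting-length scale (px)
    lc1: float = 5.0             # emitting-length modulation (px)
    clamp_ray_length: bool = True
    ray_bound_symmetric: bool = True  # |cos theta|: both tails reachable
    angular_step_deg: float = 1.0
    gap_min_run: int = 3         # consecutive hitless rays that make a gap
    tail_half_angle_deg: float = 60.0   # |theta| below this is "tail" sector
    extended_ray_parallel_tol_deg: float = 15.0

    # --- edge growing ---------------------------------------------------
    max_gap_span_factor: float = 4.0    # reject gaps wider than this * lc0
    laplace_ray_group_deg: float = 7.0  # ray group width for Laplace PCA
    laplace_window_px: int = 5
    max_gap_angle_deg: float = 90.0     # wider unfillable gap -> cell flagged
    contour_smooth_window: int = 5      # circular moving average, px
    half_max_fraction: float = 0.5      # axial stop: interior peak below
                                        # this fraction of the seed peak

    expected_half_length_px: float = 90.0  # axial reach used when
                                           # attributing edges to cells
    nucleus_to_cell_length: float = 3.5    # cell length / nucleus length
    beta_consistency_deg: float = 8.0      # max cell-vs-nucleus in-plane
                                           # orientation disagreement

    # --- stable edge -----------------------------------------------------
    stable_window_px: float = 5.0       # w in the overlap score
    stability_threshold: float = 0.30   # stable-point ratio for a stable edge
    stable_slices: int = 3              # M neighboring slices
    displacement_cap_px: float = 3.0    # per-slice boundary drift cap

    # --- reconstruction --------------------------------------------------
    closing_radius: int = 1             # 3x3x3 structuring element
    smooth_iterations: int = 5
    smooth_strength: float = 0.3

    # --- morphometry -----------------------------------------------------
    central_fraction: float = 0.5       # width is averaged over this of L
    min_axis_ratio: float = 1.05        # below: orientation indeterminate

    # --- seeding / misc --------------------------------------------------
    nucleus_threshold: float = 0.5      # fraction of channel max
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def __post_init__(self):
        for name in ("xy_pixel_um", "z_step_um", "lc0", "lc1",
                     "angular_step_deg", "stable_window_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lc0 <= self.lc1:
            raise ValueError("lc0 must exceed lc1")


@dataclass
class CellPopulation:
    """Population geometry of the cells the synthetic generator emulates.

    Means and SDs are the study's reported statistics for porcine coronary
    VSMCs: length 62.9±14.9 µm, width 4.6±0.6 µm, thickness 6.2±1.8 µm,
    a two-mode in-plane orientation mixture at −19.4±9.3° and 10.9±4.7°,
    and a half-normal out-of-plane tilt with SD 7.6°.
    """

    length_mean: float = 62.9
    length_sd: float = 14.9
    width_mean: float = 4.6
    width_sd: float = 0.6
    thickness_mean: float = 6.2
    thickness_sd: float = 1.8
    beta_means: tuple = (-19.4, 10.9)
    beta_sds: tuple = (9.3, 4.7)
    beta_weights: tuple = (0.5, 0.5)
    alpha_halfnormal_sd: float = 7.6
    # nucleus size relative to the cell (long axis / width / thickness)
    nucleus_length_fraction: float = 0.28
    nucleus_width_fraction: float = 0.5
    nucleus_thickness_fraction: float = 0.5
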