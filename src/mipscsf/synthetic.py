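"""Synthetic data emulating the hematoma-expansion monitoring experiments.

Three generators cover the three measurement channels of the animal
study design:

* :func:`simulate_csf_compensation` — cerebrospinal-fluid volume under
  the intracranial compensation mechanism (Monro–Kellie): CSF is
  displaced roughly linearly with injected blood until the compensation
  reserve is exhausted, after which the loss rate drops.  Modelled as a
  piecewise-linear trajectory with a single breakpoint.
* :func:`simulate_mips` — a dense magnetic-induction phase-shift
  recording.  CSF has by far the highest conductivity of the main brain
  compartments, so phase change tracks CSF loss during compensation;
  after compensation failure the accumulating blood drives the phase
  back up.  Respiration (~0.7 Hz) and cardiac (~4 Hz) cycles contribute
  additive periodic fluctuation on top of white measurement noise.
* :func:`generate_phantom` — T2-like MR phantoms with CSF hyperintense
  relative to all other tissue, plus exact ground-truth label maps, for
  testing segmentation-based volumetry without any acquisition.

:func:`generate_cohort` ties the three together into an 8-animal-style
bundle shaped like the packaged cohort tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .processing import RawMIPSSeries, block_smooth, normalize, pre_injection_baseline
from .schedule import InjectionSchedule
from .volume import LabelMap, MRVolume, voxel_volume_mm3

__all__ = [
    "CompensationModelParams",
    "MIPSModelParams",
    "CsfGeometry",
    "PhantomSpec",
    "CohortBundle",
    "simulate_csf_compensation",
    "simulate_mips",
    "generate_phantom",
    "generate_template",
    "generate_cohort",
    "default_phantom_suite",
    "DEFAULT_PARAM_RANGES",
    "LABELS",
]

#: Hard label codes used by phantoms and expected by the segmenter's tests.
LABELS = {"background": 0, "WM": 1, "GM": 2, "blood": 3, "CSF": 4}


# ---------------------------------------------------------------------------
# CSF compensation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompensationModelParams:
    """Piecewise-linear CSF-vs-blood compensation model.

    Defaults are a least-squares fit of the model to the packaged
    cohort's mean CSF trajectory (breakpoint by grid search): baseline
    0.87 ml, fast displacement −0.19 ml CSF per ml blood while the
    compensation reserve lasts, −0.06 ml/ml after the ~2.0 ml
    inflection.  ``noise_sd`` is per-observation volumetry noise.
    """

    csf_baseline: float = 0.87
    inflection_blood: float = 2.0
    slope_pre: float = -0.19
    slope_post: float = -0.06
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.csf_baseline <= 0:
            raise ValueError("csf_baseline must be positive")
        if self.inflection_blood <= 0:
            raise ValueError("inflection_blood must be positive")
        if self.slope_pre > 0 or self.slope_post > 0:
            raise ValueError("compensation slopes must be nonpositive")
        if abs(self.slope_post) > abs(self.slope_pre):
            raise ValueError("|slope_post| must not exceed |slope_pre|")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def csf_of_blood(params: CompensationModelParams, blood_ml) -> np.ndarray:
    """Noise-free CSF volume (ml) as a function of injected blood (ml)."""
    b = np.asarray(blood_ml, dtype=float)
    v = (
        params.csf_baseline
        + params.slope_pre * np.minimum(b, params.inflection_blood)
        + params.slope_post * np.maximum(0.0, b - params.inflection_blood)
    )
    return np.clip(v, 0.0, None)


def simulate_csf_compensation(
    params: CompensationModelParams,
    schedule: InjectionSchedule,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """CSF volume at the schedule's sample times.

    Returns ``(noisy, noise_free)`` in ml; both are clipped at zero.
    """
    if params.inflection_blood >= schedule.total_volume:
        raise ValueError("inflection_blood must lie within the injected volume range")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    clean = csf_of_blood(params, schedule.sample_blood)
    noisy = np.clip(clean + rng.normal(0.0, params.noise_sd, size=clean.shape), 0.0, None)
    return noisy, clean


# ---------------------------------------------------------------------------
# Phase-shift recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MIPSModelParams:
    """Linear compartment-volume response model for the phase signal.

    ``coef_csf`` (°/ml, > 0) scales phase change with CSF loss — CSF has
    the dominant conductivity, so a shrinking CSF compartment lowers the
    phase.  ``coef_blood`` (°/ml, >= 0) raises the phase once injected
    blood exceeds ``blood_onset_ml``, the proxy for compensation failure
    (tied by default to the compensation model's inflection).  Defaults
    for the coefficients were fit from the packaged cohort's mean
    trajectories; the periodic amplitudes/frequencies follow the
    physiological respiration and cardiac cycles.
    """

    baseline_phase: float = 100.0
    coef_csf: float = 6.0
    coef_blood: float = 1.0
    blood_onset_ml: float = 2.0
    resp_amp: float = 0.2
    cardiac_amp: float = 0.05
    resp_freq: float = 0.7
    cardiac_freq: float = 4.0
    noise_sd: float = 0.1
    sample_rate: float = 50.0  # samples per minute

    def __post_init__(self) -> None:
        if self.coef_csf <= 0:
            raise ValueError("coef_csf must be positive (CSF loss lowers the phase)")
        if self.coef_blood < 0:
            raise ValueError("coef_blood must be nonnegative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if min(self.resp_amp, self.cardiac_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")


def simulate_mips(
    mp: MIPSModelParams,
    csf_series: np.ndarray,
    schedule: InjectionSchedule,
    seed: int | np.random.Generator | None = 0,
    pre_injection_min: float = 0.0,
    animal_id: str = "synthetic",
) -> RawMIPSSeries:
    """Dense phase-shift recording driven by a CSF trajectory.

    ``csf_series`` must be aligned to ``schedule.sample_times``; it is
    linearly interpolated onto the dense sampling grid via the blood
    axis.  ``pre_injection_min`` prepends a baseline segment (t < 0,
    blood = 0) used by the normalization convention.  The sample count
    over the infusion is ``sample_rate * duration`` (2700 for the
    default 50/min x 54 min protocol).
    """
    csf_series = np.asarray(csf_series, dtype=float)
    sample_blood = schedule.sample_blood
    if csf_series.shape != sample_blood.shape:
        raise ValueError(
            f"csf_series length {csf_series.size} does not match the "
            f"schedule's {sample_blood.size} sample times"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(round(mp.sample_rate * schedule.duration))
    n_pre = int(round(mp.sample_rate * pre_injection_min))
    # infusion samples at 1/rate .. duration; baseline samples strictly before t=0
    t_min = np.concatenate([np.arange(-n_pre, 0), np.arange(1, n + 1)]) / mp.sample_rate
    blood = schedule.blood_at(t_min)

    # CSF on the dense grid: linear in blood, extrapolated to blood=0 for the baseline
    if sample_blood[0] > 0 and csf_series.size > 1:
        slope0 = (csf_series[1] - csf_series[0]) / (sample_blood[1] - sample_blood[0])
        csf0 = csf_series[0] - slope0 * sample_blood[0]
    else:
        csf0 = csf_series[0]
    csf_dense = np.interp(blood, np.r_[0.0, sample_blood], np.r_[csf0, csf_series])

    t_s = t_min * 60.0
    phase = (
        mp.baseline_phase
        + mp.coef_csf * (csf_dense - csf0)
        + mp.coef_blood * np.maximum(0.0, blood - mp.blood_onset_ml)
        + mp.resp_amp * np.sin(2.0 * np.pi * mp.resp_freq * t_s)
        + mp.cardiac_amp * np.sin(2.0 * np.pi * mp.cardiac_freq * t_s)
        + rng.normal(0.0, mp.noise_sd, size=t_s.shape)
    )
    return RawMIPSSeries(time_s=t_s, phase_deg=phase, animal_id=animal_id, schedule=schedule)


# ---------------------------------------------------------------------------
# MR phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CsfGeometry:
    """Parametric CSF compartment: two mirrored ellipsoidal ventricles.

    Offsets and semi-axes are in mm relative to the grid centre.  The
    admissible pool is the union of the two ellipsoids; a requested
    volume is realised by growing both compartments from their centres
    in (shape-normalised) radius order, so realised regions are nested
    across volumes.
    """

    centers_mm: tuple[tuple[float, float, float], ...] = ((0.0, 6.0, 0.0), (0.0, -6.0, 0.0))
    semi_axes_mm: tuple[float, float, float] = (7.0, 5.5, 5.5)


DEFAULT_TISSUE_MEANS = {"background": 0.02, "WM": 0.35, "GM": 0.55, "blood": 0.70, "CSF": 0.92}
DEFAULT_TISSUE_SDS = {"background": 0.03, "WM": 0.03, "GM": 0.03, "blood": 0.03, "CSF": 0.03}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise specification for one MR phantom.

    The default spacing reproduces the scanner geometry of the study
    protocol (0.5 mm slices, 160 mm FOV on 320x275 in-plane matrices,
    i.e. 0.5 x 0.582 mm in plane); the grid is desk-scale rather than
    full acquisition size, with spacing preserved so volumetry
    arithmetic is identical.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.582)
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    tissue_sds: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_SDS))
    brain_semi_axes_mm: tuple[float, float, float] = (21.0, 20.0, 15.0)
    gm_shell_fraction: float = 0.85  # normalised radius beyond which tissue is GM
    csf_geometry: CsfGeometry = field(default_factory=CsfGeometry)
    hematoma_center_mm: tuple[float, float, float] = (8.0, 0.0, -4.0)
    smoothing_fwhm: float = 0.6  # mm, partial-volume proxy
    noise_sd: float | None = None  # overrides tissue_sds uniformly when set
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape is too small")
        brain = {k: v for k, v in self.tissue_means.items() if k != "background"}
        if self.tissue_means["CSF"] <= max(v for k, v in brain.items() if k != "CSF"):
            raise ValueError("CSF intensity mean must be strictly greatest among brain classes")

    @property
    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.spacing)


def _grid_coords_mm(spec: PhantomSpec) -> list[np.ndarray]:
    """Per-axis physical coordinates (mm) centred on the grid midpoint."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing)
    ]


def _brain_field(spec: PhantomSpec) -> np.ndarray:
    """Normalised ellipsoidal radius of the brain compartment (<1 inside)."""
    cx, cy, cz = np.meshgrid(*_grid_coords_mm(spec), indexing="ij")
    a, b, c = spec.brain_semi_axes_mm
    return np.sqrt((cx / a) ** 2 + (cy / b) ** 2 + (cz / c) ** 2)


def _csf_rank_field(spec: PhantomSpec) -> np.ndarray:
    """Shape-normalised distance to the nearest ventricle centre."""
    cx, cy, cz = np.meshgrid(*_grid_coords_mm(spec), indexing="ij")
    a, b, c = spec.csf_geometry.semi_axes_mm
    rank = np.full(spec.grid_shape, np.inf)
    for (ox, oy, oz) in spec.csf_geometry.centers_mm:
        r = np.sqrt(((cx - ox) / a) ** 2 + ((cy - oy) / b) ** 2 + ((cz - oz) / c) ** 2)
        rank = np.minimum(rank, r)
    return rank


def _fill_to_count(rank: np.ndarray, pool: np.ndarray, n_target: int) -> np.ndarray:
    """Select the ``n_target`` pool voxels of smallest rank (stable ties)."""
    flat_idx = np.flatnonzero(pool)
    order = np.argsort(rank.ravel()[flat_idx], kind="stable")
    chosen = flat_idx[order[:n_target]]
    out = np.zeros(rank.shape, dtype=bool)
    out.ravel()[chosen] = True
    return out


def csf_pool_mask(spec: PhantomSpec) -> np.ndarray:
    """All admissible CSF voxel positions (the full ventricle pool)."""
    return (_csf_rank_field(spec) <= 1.0) & (_brain_field(spec) < spec.gm_shell_fraction)


def generate_phantom(
    spec: PhantomSpec,
    csf_volume_ml: float,
    blood_volume_ml: float = 0.0,
) -> tuple[MRVolume, LabelMap]:
    """T2-like phantom with an exact ground-truth label map.

    The CSF compartment is grown voxel-by-voxel to
    ``round(csf_volume_ml * 1000 / voxel_volume)`` voxels, so the
    ground-truth volume matches the request to within half a voxel; the
    hematoma is grown the same way around ``hematoma_center_mm``.
    Intensities are class means, Gaussian-smoothed as a partial-volume
    proxy, with additive Gaussian noise (a magnitude-image approximation
    valid at moderate SNR).
    """
    if csf_volume_ml < 0 or blood_volume_ml < 0:
        raise ValueError("requested volumes must be nonnegative")
    vox = spec.voxel_volume_mm3
    n_csf = int(round(csf_volume_ml * 1000.0 / vox))
    n_blood = int(round(blood_volume_ml * 1000.0 / vox))

    brain_r = _brain_field(spec)
    brain = brain_r < 1.0
    pool = csf_pool_mask(spec)
    if n_csf > int(pool.sum()):
        raise ValueError(
            f"requested CSF volume {csf_volume_ml} ml exceeds geometric capacity "
            f"{pool.sum() * vox / 1000.0:.3f} ml"
        )
    csf = _fill_to_count(_csf_rank_field(spec), pool, n_csf)

    cx, cy, cz = np.meshgrid(*_grid_coords_mm(spec), indexing="ij")
    hx, hy, hz = spec.hematoma_center_mm
    hem_dist = np.sqrt((cx - hx) ** 2 + (cy - hy) ** 2 + (cz - hz) ** 2)
    blood_pool = brain & ~pool
    if n_blood > int(blood_pool.sum()):
        raise ValueError("requested blood volume exceeds geometric capacity")
    blood = _fill_to_count(hem_dist, blood_pool, n_blood)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[brain] = LABELS["WM"]
    labels[brain & (brain_r >= spec.gm_shell_fraction)] = LABELS["GM"]
    labels[blood] = LABELS["blood"]
    labels[csf] = LABELS["CSF"]

    name_of = {v: k for k, v in LABELS.items()}
    intensity = np.zeros(spec.grid_shape, dtype=float)
    for code, name in name_of.items():
        intensity[labels == code] = spec.tissue_means[name]
    if spec.smoothing_fwhm > 0:
        sigma_mm = spec.smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        intensity = ndimage.gaussian_filter(
            intensity, sigma=[sigma_mm / s for s in spec.spacing]
        )
    rng = np.random.default_rng(spec.seed)
    sds = np.zeros(spec.grid_shape, dtype=float)
    for code, name in name_of.items():
        sd = spec.noise_sd if spec.noise_sd is not None else spec.tissue_sds[name]
        sds[labels == code] = sd
    if np.any(sds > 0):
        intensity = intensity + rng.normal(0.0, 1.0, size=intensity.shape) * sds

    vol = MRVolume(intensity=intensity, spacing=spec.spacing)
    truth = LabelMap(labels=labels, spacing=spec.spacing, class_names=tuple(LABELS))
    return vol, truth


def generate_template(
    spec: PhantomSpec,
    dilation_mm: float = 1.0,
    max_csf_volume_ml: float | None = None,
) -> np.ndarray:
    """Binary CSF template: the admissible compartment, dilated.

    Because realised CSF regions are nested across requested volumes,
    the union over any cohort equals the region realised at the largest
    volume; ``max_csf_volume_ml=None`` uses the full geometric pool.
    Dilation is metric (mm) via a Euclidean distance transform, so the
    template is a superset of every phantom's true mask and grows
    monotonically with ``dilation_mm``.
    """
    if dilation_mm < 0:
        raise ValueError("dilation_mm must be nonnegative")
    pool = csf_pool_mask(spec)
    if max_csf_volume_ml is None:
        base = pool
    else:
        n = int(round(max_csf_volume_ml * 1000.0 / spec.voxel_volume_mm3))
        if n > int(pool.sum()):
            raise ValueError("max_csf_volume_ml exceeds geometric capacity")
        base = _fill_to_count(_csf_rank_field(spec), pool, n)
    if dilation_mm == 0 or not base.any():
        return base.copy()
    dist = ndimage.distance_transform_edt(~base, sampling=spec.spacing)
    return dist <= dilation_mm


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Per-animal parameter ranges (uniform draws) emulating the spread of the
#: packaged cohort tables.
DEFAULT_PARAM_RANGES = {
    "csf_baseline": (0.65, 1.10),
    "inflection_blood": (1.2, 2.4),
    "slope_pre": (-0.25, -0.12),
    "slope_post": (-0.08, -0.02),
    "baseline_phase": (97.0, 101.0),
    "coef_csf": (4.5, 7.5),
    "coef_blood": (0.8, 1.3),
}


@dataclass
class CohortBundle:
    """Synthetic multi-animal study bundle shaped like the cohort tables."""

    schedule: InjectionSchedule
    mips_raw: list[RawMIPSSeries]
    mips_table: np.ndarray  # time points x animals, normalized phase
    csf_table: np.ndarray  # time points x animals, measured (noisy) CSF ml
    csf_truth: np.ndarray  # time points x animals, noise-free CSF ml
    compensation_params: list[CompensationModelParams]
    mips_params: list[MIPSModelParams]
    phantom_spec: PhantomSpec

    @property
    def n_rabbits(self) -> int:
        return self.mips_table.shape[1]

    def phantom_for(self, rabbit: int, timepoint: int, noisy: bool = True):
        """Materialise the MR phantom for one animal/time point on demand."""
        spec = self.phantom_spec
        seed = spec.seed + 1000 * rabbit + timepoint
        spec = _respec(spec, seed=seed, noise_sd=None if noisy else 0.0,
                       smoothing_fwhm=spec.smoothing_fwhm if noisy else 0.0)
        blood = float(self.schedule.sample_blood[timepoint])
        return generate_phantom(spec, float(self.csf_truth[timepoint, rabbit]), blood)


def _respec(spec: PhantomSpec, **kw) -> PhantomSpec:
    from dataclasses import replace

    return replace(spec, **kw)


def generate_cohort(
    n_rabbits: int = 8,
    schedule: InjectionSchedule | None = None,
    param_ranges: dict | None = None,
    seed: int = 0,
    noisy: bool = True,
    pre_injection_min: float = 2.0,
    phantom_spec: PhantomSpec | None = None,
) -> CohortBundle:
    """Simulate a multi-animal monitoring study.

    Per-animal model parameters are drawn uniformly from
    ``param_ranges``; the phase-reversal onset is tied to each animal's
    compensation inflection.  With ``noisy=False`` every noise source is
    switched off (phantom smoothing included), which makes the CSF
    columns exactly nonincreasing.  Reproducible: the same seed yields
    byte-identical tables.
    """
    if n_rabbits < 2:
        raise ValueError("n_rabbits must be >= 2 (correlation analyses need variation)")
    schedule = schedule or InjectionSchedule.default_protocol()
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        unknown = set(param_ranges) - set(ranges)
        if unknown:
            raise ValueError(f"unknown parameter ranges: {sorted(unknown)}")
        ranges.update(param_ranges)
    rng = np.random.default_rng(seed)

    n_t = len(schedule.sample_times)
    mips_raw: list[RawMIPSSeries] = []
    mips_table = np.empty((n_t, n_rabbits))
    csf_table = np.empty((n_t, n_rabbits))
    csf_truth = np.empty((n_t, n_rabbits))
    comp_list: list[CompensationModelParams] = []
    mp_list: list[MIPSModelParams] = []

    for j in range(n_rabbits):
        draw = {k: rng.uniform(*ranges[k]) for k in ranges}
        comp = CompensationModelParams(
            csf_baseline=draw["csf_baseline"],
            inflection_blood=draw["inflection_blood"],
            slope_pre=draw["slope_pre"],
            slope_post=draw["slope_post"],
            noise_sd=0.02 if noisy else 0.0,
        )
        mp = MIPSModelParams(
            baseline_phase=draw["baseline_phase"],
            coef_csf=draw["coef_csf"],
            coef_blood=draw["coef_blood"],
            blood_onset_ml=draw["inflection_blood"],
            resp_amp=0.2 if noisy else 0.0,
            cardiac_amp=0.05 if noisy else 0.0,
            noise_sd=0.1 if noisy else 0.0,
        )
        noisy_csf, clean_csf = simulate_csf_compensation(comp, schedule, seed=rng)
        raw = simulate_mips(
            mp, clean_csf, schedule, seed=rng,
            pre_injection_min=pre_injection_min, animal_id=f"rabbit_{j + 1}",
        )
        baseline = pre_injection_baseline(raw) if pre_injection_min > 0 else mp.baseline_phase
        blocks = normalize(block_smooth(raw), baseline)

        mips_raw.append(raw)
        mips_table[:, j] = blocks.value
        csf_table[:, j] = noisy_csf
        csf_truth[:, j] = clean_csf
        comp_list.append(comp)
        mp_list.append(mp)

    spec = phantom_spec or PhantomSpec(seed=seed)
    if not noisy:
        spec = _respec(spec, noise_sd=0.0, smoothing_fwhm=0.0)
    return CohortBundle(
        schedule=schedule,
        mips_raw=mips_raw,
        mips_table=mips_table,
        csf_table=csf_table,
        csf_truth=csf_truth,
        compensation_params=comp_list,
        mips_params=mp_list,
        phantom_spec=spec,
    )


def default_phantom_suite(seed: int = 0) -> list[tuple[PhantomSpec, float, float]]:
    """The packaged phantom suite for volumetry validation.

    Eight phantoms tracing a compensation-like CSF trajectory (1.05 down
    to 0.34 ml) against the protocol's blood grid, each with its own
    noise seed: ``[(spec, csf_volume_ml, blood_volume_ml), ...]``.
    """
    csf_volumes = [1.05, 0.92, 0.80, 0.68, 0.57, 0.47, 0.40, 0.34]
    blood_volumes = [0.33, 0.66, 1.00, 1.33, 1.66, 2.00, 2.33, 2.66]
    return [
        (PhantomSpec(seed=seed + i), v, b)
        for i, (v, b) in enumerate(zip(csf_volumes, blood_volumes))
    ]
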