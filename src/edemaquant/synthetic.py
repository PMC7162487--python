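"""In-silico study generator for drug-induced vasodilatory edema.

Emulates the animal experiment end to end so the whole pipeline can be
validated against known ground truth: three treatment arms (solvent,
L-type calcium-channel blocker, dual T&L-type blocker), each animal
scanned with an MSME proton-density protocol before drug delivery and at
six post-delivery time points, with the arterial pressure recorded in
parallel.

The forward model is deliberately the same model the analysis fits:

* per-voxel signal  SI(TE) = A * exp(-TE/T2) (+ noise), with the
  T1-saturation factor and scanner gain absorbed into A;
* edema dynamics   A(t) = PD * (1 + a*t + b)  on the ROI for t > 0,
  with the subject slope ``a`` drawn from the arm's distribution, so the
  fractional PD change is exactly linear in time;
* arterial pressure: a baseline plateau above the hypertensive inclusion
  threshold, relaxing exponentially to a reduced plateau after delivery.

Amplitudes are in arbitrary units; only ratios to the pre-delivery scan
are meaningful downstream, so the unknown scanner gain cancels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import AcquisitionParams, MultiEchoVolume

__all__ = [
    "GroupEffect",
    "SyntheticStudyConfig",
    "GroundTruthPhantom",
    "MapTrace",
    "SubjectSeries",
    "SyntheticStudy",
    "default_groups",
    "draw_slope",
    "generate_phantom",
    "simulate_subject_series",
    "simulate_map_trace",
    "simulate_study",
    "sigma_for_snr",
]

logger = logging.getLogger(__name__)

#: Baseline muscle proton-density amplitude, arbitrary units.
PD_BASE = 1000.0

#: Default scan schedule: pre-delivery plus six scans evenly spanning
#: 5-55 min after delivery.
DEFAULT_SCAN_TIMES = (0.0, 5.0, 15.0, 25.0, 35.0, 45.0, 55.0)

NOISE_MODELS = ("none", "gaussian", "rician")


@dataclass(frozen=True)
class GroupEffect:
    """Treatment-arm effect sizes.

    ``dle_mean``/``dle_sd`` parameterize the between-subject distribution
    of the linear edema slope a (fractional PD change per minute);
    ``map_drop_mean``/``map_drop_sd`` the arterial-pressure reduction in
    mmHg; ``onset_offset`` is the intercept b of the post-delivery trend.
    """

    label: str
    dle_mean: float
    dle_sd: float
    map_drop_mean: float
    map_drop_sd: float
    onset_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.dle_sd < 0 or self.map_drop_sd < 0:
            raise ValueError("effect SDs must be non-negative")


def default_groups() -> tuple[GroupEffect, ...]:
    """The three arms at published reference effect sizes.

    Group means and between-subject SDs for the edema slope (DLE, per
    minute) and the arterial-pressure reduction (mmHg) over n=16 animals
    per arm.
    """
    return (
        GroupEffect("solvent", 0.0010, 0.0001, 2.65, 6.56),
        GroupEffect("L-CCB", 0.0047, 0.0008, 68.34, 15.19),
        GroupEffect("T&L-CCB", 0.0025, 0.0004, 90.67, 11.58),
    )


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study design: arms, cohort size, scan schedule, noise model."""

    groups: tuple[GroupEffect, ...] = field(default_factory=default_groups)
    n_per_group: int = 16
    scan_times: tuple[float, ...] = DEFAULT_SCAN_TIMES
    noise_model: str = "rician"
    noise_sigma: float = 17.0  # first-echo muscle SNR ~ 50 at PD_BASE
    seed: int = 0
    truncate_slope_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        times = np.asarray(self.scan_times, dtype=float)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("scan_times must be strictly increasing")
        if times[0] != 0.0:
            raise ValueError("scan_times must start with the pre-delivery scan t=0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not self.groups:
            raise ValueError("at least one group is required")

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "label": g.label,
                    "dle_mean": g.dle_mean,
                    "dle_sd": g.dle_sd,
                    "map_drop_mean": g.map_drop_mean,
                    "map_drop_sd": g.map_drop_sd,
                    "onset_offset": g.onset_offset,
                }
                for g in self.groups
            ],
            "n_per_group": self.n_per_group,
            "scan_times": list(self.scan_times),
            "noise_model": self.noise_model,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "truncate_slope_at_zero": self.truncate_slope_at_zero,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticStudyConfig":
        groups = tuple(
            GroupEffect(
                label=g["label"],
                dle_mean=float(g["dle_mean"]),
                dle_sd=float(g["dle_sd"]),
                map_drop_mean=float(g["map_drop_mean"]),
                map_drop_sd=float(g["map_drop_sd"]),
                onset_offset=float(g.get("onset_offset", 0.0)),
            )
            for g in d.get("groups", [])
        ) or default_groups()
        kwargs = {k: d[k] for k in (
            "n_per_group", "noise_model", "noise_sigma", "seed",
            "truncate_slope_at_zero") if k in d}
        if "scan_times" in d:
            kwargs["scan_times"] = tuple(float(t) for t in d["scan_times"])
        return cls(groups=groups, **kwargs)


@dataclass
class GroundTruthPhantom:
    """Known-truth anatomy: PD and T2 maps plus tissue and ROI masks.

    ``tissue_mask`` marks the two thigh-muscle ellipses with the bone
    discs excluded; ``roi_mask`` restricts it to a block of contiguous
    slices, mirroring an ROI drawn on nine contiguous slices of the
    bilateral thighs.
    """

    pd_map: np.ndarray  # (slice, row, col), >= 0
    t2_map: np.ndarray  # ms; > 0 on tissue
    tissue_mask: np.ndarray  # bool
    roi_mask: np.ndarray  # bool, subset of tissue_mask
    roi_slices: tuple[int, int]  # [start, stop) of the ROI slice block

    def __post_init__(self) -> None:
        if np.any(self.pd_map < 0):
            raise ValueError("pd_map must be non-negative")
        if np.any(self.t2_map[self.tissue_mask] <= 0):
            raise ValueError("t2_map must be positive on tissue")
        if np.any(self.roi_mask & ~self.tissue_mask):
            raise ValueError("roi_mask must be a subset of tissue_mask")


def generate_phantom(
    params: AcquisitionParams,
    seed: int,
    n_roi_slices: int = 9,
) -> GroundTruthPhantom:
    """Build a bilateral-thigh phantom with smooth PD and T2 variation.

    Each slice holds two elliptical muscle cross-sections with a central
    circular "bone" excluded from the tissue mask.  PD varies smoothly
    around `PD_BASE` and T2 lies in the physiological muscle band
    (clipped to [20, 60] ms).  The ROI covers the tissue on
    ``n_roi_slices`` contiguous central slices.  Deterministic in seed.
    """
    ns, nr, nc = params.grid_shape
    if nr < 16 or nc < 16:
        raise ValueError("matrix dimensions must be at least 16")
    if not 1 <= n_roi_slices <= ns:
        raise ValueError(f"n_roi_slices must be in [1, {ns}]")

    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:nr, 0:nc].astype(float)

    tissue2d = np.zeros((nr, nc), dtype=bool)
    a, b = 0.30 * nr, 0.17 * nc  # ellipse semi-axes
    bone_r = 0.35 * min(a, b)
    for c0 in (0.28 * nc, 0.72 * nc):
        r0 = 0.5 * nr
        ell = ((rows - r0) / a) ** 2 + ((cols - c0) / b) ** 2 <= 1.0
        bone = (rows - r0) ** 2 + (cols - c0) ** 2 <= bone_r**2
        tissue2d |= ell & ~bone

    tissue_mask = np.broadcast_to(tissue2d, (ns, nr, nc)).copy()

    # smooth in-plane fields: a few random-phase low-order cosines
    def smooth_field() -> np.ndarray:
        f = np.zeros((nr, nc))
        for _ in range(3):
            kr, kc = rng.uniform(0.5, 2.0, size=2)
            pr, pc = rng.uniform(0, 2 * np.pi, size=2)
            f += rng.uniform(0.3, 1.0) * (
                np.cos(2 * np.pi * kr * rows / nr + pr)
                * np.cos(2 * np.pi * kc * cols / nc + pc)
            )
        return f / 3.0

    pd_map = np.zeros((ns, nr, nc))
    t2_map = np.zeros((ns, nr, nc))
    slice_mod = 1.0 + 0.02 * rng.standard_normal(ns)  # mild slice-to-slice drift
    pd2d = PD_BASE * (1.0 + 0.05 * smooth_field())
    t22d = 40.0 + 8.0 * smooth_field()
    for s in range(ns):
        pd_map[s] = np.where(tissue2d, np.clip(pd2d * slice_mod[s], 0.0, None), 0.0)
        t2_map[s] = np.where(tissue2d, np.clip(t22d, 20.0, 60.0), 0.0)

    start = (ns - n_roi_slices) // 2
    roi_mask = np.zeros_like(tissue_mask)
    roi_mask[start : start + n_roi_slices] = tissue_mask[start : start + n_roi_slices]

    return GroundTruthPhantom(
        pd_map=pd_map,
        t2_map=t2_map,
        tissue_mask=tissue_mask,
        roi_mask=roi_mask,
        roi_slices=(start, start + n_roi_slices),
    )


def _add_noise(
    signal: np.ndarray, model: str, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    if model == "none" or sigma == 0.0:
        return signal
    if model == "gaussian":
        return signal + sigma * rng.standard_normal(signal.shape)
    if model == "rician":
        # magnitude of a complex signal with iid Gaussian channel noise
        re = signal + sigma * rng.standard_normal(signal.shape)
        im = sigma * rng.standard_normal(signal.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


def draw_slope(
    effect: GroupEffect, rng: np.random.Generator, truncate_at_zero: bool = True
) -> float:
    """Draw one subject's edema slope a ~ Normal(dle_mean, dle_sd).

    Clipped at zero from below by default so the solvent arm cannot dry
    out; all default arm means sit >= 10 SD above zero, so clipping is
    practically inert there.
    """
    a = float(rng.normal(effect.dle_mean, effect.dle_sd))
    return max(a, 0.0) if truncate_at_zero else a


@dataclass
class SubjectSeries:
    """One animal's simulated scans with the generating ground truth."""

    subject_id: str
    group_label: str
    volumes: list[MultiEchoVolume]
    true_delta_pd: np.ndarray  # per scan time; 0 at t=0
    slope: float  # a, per minute
    intercept: float  # b


def simulate_subject_series(
    phantom: GroundTruthPhantom,
    effect: GroupEffect,
    config: SyntheticStudyConfig,
    subject_seed: int,
    params: AcquisitionParams,
    subject_id: str = "",
    slope: float | None = None,
) -> SubjectSeries:
    """Simulate one animal's scan series.

    The subject's edema slope is drawn once from
    Normal(dle_mean, dle_sd), clipped at zero from below (configurable);
    pass ``slope`` to pin it.  The pre-delivery scan is the unmodified
    phantom; at post-delivery time t the ROI amplitude is scaled by
    (1 + a*t + b), so the true fractional PD change is exactly a*t + b.
    """
    rng = np.random.default_rng(subject_seed)
    if slope is None:
        a = draw_slope(effect, rng, config.truncate_slope_at_zero)
    else:
        a = float(slope)
        if config.truncate_slope_at_zero:
            a = max(a, 0.0)
    b = effect.onset_offset

    tes = np.asarray(params.echo_times)
    decay = np.zeros(phantom.t2_map.shape + (tes.size,))
    on_tissue = phantom.tissue_mask
    decay[on_tissue] = np.exp(-tes / phantom.t2_map[on_tissue, None])

    times = np.asarray(config.scan_times)
    true_delta = np.where(times > 0, a * times + b, 0.0)

    volumes: list[MultiEchoVolume] = []
    for t, dpd in zip(times, true_delta):
        amp = phantom.pd_map.copy()
        amp[phantom.roi_mask] *= 1.0 + dpd
        signal = amp[..., None] * decay
        signal = _add_noise(signal, config.noise_model, config.noise_sigma, rng)
        volumes.append(
            MultiEchoVolume(signal, params, subject_id=subject_id, time_min=float(t))
        )
    return SubjectSeries(subject_id, effect.label, volumes, true_delta, a, b)


@dataclass
class MapTrace:
    """Arterial-pressure recording and the measured reduction.

    ``reduction`` is the baseline-window mean minus the post-delivery
    plateau-window mean, in mmHg.
    """

    times_min: np.ndarray  # negative = pre-delivery
    pressure_mmhg: np.ndarray
    baseline_mean: float
    plateau_mean: float
    reduction: float


def simulate_map_trace(
    effect: GroupEffect,
    duration_min: float = 60.0,
    subject_seed: int = 0,
    baseline_mmhg: float = 165.0,
    pre_min: float = 5.0,
    tau_min: float = 3.0,
    dt_min: float = 0.1,
    fluctuation_sd: float = 0.0,
) -> MapTrace:
    """Simulate one animal's mean-arterial-pressure trace.

    The pre-delivery plateau sits above the 150 mmHg hypertensive
    inclusion threshold; after delivery the pressure relaxes
    exponentially (time constant ``tau_min``) toward a plateau lowered by
    a subject-level reduction drawn Normal(map_drop_mean, map_drop_sd).
    The reported reduction is measured from the trace: mean over the
    pre-delivery window minus mean over the final 15-minute plateau
    window.  ``fluctuation_sd`` adds optional beat-to-beat variability.
    """
    if duration_min < 55.0:
        raise ValueError("duration must cover the 55-minute delivery period")
    rng = np.random.default_rng(subject_seed)
    drop = float(rng.normal(effect.map_drop_mean, effect.map_drop_sd))

    times = np.arange(-pre_min, duration_min + dt_min / 2, dt_min)
    pressure = np.full(times.shape, baseline_mmhg, dtype=float)
    post = times > 0
    pressure[post] -= drop * (1.0 - np.exp(-times[post] / tau_min))
    if fluctuation_sd > 0:
        pressure += fluctuation_sd * rng.standard_normal(times.shape)

    baseline_mean = float(pressure[times <= 0].mean())
    plateau_mean = float(pressure[times >= duration_min - 15.0].mean())
    return MapTrace(
        times_min=times,
        pressure_mmhg=pressure,
        baseline_mean=baseline_mean,
        plateau_mean=plateau_mean,
        reduction=baseline_mean - plateau_mean,
    )


def sigma_for_snr(snr: float, t2_ms: float = 40.0, first_te_ms: float = 6.5) -> float:
    """Noise sigma giving a first-echo muscle SNR at the phantom PD scale."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return PD_BASE * np.exp(-first_te_ms / t2_ms) / snr


def _child_seed(base_seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class SubjectSpec:
    subject_id: str
    group_index: int
    seed: int


class SyntheticStudy:
    """A lazily-simulated cohort: subjects are materialized on demand.

    Full-size studies are large (hundreds of 4-D volumes), so the study
    object stores only specs and seeds; ``simulate_subject`` regenerates
    any subject bit-identically.
    """

    def __init__(
        self,
        config: SyntheticStudyConfig,
        params: AcquisitionParams,
        n_roi_slices: int = 9,
        shared_phantom: bool = False,
    ):
        self.config = config
        self.params = params
        self.n_roi_slices = n_roi_slices
        self.shared_phantom = shared_phantom
        self.subjects: list[SubjectSpec] = []
        for gi, g in enumerate(config.groups):
            for k in range(config.n_per_group):
                sid = f"{g.label}_{k + 1:02d}"
                self.subjects.append(
                    SubjectSpec(sid, gi, _child_seed(config.seed, gi, k))
                )
        self._shared = (
            generate_phantom(params, _child_seed(config.seed, 9999), n_roi_slices)
            if shared_phantom
            else None
        )

    def phantom_for(self, spec: SubjectSpec) -> GroundTruthPhantom:
        if self._shared is not None:
            return self._shared
        return generate_phantom(self.params, _child_seed(spec.seed, 0), self.n_roi_slices)

    def simulate_subject(self, spec: SubjectSpec) -> tuple[SubjectSeries, MapTrace, GroundTruthPhantom]:
        phantom = self.phantom_for(spec)
        effect = self.config.groups[spec.group_index]
        series = simulate_subject_series(
            phantom, effect, self.config, _child_seed(spec.seed, 1), self.params,
            subject_id=spec.subject_id,
        )
        trace = simulate_map_trace(effect, subject_seed=_child_seed(spec.seed, 2))
        return series, trace, phantom

    def iter_subjects(self):
        for spec in self.subjects:
            yield spec, *self.simulate_subject(spec)


def simulate_study(
    config: SyntheticStudyConfig,
    params: AcquisitionParams | None = None,
    n_roi_slices: int = 9,
    shared_phantom: bool = False,
) -> SyntheticStudy:
    """Set up a synthetic study; subjects simulate lazily and deterministically."""
    if params is None:
        params = AcquisitionParams()
    logger.info(
        "synthetic study: %d groups x %d subjects, %d scan times, noise=%s",
        len(config.groups), config.n_per_group, len(config.scan_times),
        config.noise_model,
    )
    return SyntheticStudy(config, params, n_roi_slices, shared_phantom)
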