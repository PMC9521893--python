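"""Synthetic fluorescence-movie generator with complete ground truth.

Emulates microfluidic-trap GCaMP recordings of a pair of sensory neuron
somata: a Z-stack time-lapse (~350 time points at 2 s intervals, 10-15
planes) in which a chemical stimulus arrives after an initial baseline
period and each neuron responds with a calcium transient of configurable
amplitude and kinetics.  Whole-field motion (slow drift plus occasional
twitch jumps), a linear background gradient, photobleaching, Poisson shot
noise and Gaussian read noise are all optional and seeded, and the
generator emits the exact per-frame shifts, per-neuron masks, noiseless
traces and response classes so that every downstream analysis stage can be
scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import MovieStack

__all__ = [
    "NeuronSpec",
    "SceneConfig",
    "GroundTruth",
    "StaticObjectSpec",
    "transient_kernel",
    "kernel_peak_time",
    "simulate_movie",
    "simulate_static_image",
    "simulate_null_samples",
    "KINETICS_PRESETS",
]

#: Transient kinetics presets on the 2 s frame grid: "fast" recovers within
#: roughly 10-15 s, "slow" returns to steady state in about 30 s.
KINETICS_PRESETS = {
    "fast": {"tau_rise_s": 2.5, "tau_decay_s": 6.0},
    "slow": {"tau_rise_s": 4.0, "tau_decay_s": 15.0},
}

MASK_THRESHOLD_FRACTION = 0.10  # blob footprint cut, fraction of peak
UINT16_MAX = 65535


def kernel_peak_time(tau_rise_s: float, tau_decay_s: float) -> float:
    """Time at which the un-normalized double-exponential kernel peaks."""
    return tau_rise_s * np.log(1.0 + tau_decay_s / tau_rise_s)


def transient_kernel(t, tau_rise_s: float, tau_decay_s: float):
    """Normalized calcium-transient kernel.

    k(t) = c * (1 - exp(-t/tau_r)) * exp(-t/tau_d) for t >= 0, with c chosen
    so that max_t k = 1.  Returns 0 for t < 0.  Accepts scalars or arrays.
    """
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("time constants must be positive")
    if tau_decay_s <= tau_rise_s:
        raise ValueError("tau_decay_s must exceed tau_rise_s")
    t = np.asarray(t, dtype=float)
    t_star = kernel_peak_time(tau_rise_s, tau_decay_s)
    peak = (1.0 - np.exp(-t_star / tau_rise_s)) * np.exp(-t_star / tau_decay_s)
    tt = np.clip(t, 0.0, None)
    k = (1.0 - np.exp(-tt / tau_rise_s)) * np.exp(-tt / tau_decay_s) / peak
    k = np.where(t < 0, 0.0, k)
    return float(k) if k.ndim == 0 else k


@dataclass
class NeuronSpec:
    """One simulated soma: geometry, baseline brightness and response."""

    neuron_id: str
    centroid0: tuple[float, float]  # (row, col), px
    radius_px: float = 4.0
    baseline_B: float = 400.0  # counts
    amplitude_A: float = 1.0  # peak dF/F0
    tau_rise_s: float = 4.0
    tau_decay_s: float = 15.0
    onset_lag_s: float = 0.0
    true_class: str = "high"
    focus_z: int | None = None  # in-focus plane; defaults to mid-stack

    def validate(self) -> None:
        if self.radius_px <= 0 or self.baseline_B <= 0:
            raise ValueError("radius_px and baseline_B must be positive")
        if self.amplitude_A < 0 or self.onset_lag_s < 0:
            raise ValueError("amplitude_A and onset_lag_s must be nonnegative")
        if self.tau_rise_s <= 0 or self.tau_decay_s <= self.tau_rise_s:
            raise ValueError("need 0 < tau_rise_s < tau_decay_s")
        if self.true_class not in ("high", "moderate", "absent"):
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.amplitude_A == 0 and self.true_class != "absent":
            raise ValueError("amplitude 0 implies class 'absent'")


@dataclass
class SceneConfig:
    """Full description of one synthetic recording."""

    height_px: int = 128
    width_px: int = 128
    n_frames: int = 350
    n_z: int = 12
    frame_interval_s: float = 2.0
    stimulus_onset_frame: int = 40
    stimulus_duration_frames: int = 100
    neurons: list[NeuronSpec] = field(default_factory=list)
    drift_step_sd_px: float = 0.3
    twitch_prob: float = 0.02
    twitch_max_px: int = 4
    background_level: float = 100.0
    background_gradient: float = 0.0  # counts per px along columns
    read_noise_sd: float = 3.0
    shot_noise: bool = True
    bleach_rate_per_frame: float = 0.0
    pixel_size_um: float = 0.65
    z_step_um: float = 10.0
    defocus_sigma_planes: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.height_px, self.width_px, self.n_frames, self.n_z) < 1:
            raise ValueError("image/stack dimensions must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not (0 <= self.stimulus_onset_frame
                and self.stimulus_onset_frame + self.stimulus_duration_frames
                <= self.n_frames):
            raise ValueError("stimulus window must lie within the recording")
        if self.drift_step_sd_px < 0 or self.twitch_max_px < 0:
            raise ValueError("motion parameters must be nonnegative")
        if not 0 <= self.twitch_prob <= 1:
            raise ValueError("twitch_prob must be a probability")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background and noise levels must be nonnegative")
        if self.bleach_rate_per_frame < 0:
            raise ValueError("bleach_rate_per_frame must be nonnegative")
        for spec in self.neurons:
            spec.validate()
            r, c = spec.centroid0
            if not (0 <= r < self.height_px and 0 <= c < self.width_px):
                raise ValueError(f"neuron {spec.neuron_id} centroid out of bounds")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        d["neurons"] = [
            NeuronSpec(**{**n, "centroid0": tuple(n["centroid0"])})
            for n in d.get("neurons", [])
        ]
        return cls(**d)


@dataclass
class GroundTruth:
    """Simulator-emitted oracle: shifts, masks, noiseless traces, classes."""

    shifts: np.ndarray  # (T, 2) int, (dy, dx) applied to the whole field
    masks: dict[str, np.ndarray]  # neuron_id -> (T, Y, X) bool
    noiseless_traces: dict[str, np.ndarray]  # neuron_id -> (T,) float
    classes: dict[str, str]
    background_series: np.ndarray  # (T,) float
    clipped_frames: dict[str, np.ndarray]  # neuron_id -> (T,) bool
    noiseless_projection: np.ndarray  # (T, Y, X) float32

    def save(self, path) -> None:
        import tifffile

        path = str(path)
        payload = {
            "shifts": self.shifts.tolist(),
            "noiseless_traces": {k: v.tolist() for k, v in self.noiseless_traces.items()},
            "classes": self.classes,
            "background_series": self.background_series.tolist(),
            "clipped_frames": {k: v.astype(int).tolist() for k, v in self.clipped_frames.items()},
        }
        with open(path + ".json", "w") as fh:
            json.dump(payload, fh)
        label = np.zeros(next(iter(self.masks.values())).shape, dtype=np.uint8)
        for i, (_, m) in enumerate(sorted(self.masks.items()), start=1):
            label[m] = i
        tifffile.imwrite(path + "_masks.tif", label)


def _disk_footprint(shape, center, radius):
    """Boolean disk mask; used by the static-image generator."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _gaussian_blob(shape, center, radius):
    """2-D isotropic Gaussian blob with peak 1 at `center`, sigma = radius/2."""
    sigma = radius / 2.0
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def _simulate_shifts(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Whole-field integer shift per frame: rounded Gaussian random walk
    plus occasional uniform twitch jumps.  Frame 0 is always (0, 0)."""
    walk = np.zeros((cfg.n_frames, 2), dtype=float)
    for t in range(1, cfg.n_frames):
        step = rng.normal(0.0, cfg.drift_step_sd_px, size=2)
        if cfg.twitch_max_px > 0 and rng.random() < cfg.twitch_prob:
            step = step + rng.integers(-cfg.twitch_max_px, cfg.twitch_max_px + 1, size=2)
        walk[t] = walk[t - 1] + step
    return np.rint(walk).astype(int)


def shift_image(img: np.ndarray, dy: int, dx: int, fill=0) -> np.ndarray:
    """Translate a 2-D image by integer (dy, dx), filling vacated pixels."""
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def simulate_movie(config: SceneConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a movie and its exact ground truth.

    Neuron pixel intensity at frame t is B * (1 + A * k(t - onset)) * bleach(t)
    rendered as an isotropic Gaussian blob at the drifted centroid; the
    ground-truth mask is the blob footprint above 10% of peak.  Noise is
    applied after rendering (bleach -> Poisson -> Gaussian read noise ->
    clip/quantize to uint16).  The same config and seed give bit-identical
    output.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T, Z, H, W = cfg.n_frames, cfg.n_z, cfg.height_px, cfg.width_px
    shape = (H, W)

    shifts = _simulate_shifts(cfg, rng)

    # Static background field (level + linear column gradient), same on all
    # planes; the whole field moves with the animal.
    bg0 = cfg.background_level + cfg.background_gradient * np.arange(W)[None, :]
    bg0 = np.broadcast_to(bg0, shape).astype(float)

    # Per-neuron static blob (unit peak) and footprint at zero shift.
    blobs, masks0 = {}, {}
    for spec in cfg.neurons:
        blob = _gaussian_blob(shape, spec.centroid0, spec.radius_px)
        blobs[spec.neuron_id] = blob
        masks0[spec.neuron_id] = blob >= MASK_THRESHOLD_FRACTION

    # Per-plane defocus weight for each neuron, peaking at its focal plane.
    mid = Z // 2
    zw = {}
    for spec in cfg.neurons:
        fz = mid if spec.focus_z is None else spec.focus_z
        zz = np.arange(Z)
        zw[spec.neuron_id] = np.exp(-((zz - fz) ** 2) / (2.0 * cfg.defocus_sigma_planes**2))

    t_s = np.arange(T) * cfg.frame_interval_s
    onset_s = cfg.stimulus_onset_frame * cfg.frame_interval_s
    factors = {}  # neuron_id -> (T,) intensity B*(1+A*k)
    for spec in cfg.neurons:
        k = transient_kernel(t_s - onset_s - spec.onset_lag_s,
                             spec.tau_rise_s, spec.tau_decay_s)
        factors[spec.neuron_id] = spec.baseline_B * (1.0 + spec.amplitude_A * k)

    bleach = np.exp(-cfg.bleach_rate_per_frame * np.arange(T))

    data = np.empty((T, Z, H, W), dtype=np.uint16)
    noiseless_proj = np.empty((T, H, W), dtype=np.float32)
    masks = {s.neuron_id: np.empty((T, H, W), dtype=bool) for s in cfg.neurons}
    clipped = {s.neuron_id: np.zeros(T, dtype=bool) for s in cfg.neurons}
    traces = {s.neuron_id: np.empty(T, dtype=float) for s in cfg.neurons}
    background_series = np.empty(T, dtype=float)

    any_mask0 = np.zeros(shape, dtype=bool)
    for m in masks0.values():
        any_mask0 |= m

    for t in range(T):
        dy, dx = shifts[t]
        bg_t = shift_image(bg0, dy, dx) * bleach[t]
        # noiseless planes; projection computed before noise
        planes = np.empty((Z, H, W), dtype=float)
        for z in range(Z):
            frame = bg_t.copy()
            for spec in cfg.neurons:
                nid = spec.neuron_id
                contrib = blobs[nid] * (factors[nid][t] * zw[nid][z] * bleach[t])
                frame += shift_image(contrib, dy, dx)
            planes[z] = frame
        proj = planes.max(axis=0)
        noiseless_proj[t] = proj

        any_mask_t = shift_image(any_mask0, dy, dx)
        for spec in cfg.neurons:
            nid = spec.neuron_id
            m = shift_image(masks0[nid], dy, dx)
            masks[nid][t] = m
            if m.sum() < masks0[nid].sum():
                clipped[nid][t] = True
            traces[nid][t] = proj[m].mean() if m.any() else np.nan
        outside = ~any_mask_t
        background_series[t] = float(np.median(proj[outside])) if outside.any() else np.nan

        noisy = planes
        if cfg.shot_noise:
            noisy = rng.poisson(np.clip(noisy, 0, None)).astype(float)
        if cfg.read_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, cfg.read_noise_sd, size=noisy.shape)
        data[t] = np.clip(np.rint(noisy), 0, UINT16_MAX).astype(np.uint16)

    movie = MovieStack(
        data=data,
        pixel_size_um=cfg.pixel_size_um,
        z_step_um=cfg.z_step_um,
        frame_interval_s=cfg.frame_interval_s,
        stimulus_onset_frame=cfg.stimulus_onset_frame,
        stimulus_duration_frames=cfg.stimulus_duration_frames,
        source_id=f"synthetic-seed{cfg.seed}",
    )
    gt = GroundTruth(
        shifts=shifts,
        masks=masks,
        noiseless_traces=traces,
        classes={s.neuron_id: s.true_class for s in cfg.neurons},
        background_series=background_series,
        clipped_frames=clipped,
        noiseless_projection=noiseless_proj,
    )
    return movie, gt


@dataclass
class StaticObjectSpec:
    """Uniform disk object for static-image fixtures (a labeled cell)."""

    object_id: str
    center: tuple[float, float]
    radius_px: float
    level: float  # absolute counts inside the disk


def simulate_static_image(
    objects: list[StaticObjectSpec],
    shape: tuple[int, int] = (128, 128),
    n_z: int = 5,
    background_level: float = 30.0,
    background_gradient: float = 0.0,
    shot_noise: bool = False,
    read_noise_sd: float = 0.0,
    defocus_sigma_planes: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, float], dict[str, np.ndarray]]:
    """Render a static Z-stack of uniform disk objects plus ground truth.

    Returns (stack ZxYxX uint16, ground-truth background-subtracted means,
    object footprints).  The ground-truth mean for each object is the exact
    noiseless mean within its footprint, on the max projection, minus the
    background level at its location.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    bg = background_level + background_gradient * np.arange(W)[None, :]
    bg = np.broadcast_to(bg, shape).astype(float)

    mid = n_z // 2
    zz = np.arange(n_z)
    zwts = np.exp(-((zz - mid) ** 2) / (2.0 * defocus_sigma_planes**2))

    footprints, gt_means = {}, {}
    signal = np.zeros(shape, dtype=float)
    for obj in objects:
        if not (0 <= obj.center[0] < H and 0 <= obj.center[1] < W):
            raise ValueError(f"object {obj.object_id} center out of bounds")
        fp = _disk_footprint(shape, obj.center, obj.radius_px)
        footprints[obj.object_id] = fp
        signal[fp] = np.maximum(signal[fp], obj.level - bg[fp])
    # ground truth on the noiseless max projection (focal plane weight is 1)
    proj = bg + signal
    for obj in objects:
        fp = footprints[obj.object_id]
        gt_means[obj.object_id] = float(proj[fp].mean() - bg[fp].mean())

    stack = np.empty((n_z, H, W), dtype=np.uint16)
    for z in range(n_z):
        plane = bg + signal * zwts[z]
        if shot_noise:
            plane = rng.poisson(np.clip(plane, 0, None)).astype(float)
        if read_noise_sd > 0:
            plane = plane + rng.normal(0.0, read_noise_sd, size=plane.shape)
        stack[z] = np.clip(np.rint(plane), 0, UINT16_MAX).astype(np.uint16)
    return stack, gt_means, footprints


#: Amplitudes used when constructing scenes of a named response class:
#: zero for absent, mid-band for moderate, twice the "high" threshold for high.
CLASS_AMPLITUDES = {"absent": 0.0, "moderate": 0.5, "high": 1.6}


def paired_neuron_scene(left_class: str = "high", right_class: str = "high",
                        seed: int = 0, **overrides) -> SceneConfig:
    """Standard two-soma scene mirroring the paired-neuron recordings.

    A brighter fast-kinetics neuron sits left of a dimmer slow-kinetics one
    (the two somata of a pair differ markedly in brightness), on a linear
    background gradient that defeats a single global threshold.  Response
    classes map to amplitudes via CLASS_AMPLITUDES.  Geometry defaults to
    the acquisition emulated throughout: 350 frames at 2 s, stimulus onset
    at frame 40 for 100 frames, 128 x 128 px.
    """
    cfg = SceneConfig(seed=seed, background_gradient=0.3, **overrides)
    H, W = cfg.height_px, cfg.width_px
    cfg.neurons = [
        NeuronSpec("left", (H * 0.5, W * 0.30), radius_px=4.0, baseline_B=400.0,
                   amplitude_A=CLASS_AMPLITUDES[left_class],
                   true_class=left_class, **KINETICS_PRESETS["fast"]),
        NeuronSpec("right", (H * 0.55, W * 0.70), radius_px=4.0, baseline_B=180.0,
                   amplitude_A=CLASS_AMPLITUDES[right_class],
                   true_class=right_class, **KINETICS_PRESETS["slow"]),
    ]
    cfg.validate()
    return cfg


def class_suite_configs(n_per_class: int = 20, seed: int = 0,
                        n_z: int = 5, **overrides) -> list[SceneConfig]:
    """Balanced benchmark suite: `n_per_class` movies per response class
    (both neurons of a movie share the class), with per-movie seeds derived
    from the root seed."""
    configs = []
    classes = ("absent", "moderate", "high")
    for i in range(3 * n_per_class):
        cls = classes[i % 3]
        movie_seed = (seed * 7919 + i * 104729) % (2**31 - 1)
        configs.append(paired_neuron_scene(cls, cls, seed=movie_seed,
                                           n_z=n_z, **overrides))
    return configs


_DISTRIBUTIONS = {
    "normal": lambda rng, n, p: rng.normal(p.get("loc", 0.0), p.get("scale", 1.0), n),
    "lognormal": lambda rng, n, p: rng.lognormal(p.get("mean", 0.0), p.get("sigma", 1.0), n),
    "uniform": lambda rng, n, p: rng.uniform(p.get("low", 0.0), p.get("high", 1.0), n),
    "exponential": lambda rng, n, p: rng.exponential(p.get("scale", 1.0), n),
}


def simulate_null_samples(
    n_groups: int,
    n_per_group: int,
    distribution: str = "normal",
    params: dict | None = None,
    group_shifts: list[float] | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Seeded i.i.d. samples for exercising the statistics decision tree.

    All groups are drawn from the same law (a null), optionally offset by
    `group_shifts` to build simple alternatives.
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 observations per group")
    if distribution not in _DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    draw = _DISTRIBUTIONS[distribution]
    params = params or {}
    shifts = group_shifts or [0.0] * n_groups
    if len(shifts) != n_groups:
        raise ValueError("group_shifts length must equal n_groups")
    return [draw(rng, n_per_group, params) + s for s in shifts]
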