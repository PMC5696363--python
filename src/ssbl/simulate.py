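"""Synthetic ESI benchmark generator.

Reproduces, at desk scale, the statistical structure of the paper-style
simulation protocol: patch sources of given geodesic radii carrying slow
cosines or thresholded Gaussian-pulse trains, alpha-band autoregressive
noise injected at the source level plus white sensor noise at a target
SNR, and a jittered second lead field so that inversion never uses the
exact forward operator that generated the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .core import EEGRecording, LeadField, SourceSpace, SpatioTemporalSource

__all__ = [
    "PatchSpec",
    "NoiseSpec",
    "SimulationConfig",
    "make_source_space",
    "make_sensor_positions",
    "make_lead_field",
    "perturb_lead_field",
    "make_patch_sources",
    "default_patches",
    "hemisphere_layouts",
    "simulate_trial",
    "simulate_study",
]

SOURCE_RADIUS_MM = 80.0
SCALP_RADIUS_MM = 100.0
PULSE_ZERO_THRESHOLD = 1e-3  # samples below 0.1 % of a pulse maximum -> exact 0


@dataclass
class PatchSpec:
    """One active patch: spatial extent plus its time course."""

    center: int
    radius: float                       # geodesic radius, mm
    amplitude: float = 1.0
    waveform: str = "cosine"            # "cosine" | "gaussian_pulses"
    freq_hz: float = 1.0
    pulse_centers: tuple = ()           # seconds
    pulse_width: float = 0.01           # seconds
    taper: bool = False                 # Gaussian spatial taper instead of flat

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("patch radius must be positive")
        if self.waveform == "gaussian_pulses" and self.pulse_width <= 0:
            raise ValueError("pulse width must be positive")
        if self.waveform not in ("cosine", "gaussian_pulses"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass
class NoiseSpec:
    snr_db: float = 6.0
    ar_peak_band: tuple = (8.0, 12.0)
    source_sensor_split: float = 0.5
    ar_pole_radius: float = 0.97
    source_fraction: float = 0.1        # fraction of generators carrying AR noise
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.source_sensor_split <= 1.0:
            raise ValueError("source/sensor split must lie in [0, 1]")


@dataclass
class SimulationConfig:
    S: int = 300
    N: int = 32
    T: int = 101
    fs: float = 200.0
    patches: list = None                # list[PatchSpec]; None -> default preset
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    leadfield_model: str = "sphere"     # "sphere" | "smooth_random"
    crime_avoidance_jitter: float = 5.0  # mm
    n_trials: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


# ---------------------------------------------------------------------------
# Geometry and forward model
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, hemisphere: bool = False) -> np.ndarray:
    """Quasi-uniform unit directions from the golden-angle spiral."""
    i = np.arange(n) + 0.5
    z = 1.0 - i / n if hemisphere else 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _knn_adjacency(positions: np.ndarray, k: int = 6) -> np.ndarray:
    tree = cKDTree(positions)
    _, idx = tree.query(positions, k=k + 1)
    n = positions.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    adj[rows, idx[:, 1:].ravel()] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    return adj


def make_source_space(kind: str = "sphere_surface", S: int = 300,
                      seed: int = 0) -> SourceSpace:
    """Quasi-uniform generators on an 80 mm sphere surface or a 3-D grid,
    with symmetric 6-nearest-neighbour adjacency.  Deterministic in seed."""
    if S < 10:
        raise ValueError("need at least 10 generators")
    rng = np.random.default_rng(seed)
    if kind == "sphere_surface":
        pts = _fibonacci_sphere(S) @ _random_rotation(rng).T
        positions = SOURCE_RADIUS_MM * pts
    elif kind == "grid":
        side = int(np.ceil((2 * S) ** (1 / 3))) + 2
        axis = np.linspace(-SOURCE_RADIUS_MM, SOURCE_RADIUS_MM, side)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= SOURCE_RADIUS_MM]
        if pts.shape[0] < S:
            raise ValueError("grid too coarse for requested S")
        order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
        positions = pts[order[:S]] @ _random_rotation(rng).T
    else:
        raise ValueError(f"unknown source-space kind {kind!r}")
    return SourceSpace(positions=positions, adjacency=_knn_adjacency(positions))


def make_sensor_positions(n_sensors: int, seed: int = 0) -> np.ndarray:
    """Scalp electrodes: quasi-uniform points on the upper 100 mm hemisphere."""
    rng = np.random.default_rng(seed)
    pts = _fibonacci_sphere(n_sensors, hemisphere=True)
    angle = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(angle), -np.sin(angle), 0],
                    [np.sin(angle), np.cos(angle), 0], [0, 0, 1]])
    return SCALP_RADIUS_MM * pts @ rot.T


def _sphere_potential(sensor_pos: np.ndarray, gen_pos: np.ndarray) -> np.ndarray:
    """Surface potential of unit radial dipoles in a homogeneous sphere.

    Closed form of the Legendre series ``sum (2n+1) x^{n-1} P_n(cos)`` for a
    radial dipole at fractional depth ``x = b / R``.
    """
    R = np.linalg.norm(sensor_pos, axis=1)[:, None]
    b = np.linalg.norm(gen_pos, axis=1)[None, :]
    x = b / R
    cosang = (sensor_pos @ gen_pos.T) / np.maximum(R * b, 1e-12)
    denom = (1.0 - 2.0 * x * cosang + x ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        series = ((1.0 - x ** 2) / denom - 1.0) / x
    # x -> 0 limit of the bracket is 3 cos(theta)
    series = np.where(x < 1e-9, 3.0 * cosang, series)
    return series / (4.0 * np.pi * R ** 2)


def make_lead_field(space: SourceSpace, n_sensors: int, model: str = "sphere",
                    seed: int = 0) -> LeadField:
    """Analytic-sphere or graph-smoothed random gain matrix.

    Both variants are average-referenced and column-normalized; the
    smoothed-random model diffuses a Gaussian matrix three steps over the
    generator adjacency to mimic the high column correlation of realistic
    operators.
    """
    if n_sensors >= space.n_generators:
        raise ValueError("expect fewer sensors than generators")
    sensors = make_sensor_positions(n_sensors, seed=seed)
    if model == "sphere":
        K = _sphere_potential(sensors, space.positions)
    elif model == "smooth_random":
        rng = np.random.default_rng(seed)
        K = rng.standard_normal((n_sensors, space.n_generators))
        deg = np.maximum(space.adjacency.sum(axis=1), 1)
        P = space.adjacency / deg[:, None]          # row-stochastic
        for _ in range(3):
            K = 0.5 * (K + K @ P.T)
    else:
        raise ValueError(f"unknown lead-field model {model!r}")
    K = K - K.mean(axis=0, keepdims=True)           # average reference
    K = K / np.linalg.norm(K, axis=0, keepdims=True)
    lf = LeadField(K=K, generator_index=space)
    lf.meta = {"model": model, "seed": seed, "sensor_positions": sensors}
    return lf


def perturb_lead_field(K: LeadField, space: SourceSpace, jitter_mm: float = 5.0,
                       seed: int = 0) -> LeadField:
    """Lead field for inversion: rebuilt after jittering every generator and
    sensor position by independent Gaussian offsets (sd ``jitter_mm``)."""
    if jitter_mm < 0:
        raise ValueError("jitter must be nonnegative")
    if jitter_mm == 0:
        return K
    meta = getattr(K, "meta", {})
    model = meta.get("model", "sphere")
    rng = np.random.default_rng(seed)
    gen_pos = space.positions + rng.normal(scale=jitter_mm, size=space.positions.shape)
    if model == "sphere":
        sensors = meta.get("sensor_positions",
                           make_sensor_positions(K.n_sensors, seed=meta.get("seed", 0)))
        sensors = sensors + rng.normal(scale=jitter_mm, size=sensors.shape)
        # keep sensors outside the source ball
        norms = np.linalg.norm(sensors, axis=1, keepdims=True)
        sensors = sensors / norms * np.maximum(norms, SOURCE_RADIUS_MM + 5.0)
        Kp = _sphere_potential(sensors, gen_pos)
    else:
        noise = rng.standard_normal(K.K.shape)
        Kp = K.K + (jitter_mm / SOURCE_RADIUS_MM) * noise
    Kp = Kp - Kp.mean(axis=0, keepdims=True)
    Kp = Kp / np.linalg.norm(Kp, axis=0, keepdims=True)
    lf = LeadField(K=Kp, sensor_labels=list(K.sensor_labels), generator_index=space)
    lf.meta = {**meta, "jitter_mm": jitter_mm, "jitter_seed": seed}
    return lf


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------

def geodesic_distances(space: SourceSpace, centers) -> np.ndarray:
    """Graph-geodesic distances (edge lengths = Euclidean) from each center."""
    src = space.adjacency
    rows, cols = np.nonzero(src)
    w = np.linalg.norm(space.positions[rows] - space.positions[cols], axis=1)
    graph = csr_matrix((w, (rows, cols)), shape=src.shape)
    return dijkstra(graph, indices=np.atleast_1d(centers))


def _pulse_course(times: np.ndarray, centers, width: float) -> np.ndarray:
    course = np.zeros_like(times)
    for c in centers:
        course += np.exp(-0.5 * ((times - c) / width) ** 2)
    course[course < PULSE_ZERO_THRESHOLD * course.max()] = 0.0
    return course


def make_patch_sources(space: SourceSpace, patches, fs: float,
                       T: int) -> SpatioTemporalSource:
    """Assemble the S x T truth from patch specs.

    Patch support is every generator within the geodesic radius of the
    center; within-patch amplitude is constant (or Gaussian-tapered when
    requested).  Gaussian-pulse courses are thresholded so samples below
    0.1 % of their maximum are exactly zero.
    """
    times = np.arange(T) / fs
    J = np.zeros((space.n_generators, T))
    dists = geodesic_distances(space, [p.center for p in patches])
    for p, d in zip(patches, dists):
        support = d <= p.radius
        if not support.any():
            raise ValueError(f"patch at {p.center} with radius {p.radius} mm is empty")
        if p.waveform == "cosine":
            course = np.cos(2.0 * np.pi * p.freq_hz * times)
        else:
            course = _pulse_course(times, p.pulse_centers, p.pulse_width)
        weight = np.exp(-0.5 * (d[support] / (p.radius / 2.0)) ** 2) if p.taper \
            else np.ones(int(support.sum()))
        J[support] += p.amplitude * weight[:, None] * course[None, :]
    return SpatioTemporalSource(J, generator_index=space)


def hemisphere_layouts():
    """The four hemispheric arrangements of the (O, M, TL) patches."""
    return [("L", "L", "L"), ("R", "L", "L"), ("L", "L", "R"), ("R", "L", "R")]


def default_patches(space: SourceSpace, layout=("L", "L", "L"),
                    duration: float = 1.0, seed: int = 0) -> list:
    """Three patches of 30/20/10 mm radius: 1 Hz cosine, 3 Hz cosine and a
    six-pulse train, placed in the requested hemispheres without overlap."""
    rng = np.random.default_rng(seed)
    # (O, M, TL): occipital 30 mm / 1 Hz, motor 10 mm / pulse train,
    # temporal 20 mm / 3 Hz
    radii = (30.0, 10.0, 20.0)
    specs = []
    chosen = []
    pulse_centers = tuple(np.linspace(0.1, 0.9, 6) * duration)
    waves = [dict(waveform="cosine", freq_hz=1.0),
             dict(waveform="gaussian_pulses", pulse_centers=pulse_centers,
                  pulse_width=0.01),
             dict(waveform="cosine", freq_hz=3.0)]
    for side, radius, wave in zip(layout, radii, waves):
        hemi = space.positions[:, 0] < 0 if side == "L" else space.positions[:, 0] >= 0
        # keep centers under the sensor cap (upper half), as on a cortex
        candidates = np.flatnonzero(hemi & (space.positions[:, 2] > 0))
        if candidates.size == 0:
            raise ValueError("empty hemisphere in source space")
        for _ in range(200):
            center = int(rng.choice(candidates))
            if all(np.linalg.norm(space.positions[center] - space.positions[c])
                   > radius + r_prev for c, r_prev in chosen):
                break
        chosen.append((center, radius))
        specs.append(PatchSpec(center=center, radius=radius, **wave))
    return specs


# ---------------------------------------------------------------------------
# Noise and trials
# ---------------------------------------------------------------------------

def _ar_alpha_noise(n_series: int, T: int, fs: float, spec: NoiseSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """AR(2) processes with poles at the requested radius and an angular
    frequency in the middle of the alpha band."""
    f0 = 0.5 * (spec.ar_peak_band[0] + spec.ar_peak_band[1])
    theta = 2.0 * np.pi * f0 / fs
    r = spec.ar_pole_radius
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    burn = 200
    w = rng.standard_normal((n_series, T + burn))
    x = sps.lfilter([1.0], a, w, axis=1)
    return x[:, burn:]


def simulate_trial(config: SimulationConfig, trial_seed: int,
                   assets: dict | None = None):
    """One trial: returns ``(EEGRecording, truth, lead field for inversion)``.

    ``V = K (J + eta_src) + eta_sens`` with the combined noise rescaled so
    the realized SNR matches ``noise.snr_db`` exactly; ``eta_src`` is
    alpha-band AR(2) noise on a random generator subset.  ``assets`` may
    carry precomputed geometry (see :func:`simulate_study`).
    """
    if assets is None:
        assets = build_assets(config)
    space: SourceSpace = assets["space"]
    K: LeadField = assets["leadfield"]
    truth: SpatioTemporalSource = assets["truth"]
    K_inv: LeadField = assets["leadfield_inv"]

    clean = K.K @ truth.J
    sig_power = float(np.sum(clean ** 2))
    snr = config.noise.snr_db
    if np.isinf(snr):
        V = clean
    else:
        if sig_power == 0:
            raise ValueError("zero-signal truth with a finite SNR request")
        rng = np.random.default_rng(trial_seed)
        n_noisy = max(2, int(round(config.noise.source_fraction * config.S)))
        subset = rng.choice(config.S, size=n_noisy, replace=False)
        eta_src = np.zeros((config.S, config.T))
        eta_src[subset] = _ar_alpha_noise(n_noisy, config.T, config.fs,
                                          config.noise, rng)
        eta_sens = rng.standard_normal((config.N, config.T))
        target = sig_power / 10.0 ** (snr / 10.0)
        src_at_sensors = K.K @ eta_src
        split = config.noise.source_sensor_split
        c_src = np.sqrt(split * target / max(np.sum(src_at_sensors ** 2), 1e-300))
        c_sen = np.sqrt((1.0 - split) * target / max(np.sum(eta_sens ** 2), 1e-300))
        noise = c_src * src_at_sensors + c_sen * eta_sens
        noise *= np.sqrt(target / np.sum(noise ** 2))
        V = clean + noise
    rec = EEGRecording(V=V, fs=config.fs)
    return rec, truth, K_inv


def build_assets(config: SimulationConfig, layout=("L", "L", "L")) -> dict:
    """Geometry, forward operators and the truth shared by all trials."""
    space = make_source_space("sphere_surface", config.S, seed=config.seed)
    K = make_lead_field(space, config.N, model=config.leadfield_model,
                        seed=config.seed)
    patches = config.patches or default_patches(
        space, layout=layout, duration=(config.T - 1) / config.fs,
        seed=config.seed)
    truth = make_patch_sources(space, patches, config.fs, config.T)
    K_inv = perturb_lead_field(K, space, config.crime_avoidance_jitter,
                               seed=config.seed + 7919)
    return {"space": space, "leadfield": K, "truth": truth,
            "leadfield_inv": K_inv, "patches": patches}


def simulate_study(config: SimulationConfig, n_trials: int | None = None,
                   out_dir: str | Path = "study",
                   configurations=None) -> dict:
    """Write ``n_trials x len(configurations)`` trials to an archive directory.

    Each trial is a named-array container (``.npz``) holding K, K_inv, V, J,
    positions, adjacency, the trial seed and a JSON echo of the config; the
    manifest ties them together.  Fully reproducible from ``config.seed``.
    """
    n_trials = config.n_trials if n_trials is None else n_trials
    configurations = configurations or hemisphere_layouts()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "n_trials": n_trials,
                "configurations": ["".join(c) for c in configurations],
                "trials": []}
    for ci, layout in enumerate(configurations):
        assets = build_assets(config, layout=layout)
        for trial in range(n_trials):
            trial_seed = config.seed + 1000 * (ci + 1) + trial
            rec, truth, K_inv = simulate_trial(config, trial_seed, assets=assets)
            name = f"trial_c{ci}_t{trial:03d}.npz"
            np.savez(out_dir / name,
                     K=assets["leadfield"].K, K_inv=K_inv.K, V=rec.V,
                     J=truth.J, positions=assets["space"].positions,
                     adjacency=assets["space"].adjacency,
                     seed=np.array(trial_seed), fs=np.array(config.fs),
                     config=np.array(json.dumps(_config_echo(config))))
            manifest["trials"].append({"file": name, "configuration": ci,
                                       "trial": trial, "seed": trial_seed})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _config_echo(config: SimulationConfig) -> dict:
    d = asdict(config)
    d.pop("patches", None)
    return d
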