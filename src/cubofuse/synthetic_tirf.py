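"""Seeded synthetic TIRF movies of nanoparticle fusion into a bilayer.

Real TIRF stacks of cubosome–bilayer fusion consist of a fluorescent
supported-lipid-bilayer background (optionally with dark lipid domains or
brighter double-layer patches), dye-loaded particles performing 2-D
Brownian motion near the surface, and landing events after which the
particle's peak intensity decays as a power law while its footprint
spreads.  This module renders exactly that statistical structure, with
EMCCD-style Poisson + Gaussian camera noise applied last, so that every
downstream stage (detection, linking, MSD, event segmentation, power-law
fitting) can be validated against known ground truth without any
microscope data.

Conventions: pixel-centred coordinates, origin at the top-left pixel
centre, x = column index; physical positions in micrometres; default
calibration 0.16 um per pixel and 0.03 s per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PIXEL_SIZE = 0.16  # um / px
DEFAULT_FRAME_INTERVAL = 0.03  # s
DEFAULT_PSF_SIGMA_PX = 1.3  # ~diffraction-limited spot at 0.16 um/px


@dataclass(frozen=True)
class ScenePrescription:
    """Static description of a synthetic movie.

    ``bilayer_pattern`` is a per-pixel multiplier of ``background_level``:
    1.0 for a single bilayer, 2.0 inside a stacked double-layer patch and
    values below 1 for dark (e.g. DOPS-rich) domains.  ``noise`` is an
    EMCCD-style ``(poisson_gain, read_sigma)`` pair; set it to ``None``
    for noiseless rendering.  Identical (prescription, seed) pairs render
    bit-identical movies.
    """

    shape: tuple[int, int] = (128, 128)
    n_frames: int = 200
    pixel_size: float = DEFAULT_PIXEL_SIZE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    background_level: float = 100.0
    bilayer_pattern: np.ndarray | None = None
    noise: tuple[float, float] | None = (1.0, 2.0)
    psf_sigma_px: float = DEFAULT_PSF_SIGMA_PX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.bilayer_pattern is not None:
            pat = np.asarray(self.bilayer_pattern, dtype=float)
            if pat.shape != tuple(self.shape):
                raise ValueError("bilayer_pattern shape must match frame shape")
            if np.any(pat < 0):
                raise ValueError("bilayer multipliers must be non-negative")
            object.__setattr__(self, "bilayer_pattern", pat)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def background(self) -> np.ndarray:
        base = np.full(self.shape, self.background_level, dtype=float)
        if self.bilayer_pattern is not None:
            base *= self.bilayer_pattern
        return base


@dataclass(frozen=True)
class EventPrescription:
    """One particle: Brownian approach, docking, dwell, power-law fusion.

    After fusion starts (landing + dwell) the peak intensity above local
    background follows ``I(tau) = a * ((tau + t_off) / t_off)**(-n)`` and
    the spot sigma grows as ``sqrt(psf_sigma^2 + (footprint_growth *
    sqrt(tau) / pixel_size)^2)``.  ``landing_time=None`` renders a particle
    that diffuses for the whole movie without landing.
    """

    position: tuple[float, float]  # (x_um, y_um) docking position
    landing_time: float | None = 0.5  # s
    pre_landing_D: float = 2.0  # um^2/s
    a: float = 100.0  # peak counts above background
    n: float = 1.0 / 6.0
    t_off: float = DEFAULT_FRAME_INTERVAL  # s
    footprint_growth: float = 0.3  # um s^-1/2
    dwell: float = 0.3  # s

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("exponent n must be non-negative")
        if self.t_off <= 0:
            raise ValueError("t_off must be positive (t = 0 singularity)")
        if self.dwell < 0 or self.pre_landing_D < 0:
            raise ValueError("dwell and pre_landing_D must be non-negative")

    def intensity(self, tau) -> np.ndarray:
        """Peak intensity above background, tau = time since fusion start."""
        tau = np.asarray(tau, dtype=float)
        return self.a * ((tau + self.t_off) / self.t_off) ** (-self.n)


def brownian_path(D: float, n_steps: int, frame_interval: float,
                  seed_or_rng, start=(0.0, 0.0)) -> np.ndarray:
    """2-D Brownian trajectory: per-step variance 2*D*dt on each axis.

    Returns an ``(n_steps, 2)`` array of (x, y) positions in um, the first
    row being ``start``.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    steps = rng.normal(0.0, np.sqrt(2.0 * D * frame_interval), size=(n_steps - 1, 2))
    path = np.empty((n_steps, 2))
    path[0] = start
    np.cumsum(steps, axis=0, out=path[1:])
    path[1:] += start
    return path


def apply_camera_noise(frame: np.ndarray, gain: float, read_sigma: float,
                       seed_or_rng) -> np.ndarray:
    """Poisson shot noise on the gain-scaled signal plus Gaussian read noise.

    The mean over many realizations equals the noiseless frame; output is
    clipped at zero counts.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if read_sigma < 0:
        raise ValueError("read_sigma must be non-negative")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    out = rng.poisson(np.clip(frame, 0, None) * gain).astype(float) / gain
    if read_sigma > 0:
        out += rng.normal(0.0, read_sigma, size=frame.shape)
    return np.clip(out, 0.0, None)


def sample_size_distribution(mean_nm: float, sigma_log: float, n: int,
                             seed_or_rng) -> np.ndarray:
    """Lognormal particle diameters with the requested arithmetic mean.

    Matches the skewed ~200 nm hydrodynamic size distributions typical of
    cubosome dispersions; sizes modulate per-event amplitude (~ size) and
    pre-landing diffusivity (~ 1/size) in ensemble generation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    if sigma_log == 0:
        return np.full(n, float(mean_nm))
    mu = np.log(mean_nm) - 0.5 * sigma_log**2  # E[lognormal] = exp(mu + s^2/2)
    return rng.lognormal(mu, sigma_log, size=n)


def _add_gaussian_spot(frame: np.ndarray, x_px: float, y_px: float,
                       amplitude: float, sigma_px: float) -> None:
    """Accumulate a peak-normalized Gaussian spot onto ``frame`` in place."""
    ny, nx = frame.shape
    r = max(4, int(np.ceil(4.0 * sigma_px)))
    x0, y0 = int(round(x_px)), int(round(y_px))
    xs = slice(max(0, x0 - r), min(nx, x0 + r + 1))
    ys = slice(max(0, y0 - r), min(ny, y0 + r + 1))
    if xs.start >= xs.stop or ys.start >= ys.stop:
        return
    xg = np.arange(xs.start, xs.stop) - x_px
    yg = np.arange(ys.start, ys.stop) - y_px
    frame[ys, xs] += amplitude * np.exp(
        -(yg[:, None] ** 2 + xg[None, :] ** 2) / (2.0 * sigma_px**2))


def render_movie(scene: ScenePrescription, events: list[EventPrescription],
                 noiseless: bool = False, conserve_signal: bool = False,
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a movie and its ground-truth table.

    Each event draws (i) a diffusing diffraction-limited spot before
    landing, (ii) a static spot during the dwell, and (iii) a spreading
    spot whose peak follows the event's power law after fusion starts.
    With ``conserve_signal=True`` the amplitude is instead scaled so the
    frame-integrated fluorescence of the event stays constant as the
    footprint spreads (dye conservation), overriding the power law.

    Returns ``(movie, ground_truth)`` where ``movie`` is a float array of
    shape ``(n_frames, ny, nx)`` and ``ground_truth`` has one row per event
    plus its per-frame true trajectory packed as object columns.
    """
    rng = np.random.default_rng(scene.seed)
    ny, nx = scene.shape
    dt = scene.frame_interval
    background = scene.background()
    movie = np.empty((scene.n_frames, ny, nx), dtype=float)

    # Per-event trajectories, drawn up-front so noise draws stay decoupled.
    trajectories: list[np.ndarray] = []
    rows = []
    for eid, ev in enumerate(events):
        x_um, y_um = ev.position
        if not (0 <= x_um / scene.pixel_size < nx and 0 <= y_um / scene.pixel_size < ny):
            warnings.warn(f"event {eid} outside the field of view; clipped")
        if ev.landing_time is None:
            land_frame = scene.n_frames  # never lands
        else:
            if ev.landing_time + ev.dwell > scene.duration:
                raise ValueError(
                    f"event {eid}: landing + dwell exceeds movie duration")
            land_frame = int(round(ev.landing_time / dt))
        # Brownian approach generated backwards from the docking point
        # (Brownian motion is time-reversible, so statistics are unchanged).
        n_pre = max(land_frame, 0)
        if n_pre > 0:
            back = brownian_path(ev.pre_landing_D, n_pre + 1, dt, rng,
                                 start=(x_um, y_um))
            pre = back[::-1][:-1]  # positions for frames 0..land_frame-1
        else:
            pre = np.empty((0, 2))
        traj = np.empty((scene.n_frames, 2))
        traj[:n_pre] = pre[:scene.n_frames]
        traj[n_pre:] = (x_um, y_um)
        trajectories.append(traj)
        fusion_start = (None if ev.landing_time is None
                        else ev.landing_time + ev.dwell)
        rows.append({
            "event_id": eid, "x_um": x_um, "y_um": y_um,
            "landing_time_s": ev.landing_time, "dwell_s": ev.dwell,
            "fusion_start_s": fusion_start,
            "a": ev.a, "n": ev.n, "t_off": ev.t_off,
            "footprint_growth": ev.footprint_growth,
            "pre_landing_D": ev.pre_landing_D,
            "trajectory": traj,
        })

    for f in range(scene.n_frames):
        t = f * dt
        frame = background.copy()
        for ev, traj in zip(events, trajectories):
            x_px = traj[f, 0] / scene.pixel_size
            y_px = traj[f, 1] / scene.pixel_size
            fusion_start = (np.inf if ev.landing_time is None
                            else ev.landing_time + ev.dwell)
            if t < fusion_start:  # approach or dwell: diffraction-limited
                amp, sigma = ev.a, scene.psf_sigma_px
            else:
                tau = t - fusion_start
                sigma = np.hypot(scene.psf_sigma_px,
                                 ev.footprint_growth * np.sqrt(tau) / scene.pixel_size)
                if conserve_signal:
                    amp = ev.a * scene.psf_sigma_px**2 / sigma**2
                else:
                    amp = float(ev.intensity(tau))
            _add_gaussian_spot(frame, x_px, y_px, amp, sigma)
        if scene.noise is not None and not noiseless:
            gain, read_sigma = scene.noise
            frame = apply_camera_noise(frame, gain, read_sigma, rng)
        movie[f] = frame

    return movie, pd.DataFrame(rows)


def fusion_event_ensemble(
    n_events: int,
    seed: int,
    n: float = 1.0 / 6.0,
    mean_size_nm: float = 200.0,
    sigma_log: float = 0.3,
    snr: float = 10.0,
    shape: tuple[int, int] = (256, 256),
    n_frames: int = 320,
    events_per_movie: int = 20,
    background_level: float = 100.0,
    read_sigma: float = 2.0,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> list[tuple[ScenePrescription, list[EventPrescription], np.ndarray, pd.DataFrame]]:
    """Render an ensemble of fusion movies with size-modulated amplitudes.

    Particle diameters are lognormal (arithmetic mean ``mean_size_nm``);
    each event's amplitude scales with its size, its pre-landing
    diffusivity with 1/size (Stokes–Einstein), and its decay follows the
    finite-source law with exponent ``n``.  ``snr`` sets the mean amplitude
    relative to the background shot-noise sigma.  Events are laid out on a
    jittered grid so footprints stay well separated.

    Returns a list of ``(scene, events, movie, ground_truth)`` tuples.
    """
    master = np.random.default_rng(seed)
    sizes = sample_size_distribution(mean_size_nm, sigma_log, n_events, master)
    noise_sigma = np.sqrt(background_level + read_sigma**2)
    mean_amp = snr * noise_sigma
    from .particle_tracking import stokes_einstein_diameter_inverse

    out = []
    ny, nx = shape
    pixel_size = DEFAULT_PIXEL_SIZE
    # grid layout: margin + spacing chosen so grown footprints never overlap
    cols = 5
    rows_per_movie = int(np.ceil(events_per_movie / cols))
    dx_um = nx * pixel_size / cols
    dy_um = ny * pixel_size / rows_per_movie
    n_movies = int(np.ceil(n_events / events_per_movie))
    for m in range(n_movies):
        idx = np.arange(m * events_per_movie, min((m + 1) * events_per_movie, n_events))
        movie_seed = int(master.integers(0, 2**31 - 1))
        jitter_rng = np.random.default_rng(movie_seed + 1)
        events = []
        for j, i in enumerate(idx):
            size = sizes[i]
            gx = (j % cols + 0.5) * dx_um
            gy = (j // cols + 0.5) * dy_um
            pos = (gx + jitter_rng.uniform(-1, 1), gy + jitter_rng.uniform(-1, 1))
            events.append(EventPrescription(
                position=pos,
                landing_time=float(jitter_rng.uniform(0.3, 1.5)),
                pre_landing_D=stokes_einstein_diameter_inverse(size),
                a=mean_amp * size / mean_size_nm,
                n=n,
                t_off=frame_interval,
                dwell=float(jitter_rng.uniform(0.2, 0.6)),
            ))
        scene = ScenePrescription(
            shape=shape, n_frames=n_frames, pixel_size=pixel_size,
            frame_interval=frame_interval, background_level=background_level,
            noise=(1.0, read_sigma), seed=movie_seed)
        movie, gt = render_movie(scene, events)
        gt["size_nm"] = sizes[idx]
        out.append((scene, events, movie, gt))
    return out
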