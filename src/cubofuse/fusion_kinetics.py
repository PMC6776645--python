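"""Fusion-event segmentation, intensity traces, power-law fits, summaries.

A fusion event is the signature sequence seen in single-particle TIRF:
a tracked particle docks (becomes immobile), its peak intensity rises to a
maximum, then decays towards the bilayer background.  The decay is fitted
as ``I = a * t**(-n)`` in log-log space; the finite-source lipid-diffusion
model predicts n = 1/6 for whole-particle fusion against n = 1 for a 2-D
point source of dye.  The fusion time is the interval from the intensity
peak until the trace returns to background (within k sigma, sustained).

Time convention: trace times are measured from the peak frame, with the
peak frame itself assigned one frame interval (avoids log 0).  Under this
convention a rendered decay with time offset equal to the frame interval is
an exact power law in trace time, and the fitted amplitude is on the
absolute-seconds scale (counts at t = 1 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IntensityTrace:
    """Background-corrected peak-intensity time series of one event."""

    times: np.ndarray  # s since fusion start, strictly increasing, > 0
    intensity: np.ndarray  # counts above background
    background: float  # counts
    background_sigma: float  # counts
    contaminated: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.times) and (np.any(self.times <= 0)
                                or np.any(np.diff(self.times) <= 0)):
            raise ValueError("trace times must be strictly increasing and > 0")
        if self.background_sigma < 0:
            raise ValueError("background sigma must be non-negative")


@dataclass
class PowerLawFit:
    """Least-squares fit of I = a * t**(-n) in log-log space."""

    a: float  # counts at t = 1 s
    n: float
    r_squared: float  # in log-log space
    window: tuple[float, float]  # (t_min, t_max) of points used, s
    n_points: int


@dataclass
class FusionEvent:
    """One docking/fusion episode of a tracked particle."""

    position: tuple[float, float]  # um
    landing_time: float  # s (docking)
    fusion_start: float  # s (intensity peak)
    dwell: float  # s, fusion_start - landing_time
    peak_frame: int
    landing_frame: int
    end_frame: int
    track_id: int | None = None
    condition: str = ""
    trace: IntensityTrace | None = None
    fit: PowerLawFit | None = None
    fusion_time: float | None = None
    fusion_time_from_landing: float | None = None
    censored: bool | None = None


def _decay_onset(series: np.ndarray, sigma: float, window: int = 5) -> int:
    """Index where a plateau-then-decay series starts decaying.

    The raw argmax of a noisy trace lands anywhere on the docked plateau
    (the pre-fusion intensity is as high as the decay start), which shifts
    the fitted time origin.  Instead the series is boxcar-smoothed and the
    onset taken as the last frame still within one smoothed-noise sigma of
    the plateau maximum, corrected for the smoothing half-width.
    """
    series = np.asarray(series, dtype=float)
    if len(series) <= window:
        return int(np.argmax(series))
    sm = np.convolve(series, np.ones(window) / window, mode="same")
    half = window // 2
    core = sm[half:len(sm) - half]  # edge windows are padded with zeros
    m = core.max()
    # the plateau maximum is the max of ~10 smoothed noisy samples and so
    # sits ~1.5 smoothed-sigma above the plateau mean; the band must cover
    # that inflation or the onset fires early, mid-plateau
    band = max(1.5 * sigma / np.sqrt(window), 1e-9)
    cand = np.nonzero(core >= m - band)[0]
    onset = int(cand[-1]) + half + half  # last plateau window + half-width
    return min(onset, len(series) - 1)


def segment_events(tracks: pd.DataFrame, movie: np.ndarray,
                   pixel_size: float, frame_interval: float,
                   immobility_radius_px: float = 1.0,
                   immobility_window: int = 5,
                   min_peak_snr: float = 5.0,
                   condition: str = "") -> list[FusionEvent]:
    """Find docking-then-decay episodes in linked tracks.

    A track docks at the first frame where its positions stay within
    ``immobility_radius_px`` of their local mean over ``immobility_window``
    consecutive frames.  The episode qualifies as a fusion event if the
    movie intensity at the docked pixel subsequently exceeds the local
    pre-docking background by ``min_peak_snr`` sigma and then decreases.
    Dwell is the docking-to-peak interval.  Traces are left unfit.
    """
    n_frames = len(movie)
    events: list[FusionEvent] = []
    global_med = float(np.median(movie[0]))
    global_sigma = 1.4826 * float(np.median(np.abs(movie[0] - global_med)))

    for tid, tr in tracks.groupby("particle", sort=True):
        tr = tr.sort_values("frame")
        frames = tr["frame"].to_numpy()
        xy = tr[["x", "y"]].to_numpy()
        if len(tr) < immobility_window:
            continue
        dock_i = None
        for i in range(len(tr) - immobility_window + 1):
            w = xy[i:i + immobility_window]
            # consecutive frames only; gaps break the immobility window
            if frames[i + immobility_window - 1] - frames[i] != immobility_window - 1:
                continue
            if np.max(np.linalg.norm(w - w.mean(axis=0), axis=1)) < immobility_radius_px:
                dock_i = i
                break
        if dock_i is None:
            continue
        dock_frame = int(frames[dock_i])
        pos_px = xy[dock_i:dock_i + immobility_window].mean(axis=0)
        x0, y0 = int(round(pos_px[0])), int(round(pos_px[1]))
        ny, nx = movie.shape[1:]
        x0, y0 = np.clip(x0, 0, nx - 1), np.clip(y0, 0, ny - 1)

        pixel_series = movie[:, y0, x0]
        # pre-dock background, excluding frames where this particle's own
        # approach passed near the docking pixel (its spot would inflate
        # both the background and its sigma)
        near = set()
        for fr_i, (px, py) in zip(frames, xy):
            if fr_i < dock_frame and np.hypot(px - x0, py - y0) < 4.0:
                near.add(int(fr_i))
        clean = [f for f in range(dock_frame) if f not in near]
        if len(clean) >= 5:
            pre = pixel_series[clean]
            bg = float(np.median(pre))
            sigma = 1.4826 * float(np.median(np.abs(pre - bg)))
        else:
            bg, sigma = global_med, global_sigma
        sigma = max(sigma, 1e-9)

        post = pixel_series[dock_frame:]
        peak_rel = _decay_onset(post, sigma)
        peak_val = float(post[:peak_rel + 1].max())
        if peak_val < bg + min_peak_snr * sigma:
            continue
        tail = post[peak_rel:]
        if len(tail) < 3 or float(np.median(tail[len(tail) // 2:])) >= peak_val:
            continue  # no decay after the peak
        peak_frame = dock_frame + peak_rel
        events.append(FusionEvent(
            position=(float(pos_px[0] * pixel_size), float(pos_px[1] * pixel_size)),
            landing_time=dock_frame * frame_interval,
            fusion_start=peak_frame * frame_interval,
            dwell=(peak_frame - dock_frame) * frame_interval,
            peak_frame=peak_frame,
            landing_frame=dock_frame,
            end_frame=n_frames - 1,
            track_id=int(tid),
            condition=condition,
        ))
    return events


def extract_trace(movie: np.ndarray, event: FusionEvent, pixel_size: float,
                  frame_interval: float, aperture_px: int = 1,
                  background_mode: str = "prelanding",
                  other_events: list[FusionEvent] | None = None,
                  annulus_radii: tuple[int, int] = (6, 10),
                  ) -> IntensityTrace:
    """Background-corrected peak-intensity trace of an event.

    Per frame the intensity is read at the docked pixel (``aperture_px`` =
    radius 0 window) or as the maximum over a ``(2r+1)``-pixel square
    aperture.  ``background_mode``:

    - ``"prelanding"`` — median of the same pixels over frames before
      docking (falls back to annulus with a warning if fewer than 5).
    - ``"annulus"`` — per-frame median of a surrounding annulus
      (``annulus_radii`` beyond the aperture, in px), robust to slow global
      background drift and gradients; the inner radius must stay outside
      the event's grown footprint or its halo inflates the background.

    Traces whose aperture comes within 2 apertures of another concurrent
    event are flagged ``contaminated``.
    """
    ny, nx = movie.shape[1:]
    x0 = int(np.clip(round(event.position[0] / pixel_size), 0, nx - 1))
    y0 = int(np.clip(round(event.position[1] / pixel_size), 0, ny - 1))
    r = max(int(aperture_px) // 2, 0)
    ys = slice(max(0, y0 - r), min(ny, y0 + r + 1))
    xs = slice(max(0, x0 - r), min(nx, x0 + r + 1))

    if background_mode not in ("prelanding", "annulus"):
        raise ValueError("background_mode must be 'prelanding' or 'annulus'")
    mode = background_mode
    if mode == "prelanding" and event.landing_frame < 5:
        warnings.warn("too few pre-landing frames; falling back to annulus "
                      "background")
        mode = "annulus"

    frames = np.arange(event.peak_frame, event.end_frame + 1)
    raw = movie[frames[0]:frames[-1] + 1, ys, xs].max(axis=(1, 2))

    if mode == "prelanding":
        pre = movie[:event.landing_frame, ys, xs]
        bg = float(np.median(pre))
        sigma = 1.4826 * float(np.median(np.abs(pre - bg)))
        bg_per_frame = np.full(len(frames), bg)
    else:
        r_in, r_out = r + annulus_radii[0], r + annulus_radii[1]
        yy, xx = np.mgrid[0:ny, 0:nx]
        dist = np.hypot(yy - y0, xx - x0)
        mask = (dist >= r_in) & (dist <= r_out)
        ann = movie[frames[0]:frames[-1] + 1][:, mask]
        bg_per_frame = np.median(ann, axis=1)
        bg = float(bg_per_frame.mean())
        sigma = 1.4826 * float(np.median(np.abs(ann - bg_per_frame[:, None])))

    contaminated = False
    if other_events:
        for other in other_events:
            if other is event:
                continue
            if not (other.peak_frame > event.end_frame
                    or other.end_frame < event.peak_frame):
                d = np.hypot(other.position[0] - event.position[0],
                             other.position[1] - event.position[1])
                if d < 2 * (2 * r + 1) * pixel_size:
                    contaminated = True
                    break

    # peak frame assigned t = one frame interval
    times = (frames - event.peak_frame + 1) * frame_interval
    return IntensityTrace(times=times, intensity=raw - bg_per_frame,
                          background=bg, background_sigma=sigma,
                          contaminated=contaminated)


def fit_power_law(trace: IntensityTrace, min_points: int = 8,
                  noise_floor_k: float = 1.0,
                  robust: bool = False) -> PowerLawFit:
    """Fit I = a * t**(-n) by ordinary least squares on log I vs log t.

    The fit window is the contiguous run of samples above the noise floor
    (``noise_floor_k`` background sigma) starting at the trace start: once
    the decay reaches the floor, later samples are pure noise, and isolated
    positive excursions among them would flatten the fitted slope.  Fewer
    than ``min_points`` surviving samples refuses the fit.  With
    ``robust=True`` a Theil–Sen slope is used instead of OLS.
    """
    floor = max(noise_floor_k * trace.background_sigma, 0.0)
    below = np.nonzero(trace.intensity <= floor)[0]
    end = below[0] if len(below) else len(trace.intensity)
    t = trace.times[:end]
    I = trace.intensity[:end]
    if len(t) < min_points:
        raise ValueError(
            f"only {len(t)} points above the noise floor; need {min_points}")
    lt, lI = np.log(t), np.log(I)
    if robust:
        from scipy.stats import theilslopes

        slope, intercept, _, _ = theilslopes(lI, lt)
    else:
        slope, intercept = np.polyfit(lt, lI, 1)
    pred = slope * lt + intercept
    ss_tot = ((lI - lI.mean()) ** 2).sum()
    r2 = 1.0 - ((lI - pred) ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(a=float(np.exp(intercept)), n=float(-slope),
                       r_squared=float(r2),
                       window=(float(t[0]), float(t[-1])), n_points=len(t))


def fusion_time(trace: IntensityTrace, k_sigma: float = 2.0,
                sustain_frames: int = 3) -> tuple[float, bool]:
    """Time from the trace peak until intensity returns to background.

    Returns ``(time_s, censored)``: the elapsed time from the peak sample
    to the first window of ``sustain_frames`` samples whose median
    background-corrected intensity is at or below ``k_sigma`` background
    sigma.  The windowed median rejects single-frame noise dips without the
    late bias of requiring every sample below threshold (at the true
    crossing each sample is below with probability ~1/2, so a
    run-of-k rule fires systematically late).  Traces that never resolve
    are censored at the trace end.
    """
    thr = k_sigma * trace.background_sigma
    I = trace.intensity
    k = min(sustain_frames, len(I))
    for i in range(len(I) - k + 1):
        if I[i] <= thr and np.median(I[i:i + k]) <= thr:
            return float(trace.times[i] - trace.times[0]), False
    return float(trace.times[-1] - trace.times[0]), True


def analyze_events(movie: np.ndarray, events: list[FusionEvent],
                   pixel_size: float, frame_interval: float,
                   aperture_px: int = 1, background_mode: str = "prelanding",
                   k_sigma: float = 2.0, min_points: int = 8,
                   ) -> list[FusionEvent]:
    """Extract traces, fit power laws and fusion times for all events.

    Events whose fit is refused (too few points above noise) keep
    ``fit=None`` and are retained, so downstream counts stay honest.
    """
    for ev in events:
        ev.trace = extract_trace(movie, ev, pixel_size, frame_interval,
                                 aperture_px=aperture_px,
                                 background_mode=background_mode,
                                 other_events=events)
        try:
            ev.fit = fit_power_law(ev.trace, min_points=min_points)
        except ValueError:
            ev.fit = None
        ft, censored = fusion_time(ev.trace, k_sigma=k_sigma)
        ev.fusion_time = ft
        ev.censored = censored
        ev.fusion_time_from_landing = ft + ev.dwell
    return events


def analyze_movie(movie: np.ndarray, pixel_size: float, frame_interval: float,
                  detection: dict | None = None, linking: dict | None = None,
                  segmentation: dict | None = None, fitting: dict | None = None,
                  condition: str = "") -> list[FusionEvent]:
    """Full pipeline on one movie: detect, link, segment, extract, fit."""
    from . import particle_tracking as pt

    spots = pt.detect_movie(movie, **(detection or {}))
    tracks = pt.link_tracks(spots, **(linking or {}))
    events = segment_events(tracks, movie, pixel_size, frame_interval,
                            condition=condition, **(segmentation or {}))
    return analyze_events(movie, events, pixel_size, frame_interval,
                          **(fitting or {}))


def events_to_frame(events: list[FusionEvent]) -> pd.DataFrame:
    """Flatten events to the export table schema."""
    rows = []
    for i, ev in enumerate(events):
        rows.append({
            "event_id": i,
            "condition": ev.condition,
            "track_id": ev.track_id,
            "x_um": ev.position[0],
            "y_um": ev.position[1],
            "t_land_s": ev.landing_time,
            "dwell_s": ev.dwell,
            "fusion_time_s": ev.fusion_time,
            "fusion_time_from_landing_s": ev.fusion_time_from_landing,
            "a": ev.fit.a if ev.fit else np.nan,
            "n": ev.fit.n if ev.fit else np.nan,
            "r2": ev.fit.r_squared if ev.fit else np.nan,
            "censored": ev.censored,
        })
    return pd.DataFrame(rows)


@dataclass
class ConditionSummary:
    """Per-condition distribution summary of fusion times and exponents."""

    condition: str
    n_events: int
    fusion_times: np.ndarray
    exponents: np.ndarray
    mean_fusion_time: float
    median_fusion_time: float
    iqr_fusion_time: tuple[float, float]
    mean_n: float
    median_n: float
    iqr_n: tuple[float, float]
    fusion_time_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    n_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_events": self.n_events,
            "mean_fusion_time_s": self.mean_fusion_time,
            "median_fusion_time_s": self.median_fusion_time,
            "iqr_fusion_time_s": list(self.iqr_fusion_time),
            "mean_n": self.mean_n,
            "median_n": self.median_n,
            "iqr_n": list(self.iqr_n),
        }


def aggregate(events: list[FusionEvent] | pd.DataFrame,
              bins: int = 30) -> list[ConditionSummary]:
    """Group events by condition label and summarize their distributions."""
    table = events_to_frame(events) if not isinstance(events, pd.DataFrame) else events
    out = []
    for cond, grp in table.groupby("condition", sort=True, dropna=False):
        ft = grp["fusion_time_s"].dropna().to_numpy()
        ns = grp["n"].dropna().to_numpy()
        out.append(ConditionSummary(
            condition=str(cond),
            n_events=len(grp),
            fusion_times=ft,
            exponents=ns,
            mean_fusion_time=float(np.mean(ft)) if len(ft) else np.nan,
            median_fusion_time=float(np.median(ft)) if len(ft) else np.nan,
            iqr_fusion_time=tuple(np.percentile(ft, [25, 75])) if len(ft) else (np.nan, np.nan),
            mean_n=float(np.mean(ns)) if len(ns) else np.nan,
            median_n=float(np.median(ns)) if len(ns) else np.nan,
            iqr_n=tuple(np.percentile(ns, [25, 75])) if len(ns) else (np.nan, np.nan),
            fusion_time_hist=np.histogram(ft, bins=bins) if len(ft) else None,
            n_hist=np.histogram(ns, bins=bins) if len(ns) else None,
        ))
    return out


def plot_fusion_scatter(table: pd.DataFrame, ax=None):
    """Fusion time vs fitted exponent, with n = 1/6 and n = 1 reference lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond, grp in table.groupby("condition", dropna=False):
        ax.scatter(grp["fusion_time_s"], grp["n"], s=12, alpha=0.6,
                   label=str(cond))
    ax.axhline(1.0 / 6.0, ls="--", color="k", label="finite-source n = 1/6")
    ax.axhline(1.0, ls="-", color="r", label="2-D point source n = 1")
    ax.set_xlabel("fusion time (s)")
    ax.set_ylabel("fitted exponent n")
    ax.legend(fontsize=7)
    return ax
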