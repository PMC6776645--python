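"""Spot detection, trajectory linking, MSD and Stokes–Einstein sizing.

Detection follows the classic Crocker–Grier recipe: spatial bandpass
(difference of Gaussians), local-maxima picking with an exclusion radius,
and intensity-weighted centroid refinement for sub-pixel localization.
Linking is frame-to-frame optimal assignment (Hungarian algorithm) with a
displacement gate and gap memory, which preserves identities through
crossings and short disappearances and is fully deterministic.

Track tables use trackpy-style columns: ``frame``, ``x``, ``y`` (pixels),
``mass``, ``peak`` and ``particle``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

BOLTZMANN = 1.380649e-23  # J / K


def detect_spots(frame: np.ndarray, diameter_px: int = 7,
                 min_mass: float = 0.0, threshold: float | None = None,
                 noise_sigma_px: float = 1.0) -> pd.DataFrame:
    """Detect diffraction-limited spots in a single frame.

    Parameters
    ----------
    frame : 2-D array
        Raw image (counts).
    diameter_px : int, odd
        Approximate spot diameter; sets the bandpass long-wavelength cutoff
        and the local-maxima exclusion radius (no two detections closer
        than ``diameter_px // 2``).
    min_mass : float
        Minimum integrated bandpassed intensity of a detection.
    threshold : float, optional
        Absolute peak threshold on the bandpassed image.  Defaults to five
        robust standard deviations (MAD-based) of the bandpassed frame.

    Returns a DataFrame with sub-pixel ``x``, ``y`` (pixels), ``mass``
    (integrated bandpassed counts) and ``peak`` (raw counts at the maximum).
    """
    if diameter_px < 3 or diameter_px % 2 == 0:
        raise ValueError("diameter_px must be odd and >= 3")
    frame = np.asarray(frame, dtype=float)
    if frame.size and frame.max() >= 65535:
        warnings.warn("frame contains saturated (>= 16-bit full-well) pixels")

    bp = gaussian_filter(frame, noise_sigma_px) - gaussian_filter(frame, diameter_px)
    if threshold is None:
        mad = np.median(np.abs(bp - np.median(bp)))
        threshold = 5.0 * 1.4826 * mad
    radius = diameter_px // 2
    coords = peak_local_max(bp, min_distance=radius,
                            threshold_abs=max(threshold, 1e-12))

    rows = []
    ny, nx = frame.shape
    for y0, x0 in coords:
        # centroid refinement with re-centering: a window centred off the
        # true peak truncates the spot asymmetrically and biases the centroid
        yc, xc = float(y0), float(x0)
        mass = 0.0
        for _ in range(3):
            ys = slice(max(0, int(round(yc)) - radius),
                       min(ny, int(round(yc)) + radius + 1))
            xs = slice(max(0, int(round(xc)) - radius),
                       min(nx, int(round(xc)) + radius + 1))
            win = np.clip(bp[ys, xs], 0.0, None)
            mass = win.sum()
            if mass <= 1e-12:
                break
            yg, xg = np.mgrid[ys, xs]
            x_new = float((win * xg).sum() / mass)
            y_new = float((win * yg).sum() / mass)
            moved = abs(round(x_new) - round(xc)) + abs(round(y_new) - round(yc))
            xc, yc = x_new, y_new
            if moved == 0:
                break
        if mass < max(min_mass, 1e-12):
            continue
        rows.append({
            "x": xc,
            "y": yc,
            "mass": float(mass),
            "peak": float(frame[y0, x0]),
        })
    return pd.DataFrame(rows, columns=["x", "y", "mass", "peak"]).astype(float)


def detect_movie(movie: np.ndarray, **kwargs) -> pd.DataFrame:
    """Run :func:`detect_spots` on every frame; adds a ``frame`` column."""
    frames = []
    for f, img in enumerate(movie):
        df = detect_spots(img, **kwargs)
        df.insert(0, "frame", f)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def link_tracks(spots: pd.DataFrame, max_disp_px: float = 5.0,
                memory_frames: int = 2, max_candidates: int = 2000) -> pd.DataFrame:
    """Link per-frame detections into trajectories.

    Frame-by-frame globally optimal assignment on squared displacement,
    gated at ``max_disp_px``; a track missing for up to ``memory_frames``
    consecutive frames may be resumed.  Deterministic: ties are broken by
    the assignment solver's fixed ordering.

    Returns the input rows with an integer ``particle`` column.
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be positive")
    spots = spots.sort_values(["frame", "x", "y"], kind="stable").reset_index(drop=True)
    particle = np.full(len(spots), -1, dtype=int)
    next_id = 0
    # active tracks: list of dicts(id, x, y, last_frame)
    active: list[dict] = []
    big = 1e12
    for f, group in spots.groupby("frame", sort=True):
        idx = group.index.to_numpy()
        pts = group[["x", "y"]].to_numpy()
        active = [a for a in active if f - a["last_frame"] <= memory_frames + 1]
        if active and len(pts):
            if len(active) * len(pts) > max_candidates**2:
                raise RuntimeError(
                    "linking candidate matrix too large; reduce max_disp_px "
                    "or detection density")
            apos = np.array([[a["x"], a["y"]] for a in active])
            d2 = ((apos[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            cost = np.where(d2 <= max_disp_px**2, d2, big)
            rows, cols = linear_sum_assignment(cost)
            assigned_cols = set()
            for r, c in zip(rows, cols):
                if cost[r, c] >= big:
                    continue
                a = active[r]
                particle[idx[c]] = a["id"]
                a["x"], a["y"], a["last_frame"] = pts[c, 0], pts[c, 1], f
                assigned_cols.add(c)
        else:
            assigned_cols = set()
        for c in range(len(pts)):
            if c not in assigned_cols:
                particle[idx[c]] = next_id
                active.append({"id": next_id, "x": pts[c, 0], "y": pts[c, 1],
                               "last_frame": f})
                next_id += 1
    out = spots.copy()
    out["particle"] = particle
    return out


@dataclass
class MSDResult:
    """Time-averaged MSD and its Brownian fit for one track."""

    lag_times: np.ndarray  # s, starting at one frame interval
    msd: np.ndarray  # um^2
    D: float  # um^2/s, slope/4 of the through-origin fit
    fit_max_lag: float  # s
    r_squared: float
    diameter_nm: float
    temperature: float = 298.0
    viscosity: float = 0.89e-3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lag_times, "msd_um2": self.msd})


def compute_msd(track: pd.DataFrame, pixel_size: float,
                frame_interval: float, max_lag_fraction: float = 0.25,
                temperature: float = 298.0,
                viscosity: float = 0.89e-3) -> MSDResult:
    """Time-averaged MSD of one track and the 2-D Brownian fit <r^2> = 4Dt.

    Overlapping displacement pairs are averaged at each lag; the linear fit
    through the origin is restricted to the first ``max_lag_fraction`` of
    available lags (short lags carry the least statistical and confinement
    bias).  Gaps in the track are handled by pairing on frame index.
    """
    if len(track) < 10:
        raise ValueError("track too short for MSD analysis (need >= 10 points)")
    frames = track["frame"].to_numpy()
    pos = track[["x", "y"]].to_numpy() * pixel_size
    span = int(frames.max() - frames.min())
    by_frame = np.full((span + 1, 2), np.nan)
    by_frame[frames - frames.min()] = pos

    max_lag = max(1, int(span * max_lag_fraction))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    n_pairs = np.empty(len(lags))
    for i, lag in enumerate(lags):
        d = by_frame[lag:] - by_frame[:-lag]
        sq = (d**2).sum(axis=1)
        msd[i] = np.nanmean(sq)
        n_pairs[i] = np.isfinite(sq).sum()
    lag_times = lags * frame_interval

    # inverse-variance weighted through-origin fit: for overlapping
    # time-averaged MSD, var(msd_k) ~ (4 D k dt)^2 * k / N ~ k^3, so long
    # lags are strongly down-weighted (they carry almost no independent data)
    ok = np.isfinite(msd) & (n_pairs > 0)
    w = n_pairs[ok] / lags[ok].astype(float) ** 4
    slope = (w * msd[ok] * lag_times[ok]).sum() / (w * lag_times[ok] ** 2).sum()
    # linearity diagnostic: unweighted through-origin regression over the
    # full fit range (its own slope), so curvature at long lags is visible
    slope_u = (msd[ok] * lag_times[ok]).sum() / (lag_times[ok] ** 2).sum()
    ss_res = ((msd[ok] - slope_u * lag_times[ok]) ** 2).sum()
    ss_tot = ((msd[ok] - msd[ok].mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    D = max(slope / 4.0, 0.0)
    diameter = stokes_einstein_diameter(D, temperature, viscosity) if D > 0 else np.inf
    return MSDResult(lag_times=lag_times, msd=msd, D=D,
                     fit_max_lag=float(lag_times[-1]), r_squared=r2,
                     diameter_nm=diameter, temperature=temperature,
                     viscosity=viscosity)


def stokes_einstein_diameter(D: float, temperature: float = 298.0,
                             viscosity: float = 0.89e-3) -> float:
    """Hydrodynamic diameter (nm) from D (um^2/s) via d = kT / (3 pi eta D)."""
    if D <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("D, temperature and viscosity must be positive")
    d_m = BOLTZMANN * temperature / (3.0 * np.pi * viscosity * (D * 1e-12))
    return d_m * 1e9


def stokes_einstein_diameter_inverse(diameter_nm: float,
                                     temperature: float = 298.0,
                                     viscosity: float = 0.89e-3) -> float:
    """Diffusion coefficient (um^2/s) of a sphere of given diameter (nm)."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    D_m2 = BOLTZMANN * temperature / (3.0 * np.pi * viscosity * (diameter_nm * 1e-9))
    return D_m2 * 1e12
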