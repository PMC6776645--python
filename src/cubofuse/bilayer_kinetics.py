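"""Supported-lipid-bilayer formation kinetics from TIRF movies.

During solvent exchange, bilayer domains nucleate on the glass, grow and
merge until a continuous membrane covers the surface.  The per-frame
fraction of covered pixels follows a sigmoid that is well described by an
error-function growth law; the number of distinct domains rises as nuclei
appear, peaks, and falls back to one as the domains coalesce.  A seeded
nucleation-and-growth simulator provides ground truth for both analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf
from skimage.filters import threshold_otsu
from skimage.measure import label


@dataclass
class CoverageCurve:
    """Surface coverage fraction theta(t) of the bilayer."""

    times: np.ndarray  # s
    coverage: np.ndarray  # in [0, 1]
    threshold: float  # counts used to binarize


@dataclass
class ErfGrowthFit:
    """theta(t) = theta_max/2 * (1 + erf((t - t_c) / (sqrt(2) tau)))."""

    theta_max: float
    t_c: float  # midpoint, coincides with the maximum-gradient time
    tau: float  # width, s
    max_slope: float  # theta_max / (sqrt(2 pi) tau), s^-1
    r_squared: float
    flagged: bool = False  # True when the data are not sigmoidal (R^2 < 0.5)

    def __call__(self, t):
        return _erf_model(np.asarray(t, float), self.theta_max, self.t_c, self.tau)

    def gradient(self, t):
        t = np.asarray(t, float)
        return (self.theta_max / (np.sqrt(2 * np.pi) * self.tau)
                * np.exp(-((t - self.t_c) ** 2) / (2 * self.tau**2)))


@dataclass
class DomainCountSeries:
    """Connected-component counts of bilayer domains per frame."""

    times: np.ndarray
    counts: np.ndarray  # non-negative integers
    connectivity: int  # 4 or 8


def coverage_curve(movie: np.ndarray, frame_interval: float,
                   threshold: float | str = "otsu",
                   normalize: bool = True) -> CoverageCurve:
    """Per-frame fraction of pixels above threshold.

    ``threshold='otsu'`` derives a single global threshold from the pooled
    first/middle/last frames; a float fixes it (useful for regression
    tests).  With ``normalize=True`` frames are flat-field corrected by the
    final frame's smoothed illumination profile before thresholding.
    """
    if movie.ndim != 3 or len(movie) == 0:
        raise ValueError("movie must be a non-empty (frames, y, x) stack")
    movie = np.asarray(movie, dtype=float)
    if normalize:
        from scipy.ndimage import gaussian_filter

        flat = gaussian_filter(movie[-1], sigma=max(movie.shape[1] // 8, 1))
        flat = np.clip(flat / max(flat.mean(), 1e-12), 1e-3, None)
        movie = movie / flat
    if threshold == "otsu":
        sample = np.concatenate([movie[0].ravel(), movie[len(movie) // 2].ravel(),
                                 movie[-1].ravel()])
        thr = float(threshold_otsu(sample)) if sample.max() > sample.min() else np.inf
    else:
        thr = float(threshold)
    theta = (movie > thr).mean(axis=(1, 2))
    times = np.arange(len(movie)) * frame_interval
    return CoverageCurve(times=times, coverage=theta, threshold=thr)


def _erf_model(t, theta_max, t_c, tau):
    return theta_max / 2.0 * (1.0 + erf((t - t_c) / (np.sqrt(2.0) * tau)))


def fit_erf_growth(curve: CoverageCurve) -> ErfGrowthFit:
    """Least-squares error-function fit of the coverage sigmoid.

    The fitted gradient is the Gaussian derivative of the erf, peaking at
    ``t_c`` with height ``theta_max / (sqrt(2 pi) tau)``.  Non-sigmoidal
    data (log-space R^2 < 0.5) return a flagged fit rather than an error.
    """
    t, th = curve.times, curve.coverage
    theta0 = max(th.max(), 1e-6)
    above = t[th >= theta0 / 2.0]
    t_c0 = float(above[0]) if len(above) else float(t[len(t) // 2])
    tau0 = max((t[-1] - t[0]) / 10.0, 1e-6)
    popt, _ = curve_fit(_erf_model, t, th, p0=[theta0, t_c0, tau0],
                        bounds=([1e-9, t[0] - (t[-1] - t[0]), 1e-9],
                                [1.0, t[-1] + (t[-1] - t[0]), 10 * (t[-1] - t[0])]),
                        maxfev=20000)
    theta_max, t_c, tau = map(float, popt)
    resid = th - _erf_model(t, *popt)
    ss_tot = ((th - th.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return ErfGrowthFit(theta_max=theta_max, t_c=t_c, tau=tau,
                        max_slope=theta_max / (np.sqrt(2 * np.pi) * tau),
                        r_squared=float(r2), flagged=r2 < 0.5)


def count_domains(frame: np.ndarray, threshold: float,
                  connectivity: int = 8, min_area_px: int = 4) -> int:
    """Number of connected bilayer domains above threshold.

    ``connectivity`` 4 (edge) or 8 (edge+corner); components smaller than
    ``min_area_px`` pixels are treated as shot noise and discarded.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary = np.asarray(frame) > threshold
    lab, n = label(binary, connectivity=1 if connectivity == 4 else 2,
                   return_num=True)
    if min_area_px <= 1:
        return int(n)
    areas = np.bincount(lab.ravel())[1:]
    return int((areas >= min_area_px).sum())


def domain_count_series(movie: np.ndarray, frame_interval: float,
                        threshold: float, connectivity: int = 8,
                        min_area_px: int = 4) -> DomainCountSeries:
    counts = np.array([count_domains(f, threshold, connectivity, min_area_px)
                       for f in movie])
    return DomainCountSeries(times=np.arange(len(movie)) * frame_interval,
                             counts=counts, connectivity=connectivity)


@dataclass
class NucleationGrowthLog:
    """Ground truth of a nucleation-and-growth simulation."""

    nucleations: pd.DataFrame  # t_s, x_um, y_um
    merges: pd.DataFrame  # t_s, i, j — first-contact times of domain pairs


def simulate_nucleation_growth(rate: float, growth_speed: float,
                               shape: tuple[int, int] = (128, 128),
                               pixel_size: float = 0.16,
                               frame_interval: float = 1.0,
                               n_frames: int = 120,
                               seed: int = 0,
                               level: float = 100.0,
                               rough_boundary: float = 0.0,
                               max_nuclei: int | None = None,
                               nucleation_window: float | None = None,
                               ) -> tuple[np.ndarray, NucleationGrowthLog]:
    """Poisson nucleation with radially growing, merging domains.

    Nuclei appear at rate ``rate`` (per second per um^2) uniformly in space;
    each grows as a disk of radius ``growth_speed * (t - t_nuc)``.  Domains
    merge on contact; the log records every nucleation and the geometric
    first-contact time of each domain pair.  ``rough_boundary`` (0..1) adds
    a seeded radial perturbation approximating the fractal domain edges
    seen in real exchange movies.  Frames are ``level`` inside covered
    pixels, 0 outside; the resulting coverage follows an Avrami-type
    (erf-like) sigmoid.
    """
    if rate <= 0 or growth_speed <= 0:
        raise ValueError("rate and growth_speed must be positive")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    area = ny * nx * pixel_size**2
    duration = n_frames * frame_interval

    # nucleation stops after nucleation_window (solvent exchange: the
    # supersaturation pulse passes and new domains cease to appear)
    window = duration if nucleation_window is None else min(nucleation_window,
                                                            duration)
    n_nuclei = rng.poisson(rate * area * window)
    if max_nuclei is not None:
        n_nuclei = min(n_nuclei, max_nuclei)
    t_nuc = np.sort(rng.uniform(0.0, window, n_nuclei))
    xs = rng.uniform(0, nx * pixel_size, n_nuclei)
    ys = rng.uniform(0, ny * pixel_size, n_nuclei)

    # pairwise first-contact: |p_i - p_j| = v (t - t_i) + v (t - t_j);
    # a contact only counts as a merge when the two disks still belong to
    # different clusters (union-find over contacts in time order)
    contacts = []
    for i in range(n_nuclei):
        for j in range(i + 1, n_nuclei):
            d = np.hypot(xs[i] - xs[j], ys[i] - ys[j])
            t_m = (d / growth_speed + t_nuc[i] + t_nuc[j]) / 2.0
            if t_m <= duration and t_m >= max(t_nuc[i], t_nuc[j]):
                contacts.append((t_m, i, j))
    parent = list(range(n_nuclei))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    merges = []
    for t_m, i, j in sorted(contacts):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            merges.append({"t_s": t_m, "i": i, "j": j})

    yy, xx = np.mgrid[0:ny, 0:nx]
    px = (xx + 0.5) * pixel_size
    py = (yy + 0.5) * pixel_size
    movie = np.zeros((n_frames, ny, nx))
    rough = (rng.uniform(-1, 1, size=(n_nuclei, 8)) if rough_boundary > 0 else None)
    for f in range(n_frames):
        t = (f + 1) * frame_interval
        covered = np.zeros((ny, nx), dtype=bool)
        for k in range(n_nuclei):
            if t <= t_nuc[k]:
                break  # t_nuc sorted
            r = growth_speed * (t - t_nuc[k])
            dx, dy = px - xs[k], py - ys[k]
            if rough_boundary > 0:
                ang = np.arctan2(dy, dx)
                pert = sum(rough[k, m] * np.cos((m + 1) * ang) for m in range(8))
                r_eff = r * (1.0 + rough_boundary * pert / 8.0)
                covered |= np.hypot(dx, dy) <= r_eff
            else:
                covered |= dx**2 + dy**2 <= r**2
        movie[f][covered] = level
    log = NucleationGrowthLog(
        nucleations=pd.DataFrame({"t_s": t_nuc, "x_um": xs, "y_um": ys}),
        merges=pd.DataFrame(merges, columns=["t_s", "i", "j"]),
    )
    return movie, log
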