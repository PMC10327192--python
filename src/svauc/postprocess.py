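"""Post-processing helpers: peak integration, meniscus pre-estimation and
report rendering.

These mirror the secondary-analysis steps a driver script performs after
an automated run: integrating c(s) peaks into populations and
signal-weighted average sedimentation coefficients s_w, estimating a
starting meniscus position from the optical artifact in absorbance
scans, and rendering the documentation image with the data/fit overlay,
residuals and distribution.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from svauc.distribution import Distribution
from svauc.scan_io import ScanSet


@dataclass
class PeakIntegral:
    """Integral of c(s) over an s-range."""

    s_range: tuple[float, float]
    signal: float  # integrated loading (OD or fringes)
    percent: float  # of the full-grid integral
    sw: float  # signal-weighted average s in Svedberg


def _trapz_range(s: np.ndarray, c: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    """Trapezoidal integrals of c and s*c over [lo, hi] with exact
    endpoint interpolation; returns (integral c ds, integral s c ds)."""
    grid = np.concatenate(([lo], s[(s > lo) & (s < hi)], [hi]))
    cv = np.interp(grid, s, c)
    return float(np.trapezoid(cv, grid)), float(np.trapezoid(grid * cv, grid))


def integrate_distribution(dist: Distribution, s_lo: float, s_hi: float) -> PeakIntegral:
    """Integrate c(s) over [s_lo, s_hi].

    Returns the integrated signal, its percentage of the full-grid
    integral, and the signal-weighted average s_w = int s c ds / int c ds.
    """
    s = dist.s_values
    if not (s[0] <= s_lo < s_hi <= s[-1]):
        raise ValueError(
            f"integration range [{s_lo}, {s_hi}] outside grid span [{s[0]}, {s[-1]}]"
        )
    total, _ = _trapz_range(s, dist.c_values, s[0], s[-1])
    if total <= 0:
        raise ValueError("distribution carries no signal to integrate")
    signal, first_moment = _trapz_range(s, dist.c_values, s_lo, s_hi)
    sw = first_moment / signal if signal > 0 else 0.5 * (s_lo + s_hi)
    return PeakIntegral(
        s_range=(s_lo, s_hi),
        signal=signal,
        percent=100.0 * signal / total,
        sw=sw,
    )


def estimate_meniscus(scan_set: ScanSet, min_prominence_sd: float = 5.0) -> float:
    """Estimate the meniscus radius from the optical meniscus artifact.

    The time-averaged scan is searched for the largest sharp local
    maximum preceding the sedimentation-boundary region (located as the
    half-rise of the averaged profile).  Intended as a starting value
    only; accuracy is of the order of the radial sampling (~0.01 cm).
    """
    from scipy.signal import find_peaks

    avg = scan_set.signal.mean(axis=1)
    radii = scan_set.radii
    # the sedimentation boundary rises monotonically to the plateau, so
    # any prominent local maximum in the left part of the cell is an
    # optical artifact; the meniscus spike is the dominant one
    plateau = np.median(avg[len(avg) // 2 :])
    noise = np.median(np.abs(np.diff(avg))) + 1e-12
    prominence = max(min_prominence_sd * noise, 0.25 * abs(plateau))
    peaks, _ = find_peaks(np.abs(avg), prominence=prominence)
    cutoff = radii[0] + 0.5 * (radii[-1] - radii[0])
    peaks = [p for p in peaks if radii[p] < cutoff]
    if not peaks:
        raise ValueError(
            "no meniscus artifact detected; set the Meniscus parameter manually"
        )
    best = max(peaks, key=lambda p: abs(avg[p]))
    return float(radii[best])


def render_report(bundle, path, show_histogram: bool = True,
                  subtract_noise: bool = False) -> Path:
    """Render the documentation image (BMP): scan overlay with fit,
    residuals (and optional histogram), c(s) panel and info text.

    ``subtract_noise`` only changes the displayed scans (systematic noise
    removed); the underlying result files are untouched.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from PIL import Image

    fit = bundle.fit
    nr, ns = fit.residuals.shape
    data = fit.fitted_matrix + fit.residuals
    shown = data - fit.ti_noise[:, None] - fit.ri_noise[None, :] - fit.baseline \
        if subtract_noise else data
    model = fit.fitted_matrix - fit.ti_noise[:, None] - fit.ri_noise[None, :] - fit.baseline \
        if subtract_noise else fit.fitted_matrix

    fig = plt.figure(figsize=(9, 7), dpi=100)
    gs = fig.add_gridspec(3, 2, height_ratios=[2.2, 1, 1.6], width_ratios=[3, 1])
    ax_data = fig.add_subplot(gs[0, :])
    ax_res = fig.add_subplot(gs[1, 0])
    ax_hist = fig.add_subplot(gs[1, 1])
    ax_dist = fig.add_subplot(gs[2, :])

    colors = plt.cm.rainbow(np.linspace(0, 1, ns))
    for k in range(ns):
        ax_data.plot(fit.radii, shown[:, k], ".", ms=1.5, color=colors[k])
        ax_data.plot(fit.radii, model[:, k], "-", lw=0.8, color=colors[k])
    ax_data.set_xlabel("radius (cm)")
    ax_data.set_ylabel("signal")
    ax_data.set_title(
        f"{bundle.config.model} fit  rmsd = {fit.rmsd:.6f}  "
        f"meniscus = {fit.meniscus:.4f} cm  f/f0 = {fit.frictional_ratio:.3f}"
    )

    for k in range(ns):
        ax_res.plot(fit.radii, fit.residuals[:, k], "-", lw=0.5, color=colors[k])
    ax_res.axhline(0.0, color="k", lw=0.5)
    ax_res.set_ylabel("residuals")
    if show_histogram:
        ax_hist.hist(fit.residuals.ravel(), bins=25, color="gray")
        ax_hist.set_yticks([])
        ax_hist.set_title("residuals", fontsize=8)
    else:
        ax_hist.axis("off")

    dist = fit.distribution
    ax_dist.plot(dist.s_values, dist.c_values, "-", color="navy")
    ax_dist.fill_between(dist.s_values, dist.c_values, alpha=0.3, color="navy")
    ax_dist.set_xlabel("s (Svedberg)")
    ax_dist.set_ylabel("c(s)  (signal/S)")
    info = (
        f"scans: {ns}   points: {fit.n_points}   rmsd: {fit.rmsd:.6f}   "
        f"data: {bundle.config.data_directory}"
    )
    fig.text(0.01, 0.005, info, fontsize=7)
    fig.tight_layout()

    buf = io.BytesIO()
    fig.savefig(buf, format="png")
    plt.close(fig)
    buf.seek(0)
    Image.open(buf).convert("RGB").save(path, format="BMP")
    return Path(path)


def peak_table_csv(peaks: list[PeakIntegral], path) -> Path:
    """Write PeakIntegral rows as CSV for replicate/titration aggregation."""
    lines = ["s_lo,s_hi,signal,percent,sw"]
    for p in peaks:
        lines.append(
            f"{p.s_range[0]:.6g},{p.s_range[1]:.6g},{p.signal:.8g},"
            f"{p.percent:.6f},{p.sw:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
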