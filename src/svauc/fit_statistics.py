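"""Quality-of-fit statistics and experimental QC records.

The runs test (Wald-Wolfowitz) quantifies serial correlation in the fit
residuals; the histogram statistic H measures how closely the residual
histogram follows a Gaussian; the temperature record flags possible
convection artifacts from rotor-temperature drifts during the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from svauc.scan_io import ScanSet

#: Reported when the runs test is undefined (all residuals one sign).
RUNS_TEST_UNDEFINED = float("nan")


@dataclass
class QCRecord:
    """Fit statistics and experiment QC surfaced in ResultParameters.xml."""

    rmsd: float
    ssr: float
    n_points: int
    runs_test_z: float
    histogram_h: float
    temperature_start: float
    temperature_end: float
    temperature_average: float
    temperature_max_min: float
    t_last_scan: float
    w2t_last_scan: float
    check_time_stamps: bool
    rotor_speed: float
    wavelength: float


def runs_test_z(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs test Z for residual sign randomness.

    With n+ positive and n- negative residuals (zeros skipped) and R sign
    runs: mu_R = 2 n+ n- / (n+ + n-) + 1 and sigma_R^2 = 2 n+ n-
    (2 n+ n- - n+ - n-) / ((n+ + n-)^2 (n+ + n- - 1)); Z = (R - mu_R) /
    sigma_R.  Residuals are passed flattened scan-major with radii
    ascending within each scan.  Negative Z flags too few runs
    (correlated residuals); the statistic is symmetric under a global
    sign flip.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n = n_pos + n_neg
    if n < 2 or n_pos == 0 or n_neg == 0:
        import warnings

        warnings.warn("runs test undefined: residuals do not change sign")
        return RUNS_TEST_UNDEFINED
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = (
        2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n)
        / (n ** 2 * (n - 1.0))
    )
    if var <= 0:
        import warnings

        warnings.warn("runs test undefined: zero variance")
        return RUNS_TEST_UNDEFINED
    return float((runs - mu) / np.sqrt(var))


def histogram_h(residuals: np.ndarray, n_bins: int = 25, span_sd: float = 4.0) -> float:
    """Normalized squared deviation of the residual histogram from a Gaussian.

    H = sum_bins (f_obs - f_gauss)^2 / sum_bins f_gauss^2, with f_obs the
    residual histogram normalized to unit total over ``n_bins`` equal bins
    spanning +/- ``span_sd`` sample standard deviations around the sample
    mean, and f_gauss the Gaussian bin masses at the sample mean/SD.
    H >= 0 and -> 0 for Gaussian residuals; the statistic is invariant
    under affine rescaling of the residuals because bins are defined in
    SD units.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    if len(residuals) < 100:
        raise ValueError(f"histogram H needs >= 100 residuals, got {len(residuals)}")
    mean = residuals.mean()
    sd = residuals.std(ddof=0)
    if sd == 0:
        raise ValueError("histogram H undefined for zero-variance residuals")
    edges = np.linspace(mean - span_sd * sd, mean + span_sd * sd, n_bins + 1)
    counts, _ = np.histogram(residuals, bins=edges)
    f_obs = counts / len(residuals)
    cdf = norm.cdf(edges, loc=mean, scale=sd)
    f_gauss = np.diff(cdf)
    return float(np.sum((f_obs - f_gauss) ** 2) / np.sum(f_gauss ** 2))


def temperature_qc(scan_set: ScanSet) -> dict:
    """Start/end/average/max-min temperature summary over the run."""
    temps = np.asarray(scan_set.temperatures, dtype=float)
    return {
        "temperature_start": float(temps[0]),
        "temperature_end": float(temps[-1]),
        "temperature_average": float(temps.mean()),
        "temperature_max_min": float(temps.max() - temps.min()),
    }


def build_qc_record(
    scan_set: ScanSet,
    residuals: np.ndarray,
    rmsd: float,
    ssr: float,
    time_stamps_ok: bool,
) -> QCRecord:
    """Assemble the full QC record for a finished fit.

    ``residuals`` is the fit-window residual matrix [n_radii x n_scans];
    the runs test flattens it scan-major with radii ascending.
    """
    flat = np.asarray(residuals).ravel(order="F")
    temps = temperature_qc(scan_set)
    return QCRecord(
        rmsd=float(rmsd),
        ssr=float(ssr),
        n_points=int(np.asarray(residuals).size),
        runs_test_z=runs_test_z(flat),
        histogram_h=histogram_h(flat) if np.asarray(residuals).size >= 100 else float("nan"),
        t_last_scan=float(scan_set.times[-1]),
        w2t_last_scan=float(scan_set.w2t[-1]),
        check_time_stamps=bool(time_stamps_ok),
        rotor_speed=float(scan_set.rotor_speed),
        wavelength=float(scan_set.wavelength),
        **temps,
    )
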