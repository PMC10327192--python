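"""Synthetic SV-AUC datasets with known ground truth.

Generates on-disk multi-scan datasets from Lamm-equation physics: a
mixture of species (each with sedimentation coefficient, frictional
ratio and loading signal) sedimenting in a sector cell, plus the
instrument artifacts handled by the analysis — a time-invariant (TI)
radial baseline, radial-invariant (RI) per-scan offsets, Gaussian noise,
and optionally a sharp optical artifact at the meniscus as seen in
absorbance data.  Every dataset is deterministic given its seed and is
written alongside a truth manifest, so parameter-recovery tests need no
instrument data.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from svauc.lamm import SVEDBERG, CellGeometry, RotorState, diffusion_from_s, solve_lamm
from svauc.scan_io import Scan, write_scan_file


@dataclass
class Species:
    """One sedimenting species: s in Svedberg, frictional ratio f/f0,
    loading signal in OD or fringes."""

    s: float
    frictional_ratio: float
    loading: float

    def __post_init__(self) -> None:
        if self.loading <= 0:
            raise ValueError(f"loading must be > 0, got {self.loading}")


@dataclass
class TruthManifest:
    """Complete recipe for a synthetic dataset.

    Defaults mirror a typical absorbance-detected protein experiment:
    50,000 rpm at 20 degC with ~0.005 OD random noise.
    """

    species: list[Species]
    meniscus: float = 6.10
    bottom: float = 7.15
    rotor_speed: float = 50000.0
    times: np.ndarray = field(
        default_factory=lambda: np.linspace(600.0, 6000.0, 40)
    )
    radius_min: float = 5.95
    radius_step: float = 0.003
    temperature: float = 20.0
    wavelength: float = 280.0
    vbar: float = 0.73
    buffer_density: float = 1.0
    buffer_viscosity: float = 0.01002
    sigma_random: float = 0.005
    ti_amplitude: float = 0.0  # sinusoidal TI profile amplitude
    ti_period: float = 0.35  # cm
    ti_tilt: float = 0.0  # linear TI slope, signal per cm
    ri_sigma: float = 0.0  # SD of random per-scan offsets
    meniscus_artifact: float = 0.0  # amplitude of optical spike at m
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not self.species:
            raise ValueError("manifest needs at least one species")
        if not self.meniscus < self.bottom:
            raise ValueError("meniscus must lie left of bottom")

    @property
    def radii(self) -> np.ndarray:
        n = int(np.floor((self.bottom - self.radius_min) / self.radius_step)) + 1
        return self.radius_min + self.radius_step * np.arange(n)

    def ti_profile(self, radii: np.ndarray) -> np.ndarray:
        r0 = radii[0]
        return self.ti_amplitude * np.sin(
            2.0 * np.pi * (radii - r0) / self.ti_period
        ) + self.ti_tilt * (radii - r0)


def ideal_signal(manifest: TruthManifest, n_grid: int = 600) -> np.ndarray:
    """Noise-free species signal matrix [n_radii x n_scans]; zero in the
    air space left of the meniscus."""
    geom = CellGeometry(manifest.meniscus, manifest.bottom)
    rotor = RotorState(manifest.rotor_speed)
    radii = manifest.radii
    in_cell = radii >= manifest.meniscus
    total = np.zeros((len(radii), len(manifest.times)))
    t_kelvin = manifest.temperature + 273.15
    for sp in manifest.species:
        d_coef = diffusion_from_s(
            sp.s * SVEDBERG,
            sp.frictional_ratio,
            manifest.vbar,
            manifest.buffer_density,
            manifest.buffer_viscosity,
            t_kelvin,
        )
        prof = solve_lamm(
            sp.s * SVEDBERG,
            d_coef,
            rotor,
            geom,
            manifest.times,
            radii[in_cell],
            n_grid=n_grid,
        )
        total[in_cell, :] += sp.loading * prof
    return total


def generate_dataset(
    manifest: TruthManifest,
    out_dir,
    channel: str = "ra1",
    n_grid: int = 600,
) -> tuple[list[Path], Path]:
    """Write the scan files plus the truth manifest; returns their paths.

    Scan k = sum_species loading * chi(s, D; r, t_k) + TI(r) + RI_k +
    N(0, sigma^2), with headers carrying rpm, time, temperature and the
    constant-speed sedimentation clock w2t = omega^2 * t.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(manifest.seed)
    radii = manifest.radii
    signal = ideal_signal(manifest, n_grid=n_grid)
    signal = signal + manifest.ti_profile(radii)[:, None]
    if manifest.ri_sigma > 0:
        signal = signal + rng.normal(0.0, manifest.ri_sigma, len(manifest.times))[None, :]
    if manifest.meniscus_artifact > 0:
        # narrow optical spike centered on the meniscus (width ~ 2 samples)
        width = 2.0 * manifest.radius_step
        spike = manifest.meniscus_artifact * np.exp(
            -0.5 * ((radii - manifest.meniscus) / width) ** 2
        )
        signal = signal + spike[:, None]
    if manifest.sigma_random > 0:
        signal = signal + rng.normal(0.0, manifest.sigma_random, signal.shape)

    omega_sq = RotorState(manifest.rotor_speed).omega_sq
    ext = channel.lower().lstrip(".")
    paths: list[Path] = []
    for k, t in enumerate(manifest.times):
        scan = Scan(
            radii=radii,
            values=signal[:, k],
            scan_time=float(t),
            w2t=float(omega_sq * t),
            rotor_speed=manifest.rotor_speed,
            temperature=manifest.temperature,
            wavelength=manifest.wavelength,
            cell_id=1,
            data_type="R",
            title=f"synthetic SV scan {k + 1}",
        )
        path = out_dir / f"{k + 1:05d}.{ext}"
        write_scan_file(scan, path)
        paths.append(path)
    manifest_path = write_manifest(manifest, out_dir / "truth_manifest.xml")
    return paths, manifest_path


def write_manifest(manifest: TruthManifest, path) -> Path:
    """Serialize the truth manifest as XML next to the dataset."""
    root = ET.Element("TruthManifest")
    scalars = {
        "Meniscus": manifest.meniscus,
        "Bottom": manifest.bottom,
        "RotorSpeed": manifest.rotor_speed,
        "RadiusMin": manifest.radius_min,
        "RadiusStep": manifest.radius_step,
        "Temperature": manifest.temperature,
        "Wavelength": manifest.wavelength,
        "Vbar": manifest.vbar,
        "BufferDensity": manifest.buffer_density,
        "BufferViscosity": manifest.buffer_viscosity,
        "SigmaRandom": manifest.sigma_random,
        "TIAmplitude": manifest.ti_amplitude,
        "TIPeriod": manifest.ti_period,
        "TITilt": manifest.ti_tilt,
        "RISigma": manifest.ri_sigma,
        "MeniscusArtifact": manifest.meniscus_artifact,
        "Seed": manifest.seed,
    }
    for tag, value in scalars.items():
        ET.SubElement(root, tag).text = f"{value:.12g}"
    ET.SubElement(root, "Times").text = " ".join(f"{t:.10g}" for t in manifest.times)
    table = ET.SubElement(root, "SpeciesTable")
    for sp in manifest.species:
        row = ET.SubElement(table, "Species")
        ET.SubElement(row, "S").text = f"{sp.s:.10g}"
        ET.SubElement(row, "FrictionalRatio").text = f"{sp.frictional_ratio:.10g}"
        ET.SubElement(row, "Loading").text = f"{sp.loading:.10g}"
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="UTF-8", xml_declaration=True)
    return Path(path)


def read_manifest(path) -> TruthManifest:
    root = ET.parse(path).getroot()
    get = lambda tag: float(root.findtext(tag))
    species = [
        Species(
            s=float(row.findtext("S")),
            frictional_ratio=float(row.findtext("FrictionalRatio")),
            loading=float(row.findtext("Loading")),
        )
        for row in root.find("SpeciesTable")
    ]
    return TruthManifest(
        species=species,
        meniscus=get("Meniscus"),
        bottom=get("Bottom"),
        rotor_speed=get("RotorSpeed"),
        times=np.array([float(x) for x in root.findtext("Times").split()]),
        radius_min=get("RadiusMin"),
        radius_step=get("RadiusStep"),
        temperature=get("Temperature"),
        wavelength=get("Wavelength"),
        vbar=get("Vbar"),
        buffer_density=get("BufferDensity"),
        buffer_viscosity=get("BufferViscosity"),
        sigma_random=get("SigmaRandom"),
        ti_amplitude=get("TIAmplitude"),
        ti_period=get("TIPeriod"),
        ti_tilt=get("TITilt"),
        ri_sigma=get("RISigma"),
        meniscus_artifact=get("MeniscusArtifact"),
        seed=int(get("Seed")),
    )


def single_species_manifest(n_scans: int = 20, sigma: float = 0.005, seed: int = 0) -> TruthManifest:
    """Monodisperse reference condition: 5 S, f/f0 = 1.3, meniscus 6.10 cm,
    50,000 rpm, unit loading."""
    return TruthManifest(
        species=[Species(s=5.0, frictional_ratio=1.3, loading=1.0)],
        times=np.linspace(600.0, 6000.0, n_scans),
        sigma_random=sigma,
        seed=seed,
    )


def two_species_manifest(n_scans: int = 20, sigma: float = 0.005, seed: int = 0) -> TruthManifest:
    """Bimodal mixture: 5 S and 9 S with equal loadings."""
    return TruthManifest(
        species=[
            Species(s=5.0, frictional_ratio=1.3, loading=0.5),
            Species(s=9.0, frictional_ratio=1.3, loading=0.5),
        ],
        times=np.linspace(600.0, 6000.0, n_scans),
        sigma_random=sigma,
        seed=seed,
    )


def mab_like_manifest(n_scans: int = 40, sigma: float = 0.005, seed: int = 0) -> TruthManifest:
    """Stressed-antibody-like demo: monomer, degradation fragment, dimer
    and a heavier aggregate producing a multimodal boundary."""
    return TruthManifest(
        species=[
            Species(s=4.2, frictional_ratio=1.37, loading=0.02),
            Species(s=6.5, frictional_ratio=1.37, loading=0.40),
            Species(s=9.5, frictional_ratio=1.37, loading=0.18),
            Species(s=16.8, frictional_ratio=1.37, loading=0.40),
        ],
        times=np.linspace(400.0, 5200.0, n_scans),
        sigma_random=sigma,
        seed=seed,
    )
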