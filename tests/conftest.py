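import numpy as np
import pytest

from svauc.lamm import CellGeometry, RotorState
from svauc.scan_io import Scan, assemble_scan_set, read_scan_file
from svauc.synthetic import (
    Species,
    TruthManifest,
    generate_dataset,
    single_species_manifest,
    two_species_manifest,
)


@pytest.fixture(scope="session")
def rotor():
    return RotorState(50000.0)


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry(6.10, 7.15)


@pytest.fixture
def simple_scan():
    radii = np.linspace(6.0, 7.2, 200)
    return Scan(
        radii=radii,
        values=np.sin(radii) * 0.5 + 0.5,
        scan_time=600.0,
        w2t=RotorState(50000.0).omega_sq * 600.0,
        rotor_speed=50000.0,
        temperature=20.0,
    )


@pytest.fixture(scope="session")
def single_species_dataset(tmp_path_factory):
    """On-disk monodisperse dataset (5 S, f/f0 1.3, sigma 0.005, seed 0)."""
    out = tmp_path_factory.mktemp("single") / "data"
    manifest = single_species_manifest(n_scans=15, sigma=0.005, seed=0)
    paths, manifest_path = generate_dataset(manifest, out, channel="ra1")
    return manifest, paths, out


@pytest.fixture(scope="session")
def two_species_dataset(tmp_path_factory):
    """On-disk 5 S + 9 S equal-loading dataset."""
    out = tmp_path_factory.mktemp("double") / "data"
    manifest = two_species_manifest(n_scans=15, sigma=0.005, seed=0)
    paths, manifest_path = generate_dataset(manifest, out, channel="ra1")
    return manifest, paths, out


@pytest.fixture(scope="session")
def single_species_scan_set(single_species_dataset):
    _, paths, _ = single_species_dataset
    scans = [read_scan_file(p) for p in paths]
    return assemble_scan_set(scans, channel="ra1", source_paths=paths)


@pytest.fixture(scope="session")
def noiseless_scan_set():
    """Noise-free single-species scans assembled in memory."""
    manifest = TruthManifest(
        species=[Species(s=5.0, frictional_ratio=1.3, loading=1.0)],
        times=np.linspace(600.0, 6000.0, 10),
        sigma_random=0.0,
        seed=0,
    )
    from svauc.synthetic import ideal_signal

    # same solver grid as the default fit kernels, so the model space
    # contains the data exactly
    signal = ideal_signal(manifest, n_grid=400)
    radii = manifest.radii
    omega_sq = RotorState(manifest.rotor_speed).omega_sq
    scans = [
        Scan(
            radii=radii,
            values=signal[:, k],
            scan_time=t,
            w2t=omega_sq * t,
            rotor_speed=manifest.rotor_speed,
            temperature=20.0,
        )
        for k, t in enumerate(manifest.times)
    ]
    return manifest, assemble_scan_set(scans)
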