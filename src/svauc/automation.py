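"""Command-line/XML automation protocol.

The engine is driven by a three-token command line

    <engine> <mode> <handshake> <input.xml>

where mode 111 is the standard analysis mode and 112 a restricted mode
that rejects non-standard settings; the handshake string is echoed into
a completion-flag file created only after every result file has been
written, so a polling driver never observes a flag without a complete
manifest.  The input file is XML 1.0 with root ``cGMPSedfitCall`` and
one element per analysis parameter, in any order.
"""

from __future__ import annotations

import sys
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

from svauc.distribution import SGrid, build_s_grid, write_sdist
from svauc.fit_statistics import QCRecord, build_qc_record
from svauc.postprocess import render_report
from svauc.regression import FitResult, FitSpec, fit_model
from svauc.scan_io import (
    DEFAULT_SPIKE_THRESHOLD,
    assemble_scan_set,
    check_time_stamps,
    enumerate_scan_files,
    filter_spikes,
    read_scan_file,
)

ENGINE_VERSION = "svauc 0.1.0"
VALID_MODES = (111, 112)


class ProtocolError(ValueError):
    """Invalid invocation or input file; no analysis is started and no
    completion flag is written."""


@dataclass
class AnalysisConfig:
    """The complete analysis-parameter record of the input XML.

    Attribute names are snake_case forms of the XML tags; see
    ``XML_TAGS`` for the mapping.  Required parameters default to None
    and are checked in :meth:`validate`.
    """

    all_done_flag_file: str = None
    output_results_directory: str = None
    pass_through: str = ""
    data_directory: str = None
    channel: str = None
    first_scan: int = None
    last_scan: int = None
    scan_interval: int = 1
    filter_data_spikes: bool = True
    data_spike_threshold: float = DEFAULT_SPIKE_THRESHOLD
    meniscus: float = None
    meniscus_lower_limit: float = None
    meniscus_upper_limit: float = None
    bottom: float = None
    bottom_lower_limit: float = None
    bottom_upper_limit: float = None
    left_fit_limit: float = None
    right_fit_limit: float = None
    auto_run: bool = False
    auto_fit: bool = False
    auto_subtract_systematic_noise: bool = False
    show_residuals_histogram: bool = True
    model: str = "cofs"
    resolution: int = 50
    smin: float = 0.5
    smax: float = 20.0
    grid_from_file: bool = False
    use_log_space_sgrid: bool = False
    regularization_type: str = "maxent"
    regularization_p_value: float = 0.68
    suppress_baseline_correlation: bool = False
    number_computation_threads: int = 2  # advisory
    fitting_algorithm: str = "Simplex"
    starting_frictional_ratio: float = 1.2
    frictional_ratio_fitted: bool = False
    meniscus_fitted: bool = False
    bottom_fitted: bool = False
    baseline_fitted: bool = False
    ri_noise_fitted: bool = False
    ti_noise_fitted: bool = False
    vbar: float = 0.73
    buffer_density: float = 1.0
    buffer_viscosity: float = 0.01002  # Poise
    extra: dict = field(default_factory=dict)  # non-standard tags, echoed
    seed: int = 0  # simplex start randomization

    def validate(self, check_flag: bool = True) -> None:
        required = [
            "all_done_flag_file",
            "output_results_directory",
            "data_directory",
            "channel",
            "first_scan",
            "last_scan",
            "meniscus",
            "bottom",
            "left_fit_limit",
            "right_fit_limit",
        ]
        for name in required:
            if getattr(self, name) is None:
                raise ProtocolError(f"required parameter {XML_TAGS[name]} is missing")
        if check_flag and Path(self.all_done_flag_file).exists():
            raise ProtocolError(
                f"AllDoneFlagFile already exists: {self.all_done_flag_file}"
            )
        if self.model not in ("cofs", "lsgofs"):
            raise ProtocolError(f"Model must be 'cofs' or 'lsgofs', got {self.model!r}")
        if self.regularization_type not in ("maxent", "Tikhonov"):
            raise ProtocolError(
                f"RegularizationType must be 'maxent' or 'Tikhonov', "
                f"got {self.regularization_type!r}"
            )
        if not (0.5 <= self.regularization_p_value < 1.0):
            raise ProtocolError(
                f"RegularizationPvalue must be in [0.5, 1.0), "
                f"got {self.regularization_p_value}"
            )
        if self.fitting_algorithm not in ("Simplex", "Levenberg-Marquardt"):
            raise ProtocolError(
                f"FittingAlgorithm must be 'Simplex' or 'Levenberg-Marquardt', "
                f"got {self.fitting_algorithm!r}"
            )
        if not self.left_fit_limit < self.right_fit_limit:
            raise ProtocolError("LeftFitLimit must be smaller than RightFitLimit")
        if self.meniscus_fitted:
            lo, hi = self.meniscus_lower_limit, self.meniscus_upper_limit
            if lo is None or hi is None:
                raise ProtocolError(
                    "MeniscusFitted requires MeniscusLowerLimit and MeniscusUpperLimit"
                )
            if not (lo < self.meniscus < hi < self.left_fit_limit):
                raise ProtocolError(
                    "require MeniscusLowerLimit < Meniscus < MeniscusUpperLimit "
                    "< LeftFitLimit"
                )
        if self.bottom_fitted:
            lo, hi = self.bottom_lower_limit, self.bottom_upper_limit
            if lo is None or hi is None or not (lo < self.bottom < hi):
                raise ProtocolError(
                    "BottomFitted requires BottomLowerLimit < Bottom < BottomUpperLimit"
                )


#: attribute -> XML tag (Table-1 parameter names; parameters are case sensitive)
XML_TAGS = {
    "all_done_flag_file": "AllDoneFlagFile",
    "output_results_directory": "OutputResultsDirectory",
    "pass_through": "PassThrough",
    "data_directory": "DataDirectory",
    "channel": "Channel",
    "first_scan": "FirstScan",
    "last_scan": "LastScan",
    "scan_interval": "ScanInterval",
    "filter_data_spikes": "FilterDataSpikes",
    "data_spike_threshold": "DataSpikeThreshold",
    "meniscus": "Meniscus",
    "meniscus_lower_limit": "MeniscusLowerLimit",
    "meniscus_upper_limit": "MeniscusUpperLimit",
    "bottom": "Bottom",
    "bottom_lower_limit": "BottomLowerLimit",
    "bottom_upper_limit": "BottomUpperLimit",
    "left_fit_limit": "LeftFitLimit",
    "right_fit_limit": "RightFitLimit",
    "auto_run": "AutoRun",
    "auto_fit": "AutoFit",
    "auto_subtract_systematic_noise": "AutoSubtractSystematicNoise",
    "show_residuals_histogram": "ShowResidualsHistogram",
    "model": "Model",
    "resolution": "Resolution",
    "smin": "Smin",
    "smax": "Smax",
    "grid_from_file": "GridfromFile",
    "use_log_space_sgrid": "UseLogSpaceSgrid",
    "regularization_type": "RegularizationType",
    "regularization_p_value": "RegularizationPvalue",
    "suppress_baseline_correlation": "SuppressBaselineCorrelation",
    "number_computation_threads": "NumberComputationThreads",
    "fitting_algorithm": "FittingAlgorithm",
    "starting_frictional_ratio": "StartingFrictionalRatio",
    "frictional_ratio_fitted": "FrictionalRatioFitted",
    "meniscus_fitted": "MeniscusFitted",
    "bottom_fitted": "BottomFitted",
    "baseline_fitted": "BaselineFitted",
    "ri_noise_fitted": "RINoiseFitted",
    "ti_noise_fitted": "TINoiseFitted",
    "vbar": "Vbar",
    "buffer_density": "BufferDensity",
    "buffer_viscosity": "BufferViscosity",
    "seed": "Seed",
}
_TAG_TO_ATTR = {tag: attr for attr, tag in XML_TAGS.items()}
# the Method text prints the suppression switch with a single 'p'
_TAG_TO_ATTR["SupressBaselineCorrelation"] = "suppress_baseline_correlation"

_BOOL_ATTRS = {
    a for a in XML_TAGS
    if isinstance(getattr(AnalysisConfig(), a, None), bool)
}
_INT_ATTRS = {
    "first_scan", "last_scan", "scan_interval", "resolution",
    "number_computation_threads", "seed",
}
_FLOAT_ATTRS = {
    "data_spike_threshold", "meniscus", "meniscus_lower_limit",
    "meniscus_upper_limit", "bottom", "bottom_lower_limit",
    "bottom_upper_limit", "left_fit_limit", "right_fit_limit", "smin",
    "smax", "regularization_p_value", "starting_frictional_ratio", "vbar",
    "buffer_density", "buffer_viscosity",
}


def _parse_bool(text: str, tag: str) -> bool:
    t = (text or "").strip().upper()
    if t == "TRUE":
        return True
    if t == "FALSE":
        return False
    raise ProtocolError(f"parameter {tag}: expected TRUE or FALSE, got {text!r}")


def _inner_xml(element: ET.Element) -> str:
    """The verbatim content of an element, children included."""
    parts = [element.text or ""]
    for child in element:
        parts.append(ET.tostring(child, encoding="unicode"))
    return "".join(parts).strip()


def parse_command_line(argv: list[str]) -> tuple[int, str, Path]:
    """Parse the three-token invocation ``<mode> <handshake> <input.xml>``."""
    if len(argv) != 3:
        raise ProtocolError(
            f"expected exactly 3 command-line tokens (mode, handshake, input "
            f"file), got {len(argv)}"
        )
    try:
        mode = int(argv[0])
    except ValueError:
        raise ProtocolError(f"mode must be an integer, got {argv[0]!r}")
    if mode not in VALID_MODES:
        raise ProtocolError(f"unknown mode {mode}; valid modes: {VALID_MODES}")
    handshake = argv[1]
    if not handshake:
        raise ProtocolError("handshake string must be nonempty")
    input_path = Path(argv[2])
    if not input_path.is_file():
        raise ProtocolError(f"input file not found: {input_path}")
    return mode, handshake, input_path


def parse_input_xml(path, check_flag: bool = True) -> AnalysisConfig:
    """Read an ``cGMPSedfitCall`` parameter file into an
    :class:`AnalysisConfig`.

    Parameters may appear in any order; unknown tags are preserved
    verbatim in ``config.extra`` for echoing.  ``check_flag`` enforces
    the contract that the completion-flag file must not pre-exist (turn
    it off to re-parse a ResultParameters.xml after a finished run).
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ProtocolError(f"{path}: not well-formed XML: {exc}") from exc
    if root.tag != "cGMPSedfitCall":
        raise ProtocolError(
            f"{path}: root element must be cGMPSedfitCall, got {root.tag!r}"
        )
    config = AnalysisConfig()
    for element in root:
        tag = element.tag
        attr = _TAG_TO_ATTR.get(tag)
        if attr is None:
            config.extra[tag] = _inner_xml(element)
            continue
        if attr == "pass_through":
            config.pass_through = _inner_xml(element)
            continue
        text = (element.text or "").strip()
        try:
            if attr in _BOOL_ATTRS:
                value = _parse_bool(text, tag)
            elif attr in _INT_ATTRS:
                value = int(text)
            elif attr in _FLOAT_ATTRS:
                value = float(text)
            else:
                value = text
        except ValueError as exc:
            raise ProtocolError(f"parameter {tag}: malformed value {text!r}") from exc
        setattr(config, attr, value)
    config.validate(check_flag=check_flag)
    return config


def serialize_config(config: AnalysisConfig, extra_xml: str = "") -> str:
    """Render the Table-1 parameter record back to the input-XML dialect;
    ``extra_xml`` is appended verbatim inside the root (used for the
    result parameters)."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<cGMPSedfitCall>"]
    for attr, tag in XML_TAGS.items():
        value = getattr(config, attr)
        if value is None:
            continue
        if attr == "pass_through":
            lines.append(f"  <{tag}>{value}</{tag}>")
            continue
        if isinstance(value, bool):
            text = "TRUE" if value else "FALSE"
        elif isinstance(value, float):
            text = f"{value:.10g}"
        else:
            text = str(value)
        lines.append(f"  <{tag}>{text}</{tag}>")
    for tag, inner in config.extra.items():
        lines.append(f"  <{tag}>{inner}</{tag}>")
    if extra_xml:
        lines.append(extra_xml)
    lines.append("</cGMPSedfitCall>")
    return "\n".join(lines) + "\n"


@dataclass
class ResultBundle:
    """Everything a secondary driver reads back after a session."""

    config: AnalysisConfig
    fit: FitResult
    qc: QCRecord
    scan_paths: list[Path]
    manifest: dict = field(default_factory=dict)  # output name -> Path
    engine_version: str = ENGINE_VERSION
    handshake: str = ""
    mode: int = 111


def run_session(mode: int, handshake: str, config: AnalysisConfig) -> ResultBundle:
    """Execute one complete analysis session.

    Loads and optionally spike-filters the scans, runs the (optionally
    nonlinear) fit, computes statistics, writes every output file and
    creates the completion flag LAST; any failure propagates before the
    flag exists.
    """
    if mode not in VALID_MODES:
        raise ProtocolError(f"unknown mode {mode}")
    if mode == 112:
        if config.extra:
            raise ProtocolError(
                f"mode 112 rejects non-standard parameters: {sorted(config.extra)}"
            )
        if config.regularization_type != "maxent":
            raise ProtocolError(
                "mode 112 does not allow overriding RegularizationType"
            )
    config.validate(check_flag=True)

    paths = enumerate_scan_files(
        config.data_directory,
        config.channel,
        config.first_scan,
        config.last_scan,
        config.scan_interval,
    )
    scans = [read_scan_file(p) for p in paths]
    if config.filter_data_spikes:
        scans = [filter_spikes(s, config.data_spike_threshold) for s in scans]
    scan_set = assemble_scan_set(scans, channel=config.channel, source_paths=paths)
    stamps_ok, _ = check_time_stamps(paths, scans)

    from svauc.distribution import HydroParams  # local to avoid cycle at import

    grid = build_s_grid(config, config.data_directory, config.channel)
    hydro = HydroParams(
        vbar=config.vbar,
        density=config.buffer_density,
        viscosity=config.buffer_viscosity,
        frictional_ratio=config.starting_frictional_ratio,
        temperature_k=float(np.mean(scan_set.temperatures)) + 273.15,
    )
    auto_fit = config.auto_fit
    spec = FitSpec(
        model=config.model,
        s_grid=grid,
        hydro=hydro,
        meniscus=config.meniscus,
        bottom=config.bottom,
        left_fit_limit=config.left_fit_limit,
        right_fit_limit=config.right_fit_limit,
        fit_meniscus=config.meniscus_fitted and auto_fit,
        fit_bottom=config.bottom_fitted and auto_fit,
        fit_frictional_ratio=config.frictional_ratio_fitted and auto_fit,
        meniscus_bounds=(
            config.meniscus_lower_limit or 0.0,
            config.meniscus_upper_limit or np.inf,
        ),
        bottom_bounds=(
            config.bottom_lower_limit or 0.0,
            config.bottom_upper_limit or np.inf,
        ),
        fit_ti=config.ti_noise_fitted,
        fit_ri=config.ri_noise_fitted,
        fit_baseline=config.baseline_fitted,
        reg_type=config.regularization_type,
        reg_p_value=config.regularization_p_value,
        suppress_baseline_correlation=config.suppress_baseline_correlation,
        algorithm=config.fitting_algorithm,
        seed=config.seed,
    )
    fit = fit_model(spec, scan_set)
    qc = build_qc_record(scan_set, fit.residuals, fit.rmsd, fit.ssr, stamps_ok)

    bundle = ResultBundle(
        config=config,
        fit=fit,
        qc=qc,
        scan_paths=paths,
        handshake=handshake,
        mode=mode,
    )
    write_outputs(bundle, config.output_results_directory)
    write_done_flag(config.all_done_flag_file, handshake)
    bundle.manifest["AllDoneFlagFile"] = Path(config.all_done_flag_file)
    return bundle


def _write_two_column(path: Path, col1, col2) -> Path:
    with open(path, "w") as fh:
        for a, b in zip(col1, col2):
            fh.write(f"{a:.8g} {b:.8g}\n")
    return path


def write_outputs(bundle: ResultBundle, output_dir) -> dict:
    """Write the eight result artifacts.

    Into the output directory: screenshot.bmp, RInoise.dat, TInoise.dat,
    ScanRMSD.dat, distribution.dat, dfr.dat and ResultParameters.xml;
    into the data directory: sdist.<ext> and ~tmppars.<ext>.  The leaf
    output directory is created; its parent must already exist.
    """
    out = Path(output_dir)
    if not out.parent.exists():
        raise ProtocolError(f"parent of OutputResultsDirectory does not exist: {out.parent}")
    out.mkdir(exist_ok=True)
    fit = bundle.fit
    config = bundle.config
    manifest = bundle.manifest

    dist = fit.distribution
    manifest["CofsDataPath"] = _write_two_column(
        out / "distribution.dat", dist.s_values, dist.c_values
    )
    manifest["TINoisePath"] = _write_two_column(
        out / "TInoise.dat", fit.radii, fit.ti_noise
    )
    manifest["RINoisePath"] = _write_two_column(
        out / "RInoise.dat", fit.times, fit.ri_noise
    )
    manifest["ScanRMSDpath"] = _write_two_column(
        out / "ScanRMSD.dat", fit.times, fit.per_scan_rmsd
    )

    # dfr.dat: radius(TI), TI, RI (NaN-padded), then [radius, raw, fit] per scan
    nr, ns = fit.residuals.shape
    ri_col = np.full(nr, np.nan)
    ri_col[:ns] = fit.ri_noise
    blocks = [fit.radii, fit.ti_noise, ri_col]
    raw = fit.fitted_matrix + fit.residuals
    for k in range(ns):
        blocks.extend([fit.radii, raw[:, k], fit.fitted_matrix[:, k]])
    dfr = np.column_stack(blocks)
    np.savetxt(out / "dfr.dat", dfr, fmt="%.8g")
    manifest["DfrPath"] = out / "dfr.dat"

    manifest["ScreenShotPath"] = render_report(
        bundle,
        out / "screenshot.bmp",
        show_histogram=config.show_residuals_histogram,
        subtract_noise=config.auto_subtract_systematic_noise,
    )

    # sdist and fit-state snapshot live in the DATA directory
    manifest["SdistPath"] = write_sdist(
        SGrid(dist.s_values), config.data_directory, config.channel
    )
    ext = config.channel.lower().lstrip(".")
    tmppars = Path(config.data_directory) / f"~tmppars.{ext}"
    snapshot = _result_config(bundle)
    tmppars.write_text(serialize_config(snapshot))
    manifest["TmpParsPath"] = tmppars

    result_xml = out / "ResultParameters.xml"
    result_xml.write_text(_result_parameters_xml(bundle))
    manifest["ResultParametersPath"] = result_xml
    return manifest


def _result_config(bundle: ResultBundle) -> AnalysisConfig:
    """Input config with post-fit values substituted."""
    from dataclasses import replace

    fit = bundle.fit
    return replace(
        bundle.config,
        meniscus=fit.meniscus,
        bottom=fit.bottom,
        starting_frictional_ratio=fit.frictional_ratio,
        extra=dict(bundle.config.extra),
    )


def _result_parameters_xml(bundle: ResultBundle) -> str:
    fit, qc = bundle.fit, bundle.qc
    m = bundle.manifest

    def tag(name, value):
        return f"  <{name}>{value}</{name}>"

    scan_files = "\n".join(
        f"    <ScanFile>{p}</ScanFile>" for p in bundle.scan_paths
    )
    extra = "\n".join(
        [
            tag("EngineVersion", bundle.engine_version),
            tag("ScreenShotPath", m.get("ScreenShotPath", "")),
            tag("CofsDataPath", m.get("CofsDataPath", "")),
            tag("TINoisePath", m.get("TINoisePath", "")),
            tag("RINoisePath", m.get("RINoisePath", "")),
            tag("ScanRMSDpath", m.get("ScanRMSDpath", "")),
            f"  <ScanDataFilesLoaded>\n{scan_files}\n  </ScanDataFilesLoaded>",
            tag("CheckTimeStamps", "TRUE" if qc.check_time_stamps else "FALSE"),
            tag("RotorSpeed", f"{qc.rotor_speed:.10g}"),
            tag("Wavelength", f"{qc.wavelength:.10g}"),
            tag("w2tLastScan", f"{qc.w2t_last_scan:.10g}"),
            tag("tLastScan", f"{qc.t_last_scan:.10g}"),
            tag("TemperatureStart", f"{qc.temperature_start:.10g}"),
            tag("TemperatureEnd", f"{qc.temperature_end:.10g}"),
            tag("TemperatureAverage", f"{qc.temperature_average:.10g}"),
            tag("TemperatureDiffMax-Min", f"{qc.temperature_max_min:.10g}"),
            tag("FittingStepsText", fit.fitting_steps_text),
            tag("RMSD", f"{qc.rmsd:.10g}"),
            tag("RMSD-points", f"{qc.n_points}"),
            tag("RMSD-SSR", f"{qc.ssr:.10g}"),
            tag("RunsTestZ", f"{qc.runs_test_z:.10g}"),
            tag("HistogramH", f"{qc.histogram_h:.10g}"),
            tag("FrictionalRatio", f"{fit.frictional_ratio:.10g}"),
        ]
    )
    return serialize_config(_result_config(bundle), extra_xml=extra)


def write_done_flag(path, handshake: str) -> Path:
    """Atomically create the completion flag containing exactly the
    handshake string (plus one trailing newline); it must be the last
    output of a session and must not pre-exist."""
    path = Path(path)
    try:
        with open(path, "x") as fh:
            fh.write(handshake + "\n")
    except FileExistsError:
        raise ProtocolError(f"completion flag already exists: {path}")
    return path


def main(argv: list[str] | None = None) -> int:
    """Console entry point; returns a process exit code."""
    argv = sys.argv[1:] if argv is None else argv
    try:
        mode, handshake, input_path = parse_command_line(argv)
        config = parse_input_xml(input_path)
        run_session(mode, handshake, config)
    except Exception as exc:  # any failure: nonzero exit, no flag file
        print(f"svauc: error: {exc}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
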