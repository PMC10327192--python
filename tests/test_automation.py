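import numpy as np
import pytest

from svauc.automation import (
    AnalysisConfig,
    ProtocolError,
    main,
    parse_command_line,
    parse_input_xml,
    run_session,
    serialize_config,
    write_done_flag,
)

MINIMAL_XML = """<?xml version="1.0" encoding="UTF-8"?>
<cGMPSedfitCall>
  <AllDoneFlagFile>{flag}</AllDoneFlagFile>
  <OutputResultsDirectory>{outdir}</OutputResultsDirectory>
  <DataDirectory>{datadir}</DataDirectory>
  <Channel>RA1</Channel>
  <FirstScan>1</FirstScan>
  <LastScan>10</LastScan>
  <ScanInterval>1</ScanInterval>
  <Meniscus>6.10</Meniscus>
  <Bottom>7.15</Bottom>
  <LeftFitLimit>6.17</LeftFitLimit>
  <RightFitLimit>7.05</RightFitLimit>
  <Model>cofs</Model>
  <Resolution>30</Resolution>
  <Smin>1.0</Smin>
  <Smax>12.0</Smax>
  <RegularizationType>Tikhonov</RegularizationType>
  <RINoiseFitted>TRUE</RINoiseFitted>
  <StartingFrictionalRatio>1.3</StartingFrictionalRatio>
  {extra}
</cGMPSedfitCall>
"""


def _write_input(tmp_path, extra="", **overrides):
    text = MINIMAL_XML.format(
        flag=overrides.get("flag", tmp_path / "done.txt"),
        outdir=overrides.get("outdir", tmp_path / "results"),
        datadir=overrides.get("datadir", tmp_path / "data"),
        extra=extra,
    )
    path = tmp_path / "input.xml"
    path.write_text(text)
    return path


class TestCommandLine:
    def test_printed_example(self, tmp_path):
        xml = _write_input(tmp_path)
        mode, handshake, path = parse_command_line(
            ["111", "handshakestring", str(xml)]
        )
        assert mode == 111
        assert handshake == "handshakestring"
        assert path == xml

    def test_restricted_mode_accepted(self, tmp_path):
        xml = _write_input(tmp_path)
        mode, _, _ = parse_command_line(["112", "h", str(xml)])
        assert mode == 112

    def test_unknown_mode_rejected(self, tmp_path):
        xml = _write_input(tmp_path)
        with pytest.raises(ProtocolError, match="mode"):
            parse_command_line(["999", "h", str(xml)])

    def test_token_count_and_empty_handshake(self, tmp_path):
        xml = _write_input(tmp_path)
        with pytest.raises(ProtocolError, match="3"):
            parse_command_line(["111", "h"])
        with pytest.raises(ProtocolError, match="handshake"):
            parse_command_line(["111", "", str(xml)])

    def test_missing_input_file(self):
        with pytest.raises(ProtocolError, match="not found"):
            parse_command_line(["111", "h", "/nonexistent/input.xml"])


class TestParseXml:
    def test_basic_values_and_defaults(self, tmp_path):
        config = parse_input_xml(_write_input(tmp_path))
        assert config.smax == 12.0
        assert config.model == "cofs"
        # omitted spike parameters: filtering on at the default threshold
        assert config.filter_data_spikes is True
        assert config.data_spike_threshold == 0.4
        assert config.ri_noise_fitted is True
        assert config.ti_noise_fitted is False

    def test_passthrough_xml_fragment_echoed(self, tmp_path):
        frag = "<Sample><Name>lot 42</Name></Sample>"
        config = parse_input_xml(
            _write_input(tmp_path, extra=f"<PassThrough>{frag}</PassThrough>")
        )
        assert config.pass_through == frag
        text = serialize_config(config)
        assert frag in text

    def test_unknown_tags_preserved(self, tmp_path):
        config = parse_input_xml(
            _write_input(tmp_path, extra="<MyExtension>7</MyExtension>")
        )
        assert config.extra == {"MyExtension": "7"}

    def test_booleans_case_insensitive(self, tmp_path):
        config = parse_input_xml(
            _write_input(tmp_path, extra="<TINoiseFitted>true</TINoiseFitted>")
        )
        assert config.ti_noise_fitted is True

    def test_alternate_suppression_spelling(self, tmp_path):
        config = parse_input_xml(
            _write_input(
                tmp_path,
                extra="<SupressBaselineCorrelation>TRUE</SupressBaselineCorrelation>",
            )
        )
        assert config.suppress_baseline_correlation is True

    def test_malformed_number_names_tag(self, tmp_path):
        with pytest.raises(ProtocolError, match="Smin"):
            parse_input_xml(_write_input(tmp_path, extra="<Smin>abc</Smin>"))

    def test_wrong_root_rejected(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<NotTheRoot><Smin>1</Smin></NotTheRoot>")
        with pytest.raises(ProtocolError, match="cGMPSedfitCall"):
            parse_input_xml(path)

    def test_preexisting_flag_rejected_before_analysis(self, tmp_path):
        flag = tmp_path / "done.txt"
        flag.write_text("stale")
        with pytest.raises(ProtocolError, match="already exists"):
            parse_input_xml(_write_input(tmp_path, flag=flag))

    def test_serialize_roundtrip_identity(self, tmp_path):
        config = parse_input_xml(_write_input(tmp_path))
        out = tmp_path / "echo.xml"
        out.write_text(serialize_config(config))
        back = parse_input_xml(out, check_flag=True)
        from svauc.automation import XML_TAGS

        for attr in XML_TAGS:
            assert getattr(back, attr) == getattr(config, attr), attr


@pytest.fixture(scope="module")
def session_env(tmp_path_factory):
    """Small on-disk dataset plus a ready-to-run config."""
    from svauc.synthetic import generate_dataset, single_species_manifest

    tmp = tmp_path_factory.mktemp("session")
    manifest = single_species_manifest(n_scans=10, sigma=0.005, seed=0)
    generate_dataset(manifest, tmp / "data", channel="ra1")
    return tmp


def _config(tmp, tag=""):
    return AnalysisConfig(
        all_done_flag_file=str(tmp / f"done{tag}.txt"),
        output_results_directory=str(tmp / f"results{tag}"),
        data_directory=str(tmp / "data"),
        channel="RA1",
        first_scan=1,
        last_scan=10,
        scan_interval=1,
        meniscus=6.10,
        bottom=7.15,
        left_fit_limit=6.17,
        right_fit_limit=7.05,
        model="cofs",
        resolution=30,
        smin=1.0,
        smax=12.0,
        regularization_type="Tikhonov",
        ri_noise_fitted=True,
        starting_frictional_ratio=1.3,
    )


class TestRunSession:
    def test_full_session_outputs(self, session_env):
        bundle = run_session(111, "shake-1", _config(session_env, "a"))
        out = session_env / "resultsa"
        for name in (
            "screenshot.bmp",
            "distribution.dat",
            "TInoise.dat",
            "RInoise.dat",
            "ScanRMSD.dat",
            "dfr.dat",
            "ResultParameters.xml",
        ):
            assert (out / name).exists(), name
        assert (session_env / "data" / "sdist.ra1").exists()
        assert (session_env / "data" / "~tmppars.ra1").exists()
        flag = session_env / "donea.txt"
        assert flag.read_text().rstrip("\n") == "shake-1"
        # the flag is written after every manifest file
        assert all(
            flag.stat().st_mtime >= p.stat().st_mtime
            for p in bundle.manifest.values()
        )
        # distribution.dat has Resolution rows
        rows = np.loadtxt(out / "distribution.dat")
        assert rows.shape == (30, 2)

    def test_result_parameters_roundtrip_postfit(self, session_env):
        """ResultParameters.xml re-parses as a config carrying post-fit
        values and the engine's output parameters as extensions."""
        out = session_env / "resultsa"
        back = parse_input_xml(out / "ResultParameters.xml", check_flag=False)
        assert back.smax == 12.0
        assert "RMSD" in back.extra
        assert float(back.extra["RMSD"]) > 0
        assert "EngineVersion" in back.extra

    def test_dfr_reconstructs_residuals(self, session_env):
        out = session_env / "resultsa"
        dfr = np.loadtxt(out / "dfr.dat")
        n_scans = 10
        raw = dfr[:, 4::3]
        fit = dfr[:, 5::3]
        resid = raw - fit
        scan_rmsd = np.loadtxt(out / "ScanRMSD.dat")[:, 1]
        np.testing.assert_allclose(
            np.sqrt(np.mean(resid ** 2, axis=0)), scan_rmsd, atol=1e-6
        )
        # RI column is padded with NaN beyond n_scans rows
        assert np.isnan(dfr[n_scans:, 2]).all()
        assert not np.isnan(dfr[:n_scans, 2]).any()

    def test_failure_leaves_no_flag(self, session_env, tmp_path):
        config = _config(session_env, "fail")
        config.last_scan = 99  # scan files 11..99 do not exist
        with pytest.raises(FileNotFoundError):
            run_session(111, "shake-2", config)
        assert not (session_env / "donefail.txt").exists()

    def test_mode_112_rejects_extensions(self, session_env):
        config = _config(session_env, "m112")
        config.extra["Custom"] = "1"
        with pytest.raises(ProtocolError, match="112"):
            run_session(112, "h", config)
        config.extra.clear()
        config.regularization_type = "Tikhonov"
        with pytest.raises(ProtocolError, match="RegularizationType"):
            run_session(112, "h", config)
        assert not (session_env / "donem112.txt").exists()

    def test_concurrent_sessions_do_not_interfere(self, session_env):
        b1 = run_session(111, "first", _config(session_env, "c1"))
        b2 = run_session(111, "second", _config(session_env, "c2"))
        assert (session_env / "donec1.txt").read_text().rstrip("\n") == "first"
        assert (session_env / "donec2.txt").read_text().rstrip("\n") == "second"
        assert b1.fit.rmsd == pytest.approx(b2.fit.rmsd, rel=1e-12)


class TestDoneFlag:
    def test_contains_exactly_handshake(self, tmp_path):
        p = write_done_flag(tmp_path / "f.txt", "abc")
        assert p.read_text() == "abc\n"

    def test_preexisting_flag_is_contract_violation(self, tmp_path):
        write_done_flag(tmp_path / "f.txt", "abc")
        with pytest.raises(ProtocolError, match="exists"):
            write_done_flag(tmp_path / "f.txt", "abc")


class TestMain:
    def test_usage_error_exit_code(self, capsys):
        assert main(["111"]) == 1
        assert "error" in capsys.readouterr().err

    def test_cli_session(self, session_env, tmp_path):
        config = _config(session_env, "cli")
        xml = tmp_path / "in.xml"
        xml.write_text(serialize_config(config))
        assert main(["111", "cli-shake", str(xml)]) == 0
        assert (session_env / "donecli.txt").read_text().rstrip("\n") == "cli-shake"
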