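import json

import numpy as np
import pytest

from wpdcca import (FormatError, MetricsReport, PairedRecording, ParseError,
                    Recording, SchemaError, SynthConfig, generate_paired,
                    read_paired_csv, summarize_reports, write_metrics_json,
                    write_paired_csv)
from wpdcca.signal_io import read_metrics_json


def make_pair(n=64, fs=32.0):
    t = np.arange(n) / fs
    return PairedRecording(
        corrupted=Recording(np.sin(2 * np.pi * t) + 0.5, fs=fs),
        reference=Recording(np.sin(2 * np.pi * t), fs=fs),
        artifact_epochs=[(0.25, 0.75)],
    )


class TestRecordingInvariants:
    def test_rejects_nan_samples(self):
        with pytest.raises(FormatError):
            Recording(np.array([1.0, np.nan, 2.0]), fs=10.0)

    def test_rejects_nonpositive_fs(self):
        with pytest.raises(FormatError):
            Recording(np.array([1.0, 2.0]), fs=0.0)

    def test_rejects_single_sample(self):
        with pytest.raises(FormatError):
            Recording(np.array([1.0]), fs=10.0)

    def test_duration(self):
        rec = Recording(np.zeros(30), fs=10.0)
        assert rec.duration_s == pytest.approx(3.0)


class TestPairedInvariants:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(FormatError):
            PairedRecording(Recording(np.zeros(5), 10.0),
                            Recording(np.zeros(4), 10.0))

    def test_unequal_fs_rejected(self):
        with pytest.raises(FormatError):
            PairedRecording(Recording(np.zeros(5), 10.0),
                            Recording(np.zeros(5), 20.0))

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(FormatError):
            PairedRecording(Recording(np.zeros(50), 10.0),
                            Recording(np.zeros(50), 10.0),
                            artifact_epochs=[(0.0, 2.0), (1.0, 3.0)])

    def test_epoch_outside_record_rejected(self):
        with pytest.raises(FormatError):
            PairedRecording(Recording(np.zeros(50), 10.0),
                            Recording(np.zeros(50), 10.0),
                            artifact_epochs=[(4.0, 6.0)])


class TestPairedCsv:
    def test_identity_pair_roundtrip(self, tmp_path):
        path = tmp_path / "pair.csv"
        path.write_text("corrupted,reference\n1,1\n2,2\n3,3\n")
        pair = read_paired_csv(path, fs=10.0)
        assert pair.n_samples == 3
        assert pair.duration_s == pytest.approx(0.3)
        np.testing.assert_allclose(pair.corrupted.samples, [1, 2, 3])

    def test_shorter_reference_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("corrupted,reference\n1,1\n2,2\n3,\n")
        with pytest.raises(FormatError):
            read_paired_csv(path, fs=10.0)

    def test_nonnumeric_cell_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("corrupted,reference\n1,1\n2,x\n")
        with pytest.raises(ParseError):
            read_paired_csv(path, fs=10.0)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("corrupted,other\n1,1\n2,2\n")
        with pytest.raises(SchemaError):
            read_paired_csv(path, fs=10.0)

    def test_time_column_validated_against_fs(self, tmp_path):
        path = tmp_path / "pair.csv"
        path.write_text("time,corrupted,reference\n0.0,1,1\n0.5,2,2\n1.0,3,3\n")
        with pytest.raises(FormatError):
            read_paired_csv(path, fs=10.0)  # time implies 2 Hz
        pair = read_paired_csv(path, fs=2.0)
        assert pair.fs == 2.0

    def test_synthetic_roundtrip_preserves_samples_and_epochs(self, tmp_path):
        cfg = SynthConfig(duration_s=130.0, fs=64.0, artifact_interval_s=60.0,
                          artifact_duration_range_s=(5.0, 10.0), seed=3)
        pair = generate_paired(cfg)
        path = tmp_path / "pair.csv"
        write_paired_csv(pair, path)
        back = read_paired_csv(path, fs=64.0)
        np.testing.assert_allclose(back.corrupted.samples,
                                   pair.corrupted.samples, atol=1e-9)
        np.testing.assert_allclose(back.reference.samples,
                                   pair.reference.samples, atol=1e-9)
        assert back.artifact_epochs == pair.artifact_epochs

    def test_empty_epochs_sidecar(self, tmp_path):
        pair = make_pair()
        pair = PairedRecording(pair.corrupted, pair.reference, [])
        path = tmp_path / "pair.csv"
        write_paired_csv(pair, path)
        sidecar = json.loads((tmp_path / "pair.epochs.json").read_text())
        assert sidecar["artifact_epochs"] == []

    def test_row_count_matches_duration_times_rate(self, tmp_path):
        # 540 s at 256 Hz -> 138,240 data rows
        n = 540 * 256
        rng = np.random.default_rng(0)
        pair = PairedRecording(Recording(rng.standard_normal(n), 256.0),
                               Recording(rng.standard_normal(n), 256.0))
        path = tmp_path / "pair.csv"
        write_paired_csv(pair, path)
        with open(path) as fh:
            rows = sum(1 for _ in fh) - 1  # header
        assert rows == 138240


class TestMetricsJson:
    def test_roundtrip_field_equality(self, tmp_path):
        rep = MetricsReport(delta_snr_db=6.02, eta_pct=57.14, rho_before=0.6,
                            rho_after=0.8, method="WPD(db1) j=4",
                            extra={"removed_components": [0]})
        path = tmp_path / "rep.json"
        write_metrics_json(rep, path)
        back = read_metrics_json(path)
        assert back == rep
        assert round(back.delta_snr_db, 2) == 6.02

    def test_batch_summary_is_arithmetic_mean(self):
        reports = [MetricsReport(delta_snr_db=d, eta_pct=e, rho_before=0.5,
                                 rho_after=0.9, method="m")
                   for d, e in [(10.0, 40.0), (20.0, 50.0), (30.0, 75.0)]]
        s = summarize_reports(reports)
        assert s["n_records"] == 3
        assert s["mean_delta_snr_db"] == pytest.approx(20.0)
        assert s["mean_eta_pct"] == pytest.approx(55.0)
        assert s["sd_eta_pct"] == pytest.approx(np.std([40.0, 50.0, 75.0]))

    def test_rho_outside_unit_interval_rejected(self):
        with pytest.raises(FormatError):
            MetricsReport(delta_snr_db=0.0, eta_pct=0.0, rho_before=1.5,
                          rho_after=0.0, method="m")
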