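"""FCS 3.0 and CSV round trips, integer log decoding, and error reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import flowmrd as fm
from flowmrd.fcs import CSVError, FCSError


def _make_int_fcs(path, columns, pnb=16, pne=("0,0", "0,0"), pnr=(1024, 1024),
                  byteord="1,2,3,4", version=b"FCS3.0", mode="L"):
    """Hand-assemble an integer-datatype FCS 3.0 file for decode tests."""
    values = np.asarray(columns, dtype=np.uint64).T  # rows = events
    n_tot, n_par = values.shape
    dtype = {8: "u1", 16: "u2", 32: "u4"}[pnb]
    endian = "<" if byteord == "1,2,3,4" else ">"
    data = values.astype(f"{endian}{dtype}").tobytes()

    def text_for(data_beg):
        kv = [
            ("$BEGINDATA", str(data_beg)), ("$ENDDATA", str(data_beg + len(data) - 1)),
            ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
            ("$BYTEORD", byteord), ("$DATATYPE", "I"), ("$MODE", mode),
            ("$NEXTDATA", "0"), ("$PAR", str(n_par)), ("$TOT", str(n_tot)),
        ]
        for i in range(1, n_par + 1):
            kv += [(f"$P{i}B", str(pnb)), (f"$P{i}E", pne[i - 1]),
                   (f"$P{i}N", f"ch{i}"), (f"$P{i}R", str(pnr[i - 1]))]
        return ("/" + "".join(f"{k}/{v}/" for k, v in kv)).encode()

    data_beg = 58
    for _ in range(5):
        text = text_for(data_beg)
        if 58 + len(text) == data_beg:
            break
        data_beg = 58 + len(text)
    header = (version + b"    " + f"{58:>8d}".encode()
              + f"{58 + len(text) - 1:>8d}".encode()
              + f"{data_beg:>8d}".encode()
              + f"{data_beg + len(data) - 1:>8d}".encode()
              + b"       0" + b"       0")
    path.write_bytes(header + text + data)
    return path


class TestRoundTrip:
    def test_fcs_identity(self, small_matrix, tmp_path):
        got = fm.read_fcs(fm.write_fcs(small_matrix, tmp_path / "m.fcs"))
        assert np.array_equal(got.values, small_matrix.values)
        assert got.channel_names == ["FSC", "SSC"]
        assert got.channels[1].stain_name == "side"

    def test_empty_specimen(self, small_matrix, tmp_path):
        empty = fm.EventMatrix(np.empty((0, 2)), small_matrix.channels, "e")
        got = fm.read_fcs(fm.write_fcs(empty, tmp_path / "e.fcs"))
        assert got.n_events == 0
        assert got.channel_names == ["FSC", "SSC"]

    def test_large_synthetic_specimen(self, tmp_path):
        spec = fm.donor_spec(seed=9, n_events=100_000)
        events = fm.simulate_specimen(spec).events
        got = fm.read_fcs(fm.write_fcs(events, tmp_path / "big.fcs"))
        assert got.channel_names == list(fm.DEFAULT_CHANNELS)
        # values pass through float32 storage; compare against that cast
        assert np.array_equal(got.values, events.values.astype("<f4").astype(float))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(vals=arrays(np.float32, (7, 3),
                       elements=st.floats(0, 1e6, width=32, allow_nan=False)))
    def test_fcs_roundtrip_property(self, vals, tmp_path_factory):
        m = fm.EventMatrix(vals.astype(float),
                           [fm.ChannelInfo(n) for n in ("a", "b", "c")], "h")
        p = tmp_path_factory.mktemp("fcs") / "h.fcs"
        assert np.array_equal(fm.read_fcs(fm.write_fcs(m, p)).values, m.values)

    def test_csv_roundtrip(self, small_matrix, tmp_path):
        got = fm.read_csv(fm.export_csv(small_matrix, tmp_path / "m.csv"))
        assert got.channel_names == ["FSC", "SSC"]
        np.testing.assert_allclose(got.values, small_matrix.values, rtol=1e-9)

    def test_csv_layout(self, tmp_path):
        m = fm.EventMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]),
                           [fm.ChannelInfo("FSC"), fm.ChannelInfo("SSC")], "x")
        lines = fm.export_csv(m, tmp_path / "x.csv").read_text().splitlines()
        assert lines[0] == "FSC,SSC"
        assert [float(v) for v in lines[1].split(",")] == [1.0, 2.0]
        assert [float(v) for v in lines[2].split(",")] == [3.0, 4.0]


class TestIntegerDecode:
    def test_log_amplified_decode(self, tmp_path):
        # stored count 512 with 4 decades over range 1024 -> 10^(4*512/1024) = 100
        p = _make_int_fcs(tmp_path / "log.fcs", columns=[[512, 256], [0, 1024]],
                          pne=("4.0,0.0", "0,0"))
        got = fm.read_fcs(p)
        np.testing.assert_allclose(got.values[:, 0], [100.0, 10.0 ** (4 * 256 / 1024)])
        # linear channel passes through unchanged
        np.testing.assert_array_equal(got.values[:, 1], [0.0, 1024.0])

    def test_decode_matches_closed_form_everywhere(self, tmp_path):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 1024, size=(2, 50))
        p = _make_int_fcs(tmp_path / "r.fcs", columns=raw,
                          pne=("3.5,0.0", "2.0,0.0"), pnr=(1024, 512))
        got = fm.read_fcs(p)
        np.testing.assert_allclose(got.values[:, 0], 10.0 ** (3.5 * raw[0] / 1024))
        np.testing.assert_allclose(got.values[:, 1], 10.0 ** (2.0 * raw[1] / 512))

    def test_big_endian_integer(self, tmp_path):
        p = _make_int_fcs(tmp_path / "be.fcs", columns=[[7, 300], [1, 2]],
                          byteord="4,3,2,1")
        np.testing.assert_array_equal(fm.read_fcs(p).values,
                                      [[7.0, 1.0], [300.0, 2.0]])


class TestErrors:
    def test_unsupported_version(self, tmp_path):
        p = _make_int_fcs(tmp_path / "v2.fcs", columns=[[1, 2], [3, 4]],
                          version=b"FCS2.0")
        with pytest.raises(FCSError, match="FCS2.0"):
            fm.read_fcs(p)

    def test_non_list_mode(self, tmp_path):
        p = _make_int_fcs(tmp_path / "u.fcs", columns=[[1, 2], [3, 4]], mode="U")
        with pytest.raises(FCSError, match=r"\$MODE"):
            fm.read_fcs(p)

    def test_truncated_data_segment(self, small_matrix, tmp_path):
        p = fm.write_fcs(small_matrix, tmp_path / "t.fcs")
        p.write_bytes(p.read_bytes()[:-5])
        with pytest.raises(FCSError, match="truncated"):
            fm.read_fcs(p)

    def test_tot_inconsistent_with_data(self, small_matrix, tmp_path):
        p = fm.write_fcs(small_matrix, tmp_path / "t.fcs")
        blob = p.read_bytes().replace(b"$TOT/3/", b"$TOT/9/")
        p.write_bytes(blob)
        with pytest.raises(FCSError, match=r"\$TOT"):
            fm.read_fcs(p)

    def test_duplicate_channel_names_rejected(self):
        with pytest.raises(FCSError, match="duplicate"):
            fm.EventMatrix(np.ones((2, 2)),
                           [fm.ChannelInfo("CD7"), fm.ChannelInfo("CD7")], "d")

    def test_csv_missing_cell_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("FSC,SSC\n1,2\n3,4\n5,6\n7,8\n9\n")
        with pytest.raises(CSVError, match="row 5"):
            fm.read_csv(p)

    def test_csv_non_numeric_cell(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("FSC,SSC\n1,2\n3,oops\n")
        with pytest.raises(CSVError, match="row 2"):
            fm.read_csv(p)
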