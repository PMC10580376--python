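"""Calibration, sampling and persistence of incidence models."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import airrshare as a
from airrshare import ModelUnusableError, ValidationError
from airrshare.incidence import IncidenceModel


def _receptor(tag, pgen):
    return a.Receptor(f"CASS{tag}F", "V1", "J1", pgen)


TWO_BY_TWO = dict(
    pgen_binning=a.PgenBinning((-6.0,)),
    incidence_binning=a.IncidenceBinning((0.0, 0.1, 1.0)),
)


class TestBinning:
    def test_pgen_bins_are_half_open_and_clamped(self):
        b = a.PgenBinning((-12.0, -9.0, -6.0))
        assert b.n_bins == 4
        assert b.bin_of(1e-13) == 0  # below first edge clamps down
        assert b.bin_of(1e-12) == 1  # left-closed
        assert b.bin_of(10 ** -9.0) == 2
        assert b.bin_of(1e-3) == 3  # above last edge clamps up
        assert b.bin_of(0.0) == 0

    def test_incidence_bins_left_closed_right_open(self):
        b = a.IncidenceBinning((0.0, 0.02, 0.05, 1.0))
        assert b.bin_of(0.0) == 0
        assert b.bin_of(0.02) == 1
        assert b.bin_of(0.049999) == 1
        assert b.bin_of(1.0) == 2  # top bin closed at 1

    def test_monotone_support(self):
        # increasing an observed count never moves a sequence to a lower bin
        b = a.IncidenceBinning()
        n = 500
        bins = [b.bin_of(c / n) for c in range(2, n + 1)]
        assert all(x <= y for x, y in zip(bins, bins[1:]))


class TestCalibrate:
    def test_point_mass_single_cell(self):
        # 10 public sequences, one pgen bin, all seen in 2 of 200 repertoires
        occ = {_receptor(a.AMINO_ACIDS[i] * 2, 1e-8): 2 for i in range(10)}
        sig, pub = a.calibrate(occ, 200, None)
        row = pub.table[pub.pgen_binning.bin_of(1e-8)]
        ibin = pub.incidence_binning.bin_of(2 / 200)
        assert row[ibin] == 1.0
        assert row.sum() == pytest.approx(1.0)

    def test_empty_signal_ids_leaves_signal_component_empty(self):
        occ = {_receptor("AA", 1e-8): 3}
        sig, pub = a.calibrate(occ, 100, None, signal_ids=())
        assert all(sig.row_is_empty(i) for i in range(sig.pgen_binning.n_bins))
        assert not pub.row_is_empty(pub.pgen_binning.bin_of(1e-8))

    def test_hand_tallied_two_by_two(self):
        # oracle: manual tally. pgen bins split at 1e-6; incidence at 0.1.
        occ = {
            _receptor("AA", 1e-8): 4,   # low pgen, low incidence
            _receptor("CC", 1e-8): 20,  # low pgen, high incidence
            _receptor("DD", 1e-8): 5,   # low pgen, low incidence
            _receptor("EE", 1e-3): 30,  # high pgen, high incidence
            _receptor("FF", 1e-3): 2,   # high pgen, low incidence
            _receptor("GG", 1e-3): 50,  # high pgen, high incidence
        }
        sig, pub = a.calibrate(occ, 100, None, **TWO_BY_TWO)
        np.testing.assert_allclose(pub.table, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])

    def test_signal_uses_positive_denominator(self):
        # count 30 of 100 positives lands in a higher bin than 30 of 300 total
        sig_rec = _receptor("AA", 1e-8)
        occ = {sig_rec: 30}
        sig, _ = a.calibrate(
            occ, 300, None, signal_ids={sig_rec}, signal_denominator=100,
            **TWO_BY_TWO,
        )
        assert sig.table[0, 1] == 1.0  # 30/100 = 0.3 -> high bin

    def test_count_below_two_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            a.calibrate({_receptor("AA", 1e-8): 1}, 100, None)

    def test_count_above_denominator_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            a.calibrate({_receptor("AA", 1e-8): 101}, 100, None)

    def test_missing_pgen_lists_offenders(self):
        rec = a.Receptor("CASSQQF", "V1", "J1")  # no pgen annotation
        with pytest.raises(ValidationError, match="CASSQQF"):
            a.calibrate({rec: 5}, 100, None)

    def test_smaller_cohorts_inflate_incidence_estimates(self):
        # fixed true per-repertoire carriage probability; at n=50 only the
        # luckier sequences clear the publicness threshold, biasing the
        # learned incidence fractions upward relative to n=500
        rng = np.random.default_rng(0)
        q = 0.03  # true carriage probability per repertoire
        means = {}
        for n in (50, 500):
            occ = {}
            for i in range(4000):
                c = rng.binomial(n, q)
                if c >= 2:
                    occ[_receptor(f"{'AG'[i % 2]}{i:05d}".translate(
                        str.maketrans("0123456789", "ACDEFGHIKL")), 1e-8)] = c
            _, pub = a.calibrate(occ, n, None)
            # mean incidence fraction implied by the learned row
            row = pub.table[pub.pgen_binning.bin_of(1e-8)]
            mids = [
                (l + r) / 2 for l, r in zip(
                    pub.incidence_binning.edges[:-1], pub.incidence_binning.edges[1:]
                )
            ]
            means[n] = float(np.dot(row, mids))
        assert means[50] > means[500]


class TestSampleIncidenceCount:
    def _point_mass_model(self, lo, hi):
        binning = a.IncidenceBinning((0.0, lo, hi, 1.0))
        table = np.zeros((2, 3))
        table[:, 1] = 1.0
        return IncidenceModel(a.PgenBinning((-6.0,)), binning, table, "public")

    def test_degenerate_row_gives_fixed_count(self, rng):
        model = self._point_mass_model(0.10, 0.1000001)
        for _ in range(20):
            assert a.sample_incidence_count(model, 1e-8, 100, rng) == 10

    def test_counts_never_below_two(self, rng):
        model = self._point_mass_model(0.0001, 0.001)
        counts = [a.sample_incidence_count(model, 1e-8, 100, rng) for _ in range(200)]
        assert min(counts) == 2

    def test_bin_frequencies_match_row(self, rng):
        # row 90% below 2%, 10% in [2%,10%): check the 10% arm at 3 SE
        binning = a.IncidenceBinning((0.0, 0.02, 0.1, 1.0))
        model = IncidenceModel(
            a.PgenBinning((-6.0,)), binning,
            np.array([[0.9, 0.1, 0.0], [0.9, 0.1, 0.0]]), "public",
        )
        n_draws = 10_000
        counts = np.array([
            a.sample_incidence_count(model, 1e-8, 1000, rng)
            for _ in range(n_draws)
        ])
        # count >= 21 requires fraction >= 0.0205, reachable only from the
        # high bin: p = 0.1 x (0.1 - 0.0205) / 0.08 (uniform within the bin)
        p0 = 0.1 * (0.1 - 0.0205) / 0.08
        frac_high = np.mean(counts >= 21)
        se = np.sqrt(p0 * (1 - p0) / n_draws)
        assert abs(frac_high - p0) < 3 * se

    def test_empty_row_borrows_lower_bin(self, rng):
        table = np.zeros((2, 3))
        table[0, 1] = 1.0  # only the low-pgen row is populated
        model = IncidenceModel(
            a.PgenBinning((-6.0,)), a.IncidenceBinning((0.0, 0.1, 0.2, 1.0)),
            table, "public", row_counts=np.array([5, 0]),
        )
        c = a.sample_incidence_count(model, 1e-3, 100, rng)  # high-pgen query
        assert 10 <= c <= 20

    def test_all_rows_empty_is_unusable(self, rng):
        model = IncidenceModel(
            a.PgenBinning((-6.0,)), a.IncidenceBinning((0.0, 0.1, 1.0)),
            np.zeros((2, 2)), "public", row_counts=np.zeros(2, dtype=int),
        )
        with pytest.raises(ModelUnusableError):
            a.sample_incidence_count(model, 1e-8, 100, rng)


class TestMaxIncidenceFraction:
    def test_single_bin(self):
        model = IncidenceModel(
            a.PgenBinning((-6.0,)), a.IncidenceBinning((0.0, 0.02, 1.0)),
            np.array([[1.0, 0.0], [1.0, 0.0]]), "public",
        )
        assert a.max_incidence_fraction(model, 1e-8) == 0.02

    def test_highest_nonzero_bin_wins(self):
        model = IncidenceModel(
            a.PgenBinning((-6.0,)),
            a.IncidenceBinning((0.0, 0.02, 0.2, 0.3, 1.0)),
            np.array([[0.5, 0.0, 0.5, 0.0]] * 2), "public",
        )
        assert a.max_incidence_fraction(model, 1e-8) == 0.3

    def test_fixture_signal_model_caps_at_30_percent(self, signal_model):
        # the bundled signal component never allows >30% population incidence
        for pgen in (1e-14, 1e-11, 1e-8, 1e-4):
            assert a.max_incidence_fraction(signal_model, pgen) == 0.3


class TestPersistence:
    def test_json_round_trip(self, signal_model, tmp_path):
        path = tmp_path / "m.json"
        a.save_model(signal_model, path)
        assert a.load_model(path) == signal_model

    def test_tsv_round_trip_with_empty_row(self, tmp_path):
        table = np.zeros((2, 2))
        table[0] = [0.25, 0.75]
        model = IncidenceModel(
            a.PgenBinning((-6.0,)), a.IncidenceBinning((0.0, 0.1, 1.0)),
            table, "signal", row_counts=np.array([4, 0]),
        )
        path = tmp_path / "m.tsv"
        a.save_model(model, path)
        loaded = a.load_model(path)
        assert loaded == model
        assert loaded.row_is_empty(1)

    def test_unnormalized_row_names_the_row(self, tmp_path):
        import json

        doc = {
            "version": 1, "component_label": "public",
            "pgen_log10_edges": [-6.0],
            "incidence_edges": [0.0, 0.1, 1.0],
            "rows": [[0.5, 0.3], [0.5, 0.5]],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="row 0"):
            a.load_model(path)

    def test_unknown_version_rejected(self, tmp_path):
        import json

        doc = {
            "version": 99, "component_label": "public",
            "pgen_log10_edges": [-6.0],
            "incidence_edges": [0.0, 1.0],
            "rows": [[1.0], [1.0]],
        }
        path = tmp_path / "v99.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="version"):
            a.load_model(path)

    def test_hand_written_two_by_two_loads_verbatim(self, tmp_path):
        path = tmp_path / "hand.json"
        path.write_text(
            '{"version": 1, "component_label": "signal",'
            ' "pgen_log10_edges": [-9.0],'
            ' "incidence_edges": [0.0, 0.05, 1.0],'
            ' "rows": [[0.75, 0.25], [0.1, 0.9]]}'
        )
        model = a.load_model(path)
        np.testing.assert_array_equal(model.table, [[0.75, 0.25], [0.1, 0.9]])
        assert model.component_label == "signal"


@given(count=st.integers(min_value=2, max_value=500))
def test_bin_of_count_fraction_is_monotone(count):
    b = a.IncidenceBinning()
    assert b.bin_of(count / 500) <= b.bin_of(min(count + 1, 500) / 500)
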