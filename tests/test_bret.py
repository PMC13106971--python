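"""BRET-efficiency readout, phase/modulation, per-cell and series tables."""

import numpy as np
import pandas as pd
import pytest

import lumiphasor as lp


AXIS = lp.BretAxis(donor=(0.2, 0.7), acceptor=(-0.7, 0.3))


class TestBretEfficiency:
    def test_endpoints(self):
        assert lp.bret_efficiency(*AXIS.donor, AXIS) == pytest.approx(0.0, abs=1e-12)
        assert lp.bret_efficiency(*AXIS.acceptor, AXIS) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_along_chord(self):
        ts = np.linspace(0, 1, 11)
        pts_g = AXIS.donor[0] + ts * (AXIS.acceptor[0] - AXIS.donor[0])
        pts_s = AXIS.donor[1] + ts * (AXIS.acceptor[1] - AXIS.donor[1])
        eff = lp.bret_efficiency(pts_g, pts_s, AXIS)
        np.testing.assert_allclose(eff, ts, atol=1e-12)
        assert (np.diff(eff) > 0).all()

    def test_degenerate_axis_rejected(self):
        with pytest.raises(lp.ParameterError):
            lp.BretAxis(donor=(0.1, 0.1), acceptor=(0.1, 0.1))

    def test_nan_propagates(self):
        eff = lp.bret_efficiency(np.array([np.nan, 0.2]), np.array([0.1, 0.7]), AXIS)
        assert np.isnan(eff[0]) and np.isfinite(eff[1])

    def test_simulated_sensor_recovers_photon_fraction(self, filters, library):
        """A noiseless sensor with acceptor photon fraction E reads back E
        through the full pipeline, to 1e-9 (linearity of the transform)."""
        spectra = lp.library_spectra(library)
        axis = lp.BretAxis.from_spectra(spectra["NanoLuc"], spectra["mNeonGreen"])
        for e in (0.0, 0.4, 1.0):
            sensor = lp.ReporterModel(
                "sensor", spectra["NanoLuc"], spectra["mNeonGreen"], efficiency=e
            )
            scene = lp.Scene(16, 16, [lp.CellSpec((8, 8), 5, "sensor", 400.0)])
            ph, _ = lp.simulate_phasor(
                scene, {"sensor": sensor}, filters, lp.CameraModel.ideal(),
                n_frames=1, noise=False,
            )
            eff = lp.bret_efficiency(ph.g[ph.mask], ph.s[ph.mask], axis)
            np.testing.assert_allclose(eff, e, atol=1e-9)


class TestPhaseModulation:
    @pytest.mark.parametrize(
        "g,s,phase,mod",
        [
            (1.0, 0.0, 0.0, 1.0),
            (0.0, 1.0, np.pi / 2, 1.0),
            (-0.3, -0.3, -3 * np.pi / 4, 0.3 * np.sqrt(2)),
            (0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_closed_form_values(self, g, s, phase, mod):
        p, m = lp.phase_modulation(g, s)
        assert p == pytest.approx(phase, abs=1e-12)
        assert m == pytest.approx(mod, abs=1e-12)

    def test_polar_round_trip(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(-0.7, 0.7, 100)
        s = rng.uniform(-0.7, 0.7, 100)
        phase, mod = lp.phase_modulation(g, s)
        np.testing.assert_allclose(mod * np.cos(phase), g, atol=1e-12)
        np.testing.assert_allclose(mod * np.sin(phase), s, atol=1e-12)


class TestPerCellStats:
    def make_phasor(self, g_vals, labels, intensity=None):
        g = np.asarray(g_vals, dtype=float)
        s = np.zeros_like(g)
        labels = np.asarray(labels, dtype=np.int32)
        mask = labels > 0
        inten = np.ones_like(g) if intensity is None else np.asarray(intensity, float)
        return lp.PhasorImage(g=g, s=s, intensity=inten, mask=mask, labels=labels)

    def test_uniform_cell_mean_equals_pixel_value(self):
        ph = self.make_phasor([[0.4, 0.4], [0.4, 0.0]], [[1, 1], [1, 0]])
        table = lp.per_cell_stats(ph)
        assert len(table) == 1
        assert table.loc[0, "g"] == pytest.approx(0.4)
        assert table.loc[0, "area"] == 3

    def test_intensity_weighting_scale_invariant(self):
        g = [[0.2, 0.8]]
        labels = [[1, 1]]
        t1 = lp.per_cell_stats(self.make_phasor(g, labels, intensity=[[1.0, 3.0]]))
        t2 = lp.per_cell_stats(self.make_phasor(g, labels, intensity=[[2.0, 6.0]]))
        assert t1.loc[0, "g"] == pytest.approx(0.65)
        assert t2.loc[0, "g"] == pytest.approx(t1.loc[0, "g"], abs=1e-12)

    def test_empty_labeling_gives_empty_table(self):
        ph = self.make_phasor([[0.1]], [[0]])
        assert len(lp.per_cell_stats(ph)) == 0

    def test_two_cells_with_distinct_efficiencies(self, filters, library):
        """Cells expressing sensors at E=0.2 and E=0.7 recovered within
        0.02 per cell at 1e4 aggregate photons/pixel."""
        spectra = lp.library_spectra(library)
        donor, acceptor = spectra["NanoLuc"], spectra["mNeonGreen"]
        axis = lp.BretAxis.from_spectra(donor, acceptor)
        lib = {
            "low": lp.ReporterModel("low", donor, acceptor, efficiency=0.2),
            "high": lp.ReporterModel("high", donor, acceptor, efficiency=0.7),
        }
        scene = lp.Scene(
            32, 32,
            [
                lp.CellSpec((9, 9), 6, "low", 500.0),
                lp.CellSpec((23, 23), 6, "high", 500.0),
            ],
        )
        cam = lp.CameraModel(dark_offset=100.0, read_noise_sd=1.5)
        ph, truth = lp.simulate_phasor(
            scene, lib, filters, cam, n_frames=20, seed=15, noise=True, sigma=1.0
        )
        ph.labels = truth.labels * ph.mask
        table = lp.per_cell_stats(ph, axis=axis).set_index("cell_id")
        assert table.loc[1, "efficiency"] == pytest.approx(0.2, abs=0.02)
        assert table.loc[2, "efficiency"] == pytest.approx(0.7, abs=0.02)


class TestSeriesAssemble:
    def cell_row(self, cell_id, time, row, col, eff=0.5):
        rec = {}
        rec.update(
            cell_id=cell_id, area=10, centroid_row=row, centroid_col=col,
            g=0.0, s=0.0, efficiency=eff, phase=0.0, modulation=0.0,
            total_intensity=100.0, time=time, depth=0,
        )
        return rec

    def table(self, rows):
        from lumiphasor.bret import CELL_COLUMNS

        return pd.DataFrame(rows, columns=CELL_COLUMNS)

    def test_static_cell_tracked_over_time(self):
        tables = [
            self.table([self.cell_row(1, t, 10.0, 10.0)]) for t in range(5)
        ]
        series = lp.series_assemble(tables)
        assert len(series) == 5
        assert series["track_id"].nunique() == 1

    def test_absent_time_point_leaves_gap(self):
        tables = [
            self.table([self.cell_row(1, 0, 10.0, 10.0)]),
            self.table([]),  # cell absent: no row, no imputation
            self.table([self.cell_row(1, 2, 10.5, 10.2)]),
        ]
        series = lp.series_assemble(tables)
        assert len(series) == 2
        assert series["track_id"].nunique() == 1
        assert set(series["time"]) == {0, 2}

    def test_distant_cell_starts_new_track(self):
        tables = [
            self.table([self.cell_row(1, 0, 10.0, 10.0)]),
            self.table([self.cell_row(1, 1, 40.0, 40.0)]),
        ]
        series = lp.series_assemble(tables, match_radius=10.0)
        assert series["track_id"].nunique() == 2

    def test_ambiguous_match_flagged(self):
        tables = [
            self.table(
                [self.cell_row(1, 0, 10.0, 10.0), self.cell_row(2, 0, 14.0, 10.0)]
            ),
            self.table([self.cell_row(1, 1, 11.0, 10.0)]),
        ]
        with pytest.warns(UserWarning, match="ambiguous"):
            series = lp.series_assemble(tables, match_radius=10.0)
        t1 = series[series["time"] == 1]
        assert bool(t1["ambiguous_match"].iloc[0])

    def test_simulated_cleavage_time_course_monotone(self, filters, library):
        """Sensor efficiency falling 0.8 -> 0.1 over 8 steps: the recovered
        per-cell series is strictly decreasing with max error < 0.02."""
        spectra = lp.library_spectra(library)
        donor, acceptor = spectra["NanoLuc"], spectra["mNeonGreen"]
        axis = lp.BretAxis.from_spectra(donor, acceptor)
        cam = lp.CameraModel(dark_offset=100.0, read_noise_sd=1.5)
        efficiencies = np.linspace(0.8, 0.1, 8)
        tables = []
        for t, e in enumerate(efficiencies):
            lib = {"sensor": lp.ReporterModel("sensor", donor, acceptor, efficiency=e)}
            scene = lp.Scene(20, 20, [lp.CellSpec((10, 10), 6, "sensor", 500.0)])
            ph, truth = lp.simulate_phasor(
                scene, lib, filters, cam, n_frames=20, seed=300 + t,
                noise=True, sigma=1.0,
            )
            ph.labels = truth.labels * ph.mask
            tables.append(lp.per_cell_stats(ph, axis=axis, time=t))
        series = lp.series_assemble(tables)
        eff = series.sort_values("time")["efficiency"].to_numpy()
        assert len(eff) == 8
        np.testing.assert_allclose(eff, efficiencies, atol=0.02)
        assert (np.diff(eff) < 0).all()
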