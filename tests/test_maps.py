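"""Isopotential/isointegral maps, grid interpolation, trace rendering."""

import dataclasses

import numpy as np
import pytest
from lxml import etree

from xmlbspm.equations import SignalMatrix, resolve_signals
from xmlbspm.errors import MapError
from xmlbspm.maps import (
    PotentialMap,
    interpolate_grid,
    isointegral,
    isopotential,
    render_traces_svg,
    st40_map,
)
from xmlbspm.model import Annotations, LeadAnnotation


def matrix(values, freq=1000.0):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return SignalMatrix(
        values=values,
        lead_ids=list(range(1, n + 1)),
        x=np.arange(n, dtype=float),
        y=np.zeros(n),
        frequency_hz=freq,
    )


class TestIsopotential:
    def test_constant_signal_gives_constant_map(self):
        sig = matrix(np.full((5, 10), 3.25))
        pmap = isopotential(sig, 4.2)
        np.testing.assert_array_equal(pmap.values, np.full(5, 3.25))
        assert pmap.units == "uV"

    def test_t_zero_is_first_sample(self):
        sig = matrix([[7.0, 1.0, 1.0], [9.0, 2.0, 2.0]])
        np.testing.assert_array_equal(isopotential(sig, 0.0).values, [7.0, 9.0])

    def test_40ms_at_1000hz_is_index_40(self):
        values = np.zeros((1, 100))
        values[0, 40] = 5.0
        assert isopotential(matrix(values), 40.0).values[0] == 5.0

    def test_round_half_up_indexing(self):
        values = np.zeros((1, 10))
        values[0, 3] = 1.0
        # 2.5 ms at 1000 Hz -> index 3 under half-up rounding
        assert isopotential(matrix(values), 2.5).values[0] == 1.0

    def test_out_of_range_instant(self):
        with pytest.raises(MapError):
            isopotential(matrix(np.zeros((2, 10))), 10.0)  # duration is exactly 10 ms
        with pytest.raises(MapError):
            isopotential(matrix(np.zeros((2, 10))), -1.0)


class TestIsointegral:
    def test_constant_one_microvolt_over_100ms(self):
        sig = matrix(np.ones((3, 200)))
        pmap = isointegral(sig, 0.0, 100.0)
        np.testing.assert_array_equal(pmap.values, np.full(3, 100.0))
        assert pmap.units == "uV.ms"

    def test_halving_frequency_doubles_integral(self):
        values = np.random.default_rng(0).normal(size=(4, 50))
        full = isointegral(matrix(values, freq=1000.0), 0.0, 50.0)
        half = isointegral(matrix(values, freq=500.0), 0.0, 100.0)
        np.testing.assert_allclose(half.values, 2 * full.values)

    def test_zero_mean_beat_integrates_near_zero(self, lux_signals):
        centred = dataclasses.replace(
            lux_signals,
            values=lux_signals.values - lux_signals.values.mean(axis=1, keepdims=True),
        )
        window = (0.0, centred.n_samples * 1000.0 / centred.frequency_hz)
        net = isointegral(centred, *window).values
        gross = isointegral(
            dataclasses.replace(centred, values=np.abs(centred.values)), *window
        ).values
        assert np.all(np.abs(net) < 0.01 * gross + 1e-9)

    def test_additivity_over_adjacent_windows_is_exact(self, lux_doc):
        # stored-unit BSPM signals are integer-valued, so every rectangle-rule
        # partial sum is exact in float64 and window additivity has zero error
        values = np.array([lead.samples for lead in lux_doc.leads], dtype=float)
        sig = matrix(values)
        a = isointegral(sig, 0.0, 130.0).values
        b = isointegral(sig, 130.0, 600.0).values
        c = isointegral(sig, 0.0, 600.0).values
        np.testing.assert_array_equal(a + b, c)

    def test_additivity_on_physical_units_to_rounding(self, lux_signals):
        a = isointegral(lux_signals, 0.0, 130.0).values
        b = isointegral(lux_signals, 130.0, 600.0).values
        c = isointegral(lux_signals, 0.0, 600.0).values
        np.testing.assert_allclose(a + b, c, rtol=1e-12, atol=1e-9)

    def test_empty_window_rejected(self):
        sig = matrix(np.ones((2, 100)))
        with pytest.raises(MapError):
            isointegral(sig, 50.0, 50.0)
        with pytest.raises(MapError):
            isointegral(sig, 50.0, 50.2)  # rounds to the same index


class TestSt40:
    def test_wildcard_offset_maps_to_offset_plus_40ms(self, lux_doc, lux_signals):
        qrs_offset = lux_doc.header.annotations.lead_annotations[0].markers["qrsOffset"][0]
        pmap = st40_map(lux_doc, lux_signals)
        expected = isopotential(lux_signals, qrs_offset + 40.0)  # 1000 Hz: idx == ms
        np.testing.assert_array_equal(pmap.values, expected.values)

    def test_missing_annotations_is_error(self, lux_doc, lux_signals):
        doc = dataclasses.replace(lux_doc)
        doc.header = dataclasses.replace(doc.header, annotations=None)
        with pytest.raises(MapError, match="qrsOffset"):
            st40_map(doc, lux_signals)

    def test_per_lead_markers_shift_only_their_electrodes(self, lux_doc, lux_signals):
        wildcard = st40_map(lux_doc, lux_signals)
        offset = lux_doc.header.annotations.lead_annotations[0].markers["qrsOffset"][0]
        doc = dataclasses.replace(lux_doc)
        doc.header = dataclasses.replace(
            doc.header,
            annotations=Annotations(
                lead_annotations=[
                    LeadAnnotation("*", {"qrsOffset": [offset]}),
                    LeadAnnotation("7", {"qrsOffset": [offset - 10]}),
                ]
            ),
        )
        shifted = st40_map(doc, lux_signals)
        i7 = lux_signals.lead_ids.index(7)
        expected_shift = isopotential(lux_signals, (offset - 10) + 40.0).values[i7]
        assert shifted.values[i7] == expected_shift
        mask = np.ones(len(wildcard.values), dtype=bool)
        mask[i7] = False
        np.testing.assert_array_equal(shifted.values[mask], wildcard.values[mask])


def square_map(values):
    return PotentialMap(
        kind="isopotential",
        lead_ids=[1, 2, 3, 4],
        x=np.array([0.0, 1.0, 0.0, 1.0]),
        y=np.array([0.0, 0.0, 1.0, 1.0]),
        values=np.asarray(values, dtype=float),
        time_spec=0.0,
        units="uV",
    )


class TestInterpolateGrid:
    def test_constant_field_everywhere(self):
        raster = interpolate_grid(square_map([4.5] * 4), 9, 9).values
        inside = raster[~np.isnan(raster)]
        assert inside.size > 0
        np.testing.assert_allclose(inside, 4.5, rtol=1e-12)

    def test_electrode_positions_reproduce_values(self):
        pmap = square_map([1.0, 2.0, 3.0, 4.0])
        raster = interpolate_grid(pmap, 2, 2).values  # grid nodes == corners
        np.testing.assert_allclose(raster.ravel(), [1.0, 2.0, 3.0, 4.0], atol=1e-9)

    def test_center_of_unit_square_plane(self):
        # values = y-plane: every triangulation interpolates exactly y
        pmap = square_map([0.0, 0.0, 1.0, 1.0])
        raster = interpolate_grid(pmap, 3, 3).values
        assert raster[1, 1] == pytest.approx(0.5, abs=1e-12)

    def test_maximum_principle(self, lux_signals):
        pmap = isopotential(lux_signals, 225.0)
        raster = interpolate_grid(pmap, 40, 30).values
        inside = raster[~np.isnan(raster)]
        assert inside.min() >= pmap.values.min() - 1e-9
        assert inside.max() <= pmap.values.max() + 1e-9

    def test_wrap_horizontal_covers_the_seam(self, lux_signals):
        pmap = isopotential(lux_signals, 225.0)
        plain = interpolate_grid(pmap, 40, 30).values
        wrapped = interpolate_grid(pmap, 40, 30, wrap_horizontal=True, width=1000.0).values
        assert np.isnan(wrapped).sum() <= np.isnan(plain).sum()

    def test_collinear_electrodes_rejected(self):
        pmap = PotentialMap(
            kind="isopotential",
            lead_ids=[1, 2, 3],
            x=np.array([0.0, 1.0, 2.0]),
            y=np.array([0.0, 0.0, 0.0]),
            values=np.array([1.0, 2.0, 3.0]),
            time_spec=0.0,
            units="uV",
        )
        with pytest.raises(MapError):
            interpolate_grid(pmap, 5, 5)


class TestRenderTraces:
    def test_one_polyline_per_lead(self, lux_doc, lux_signals):
        svg = render_traces_svg(lux_doc, lux_signals)
        root = etree.fromstring(svg)  # well-formed
        polylines = root.findall(".//{*}polyline")
        assert len(polylines) == 192
        ids = {el.get("id") for el in polylines}
        assert ids == {f"lead-{lead.lead_id}" for lead in lux_doc.leads}

    @pytest.mark.parametrize("wave_scale", [0.04, 0.1])
    def test_vertical_extent_scales_with_wavescale(self, lux_doc, wave_scale):
        doc = dataclasses.replace(lux_doc)
        doc.header = dataclasses.replace(doc.header)
        doc.header.diagram = dataclasses.replace(doc.header.diagram, wave_scale=wave_scale)
        sig = resolve_signals(doc)
        svg = render_traces_svg(doc, sig)
        root = etree.fromstring(svg)
        el = root.find(".//{*}polyline[@id='lead-1']")
        ys = [float(p.split(",")[1]) for p in el.get("points").split()]
        signal = sig.row(1)
        expected = (signal.max() - signal.min()) * wave_scale
        assert max(ys) - min(ys) == pytest.approx(expected, abs=0.05)
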