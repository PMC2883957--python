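"""Isopotential / isointegral map computation and scalar-trace rendering.

An isopotential map is the per-electrode potential field at one instant; an
isointegral map is the per-electrode time integral of potential over a
window (microvolt-milliseconds).  The ST40 map — the isopotential field
40 ms after QRS offset — is a common aid in assessing ischaemia and is
derived from the document's beat-marker annotations.

Conventions: the time-to-index mapping is round-half-up (sub-sample
behaviour is otherwise unspecified in the format); integration uses the
rectangle rule, under which window additivity holds exactly; in rendered
SVG a positive deflection is drawn upward, i.e. toward decreasing SVG y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lxml import etree
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .errors import MapError
from .equations import SignalMatrix
from .model import BspmDocument, resolve_lead_annotation
from .xmlio import resolve_diagram

__all__ = [
    "PotentialMap",
    "GridRaster",
    "isopotential",
    "isointegral",
    "st40_map",
    "interpolate_grid",
    "render_traces_svg",
]

#: Default stroke colours per thoracic location class for rendered traces.
LOCATION_COLOURS = {"A": "#c0392b", "P": "#2980b9", "LL": "#27ae60", "RL": "#8e44ad"}


@dataclass
class PotentialMap:
    """Per-electrode scalar field with its provenance.

    ``kind`` is ``"isopotential"`` (units microvolts, ``time_spec`` an
    instant in ms) or ``"isointegral"`` (units microvolt-ms, ``time_spec``
    a ``(t0, t1)`` window in ms).  One entry per resolved lead, coordinates
    copied from the leads.
    """

    kind: str
    lead_ids: list[int]
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    time_spec: object
    units: str


@dataclass
class GridRaster:
    """Interpolated raster for contouring: ``values[iy, ix]`` over the box
    ``[x0, x1] x [y0, y1]``; cells outside the electrode hull are NaN."""

    values: np.ndarray
    x0: float
    x1: float
    y0: float
    y1: float


def _time_to_index(t_ms: float, frequency_hz: float) -> int:
    # round-half-up, not banker's rounding
    return math.floor(t_ms * frequency_hz / 1000.0 + 0.5)


def isopotential(signals: SignalMatrix, t_ms: float, frequency_hz: Optional[float] = None) -> PotentialMap:
    """Per-electrode potential at instant ``t_ms`` (milliseconds).

    The sample index is ``round(t_ms * f / 1000)`` (half-up); no sub-sample
    interpolation is performed.
    """
    f = frequency_hz if frequency_hz is not None else signals.frequency_hz
    duration_ms = signals.n_samples / f * 1000.0
    if not (0 <= t_ms < duration_ms):
        raise MapError(f"instant {t_ms} ms outside record duration [0, {duration_ms}) ms")
    idx = _time_to_index(t_ms, f)
    if idx >= signals.n_samples:
        idx = signals.n_samples - 1
    return PotentialMap(
        kind="isopotential",
        lead_ids=list(signals.lead_ids),
        x=signals.x.copy(),
        y=signals.y.copy(),
        values=signals.values[:, idx].copy(),
        time_spec=t_ms,
        units="uV",
    )


def isointegral(
    signals: SignalMatrix,
    t0_ms: float,
    t1_ms: float,
    frequency_hz: Optional[float] = None,
) -> PotentialMap:
    """Per-electrode rectangle-rule integral over ``[t0_ms, t1_ms)``.

    Value = sum of samples in ``[index(t0), index(t1))`` times the sample
    period in ms; units microvolt-ms.  Adjacent windows add exactly.
    """
    f = frequency_hz if frequency_hz is not None else signals.frequency_hz
    duration_ms = signals.n_samples / f * 1000.0
    if not (0 <= t0_ms < t1_ms <= duration_ms):
        raise MapError(
            f"window [{t0_ms}, {t1_ms}) ms invalid for record duration {duration_ms} ms"
        )
    i0 = _time_to_index(t0_ms, f)
    i1 = min(_time_to_index(t1_ms, f), signals.n_samples)
    if i1 <= i0:
        raise MapError(f"window [{t0_ms}, {t1_ms}) ms contains no samples")
    dt_ms = 1000.0 / f
    return PotentialMap(
        kind="isointegral",
        lead_ids=list(signals.lead_ids),
        x=signals.x.copy(),
        y=signals.y.copy(),
        values=signals.values[:, i0:i1].sum(axis=1) * dt_ms,
        time_spec=(t0_ms, t1_ms),
        units="uV.ms",
    )


def st40_map(doc: BspmDocument, signals: SignalMatrix) -> PotentialMap:
    """The ST40 isopotential map: potential 40 ms after QRS offset.

    Each electrode uses its own ``qrsOffset`` beat marker when per-lead
    annotations differ; the ``"*"`` wildcard annotation covers the rest.
    Raises :class:`MapError` when no ``qrsOffset`` marker resolves for some
    lead.
    """
    f = signals.frequency_hz
    values = np.empty(signals.n_leads)
    times = np.empty(signals.n_leads)
    for i, lead_id in enumerate(signals.lead_ids):
        ann = resolve_lead_annotation(doc, lead_id)
        if ann is None or not ann.markers.get("qrsOffset"):
            raise MapError(
                f"no qrsOffset beat marker resolves for lead {lead_id}; "
                "an ST40 map requires QRS offset annotations"
            )
        offset_idx = ann.markers["qrsOffset"][0]
        t_ms = offset_idx * 1000.0 / f + 40.0
        idx = _time_to_index(t_ms, f)
        if idx >= signals.n_samples:
            raise MapError(
                f"lead {lead_id}: ST40 instant {t_ms} ms is past the end of the record"
            )
        values[i] = signals.values[i, idx]
        times[i] = t_ms
    return PotentialMap(
        kind="isopotential",
        lead_ids=list(signals.lead_ids),
        x=signals.x.copy(),
        y=signals.y.copy(),
        values=values,
        time_spec=float(times[0]) if np.all(times == times[0]) else times,
        units="uV",
    )


def interpolate_grid(
    pmap: PotentialMap,
    nx: int,
    ny: int,
    wrap_horizontal: bool = False,
    width: Optional[float] = None,
) -> GridRaster:
    """Piecewise-linear interpolation of a map onto an ``ny x nx`` raster.

    Electrode values are interpolated on a Delaunay triangulation; raster
    cells outside the convex hull are NaN.  ``wrap_horizontal`` duplicates
    the electrodes shifted by ``width`` (the unrolled-diagram width, default
    the electrode x-extent) on both sides, emulating the closed thorax so
    the seam between the left and right edges of the unrolled torso is
    interpolated rather than left missing.
    """
    pts = np.column_stack([pmap.x, pmap.y])
    vals = np.asarray(pmap.values, dtype=float)
    if len(pts) < 3:
        raise MapError("interpolation needs at least 3 electrodes")
    if wrap_horizontal:
        if width is None:
            width = float(pmap.x.max() - pmap.x.min())
        shifted = [pts, pts + [width, 0.0], pts - [width, 0.0]]
        all_pts = np.vstack(shifted)
        all_vals = np.concatenate([vals, vals, vals])
    else:
        all_pts, all_vals = pts, vals
    try:
        tri = Delaunay(all_pts)
    except QhullError as exc:
        raise MapError(f"degenerate electrode geometry (collinear?): {exc}") from exc
    interp = LinearNDInterpolator(tri, all_vals)

    x0, x1 = float(pmap.x.min()), float(pmap.x.max())
    y0, y1 = float(pmap.y.min()), float(pmap.y.max())
    gx = np.linspace(x0, x1, nx)
    gy = np.linspace(y0, y1, ny)
    mx, my = np.meshgrid(gx, gy)
    raster = interp(mx, my)
    return GridRaster(values=raster, x0=x0, x1=x1, y0=y0, y1=y1)


def render_traces_svg(
    doc: BspmDocument,
    signals: SignalMatrix,
    colour_by_location: bool = False,
) -> bytes:
    """Render every lead as a scalar trace over the resolved torso diagram.

    Each lead becomes a ``polyline`` (id ``lead-N``) of its samples scaled
    by the diagram's ``waveScale`` in both time and amplitude and centred on
    the lead's electrode position; positive potential deflects upward.  With
    ``colour_by_location`` traces are stroked per thoracic location class
    (anterior/posterior/lateral).  Returns serialized SVG bytes.
    """
    svg_markup, _provenance = resolve_diagram(doc)
    root = etree.fromstring(svg_markup.encode("utf-8"))
    nsmap = root.nsmap.get(None)
    tag = ("{%s}" % nsmap) + "polyline" if nsmap else "polyline"
    scale = doc.header.diagram.wave_scale

    group_tag = ("{%s}" % nsmap) + "g" if nsmap else "g"
    group = etree.SubElement(root, group_tag)
    group.set("id", "bspm-traces")
    group.set("fill", "none")
    group.set("stroke-width", "0.5")

    n = signals.n_samples
    t_centred = (np.arange(n) - (n - 1) / 2.0) * scale
    for i, lead_id in enumerate(signals.lead_ids):
        xs = signals.x[i] + t_centred
        ys = signals.y[i] - signals.values[i] * scale  # positive drawn upward
        points = " ".join(f"{px:.2f},{py:.2f}" for px, py in zip(xs, ys))
        el = etree.SubElement(group, tag)
        el.set("id", f"lead-{lead_id}")
        loc = signals.location[i]
        colour = LOCATION_COLOURS.get(loc, "#000000") if colour_by_location else "#000000"
        el.set("stroke", colour)
        if loc is not None:
            el.set("class", f"location-{loc}")
        el.set("points", points)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")
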