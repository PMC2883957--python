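"""Deterministic, physiologically-shaped synthetic BSPM fixtures.

Real BSPM datasets (Lux-192, Kornreich-117) are not redistributable, so this
module generates complete stand-in documents with the same shape: electrode
layouts, a small unrolled-torso SVG, and averaged-beat signals from a single
moving-dipole source.

The signal model places a dipole on the axis of a cylindrical torso whose
surface carries the electrodes (the unrolled 2D diagram maps to the cylinder
by azimuth ``theta = 2*pi*x/width`` and height from ``y``).  The dipole
moment is a sum of Gaussian wave components — P, the two QRS phases and T —

    d(t) = sum_w  a_w * exp(-(t - mu_w)^2 / (2 sigma_w^2))

and each electrode at surface point ``p`` sees the far-field potential

    phi(p, t) = k * (p_hat . d(t)) / |p|^2

This is a deliberately simplified single-dipole kernel, not a boundary-element
torso model: fixtures need realistic spatial coherence (smooth fields,
antipodal sign inversion for horizontal moments), not clinical fidelity.
Samples are stored as integers with the record's ``sampleMultiplier`` chosen
so the peak stored magnitude is about 2000, which exercises the multiplier
path of the format.

Everything is deterministic given the seed; the same seed yields
byte-identical serialised documents.
"""

from __future__ import annotations

import datetime
import math
import random
from dataclasses import dataclass, field

import numpy as np

from . import equations, transforms
from .model import (
    Annotations,
    BspmDocument,
    BspmType,
    Comment,
    CommentSection,
    Diagram,
    Header,
    Lead,
    LeadAnnotation,
    LimbLead,
    LIMB_LEAD_NAMES,
    Patient,
    Record,
    Sex,
    Transformation,
    TransformLead,
)

__all__ = [
    "ElectrodeLayout",
    "Wave",
    "DipoleBeatModel",
    "default_beat_model",
    "make_lux192_layout",
    "make_kornreich117_layout",
    "make_torso_svg",
    "simulate_bspm",
    "lux192_preset",
    "kornreich117_preset",
    "random_document",
]


@dataclass
class ElectrodeLayout:
    """Electrode ids and 2D diagram coordinates for one BSPM configuration."""

    name: str
    width: float
    height: float
    electrodes: list[tuple[int, float, float]]  # (lead_id, x, y)

    def __len__(self) -> int:
        return len(self.electrodes)


def make_lux192_layout(width: float = 1000.0, height: float = 700.0) -> ElectrodeLayout:
    """The Lux-192 grid: a 12 x 16 array of 192 electrodes.

    Rows are equally spaced over the vertical band between 15% and 85% of
    the diagram height (suprasternal notch to umbilicus); columns are
    equidistant across the full width (the whole unrolled thorax).  Lead
    numbering is column-major — top-to-bottom within a column, columns left
    to right — a declared stand-in convention: the historical Lux numbering
    is not recoverable here, and the built-in transformation constants are
    applied to this numbering as given.
    """
    n_rows, n_cols = 12, 16
    ys = [height * (0.15 + 0.70 * r / (n_rows - 1)) for r in range(n_rows)]
    xs = [(c + 0.5) * width / n_cols for c in range(n_cols)]
    electrodes = [
        (c * n_rows + r + 1, xs[c], ys[r])
        for c in range(n_cols)
        for r in range(n_rows)
    ]
    return ElectrodeLayout("Lux-192", width, height, electrodes)


def make_kornreich117_layout(
    width: float = 1000.0, height: float = 700.0, seed: int = 0
) -> ElectrodeLayout:
    """A Kornreich-117 stand-in: 9 rows x 13 columns = 117 electrodes with
    unequal, seed-deterministic column spacing (the published layout's
    columns are not equidistant)."""
    n_rows, n_cols = 9, 13
    rng = random.Random(seed)
    weights = [rng.uniform(0.5, 1.8) for _ in range(n_cols)]
    total = sum(weights)
    xs = []
    acc = 0.0
    for w in weights:
        xs.append(round((acc + w / 2) / total * width, 2))
        acc += w
    ys = [round(height * (0.15 + 0.70 * r / (n_rows - 1)), 2) for r in range(n_rows)]
    electrodes = [
        (c * n_rows + r + 1, xs[c], ys[r])
        for c in range(n_cols)
        for r in range(n_rows)
    ]
    return ElectrodeLayout("Kornreich-117", width, height, electrodes)


def make_torso_svg(width: float = 1000.0, height: float = 700.0) -> str:
    """A small (< 2 KiB) unrolled-torso outline as SVG markup.

    Two torso halves (anterior | posterior) side by side, each a rounded
    outline with a neck notch and shoulder slopes, on the stated viewBox.
    """
    w, h = float(width), float(height)

    def half(x0: float) -> str:
        hw = w / 2
        return (
            f"M {x0 + 0.08 * hw:.0f},{0.12 * h:.0f} "
            f"Q {x0 + 0.02 * hw:.0f},{0.5 * h:.0f} {x0 + 0.10 * hw:.0f},{0.95 * h:.0f} "
            f"L {x0 + 0.90 * hw:.0f},{0.95 * h:.0f} "
            f"Q {x0 + 0.98 * hw:.0f},{0.5 * h:.0f} {x0 + 0.92 * hw:.0f},{0.12 * h:.0f} "
            f"L {x0 + 0.62 * hw:.0f},{0.05 * h:.0f} "
            f"Q {x0 + 0.5 * hw:.0f},{0.12 * h:.0f} {x0 + 0.38 * hw:.0f},{0.05 * h:.0f} Z"
        )

    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="0 0 {w:.0f} {h:.0f}" width="{w:.0f}" height="{h:.0f}">'
        f'<path d="{half(0.0)}" fill="none" stroke="#555" stroke-width="2"/>'
        f'<path d="{half(w / 2)}" fill="none" stroke="#555" stroke-width="2"/>'
        f'<line x1="{w / 2:.0f}" y1="{0.05 * h:.0f}" x2="{w / 2:.0f}" '
        f'y2="{0.95 * h:.0f}" stroke="#bbb" stroke-width="1" stroke-dasharray="6 6"/>'
        "</svg>"
    )
    assert len(svg.encode()) <= 2048
    return svg


@dataclass(frozen=True)
class Wave:
    """One Gaussian component of the dipole moment."""

    name: str
    amplitude: tuple[float, float, float]  # 3D moment, arbitrary units
    mu_ms: float
    sigma_ms: float


@dataclass
class DipoleBeatModel:
    """Parameters of the single-dipole averaged-beat simulator.

    ``waves`` must be time-ordered (P before QRS before T) with positive
    widths.  ``k`` is an overall conductivity/gain scale; the torso cylinder
    radius derives from the diagram width (circumference = width).
    """

    waves: tuple[Wave, ...] = ()
    k: float = 1.0

    def __post_init__(self):
        mus = [w.mu_ms for w in self.waves]
        if any(w.sigma_ms <= 0 for w in self.waves):
            raise ValueError("wave widths must be positive")
        if mus != sorted(mus):
            raise ValueError("waves must be ordered in time (P < QRS1 <= QRS2 < T)")

    def moment(self, t_ms: np.ndarray) -> np.ndarray:
        """Dipole moment d(t): shape (3, len(t_ms))."""
        d = np.zeros((3, len(t_ms)))
        for wav in self.waves:
            g = np.exp(-((t_ms - wav.mu_ms) ** 2) / (2.0 * wav.sigma_ms**2))
            d += np.asarray(wav.amplitude)[:, None] * g
        return d


def default_beat_model() -> DipoleBeatModel:
    """A plausible averaged beat spanning ~600 ms.

    P wave at 120 ms (low, broad), a biphasic QRS at 210/225 ms (sharp,
    large) and a T wave at 400 ms (broad); amplitudes give an R-dominant
    beat with discordant T in the z axis.
    """
    return DipoleBeatModel(
        waves=(
            Wave("P", (0.10, 0.05, 0.02), 120.0, 12.0),
            Wave("QRS1", (-0.60, -0.30, 0.20), 210.0, 6.0),
            Wave("QRS2", (1.50, 1.00, -0.50), 225.0, 7.0),
            Wave("T", (0.40, 0.30, -0.10), 400.0, 30.0),
        ),
        # gain chosen so surface potentials peak around 2 mV on the default
        # Lux-192 geometry (microvolt units)
        k=3.0e7,
    )


# Fixed remote cylinder-frame points (units of R and H) for the legacy
# limb leads retained by Kornreich-style datasets.
_LIMB_POINTS = {
    "VR": (1.6, -1.1, 1.4),  # right shoulder, off the electrode band
    "VL": (-1.6, -1.1, 1.4),  # left shoulder
    "VF": (0.0, 0.4, -2.2),  # left foot, below the band
}


def _electrode_positions(layout: ElectrodeLayout) -> np.ndarray:
    """Map 2D diagram coordinates onto the torso cylinder surface."""
    radius = layout.width / (2.0 * math.pi)
    pts = np.empty((len(layout), 3))
    for i, (_lid, x, y) in enumerate(layout.electrodes):
        theta = 2.0 * math.pi * x / layout.width
        z = (layout.height / 2.0 - y)
        pts[i] = (radius * math.cos(theta), radius * math.sin(theta), z)
    norms = np.linalg.norm(pts, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate geometry: electrode at the dipole axis")
    return pts


def _dipole_potentials(points: np.ndarray, moment: np.ndarray, k: float) -> np.ndarray:
    """phi(p, t) = k * (p_hat . d(t)) / |p|^2, shape (n_points, n_samples)."""
    norms = np.linalg.norm(points, axis=1)
    unit = points / norms[:, None]
    return k * (unit @ moment) / (norms**2)[:, None]


def _wave_markers(model: DipoleBeatModel, n_samples: int, frequency_hz: float) -> dict[str, list[int]]:
    """Wildcard beat markers at mu +/- 3 sigma of each wave (a fixture
    convention), as 0-based sample indices clipped to the record."""
    by_name = {w.name: w for w in model.waves}

    def idx(t_ms: float) -> int:
        return int(np.clip(math.floor(t_ms * frequency_hz / 1000.0 + 0.5), 0, n_samples - 1))

    markers: dict[str, list[int]] = {}
    if "P" in by_name:
        w = by_name["P"]
        markers["pOnset"] = [idx(w.mu_ms - 3 * w.sigma_ms)]
        markers["pOffset"] = [idx(w.mu_ms + 3 * w.sigma_ms)]
    qrs = [by_name[n] for n in ("QRS1", "QRS2") if n in by_name]
    if qrs:
        markers["qrsOnset"] = [idx(qrs[0].mu_ms - 3 * qrs[0].sigma_ms)]
        markers["qrsOffset"] = [idx(qrs[-1].mu_ms + 3 * qrs[-1].sigma_ms)]
    if "T" in by_name:
        w = by_name["T"]
        markers["tOnset"] = [idx(w.mu_ms - 3 * w.sigma_ms)]
        markers["tOffset"] = [idx(w.mu_ms + 3 * w.sigma_ms)]
    return markers


def simulate_bspm(
    layout: ElectrodeLayout,
    n_samples: int,
    frequency_hz: float,
    model: DipoleBeatModel | None = None,
    bspm_type: BspmType = BspmType.AVERAGED_BEATS,
    include_limb_leads: bool = False,
    seed: int = 0,
    include_transformations: bool = False,
) -> BspmDocument:
    """Simulate a complete, valid averaged-beat BSPM document.

    Signals come from the dipole model over the cylindrical torso implied by
    the layout; samples are stored as integers with ``sampleMultiplier``
    set so the peak stored magnitude is ~2000.  The document carries a
    synthetic patient, wildcard beat markers derived from the wave
    parameters, the torso SVG, and — when ``include_limb_leads`` — VR/VL/VF
    signals sampled at three fixed remote points.  The result passes
    :func:`xmlbspm.model.validate_document` with zero errors.
    """
    if model is None:
        model = default_beat_model()
    if n_samples <= 0 or frequency_hz <= 0:
        raise ValueError("n_samples and frequency_hz must be positive")

    t_ms = np.arange(n_samples) * 1000.0 / frequency_hz
    moment = model.moment(t_ms)
    points = _electrode_positions(layout)
    phi = _dipole_potentials(points, moment, model.k)

    radius = layout.width / (2.0 * math.pi)
    limb_phi: dict[str, np.ndarray] = {}
    if include_limb_leads:
        limb_pts = np.array(
            [
                (sx * radius, sy * radius, sz * layout.height)
                for sx, sy, sz in _LIMB_POINTS.values()
            ]
        )
        limb_mat = _dipole_potentials(limb_pts, moment, model.k)
        limb_phi = dict(zip(_LIMB_POINTS.keys(), limb_mat))

    peak = float(np.abs(phi).max())
    if peak == 0:
        multiplier = 1.0
    else:
        multiplier = float(f"{peak / 2000.0:.6g}")
    stored = np.rint(phi / multiplier).astype(int)
    limb_stored = {
        name: np.rint(v / multiplier).astype(int) for name, v in limb_phi.items()
    }

    leads = []
    for i, (lid, x, y) in enumerate(layout.electrodes):
        leads.append(
            Lead(
                lead_id=lid,
                x=x,
                y=y,
                samples=[int(v) for v in stored[i]],
                location="A" if x < layout.width / 2 else "P",
            )
        )

    record = Record(
        layout_name=layout.name,
        lead_count=len(leads),
        samples_per_lead=n_samples,
        frequency_hz=frequency_hz,
        sample_multiplier=multiplier,
        recording_device="xmlbspm dipole simulator",
    )
    annotations = Annotations(
        lead_annotations=[
            LeadAnnotation(lead_id="*", markers=_wave_markers(model, n_samples, frequency_hz))
        ],
        hr=60,
    )
    patient = Patient(
        patient_id=f"SYN-{seed:06d}",
        full_name="Synthetic Subject",
        sex=Sex.UNSPECIFIED,
    )
    limb_leads = None
    if include_limb_leads:
        limb_leads = [
            LimbLead(name=name, samples=[int(v) for v in limb_stored[name]])
            for name in _LIMB_POINTS
        ]
    transformations = None
    if include_transformations:
        transformations = [
            transforms.lux192_to_12lead_transformation(),
            transforms.lux192_to_vcg_transformation(),
        ]
    header = Header(
        record=record,
        diagram=Diagram(embedded_svg=make_torso_svg(layout.width, layout.height)),
        patient=patient,
        annotations=annotations,
        limb_leads=limb_leads,
        transformations=transformations,
    )
    doc_id = f"{layout.name.lower()}-synthetic-{seed}"
    return BspmDocument(bspm_type=bspm_type, doc_id=doc_id, header=header, leads=leads)


def lux192_preset(seed: int = 0, include_transformations: bool = False) -> BspmDocument:
    """The Lux-192 study condition: 192 leads x 600 samples at 1000 Hz."""
    return simulate_bspm(
        make_lux192_layout(),
        n_samples=600,
        frequency_hz=1000.0,
        seed=seed,
        include_transformations=include_transformations,
    )


def kornreich117_preset(seed: int = 0) -> BspmDocument:
    """The Kornreich-117 study condition: 117 leads x 300 samples at 500 Hz
    plus the legacy VR/VL/VF limb leads."""
    return simulate_bspm(
        make_kornreich117_layout(seed=seed),
        n_samples=300,
        frequency_hz=500.0,
        include_limb_leads=True,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# randomized small documents for round-trip property testing

def random_document(seed: int) -> BspmDocument:
    """A small randomized but always-valid document.

    Exercises optional metadata presence, calc leads (in transform-type
    documents), limb leads, comments, transformations, non-default
    multiplier/waveScale — the surface a serialiser must round-trip.
    """
    rng = random.Random(seed)
    n_leads = rng.randint(2, 6)
    n_samples = rng.randint(4, 12)
    bspm_type = rng.choice(list(BspmType))
    width, height = 400.0, 300.0

    leads: list[Lead] = []
    raw_ids: list[int] = []
    for i in range(n_leads):
        lid = i + 1
        leads.append(
            Lead(
                lead_id=lid,
                x=round(rng.uniform(0, width), 2),
                y=round(rng.uniform(0, height), 2),
                samples=[rng.randint(-2000, 2000) for _ in range(n_samples)],
                location=rng.choice([None, "A", "P", "LL", "RL"]),
                myocardial_region=rng.choice([None, "An", "Ap", "S"]),
            )
        )
        raw_ids.append(lid)
    if bspm_type in (BspmType.AVERAGED_BEATS_TRANSFORM, BspmType.CONTINUOUS_TRANSFORM):
        a, b = rng.sample(raw_ids, 2)
        leads.append(
            Lead(
                lead_id=n_leads + 1,
                x=round(rng.uniform(0, width), 2),
                y=round(rng.uniform(0, height), 2),
                data_kind="calc",
                expression=equations.parse_expression(f"([Lead{a}] + [Lead{b}])/2"),
            )
        )

    multiplier = rng.choice([1, 1, 0.5, 2.5, 0.001220703125])
    record = Record(
        layout_name=f"Random-{n_leads}",
        lead_count=len(leads),
        samples_per_lead=n_samples,
        frequency_hz=rng.choice([250.0, 500.0, 1000.0, 2048.0]),
        sample_multiplier=multiplier,
        recording_device=rng.choice([None, "SIM-1", "VCM-3000"]),
        investigator=rng.choice([None, "A. Tester"]),
        notes=rng.choice([None, "randomized fixture"]),
    )

    patient = None
    if rng.random() < 0.7:
        patient = Patient(
            patient_id=f"P{rng.randint(1, 9999):04d}",
            full_name=rng.choice([None, "Jane Doe"]),
            sex=rng.choice([None, Sex.MALE, Sex.FEMALE, Sex.UNKNOWN]),
            dob=rng.choice([None, datetime.date(1984, 6, 24)]),
        )

    annotations = None
    if rng.random() < 0.8:
        anns = [
            LeadAnnotation(
                lead_id="*",
                markers={"qrsOffset": [rng.randrange(n_samples)]},
            )
        ]
        if rng.random() < 0.5:
            anns.append(
                LeadAnnotation(
                    lead_id=str(rng.choice(raw_ids)),
                    markers={
                        "qrsOnset": [rng.randrange(n_samples)],
                        "tOffset": [rng.randrange(n_samples)],
                    },
                )
            )
        annotations = Annotations(lead_annotations=anns, hr=rng.choice([None, 60, 72]))

    comments = None
    if rng.random() < 0.4:
        comments = [
            CommentSection(
                lead_id=rng.choice(["*", str(raw_ids[0])]),
                ms=rng.choice([None, 120.5]),
                comments=[
                    Comment(
                        full_name="Dr. Reviewer",
                        date=datetime.date(2009, 8, 28),
                        time=datetime.time(12, 50, 0),
                        text="note",
                        email=rng.choice([None, "reviewer@example.org"]),
                    )
                ],
            )
        ]

    limb_leads = None
    if rng.random() < 0.4:
        names = rng.sample(list(LIMB_LEAD_NAMES), rng.randint(1, 3))
        limb_leads = [
            LimbLead(name=n, samples=[rng.randint(-500, 500) for _ in range(n_samples)])
            for n in names
        ]

    transformations = None
    if rng.random() < 0.4:
        a, b = rng.sample(raw_ids, 2)
        transformations = [
            Transformation(
                name="pair mean",
                url=rng.choice([None, "http://example.org/t.xml"]),
                transform_leads=[
                    TransformLead(
                        name="M",
                        expression=equations.parse_expression(f"([Lead{a}] + [Lead{b}])/2"),
                    )
                ],
            )
        ]

    header = Header(
        record=record,
        diagram=Diagram(
            embedded_svg=make_torso_svg(width, height),
            url=rng.choice([None, "http://example.org/torso.svg"]),
            wave_scale=rng.choice([0.04, 0.04, 0.1, 0.02]),
        ),
        patient=patient,
        annotations=annotations,
        comments=comments,
        limb_leads=limb_leads,
        transformations=transformations,
    )
    return BspmDocument(
        bspm_type=bspm_type,
        doc_id=f"random-{seed}",
        header=header,
        leads=leads,
    )
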