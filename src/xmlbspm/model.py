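"""Domain model for XML-BSPM documents.

A body surface potential map (BSPM) records the heart's electrical activity
through a large custom array of unipolar torso electrodes (32-219 in published
layouts) rather than the ten standardised electrodes of the 12-lead ECG.  The
XML-BSPM format stores one document per recording: a metadata header (patient,
record settings, beat-marker annotations, comments, limb leads, derived-lead
transformations, and an SVG torso diagram that anchors a 2D electrode
coordinate system) followed by the per-lead sample data.

This module defines the in-memory form of such a document plus structural
validation.  Parsing and serialisation live in :mod:`xmlbspm.xmlio`.

Conventions adopted here and documented for users:

* Electrode ``x``/``y`` coordinates are in the embedded SVG's user-unit space,
  origin top-left, x rightwards, y downwards (the SVG convention).
* Beat-marker values are 0-based sample offsets into each lead's samples.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from lxml import etree

__all__ = [
    "BspmType",
    "TRANSFORM_TYPES",
    "Sex",
    "LIMB_LEAD_NAMES",
    "LOCATIONS",
    "MYOCARDIAL_REGIONS",
    "MARKER_KINDS",
    "Patient",
    "Record",
    "LeadAnnotation",
    "Annotations",
    "Comment",
    "CommentSection",
    "LimbLead",
    "TransformLead",
    "Transformation",
    "Diagram",
    "Lead",
    "Header",
    "BspmDocument",
    "ValidationIssue",
    "validate_document",
    "resolve_lead_annotation",
]


class BspmType(str, Enum):
    """The four canonical kinds of BSPM document.

    ``*-TRANSFORM`` values are the only ones in which leads may carry
    equations (``data="calc"``) instead of raw sample values.
    """

    AVERAGED_BEATS = "AVERAGED-BEATS-BSPM"
    AVERAGED_BEATS_TRANSFORM = "AVERAGED-BEATS-BSPM-TRANSFORM"
    CONTINUOUS = "CONTINUOUS-BSPM"
    CONTINUOUS_TRANSFORM = "CONTINUOUS-BSPM-TRANSFORM"


TRANSFORM_TYPES = frozenset(
    {BspmType.AVERAGED_BEATS_TRANSFORM, BspmType.CONTINUOUS_TRANSFORM}
)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNSPECIFIED = "unspecified"
    UNKNOWN = "unknown"


#: Valid limb-lead names: the augmented and bipolar limb leads plus the legacy
#: unipolar VF/VR/VL leads retained by older datasets (e.g. Kornreich-117).
LIMB_LEAD_NAMES = ("aVF", "aVR", "aVL", "I", "II", "III", "VF", "VR", "VL")

#: General thoracic area of an electrode: Anterior, Posterior, Left/Right Lateral.
LOCATIONS = ("A", "P", "LL", "RL")

#: Myocardial region codes (e.g. ``Ap`` apical, ``An`` anterior, ``S`` septal).
MYOCARDIAL_REGIONS = ("An", "HP", "TP", "IP", "I", "L", "Ap", "RV", "S")

#: Beat-marker kinds storable per lead annotation, in canonical order.
MARKER_KINDS = (
    "pOnset",
    "pOffset",
    "qrsOnset",
    "qrsOffset",
    "tOnset",
    "tOffset",
    "uOnset",
    "uOffset",
)


@dataclass
class Patient:
    patient_id: str
    full_name: Optional[str] = None
    sex: Optional[Sex] = None
    dob: Optional[datetime.date] = None
    address: Optional[str] = None
    city: Optional[str] = None
    state: Optional[str] = None
    country: Optional[str] = None
    postal_code: Optional[str] = None
    phone: Optional[str] = None
    fax: Optional[str] = None
    email: Optional[str] = None
    diagnosis: Optional[str] = None
    computerised_diagnosis: Optional[str] = None


@dataclass
class Record:
    """Recording settings.

    ``frequency_hz`` is stored in the file as a string such as ``"1000 Hz"``
    and parsed to samples/second.  ``sample_multiplier`` scales stored sample
    values into actual amplitudes (microvolts); it defaults to 1 when the
    attribute is absent.
    """

    layout_name: str
    lead_count: int
    samples_per_lead: int
    frequency_hz: float
    sample_multiplier: float = 1.0
    recording_device: Optional[str] = None
    recording_date: Optional[datetime.date] = None
    recording_time: Optional[datetime.time] = None
    investigator: Optional[str] = None
    notes: Optional[str] = None


@dataclass
class LeadAnnotation:
    """Beat markers for one lead, or for all leads when ``lead_id == "*"``.

    Marker values are 0-based sample indices.
    """

    lead_id: str
    markers: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class Annotations:
    lead_annotations: list[LeadAnnotation] = field(default_factory=list)
    hr: Optional[int] = None  # beats per minute
    p_axis: Optional[int] = None  # degrees
    qrs_axis: Optional[int] = None
    t_axis: Optional[int] = None


@dataclass
class Comment:
    full_name: str
    date: datetime.date
    time: datetime.time
    text: str
    email: Optional[str] = None


@dataclass
class CommentSection:
    """Comments grouped around one region of one lead (forum-style)."""

    comments: list[Comment]
    lead_id: Optional[str] = None  # "*" for the whole map
    ms: Optional[float] = None
    mv: Optional[float] = None


@dataclass
class LimbLead:
    name: str  # one of LIMB_LEAD_NAMES
    samples: list[float] = field(default_factory=list)


@dataclass
class TransformLead:
    """One derived lead: a name plus the equation that computes it.

    ``expression`` is an :class:`xmlbspm.equations.Expression` AST.
    """

    name: str
    expression: object
    x: Optional[float] = None
    y: Optional[float] = None
    location: Optional[str] = None
    myocardial_region: Optional[str] = None


@dataclass
class Transformation:
    name: str
    transform_leads: list[TransformLead] = field(default_factory=list)
    url: Optional[str] = None


@dataclass
class Diagram:
    """The unrolled 2D torso diagram anchoring electrode coordinates.

    ``embedded_svg`` is the simplistic fallback diagram carried inside the
    document (CDATA); ``url`` optionally points at a richer external SVG.
    ``wave_scale`` scales rendered scalar traces relative to the diagram
    (default 0.04, i.e. 4%).
    """

    embedded_svg: str
    url: Optional[str] = None
    wave_scale: float = 0.04


@dataclass
class Lead:
    """One unipolar BSPM channel.

    Exactly one of ``samples`` (``data_kind == "raw"``) or ``expression``
    (``data_kind == "calc"``) carries the lead's content.
    """

    lead_id: int
    x: float
    y: float
    data_kind: str = "raw"
    samples: Optional[list[float]] = None
    expression: Optional[object] = None
    location: Optional[str] = None
    myocardial_region: Optional[str] = None


@dataclass
class Header:
    record: Record
    diagram: Diagram
    patient: Optional[Patient] = None
    annotations: Optional[Annotations] = None
    comments: Optional[list[CommentSection]] = None
    limb_leads: Optional[list[LimbLead]] = None
    transformations: Optional[list[Transformation]] = None


@dataclass
class BspmDocument:
    bspm_type: BspmType
    doc_id: str
    header: Header
    leads: list[Lead] = field(default_factory=list)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    path: str
    message: str


def _svg_root_ok(markup: str) -> bool:
    try:
        root = etree.fromstring(markup.encode("utf-8"))
    except etree.XMLSyntaxError:
        return False
    return etree.QName(root).localname == "svg"


def validate_document(doc: BspmDocument, strict: bool = False) -> list[ValidationIssue]:
    """Check a document against every structural invariant of the format.

    Returns a list of issues; an empty list means the document is valid.
    Nothing is raised — a leniently parsed document can be inspected issue by
    issue.  With ``strict=True`` a missing ``patient`` or ``annotations``
    header element is an error (the format's element tables mark both
    required); by default it is a warning, following the format's prose which
    treats both as optional for database-backed datasets.
    """
    issues: list[ValidationIssue] = []

    def err(path: str, message: str) -> None:
        issues.append(ValidationIssue("error", path, message))

    def warn(path: str, message: str) -> None:
        issues.append(ValidationIssue("warning", path, message))

    if not isinstance(doc.bspm_type, BspmType):
        err("bspm/@type", f"unknown bspm type {doc.bspm_type!r}")
    if not doc.doc_id:
        err("bspm/@id", "document id must be non-empty")

    rec = doc.header.record
    if rec.lead_count != len(doc.leads):
        err(
            "header/record/@leads",
            f"lead count mismatch: record declares {rec.lead_count}, "
            f"document stores {len(doc.leads)}",
        )
    if rec.lead_count <= 0:
        err("header/record/@leads", "lead count must be positive")
    if rec.samples_per_lead <= 0:
        err("header/record/@samples", "samples per lead must be positive")
    if not rec.frequency_hz > 0:
        err("header/record/@frequency", "sampling frequency must be positive")
    if rec.sample_multiplier == 0:
        err("header/record/@sampleMultiplier", "sample multiplier must be non-zero")

    # patient / annotations presence
    if doc.header.patient is None:
        (err if strict else warn)("header/patient", "patient element absent")
    elif not doc.header.patient.patient_id:
        err("header/patient/@id", "patient id must be non-empty")
    if doc.header.patient is not None and doc.header.patient.sex is not None:
        if not isinstance(doc.header.patient.sex, Sex):
            err("header/patient/sex", f"invalid sex value {doc.header.patient.sex!r}")

    lead_ids = [lead.lead_id for lead in doc.leads]
    id_set = set(lead_ids)
    if len(id_set) != len(lead_ids):
        dupes = sorted({i for i in lead_ids if lead_ids.count(i) > 1})
        err("leads", f"duplicate lead ids: {dupes}")

    if doc.header.annotations is None:
        (err if strict else warn)("header/annotations", "annotations element absent")
    else:
        ann = doc.header.annotations
        if not ann.lead_annotations:
            err("header/annotations", "annotations present but contain no leadAnn entry")
        for i, la in enumerate(ann.lead_annotations):
            path = f"header/annotations/leadAnn[{i}]"
            if la.lead_id != "*":
                try:
                    ref = int(la.lead_id)
                except (TypeError, ValueError):
                    err(path, f"leadID must be '*' or a decimal lead id, got {la.lead_id!r}")
                else:
                    if ref not in id_set:
                        err(path, f"leadID {ref} does not match any lead in the document")
            for kind, values in la.markers.items():
                if kind not in MARKER_KINDS:
                    err(path, f"unknown beat marker kind {kind!r}")
                for v in values:
                    if not (0 <= v < rec.samples_per_lead):
                        err(
                            path,
                            f"{kind} marker {v} outside sample range "
                            f"[0, {rec.samples_per_lead})",
                        )

    if doc.header.comments is not None:
        for i, section in enumerate(doc.header.comments):
            path = f"header/comments/section[{i}]"
            if not section.comments:
                err(path, "comment section contains no comment")
            for j, c in enumerate(section.comments):
                if not c.full_name:
                    err(f"{path}/comment[{j}]", "comment fullName missing")
                if c.date is None:
                    err(f"{path}/comment[{j}]", "comment date missing")
                if c.time is None:
                    err(f"{path}/comment[{j}]", "comment time missing")

    if doc.header.limb_leads is not None:
        for i, ll in enumerate(doc.header.limb_leads):
            if ll.name not in LIMB_LEAD_NAMES:
                err(
                    f"header/limbLeads/limbLead[{i}]",
                    f"invalid limb lead name {ll.name!r}",
                )

    if doc.header.transformations is not None:
        for i, t in enumerate(doc.header.transformations):
            if not t.name:
                err(f"header/transformations/transformation[{i}]", "name missing")
            if not t.transform_leads:
                err(
                    f"header/transformations/transformation[{i}]",
                    "transformation contains no transformLead",
                )

    dia = doc.header.diagram
    if not (0 < dia.wave_scale <= 1):
        err("header/diagram/@waveScale", f"waveScale {dia.wave_scale} outside (0, 1]")
    if not dia.embedded_svg or not _svg_root_ok(dia.embedded_svg):
        err("header/diagram", "embedded diagram is not well-formed SVG")

    allow_calc = doc.bspm_type in TRANSFORM_TYPES
    for i, lead in enumerate(doc.leads):
        path = f"leads/lead[{i}](id={lead.lead_id})"
        if lead.data_kind not in ("raw", "calc"):
            err(path, f"data attribute must be 'raw' or 'calc', got {lead.data_kind!r}")
        elif lead.data_kind == "raw":
            if lead.samples is None:
                err(path, "raw lead stores no samples")
            elif len(lead.samples) != rec.samples_per_lead:
                err(
                    path,
                    f"raw lead stores {len(lead.samples)} samples, "
                    f"record declares {rec.samples_per_lead}",
                )
        else:  # calc
            if lead.expression is None:
                err(path, "calc lead stores no equation")
            if not allow_calc:
                err(
                    path,
                    "calc lead present but document type is "
                    f"{doc.bspm_type.value}; calculated leads require a "
                    "*-TRANSFORM document type",
                )
        if lead.location is not None and lead.location not in LOCATIONS:
            err(path, f"invalid location {lead.location!r}")
        if (
            lead.myocardial_region is not None
            and lead.myocardial_region not in MYOCARDIAL_REGIONS
        ):
            err(path, f"invalid myocardialRegion {lead.myocardial_region!r}")

    return issues


def resolve_lead_annotation(doc: BspmDocument, lead_id: int) -> Optional[LeadAnnotation]:
    """Return the beat markers that apply to ``lead_id``.

    A lead-specific annotation takes precedence over the ``"*"`` wildcard
    annotation; with neither present the result is ``None``.  Total: never
    raises for any lead id.
    """
    ann = doc.header.annotations
    if ann is None:
        return None
    wildcard = None
    for la in ann.lead_annotations:
        if la.lead_id == "*":
            if wildcard is None:
                wildcard = la
        else:
            try:
                if int(la.lead_id) == lead_id:
                    return la
            except (TypeError, ValueError):
                continue
    return wildcard


def iter_lead_ids(doc: BspmDocument) -> Iterable[int]:
    """Yield lead ids in document order."""
    for lead in doc.leads:
        yield lead.lead_id
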