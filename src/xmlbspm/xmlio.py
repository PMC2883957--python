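"""Read and write XML-BSPM documents.

The on-disk form is a single ``bspm`` root element with a ``header`` (the
metadata) and a ``leads`` section (the sample data), sample payloads as
comma-separated values, and the torso diagram embedded as CDATA-wrapped SVG.
Defaults (``sampleMultiplier`` 1, ``waveScale`` 0.04, ``data`` ``raw``) are
applied on read and elided on write, which keeps files compact.

Serialisation dialect choices (no namespace, shortest exact decimal numbers,
header children in table order) are documented in the package's methods note;
``read_bspm(write_bspm(doc))`` reproduces ``doc`` exactly.
"""

from __future__ import annotations

import datetime
import gzip
import io
import re
import warnings
import zlib
from pathlib import Path
from typing import Callable, Optional, Union

from lxml import etree

from . import equations
from .errors import BspmParseError, BspmSchemaError, BspmValidationError, DiagramError
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
    MARKER_KINDS,
    Patient,
    Record,
    Sex,
    Transformation,
    TransformLead,
    validate_document,
)

__all__ = [
    "read_bspm",
    "write_bspm",
    "resolve_diagram",
    "compression_stats",
    "parse_transformation_element",
    "build_transformation_element",
]

Source = Union[str, Path, bytes, io.IOBase]

#: The published prose occasionally names the continuous types with an extra
#: "BEATS"; lenient parsing maps those onto the canonical values.
_TYPE_ALIASES = {
    "CONTINUOUS-BEATS-BSPM": BspmType.CONTINUOUS,
    "CONTINUOUS-BEATS-BSPM-TRANSFORM": BspmType.CONTINUOUS_TRANSFORM,
}

_FREQ_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*(?:hz)?\s*$", re.I)
_TIME_RE = re.compile(r"^(\d{1,2}):(\d{2}):(\d{2})(?:[:.](\d{1,3}))?$")


# ---------------------------------------------------------------------------
# primitive value codecs

def _fmt_num(v: float, precision: Optional[int] = None) -> str:
    """Shortest exact decimal; integers without a decimal point."""
    if precision is not None and not float(v).is_integer():
        v = round(float(v), precision)
    if float(v).is_integer() and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def _parse_num(s: str) -> float:
    s = s.strip()
    try:
        return int(s)
    except ValueError:
        return float(s)


def _parse_csv_numbers(text: Optional[str]) -> list[float]:
    if text is None or not text.strip():
        return []
    return [_parse_num(tok) for tok in text.split(",")]


def _fmt_csv_numbers(values, precision: Optional[int] = None) -> str:
    return ",".join(_fmt_num(v, precision) for v in values)


def _parse_frequency(s: str, path: str) -> float:
    m = _FREQ_RE.match(s)
    if not m:
        raise BspmSchemaError(f"cannot parse frequency {s!r}", path)
    return float(m.group(1))


def _fmt_time(t: datetime.time) -> str:
    return f"{t.hour:02d}:{t.minute:02d}:{t.second:02d}:{t.microsecond // 1000:03d}"


def _parse_time(s: str, path: str) -> datetime.time:
    m = _TIME_RE.match(s.strip())
    if not m:
        raise BspmSchemaError(f"cannot parse time {s!r} (expected HH:MM:SS:SSS)", path)
    h, mi, sec = int(m.group(1)), int(m.group(2)), int(m.group(3))
    ms = int(m.group(4)) if m.group(4) else 0
    return datetime.time(h, mi, sec, ms * 1000)


def _parse_date(s: str, path: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(s.strip())
    except ValueError as exc:
        raise BspmSchemaError(f"cannot parse date {s!r} (expected YYYY-MM-DD)", path) from exc


def _req_attr(elem, name: str, path: str) -> str:
    v = elem.get(name)
    if v is None:
        raise BspmSchemaError(f"missing required attribute '{name}'", path)
    return v


def _req_child(elem, name: str, path: str):
    child = elem.find(name)
    if child is None:
        raise BspmSchemaError(f"missing required element '{name}'", path)
    return child


def _text(elem) -> str:
    return elem.text or ""


# ---------------------------------------------------------------------------
# reading

def read_bspm(source: Source) -> BspmDocument:
    """Parse an XML-BSPM document from a path, byte string or binary stream.

    Defaults are applied (``sampleMultiplier`` 1, ``waveScale`` 0.04,
    ``data`` ``raw``), CSV payloads are split tolerating surrounding
    whitespace, and the frequency string is parsed as a number with an
    optional case-insensitive ``Hz`` suffix.  Malformed XML raises
    :class:`BspmParseError` with line/column; structural violations raise
    :class:`BspmSchemaError` naming the path.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, (str, Path)):
            root = etree.parse(str(source)).getroot()
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise BspmParseError(str(exc), exc.lineno, exc.position[1] if exc.position else None) from exc

    if etree.QName(root).localname != "bspm":
        raise BspmSchemaError(f"root element is '{etree.QName(root).localname}', expected 'bspm'", "/")

    type_str = _req_attr(root, "type", "bspm")
    try:
        bspm_type = BspmType(type_str)
    except ValueError:
        if type_str in _TYPE_ALIASES:
            bspm_type = _TYPE_ALIASES[type_str]
            warnings.warn(
                f"bspm type {type_str!r} is a legacy alias; interpreting as "
                f"{bspm_type.value!r}",
                stacklevel=2,
            )
        else:
            raise BspmSchemaError(f"unknown bspm type {type_str!r}", "bspm/@type")
    doc_id = _req_attr(root, "id", "bspm")

    ns = _localname_map(root)
    header_el = _req_child(root, ns("header"), "bspm")
    leads_el = _req_child(root, ns("leads"), "bspm")

    header = _read_header(header_el, ns)
    leads = [
        _read_lead(el, i, header.record)
        for i, el in enumerate(leads_el.iterfind(ns("lead")))
    ]

    return BspmDocument(bspm_type=bspm_type, doc_id=doc_id, header=header, leads=leads)


def _localname_map(root) -> Callable[[str], str]:
    """The format declares no namespace, but accept any default namespace."""
    qname = etree.QName(root)
    if qname.namespace:
        prefix = "{%s}" % qname.namespace
        return lambda name: prefix + name
    return lambda name: name


def _read_header(el, ns) -> Header:
    path = "bspm/header"
    patient = None
    pat_el = el.find(ns("patient"))
    if pat_el is not None:
        patient = _read_patient(pat_el, ns)
    record = _read_record(_req_child(el, ns("record"), path), ns)
    annotations = None
    ann_el = el.find(ns("annotations"))
    if ann_el is not None:
        annotations = _read_annotations(ann_el, ns)
    comments = None
    com_el = el.find(ns("comments"))
    if com_el is not None:
        comments = [_read_section(s, ns, i) for i, s in enumerate(com_el.iterfind(ns("section")))]
    limb_leads = None
    ll_el = el.find(ns("limbLeads"))
    if ll_el is not None:
        limb_leads = [
            LimbLead(
                name=_req_attr(l, "name", "header/limbLeads/limbLead"),
                samples=_parse_csv_numbers(l.text),
            )
            for l in ll_el.iterfind(ns("limbLead"))
        ]
    transformations = None
    tr_el = el.find(ns("transformations"))
    if tr_el is not None:
        transformations = [
            parse_transformation_element(t, f"header/transformations/transformation[{i}]")
            for i, t in enumerate(tr_el.iterfind(ns("transformation")))
        ]
    diagram = _read_diagram(_req_child(el, ns("diagram"), path))
    return Header(
        record=record,
        diagram=diagram,
        patient=patient,
        annotations=annotations,
        comments=comments,
        limb_leads=limb_leads,
        transformations=transformations,
    )


def _read_patient(el, ns) -> Patient:
    path = "bspm/header/patient"

    def opt(name: str) -> Optional[str]:
        child = el.find(ns(name))
        return None if child is None else _text(child)

    sex_text = opt("sex")
    sex = None
    if sex_text is not None:
        try:
            sex = Sex(sex_text)
        except ValueError:
            raise BspmSchemaError(f"invalid sex value {sex_text!r}", path + "/sex")
    dob_text = opt("DOB")
    return Patient(
        patient_id=_req_attr(el, "id", path),
        full_name=opt("fullName"),
        sex=sex,
        dob=_parse_date(dob_text, path + "/DOB") if dob_text else None,
        address=opt("address"),
        city=opt("city"),
        state=opt("state"),
        country=opt("country"),
        postal_code=opt("postalCode"),
        phone=opt("phone"),
        fax=opt("fax"),
        email=opt("email"),
        diagnosis=opt("diagnosis"),
        computerised_diagnosis=opt("computerisedDiagnosis"),
    )


def _read_record(el, ns) -> Record:
    path = "bspm/header/record"
    mult_s = el.get("sampleMultiplier")
    rdate = el.get("recordingDate")
    rtime = el.get("recordingTime")
    notes_el = el.find(ns("notes"))
    return Record(
        layout_name=_req_attr(el, "layoutName", path),
        lead_count=int(_req_attr(el, "leads", path)),
        samples_per_lead=int(_req_attr(el, "samples", path)),
        frequency_hz=_parse_frequency(_req_attr(el, "frequency", path), path + "/@frequency"),
        sample_multiplier=_parse_num(mult_s) if mult_s is not None else 1.0,
        recording_device=el.get("recordingDevice"),
        recording_date=_parse_date(rdate, path + "/@recordingDate") if rdate else None,
        recording_time=_parse_time(rtime, path + "/@recordingTime") if rtime else None,
        investigator=el.get("investigator"),
        notes=_text(notes_el) if notes_el is not None else None,
    )


def _read_annotations(el, ns) -> Annotations:
    lead_anns = []
    for la in el.iterfind(ns("leadAnn")):
        markers: dict[str, list[int]] = {}
        for kind in MARKER_KINDS:
            m = la.find(ns(kind))
            if m is not None:
                markers[kind] = [int(v) for v in _parse_csv_numbers(m.text)]
        lead_anns.append(
            LeadAnnotation(lead_id=_req_attr(la, "leadID", "header/annotations/leadAnn"), markers=markers)
        )
    return Annotations(
        lead_annotations=lead_anns,
        hr=int(el.get("HR")) if el.get("HR") else None,
        p_axis=int(el.get("pAxis")) if el.get("pAxis") else None,
        qrs_axis=int(el.get("qrsAxis")) if el.get("qrsAxis") else None,
        t_axis=int(el.get("tAxis")) if el.get("tAxis") else None,
    )


def _read_section(el, ns, i: int) -> CommentSection:
    path = f"header/comments/section[{i}]"
    comments = []
    for c in el.iterfind(ns("comment")):
        comments.append(
            Comment(
                full_name=_req_attr(c, "fullName", path + "/comment"),
                date=_parse_date(_req_attr(c, "date", path + "/comment"), path),
                time=_parse_time(_req_attr(c, "time", path + "/comment"), path),
                email=c.get("email"),
                text=_text(c),
            )
        )
    ms = el.get("ms")
    mv = el.get("mV")
    return CommentSection(
        comments=comments,
        lead_id=el.get("leadID"),
        ms=_parse_num(ms) if ms is not None else None,
        mv=_parse_num(mv) if mv is not None else None,
    )


def parse_transformation_element(el, path: str) -> Transformation:
    """Parse a ``transformation`` element (in-document or external file form)."""
    ns = _localname_map(el)
    leads = []
    for i, tl in enumerate(el.iterfind(ns("transformLead"))):
        tl_path = f"{path}/transformLead[{i}]"
        x = tl.get("x")
        y = tl.get("y")
        leads.append(
            TransformLead(
                name=_req_attr(tl, "name", tl_path),
                expression=equations.parse_expression(_text(tl)),
                x=_parse_num(x) if x is not None else None,
                y=_parse_num(y) if y is not None else None,
                location=tl.get("location"),
                myocardial_region=tl.get("myocardialRegion"),
            )
        )
    return Transformation(name=_req_attr(el, "name", path), url=el.get("url"), transform_leads=leads)


def _read_diagram(el) -> Diagram:
    ws = el.get("waveScale")
    return Diagram(
        embedded_svg=_text(el),
        url=el.get("url"),
        wave_scale=_parse_num(ws) if ws is not None else 0.04,
    )


def _read_lead(el, i: int, record: Record) -> Lead:
    path = f"bspm/leads/lead[{i}]"
    data_kind = el.get("data", "raw")
    samples = None
    expression = None
    if data_kind == "calc":
        expression = equations.parse_expression(_text(el))
    else:
        samples = _parse_csv_numbers(el.text)
    return Lead(
        lead_id=int(_req_attr(el, "id", path)),
        x=_parse_num(_req_attr(el, "x", path)),
        y=_parse_num(_req_attr(el, "y", path)),
        data_kind=data_kind,
        samples=samples,
        expression=expression,
        location=el.get("location"),
        myocardial_region=el.get("myocardialRegion"),
    )


# ---------------------------------------------------------------------------
# writing

def write_bspm(
    doc: BspmDocument,
    indent: bool = True,
    numeric_precision: Optional[int] = None,
) -> bytes:
    """Serialise a valid document to UTF-8 XML bytes.

    The embedded SVG is wrapped in a CDATA section; attributes equal to their
    defaults are omitted.  An invalid document is refused with the first
    validation error.  ``numeric_precision`` optionally rounds non-integral
    floats to that many decimals; by default values are written in their
    shortest exact decimal form.
    """
    errors = [i for i in validate_document(doc) if i.severity == "error"]
    if errors:
        first = errors[0]
        raise BspmValidationError(
            f"refusing to serialise invalid document: {first.path}: {first.message}"
        )

    p = numeric_precision
    root = etree.Element("bspm", type=doc.bspm_type.value, id=doc.doc_id)
    header = etree.SubElement(root, "header")

    h = doc.header
    if h.patient is not None:
        _build_patient(header, h.patient)
    _build_record(header, h.record, p)
    if h.annotations is not None:
        _build_annotations(header, h.annotations)
    if h.comments is not None:
        com = etree.SubElement(header, "comments")
        for section in h.comments:
            _build_section(com, section, p)
    if h.limb_leads is not None:
        lls = etree.SubElement(header, "limbLeads")
        for ll in h.limb_leads:
            el = etree.SubElement(lls, "limbLead", name=ll.name)
            el.text = _fmt_csv_numbers(ll.samples, p)
    if h.transformations is not None:
        trs = etree.SubElement(header, "transformations")
        for t in h.transformations:
            trs.append(build_transformation_element(t, p))
    _build_diagram(header, h.diagram, p)

    leads_el = etree.SubElement(root, "leads")
    for lead in doc.leads:
        el = etree.SubElement(leads_el, "lead", id=str(lead.lead_id))
        el.set("x", _fmt_num(lead.x, p))
        el.set("y", _fmt_num(lead.y, p))
        if lead.location is not None:
            el.set("location", lead.location)
        if lead.myocardial_region is not None:
            el.set("myocardialRegion", lead.myocardial_region)
        if lead.data_kind != "raw":
            el.set("data", lead.data_kind)
        if lead.data_kind == "calc":
            el.text = equations.pretty_print(lead.expression)
        else:
            el.text = _fmt_csv_numbers(lead.samples, p)

    if indent:
        etree.indent(root, space="  ")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


def _build_patient(parent, pat: Patient) -> None:
    el = etree.SubElement(parent, "patient", id=pat.patient_id)
    fields = [
        ("fullName", pat.full_name),
        ("sex", pat.sex.value if pat.sex is not None else None),
        ("DOB", pat.dob.isoformat() if pat.dob is not None else None),
        ("address", pat.address),
        ("city", pat.city),
        ("state", pat.state),
        ("country", pat.country),
        ("postalCode", pat.postal_code),
        ("phone", pat.phone),
        ("fax", pat.fax),
        ("email", pat.email),
        ("diagnosis", pat.diagnosis),
        ("computerisedDiagnosis", pat.computerised_diagnosis),
    ]
    for name, value in fields:
        if value is not None:
            etree.SubElement(el, name).text = value


def _build_record(parent, rec: Record, p: Optional[int]) -> None:
    el = etree.SubElement(parent, "record")
    if rec.recording_device is not None:
        el.set("recordingDevice", rec.recording_device)
    if rec.recording_time is not None:
        el.set("recordingTime", _fmt_time(rec.recording_time))
    if rec.recording_date is not None:
        el.set("recordingDate", rec.recording_date.isoformat())
    if rec.investigator is not None:
        el.set("investigator", rec.investigator)
    el.set("layoutName", rec.layout_name)
    el.set("leads", str(rec.lead_count))
    el.set("samples", str(rec.samples_per_lead))
    el.set("frequency", f"{_fmt_num(rec.frequency_hz)} Hz")
    if rec.sample_multiplier != 1:
        el.set("sampleMultiplier", _fmt_num(rec.sample_multiplier, p))
    if rec.notes is not None:
        etree.SubElement(el, "notes").text = rec.notes


def _build_annotations(parent, ann: Annotations) -> None:
    el = etree.SubElement(parent, "annotations")
    if ann.hr is not None:
        el.set("HR", str(ann.hr))
    if ann.p_axis is not None:
        el.set("pAxis", str(ann.p_axis))
    if ann.qrs_axis is not None:
        el.set("qrsAxis", str(ann.qrs_axis))
    if ann.t_axis is not None:
        el.set("tAxis", str(ann.t_axis))
    for la in ann.lead_annotations:
        la_el = etree.SubElement(el, "leadAnn", leadID=la.lead_id)
        for kind in MARKER_KINDS:
            if kind in la.markers:
                etree.SubElement(la_el, kind).text = ",".join(
                    str(v) for v in la.markers[kind]
                )


def _build_section(parent, section: CommentSection, p: Optional[int]) -> None:
    el = etree.SubElement(parent, "section")
    if section.lead_id is not None:
        el.set("leadID", section.lead_id)
    if section.ms is not None:
        el.set("ms", _fmt_num(section.ms, p))
    if section.mv is not None:
        el.set("mV", _fmt_num(section.mv, p))
    for c in section.comments:
        c_el = etree.SubElement(el, "comment", fullName=c.full_name)
        if c.email is not None:
            c_el.set("email", c.email)
        c_el.set("date", c.date.isoformat())
        c_el.set("time", _fmt_time(c.time))
        c_el.text = c.text


def build_transformation_element(t: Transformation, p: Optional[int] = None):
    """Build a ``transformation`` element (also the external-file root form)."""
    el = etree.Element("transformation", name=t.name)
    if t.url is not None:
        el.set("url", t.url)
    for tl in t.transform_leads:
        tl_el = etree.SubElement(el, "transformLead", name=tl.name)
        if tl.x is not None:
            tl_el.set("x", _fmt_num(tl.x, p))
        if tl.y is not None:
            tl_el.set("y", _fmt_num(tl.y, p))
        if tl.location is not None:
            tl_el.set("location", tl.location)
        if tl.myocardial_region is not None:
            tl_el.set("myocardialRegion", tl.myocardial_region)
        tl_el.text = equations.pretty_print(tl.expression)
    return el


def _build_diagram(parent, dia: Diagram, p: Optional[int]) -> None:
    el = etree.SubElement(parent, "diagram")
    if dia.url is not None:
        el.set("url", dia.url)
    if dia.wave_scale != 0.04:
        el.set("waveScale", _fmt_num(dia.wave_scale, p))
    if "]]>" in dia.embedded_svg:
        raise BspmValidationError(
            "embedded SVG contains ']]>' which cannot be stored in a CDATA "
            "section; remove or re-encode the sequence"
        )
    el.text = etree.CDATA(dia.embedded_svg)


# ---------------------------------------------------------------------------
# diagram resolution and compression statistics

def resolve_diagram(
    doc: BspmDocument,
    allow_external: bool = False,
    fetcher: Optional[Callable[[str], Union[str, bytes]]] = None,
) -> tuple[str, str]:
    """Return ``(svg_markup, provenance)`` for the document's torso diagram.

    The format stores a URL to a rich external diagram plus a simplistic
    embedded fallback.  With ``allow_external`` and a working ``fetcher`` the
    external SVG is preferred; any fetch failure falls back to the embedded
    copy.  Provenance is ``"external"`` or ``"embedded"``.  If no usable
    diagram exists at all the document cannot be displayed and
    :class:`DiagramError` is raised.
    """
    dia = doc.header.diagram
    if allow_external and dia.url and fetcher is not None:
        try:
            content = fetcher(dia.url)
            if isinstance(content, bytes):
                content = content.decode("utf-8")
            etree.fromstring(content.encode("utf-8"))
            return content, "external"
        except Exception:
            pass  # fall back to the embedded copy
    svg = dia.embedded_svg
    if svg:
        try:
            etree.fromstring(svg.encode("utf-8"))
            return svg, "embedded"
        except etree.XMLSyntaxError:
            pass
    raise DiagramError(
        "no usable torso diagram: external fetch unavailable or failed and "
        "the embedded SVG is absent or unparseable"
    )


def compression_stats(serialized: bytes) -> dict[str, int]:
    """Sizes of the raw bytes and their deflate- and gzip-compressed forms.

    Uses the default compression level; the gzip stream is written with a
    zeroed timestamp so the statistic is deterministic.
    """
    if not serialized:
        raise ValueError("empty byte stream")
    return {
        "rawBytes": len(serialized),
        "deflateBytes": len(zlib.compress(serialized)),
        "gzipBytes": len(gzip.compress(serialized, mtime=0)),
    }
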