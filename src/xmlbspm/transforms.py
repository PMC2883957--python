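"""Built-in Lux-192 transformation sets and generic transformation application.

A BSPM rarely samples the exact electrode sites of the 12-lead ECG or the
Frank vectorcardiogram, so derived leads are expressed as equations over the
map's own unipolar leads.  For the Lux-192 layout the torso sites of the
Mason-Likar (proximal) limb electrodes coincide with map electrodes: lead 25
is the right arm (RA), lead 85 the left arm (LA) and lead 96 the left foot
(LF), yielding the exercise variant of the 12-lead ECG.  The Wilson central
terminal cancels in every difference of unipolar leads, so plain differences
are correct:

    I = LA - RA,  II = LF - RA,  III = LF - LA          (Einthoven)
    aVR = RA - (LA+LF)/2, aVL = LA - (RA+LF)/2, aVF = LF - (RA+LA)/2
                                                         (Goldberger)

V1 is interpolated midway between map leads 52 and 53.  The Einthoven and
Goldberger formulas themselves are standard electrocardiography, not part of
the stored dataset.  The remaining precordial leads V2-V6 have no published
interpolation for this layout and are left as an extension point: supply
them through an external transformation file.

The Frank VCG sites are all map electrodes: I=16, A=100, H=145, F=156, E=64,
M=148.  Axis polarity follows the common Frank convention — X positive
leftward (A-I), Y positive inferior (F-H), Z positive posterior (M-E) — with
an optional flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lxml import etree

from . import equations, xmlio
from .errors import BspmParseError, BspmSchemaError, EquationEvalError
from .model import BspmDocument, Transformation, TransformLead

__all__ = [
    "Lux192TransformConstants",
    "LUX192",
    "lux192_to_12lead_transformation",
    "lux192_to_vcg_transformation",
    "apply_transformation",
    "load_external_transformation",
    "write_transformation",
]


@dataclass(frozen=True)
class Lux192TransformConstants:
    """Lux-192 lead numbers of the special electrode sites."""

    right_arm_lead: int = 25
    left_arm_lead: int = 85
    left_foot_lead: int = 96
    v1_source_leads: tuple[int, int] = (52, 53)
    # Frank electrode label -> Lux-192 lead number
    vcg_leads: tuple[tuple[str, int], ...] = (
        ("I", 16),
        ("A", 100),
        ("H", 145),
        ("F", 156),
        ("E", 64),
        ("M", 148),
    )

    def vcg(self) -> dict[str, int]:
        return dict(self.vcg_leads)


LUX192 = Lux192TransformConstants()


def _e(text: str) -> equations.Expression:
    return equations.parse_expression(text)


def lux192_to_12lead_transformation(
    precordial: dict[str, str] | None = None,
) -> Transformation:
    """The 12-lead ECG (Mason-Likar exercise variant) from a Lux-192 map.

    Returns a Transformation with I, II, III, aVR, aVL, aVF and the
    interpolated V1.  ``precordial`` may supply equation text for further
    chest leads (e.g. ``{"V2": "([Lead56]+[Lead57])/2"}``); without it only
    the seven constructible leads are emitted.
    """
    ra, la, lf = LUX192.right_arm_lead, LUX192.left_arm_lead, LUX192.left_foot_lead
    s52, s53 = LUX192.v1_source_leads
    entries = [
        ("I", f"[Lead{la}] - [Lead{ra}]"),
        ("II", f"[Lead{lf}] - [Lead{ra}]"),
        ("III", f"[Lead{lf}] - [Lead{la}]"),
        ("aVR", f"[Lead{ra}] - ([Lead{la}] + [Lead{lf}])/2"),
        ("aVL", f"[Lead{la}] - ([Lead{ra}] + [Lead{lf}])/2"),
        ("aVF", f"[Lead{lf}] - ([Lead{ra}] + [Lead{la}])/2"),
        ("V1", f"([Lead{s52}] + [Lead{s53}])/2"),
    ]
    if precordial:
        entries.extend(sorted(precordial.items()))
    return Transformation(
        name="12-lead ECG",
        transform_leads=[TransformLead(name=n, expression=_e(t)) for n, t in entries],
    )


def lux192_to_vcg_transformation(flip_polarity: bool = False) -> Transformation:
    """The Frank-system vectorcardiogram (X, Y, Z) from a Lux-192 map.

    Default polarity: X = A - I (positive leftward), Y = F - H (positive
    inferior), Z = M - E (positive posterior).  ``flip_polarity`` negates all
    three axes for the opposite convention.
    """
    v = LUX192.vcg()
    pairs = [("X", v["A"], v["I"]), ("Y", v["F"], v["H"]), ("Z", v["M"], v["E"])]
    leads = []
    for name, pos, neg in pairs:
        if flip_polarity:
            pos, neg = neg, pos
        leads.append(TransformLead(name=name, expression=_e(f"[Lead{pos}] - [Lead{neg}]")))
    return Transformation(name="VCG", transform_leads=leads)


def apply_transformation(
    doc: BspmDocument, transformation: Transformation
) -> dict[str, np.ndarray]:
    """Evaluate every transformLead of a transformation against a document.

    Returns an ordered mapping of derived-lead name to its sample vector
    (length ``samplesPerLead``, actual units).  Signals are resolved through
    :func:`xmlbspm.equations.resolve_signals`, so the sample multiplier is
    applied and calc leads are available to the equations.  A missing lead or
    limb-lead reference raises naming both the transformLead and the
    reference.
    """
    sig = equations.resolve_signals(doc)
    lead_map = {lid: sig.values[i] for i, lid in enumerate(sig.lead_ids)}
    out: dict[str, np.ndarray] = {}
    for tl in transformation.transform_leads:
        try:
            out[tl.name] = equations.evaluate(
                tl.expression, lead_map, sig.limb_leads, n=sig.n_samples
            )
        except EquationEvalError as exc:
            raise EquationEvalError(
                f"transformLead {tl.name!r} of {transformation.name!r}: {exc}"
            ) from exc
    return out


def load_external_transformation(content: bytes) -> Transformation:
    """Parse an external transformation XML file (root ``transformation``).

    External files use exactly the in-document element form, so BSPM files
    can share one set of equations by URL.
    """
    try:
        root = etree.fromstring(content)
    except etree.XMLSyntaxError as exc:
        raise BspmParseError(str(exc), exc.lineno) from exc
    if etree.QName(root).localname != "transformation":
        raise BspmSchemaError(
            f"root element is {etree.QName(root).localname!r}, expected 'transformation'",
            "/",
        )
    return xmlio.parse_transformation_element(root, "transformation")


def write_transformation(transformation: Transformation) -> bytes:
    """Serialise a transformation to the external-file XML form."""
    el = xmlio.build_transformation_element(transformation)
    etree.indent(el, space="  ")
    return etree.tostring(el, xml_declaration=True, encoding="UTF-8")
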