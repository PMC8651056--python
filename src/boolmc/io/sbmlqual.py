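"""SBML-qual reader (import only).

Parses the qualitative-models extension of SBML: ``qualitativeSpecies``
(id, maxLevel, initialLevel) and ``transition`` elements whose
``functionTerm`` MathML decides the target level; the ``defaultTerm``
applies when no function term matches.  The supported MathML subset is
``and / or / not / xor`` over comparisons (``eq, neq, geq, gt, leq,
lt``) between a species and an integer constant, bare Boolean species,
and the constants ``true``/``false``.  Sign/threshold attributes on
transition inputs are ignored: the math is authoritative.

Species without any transition are treated as inputs held at their
initial level.
"""

from __future__ import annotations

from lxml import etree

from .bnet import FormatError
from ..multivalued import (
    LevelAnd,
    LevelCmp,
    LevelConst,
    LevelExpr,
    LevelNot,
    LevelOr,
    LevelXor,
    MultiValuedModel,
    Variable,
)

__all__ = ["read_sbml_qual"]

QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATH_NS = "http://www.w3.org/1998/Math/MathML"


def _qual(tag: str) -> str:
    return f"{{{QUAL_NS}}}{tag}"


def _math(tag: str) -> str:
    return f"{{{MATH_NS}}}{tag}"


def _local(element) -> str:
    return etree.QName(element).localname


_CMP_TAGS = {"eq": "eq", "neq": "neq", "geq": "geq", "gt": "gt", "leq": "leq", "lt": "lt"}
_LOGIC_TAGS = {"and": LevelAnd, "or": LevelOr, "xor": LevelXor}


def _parse_operand(element) -> tuple[str, str | None, int | None]:
    """Returns (kind, name, value): kind is 'ci' or 'cn'."""
    tag = _local(element)
    if tag == "ci":
        return "ci", element.text.strip(), None
    if tag == "cn":
        text = (element.text or "").strip()
        try:
            value = int(float(text))
        except ValueError:
            raise FormatError(f"non-integer constant {text!r} in qual math") from None
        return "cn", None, value
    raise FormatError(f"unsupported MathML operand <{tag}>")


def _parse_math_node(element) -> LevelExpr:
    tag = _local(element)
    if tag == "apply":
        children = [c for c in element if isinstance(c.tag, str)]
        if not children:
            raise FormatError("empty <apply> in qual math")
        op = _local(children[0])
        args = children[1:]
        if op in _CMP_TAGS:
            if len(args) != 2:
                raise FormatError(f"comparison <{op}> needs two operands")
            a = _parse_operand(args[0])
            b = _parse_operand(args[1])
            if a[0] == "ci" and b[0] == "cn":
                return LevelCmp(a[1], op, b[2])
            if a[0] == "cn" and b[0] == "ci":
                flipped = {"geq": "leq", "leq": "geq", "gt": "lt", "lt": "gt"}
                return LevelCmp(b[1], flipped.get(op, op), a[2])
            raise FormatError(
                f"comparison <{op}> must relate a species to an integer level"
            )
        if op in _LOGIC_TAGS:
            return _LOGIC_TAGS[op](tuple(_parse_math_node(a) for a in args))
        if op == "not":
            if len(args) != 1:
                raise FormatError("<not> needs exactly one operand")
            return LevelNot(_parse_math_node(args[0]))
        raise FormatError(f"unsupported MathML operator <{op}>")
    if tag == "ci":
        # bare Boolean species: active means level >= 1
        return LevelCmp(element.text.strip(), "geq", 1)
    if tag == "true":
        return LevelConst(True)
    if tag == "false":
        return LevelConst(False)
    raise FormatError(f"unsupported MathML element <{tag}>")


def _parse_math(math_element) -> LevelExpr:
    children = [c for c in math_element if isinstance(c.tag, str)]
    if len(children) != 1:
        raise FormatError("<math> must contain exactly one expression")
    return _parse_math_node(children[0])


def read_sbml_qual(source) -> MultiValuedModel:
    """Read an SBML-qual document (path, file object, or bytes/str)."""
    if isinstance(source, (str, bytes)) and (
        isinstance(source, bytes) or source.lstrip().startswith("<")
    ):
        data = source.encode() if isinstance(source, str) else source
        root = etree.fromstring(data)
    else:
        root = etree.parse(source).getroot()

    species_elements = root.findall(f".//{_qual('qualitativeSpecies')}")
    if not species_elements:
        raise FormatError("document contains no qual:qualitativeSpecies")
    variables: dict[str, Variable] = {}
    order: list[str] = []
    for el in species_elements:
        sid = el.get(_qual("id")) or el.get("id")
        if not sid:
            raise FormatError("qualitativeSpecies without an id")
        max_level = int(el.get(_qual("maxLevel")) or el.get("maxLevel") or 1)
        initial = el.get(_qual("initialLevel")) or el.get("initialLevel")
        variables[sid] = Variable(
            name=sid,
            max_level=max_level,
            rules=None,  # input until a transition targets it
            initial_level=int(initial) if initial is not None else None,
        )
        order.append(sid)

    for tr in root.findall(f".//{_qual('transition')}"):
        outputs = tr.findall(f".//{_qual('output')}")
        if not outputs:
            raise FormatError("transition without an output species")
        target_ids = []
        for out in outputs:
            sid = out.get(_qual("qualitativeSpecies")) or out.get("qualitativeSpecies")
            if sid not in variables:
                raise FormatError(f"transition output references unknown species {sid!r}")
            target_ids.append(sid)
        rules: list[tuple[LevelExpr, int]] = []
        for term in tr.findall(f".//{_qual('functionTerm')}"):
            level = term.get(_qual("resultLevel")) or term.get("resultLevel")
            if level is None:
                raise FormatError("functionTerm without resultLevel")
            math = term.find(_math("math"))
            if math is None:
                raise FormatError("functionTerm without <math>")
            rules.append((_parse_math(math), int(level)))
        default = tr.find(f".//{_qual('defaultTerm')}")
        if default is None:
            raise FormatError("transition lacks a defaultTerm")
        default_level = default.get(_qual("resultLevel")) or default.get("resultLevel")
        if default_level is None:
            raise FormatError("defaultTerm without resultLevel")
        for sid in target_ids:
            var = variables[sid]
            for _, level in rules:
                if level > var.max_level:
                    raise FormatError(
                        f"resultLevel {level} exceeds maxLevel {var.max_level} of {sid!r}"
                    )
            if int(default_level) > var.max_level:
                raise FormatError(
                    f"default resultLevel {default_level} exceeds maxLevel of {sid!r}"
                )
            var.rules = list(rules)
            var.default_level = int(default_level)

    return MultiValuedModel(
        variables=[variables[name] for name in order], provenance="sbml-qual"
    )
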