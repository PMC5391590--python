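"""ICD-10 / CCAM code sets and family-matching semantics.

Diagnosis codes are dotted ICD-10 strings (``I26.0``, ``Z37.0``).  A code
*pattern* can designate a whole family:

* ``"O35.x"`` — any code starting with ``O35`` (``O35``, ``O35.1``, ...),
* ``"I26"`` — a bare three-character category, also matched as a prefix,
* anything else (``"G56.0"``) — matched exactly.

Procedure codes (CCAM style, e.g. ``AHPA009``) are always matched exactly.
The pulmonary-embolism diagnosis list and the PE-diagnostic procedure list
default to small plausible sets and are configurable: real-world extractions
should supply the locally validated lists.
"""

from __future__ import annotations

from typing import Callable, Iterable

# Delivery coding: single live birth, with exclusions for fetal-anomaly /
# abnormal-antenatal-screening stays that can carry delivery codes too.
DELIVERY_DX = "Z37.0"
DELIVERY_EXCLUSION_DX = ("O35.x", "O28.x")

# Primary diagnoses compatible with a delivery admission (obstetric chapter).
DELIVERY_COMPATIBLE_PRIMARY = ("O80.x", "O81.x", "O82.x", "O83.x", "O84.x", "Z37.x")

# CCAM-style dated procedures marking the delivery itself.
DELIVERY_PROCEDURES = ("JQGD010", "JQGA002")

# Default pulmonary-embolism diagnosis set (configurable).
DEFAULT_PE_DX = ("I26.0", "I26.9", "O88.2")

# Synthetic placeholder codes for dated PE-diagnostic imaging procedures
# (configurable; stands in for the CT-angiography / scintigraphy CCAM list).
DEFAULT_PE_PROCEDURES = ("ZBQK001", "ZBQK002")

# Negative-control exposure: carpal-tunnel syndrome + median-nerve release.
NEGATIVE_CONTROL_DX = "G56.0"
NEGATIVE_CONTROL_PROCEDURE = "AHPA009"


def _single_matcher(pattern: str) -> Callable[[str], bool]:
    if pattern.endswith(".x"):
        prefix = pattern[:-2]
        return lambda code: code.startswith(prefix)
    if "." not in pattern and len(pattern) <= 3:
        return lambda code: code.startswith(pattern)
    return lambda code: code == pattern


def code_matcher(patterns: Iterable[str]) -> Callable[[str], bool]:
    """Return a predicate testing a code against a collection of patterns."""
    matchers = tuple(_single_matcher(p) for p in patterns)
    if not matchers:
        return lambda code: False

    def match(code: str) -> bool:
        return any(m(code) for m in matchers)

    return match


def matches(code: str, pattern: str) -> bool:
    """Test one code against one pattern (see module docstring for rules)."""
    return _single_matcher(pattern)(code)
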