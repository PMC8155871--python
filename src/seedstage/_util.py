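"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as printed report tables do.

    numpy/python round() rounds half to even; report tables round 0.245 -> 0.25.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def stage_label(index: int) -> str:
    """Ordinal maturity-stage label, 1-based ('MS1'..)."""
    return f"MS{int(index)}"


def stage_index(label) -> int:
    """Inverse of :func:`stage_label`; also accepts plain integers."""
    if isinstance(label, (int,)):
        return int(label)
    s = str(label).strip()
    if s.upper().startswith("MS"):
        return int(s[2:])
    return int(s)
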