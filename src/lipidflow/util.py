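"""Small shared numeric helpers."""

from __future__ import annotations


def percent(part: float, whole: float, ndigits: int | None = None) -> float:
    """100 * part / whole, optionally rounded (ndigits=0 returns an int-valued
    float rounded half away from banker's only via round())."""
    if whole == 0:
        raise ZeroDivisionError("whole must be non-zero")
    value = 100.0 * part / whole
    return value if ndigits is None else round(value, ndigits)


def relative_increase_percent(new: float, old: float,
                              ndigits: int | None = None) -> float:
    """Percent increase of ``new`` over ``old``: 100 * (new - old) / old."""
    if old == 0:
        raise ZeroDivisionError("old must be non-zero")
    value = 100.0 * (new - old) / old
    return value if ndigits is None else round(value, ndigits)
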