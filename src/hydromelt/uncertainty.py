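"""Parenthesized last-digit uncertainty notation, e.g. ``0.832 (4)``.

The convention in published hydration tables: the number in parentheses
is the 1-sigma uncertainty expressed in units of the last printed digit
of the value, so ``0.832 (4)`` means 0.832 ± 0.004 and ``226 (3)`` means
226 ± 3.  Multi-digit errors such as ``241 (147)`` are allowed.
"""

from __future__ import annotations

import math
import re

from .errors import InvalidInputError

_PAREN_RE = re.compile(
    r"^\s*(?P<bound>[<>]?)\s*(?P<value>[+-]?\d+(?:\.\d+)?)\s*\(\s*(?P<err>\d+)\s*\)\s*$"
)


def format_paren(value: float, err: float) -> str:
    """Format ``value ± err`` in last-digit parenthesis notation.

    The number of printed decimals is chosen from the magnitude of the
    error (the error occupies the last one or two digits); errors >= 1
    produce integer formatting.
    """
    if err < 0 or not math.isfinite(err):
        raise InvalidInputError("err must be finite and >= 0")
    if err == 0:
        return f"{value:g}"
    if err >= 0.95:
        return f"{value:.0f} ({err:.0f})"
    decimals = -math.floor(math.log10(err))
    err_digits = round(err * 10 ** decimals)
    if err_digits >= 10:  # e.g. err=0.095 rounds up a decade
        decimals -= 1
        err_digits = round(err * 10 ** decimals)
    return f"{value:.{decimals}f} ({err_digits:d})"


def parse_paren(text: str) -> tuple[float, float]:
    """Parse ``"0.832 (4)"`` → ``(0.832, 0.004)``.

    Leading ``>`` / ``<`` lower/upper-bound markers are accepted and
    ignored for the numeric value.
    """
    m = _PAREN_RE.match(text)
    if m is None:
        raise InvalidInputError(f"not in parenthesized-uncertainty notation: {text!r}")
    value_str = m.group("value")
    err_digits = int(m.group("err"))
    if "." in value_str:
        decimals = len(value_str.split(".")[1])
    else:
        decimals = 0
    return float(value_str), err_digits * 10.0 ** (-decimals)
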