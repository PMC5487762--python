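"""Shared activity-class vocabulary and label coercion helpers."""

from __future__ import annotations

import numpy as np

INHIBITOR = "inhibitor"
NON_INHIBITOR = "non-inhibitor"
EXCLUDED = "excluded"
UNKNOWN = "unknown"
UNPREDICTED = "unpredicted"

HIGHER_IS_INHIBITOR = "higher_is_inhibitor"
LOWER_IS_INHIBITOR = "lower_is_inhibitor"
ORIENTATIONS = (HIGHER_IS_INHIBITOR, LOWER_IS_INHIBITOR)

BINARY_LABELS = (INHIBITOR, NON_INHIBITOR)


def as_binary(labels, allow_unpredicted: bool = False) -> np.ndarray:
    """Map a label vector to float {1.0, 0.0} with 1 = inhibitor.

    Accepts the string vocabulary, booleans or 0/1 integers. With
    ``allow_unpredicted`` the ``"unpredicted"`` marker (or NaN) maps to NaN
    instead of raising.
    """
    arr = np.asarray(labels, dtype=object).ravel()
    out = np.empty(arr.shape, dtype=float)
    for i, v in enumerate(arr):
        if v == INHIBITOR or v is True or v == 1:
            out[i] = 1.0
        elif v == NON_INHIBITOR or v is False or v == 0:
            out[i] = 0.0
        elif allow_unpredicted and (
            v == UNPREDICTED or v is None or (isinstance(v, float) and np.isnan(v))
        ):
            out[i] = np.nan
        else:
            raise ValueError(f"cannot interpret label {v!r} as binary activity class")
    return out


def from_binary(binary, template) -> np.ndarray:
    """Inverse of :func:`as_binary`, emitting labels in the style of ``template``.

    If ``template`` contains activity-class strings, strings are returned;
    otherwise 0/1 integers.
    """
    tmpl = np.asarray(template, dtype=object).ravel()
    stringy = any(isinstance(v, str) for v in tmpl)
    b = np.asarray(binary, dtype=float).ravel()
    if stringy or np.isnan(b).any():
        out = np.empty(b.shape, dtype=object)
        out[np.isnan(b)] = UNPREDICTED
        out[b == 1.0] = INHIBITOR
        out[b == 0.0] = NON_INHIBITOR
        return out
    return b.astype(int)
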