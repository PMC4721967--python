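"""The eight-class conformational taxonomy of a dimeric coiled-coil molecule.

A molecule is classified by three binary structural features seen in its
traced anatomy: whether the N terminus is splayed, whether the C terminus is
splayed, and whether a central unwinding bubble is present.
"""

from __future__ import annotations

from itertools import product


def conformation_label(n_splay: bool, c_splay: bool, bubble: bool) -> str:
    """Canonical class label for a (N-splay, C-splay, bubble) combination."""
    parts = []
    if n_splay:
        parts.append("splayN")
    if c_splay:
        parts.append("splayC")
    if bubble:
        parts.append("bubble")
    return "+".join(parts) if parts else "rod"


#: All eight class labels, rod first, in a fixed reporting order.
ALL_CLASSES: tuple[str, ...] = tuple(
    conformation_label(n, c, b) for n, c, b in product((False, True), repeat=3)
)


def class_features(label: str) -> tuple[bool, bool, bool]:
    """Invert :func:`conformation_label` -> (n_splay, c_splay, bubble)."""
    if label == "rod":
        return (False, False, False)
    parts = set(label.split("+"))
    unknown = parts - {"splayN", "splayC", "bubble"}
    if unknown or not parts:
        raise ValueError(f"unknown conformation label {label!r}")
    return ("splayN" in parts, "splayC" in parts, "bubble" in parts)
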