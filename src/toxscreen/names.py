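"""Compound-name normalization shared by record lookup and report merging.

Hazard databases and assignment outputs disagree on stereochemistry
prefixes ("L-glutamic acid" vs "glutamic acid"), so lookups fall back to a
normalized key: case-folded, whitespace-collapsed, with a leading
stereo-descriptor prefix (L-, D-, DL-, (+)-, (-)-, (+/-)-) stripped.
"""

from __future__ import annotations

import re

_STEREO_PREFIX = re.compile(
    r"^(?:dl-|d-|l-|\(\+\)-|\(-\)-|\(−\)-|\(\+/-\)-|\(±\)-)",
    re.IGNORECASE,
)


def casefold_name(name: str) -> str:
    """Primary lookup key: case-insensitive, whitespace-collapsed."""
    return " ".join(name.split()).casefold()


def normalize_name(name: str) -> str:
    """Secondary lookup key: casefolded with stereo prefixes stripped."""
    key = casefold_name(name)
    while True:
        stripped = _STEREO_PREFIX.sub("", key)
        if stripped == key:
            return key
        key = stripped
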