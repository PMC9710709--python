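"""DNA alphabet helpers: encoding, reverse complement, sanitization.

Internally sequences are encoded over {0: sentinel, 1: A, 2: C, 3: G,
4: T}; the sentinel sorts below every base. Ambiguous characters are
never encoded: callers split sequences at non-ACGT runs first.
"""

from __future__ import annotations

import re

import numpy as np

SENTINEL = 0
ALPHABET = "ACGT"
NSYMBOLS = 5  # sentinel + 4 bases

_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}
_DECODE = np.array([ord("$"), ord("A"), ord("C"), ord("G"), ord("T")], dtype=np.uint8)

# byte value -> code, 255 for anything that is not an uppercase base
_BYTE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _BYTE_CODE[ord(_b)] = _c

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_ACGT_RUN = re.compile(r"[ACGT]+")


def complement_code(code: int) -> int:
    """Complement of an encoded base (A<->T, C<->G)."""
    return 5 - code


def reverse_complement(s: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return s.translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> str:
    """Lexicographically smaller of a string and its reverse complement."""
    rc = reverse_complement(s)
    return s if s <= rc else rc


def encode(s: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array.

    Raises ValueError on any character outside ACGT.
    """
    codes = _BYTE_CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() == 255:
        bad = s[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid symbol {bad!r}: expected one of A,C,G,T")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def split_fragments(s: str) -> list[tuple[int, str]]:
    """Split an (uppercased) sequence at non-ACGT runs.

    Returns ``(offset, fragment)`` pairs; offsets refer to the original
    string. Characters such as N are dropped, so no fragment spans them.
    """
    return [(m.start(), m.group(0)) for m in _ACGT_RUN.finditer(s)]
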