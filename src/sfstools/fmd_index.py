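"""Bidirectional FM-index over a DNA string collection.

The index stores the Burrows-Wheeler transform of the concatenation of
all indexed fragments (each terminated by a sentinel that sorts below
every base). In the default ``both`` strand mode the reverse complement
of every fragment is indexed too, so one BWT supports both backward
(prepend) and forward (append) extension of a *bi-interval*: the triple
``[i, j, l]`` holding the suffix-array interval ``[i, i+l)`` of a string
Q, the interval ``[j, j+l)`` of its mate (reverse complement), and the
shared width ``l`` = number of occurrences of Q.

``single`` strand mode indexes only the given orientation; forward
extension is then served by a second BWT built over the *reversed*
fragments, with the mate interval tracking ``reverse(Q)``. This mode
exists so that membership is over one strand only, which some of the
theoretical guarantees (and their tests) require.
"""

from __future__ import annotations

import logging
import zipfile
from typing import Iterable, NamedTuple

import numpy as np

from sfstools.alphabet import NSYMBOLS, SENTINEL, encode, split_fragments

logger = logging.getLogger(__name__)

_MAGIC = "SFSTOOLS-FMD-INDEX"
_FORMAT_VERSION = 1

_CHAR_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


class IndexFormatError(ValueError):
    """Raised when an index file is corrupt or has an unsupported version."""


class BiInterval(NamedTuple):
    """Paired suffix-array intervals of a string and its mate.

    ``i``: start of the Q-interval, ``j``: start of the mate interval
    (reverse complement in ``both`` mode, reversed string in ``single``
    mode), ``l``: shared width = occurrence count of Q in the indexed
    text. ``l == 0`` means Q does not occur.
    """

    i: int
    j: int
    l: int

    @property
    def empty(self) -> bool:
        return self.l == 0


def _suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array of a small-alphabet uint8 text, by prefix doubling.

    O(n log^2 n); adequate at the scales this package targets. Sentinels
    all share code 0, which yields the plain suffix array of the
    concatenation -- correct for counting ACGT queries, which can never
    match across a sentinel.
    """
    n = text.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = text.astype(np.int32)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int32)
        if k < n:
            key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1 = rank[sa]
        r2 = key2[sa]
        changed = np.empty(n, dtype=np.int32)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.cumsum(changed, dtype=np.int32)
        rank = np.empty(n, dtype=np.int32)
        rank[sa] = new_rank
        if int(new_rank[-1]) == n - 1:
            return sa
        k *= 2


def _bwt_from_text(text: np.ndarray) -> np.ndarray:
    sa = _suffix_array(text)
    prev = np.where(sa == 0, text.size - 1, sa - 1)
    return text[prev]


class _Half:
    """One BWT with its rank structure (cumulative occurrence table)."""

    __slots__ = ("bwt", "occ", "C")

    def __init__(self, bwt: np.ndarray):
        self.bwt = bwt
        n = bwt.size
        occ = np.zeros((n + 1, NSYMBOLS), dtype=np.int32)
        for c in range(NSYMBOLS):
            np.cumsum(bwt == c, dtype=np.int32, out=occ[1:, c])
        self.occ = occ
        counts = occ[n]
        self.C = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    @classmethod
    def from_text(cls, text: np.ndarray) -> "_Half":
        return cls(_bwt_from_text(text))


def _extend(occ: np.ndarray, C: np.ndarray, i: int, j: int, l: int, a: int,
            desc: bool) -> tuple[int, int, int]:
    """Backward-extend interval [i, i+l) with symbol ``a``; update mate j.

    Within the mate interval, sub-intervals for the possible following
    characters appear in sentinel-first order; whether the extending
    symbol's slot is addressed through its complement (``desc``, reverse-
    complement mates) or directly (ascending, reversed-string mates)
    depends on the strand mode.
    """
    bot = occ[i]
    top = occ[i + l]
    i2 = int(C[a]) + int(bot[a])
    l2 = int(top[a]) - int(bot[a])
    before = int(top[SENTINEL]) - int(bot[SENTINEL])
    if desc:
        for c in range(a + 1, NSYMBOLS):
            before += int(top[c]) - int(bot[c])
    else:
        for c in range(1, a):
            before += int(top[c]) - int(bot[c])
    return i2, j + before, l2


class FMDIndex:
    """Queryable index over a string collection (and optionally its
    reverse complements), supporting bi-interval extension.

    Not built directly: use :func:`build_index` or :func:`load_index`.
    """

    def __init__(self, fwd: _Half, rev: _Half | None, strand_mode: str,
                 n_sequences: int):
        if strand_mode not in ("both", "single"):
            raise ValueError(f"unknown strand_mode {strand_mode!r}")
        self._fwd = fwd
        self._rev = fwd if rev is None else rev
        self.strand_mode = strand_mode
        self.n_sequences = n_sequences
        # instrumentation: number of extension / init queries served
        self.counters = {"init": 0, "backward": 0, "forward": 0}

    # -- introspection -------------------------------------------------

    @property
    def bwt_length(self) -> int:
        return int(self._fwd.bwt.size)

    @property
    def n_suffixes(self) -> int:
        """Width of the empty-string interval (= total indexed suffixes)."""
        return int(self._fwd.bwt.size)

    def reset_counters(self) -> None:
        for k in self.counters:
            self.counters[k] = 0

    # -- code-level operations (hot path, used by the search) ----------

    def init_code(self, a: int) -> BiInterval:
        self.counters["init"] += 1
        C = self._fwd.C
        l = int(C[a + 1]) - int(C[a])
        j = int(C[5 - a]) if self.strand_mode == "both" else int(C[a])
        return BiInterval(int(C[a]), j, l)

    def backward_code(self, iv: BiInterval, a: int) -> BiInterval:
        if iv.l == 0:
            return BiInterval(iv.i, iv.j, 0)
        self.counters["backward"] += 1
        half = self._fwd
        i2, j2, l2 = _extend(half.occ, half.C, iv.i, iv.j, iv.l, a,
                             self.strand_mode == "both")
        return BiInterval(i2, j2, l2)

    def forward_code(self, iv: BiInterval, a: int) -> BiInterval:
        if iv.l == 0:
            return BiInterval(iv.i, iv.j, 0)
        self.counters["forward"] += 1
        if self.strand_mode == "both":
            half, a2, desc = self._fwd, 5 - a, True
        else:
            half, a2, desc = self._rev, a, False
        j2, i2, l2 = _extend(half.occ, half.C, iv.j, iv.i, iv.l, a2, desc)
        return BiInterval(i2, j2, l2)

    # -- character-level public operations -----------------------------

    @staticmethod
    def _code(symbol: str) -> int:
        code = _CHAR_CODE.get(symbol)
        if code is None:
            raise ValueError(
                f"invalid symbol {symbol!r}: expected one of A,C,G,T")
        return code

    def init_interval(self, symbol: str) -> BiInterval:
        """Bi-interval of a single character."""
        return self.init_code(self._code(symbol))

    def backward_extension(self, interval: BiInterval, symbol: str) -> BiInterval:
        """Bi-interval of ``symbol + Q`` given the bi-interval of Q."""
        return self.backward_code(interval, self._code(symbol))

    def forward_extension(self, interval: BiInterval, symbol: str) -> BiInterval:
        """Bi-interval of ``Q + symbol`` given the bi-interval of Q."""
        return self.forward_code(interval, self._code(symbol))

    def interval_of(self, s: str) -> BiInterval:
        """Bi-interval of an arbitrary ACGT string, by chained backward
        extension (right to left)."""
        if not s:
            raise ValueError("empty query")
        codes = encode(s)
        iv = self.init_code(int(codes[-1]))
        for a in codes[-2::-1]:
            if iv.l == 0:
                return iv
            iv = self.backward_code(iv, int(a))
        return iv

    def occurs(self, s: str) -> bool:
        """True iff ``s`` occurs in the indexed text (both strands when
        strand_mode is ``both``)."""
        return self.interval_of(s).l > 0

    def count(self, s: str) -> int:
        """Number of occurrences of ``s`` in the indexed text."""
        return self.interval_of(s).l


def build_index(sequences: Iterable[str], strand_mode: str = "both") -> FMDIndex:
    """Build an index over ``sequences``.

    Sequences are uppercased and split at non-ACGT runs; a sequence with
    no ACGT character at all is skipped with a warning. Raises
    ValueError for an empty collection (nothing to index) or an unknown
    strand mode.
    """
    if strand_mode not in ("both", "single"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seqs = list(sequences)
    if not seqs:
        raise ValueError("nothing to index: empty collection")
    fragments: list[np.ndarray] = []
    n_sequences = 0
    for k, seq in enumerate(seqs):
        frags = split_fragments(seq.upper())
        if not frags:
            logger.warning("sequence %d has no ACGT characters; skipped", k)
            continue
        n_sequences += 1
        fragments.extend(encode(frag) for _, frag in frags)
    if not fragments:
        raise ValueError("nothing to index: no ACGT content in collection")

    sent = np.array([SENTINEL], dtype=np.uint8)
    parts: list[np.ndarray] = []
    for frag in fragments:
        parts.append(frag)
        parts.append(sent)
    if strand_mode == "both":
        for frag in fragments:
            parts.append((5 - frag)[::-1])  # reverse complement
            parts.append(sent)
        text = np.concatenate(parts)
        return FMDIndex(_Half.from_text(text), None, "both", n_sequences)
    text = np.concatenate(parts)
    rev_parts: list[np.ndarray] = []
    for frag in fragments:
        rev_parts.append(frag[::-1])
        rev_parts.append(sent)
    rev_text = np.concatenate(rev_parts)
    return FMDIndex(_Half.from_text(text), _Half.from_text(rev_text),
                    "single", n_sequences)


def save_index(index: FMDIndex, path) -> None:
    """Serialize an index to a single file (versioned container)."""
    payload = {
        "magic": np.frombuffer(_MAGIC.encode(), dtype=np.uint8),
        "version": np.array([_FORMAT_VERSION], dtype=np.int64),
        "strand_mode": np.array([0 if index.strand_mode == "both" else 1],
                                dtype=np.int64),
        "n_sequences": np.array([index.n_sequences], dtype=np.int64),
        "bwt_fwd": index._fwd.bwt,
    }
    if index.strand_mode == "single":
        payload["bwt_rev"] = index._rev.bwt
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_index(path) -> FMDIndex:
    """Load an index written by :func:`save_index`.

    Raises IndexFormatError for corrupt, truncated or version-mismatched
    files. Rank structures are rebuilt on load, so queries answer
    identically to the saved index.
    """
    try:
        with np.load(path) as data:
            files = set(data.files)
            if "magic" not in files or "version" not in files:
                raise IndexFormatError(f"{path}: not an sfstools index file")
            if data["magic"].tobytes().decode("ascii", "replace") != _MAGIC:
                raise IndexFormatError(f"{path}: not an sfstools index file")
            version = int(data["version"][0])
            if version != _FORMAT_VERSION:
                raise IndexFormatError(
                    f"{path}: unsupported index format version {version}")
            strand_mode = "both" if int(data["strand_mode"][0]) == 0 else "single"
            n_sequences = int(data["n_sequences"][0])
            fwd = _Half(data["bwt_fwd"].astype(np.uint8))
            rev = None
            if strand_mode == "single":
                if "bwt_rev" not in files:
                    raise IndexFormatError(f"{path}: missing reverse BWT")
                rev = _Half(data["bwt_rev"].astype(np.uint8))
    except IndexFormatError:
        raise
    except (OSError, ValueError, zipfile.BadZipFile, KeyError, EOFError) as exc:
        raise IndexFormatError(f"{path}: corrupt or unreadable index file "
                               f"({exc})") from exc
    return FMDIndex(fwd, rev, strand_mode, n_sequences)
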