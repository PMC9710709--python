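"""Enumeration of target-specific strings against an FMD index.

For a target string ``t`` and an indexed reference collection, a
*t-specific string* is a substring of ``t`` that does not occur in the
index and none of whose proper substrings is itself absent (the
substring-free property). The exact search enumerates all of them; the
relaxed search trades completeness for a linear query budget and emits a
subset occupying pairwise disjoint intervals of ``t``.

Both searches alternate between backward extension (grow the current
match leftward until it falls out of the index) and forward extension
(re-scan rightward from the failure point to find the shortest absent
string starting there). The exact variant resumes from the interval of
the emitted string minus its last character, so successive emissions may
overlap on ``t``; the relaxed variant restarts one position left of the
last emission start, so they cannot.
"""

from __future__ import annotations

import multiprocessing
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from sfstools.alphabet import canonical, encode, split_fragments
from sfstools.fmd_index import FMDIndex

MODES = ("exact", "relaxed")


@dataclass(frozen=True)
class SfsEmission:
    """One emitted specific string: ``sequence == t[begin:end)`` on the
    target it came from."""

    sequence: str
    target_id: str
    begin: int
    end: int


@dataclass
class SfsTable:
    """Aggregated occurrence counts of specific strings.

    Counts are keyed by the canonical form ``min(s, rc(s))`` so that a
    string and its reverse complement (the same event on opposite read
    strands) share one entry. Every emission event contributes 1.
    """

    counts: dict[str, int] = field(default_factory=dict)
    tau: int | None = None

    def add(self, sequence: str, n: int = 1) -> None:
        key = canonical(sequence)
        self.counts[key] = self.counts.get(key, 0) + n

    def merge(self, other: "SfsTable") -> None:
        for key, n in other.counts.items():
            self.counts[key] = self.counts.get(key, 0) + n

    def total(self) -> int:
        return sum(self.counts.values())

    def sorted_items(self) -> list[tuple[str, int]]:
        """Deterministic order: descending count, then lexicographic."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def __len__(self) -> int:
        return len(self.counts)


def filter_by_abundance(table: SfsTable, tau: int) -> SfsTable:
    """Keep entries seen at least ``tau`` times."""
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    kept = {s: n for s, n in table.counts.items() if n >= tau}
    return SfsTable(counts=kept, tau=tau)


# ---------------------------------------------------------------------
# core per-string searches (operate on encoded fragments)
# ---------------------------------------------------------------------

def _search_exact_codes(codes: np.ndarray, index: FMDIndex) -> list[tuple[int, int]]:
    """Exact search; returns half-open intervals of all specific strings.

    Worst case quadratic in ``len(codes)`` when emissions overlap heavily.
    """
    n = len(codes)
    out: list[tuple[int, int]] = []
    b = n - 1
    iv = index.init_code(int(codes[b]))
    while True:
        if iv.l == 0:
            # the character itself is absent: shortest specific string at b
            out.append((b, b + 1))
            b -= 1
            if b < 0:
                return out
            iv = index.init_code(int(codes[b]))
            continue
        # backward phase: grow leftward while still in the index
        while iv.l != 0 and b > 0:
            b -= 1
            iv = index.backward_code(iv, int(codes[b]))
        if iv.l != 0:
            # reached b == 0 with the prefix still present: no more starts
            return out
        # forward phase: shortest absent string starting at b
        e = b
        iv = index.init_code(int(codes[e]))
        if iv.l == 0:
            out.append((b, b + 1))
            b -= 1
            if b < 0:
                return out
            iv = index.init_code(int(codes[b]))
            continue
        saved = iv
        while iv.l != 0:
            saved = iv
            e += 1
            iv = index.forward_code(iv, int(codes[e]))
        out.append((b, e + 1))
        # resume from the emitted string minus its last character, whose
        # interval was saved during the forward phase; the next emission
        # may overlap this one
        iv = saved


def _search_relaxed_codes(codes: np.ndarray, index: FMDIndex) -> list[tuple[int, int]]:
    """Relaxed search; emitted intervals are pairwise disjoint and at
    most ``2 * len(codes)`` extension queries are issued."""
    n = len(codes)
    out: list[tuple[int, int]] = []
    b = n - 1
    iv = index.init_code(int(codes[b]))
    while True:
        if iv.l == 0:
            out.append((b, b + 1))
            b -= 1
            if b < 0:
                return out
            iv = index.init_code(int(codes[b]))
            continue
        while iv.l != 0 and b > 0:
            b -= 1
            iv = index.backward_code(iv, int(codes[b]))
        if iv.l != 0:
            return out
        e = b
        iv = index.init_code(int(codes[e]))
        if iv.l == 0:
            out.append((b, b + 1))
            b -= 1
            if b < 0:
                return out
            iv = index.init_code(int(codes[b]))
            continue
        while iv.l != 0:
            e += 1
            iv = index.forward_code(iv, int(codes[e]))
        out.append((b, e + 1))
        # restart one position left of this emission's start
        b -= 1
        if b < 0:
            return out
        iv = index.init_code(int(codes[b]))


_CODE_SEARCH = {"exact": _search_exact_codes, "relaxed": _search_relaxed_codes}


def _check_target(t: str) -> None:
    if not t:
        raise ValueError("empty target string")


def search_exact(t: str, index: FMDIndex, target_id: str = "target") -> list[SfsEmission]:
    """All specific strings of ``t`` (ACGT-only) against the index.

    The set of distinct emitted sequences is exactly the substring-free
    set of substrings of ``t`` absent from the index; the same sequence
    may be emitted at several positions.
    """
    _check_target(t)
    codes = encode(t)
    return [SfsEmission(t[b:e], target_id, b, e)
            for b, e in _search_exact_codes(codes, index)]


def search_relaxed(t: str, index: FMDIndex, target_id: str = "target") -> list[SfsEmission]:
    """A disjoint-interval subset of the specific strings of ``t``,
    found with at most two extension queries per symbol."""
    _check_target(t)
    codes = encode(t)
    return [SfsEmission(t[b:e], target_id, b, e)
            for b, e in _search_relaxed_codes(codes, index)]


def _emissions_for_target(target_id: str, seq: str, index: FMDIndex,
                          mode: str) -> list[SfsEmission]:
    """Search one target, splitting at non-ACGT runs; emission
    coordinates refer to the original sequence."""
    core = _CODE_SEARCH[mode]
    out: list[SfsEmission] = []
    for offset, frag in split_fragments(seq.upper()):
        for b, e in core(encode(frag), index):
            out.append(SfsEmission(frag[b:e], target_id, offset + b, offset + e))
    return out


# ---------------------------------------------------------------------
# collection-level search with deterministic parallel merging
# ---------------------------------------------------------------------

_WORKER_INDEX: FMDIndex | None = None
_WORKER_MODE: str = "exact"


def _run_chunk(chunk: list[tuple[str, str]]) -> tuple[Counter, list[SfsEmission]]:
    counts: Counter = Counter()
    emissions: list[SfsEmission] = []
    for target_id, seq in chunk:
        for em in _emissions_for_target(target_id, seq, _WORKER_INDEX, _WORKER_MODE):
            counts[canonical(em.sequence)] += 1
            emissions.append(em)
    return counts, emissions


def _run_chunks_parallel(chunks: list[list[tuple[str, str]]], index: FMDIndex,
                         mode: str, threads: int):
    global _WORKER_INDEX, _WORKER_MODE
    _WORKER_INDEX, _WORKER_MODE = index, mode
    try:
        if threads > 1 and "fork" in multiprocessing.get_all_start_methods():
            ctx = multiprocessing.get_context("fork")
            with ctx.Pool(processes=threads) as pool:
                return pool.map(_run_chunk, chunks)
        return [_run_chunk(chunk) for chunk in chunks]
    finally:
        _WORKER_INDEX = None


def search_collection(
    targets: Iterable[tuple[str, str]],
    index: FMDIndex,
    mode: str = "exact",
    tau: int | None = None,
    threads: int = 1,
    collect_emissions: bool = False,
):
    """Search every ``(id, sequence)`` target and aggregate counts.

    Targets are independent, so the collection is partitioned into
    chunks and merged by canonical key; the result is identical for any
    ``threads`` value and any chunking. Returns the :class:`SfsTable`
    (tau-filtered when ``tau`` is given), or ``(table, emissions)`` when
    ``collect_emissions`` is set, with emissions in input order.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    items = list(targets)
    if not items:
        raise ValueError("empty target collection")
    threads = max(1, int(threads))
    n_chunks = threads * 4 if threads > 1 else 1
    size = max(1, (len(items) + n_chunks - 1) // n_chunks)
    chunks = [items[k:k + size] for k in range(0, len(items), size)]

    results = _run_chunks_parallel(chunks, index, mode, threads)

    table = SfsTable()
    emissions: list[SfsEmission] = []
    for counts, chunk_emissions in results:  # chunk order = input order
        for key, n in counts.items():
            table.counts[key] = table.counts.get(key, 0) + n
        if collect_emissions:
            emissions.extend(chunk_emissions)
    if tau is not None:
        table = filter_by_abundance(table, tau)
    if collect_emissions:
        return table, emissions
    return table


# ---------------------------------------------------------------------
# edit distance
# ---------------------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit costs (vectorized row DP)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    bn = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    m = bn.size
    idx = np.arange(m + 1, dtype=np.int64)
    prev = idx.copy()
    cur = np.empty(m + 1, dtype=np.int64)
    for row, ca in enumerate(a.encode("ascii"), start=1):
        cur[0] = row
        np.minimum(prev[1:] + 1, prev[:-1] + (bn != ca), out=cur[1:])
        # propagate left-to-right insertions in one pass
        np.minimum.accumulate(cur - idx, out=cur)
        cur += idx
        prev, cur = cur, prev
    return int(prev[-1])
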