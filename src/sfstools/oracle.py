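"""Brute-force reference solvers, for testing only.

These enumerate substrings explicitly (cubic time and memory) and act as
the independent ground truth for the index and the search algorithms.
They refuse instances beyond a small size guard.
"""

from __future__ import annotations

from sfstools.alphabet import reverse_complement

#: total reference length above which the oracle refuses to run
SIZE_GUARD = 5000


def _check_size(t: str, references: list[str]) -> None:
    total = len(t) + sum(len(r) for r in references)
    if total > SIZE_GUARD:
        raise ValueError(
            f"oracle instance too large ({total} > {SIZE_GUARD} characters); "
            "the oracle is test-only")


def substring_universe(references: list[str], strand_mode: str = "both",
                       max_len: int | None = None) -> set[str]:
    """All substrings of the references (and reverse complements when
    ``strand_mode == 'both'``) up to length ``max_len``."""
    strings = list(references)
    if strand_mode == "both":
        strings += [reverse_complement(r) for r in references]
    universe: set[str] = set()
    for r in strings:
        n = len(r)
        for b in range(n):
            hi = n if max_len is None else min(n, b + max_len)
            for e in range(b + 1, hi + 1):
                universe.add(r[b:e])
    return universe


def oracle_sfs(t: str, references: list[str], strand_mode: str = "both") -> set[str]:
    """Substring-free set of substrings of ``t`` absent from the references.

    Enumerates every substring of ``t``, keeps those missing from the
    substring universe, then drops any member with a proper substring
    that is also missing (a missing string is minimal iff both of its
    length-minus-one substrings are present).
    """
    _check_size(t, references)
    universe = substring_universe(references, strand_mode, max_len=len(t))
    n = len(t)
    absent: set[str] = set()
    for b in range(n):
        for e in range(b + 1, n + 1):
            s = t[b:e]
            if s not in universe:
                absent.add(s)
    result: set[str] = set()
    for s in absent:
        if len(s) == 1:
            result.add(s)
        elif s[1:] in universe and s[:-1] in universe:
            result.add(s)
    return result


def oracle_sfs_per_start(t: str, references: list[str],
                         strand_mode: str = "both") -> set[str]:
    """Alternative construction: per start position, the shortest absent
    prefix; candidates properly containing another candidate are dropped.

    Must agree with :func:`oracle_sfs` -- used as a cross-check.
    """
    _check_size(t, references)
    universe = substring_universe(references, strand_mode, max_len=len(t))
    n = len(t)
    ends: dict[int, int] = {}
    for b in range(n):
        for e in range(b + 1, n + 1):
            if t[b:e] not in universe:
                ends[b] = e
                break
    result: set[str] = set()
    min_end_right = n + 2
    for b in sorted(ends, reverse=True):
        e = ends[b]
        if e < min_end_right:
            result.add(t[b:e])
        min_end_right = min(min_end_right, e)
    return result


def oracle_occurrence_count(q: str, references: list[str],
                            strand_mode: str = "both") -> int:
    """Occurrences of ``q`` across the references (and their reverse
    complements when ``strand_mode == 'both'``), counting overlaps."""
    _check_size(q, references)
    strings = list(references)
    if strand_mode == "both":
        strings += [reverse_complement(r) for r in references]
    total = 0
    for r in strings:
        for b in range(len(r) - len(q) + 1):
            if r[b:b + len(q)] == q:
                total += 1
    return total
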