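"""Synthetic diploid trio with coordinate-tracked variants and reads.

Builds an ancestral genome, two haplotypes per parent carrying an
inherited variant pool, and a child that copies one haplotype per parent
(optionally with crossovers) plus de novo structural variants. Long
reads are sampled per haplotype with a truncated-normal length model and
optional per-base errors. Every read records its source interval, so
whether a specific string overlaps a variant is decided by coordinate
liftover instead of alignment.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sfstools.alphabet import ALPHABET, reverse_complement

PARENT_HAPLOTYPES = ("father_1", "father_2", "mother_1", "mother_2")
CHILD_HAPLOTYPES = ("child_1", "child_2")

#: (mean, sd, min) read length in bases; HiFi-like at desk scale
DEFAULT_READ_LENGTH_MODEL = (10_000, 2_000, 1_000)

#: substitution : insertion : deletion mix for injected errors
ERROR_MIX = (0.6, 0.2, 0.2)


@dataclass(frozen=True)
class Variant:
    vid: int
    kind: str            # snp | insertion | deletion | inversion
    ref_pos: int         # 0-based on the ancestral genome
    length: int          # bases inserted / deleted / inverted (1 for snp)
    alt: str | None      # inserted sequence (insertion / snp)
    origin: str          # inherited | de_novo

    def ref_span(self) -> tuple[int, int]:
        """Occupied interval on the ancestral genome (insertions are a
        point between ref_pos-1 and ref_pos)."""
        if self.kind in ("deletion", "inversion"):
            return self.ref_pos, self.ref_pos + self.length
        if self.kind == "snp":
            return self.ref_pos, self.ref_pos + 1
        return self.ref_pos, self.ref_pos


@dataclass(frozen=True)
class Placement:
    """A variant realized on one haplotype, in haplotype coordinates.

    Deletions have ``hap_begin == hap_end`` (the junction point).
    """

    variant: Variant
    hap_begin: int
    hap_end: int


@dataclass
class Haplotype:
    hap_id: str
    sequence: str
    #: identity segments (hap_start, hap_end, anc_start), sorted
    segments: list[tuple[int, int, int]]
    placements: list[Placement]
    source: str | None = None  # parental haplotype copied (child only)

    def hap_to_anc(self, pos: int) -> int | None:
        """Ancestral position of a haplotype position, or None if the
        position lies inside variant-derived sequence."""
        k = bisect.bisect_right(self._starts(), pos) - 1
        if k < 0:
            return None
        hs, he, anc = self.segments[k]
        if pos < he:
            return anc + (pos - hs)
        return None

    def anc_to_hap(self, anc_pos: int) -> int | None:
        for hs, he, anc in self.segments:
            if anc <= anc_pos < anc + (he - hs):
                return hs + (anc_pos - anc)
        return None

    def _starts(self) -> list[int]:
        cached = getattr(self, "_start_cache", None)
        if cached is None or len(cached) != len(self.segments):
            cached = [s[0] for s in self.segments]
            object.__setattr__(self, "_start_cache", cached)
        return cached


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    haplotype_id: str
    hap_begin: int
    hap_end: int          # 0-based half-open, pre-error coordinates
    strand: str           # '+' or '-'
    errors_injected: int


@dataclass
class TrioSim:
    genome: str
    haplotypes: dict[str, Haplotype]
    variants: list[Variant]
    reads: dict[str, list[SimulatedRead]] = field(default_factory=dict)

    @property
    def de_novo_variants(self) -> list[Variant]:
        return [v for v in self.variants if v.origin == "de_novo"]

    def read_by_id(self) -> dict[str, SimulatedRead]:
        return {r.read_id: r for reads in self.reads.values() for r in reads}


def generate_genome(length: int, seed) -> str:
    """Uniform i.i.d. ACGT string of the given length (deterministic for
    a fixed seed)."""
    if length < 1000:
        raise ValueError(f"genome length must be >= 1000, got {length}")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    return "".join(ALPHABET[c] for c in codes.tolist())


def _random_dna(rng, length: int) -> str:
    return "".join(ALPHABET[c] for c in rng.integers(0, 4, size=length).tolist())


def _place_variants(rng, genome_len: int, specs: list[tuple[str, int, str]],
                    edge_margin: int, min_gap: int) -> list[Variant]:
    """Rejection-sample non-overlapping ancestral positions for
    (kind, length, origin) specs; raises if placement keeps failing."""
    occupied: list[tuple[int, int]] = []
    variants: list[Variant] = []
    lo, hi = edge_margin, genome_len - edge_margin
    if hi <= lo:
        raise ValueError("genome too short for the requested edge margin")
    for vid, (kind, length, origin) in enumerate(specs):
        for _attempt in range(1000):
            pos = int(rng.integers(lo, hi - length)) if hi - length > lo else None
            if pos is None:
                break
            span = (pos - min_gap, pos + length + min_gap)
            if any(s < span[1] and span[0] < e for s, e in occupied):
                continue
            occupied.append((span[0], span[1]))
            break
        else:
            raise ValueError(
                "could not place all variants without overlap; "
                "reduce counts or sizes, or use a longer genome")
        if pos is None:
            raise ValueError("variant longer than the placeable region")
        alt = _random_dna(rng, length) if kind == "insertion" else None
        variants.append(Variant(vid, kind, pos, length, alt, origin))
    return variants


def _resolve_snp_alts(rng, genome: str, variants: list[Variant]) -> list[Variant]:
    out = []
    for v in variants:
        if v.kind == "snp" and v.alt is None:
            choices = [b for b in ALPHABET if b != genome[v.ref_pos]]
            out.append(Variant(v.vid, v.kind, v.ref_pos, v.length,
                               choices[int(rng.integers(0, 3))], v.origin))
        else:
            out.append(v)
    return out


def _apply_variants(genome: str, variants: list[Variant]) -> tuple[
        str, list[tuple[int, int, int]], list[Placement]]:
    """Realize variants (sorted by ancestral position) on the genome,
    returning the haplotype sequence, identity liftover segments, and
    per-variant haplotype intervals."""
    parts: list[str] = []
    segments: list[tuple[int, int, int]] = []
    placements: list[Placement] = []
    anc = 0
    h = 0
    for v in sorted(variants, key=lambda v: (v.ref_pos, v.vid)):
        if v.ref_pos > anc:
            parts.append(genome[anc:v.ref_pos])
            segments.append((h, h + (v.ref_pos - anc), anc))
            h += v.ref_pos - anc
            anc = v.ref_pos
        elif v.ref_pos < anc:
            raise ValueError("overlapping variants on one haplotype")
        if v.kind == "snp":
            parts.append(v.alt)
            placements.append(Placement(v, h, h + 1))
            h += 1
            anc += 1
        elif v.kind == "insertion":
            parts.append(v.alt)
            placements.append(Placement(v, h, h + v.length))
            h += v.length
        elif v.kind == "deletion":
            placements.append(Placement(v, h, h))
            anc += v.length
        elif v.kind == "inversion":
            parts.append(reverse_complement(genome[anc:anc + v.length]))
            placements.append(Placement(v, h, h + v.length))
            h += v.length
            anc += v.length
        else:
            raise ValueError(f"unknown variant kind {v.kind!r}")
    if anc < len(genome):
        parts.append(genome[anc:])
        segments.append((h, h + (len(genome) - anc), anc))
    return "".join(parts), segments, placements


def _denovo_kind_counts(n: int) -> dict[str, int]:
    """Split n as evenly as possible among insertion/deletion/inversion."""
    base, extra = divmod(n, 3)
    kinds = ("insertion", "deletion", "inversion")
    return {k: base + (1 if i < extra else 0) for i, k in enumerate(kinds)}


def make_trio(
    genome: str,
    n_inherited: int,
    n_denovo: int,
    sv_size_range: tuple[int, int] = (50, 500),
    recombination: bool = False,
    seed=0,
    inherited_size_range: tuple[int, int] = (1, 100),
    edge_margin: int = 1000,
    min_gap: int = 50,
) -> TrioSim:
    """Simulate a diploid trio over ``genome``.

    Parents carry ``n_inherited`` insertion/deletion variants (each
    parental haplotype carries each pool variant with probability 1/2);
    each child haplotype copies one haplotype of one parent (crossovers
    only when ``recombination``) and additionally receives its share of
    ``n_denovo`` structural variants split as evenly as possible among
    insertions, deletions and inversions, sized from ``sv_size_range``.
    """
    rng = np.random.default_rng(seed)
    specs: list[tuple[str, int, str]] = []
    for _ in range(n_inherited):
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        length = int(rng.integers(inherited_size_range[0],
                                  inherited_size_range[1] + 1))
        specs.append((kind, length, "inherited"))
    for kind, count in _denovo_kind_counts(n_denovo).items():
        for _ in range(count):
            length = int(rng.integers(sv_size_range[0], sv_size_range[1] + 1))
            specs.append((kind, length, "de_novo"))
    variants = _place_variants(rng, len(genome), specs, edge_margin, min_gap)
    variants = _resolve_snp_alts(rng, genome, variants)
    inherited = [v for v in variants if v.origin == "inherited"]
    de_novo = [v for v in variants if v.origin == "de_novo"]

    # parental haplotypes: random subsets of the inherited pool. Each
    # pool variant is placed on at least two of the four parental
    # haplotypes: inherited variants model population polymorphisms, and
    # a variant private to a single haplotype would leave every long
    # window spanning it backed by only that haplotype's reads -- a read
    # containment gap indistinguishable from real novelty.
    carried: dict[str, list[Variant]] = {h: [] for h in PARENT_HAPLOTYPES}
    for v in inherited:
        while True:
            mask = [rng.random() < 0.5 for _ in PARENT_HAPLOTYPES]
            if sum(mask) >= 2:
                break
        for hap_id, hit in zip(PARENT_HAPLOTYPES, mask):
            if hit:
                carried[hap_id].append(v)

    haplotypes: dict[str, Haplotype] = {}
    for hap_id in PARENT_HAPLOTYPES:
        seq, segments, placements = _apply_variants(genome, carried[hap_id])
        haplotypes[hap_id] = Haplotype(hap_id, seq, segments, placements)

    # child: one haplotype per parent
    denovo_carrier = [CHILD_HAPLOTYPES[int(rng.integers(0, 2))] for _ in de_novo]
    for child_id, parent in zip(CHILD_HAPLOTYPES, ("father", "mother")):
        source_hap = f"{parent}_{1 + int(rng.integers(0, 2))}"
        if recombination:
            child_inherited = _recombine_pool(rng, parent, carried)
            source_label = f"{parent}_recombined"
        else:
            child_inherited = list(carried[source_hap])
            source_label = source_hap
        child_denovo = [v for v, c in zip(de_novo, denovo_carrier)
                        if c == child_id]
        seq, segments, placements = _apply_variants(
            genome, child_inherited + child_denovo)
        haplotypes[child_id] = Haplotype(child_id, seq, segments, placements,
                                         source=source_label)
    return TrioSim(genome=genome, haplotypes=haplotypes, variants=variants)


def _recombine_pool(rng, parent: str, carried: dict[str, list[Variant]]
                    ) -> list[Variant]:
    """Single random crossover: inherited variants are taken from one
    parental haplotype left of the breakpoint and the other right of it."""
    h1, h2 = f"{parent}_1", f"{parent}_2"
    if rng.random() < 0.5:
        h1, h2 = h2, h1
    all_pos = sorted({v.ref_pos for v in carried[h1] + carried[h2]})
    if not all_pos:
        return []
    cut = int(rng.choice(all_pos))
    picked = [v for v in carried[h1] if v.ref_pos < cut]
    picked += [v for v in carried[h2] if v.ref_pos >= cut]
    # drop any overlap introduced at the junction (should not occur with
    # a globally non-overlapping pool, but assert rather than assume)
    picked.sort(key=lambda v: v.ref_pos)
    return picked


# ---------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------

def _inject_errors(rng, seq: str, error_rate: float) -> tuple[str, int]:
    out: list[str] = []
    n_err = 0
    for ch in seq:
        if rng.random() >= error_rate:
            out.append(ch)
            continue
        n_err += 1
        u = rng.random()
        if u < ERROR_MIX[0]:  # substitution
            choices = [b for b in ALPHABET if b != ch]
            out.append(choices[int(rng.integers(0, 3))])
        elif u < ERROR_MIX[0] + ERROR_MIX[1]:  # insertion
            out.append(ch)
            out.append(ALPHABET[int(rng.integers(0, 4))])
        # deletion: emit nothing
    return "".join(out), n_err


def simulate_reads(
    haplotypes: dict[str, str],
    coverage_per_haplotype: float,
    read_length_model: tuple[int, int, int] = DEFAULT_READ_LENGTH_MODEL,
    error_rate: float = 0.0,
    seed=0,
) -> list[SimulatedRead]:
    """Sample reads per haplotype until the requested mean coverage.

    Starts are uniform (reads overlapping either end are clipped, so
    coverage stays uniform across the haplotype), lengths follow a
    truncated normal, strands are equiprobable. Error positions follow a
    per-base rate with a 6:2:2 substitution:insertion:deletion mix;
    source coordinates are recorded before error injection.
    """
    if coverage_per_haplotype <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    mean, sd, min_len = read_length_model
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for hap_id in sorted(haplotypes):
        hap = haplotypes[hap_id]
        L = len(hap)
        floor = min(min_len, L)
        target = coverage_per_haplotype * L
        sampled = 0
        serial = 0
        while sampled < target:
            length = int(round(rng.normal(mean, sd)))
            length = max(floor, min(length, L))
            start = int(rng.integers(-(length - 1), L)) if length > 1 else \
                int(rng.integers(0, L))
            begin = max(0, start)
            end = min(L, start + length)
            if end - begin < floor:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            chunk = hap[begin:end]
            if strand == "-":
                chunk = reverse_complement(chunk)
            n_err = 0
            if error_rate > 0:
                chunk, n_err = _inject_errors(rng, chunk, error_rate)
            reads.append(SimulatedRead(
                read_id=f"{hap_id}:{serial}",
                sequence=chunk,
                haplotype_id=hap_id,
                hap_begin=begin,
                hap_end=end,
                strand=strand,
                errors_injected=n_err,
            ))
            sampled += end - begin
            serial += 1
    return reads


# ---------------------------------------------------------------------
# coordinate liftover / variant overlap
# ---------------------------------------------------------------------

def lift_read_interval(read: SimulatedRead, begin: int, end: int
                       ) -> tuple[int, int]:
    """Map a half-open interval on the read sequence to haplotype
    coordinates (exact for error-free reads; with injected errors the
    mapping is approximate and clamped to the read's source interval)."""
    if not 0 <= begin < end:
        raise ValueError("invalid interval")
    if read.strand == "+":
        hb = read.hap_begin + begin
        he = read.hap_begin + end
    else:
        hb = read.hap_end - end
        he = read.hap_end - begin
    hb = max(read.hap_begin, min(hb, read.hap_end))
    he = max(read.hap_begin, min(he, read.hap_end))
    return hb, he


def placement_overlaps(placement: Placement, hb: int, he: int) -> bool:
    """Breakpoint-inclusive overlap convention.

    Deletions are covered only by intervals that span the junction point
    with at least one base on each side; every other kind by plain
    half-open interval intersection (for inversions this covers both
    'crosses a breakpoint' and 'lies inside the inverted segment').
    """
    if placement.variant.kind == "deletion":
        return hb < placement.hap_begin < he
    return hb < placement.hap_end and placement.hap_begin < he


def variant_overlap(emission, read: SimulatedRead, trio: TrioSim) -> list[Variant]:
    """Truth variants whose haplotype placement intersects the lifted
    coordinates of an emission from this read."""
    if emission.target_id != read.read_id:
        raise ValueError(
            f"emission target {emission.target_id!r} does not match read "
            f"{read.read_id!r}")
    hb, he = lift_read_interval(read, emission.begin, emission.end)
    hap = trio.haplotypes[read.haplotype_id]
    return [p.variant for p in hap.placements if placement_overlaps(p, hb, he)]


# ---------------------------------------------------------------------
# tabular exports (used by the CLI and the evaluation module)
# ---------------------------------------------------------------------

def truth_frame(trio: TrioSim) -> pd.DataFrame:
    """One row per (variant, carrier haplotype) with haplotype coords."""
    rows = []
    for hap_id, hap in sorted(trio.haplotypes.items()):
        for p in hap.placements:
            v = p.variant
            rows.append({
                "variant_id": v.vid,
                "kind": v.kind,
                "origin": v.origin,
                "haplotype_id": hap_id,
                "hap_begin": p.hap_begin,
                "hap_end": p.hap_end,
                "ref_pos": v.ref_pos,
                "length": v.length,
            })
    return pd.DataFrame(rows, columns=["variant_id", "kind", "origin",
                                       "haplotype_id", "hap_begin", "hap_end",
                                       "ref_pos", "length"])


def reads_frame(reads: list[SimulatedRead]) -> pd.DataFrame:
    rows = [{
        "read_id": r.read_id,
        "haplotype_id": r.haplotype_id,
        "hap_begin": r.hap_begin,
        "hap_end": r.hap_end,
        "strand": r.strand,
        "errors_injected": r.errors_injected,
    } for r in reads]
    return pd.DataFrame(rows, columns=["read_id", "haplotype_id", "hap_begin",
                                       "hap_end", "strand", "errors_injected"])
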