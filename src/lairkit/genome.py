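"""Core genomic domain types: builds, allelic states, segments, karyotypes.

An *allelic state* is the integer count of each parental allele in a genomic
region, written as a string of ``A`` characters for the major allele followed
by ``B`` characters for the minor allele: ``[AB]`` normal heterozygous,
``[A]`` monosomy / LOH, ``[AA]`` copy-neutral LOH, ``[AAB]`` imbalanced gain,
``[AABB]`` amplified heterozygous, ``[AAAA]`` amplified LOH, and so on.
Parental phase is not tracked, so (a, b) is always ordered a >= b.

The *LAIR index* of a karyotype is the DNA index implied by its allelic-state
assignment: the weighted mean copy number over the covered genome divided by
the diploid copy number 2.  A normal heterozygous genome has index 1.0 and a
fully haploidised genome 0.5, matching the scale on which flow-cytometric DNA
indices are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomeBuild",
    "AllelicState",
    "Segment",
    "Karyotype",
    "GRCH37",
    "canonical_state",
    "parse_state",
    "enumerate_states",
    "lair_index",
]

# GRCh37 / hg19 chromosome lengths in base pairs.
_GRCH37_LENGTHS: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome-name -> length map for one reference build.

    Coordinates throughout the package are 1-based inclusive.
    """

    lengths: Mapping[str, int]
    tag: str = "GRCh37"

    def __post_init__(self) -> None:
        if len(self.lengths) != 24:
            raise ValueError(f"expected 24 chromosomes, got {len(self.lengths)}")
        missing = [c for c in AUTOSOMES + ("chrX", "chrY") if c not in self.lengths]
        if missing:
            raise ValueError(f"missing chromosomes: {missing}")
        bad = [c for c, n in self.lengths.items() if n <= 0]
        if bad:
            raise ValueError(f"non-positive chromosome lengths: {bad}")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return AUTOSOMES

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]


GRCH37 = GenomeBuild(lengths=_GRCH37_LENGTHS, tag="GRCh37")


@dataclass(frozen=True, order=True)
class AllelicState:
    """Integer allele dosage (a, b) with a >= b >= 0.

    ``a`` counts the major parental allele, ``b`` the minor one.  The state
    is heterozygous iff at least one copy of the minor allele survives.
    """

    a: int
    b: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(f"negative allele counts: ({self.a}, {self.b})")
        if self.a < self.b:
            raise ValueError("major count a must be >= minor count b; use canonical_state")

    @property
    def copies(self) -> int:
        return self.a + self.b

    @property
    def heterozygous(self) -> bool:
        return self.b >= 1

    @property
    def label(self) -> str:
        if self.copies == 0:
            return "0"
        return "A" * self.a + "B" * self.b

    def doubled(self) -> "AllelicState":
        """The state after endoreduplication (whole-genome doubling)."""
        return AllelicState(2 * self.a, 2 * self.b)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.label}]"


def canonical_state(a: int, b: int) -> AllelicState:
    """Build an :class:`AllelicState`, reordering so the major allele is first.

    Parental labels are arbitrary, so (1, 2) and (2, 1) denote the same
    imbalanced-gain state ``AAB``.
    """
    if a < 0 or b < 0:
        raise ValueError(f"negative allele counts: ({a}, {b})")
    if a < b:
        a, b = b, a
    return AllelicState(a, b)


def parse_state(label: str) -> AllelicState:
    """Parse a canonical state label such as ``AAB`` (or ``[AAB]``)."""
    s = label.strip().strip("[]")
    if s == "0":
        return AllelicState(0, 0)
    if not s or set(s) - {"A", "B"}:
        raise ValueError(f"unparseable allelic-state label: {label!r}")
    a = s.count("A")
    b = s.count("B")
    if s != "A" * a + "B" * b:
        raise ValueError(f"non-canonical allelic-state label: {label!r}")
    return canonical_state(a, b)


def enumerate_states(max_copies: int, include_null: bool = False) -> list[AllelicState]:
    """All states (a, b) with a >= b >= 0 and 1 <= a+b <= max_copies.

    Sorted by total copy number, then by minor-allele count, so LOH states
    precede balanced ones at each dosage.  ``include_null`` prepends the
    zero-copy state (homozygous deletion), which the printed vocabulary does
    not use but a caller may want in its search space.
    """
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    states: list[AllelicState] = []
    if include_null:
        states.append(AllelicState(0, 0))
    for total in range(1, max_copies + 1):
        for b in range(0, total // 2 + 1):
            states.append(AllelicState(total - b, b))
    return states


@dataclass(frozen=True)
class Segment:
    """A genomic interval with summary statistics of the two array tracks.

    ``median_r`` is the normalized total-intensity summary (diploid-relative
    ratio); ``median_lair`` the lesser-allele-intensity-ratio summary in
    [0, 1], or ``None`` where no reference-heterozygous marker informs it.
    Coordinates are 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    n_markers: int = 1
    median_r: float | None = None
    median_lair: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.n_markers < 1:
            raise ValueError("segment must contain at least one marker")
        if self.median_lair is not None and not (0.0 <= self.median_lair <= 1.0):
            raise ValueError(f"LAIR summary outside [0, 1]: {self.median_lair}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Karyotype:
    """An allelic-state assignment covering one or more chromosomes.

    ``segments`` maps each covered base to exactly one state: within a
    chromosome the (extent, state) pairs are non-overlapping and sorted.
    ``sex`` is the sex of the reference genome and controls the expected
    X-chromosome dosage in downstream simulation.
    """

    segments: list[tuple[Segment, AllelicState]] = field(default_factory=list)
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        self._validate()

    def _validate(self) -> None:
        by_chrom: dict[str, list[Segment]] = {}
        for seg, _ in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for left, right in zip(segs, segs[1:]):
                if right.start <= left.end:
                    raise ValueError(f"overlapping segments on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for seg, _ in self.segments:
            if seg.chrom not in seen:
                seen.append(seg.chrom)
        return seen

    def doubled(self) -> "Karyotype":
        return Karyotype(
            segments=[(seg, st.doubled()) for seg, st in self.segments], sex=self.sex
        )

    def state_at(self, chrom: str, pos: int) -> AllelicState | None:
        for seg, st in self.segments:
            if seg.chrom == chrom and seg.start <= pos <= seg.end:
                return st
        return None

    def to_tsv(self, path) -> None:
        """Write a BED-like TSV (chrom, start, end, state_label; 1-based inclusive)."""
        with open(path, "w") as fh:
            fh.write("# 1-based inclusive coordinates\n")
            fh.write("chrom\tstart\tend\tstate_label\n")
            for seg, st in self.segments:
                fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{st.label}\n")


def lair_index(
    karyotype: Karyotype,
    build: GenomeBuild = GRCH37,
    weighting: str = "length",
    marker_positions: Sequence[tuple[str, int]] | None = None,
) -> float:
    """DNA index implied by an allelic-state assignment.

    Sums allele copies over the covered genome and divides by the diploid
    expectation: ``sum(w * copies) / (2 * sum(w))`` with weights ``w`` equal
    to covered bases (``weighting='length'``) or to the number of markers
    falling inside each segment (``weighting='marker'``).  An all-``AB``
    genome scores exactly 1.0 and an all-``A`` genome exactly 0.5; doubling
    every state doubles the index, which is how endoreduplication doubles
    the flow-cytometric DNA index.
    """
    if not karyotype.segments:
        raise ValueError("empty karyotype")
    if weighting not in ("length", "marker"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "marker" and marker_positions is None:
        raise ValueError("marker weighting requires marker_positions")

    total_w = 0.0
    total_wc = 0.0
    for seg, state in karyotype.segments:
        if weighting == "length":
            w = float(seg.length)
        else:
            w = float(
                sum(
                    1
                    for chrom, pos in marker_positions  # type: ignore[union-attr]
                    if chrom == seg.chrom and seg.start <= pos <= seg.end
                )
            )
        total_w += w
        total_wc += w * state.copies
    if total_w == 0:
        raise ValueError("karyotype has zero total weight")
    return total_wc / (2.0 * total_w)
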