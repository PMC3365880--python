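"""Genomic phenotype classification and cohort-level summaries.

Three genomic phenotypes are distinguished.  *Near-haploid*: at least half
the autosomal genome homozygous with a near-haploid dominant DNA index
(< 0.9).  *Endoreduplicated near-homozygous*: the same homozygous pattern at
copy-neutral dosage (dominant DI >= 0.9), the footprint of whole-genome
doubling after haploidisation.  Everything else is *conventional*.  The
near-homozygous umbrella covers the first two.  Chromosome-7 heterozygous
retention - the hallmark of the oncocytic follicular carcinomas that
motivate these rules - is flagged whenever at least one B allele survives
on most of chromosome 7.

The packaged cohort tables carry the published per-case summaries (DNA
indices, chromosome 6/7 allelic states, FISH counts, mutation flags) for a
27-tumour recurrent cohort and a 20-tumour validation cohort, against which
the record-level rules reproduce the cohort counts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .flow import doubling_pairs
from .genome import GRCH37, GenomeBuild, parse_state
from .segmentation import CalibrationResult, fish_concordance

__all__ = [
    "CohortRecord",
    "PhenotypeCall",
    "phenotype_from_assignment",
    "phenotype_from_record",
    "load_table1",
    "load_table2",
    "cohort_summary",
    "DI_ENDOREDUPLICATION_THRESHOLD",
]

# DNA index separating near-haploid from endoreduplicated near-homozygous
# genomes: observed near-haploid DIs span 0.53-0.73 and endoreduplicated
# dominant DIs 0.98-1.28; 0.9 bisects the gap.
DI_ENDOREDUPLICATION_THRESHOLD = 0.9

_PTC_VARIANT_TYPES = {"PTC", "PTC-OV", "PTC Tall Cell", "FVPC"}

_TABLE1_SHA256 = "e5dc669594e0c108ed3b7cdc43b184219a9e594026b54200c489e3eae62e9713"
_TABLE2_SHA256 = "dbf08aa17972027e0a832d44d8132c3dbc95580edb6f2ad6cc72f03098ab599c"


@dataclass
class CohortRecord:
    """One published per-case summary row.

    The initial-cohort rows carry DNA indices, chromosome 6/7 allelic states
    and FISH counts plus mutation flags; validation-cohort rows carry the
    diagnosis, the near-homozygous phenotype flag, recurrence and footnote
    annotations (``repeat_of_case_9`` marks the patient analysed in both
    cohorts).
    """

    case: int
    tumour_type: str
    sex: str | None = None
    age: int | None = None
    dis: list[float] = field(default_factory=list)
    dominant_di: float | None = None
    chr6_state: str | None = None
    chr6_fish: str | None = None
    chr7_state: str | None = None
    chr7_fish: str | None = None
    mutations: dict[str, str] = field(default_factory=dict)
    near_homozygous: bool | None = None
    recurrence: str | None = None
    footnotes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dis):
            raise ValueError(f"case {self.case}: non-positive DNA index")
        for label in (self.chr6_state, self.chr7_state):
            if label is not None:
                parse_state(label)  # raises on unparseable state labels

    @property
    def is_repeat_patient(self) -> bool:
        return any(f.startswith("repeat_of") for f in self.footnotes)


@dataclass
class PhenotypeCall:
    """Genomic phenotype of one tumour."""

    phenotype: str  # near_haploid | endoreduplicated_near_homozygous | conventional
    near_homozygous: bool
    chr7_retained: bool | None = None  # None = undetermined
    homozygous_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.phenotype in ("near_haploid", "endoreduplicated_near_homozygous"):
            if not self.near_homozygous:
                raise ValueError("haploidisation subtypes imply the near-homozygous flag")


def _subtype(dominant_di: float) -> str:
    if dominant_di < DI_ENDOREDUPLICATION_THRESHOLD:
        return "near_haploid"
    return "endoreduplicated_near_homozygous"


def phenotype_from_assignment(
    result: CalibrationResult, build: GenomeBuild = GRCH37, min_autosomes: int = 20
) -> PhenotypeCall:
    """Classify a tumour from its calibrated genome-wide segment calls.

    The homozygous fraction is the autosomal length in states without a B
    allele over the total called autosomal length; >= 0.5 raises the
    near-homozygous umbrella flag, and the dominant flow DI then separates
    near-haploid from endoreduplicated.  Chromosome-7 retention requires
    more than half of chromosome 7's length in a heterozygous state; with
    no chromosome-7 calls it is reported as undetermined (None).
    """
    autosomes = set(build.autosomes)
    covered = {c.segment.chrom for c in result.calls if c.segment.chrom in autosomes}
    if len(covered) < min_autosomes:
        raise ValueError(f"calls cover only {len(covered)} autosomes; need >= {min_autosomes}")
    tot = hom = 0.0
    chr7_tot = chr7_het = 0.0
    for call in result.calls:
        chrom = call.segment.chrom
        if chrom not in autosomes:
            continue
        length = call.segment.length
        tot += length
        if not call.state.heterozygous:
            hom += length
        if chrom == "chr7":
            chr7_tot += length
            if call.state.heterozygous:
                chr7_het += length
    fraction = hom / tot
    umbrella = fraction >= 0.5
    chr7_retained = None if chr7_tot == 0 else (chr7_het / build.length("chr7") > 0.5)
    phenotype = _subtype(result.flow_di) if umbrella else "conventional"
    return PhenotypeCall(
        phenotype=phenotype,
        near_homozygous=umbrella,
        chr7_retained=chr7_retained,
        homozygous_fraction=fraction,
    )


def phenotype_from_record(record: CohortRecord) -> PhenotypeCall:
    """Classify a published summary row.

    The chromosome-6 allelic state stands proxy for genome-wide LOH (these
    tumours lose heterozygosity on chromosome 6 whenever the genome is
    near-homozygous): a homozygous chromosome-6 state raises the umbrella
    flag, and the dominant DNA index selects the subtype.  Chromosome-7
    retention means its printed state keeps at least one B allele.
    """
    if record.chr6_state is None or not record.dis:
        raise ValueError(f"case {record.case}: needs a chr6 state and at least one DNA index")
    chr6 = parse_state(record.chr6_state)
    umbrella = not chr6.heterozygous
    dom = record.dominant_di if record.dominant_di is not None else record.dis[0]
    chr7 = parse_state(record.chr7_state) if record.chr7_state else None
    return PhenotypeCall(
        phenotype=_subtype(dom) if umbrella else "conventional",
        near_homozygous=umbrella,
        chr7_retained=None if chr7 is None else chr7.heterozygous,
    )


# ---------------------------------------------------------------------------
# packaged cohort tables


def _fixture_text(name: str, sha256: str) -> str:
    path = resources.files("lairkit").joinpath(f"data/{name}")
    text = path.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != sha256:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    return text


def load_table1() -> list[CohortRecord]:
    """The 27-case recurrent-cohort table (DNA indices, allelic states, FISH, mutations)."""
    import io

    text = _fixture_text("table1.csv", _TABLE1_SHA256)
    df = pd.read_csv(io.StringIO(text), dtype=str).replace({np.nan: None})
    records = []
    for _, row in df.iterrows():
        dis = [float(x) for x in row["dna_indices"].split("/")]
        records.append(
            CohortRecord(
                case=int(row["case"]),
                tumour_type=row["tumour_type"],
                sex=row["sex"],
                age=int(row["age"]),
                dis=dis,
                dominant_di=float(row["dominant_di"]),
                chr6_state=row["chr6_state"],
                chr6_fish=row["chr6_fish"],
                chr7_state=row["chr7_state"],
                chr7_fish=row["chr7_fish"],
                mutations={
                    "BRAF": row["braf"],
                    "EGFR": row["egfr"],
                    "RAS": row["ras"],
                    "PIK3CA": row["pik3ca"],
                },
            )
        )
    if len(records) != 27:
        raise ValueError(f"expected 27 records, got {len(records)}")
    return records


def load_table2() -> list[CohortRecord]:
    """The 20-case validation-cohort table (diagnosis, near-homozygous flag, recurrence)."""
    import io

    text = _fixture_text("table2.csv", _TABLE2_SHA256)
    df = pd.read_csv(io.StringIO(text), dtype=str).replace({np.nan: None})
    records = []
    for _, row in df.iterrows():
        foot = tuple((row["footnote"] or "").split(";")) if row["footnote"] else ()
        records.append(
            CohortRecord(
                case=int(row["case"]),
                tumour_type=row["diagnosis"],
                near_homozygous=row["near_homozygous"] == "Yes",
                recurrence=row["recurrence"],
                footnotes=foot,
            )
        )
    if len(records) != 20:
        raise ValueError(f"expected 20 records, got {len(records)}")
    return records


# ---------------------------------------------------------------------------
# cohort summaries


def _round_half_up_pct(num: int, den: int) -> int:
    return int(np.floor(100.0 * num / den + 0.5))


def cohort_summary(records: list[CohortRecord]) -> dict:
    """Cohort-level counts from per-case records.

    For initial-cohort records (with allelic states): the single-population
    percentage, near-homozygous / near-haploid-dominant / doubling-pair
    counts among the oncocytic follicular carcinomas (FTC-OV), the FISH
    exception count, and the BRAF mutation rate among papillary carcinomas
    and variants.  For validation-cohort records (with a published
    near-homozygous flag): near-homozygous counts with and without the
    patient repeated from the initial cohort.  Record order never matters.
    """
    records = sorted(records, key=lambda r: r.case)
    if records and records[0].chr6_state is not None:
        return _summary_initial(records)
    return _summary_validation(records)


def _summary_initial(records: list[CohortRecord]) -> dict:
    n = len(records)
    single = sum(1 for r in records if len(r.dis) == 1)
    ftc_ov = [r for r in records if r.tumour_type == "FTC-OV"]
    calls = {r.case: phenotype_from_record(r) for r in records}
    nh_ftc_ov = [r for r in ftc_ov if calls[r.case].near_homozygous]
    haploid_dom = [r for r in nh_ftc_ov if calls[r.case].phenotype == "near_haploid"]
    doubling = [r for r in haploid_dom if len(r.dis) >= 2 and doubling_pairs(r.dis)]

    states, fish = [], []
    for r in records:
        for st, fc in ((r.chr6_state, r.chr6_fish), (r.chr7_state, r.chr7_fish)):
            if st is not None:
                states.append(st)
                fish.append(fc)
    _, n_exceptions = fish_concordance(states, fish)

    ptc_like = [r for r in records if r.tumour_type in _PTC_VARIANT_TYPES]
    braf_pos = [r for r in ptc_like if r.mutations.get("BRAF") == "+"]
    return {
        "n_records": n,
        "pct_single_population": _round_half_up_pct(single, n),
        "n_ftc_ov": len(ftc_ov),
        "n_ftc_ov_near_homozygous": len(nh_ftc_ov),
        "n_ftc_ov_near_haploid_dominant": len(haploid_dom),
        "n_near_haploid_ftc_ov_with_doubling": len(doubling),
        "n_ftc_ov_chr7_retained": sum(1 for r in ftc_ov if calls[r.case].chr7_retained),
        "n_fish_exceptions": n_exceptions,
        "n_ptc_and_variants": len(ptc_like),
        "n_braf_positive_ptc": len(braf_pos),
        "pct_braf_positive_ptc": _round_half_up_pct(len(braf_pos), len(ptc_like)),
    }


def _summary_validation(records: list[CohortRecord]) -> dict:
    nh = [r for r in records if r.near_homozygous]
    nh_new = [r for r in nh if not r.is_repeat_patient]
    return {
        "n_records": len(records),
        "n_near_homozygous": len(nh),
        "n_near_homozygous_excluding_repeat": len(nh_new),
    }
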