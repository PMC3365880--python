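"""Synthetic ground truth: karyotypes, array signals, DNA histograms, cohorts.

The generator emulates the study design end to end: an integer allelic-state
karyotype per tumour, Illumina-style genotyping-array signals under that
karyotype (two allele intensities per marker, roughly one third of markers
heterozygous in the reference), and gated flow-cytometry DNA histograms with
G0/G1, S-phase and G2/M components plus a diploid stromal reference
population.  Every stage of the inference pipeline can therefore be tested
against known truth without external data.

Signal model for a marker in allelic state (a, b) at tumour fraction f,
reference-heterozygous:

    R*    = (f*(a+b) + 2*(1-f)) / 2           normalized total intensity
    LAIR* = (f*b + (1-f)) / (f*a + (1-f))     lesser allele intensity ratio

Observations are these expectations plus Gaussian noise (sd ``sigma_r`` and
``sigma_l``), LAIR clipped to [0, 1]; reference-homozygous markers carry
only the intensity signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import ArraySample
from .flow import FlowHistogram
from .genome import (
    GRCH37,
    AllelicState,
    GenomeBuild,
    Karyotype,
    Segment,
    canonical_state,
    lair_index,
)

__all__ = [
    "SignalModel",
    "ScenarioProfile",
    "SCENARIOS",
    "SimulatedSample",
    "simulate_karyotype",
    "make_marker_panel",
    "simulate_array",
    "simulate_reference",
    "simulate_flow_histogram",
    "simulate_cohort",
    "expected_marker_signals",
]


@dataclass(frozen=True)
class SignalModel:
    """Array signal-model parameters.

    f          tumour cell fraction in (0, 1]
    sigma_r    per-marker noise sd on the normalized total intensity R
    sigma_l    per-marker noise sd on LAIR
    p_het      fraction of reference-heterozygous markers
    density    markers per Mb (1/Mb emulates a 6k-scale panel, 10/Mb a
               CytoSNP-scale one)
    gain       arbitrary fluorescence units per allele copy
    scale_sd   log-sd of the per-sample multiplicative intensity scale
    nc_rate    fraction of no-call reference genotypes
    crosstalk  sd of the spurious off-allele signal at homozygous markers,
               as a fraction of the per-copy gain
    """

    f: float = 1.0
    sigma_r: float = 0.08
    sigma_l: float = 0.05
    p_het: float = 0.33
    density: float = 1.0
    seed: int = 0
    gain: float = 1000.0
    scale_sd: float = 0.10
    nc_rate: float = 0.002
    crosstalk: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.f <= 1.0):
            raise ValueError("tumour fraction f must be in (0, 1]")
        if self.sigma_r < 0 or self.sigma_l < 0:
            raise ValueError("noise sds must be non-negative")
        if not (0.0 < self.p_het < 1.0):
            raise ValueError("p_het must be in (0, 1)")
        if self.density <= 0:
            raise ValueError("marker density must be positive")


@dataclass(frozen=True)
class ScenarioProfile:
    """A named genomic phenotype scenario.

    ``retained`` lists autosome numbers kept heterozygous during
    haploidisation (chromosome 7 by default, as in the tumours that motivate
    the scenario); ``partial_retained`` maps an autosome number to the
    distal fraction of its length kept heterozygous.
    """

    name: str
    retained: frozenset[int] = frozenset({7})
    partial_retained: tuple[tuple[int, float], ...] = ()
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.name in (
            "near_haploid_chr7AB",
            "endoreduplicated",
            "bimodal_haploid_plus_doubled",
        ) and not self.retained:
            raise ValueError("haploidisation scenarios need a non-empty retained set")


SCENARIOS = (
    "near_haploid_chr7AB",
    "endoreduplicated",
    "bimodal_haploid_plus_doubled",
    "diploid_normal",
    "ptc_like_chr22_loss",
    "near_tetraploid",
)


def _whole(chrom: str, build: GenomeBuild) -> Segment:
    return Segment(chrom=chrom, start=1, end=build.length(chrom))


def simulate_karyotype(
    profile: ScenarioProfile, build: GenomeBuild = GRCH37, seed: int = 0
) -> Karyotype:
    """Ground-truth karyotype for a scenario (deterministic given its profile).

    Haploidisation scenarios set every autosome to [A] except the retained
    set, kept [AB]; endoreduplication doubles that pattern to [AA]/[AABB].
    The X chromosome follows the haploidised genome ([A]); a diploid female
    genome keeps X at [AB].
    """
    if profile.name not in SCENARIOS:
        raise ValueError(f"unknown scenario profile: {profile.name!r}")
    partial = dict(profile.partial_retained)
    segs: list[tuple[Segment, AllelicState]] = []
    ab = canonical_state(1, 1)
    a1 = canonical_state(1, 0)

    def base_states() -> list[tuple[Segment, AllelicState]]:
        """Near-haploid pattern: A everywhere, AB on retained chromosomes."""
        out: list[tuple[Segment, AllelicState]] = []
        for i in range(1, 23):
            chrom = f"chr{i}"
            if i in partial:
                frac = partial[i]
                length = build.length(chrom)
                cut = int(round(length * (1.0 - frac)))
                out.append((Segment(chrom, 1, cut), a1))
                out.append((Segment(chrom, cut + 1, length), ab))
            elif i in profile.retained:
                out.append((_whole(chrom, build), ab))
            else:
                out.append((_whole(chrom, build), a1))
        out.append((_whole("chrX", build), a1))
        return out

    if profile.name in ("near_haploid_chr7AB", "bimodal_haploid_plus_doubled"):
        segs = base_states()
    elif profile.name == "endoreduplicated":
        segs = [(s, st.doubled()) for s, st in base_states()]
    elif profile.name == "diploid_normal":
        for i in range(1, 23):
            segs.append((_whole(f"chr{i}", build), ab))
        segs.append((_whole("chrX", build), ab if profile.sex == "female" else a1))
    elif profile.name == "ptc_like_chr22_loss":
        for i in range(1, 23):
            segs.append((_whole(f"chr{i}", build), a1 if i == 22 else ab))
        segs.append((_whole("chrX", build), ab if profile.sex == "female" else a1))
    elif profile.name == "near_tetraploid":
        aabb = canonical_state(2, 2)
        for i in range(1, 23):
            segs.append((_whole(f"chr{i}", build), aabb))
        segs.append((_whole("chrX", build), aabb if profile.sex == "female" else canonical_state(2, 0)))
    return Karyotype(segments=segs, sex=profile.sex)


def make_marker_panel(
    model: SignalModel,
    build: GenomeBuild = GRCH37,
    chromosomes: list[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """A shared marker panel: positions and reference genotypes.

    Markers are placed uniformly along each chromosome at ``model.density``
    markers per Mb; the reference genotype is AB with probability
    ``model.p_het`` and otherwise AA or BB equiprobably.  Tumour and
    reference samples simulated on the same panel share these germline
    genotypes, which is what makes the LAIR track computable.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    chroms = chromosomes or [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    rows = []
    for chrom in chroms:
        length = build.length(chrom)
        n = max(3, int(round(length * model.density / 1e6)))
        pos = np.unique(rng.integers(1, length + 1, size=2 * n))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        u = rng.random(n)
        gt = np.where(u < model.p_het, "AB", np.where(u < model.p_het + (1 - model.p_het) / 2, "AA", "BB"))
        nc = rng.random(n) < model.nc_rate
        gt = np.where(nc, "NC", gt)
        for k in range(n):
            rows.append((f"{chrom}_m{k:05d}", chrom, int(pos[k]), gt[k]))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "gtype_ref"])


# closed-form per-marker expectations shared with the calibration stage
from .segmentation import expected_signals as expected_marker_signals  # noqa: E402


def _states_at(karyotype: Karyotype, panel: pd.DataFrame) -> list[AllelicState | None]:
    chroms = panel["chrom"].to_numpy()
    pos = panel["pos"].to_numpy()
    out: list[AllelicState | None] = [None] * len(panel)
    for seg, st in karyotype.segments:
        hit = np.flatnonzero((chroms == seg.chrom) & (pos >= seg.start) & (pos <= seg.end))
        for i in hit:
            out[i] = st
    return out


def simulate_array(
    karyotype: Karyotype,
    model: SignalModel,
    build: GenomeBuild = GRCH37,
    panel: pd.DataFrame | None = None,
    sample_id: str = "sim",
    seed: int | None = None,
) -> tuple[ArraySample, pd.DataFrame]:
    """Simulate one array sample under a ground-truth karyotype.

    Returns the sample (raw intensities, no derived tracks yet) and a truth
    table (marker_id, chrom, pos, true_state, true_copies).  Markers whose
    position falls outside the karyotype raise, since every simulated
    chromosome must be covered by exactly one state.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    if panel is None:
        panel = make_marker_panel(model, build, chromosomes=karyotype.chromosomes, seed=int(rng.integers(2**31)))
    states = _states_at(karyotype, panel)
    uncovered = [i for i, s in enumerate(states) if s is None]
    if uncovered:
        row = panel.iloc[uncovered[0]]
        raise ValueError(f"marker {row['marker_id']} at {row['chrom']}:{row['pos']} not covered by karyotype")

    n = len(panel)
    scale = model.gain * float(np.exp(rng.normal(0.0, model.scale_sd)))
    f = model.f
    a = np.array([s.a for s in states], float)
    b = np.array([s.b for s in states], float)
    gt = panel["gtype_ref"].to_numpy()
    swap = rng.random(n) < 0.5
    eps_r = rng.normal(0.0, 1.0, n) * model.sigma_r
    eps_l = rng.normal(0.0, 1.0, n) * model.sigma_l
    cross = np.abs(rng.normal(0.0, max(model.crosstalk, 1e-300), n))

    r_star = (f * (a + b) + 2.0 * (1.0 - f)) / 2.0
    lair_star = (f * b + (1.0 - f)) / np.maximum(f * a + (1.0 - f), 1e-12)
    r_obs = np.maximum(r_star + eps_r, 0.01)
    tot = 2.0 * scale * r_obs

    # reference-heterozygous: split the total by the noisy LAIR; the major
    # parental allele maps to assay allele A or B at random
    lair_obs = np.clip(lair_star + eps_l, 0.0, 1.0)
    hi = tot / (1.0 + lair_obs)
    lo = tot - hi
    x_het = np.where(swap, lo, hi)
    y_het = tot - x_het
    # reference-homozygous: all germline copies carry one assay allele
    noise = scale * cross
    x_hom = np.where(gt == "BB", noise, tot)
    y_hom = np.where(gt == "BB", tot, noise)

    het = gt == "AB"
    x = np.where(het, x_het, x_hom)
    y = np.where(het, y_het, y_hom)
    gcs = rng.uniform(0.55, 1.0, n)
    df = panel.copy()
    df["x_raw"] = x
    df["y_raw"] = y
    df["gcs"] = gcs
    sample = ArraySample(sample_id, df)
    truth = panel[["marker_id", "chrom", "pos"]].copy()
    truth["true_state"] = [s.label for s in states]
    truth["true_copies"] = [s.copies for s in states]
    return sample, truth


def simulate_reference(
    panel: pd.DataFrame,
    model: SignalModel,
    build: GenomeBuild = GRCH37,
    sample_id: str = "ref",
    seed: int | None = None,
) -> ArraySample:
    """A diploid (female) reference sample on the shared panel."""
    profile = ScenarioProfile(name="diploid_normal", sex="female")
    karyo = simulate_karyotype(profile, build)
    karyo = Karyotype(
        segments=[(s, st) for s, st in karyo.segments if s.chrom in set(panel["chrom"])],
        sex="female",
    )
    sample, _ = simulate_array(karyo, model, build, panel=panel, sample_id=sample_id, seed=seed)
    return sample


def simulate_flow_histogram(
    populations: list[tuple[float, float, float]],
    cv: float = 0.04,
    n_events: int = 20000,
    bins: int = 256,
    seed: int = 0,
    channel_gain: float = 200.0,
) -> tuple[FlowHistogram, FlowHistogram]:
    """Simulate gated stromal and epithelial DNA-content histograms.

    ``populations`` lists tumour populations as (dna_index, fraction,
    g2m_fraction); within a population the events split into a G0/G1
    Gaussian at ``dna_index``, a G2/M Gaussian at twice that position, and a
    flat S-phase bridge in between carrying half the G2/M weight (a cycling
    population's S compartment).  Any unassigned event fraction becomes
    uniform debris.  The stromal histogram holds one diploid population at
    relative position 1.0 and shares the fluorescence axis.  Deterministic
    given the seed.
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    if n_events < 1000:
        raise ValueError("need at least 1000 events")
    fractions = sum(p[1] for p in populations)
    if fractions > 1.0 + 1e-9:
        raise ValueError("population fractions sum to more than 1")
    rng = np.random.default_rng(seed)

    max_di = max([p[0] for p in populations] + [1.0])
    upper_rel = max(2.6, 2.3 * max_di)
    upper = channel_gain * upper_rel
    edges = np.linspace(0.0, upper, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def _draw(pops: list[tuple[float, float, float]], tag: str, sub_seed: int) -> FlowHistogram:
        r = np.random.default_rng(sub_seed)
        comp_p: list[float] = []
        comp_kind: list[tuple[str, float]] = []
        for di, frac, g2m in pops:
            s_frac = 0.5 * g2m
            g1 = max(1.0 - g2m - s_frac, 0.0)
            comp_p += [frac * g1, frac * s_frac, frac * g2m]
            comp_kind += [("g1", di), ("s", di), ("g2m", di)]
        debris = max(1.0 - sum(p[1] for p in pops), 0.0)
        comp_p.append(debris)
        comp_kind.append(("debris", 0.0))
        p = np.asarray(comp_p)
        p = p / p.sum()
        counts = r.multinomial(n_events, p)
        values = []
        for (kind, di), m in zip(comp_kind, counts):
            if m == 0:
                continue
            mu = channel_gain * di
            if kind == "g1":
                values.append(r.normal(mu, cv * mu, m))
            elif kind == "g2m":
                values.append(r.normal(2 * mu, 2 * cv * mu, m))
            elif kind == "s":
                values.append(r.uniform(mu, 2 * mu, m))
            else:
                values.append(r.uniform(0.02 * upper, 0.98 * upper, m))
        v = np.clip(np.concatenate(values), 1e-6, upper - 1e-6)
        hist, _ = np.histogram(v, bins=edges)
        return FlowHistogram(population=tag, bin_centers=centers, counts=hist.astype(float))

    stromal = _draw([(1.0, 0.95, 0.04)], "stromal", int(rng.integers(2**31)))
    epithelial = _draw(populations, "epithelial", int(rng.integers(2**31)))
    return stromal, epithelial


@dataclass
class SimulatedSample:
    """One end-to-end simulated tumour with its ground truth."""

    sample_id: str
    scenario: str
    karyotype: Karyotype
    array: ArraySample
    truth: pd.DataFrame
    references: list[ArraySample]
    stromal: FlowHistogram
    epithelial: FlowHistogram
    true_di: float
    true_dis: list[float] = field(default_factory=list)

    @property
    def near_homozygous(self) -> bool:
        """Whether >= half the autosomal genome is truly homozygous."""
        tot = hom = 0
        for seg, st in self.karyotype.segments:
            if seg.chrom == "chrX":
                continue
            tot += seg.length
            if not st.heterozygous:
                hom += seg.length
        return hom / tot >= 0.5


def simulate_cohort(
    n_ftc_ov: int,
    n_other: int,
    model: SignalModel | None = None,
    seed: int = 1,
    build: GenomeBuild = GRCH37,
    n_events: int = 20000,
    n_references: int = 2,
) -> list[SimulatedSample]:
    """Simulate a mixed cohort emulating the study composition.

    Oncocytic follicular carcinoma (FTC-OV) samples alternate between the
    near-haploid, endoreduplicated and bimodal scenarios, always retaining
    chromosome 7 heterozygous plus 0-2 further random autosomes (never 3, 6
    or 22, on which these tumours always lose heterozygosity).  The
    remaining samples alternate between a normal diploid genome and a
    papillary-like genome with chromosome 22 loss.
    """
    if n_ftc_ov < 0 or n_other < 0:
        raise ValueError("cohort counts must be non-negative")
    model = model or SignalModel()
    rng = np.random.default_rng(seed)
    samples: list[SimulatedSample] = []
    ftc_cycle = ["near_haploid_chr7AB", "endoreduplicated", "bimodal_haploid_plus_doubled"]
    other_cycle = ["diploid_normal", "ptc_like_chr22_loss"]
    extra_pool = sorted(set(range(1, 23)) - {3, 6, 7, 22})

    def build_one(idx: int, scenario: str) -> SimulatedSample:
        sex = "female" if rng.random() < 0.5 else "male"
        if scenario in ftc_cycle:
            n_extra = int(rng.integers(0, 3))
            extras = rng.choice(extra_pool, size=n_extra, replace=False) if n_extra else []
            retained = frozenset({7} | {int(c) for c in extras})
        else:
            retained = frozenset({7})
        profile = ScenarioProfile(name=scenario, retained=retained, sex=sex)
        karyo = simulate_karyotype(profile, build, seed=int(rng.integers(2**31)))
        panel = make_marker_panel(model, build, chromosomes=karyo.chromosomes, seed=int(rng.integers(2**31)))
        arr, truth = simulate_array(karyo, model, build, panel=panel, sample_id=f"sim{idx:03d}", seed=int(rng.integers(2**31)))
        refs = [
            simulate_reference(panel, model, build, sample_id=f"sim{idx:03d}_ref{j}", seed=int(rng.integers(2**31)))
            for j in range(n_references)
        ]
        di = lair_index(karyo, build)
        if scenario == "bimodal_haploid_plus_doubled":
            pops = [(di, 0.55, 0.12), (2.0 * di, 0.35, 0.12)]
            dis = [di, 2.0 * di]
        else:
            pops = [(di, 0.90, 0.12)]
            dis = [di]
        stromal, epithelial = simulate_flow_histogram(
            pops, cv=0.04, n_events=n_events, seed=int(rng.integers(2**31))
        )
        return SimulatedSample(
            sample_id=f"sim{idx:03d}",
            scenario=scenario,
            karyotype=karyo,
            array=arr,
            truth=truth,
            references=refs,
            stromal=stromal,
            epithelial=epithelial,
            true_di=di,
            true_dis=dis,
        )

    idx = 0
    for i in range(n_ftc_ov):
        samples.append(build_one(idx, ftc_cycle[i % len(ftc_cycle)]))
        idx += 1
    for i in range(n_other):
        samples.append(build_one(idx, other_cycle[i % len(other_cycle)]))
        idx += 1
    return samples
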