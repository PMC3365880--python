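"""Joint R/LAIR segmentation and DNA-index-calibrated allelic-state calling.

Self-normalized array intensities fix only relative dosage: a genome that is
``A`` everywhere and one that is ``AA`` everywhere produce identical R and
LAIR tracks.  The flow-cytometric DNA index breaks this degeneracy: among
all integer allelic-state assignments compatible with the tracks, the caller
prefers the one whose implied LAIR index (the DNA index computed from the
summed allele copies) matches the measured DI.

Segmentation is a CBS-style recursive binary split with a permutation test,
run independently on the intensity (R) track and on the defined-LAIR track;
breakpoints from both tracks are pooled, which is what lets a copy-neutral
LOH boundary (visible only in LAIR) be found.

Calibration minimizes, over a tumour-fraction grid and an intensity-scale
grid,

    sum_seg w_seg * [((s*R - R*)/sigma_R)^2 + ((LAIR - LAIR*)/sigma_L)^2]
        + lambda_di * |implied_index - flow_DI|

with length weights w_seg and closed-form expectations R*, LAIR* per state.
The DI penalty couples segments only through the implied index, which is
linear in per-segment copy number; the coupled problem is solved by a
Lagrangian sweep over the penalty slope followed by single-segment exchange
refinement of the exact objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .arrays import ArraySample
from .genome import (
    GRCH37,
    AllelicState,
    GenomeBuild,
    Karyotype,
    Segment,
    enumerate_states,
    parse_state,
)

__all__ = [
    "SegmentCall",
    "CalibrationResult",
    "segment_tracks",
    "expected_signals",
    "calibrate_states",
    "implied_copy_number",
    "fish_concordance",
    "estimate_track_noise",
    "call_sample",
]


def expected_signals(state: AllelicState, f: float) -> tuple[float, float | None]:
    """Closed-form (R*, LAIR*) for a state at tumour fraction f.

    The sample is a two-component mixture of tumour cells (fraction f, state
    (a, b)) and diploid stromal cells:

        R*    = (f*(a+b) + 2*(1-f)) / 2
        LAIR* = (f*b + (1-f)) / (f*a + (1-f))

    LAIR* is undefined for the zero-copy state at f = 1.
    """
    if 1.0 < f <= 1.0 + 1e-9:  # tolerate float drift from grid construction
        f = 1.0
    if not (0.0 < f <= 1.0):
        raise ValueError("tumour fraction f must be in (0, 1]")
    r = (f * state.copies + 2.0 * (1.0 - f)) / 2.0
    den = f * state.a + (1.0 - f)
    if den == 0:
        return r, None
    return r, (f * state.b + (1.0 - f)) / den


# ---------------------------------------------------------------------------
# segmentation


def _max_t_split(v: np.ndarray) -> tuple[int, float]:
    """Best binary split of a sequence by a two-sample t-like statistic."""
    n = len(v)
    s = np.cumsum(v)
    i = np.arange(1, n)
    mean_l = s[:-1] / i
    mean_r = (s[-1] - s[:-1]) / (n - i)
    sd = max(float(np.std(v, ddof=1)), 1e-8)
    t = np.abs(mean_l - mean_r) / (sd * np.sqrt(1.0 / i + 1.0 / (n - i)))
    # forbid size-1 flanks so the statistic has a variance estimate
    t[0] = t[-1] = 0.0
    j = int(np.argmax(t))
    return j + 1, float(t[j])


def _split_significant(
    v: np.ndarray, alpha: float, n_permutations: int, rng: np.random.Generator
) -> int | None:
    """Index of an accepted changepoint (permutation p < alpha), or None."""
    n = len(v)
    if n < 4:
        return None
    cut, t_obs = _max_t_split(v)
    if t_obs <= 0:
        return None
    perm = rng.permuted(np.broadcast_to(v, (n_permutations, n)), axis=1)
    s = np.cumsum(perm, axis=1)
    i = np.arange(1, n)
    mean_l = s[:, :-1] / i
    mean_r = (s[:, -1:] - s[:, :-1]) / (n - i)
    sd = np.maximum(perm.std(axis=1, ddof=1), 1e-8)
    t = np.abs(mean_l - mean_r) / (sd[:, None] * np.sqrt(1.0 / i + 1.0 / (n - i)))
    t[:, 0] = t[:, -1] = 0.0
    t_max = t.max(axis=1)
    p = (1.0 + float((t_max >= t_obs).sum())) / (n_permutations + 1.0)
    return cut if p < alpha else None


def _recursive_cuts(
    v: np.ndarray, alpha: float, n_permutations: int, rng: np.random.Generator, offset: int = 0
) -> list[int]:
    cut = _split_significant(v, alpha, n_permutations, rng)
    if cut is None:
        return []
    return (
        _recursive_cuts(v[:cut], alpha, n_permutations, rng, offset)
        + [offset + cut]
        + _recursive_cuts(v[cut:], alpha, n_permutations, rng, offset + cut)
    )


def _sd_undo(v: np.ndarray, cuts: list[int], undo_sd: float) -> list[int]:
    """Remove changepoints whose flanking means differ by < undo_sd * noise.

    Noise is estimated robustly from first differences, which are immune to
    the segment structure itself.
    """
    if not cuts:
        return cuts
    sigma = 1.4826 * float(np.median(np.abs(np.diff(v)))) / np.sqrt(2.0) if len(v) > 1 else 0.0
    cuts = sorted(cuts)
    while cuts:
        bounds = [0] + cuts + [len(v)]
        means = [v[lo:hi].mean() for lo, hi in zip(bounds[:-1], bounds[1:])]
        gaps = [abs(means[i + 1] - means[i]) for i in range(len(cuts))]
        k = int(np.argmin(gaps))
        if gaps[k] >= undo_sd * sigma:
            break
        cuts.pop(k)
    return cuts


def segment_tracks(
    sample: ArraySample,
    min_markers: int = 10,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    undo_sd: float = 3.0,
    seed: int = 0,
    build: GenomeBuild = GRCH37,
) -> list[Segment]:
    """Segment the R and LAIR tracks jointly, per chromosome.

    Changepoints accepted on either track (recursive binary splitting, max-t
    statistic, seeded permutation test at level ``alpha``) are pruned by the
    sd-undo rule (a split survives only if its flanking means differ by at
    least ``undo_sd`` track-noise units) and then pooled; runs shorter than
    ``min_markers`` are merged into the neighbour with the closer mean R.
    Segment extents span the whole chromosome, with internal boundaries
    midway between flanking markers; summaries are medians.
    """
    if min_markers < 2:
        raise ValueError("min_markers must be >= 2")
    if "r" not in sample.markers.columns:
        raise ValueError("sample lacks the normalized R track; run normalize_intensities")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    df = sample.markers
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom].reset_index(drop=True)
        n = len(sub)
        r = sub["r"].to_numpy(float)
        if n < min_markers:
            segments.append(_summarize(chrom, sub, 0, n, build))
            continue
        cuts = set(_sd_undo(r, _recursive_cuts(r, alpha, n_permutations, rng), undo_sd))
        if "lair" in sub.columns:
            lair = sub["lair"].to_numpy(float)
            het_idx = np.flatnonzero(~np.isnan(lair))
            if len(het_idx) >= 4:
                lv = lair[het_idx]
                for c in _sd_undo(lv, _recursive_cuts(lv, alpha, n_permutations, rng), undo_sd):
                    cuts.add(int(het_idx[c]))  # cut before this marker
        bounds = sorted(cuts)
        runs = _merge_short_runs(r, [0] + bounds + [n], min_markers)
        for lo, hi in zip(runs[:-1], runs[1:]):
            segments.append(_summarize(chrom, sub, lo, hi, build))
    return segments


def _merge_short_runs(r: np.ndarray, bounds: list[int], min_markers: int) -> list[int]:
    """Drop boundaries of runs shorter than min_markers, toward the closer-mean neighbour."""
    bounds = list(bounds)
    while len(bounds) > 2:
        sizes = np.diff(bounds)
        k = int(np.argmin(sizes))
        if sizes[k] >= min_markers:
            break
        lo, hi = bounds[k], bounds[k + 1]
        seg_mean = r[lo:hi].mean()
        left_mean = r[bounds[k - 1]: lo].mean() if k > 0 else None
        right_mean = r[hi: bounds[k + 2]].mean() if k + 2 < len(bounds) else None
        if left_mean is None:
            bounds.pop(k + 1)
        elif right_mean is None:
            bounds.pop(k)
        elif abs(seg_mean - left_mean) <= abs(seg_mean - right_mean):
            bounds.pop(k)
        else:
            bounds.pop(k + 1)
    return bounds


def _summarize(chrom, sub, lo, hi, build: GenomeBuild) -> Segment:
    pos = sub["pos"].to_numpy()
    n = len(sub)
    start = 1 if lo == 0 else int((pos[lo - 1] + pos[lo]) // 2) + 1
    end = build.length(chrom) if hi == n else int((pos[hi - 1] + pos[hi]) // 2)
    r = sub["r"].to_numpy(float)[lo:hi]
    med_r = float(np.median(r))
    med_lair = None
    if "lair" in sub.columns:
        lv = sub["lair"].to_numpy(float)[lo:hi]
        lv = lv[~np.isnan(lv)]
        if len(lv):
            med_lair = float(np.median(lv))
    return Segment(
        chrom=chrom, start=start, end=end, n_markers=hi - lo,
        median_r=med_r, median_lair=med_lair,
    )


def estimate_track_noise(sample: ArraySample, segments: list[Segment]) -> tuple[float, float]:
    """Robust (sigma_R, sigma_L) from within-segment median absolute deviations."""
    df = sample.markers
    res_r: list[np.ndarray] = []
    res_l: list[np.ndarray] = []
    for seg in segments:
        m = (df["chrom"] == seg.chrom) & (df["pos"] >= seg.start) & (df["pos"] <= seg.end)
        r = df.loc[m, "r"].to_numpy(float)
        if len(r) >= 3:
            res_r.append(np.abs(r - np.median(r)))
        if "lair" in df.columns:
            lv = df.loc[m, "lair"].to_numpy(float)
            lv = lv[~np.isnan(lv)]
            if len(lv) >= 3:
                res_l.append(np.abs(lv - np.median(lv)))
    sigma_r = 1.4826 * float(np.median(np.concatenate(res_r))) if res_r else 0.08
    sigma_l = 1.4826 * float(np.median(np.concatenate(res_l))) if res_l else 0.05
    return max(sigma_r, 0.01), max(sigma_l, 0.01)


# ---------------------------------------------------------------------------
# calibration


@dataclass
class SegmentCall:
    """A segment with its calibrated allelic state."""

    segment: Segment
    state: AllelicState
    residual_r: float = 0.0
    residual_lair: float = 0.0
    di_resolved: bool = False  # the DI penalty overrode the local residual optimum

    @property
    def copies(self) -> int:
        return self.state.copies


@dataclass
class CalibrationResult:
    """Genome-wide allelic-state assignment calibrated against the flow DI."""

    calls: list[SegmentCall] = field(default_factory=list)
    f: float = 1.0
    scale: float = 1.0
    lair_index: float = 0.0
    flow_di: float = 1.0
    total_cost: float = 0.0

    @property
    def di_gap(self) -> float:
        return abs(self.lair_index - self.flow_di)

    def karyotype(self, sex: str = "female") -> Karyotype:
        return Karyotype(segments=[(c.segment, c.state) for c in self.calls], sex=sex)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [c.segment.chrom for c in self.calls],
                "start": [c.segment.start for c in self.calls],
                "end": [c.segment.end for c in self.calls],
                "n_markers": [c.segment.n_markers for c in self.calls],
                "median_r": [c.segment.median_r for c in self.calls],
                "median_lair": [c.segment.median_lair for c in self.calls],
                "state_label": [c.state.label for c in self.calls],
                "copies": [c.copies for c in self.calls],
                "ambiguity_flag": [c.di_resolved for c in self.calls],
            }
        )

    def summary_json(self) -> str:
        return json.dumps(
            {
                "flow_di": self.flow_di,
                "lair_index": self.lair_index,
                "f": self.f,
                "scale": self.scale,
                "total_cost": self.total_cost,
            }
        )


def _cost_matrices(
    segments: list[Segment],
    states: list[AllelicState],
    f: float,
    scale: float,
    sigma_r: float,
    sigma_l: float,
    weights: np.ndarray,
) -> np.ndarray:
    """Length-weighted squared residual of every (segment, state) pair."""
    n_seg, n_st = len(segments), len(states)
    cost = np.zeros((n_seg, n_st))
    r_star = np.array([expected_signals(st, f)[0] for st in states])
    l_star = np.array(
        [np.nan if expected_signals(st, f)[1] is None else expected_signals(st, f)[1] for st in states]
    )
    for i, seg in enumerate(segments):
        rr = ((scale * seg.median_r - r_star) / sigma_r) ** 2
        if seg.median_lair is not None:
            ll = np.where(
                np.isnan(l_star), 1e6, ((seg.median_lair - np.nan_to_num(l_star)) / sigma_l) ** 2
            )
        else:
            ll = np.zeros(n_st)
        cost[i] = weights[i] * (rr + ll)
    # infinitesimal preference for fewer copies breaks exact ties
    cost += 1e-9 * np.array([st.copies for st in states])[None, :]
    return cost


def _optimize_assignment(
    cost: np.ndarray,
    tau: np.ndarray,
    flow_di: float,
    lambda_di: float,
    n_slopes: int = 201,
) -> tuple[np.ndarray, float]:
    """Minimize sum(cost[i, a_i]) + lambda*|sum(tau[i, a_i]) - flow_di|.

    The implied index is linear in the assignment, so a sweep over the
    Lagrangian slope in [-lambda, lambda] traces candidate solutions (exact
    whenever the unconstrained optimum lands on one side of the DI); a
    single-segment exchange pass then refines the exact objective.
    """
    n_seg = cost.shape[0]

    def exact_obj(assign: np.ndarray) -> float:
        idx = tau[np.arange(n_seg), assign].sum()
        return cost[np.arange(n_seg), assign].sum() + lambda_di * abs(idx - flow_di)

    slopes = np.linspace(-lambda_di, lambda_di, n_slopes)
    mod = cost[None, :, :] + slopes[:, None, None] * tau[None, :, :]
    assigns = np.asarray(mod.argmin(axis=2))
    cand = {tuple(a) for a in assigns}
    best = min(cand, key=lambda a: exact_obj(np.asarray(a)))
    best = np.asarray(best)
    best_obj = exact_obj(best)

    improved = True
    while improved:
        improved = False
        for i in range(n_seg):
            cur = best[i]
            for s in range(cost.shape[1]):
                if s == cur:
                    continue
                trial = best.copy()
                trial[i] = s
                obj = exact_obj(trial)
                if obj < best_obj - 1e-12:
                    best, best_obj = trial, obj
                    improved = True
    return best, float(best_obj)


def calibrate_states(
    segments: list[Segment],
    flow_di: float,
    f_grid: tuple[float, ...] = (1.0,),
    max_copies: int = 6,
    lambda_di: float = 5.0,
    sigma_r: float = 0.08,
    sigma_l: float = 0.05,
    scale_grid: np.ndarray | None = None,
    include_null: bool = False,
) -> CalibrationResult:
    """Assign an integer allelic state to every segment, DI-calibrated.

    Searches tumour fraction over ``f_grid`` and the lost intensity scale
    (the R track is self-normalized to autosomal median 1) over
    ``scale_grid``; for each candidate the coupled assignment problem is
    solved and the best exact objective wins.  The DI penalty is soft
    (weight ``lambda_di`` per unit of DNA index), strong enough to flip an
    otherwise scale-degenerate all-homozygous genome between genome-[A]
    (flow DI near 0.5) and genome-[AA] (flow DI near 1.0), yet tolerant of
    the two-decimal measurement error of the flow DI itself.
    """
    if not segments:
        raise ValueError("no segments to calibrate")
    if flow_di <= 0:
        raise ValueError("flow_di must be positive")
    states = enumerate_states(max_copies, include_null=include_null)
    if scale_grid is None:
        scale_grid = np.arange(0.25, 3.0 + 1e-9, 0.025)

    lengths = np.array([s.length for s in segments], float)
    weights = lengths / lengths.sum()
    copies = np.array([st.copies for st in states], float)
    tau = weights[:, None] * copies[None, :] / 2.0  # per-(segment,state) index share

    # cheap lower bound per (f, scale): residual-only optimum prunes the grid
    cands: list[tuple[float, float, float, np.ndarray]] = []
    for f in f_grid:
        for s in scale_grid:
            cost = _cost_matrices(segments, states, f, s, sigma_r, sigma_l, weights)
            cands.append((float(cost.min(axis=1).sum()), f, float(s), cost))
    cands.sort(key=lambda t: t[0])

    best: tuple[float, np.ndarray, float, float, np.ndarray] | None = None
    for base, f, s, cost in cands:
        if best is not None and base >= best[0]:
            break
        assign, obj = _optimize_assignment(cost, tau, flow_di, lambda_di)
        if best is None or obj < best[0]:
            best = (obj, assign, f, s, cost)
    if best is None:  # pragma: no cover - guarded by the empty-segments check
        raise RuntimeError("no feasible assignment; try a larger max_copies")
    obj, assign, f, s, cost = best

    local_opt = cost.argmin(axis=1)
    calls = []
    idx = 0.0
    for i, seg in enumerate(segments):
        st = states[assign[i]]
        r_star, l_star = expected_signals(st, f)
        calls.append(
            SegmentCall(
                segment=seg,
                state=st,
                residual_r=float(s * seg.median_r - r_star),
                residual_lair=(
                    float(seg.median_lair - l_star)
                    if seg.median_lair is not None and l_star is not None
                    else 0.0
                ),
                di_resolved=bool(assign[i] != local_opt[i]),
            )
        )
        idx += tau[i, assign[i]]
    return CalibrationResult(
        calls=calls, f=f, scale=s, lair_index=float(idx), flow_di=flow_di, total_cost=obj
    )


def implied_copy_number(state: AllelicState | str) -> int:
    """Total copy number implied by an allelic state (a + b)."""
    if isinstance(state, str):
        state = parse_state(state)
    return state.copies


def fish_concordance(
    states: list[AllelicState | str],
    fish_counts: list[object],
) -> tuple[list[dict], int]:
    """Compare allelic-state implied copy numbers with FISH probe counts.

    An entry is concordant iff the FISH count equals the implied copy
    number.  A mixture entry such as ``"3-4"`` (two intermingled copy
    numbers) is discordant with any single implied value.  Undetermined
    entries (None, NaN, ``"nd"``, empty) are skipped.  Returns per-entry
    verdicts and the number of discordant entries.
    """
    verdicts: list[dict] = []
    exceptions = 0
    for state, fish in zip(states, fish_counts):
        st = parse_state(state) if isinstance(state, str) else state
        parsed = _parse_fish(fish)
        if parsed is None:
            verdicts.append({"state": st.label, "fish": None, "verdict": "skipped"})
            continue
        if isinstance(parsed, tuple):  # mixture
            concordant = False
        else:
            concordant = parsed == st.copies
        verdicts.append(
            {"state": st.label, "fish": parsed, "verdict": "concordant" if concordant else "discordant"}
        )
        if not concordant:
            exceptions += 1
    return verdicts, exceptions


def _parse_fish(entry: object) -> int | tuple[int, int] | None:
    if entry is None:
        return None
    if isinstance(entry, float):
        if np.isnan(entry):
            return None
        entry = int(entry)
    if isinstance(entry, (int, np.integer)):
        return int(entry)
    s = str(entry).strip()
    if s in ("", "nd", "NA", "na", "-"):
        return None
    for dash in ("–", "—"):
        s = s.replace(dash, "-")
    if "-" in s:
        lo, _, hi = s.partition("-")
        try:
            return (int(lo), int(hi))
        except ValueError:
            raise ValueError(f"unparseable FISH entry: {entry!r}") from None
    try:
        return int(s)
    except ValueError:
        raise ValueError(f"unparseable FISH entry: {entry!r}") from None


# ---------------------------------------------------------------------------
# convenience pipeline


def call_sample(
    sample: ArraySample,
    references: list[ArraySample],
    flow_di: float,
    f_grid: tuple[float, ...] = (1.0,),
    min_gcs: float = 0.25,
    min_markers: int = 10,
    alpha: float = 0.01,
    max_copies: int = 6,
    lambda_di: float = 5.0,
    seed: int = 0,
    build: GenomeBuild = GRCH37,
    female_reference: bool = True,
) -> CalibrationResult:
    """Filter, normalize, compute LAIR, segment, and calibrate one sample."""
    from .arrays import compute_lair, filter_markers, normalize_intensities

    filt = filter_markers(sample, min_gcs=min_gcs)
    refs = [filter_markers(r, min_gcs=0.0) for r in references]
    norm = normalize_intensities(filt, refs)
    norm = compute_lair(norm, refs, female_reference=female_reference)
    segments = segment_tracks(norm, min_markers=min_markers, alpha=alpha, seed=seed, build=build)
    sigma_r, sigma_l = estimate_track_noise(norm, segments)
    return calibrate_states(
        segments,
        flow_di,
        f_grid=f_grid,
        max_copies=max_copies,
        lambda_di=lambda_di,
        sigma_r=sigma_r,
        sigma_l=sigma_l,
    )
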