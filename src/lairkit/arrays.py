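"""SNP-array sample handling: the R and LAIR marker tracks.

A sample is a table of markers with reference genotype, two allele
intensities and a genotype call score (GCS).  Two derived tracks drive all
downstream inference:

* ``R`` — normalized total intensity, the diploid-relative copy-number
  signal: raw total intensity divided, marker by marker, by the median
  total intensity over a panel of diploid reference samples, then rescaled
  so the sample's autosomal median is 1 (self-normalization; the absolute
  scale is recovered later during DNA-index calibration).
* ``LAIR`` — the lesser allele intensity ratio, defined only at markers the
  reference calls heterozygous: the ratio of the weaker to the stronger
  reference-scaled allele intensity.  It is close to 1 when both parental
  alleles contribute as in the reference, close to 0 under LOH, and takes
  intermediate values under allelic imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArraySample",
    "ArrayParseError",
    "read_array",
    "write_array",
    "write_tracks",
    "filter_markers",
    "normalize_intensities",
    "compute_lair",
    "chromosome_sort_key",
]

REQUIRED_COLUMNS = ["marker_id", "chrom", "pos", "gtype_ref", "x_raw", "y_raw", "gcs"]

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}


def chromosome_sort_key(chrom: str) -> int:
    """Numeric sort rank for chr1..chr22, chrX, chrY."""
    try:
        return _CHROM_ORDER[chrom]
    except KeyError:
        raise ArrayParseError(f"unsortable chromosome name: {chrom!r}") from None


class ArrayParseError(ValueError):
    """Raised for malformed array sample tables."""


@dataclass
class ArraySample:
    """One array sample: marker table plus derived tracks.

    ``markers`` columns: marker_id, chrom, pos, gtype_ref, x_raw, y_raw, gcs,
    and after processing r_ref (reference-relative R), r (self-normalized R)
    and lair (NaN where undefined).  Markers are sorted by (chromosome,
    position).
    """

    sample_id: str
    markers: pd.DataFrame
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ArrayParseError(f"missing columns: {missing}")
        df = self.markers
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ArrayParseError(f"duplicate marker id: {dup!r}")
        if (df["pos"] < 1).any():
            raise ArrayParseError("marker positions must be >= 1 (1-based)")
        if (df[["x_raw", "y_raw"]] < 0).to_numpy().any():
            raise ArrayParseError("negative allele intensities")
        bad_gt = set(df["gtype_ref"].unique()) - {"AA", "AB", "BB", "NC"}
        if bad_gt:
            raise ArrayParseError(f"invalid reference genotypes: {sorted(bad_gt)}")
        order = df["chrom"].map(chromosome_sort_key)
        df = df.assign(_ord=order).sort_values(["_ord", "pos"], kind="mergesort")
        self.markers = df.drop(columns="_ord").reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def het_mask(self) -> np.ndarray:
        return (self.markers["gtype_ref"] == "AB").to_numpy()

    def copy(self) -> "ArraySample":
        return ArraySample(self.sample_id, self.markers.copy(), dict(self.filter_log))


def read_array(path, sample_id: str | None = None) -> ArraySample:
    """Read a tab-separated array sample table.

    Expects header columns marker_id, chrom, pos, gtype_ref, x_raw, y_raw,
    gcs.  Records are sorted and validated; no-call (NC) genotypes are kept
    but flagged for removal by :func:`filter_markers`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"marker_id": str, "chrom": str})
    sid = sample_id if sample_id is not None else str(path)
    return ArraySample(sid, df)


def write_array(sample: ArraySample, path) -> None:
    """Write the raw marker table in the TSV dialect read by :func:`read_array`."""
    sample.markers[REQUIRED_COLUMNS].to_csv(path, sep="\t", index=False)


def write_tracks(sample: ArraySample, path) -> None:
    """Write the derived per-marker tracks (marker_id, chrom, pos, R, LAIR).

    The LAIR field is left empty where undefined.
    """
    cols = ["marker_id", "chrom", "pos"]
    df = sample.markers[cols].copy()
    df["r"] = sample.markers.get("r", np.nan)
    df["lair"] = sample.markers.get("lair", np.nan)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def filter_markers(
    sample: ArraySample,
    min_gcs: float = 0.25,
    chromosomes: set[str] | None = None,
) -> ArraySample:
    """Drop low-quality markers.

    Removes markers with call score below ``min_gcs``, no-call reference
    genotypes, and (when given) chromosomes outside ``chromosomes``.  The
    per-reason removal counts are recorded in ``filter_log``.
    """
    if not (0.0 <= min_gcs <= 1.0):
        raise ValueError("min_gcs must be in [0, 1]")
    df = sample.markers
    low_gcs = df["gcs"] < min_gcs
    no_call = df["gtype_ref"] == "NC"
    off_chrom = (
        ~df["chrom"].isin(chromosomes)
        if chromosomes is not None
        else pd.Series(False, index=df.index)
    )
    keep = ~(low_gcs | no_call | off_chrom)
    if not keep.any():
        raise ValueError(f"no markers left after filtering sample {sample.sample_id!r}")
    log = {
        "low_gcs": int((low_gcs & ~no_call & ~off_chrom).sum()),
        "no_call": int(no_call.sum()),
        "off_chromosome": int((off_chrom & ~no_call).sum()),
        "retained": int(keep.sum()),
    }
    out = ArraySample(sample.sample_id, df.loc[keep].reset_index(drop=True))
    out.filter_log = log
    return out


def _check_panel(sample: ArraySample, references: list[ArraySample]) -> None:
    if not references:
        raise ValueError("at least one diploid reference sample is required")
    ids = sample.markers["marker_id"]
    for ref in references:
        missing = set(ids) - set(ref.markers["marker_id"])
        if missing:
            shown = sorted(missing)[:5]
            raise ValueError(
                f"reference {ref.sample_id!r} lacks {len(missing)} markers, e.g. {shown}"
            )


def _aligned(reference: ArraySample, ids: pd.Series) -> pd.DataFrame:
    return reference.markers.set_index("marker_id").loc[ids]


def normalize_intensities(
    sample: ArraySample, reference_samples: list[ArraySample]
) -> ArraySample:
    """Attach the normalized total-intensity track R.

    Per marker, R is the total intensity divided by the median total
    intensity over the reference panel (``r_ref``, diploid-relative); the
    stored ``r`` track is additionally rescaled so that the autosomal median
    equals 1.  The self-normalized track is therefore invariant to any
    positive rescaling of the sample's raw intensities; the lost absolute
    scale is re-estimated during allelic-state calibration against the
    flow-cytometric DNA index.
    """
    _check_panel(sample, reference_samples)
    out = sample.copy()
    df = out.markers
    ids = df["marker_id"]
    tot = (df["x_raw"] + df["y_raw"]).to_numpy(float)
    ref_tot = np.median(
        np.column_stack(
            [
                (_aligned(r, ids)["x_raw"] + _aligned(r, ids)["y_raw"]).to_numpy(float)
                for r in reference_samples
            ]
        ),
        axis=1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ref = np.where(ref_tot > 0, tot / ref_tot, np.nan)
    autosomal = df["chrom"].isin(AUTOSOME_SET).to_numpy()
    med = np.nanmedian(r_ref[autosomal])
    if not np.isfinite(med) or med <= 0:
        raise ValueError("cannot self-normalize: non-positive autosomal median R")
    df["r_ref"] = r_ref
    df["r"] = r_ref / med
    return out


AUTOSOME_SET = {f"chr{i}" for i in range(1, 23)}


def compute_lair(
    sample: ArraySample,
    reference_samples: list[ArraySample],
    female_reference: bool = True,
) -> ArraySample:
    """Attach the LAIR track at reference-heterozygous markers.

    Each allele intensity is first scaled by its median over the reference
    panel at the same marker (per-allele, per-marker scaling), then
    LAIR = min(x', y') / max(x', y').  Markers where both scaled intensities
    vanish are flagged missing (NaN) rather than raising.  For a male
    reference the X chromosome is hemizygous, so its LAIR is left undefined
    and X is interpreted through intensity only.
    """
    _check_panel(sample, reference_samples)
    out = sample.copy()
    df = out.markers
    ids = df["marker_id"]
    ref_x = np.column_stack(
        [_aligned(r, ids)["x_raw"].to_numpy(float) for r in reference_samples]
    )
    ref_y = np.column_stack(
        [_aligned(r, ids)["y_raw"].to_numpy(float) for r in reference_samples]
    )
    med_x = np.median(ref_x, axis=1)
    med_y = np.median(ref_y, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        xs = np.where(med_x > 0, df["x_raw"].to_numpy(float) / med_x, np.nan)
        ys = np.where(med_y > 0, df["y_raw"].to_numpy(float) / med_y, np.nan)
        lo = np.minimum(xs, ys)
        hi = np.maximum(xs, ys)
        lair = np.where(hi > 0, lo / hi, np.nan)
    het = out.het_mask()
    if not female_reference:
        het = het & (df["chrom"] != "chrX").to_numpy()
    lair = np.where(het, lair, np.nan)
    df["lair"] = np.clip(lair, 0.0, 1.0)
    out.filter_log.setdefault("lair_missing", int(np.isnan(lair[het]).sum()))
    return out
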