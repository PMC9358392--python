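"""Absolute copy-number profiling from human-specific DBS fragments.

Pipeline: count fragment midpoints in fixed-width genomic bins (30 kb or
500 kb), correct counts for GC content and mappability by stratified median
ratios, segment the corrected signal per chromosome with a penalised
least-squares changepoint fit, then fit absolute copy number by grid search
over tumour ploidy (psi) and cellularity (c).

The relative-to-absolute transform for a segment with relative (mean-1
normalised) coverage r is

    absolute(r) = (r * D - 2 * (1 - c)) / c,   D = c * psi + 2 * (1 - c),

and the goodness of a candidate (psi, c) is the segment-length-weighted
mean absolute deviation of segment absolute values from the nearest
integers; the grid minimiser wins. For PDX blood spots the human-specific
compartment is purely tumour-derived, so cellularity defaults to a fixed
1.0 (the full grid remains available). Driver gains/losses follow the
COSMIC ploidy-conditional total-copy-number rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoordinateError, CorrectionError, CoverageError, FitError
from .genome import GenomeLayout
from .species import HUMAN_SPECIFIC

__all__ = [
    "AcnFit",
    "bin_fragments",
    "correct_counts",
    "segment_bins",
    "fit_absolute",
    "relative_from_absolute",
    "cosmic_call",
    "call_driver_cna",
    "project_to_bins",
    "profile_correlation",
    "acn_pipeline",
    "DEFAULT_PLOIDY_GRID",
    "DEFAULT_CELLULARITY_GRID",
    "MIN_ACN_FRAGMENTS",
]

DEFAULT_PLOIDY_GRID = np.round(np.arange(1.5, 5.5 + 1e-9, 0.05), 10)
DEFAULT_CELLULARITY_GRID = np.round(np.arange(0.1, 1.0 + 1e-9, 0.01), 10)

#: Operating floor: ACN fitting refuses samples with fewer human-specific
#: fragments unless forced.
MIN_ACN_FRAGMENTS = 500_000


@dataclass
class AcnFit:
    """An absolute copy-number solution."""

    ploidy: float
    cellularity: float
    goodness: float  # length-weighted MAD of segment ACN from nearest integers
    segments: pd.DataFrame  # chromosome, start, end, n_bins, relative_value, absolute_value


def bin_fragments(
    fragments: pd.DataFrame, bin_width: int, layout: GenomeLayout
) -> pd.DataFrame:
    """Count human-specific fragment midpoints in fixed-width bins.

    Each fragment is assigned to exactly one bin by its midpoint
    (half-open bins; a midpoint exactly on a boundary goes to the
    higher bin). Returns the full bin grid with a ``raw_count`` column.
    """
    frag = fragments
    if "category" in frag.columns:
        frag = frag.loc[frag["category"] == HUMAN_SPECIFIC]
    bins = layout.bins(bin_width)
    counts = np.zeros(len(bins), dtype=np.int64)
    # per-chromosome offsets into the concatenated bin table
    offsets: dict[str, tuple[int, int]] = {}
    for chrom, idx in bins.groupby("chromosome", sort=False).indices.items():
        offsets[chrom] = (int(idx[0]), len(idx))
    for chrom, grp in frag.groupby("chromosome", sort=False):
        if chrom not in offsets:
            raise CoordinateError(f"fragment on unknown chromosome {chrom!r}")
        chrom_len = layout.chrom_length(chrom)
        start = grp["start"].to_numpy(dtype=float)
        end = grp["end"].to_numpy(dtype=float)
        if (start < 0).any() or (end > chrom_len).any():
            raise CoordinateError(f"fragment beyond the end of {chrom} (length {chrom_len})")
        mid = (start + end) / 2.0
        which = np.minimum((mid // bin_width).astype(np.int64), offsets[chrom][1] - 1)
        offset = offsets[chrom][0]
        np.add.at(counts, offset + which, 1)
    out = bins.copy()
    out["raw_count"] = counts
    return out


def correct_counts(
    bins: pd.DataFrame,
    mappability_floor: float = 0.5,
    n_gc_strata: int = 10,
    n_map_strata: int = 5,
    min_stratum_bins: int = 10,
) -> pd.DataFrame:
    """GC/mappability bias correction by stratified median ratios.

    Bins are stratified into GC deciles x mappability quintiles (quantile
    edges over usable bins); each bin's count is divided by its stratum's
    median raw count, falling back to the global median for strata with
    fewer than ``min_stratum_bins`` usable bins, then rescaled so the mean
    corrected signal over usable bins is 1. Bins with mappability below
    ``mappability_floor`` are flagged unusable and get NaN corrected signal.
    """
    out = bins.copy()
    if "usable" not in out.columns:
        out["usable"] = True
    out.loc[out["mappability"] < mappability_floor, "usable"] = False
    usable = out["usable"].to_numpy(dtype=bool)
    if not usable.any():
        raise CorrectionError("no usable bins after mappability filtering")
    raw = out["raw_count"].to_numpy(dtype=float)
    global_median = float(np.median(raw[usable]))
    if global_median <= 0:
        raise CorrectionError("median raw count over usable bins is zero")

    def _strata(values: np.ndarray, k: int) -> np.ndarray:
        edges = np.unique(np.quantile(values[usable], np.linspace(0, 1, k + 1)))
        return np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)

    gc_stratum = _strata(out["gc"].to_numpy(dtype=float), n_gc_strata)
    map_stratum = _strata(out["mappability"].to_numpy(dtype=float), n_map_strata)
    stratum = gc_stratum * n_map_strata + map_stratum

    denominators = np.full(len(out), global_median)
    for s in np.unique(stratum[usable]):
        members = usable & (stratum == s)
        if members.sum() >= min_stratum_bins:
            med = float(np.median(raw[members]))
            if med > 0:
                denominators[stratum == s] = med
    corrected = raw / denominators
    mean_usable = corrected[usable].mean()
    if mean_usable <= 0:
        raise CorrectionError("corrected signal has non-positive mean")
    corrected = corrected / mean_usable
    corrected[~usable] = np.nan
    out["corrected"] = corrected
    return out


def _segment_1d(values: np.ndarray, penalty: Optional[float]) -> list[tuple[int, int]]:
    """Optimal partitioning of a 1-D signal under cost RSS + penalty/segment.

    O(n^2) dynamic programme. The default penalty is SIC-style,
    ``2 * sigma^2 * log(n)`` with sigma estimated robustly from first
    differences, floored so that noiseless constant signals collapse to a
    single segment. Returns half-open index ranges.
    """
    n = len(values)
    if n == 0:
        return []
    if penalty is None:
        if n > 1:
            diffs = np.diff(values)
            sigma = np.median(np.abs(diffs - np.median(diffs))) / 0.6745 / np.sqrt(2.0)
        else:
            sigma = 0.0
        # 5x the classic SIC constant: copy-number steps are large relative
        # to bin noise at these depths, and the stiffer penalty keeps pure
        # noise from splitting (calibrated so constant signal -> 1 segment)
        penalty = max(10.0 * sigma**2 * np.log(max(n, 2)), 1e-10)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    cs2 = np.concatenate([[0.0], np.cumsum(values**2)])
    idx = np.arange(n + 1, dtype=float)
    best = np.full(n + 1, np.inf)
    best[0] = 0.0
    back = np.zeros(n + 1, dtype=np.int64)
    for j in range(1, n + 1):
        s = cs[j] - cs[:j]
        seg_cost = (cs2[j] - cs2[:j]) - s * s / (j - idx[:j])
        costs = best[:j] + penalty + seg_cost
        i_best = int(np.argmin(costs))  # argmin keeps the earliest tie
        best[j] = costs[i_best]
        back[j] = i_best
    breaks = []
    j = n
    while j > 0:
        i = int(back[j])
        breaks.append((i, j))
        j = i
    return breaks[::-1]


def segment_bins(bins: pd.DataFrame, penalty: Optional[float] = None) -> pd.DataFrame:
    """Segment corrected bin signal per chromosome into constant pieces.

    Only usable bins participate; each segment spans from the start of its
    first member bin to the end of its last, with ``relative_value`` the
    mean corrected signal of member bins.
    """
    rows = []
    usable = bins.loc[bins["usable"].astype(bool)]
    for chrom, grp in usable.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        values = grp["corrected"].to_numpy(dtype=float)
        for i, j in _segment_1d(values, penalty):
            rows.append(
                {
                    "chromosome": chrom,
                    "start": int(grp["start"].iloc[i]),
                    "end": int(grp["end"].iloc[j - 1]),
                    "n_bins": j - i,
                    "relative_value": float(values[i:j].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "n_bins", "relative_value"])


def relative_from_absolute(absolute: np.ndarray, ploidy: float, cellularity: float) -> np.ndarray:
    """Inverse transform: expected relative coverage of absolute copies."""
    d = cellularity * ploidy + 2.0 * (1.0 - cellularity)
    return (cellularity * np.asarray(absolute, dtype=float) + 2.0 * (1.0 - cellularity)) / d


def fit_absolute(
    segments: pd.DataFrame,
    ploidy_grid: Optional[Sequence[float]] = None,
    cellularity_grid: Optional[Sequence[float]] = None,
    guide_ploidy: Optional[float] = None,
) -> AcnFit:
    """Grid-search ploidy/cellularity minimising distance to integer copies.

    ``guide_ploidy`` (e.g. from a matched tumour-tissue fit of the same
    patient line) restricts the ploidy grid to +/- 0.5 around the guide.
    Ties are broken toward lower ploidy, then higher cellularity, so flat
    (ploidy-unidentifiable) profiles resolve deterministically — a profile
    with no detectable SCNAs fits as diploid.
    """
    if segments.empty:
        raise FitError("no segments to fit")
    psi = np.asarray(DEFAULT_PLOIDY_GRID if ploidy_grid is None else ploidy_grid, dtype=float)
    cel = np.asarray(
        [1.0] if cellularity_grid is None else cellularity_grid, dtype=float
    )
    if guide_ploidy is not None:
        psi = psi[(psi >= guide_ploidy - 0.5) & (psi <= guide_ploidy + 0.5)]
    if psi.size == 0 or cel.size == 0:
        raise FitError("empty ploidy/cellularity grid")
    r = segments["relative_value"].to_numpy(dtype=float)
    w = segments["n_bins"].to_numpy(dtype=float)
    # (n_psi, n_cel) goodness surface
    d = cel[None, :] * psi[:, None] + 2.0 * (1.0 - cel[None, :])
    absolute = (
        r[None, None, :] * d[:, :, None] - 2.0 * (1.0 - cel[None, :, None])
    ) / cel[None, :, None]
    goodness = (w[None, None, :] * np.abs(absolute - np.round(absolute))).sum(axis=2) / w.sum()
    # tie-break: lower ploidy, then higher cellularity
    flat = np.round(goodness, 12).ravel()
    order = np.lexsort((-np.tile(cel, psi.size), np.repeat(psi, cel.size), flat))
    k = order[0]
    i, j = divmod(int(k), cel.size)
    out = segments.copy()
    out["absolute_value"] = absolute[i, j, :]
    return AcnFit(
        ploidy=float(psi[i]),
        cellularity=float(cel[j]),
        goodness=float(goodness[i, j]),
        segments=out,
    )


def cosmic_call(ploidy: float, total_copy_number: float) -> str:
    """COSMIC high-level amplification / homozygous deletion rule.

    Gain: psi <= 2.7 and TCN >= 5, or psi > 2.7 and TCN >= 9.
    Loss: psi <= 2.7 and TCN == 0, or psi > 2.7 and TCN < psi - 2.7.
    """
    if ploidy <= 2.7:
        if total_copy_number >= 5:
            return "gain"
        if total_copy_number == 0:
            return "loss"
    else:
        if total_copy_number >= 9:
            return "gain"
        if total_copy_number < ploidy - 2.7:
            return "loss"
    return "none"


def call_driver_cna(fit: AcnFit, gene_regions: pd.DataFrame) -> pd.DataFrame:
    """Call driver gains/losses over gene regions.

    ``gene_regions`` needs ``chromosome, start, end, name``. The gene-level
    total copy number is the overlap-length-weighted mean of segment
    absolute values across the region; regions untouched by any segment
    raise :class:`CoverageError`.
    """
    seg = fit.segments
    rows = []
    for region in gene_regions.itertuples(index=False):
        mask = (
            (seg["chromosome"] == region.chromosome)
            & (seg["end"] > region.start)
            & (seg["start"] < region.end)
        )
        hits = seg.loc[mask]
        if hits.empty:
            raise CoverageError(
                f"gene {region.name} ({region.chromosome}:{region.start}-{region.end}) "
                "is not covered by any segment"
            )
        overlap = np.minimum(hits["end"], region.end) - np.maximum(hits["start"], region.start)
        tcn = float(np.average(hits["absolute_value"], weights=overlap))
        rows.append(
            {
                "name": region.name,
                "chromosome": region.chromosome,
                "start": region.start,
                "end": region.end,
                "total_copy_number": tcn,
                "call": cosmic_call(fit.ploidy, tcn),
            }
        )
    return pd.DataFrame(rows)


def project_to_bins(fit: AcnFit, layout: GenomeLayout, bin_width: int = 500_000) -> pd.DataFrame:
    """Project segment absolute values onto a fixed bin grid.

    Per-bin value is the overlap-length-weighted mean of covering segments;
    uncovered bins get NaN.
    """
    bins = layout.bins(bin_width)
    values = np.full(len(bins), np.nan)
    for chrom, grp in fit.segments.groupby("chromosome", sort=False):
        idx = bins.index[bins["chromosome"] == chrom]
        if len(idx) == 0:
            continue
        bstart = bins.loc[idx, "start"].to_numpy()
        bend = bins.loc[idx, "end"].to_numpy()
        num = np.zeros(len(idx))
        den = np.zeros(len(idx))
        for s in grp.itertuples(index=False):
            overlap = np.clip(
                np.minimum(bend, s.end) - np.maximum(bstart, s.start), 0, None
            ).astype(float)
            num += overlap * s.absolute_value
            den += overlap
        values[idx] = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    out = bins
    out["absolute_value"] = values
    return out


def profile_correlation(
    fit_a: AcnFit, fit_b: AcnFit, layout: GenomeLayout, bin_width: int = 500_000
) -> tuple[float, float]:
    """Bin-wise Pearson correlation of two absolute profiles.

    Both profiles are projected onto the same bin grid; only bins covered
    in both are retained. Zero variance in either profile yields
    ``(nan, nan)``.
    """
    a = project_to_bins(fit_a, layout, bin_width)["absolute_value"].to_numpy()
    b = project_to_bins(fit_b, layout, bin_width)["absolute_value"].to_numpy()
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def acn_pipeline(
    fragments: pd.DataFrame,
    bin_annotation: pd.DataFrame,
    layout: GenomeLayout,
    bin_width: int = 30_000,
    guide_ploidy: Optional[float] = None,
    cellularity_grid: Optional[Sequence[float]] = None,
    min_fragments: int = MIN_ACN_FRAGMENTS,
    force: bool = False,
) -> AcnFit:
    """End-to-end ACN profile from a classified fragment table.

    ``bin_annotation`` carries ``chromosome, start, end, gc, mappability``
    on the same grid as ``bin_width``. Samples below the human-specific
    fragment floor are refused unless ``force`` is set.
    """
    human = fragments.loc[fragments["category"] == HUMAN_SPECIFIC]
    if len(human) < min_fragments and not force:
        raise FitError(
            f"only {len(human)} human-specific fragments; ACN fitting needs >= "
            f"{min_fragments} (pass force=True to override)"
        )
    bins = bin_fragments(human, bin_width, layout)
    bins = bins.merge(bin_annotation, on=["chromosome", "start", "end"], how="left")
    if bins["gc"].isna().any() or bins["mappability"].isna().any():
        raise CorrectionError("bin annotation does not cover the bin grid")
    bins = correct_counts(bins)
    segments = segment_bins(bins)
    return fit_absolute(segments, guide_ploidy=guide_ploidy, cellularity_grid=cellularity_grid)
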