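"""Xenograft Tumour Fraction (xTF) and fragmentomic summaries.

The xTF of a dried-blood-spot sequencing sample is the fraction of
species-specific fragments that are human-specific, restricted to fragments
longer than 30 bp (strictly), after removal of fragments overlapping
blacklisted genomic intervals:

    xTF = n_human_specific(>30 bp) / (n_human_specific + n_mouse_specific)(>30 bp)

Human-specific DBS fragments in a xenograft mouse are tumour-derived, so
xTF measures circulating tumour burden. Sub-31 bp fragments are excluded
because short spurious cross-genome alignments concentrate there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import (
    EmptyDistributionError,
    FormatError,
    NormalisationError,
    RankError,
    UndefinedXtfError,
)
from .species import HUMAN_SPECIFIC, MOUSE_SPECIFIC

__all__ = [
    "DbsSample",
    "XtfSeries",
    "SlopeFit",
    "read_bed",
    "filter_blacklist",
    "compute_xtf",
    "fragment_length_mode",
    "normalize_to_baseline",
    "xtf_change_rate",
]

DEFAULT_MIN_FRAGMENT_BP = 30


@dataclass
class DbsSample:
    """One dried-blood-spot sample with its classified fragments."""

    sample_id: str
    mouse_id: str = ""
    patient_line: str = ""
    arm: str = ""  # treated / control / healthy
    day: int = 0
    fragments: Optional[pd.DataFrame] = None
    xtf: Optional[float] = None
    expected_fraction: Optional[float] = None  # set for in-silico dilution samples


@dataclass
class XtfSeries:
    """Ordered xTF time series for one mouse, optionally baseline-normalised."""

    mouse_id: str
    points: list[tuple[int, float]] = field(default_factory=list)  # (day, xtf)
    normalised: Optional[list[tuple[int, float]]] = None


@dataclass
class SlopeFit:
    """Pooled OLS fit of (normalised) xTF on study day."""

    slope: float
    intercept: float
    stderr: float
    n_points: int
    n_mice: int


def read_bed(path: str) -> pd.DataFrame:
    """Parse a 3+ column BED file (0-based half-open intervals).

    Raises :class:`FormatError` naming the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has {len(parts)} fields, need >= 3")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def _build_trees(blacklist: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in blacklist.groupby("chromosome", sort=False):
        trees[chrom] = IntervalTree.from_tuples(zip(grp["start"], grp["end"]))
    return trees


def filter_blacklist(
    fragments: pd.DataFrame,
    human_blacklist: Optional[pd.DataFrame] = None,
    mouse_blacklist: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Drop fragments overlapping (>= 1 bp) a blacklist of their assigned genome.

    Human-specific fragments are screened against the human blacklist,
    mouse-specific against the mouse one; unresolved/unmapped fragments pass
    (they carry no assigned coordinates and never enter any count).
    """
    keep = np.ones(len(fragments), dtype=bool)
    cat = fragments["category"].to_numpy(dtype=object)
    for species, blacklist in ((HUMAN_SPECIFIC, human_blacklist), (MOUSE_SPECIFIC, mouse_blacklist)):
        if blacklist is None or blacklist.empty:
            continue
        trees = _build_trees(blacklist)
        mask = cat == species
        idx = np.flatnonzero(mask)
        chroms = fragments["chromosome"].to_numpy(dtype=object)[idx]
        starts = fragments["start"].to_numpy()[idx]
        ends = fragments["end"].to_numpy()[idx]
        for j, chrom, s, e in zip(idx, chroms, starts, ends):
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps(int(s), int(e)):
                keep[j] = False
    return fragments.loc[keep].reset_index(drop=True)


def compute_xtf(sample, min_fragment_bp: int = DEFAULT_MIN_FRAGMENT_BP) -> float:
    """Compute xTF for a :class:`DbsSample` or a raw fragment table.

    Only species-specific fragments with length strictly greater than
    ``min_fragment_bp`` are counted. Raises :class:`UndefinedXtfError` when
    the denominator is zero.
    """
    if min_fragment_bp < 0:
        raise ValueError("min_fragment_bp must be >= 0")
    fragments = sample.fragments if isinstance(sample, DbsSample) else sample
    cat = fragments["category"].to_numpy(dtype=object)
    length = fragments["fragment_length"].to_numpy(dtype=float)
    long_enough = length > min_fragment_bp
    n_human = int(((cat == HUMAN_SPECIFIC) & long_enough).sum())
    n_mouse = int(((cat == MOUSE_SPECIFIC) & long_enough).sum())
    denom = n_human + n_mouse
    if denom == 0:
        raise UndefinedXtfError(
            f"no species-specific fragments > {min_fragment_bp} bp; xTF undefined"
        )
    xtf = n_human / denom
    if isinstance(sample, DbsSample):
        sample.xtf = xtf
    return xtf


def xtf_counts(fragments: pd.DataFrame, min_fragment_bp: int = DEFAULT_MIN_FRAGMENT_BP) -> tuple[int, int]:
    """(n_human_specific, n_mouse_specific) above the length threshold."""
    cat = fragments["category"].to_numpy(dtype=object)
    length = fragments["fragment_length"].to_numpy(dtype=float)
    long_enough = length > min_fragment_bp
    return (
        int(((cat == HUMAN_SPECIFIC) & long_enough).sum()),
        int(((cat == MOUSE_SPECIFIC) & long_enough).sum()),
    )


def fragment_length_mode(
    fragments: pd.DataFrame, category: str
) -> tuple[int, pd.DataFrame]:
    """Modal fragment length of one category, with the 1 bp histogram.

    The mode is the smallest length attaining the maximum count. Returns
    ``(mode, histogram)`` where the histogram covers the observed range with
    columns ``length, count``.
    """
    lengths = fragments.loc[fragments["category"] == category, "fragment_length"]
    lengths = lengths.dropna().astype(int)
    if lengths.empty:
        raise EmptyDistributionError(f"no fragments of category {category!r}")
    lo, hi = int(lengths.min()), int(lengths.max())
    counts = np.bincount(lengths.to_numpy() - lo, minlength=hi - lo + 1)
    mode = lo + int(np.argmax(counts))  # argmax returns the first (smallest) maximiser
    hist = pd.DataFrame({"length": np.arange(lo, hi + 1), "count": counts})
    return mode, hist


def normalize_to_baseline(series: XtfSeries, baseline_day: int = 1) -> XtfSeries:
    """Divide each point by the baseline-day xTF (day 1 by default).

    Raises :class:`NormalisationError` when the baseline point is missing or
    zero; callers exclude such mice from downstream slope fits.
    """
    baseline = dict(series.points).get(baseline_day)
    if baseline is None:
        raise NormalisationError(f"mouse {series.mouse_id}: no day-{baseline_day} baseline point")
    if baseline == 0:
        raise NormalisationError(f"mouse {series.mouse_id}: baseline xTF is zero")
    series.normalised = [(day, x / baseline) for day, x in series.points]
    return series


def xtf_change_rate(points: pd.DataFrame, value_column: str = "xtf") -> SlopeFit:
    """Pooled OLS slope of (normalised) xTF on day across all mice of a group.

    ``points`` needs columns ``mouse_id, day`` and the value column. All
    mouse-timepoints are pooled into a single ordinary least-squares fit,
    not averaged per mouse.
    """
    days = points["day"].to_numpy(dtype=float)
    values = points[value_column].to_numpy(dtype=float)
    if len(np.unique(days)) < 2:
        raise RankError("need >= 2 distinct days to fit an xTF slope")
    import statsmodels.api as sm

    design = sm.add_constant(days)
    fit = sm.OLS(values, design).fit()
    return SlopeFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        stderr=float(fit.bse[1]),
        n_points=len(points),
        n_mice=int(points["mouse_id"].nunique()),
    )
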