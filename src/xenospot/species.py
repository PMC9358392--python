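"""Species assignment of sequenced fragments in xenograft samples.

Each fragment from a dried-blood-spot library is aligned independently to a
human and a mouse reference. A fragment is *human-specific* when its best
human alignment strictly beats both its best mouse alignment (or mouse is
unmapped) and its own next-best human alignment (or there is none);
*mouse-specific* symmetrically. Cross-genome ties and within-genome
multi-mapping ties are *unresolved*; fragments mapping to neither genome are
*unmapped*. Only species-specific fragments flow into the xenograft tumour
fraction and copy-number analyses.

Fragments are counted once per template (read pair), never per mate: a
fragment is a molecule, and the tumour fraction is a molecule fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import pysam

from .errors import FormatError, MalformedRecordError

__all__ = [
    "CATEGORIES",
    "HUMAN_SPECIFIC",
    "MOUSE_SPECIFIC",
    "UNRESOLVED",
    "UNMAPPED",
    "AlignedReadPair",
    "classify_fragment",
    "classify_frame",
    "classify_sam_pair_stream",
    "fragment_records_from_pairs",
    "PAIR_COLUMNS",
    "FRAGMENT_COLUMNS",
]

HUMAN_SPECIFIC = "human_specific"
MOUSE_SPECIFIC = "mouse_specific"
UNRESOLVED = "unresolved"
UNMAPPED = "unmapped"
CATEGORIES = (HUMAN_SPECIFIC, MOUSE_SPECIFIC, UNRESOLVED, UNMAPPED)

#: Canonical column layout of a bulk table of aligned read pairs. Absent
#: scores/loci are NaN. One row per template.
PAIR_COLUMNS = [
    "fragment_id",
    "human_best",
    "human_next",
    "mouse_best",
    "mouse_next",
    "human_chrom",
    "human_start",
    "human_end",
    "human_length",
    "mouse_chrom",
    "mouse_start",
    "mouse_end",
    "mouse_length",
    "truth_species",
]

#: Canonical column layout of a species-classified fragment table. The
#: coordinate columns refer to the assigned genome.
FRAGMENT_COLUMNS = ["fragment_id", "category", "chromosome", "start", "end", "fragment_length"]


@dataclass
class AlignedReadPair:
    """One sequenced fragment with its alignments against two genomes.

    Scores are integers (higher = better); ``None`` means no alignment /
    no annotation. Loci are ``(chromosome, start, end, fragment_length)``
    tuples in 0-based half-open convention.
    """

    fragment_id: str
    human_best: Optional[int] = None
    human_next: Optional[int] = None
    mouse_best: Optional[int] = None
    mouse_next: Optional[int] = None
    human_locus: Optional[tuple] = None
    mouse_locus: Optional[tuple] = None
    truth_species: Optional[str] = None

    def validate(self) -> None:
        for genome, best, nxt in (
            ("human", self.human_best, self.human_next),
            ("mouse", self.mouse_best, self.mouse_next),
        ):
            if nxt is not None and best is None:
                raise MalformedRecordError(
                    f"{self.fragment_id}: {genome} next-best score without a best score"
                )
            if nxt is not None and best is not None and nxt > best:
                raise MalformedRecordError(
                    f"{self.fragment_id}: {genome} next-best score {nxt} > best {best}"
                )
        for genome, locus in (("human", self.human_locus), ("mouse", self.mouse_locus)):
            if locus is not None and locus[3] <= 0:
                raise MalformedRecordError(
                    f"{self.fragment_id}: non-positive {genome} fragment length {locus[3]}"
                )


def classify_fragment(pair: AlignedReadPair) -> str:
    """Assign one of the four species categories to a read pair.

    Within-genome uniqueness requires strict best > next-best; a missing
    next-best score is treated as unique.
    """
    pair.validate()
    hb, hn = pair.human_best, pair.human_next
    mb, mn = pair.mouse_best, pair.mouse_next
    if hb is None and mb is None:
        return UNMAPPED
    human_ok = hb is not None and (mb is None or hb > mb) and (hn is None or hb > hn)
    mouse_ok = mb is not None and (hb is None or mb > hb) and (mn is None or mb > mn)
    if human_ok:
        return HUMAN_SPECIFIC
    if mouse_ok:
        return MOUSE_SPECIFIC
    return UNRESOLVED


def classify_frame(pairs: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_fragment` over a :data:`PAIR_COLUMNS` table.

    Returns a Series of category strings aligned with ``pairs.index``.
    """
    hb = pairs["human_best"].to_numpy(dtype=float)
    hn = pairs["human_next"].to_numpy(dtype=float)
    mb = pairs["mouse_best"].to_numpy(dtype=float)
    mn = pairs["mouse_next"].to_numpy(dtype=float)
    for genome, best, nxt in (("human", hb, hn), ("mouse", mb, mn)):
        bad = ~np.isnan(nxt) & (np.isnan(best) | (nxt > best))
        if bad.any():
            first = pairs["fragment_id"].iloc[int(np.flatnonzero(bad)[0])]
            raise MalformedRecordError(f"{first}: {genome} next-best score inconsistent with best")
    for genome, col in (("human", "human_length"), ("mouse", "mouse_length")):
        if col in pairs.columns:
            ln = pairs[col].to_numpy(dtype=float)
            bad = ~np.isnan(ln) & (ln <= 0)
            if bad.any():
                first = pairs["fragment_id"].iloc[int(np.flatnonzero(bad)[0])]
                raise MalformedRecordError(f"{first}: non-positive {genome} fragment length")

    human_ok = ~np.isnan(hb) & (np.isnan(mb) | (hb > mb)) & (np.isnan(hn) | (hb > hn))
    mouse_ok = ~np.isnan(mb) & (np.isnan(hb) | (mb > hb)) & (np.isnan(mn) | (mb > mn))
    out = np.full(len(pairs), UNRESOLVED, dtype=object)
    out[np.isnan(hb) & np.isnan(mb)] = UNMAPPED
    out[human_ok] = HUMAN_SPECIFIC
    out[mouse_ok & ~human_ok] = MOUSE_SPECIFIC
    return pd.Series(out, index=pairs.index, name="category")


def fragment_records_from_pairs(
    pairs: pd.DataFrame, categories: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Build a classified fragment table from an aligned-pair table.

    Coordinates and length are taken from the assigned genome; unresolved
    and unmapped fragments keep NaN coordinates. ``truth_species`` (and any
    other extra columns present) are carried through.
    """
    if categories is None:
        categories = classify_frame(pairs)
    cat = categories.to_numpy(dtype=object)
    n = len(pairs)
    out = pd.DataFrame(
        {
            "fragment_id": pairs["fragment_id"].to_numpy(),
            "category": cat,
            "chromosome": np.full(n, None, dtype=object),
            "start": np.full(n, np.nan),
            "end": np.full(n, np.nan),
            "fragment_length": np.full(n, np.nan),
        }
    )
    for species, prefix in ((HUMAN_SPECIFIC, "human"), (MOUSE_SPECIFIC, "mouse")):
        mask = cat == species
        if not mask.any():
            continue
        out.loc[mask, "chromosome"] = pairs.loc[mask, f"{prefix}_chrom"].to_numpy()
        out.loc[mask, "start"] = pairs.loc[mask, f"{prefix}_start"].to_numpy()
        out.loc[mask, "end"] = pairs.loc[mask, f"{prefix}_end"].to_numpy()
        out.loc[mask, "fragment_length"] = pairs.loc[mask, f"{prefix}_length"].to_numpy()
    if "truth_species" in pairs.columns:
        out["truth_species"] = pairs["truth_species"].to_numpy()
    if "spurious" in pairs.columns:
        out["spurious"] = pairs["spurious"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# SAM/BAM adapter


def _template_summary(name: str, records: list) -> tuple:
    """Collapse one template's primary alignments in one genome.

    Returns (best, next_best, locus) where locus is
    (chrom, start, end, fragment_length) or None.
    """
    primaries = [r for r in records if not r.is_secondary and not r.is_supplementary]
    mapped = [r for r in primaries if not r.is_unmapped]
    if not mapped:
        return None, None, None
    if len(mapped) != 2:
        raise FormatError(f"orphaned mate for template {name!r}: {len(mapped)} mapped primaries")
    r1 = next((r for r in mapped if r.is_read1), mapped[0])
    best = r1.get_tag("AS") if r1.has_tag("AS") else None
    nxt = r1.get_tag("XS") if r1.has_tag("XS") else None
    if best is None:
        raise FormatError(f"template {name!r}: mapped record lacks an alignment-score (AS) tag")
    tlen = abs(r1.template_length)
    if tlen <= 0:
        raise FormatError(f"template {name!r}: non-positive template length {r1.template_length}")
    start = min(r.reference_start for r in mapped)
    return best, nxt, (r1.reference_name, start, start + tlen, tlen)


def _iter_name_groups(path: str) -> Iterator[tuple[str, list]]:
    """Yield (template name, records) groups from a name-sorted SAM/BAM."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        current: Optional[str] = None
        bucket: list = []
        last: Optional[str] = None
        for rec in fh:
            name = rec.query_name
            if name != current:
                if current is not None:
                    yield current, bucket
                if last is not None and name < last:
                    raise FormatError(
                        f"input not name-sorted: {name!r} follows {last!r}"
                    )
                last, current, bucket = name, name, []
            bucket.append(rec)
        if current is not None:
            yield current, bucket


def classify_sam_pair_stream(human_path: str, mouse_path: str) -> pd.DataFrame:
    """Merge two name-sorted per-genome SAM/BAM streams into classified pairs.

    One row per template, :data:`PAIR_COLUMNS` plus ``category``. A template
    present in only one stream is treated as unmapped in the other genome.
    """
    rows: list[dict] = []

    def _row(name: str, human: tuple, mouse: tuple) -> dict:
        hb, hn, hloc = human
        mb, mn, mloc = mouse
        return {
            "fragment_id": name,
            "human_best": hb,
            "human_next": hn,
            "mouse_best": mb,
            "mouse_next": mn,
            "human_chrom": hloc[0] if hloc else None,
            "human_start": hloc[1] if hloc else np.nan,
            "human_end": hloc[2] if hloc else np.nan,
            "human_length": hloc[3] if hloc else np.nan,
            "mouse_chrom": mloc[0] if mloc else None,
            "mouse_start": mloc[1] if mloc else np.nan,
            "mouse_end": mloc[2] if mloc else np.nan,
            "mouse_length": mloc[3] if mloc else np.nan,
            "truth_species": None,
        }

    absent = (None, None, None)
    hiter = _iter_name_groups(human_path)
    miter = _iter_name_groups(mouse_path)
    h = next(hiter, None)
    m = next(miter, None)
    while h is not None or m is not None:
        if m is None or (h is not None and h[0] < m[0]):
            rows.append(_row(h[0], _template_summary(*h), absent))
            h = next(hiter, None)
        elif h is None or m[0] < h[0]:
            rows.append(_row(m[0], absent, _template_summary(*m)))
            m = next(miter, None)
        else:
            rows.append(_row(h[0], _template_summary(*h), _template_summary(*m)))
            h = next(hiter, None)
            m = next(miter, None)

    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    pairs["category"] = classify_frame(pairs)
    return pairs
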