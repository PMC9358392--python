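"""Synthetic data generation for the whole pipeline.

Nothing in the package requires real sequencing data: this module emulates
the statistical structure of dried-blood-spot shallow WGS in xenograft mice
at desk scale —

* fragment-length mixtures with a ctDNA mode at 146 bp and a cfDNA mode at
  166 bp, plus a sub-50 bp spurious cross-genome alignment class;
* read depth across genomic bins driven by an integer copy-number profile
  with optional multiplicative GC bias;
* per-mouse tumour growth trajectories that are piecewise-linear on the
  cube-root scale with random intercepts and arm-specific residual noise;
* xTF time series coupled to tumour burden.

Every generator takes an explicit seed, is byte-reproducible, and returns a
manifest embedding its generating parameters; recovery tests read truth
only from the manifest.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenomeLayout, HUMAN_TOY, MOUSE_TOY

__all__ = [
    "FragmentModel",
    "CohortDesign",
    "simulate_fragments",
    "simulate_fragment_pool",
    "simulate_cohort",
    "simulate_study",
    "simulate_bin_annotation",
    "flat_cn_profile",
    "make_cn_profile",
]


@dataclass(frozen=True)
class FragmentModel:
    """Fragment-length and alignment-score model for synthetic DBS reads.

    Lengths are drawn from discretised asymmetric-Laplace pmfs peaked
    exactly at the configured modes (146 bp for tumour-derived ctDNA,
    166 bp for host cfDNA), with a shorter left tail and a longer right
    tail. ``spurious_rate`` is the per-fragment probability that a
    mouse-origin molecule emits a short, low-scoring human alignment while
    failing to align to mouse — the false-positive channel observed in
    healthy control mice, whose lengths fall mostly below
    ``spurious_length_cap``.
    """

    ctdna_mode: int = 146
    cfdna_mode: int = 166
    spread: float = 25.0  # right-tail decay scale, bp; left tail is 0.4x
    spurious_rate: float = 5e-4
    spurious_length_cap: int = 50
    score_base: int = 60
    min_score_gap: int = 5  # cross-genome score gap floor for genuine reads

    def __post_init__(self) -> None:
        if self.ctdna_mode <= 30 or self.cfdna_mode <= 30:
            raise ValueError("fragment modes must exceed 30 bp")
        if not 0.0 <= self.spurious_rate <= 1.0:
            raise ValueError("spurious_rate must be in [0, 1]")


def _length_pmf(mode: int, spread: float, lo: int = 31, hi: int = 500):
    """Discretised unimodal pmf with its argmax at ``mode``.

    A narrow core (the sharp nucleosomal peak) over asymmetric exponential
    shoulders — short left tail, longer right tail. The core keeps the
    empirical mode pinned to the configured peak at moderate sample sizes.
    """
    support = np.arange(lo, hi + 1)
    dist = support - mode
    left, right = 0.4 * spread, spread
    shoulders = np.where(dist < 0, np.exp(dist / left), np.exp(-dist / right))
    shoulders /= shoulders.sum()
    core = np.exp(-np.abs(dist) / 3.0)
    core /= core.sum()
    p = 0.3 * core + 0.7 * shoulders
    return support, p / p.sum()


def flat_cn_profile(
    layout: GenomeLayout = HUMAN_TOY, bin_width: int = 30_000, copies: int = 2
) -> pd.DataFrame:
    """A constant integer copy-number profile over a binned layout."""
    bins = layout.bins(bin_width)
    bins["copies"] = copies
    return bins


def make_cn_profile(segments: list[tuple[str, int, int, int]], bin_width: int = 30_000,
                    layout: GenomeLayout = HUMAN_TOY) -> pd.DataFrame:
    """Build a binned integer profile from (chrom, start, end, copies) segments.

    Bins not covered by any segment keep 2 copies.
    """
    bins = flat_cn_profile(layout, bin_width)
    mid = (bins["start"] + bins["end"]) / 2
    for chrom, start, end, copies in segments:
        mask = (bins["chromosome"] == chrom) & (mid >= start) & (mid < end)
        bins.loc[mask, "copies"] = copies
    return bins


def simulate_bin_annotation(
    layout: GenomeLayout = HUMAN_TOY, bin_width: int = 30_000, seed: int = 0
) -> pd.DataFrame:
    """GC fraction and mappability per bin, smooth along each chromosome."""
    rng = np.random.default_rng(seed)
    bins = layout.bins(bin_width)
    gc = np.empty(len(bins))
    mappability = np.empty(len(bins))
    for _, idx in bins.groupby("chromosome", sort=False).indices.items():
        k = len(idx)
        x = np.linspace(0, 6 * math.pi, k)
        gc[idx] = 0.45 + 0.08 * np.sin(x + rng.uniform(0, 2 * math.pi)) + rng.normal(0, 0.01, k)
        mappability[idx] = np.clip(0.95 - 0.1 * rng.random(k) ** 3 + rng.normal(0, 0.01, k), 0, 1)
    bins["gc"] = np.clip(gc, 0.2, 0.75)
    bins["mappability"] = mappability
    return bins


def _uniform_positions(rng, layout: GenomeLayout, lengths: np.ndarray):
    """Uniform fragment placement across a layout, fragments fully inside."""
    chrom_names = list(layout.chromosomes)
    chrom_lens = np.array([layout.chromosomes[c] for c in chrom_names], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    which = rng.choice(len(chrom_names), size=len(lengths), p=probs)
    max_start = chrom_lens[which] - lengths
    starts = np.floor(rng.random(len(lengths)) * np.maximum(max_start, 1)).astype(np.int64)
    chroms = np.array(chrom_names, dtype=object)[which]
    return chroms, starts, starts + lengths.astype(np.int64)


def _profile_positions(rng, cn_profile: pd.DataFrame, lengths: np.ndarray,
                       gc_bias=None):
    """Fragment placement proportional to copy number (x optional GC bias)."""
    widths = (cn_profile["end"] - cn_profile["start"]).to_numpy(dtype=float)
    weights = cn_profile["copies"].to_numpy(dtype=float) * widths
    if gc_bias is not None:
        if "gc" not in cn_profile.columns:
            raise ValueError("gc_bias requested but cn_profile has no 'gc' column")
        weights = weights * np.asarray(gc_bias(cn_profile["gc"].to_numpy(dtype=float)))
    probs = weights / weights.sum()
    which = rng.choice(len(cn_profile), size=len(lengths), p=probs)
    bin_start = cn_profile["start"].to_numpy()[which]
    bin_end = cn_profile["end"].to_numpy()[which]
    starts = bin_start + np.floor(rng.random(len(lengths)) * (bin_end - bin_start)).astype(np.int64)
    # keep fragments inside the chromosome at the trailing bin
    starts = np.minimum(starts, np.maximum(bin_end - lengths.astype(np.int64), 0))
    chroms = cn_profile["chromosome"].to_numpy(dtype=object)[which]
    return chroms, starts, starts + lengths.astype(np.int64)


def simulate_fragments(
    n: int,
    true_xtf: float,
    cn_profile: Optional[pd.DataFrame] = None,
    model: Optional[FragmentModel] = None,
    seed: int = 0,
    gc_bias=None,
    human_layout: GenomeLayout = HUMAN_TOY,
    mouse_layout: GenomeLayout = MOUSE_TOY,
) -> tuple[pd.DataFrame, dict]:
    """Simulate aligned read pairs with truth labels for one DBS sample.

    Species truth is Bernoulli(``true_xtf``). Human fragments are placed
    proportional to ``cn_profile`` (flat diploid toy genome by default) and
    draw ctDNA-model lengths; mouse fragments are uniform on the mouse toy
    genome with cfDNA-model lengths. Genuine alignments carry a cross-genome
    score gap >= ``model.min_score_gap`` and a unique within-genome best, so
    an error-free classifier recovers truth exactly; the spurious channel
    emits short human-only alignments from mouse molecules.

    Returns ``(pairs, manifest)`` where ``pairs`` follows
    :data:`xenospot.species.PAIR_COLUMNS` plus a ``spurious`` flag.
    """
    if not 0.0 <= true_xtf <= 1.0:
        raise ValueError(f"true_xtf must be in [0, 1], got {true_xtf}")
    if n <= 0:
        raise ValueError("n must be positive")
    model = model or FragmentModel()
    if cn_profile is None:
        cn_profile = flat_cn_profile(human_layout)
    rng = np.random.default_rng(seed)

    is_human = rng.random(n) < true_xtf
    n_h = int(is_human.sum())
    n_m = n - n_h

    human_best = np.full(n, np.nan)
    human_next = np.full(n, np.nan)
    mouse_best = np.full(n, np.nan)
    mouse_next = np.full(n, np.nan)
    chrom_h = np.full(n, None, dtype=object)
    start_h = np.full(n, np.nan)
    end_h = np.full(n, np.nan)
    len_h = np.full(n, np.nan)
    chrom_m = np.full(n, None, dtype=object)
    start_m = np.full(n, np.nan)
    end_m = np.full(n, np.nan)
    len_m = np.full(n, np.nan)
    spurious = np.zeros(n, dtype=bool)

    ct_support, ct_p = _length_pmf(model.ctdna_mode, model.spread)
    cf_support, cf_p = _length_pmf(model.cfdna_mode, model.spread)

    def genuine_scores(count):
        best = model.score_base + rng.integers(-3, 4, size=count)
        gap = rng.integers(model.min_score_gap, 31, size=count)
        other = np.where(rng.random(count) < 0.5, best - gap, np.nan)
        nxt = np.where(rng.random(count) < 0.3, best - rng.integers(5, 21, size=count), np.nan)
        return best.astype(float), nxt, other

    if n_h:
        hidx = np.flatnonzero(is_human)
        lengths = rng.choice(ct_support, size=n_h, p=ct_p)
        chroms, starts, ends = _profile_positions(rng, cn_profile, lengths, gc_bias)
        best, nxt, other = genuine_scores(n_h)
        human_best[hidx], human_next[hidx], mouse_best[hidx] = best, nxt, other
        chrom_h[hidx], start_h[hidx], end_h[hidx], len_h[hidx] = chroms, starts, ends, lengths

    if n_m:
        midx = np.flatnonzero(~is_human)
        spur = rng.random(n_m) < model.spurious_rate
        gen = midx[~spur]
        if len(gen):
            lengths = rng.choice(cf_support, size=len(gen), p=cf_p)
            chroms, starts, ends = _uniform_positions(rng, mouse_layout, lengths)
            best, nxt, other = genuine_scores(len(gen))
            mouse_best[gen], mouse_next[gen], human_best[gen] = best, nxt, other
            chrom_m[gen], start_m[gen], end_m[gen], len_m[gen] = chroms, starts, ends, lengths
        sp = midx[spur]
        if len(sp):
            spurious[sp] = True
            # mostly sub-cap lengths; a minority draw from the ctDNA curve
            short = rng.random(len(sp)) < 0.85
            lengths = np.where(
                short,
                rng.integers(20, model.spurious_length_cap, size=len(sp)),
                rng.choice(ct_support, size=len(sp), p=ct_p),
            )
            chroms, starts, ends = _uniform_positions(rng, human_layout, lengths)
            human_best[sp] = (25 + rng.integers(0, 11, size=len(sp))).astype(float)
            chrom_h[sp], start_h[sp], end_h[sp], len_h[sp] = chroms, starts, ends, lengths

    pairs = pd.DataFrame(
        {
            "fragment_id": np.char.add("frag", np.arange(n).astype(str)),
            "human_best": human_best,
            "human_next": human_next,
            "mouse_best": mouse_best,
            "mouse_next": mouse_next,
            "human_chrom": chrom_h,
            "human_start": start_h,
            "human_end": end_h,
            "human_length": len_h,
            "mouse_chrom": chrom_m,
            "mouse_start": start_m,
            "mouse_end": end_m,
            "mouse_length": len_m,
            "truth_species": np.where(is_human, "human", "mouse"),
            "spurious": spurious,
        }
    )
    manifest = {
        "generator": "simulate_fragments",
        "n": n,
        "true_xtf": true_xtf,
        "seed": seed,
        "model": asdict(model),
        "gc_bias": gc_bias is not None,
    }
    return pairs, manifest


def simulate_fragment_pool(
    n: int,
    species: str,
    model: Optional[FragmentModel] = None,
    seed: int = 0,
    cn_profile: Optional[pd.DataFrame] = None,
    layout: Optional[GenomeLayout] = None,
) -> pd.DataFrame:
    """A pool of error-free classified fragments of one species.

    Lightweight counterpart of :func:`simulate_fragments` used for dilution
    pools: emits a classified fragment table directly (category equals
    truth), skipping alignment scores.
    """
    if species not in ("human", "mouse"):
        raise ValueError("species must be 'human' or 'mouse'")
    model = model or FragmentModel()
    rng = np.random.default_rng(seed)
    if species == "human":
        support, p = _length_pmf(model.ctdna_mode, model.spread)
        lengths = rng.choice(support, size=n, p=p)
        profile = cn_profile if cn_profile is not None else flat_cn_profile(layout or HUMAN_TOY)
        chroms, starts, ends = _profile_positions(rng, profile, lengths)
        category = "human_specific"
    else:
        support, p = _length_pmf(model.cfdna_mode, model.spread)
        lengths = rng.choice(support, size=n, p=p)
        chroms, starts, ends = _uniform_positions(rng, layout or MOUSE_TOY, lengths)
        category = "mouse_specific"
    return pd.DataFrame(
        {
            "fragment_id": np.char.add(f"{species}", np.arange(n).astype(str)),
            "category": category,
            "chromosome": chroms,
            "start": starts,
            "end": ends,
            "fragment_length": lengths.astype(np.int64),
        }
    )


# ---------------------------------------------------------------------------
# Growth cohorts


@dataclass(frozen=True)
class CohortDesign:
    """Generating parameters for one patient line's treated/control cohort.

    Tumour volumes follow a continuous piecewise-linear mean on the
    cube-root scale: treated mice grow at ``beta1`` mm/day^(1/3) until
    ``t1`` (onset of treatment effect), shrink at ``beta2`` on [t1, t2),
    and regrow at ``beta3`` from ``t2``; controls grow at ``beta_control``
    throughout. Each mouse adds a Normal(0, tau^2) random intercept and
    arm-specific iid residual noise. Defaults mirror a carboplatin-style
    response experiment: treatment starts at ~500 mm^3 (alpha = 500^(1/3)),
    weekly callipering for nine weeks, blood spots on days 1/16/29.

    xTF at sampling days is the baseline xTF scaled by relative latent
    tumour volume (power ``coupling``) with multiplicative log-normal
    noise, truncated to [0, 1].
    """

    n_mice: int = 5
    # weekly callipering from engraftment (negative days) to study end;
    # day 1 is the first dose
    measurement_days: tuple[int, ...] = (-20, -13, -6, 1, 8, 15, 22, 29, 36, 43, 50, 57, 64)
    sampling_days: tuple[int, ...] = (1, 16, 29)
    alpha: float = 7.937  # cbrt(500 mm^3)
    beta1: float = 0.12
    beta2: float = -0.08
    beta3: float = 0.12
    beta_control: float = 0.12
    tau: float = 0.3
    sigma_treated: float = 0.3
    sigma_control: float = 0.15
    t1: float = 8.0
    t2: float = 29.0
    baseline_xtf: float = 0.05
    coupling: float = 1.0
    xtf_noise_sd: float = 0.1
    patient_line: str = "lineA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t1 >= self.t2:
            raise ValueError("need t1 < t2")
        for name in ("tau", "sigma_treated", "sigma_control", "xtf_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def piecewise_mean(days, alpha, beta1, beta2, beta3, t1, t2):
    """Treated-arm fixed-effect mean on the cube-root scale."""
    t = np.asarray(days, dtype=float)
    return (
        alpha
        + beta1 * t
        + (beta2 - beta1) * np.clip(t - t1, 0, None)
        + (beta3 - beta2) * np.clip(t - t2, 0, None)
    )


def _dims_from_volume(volume: np.ndarray) -> np.ndarray:
    # equal h = w = d such that pi/6 h w d reproduces the volume
    return np.cbrt(6.0 * np.asarray(volume) / math.pi)


def simulate_cohort(design: CohortDesign) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate calliper measurements and xTF samples for one patient line.

    Returns ``(measurements, xtf_samples, manifest)``. Measurements carry
    ``mouse_id, patient_line, arm, day, h, w, d, volume``; xTF samples carry
    ``sample_id, mouse_id, patient_line, arm, day, xtf``.
    """
    rng = np.random.default_rng(design.seed)
    d = design
    meas_rows, xtf_rows = [], []
    days = np.asarray(d.measurement_days, dtype=float)
    sdays = np.asarray(d.sampling_days, dtype=float)
    baseline_day = float(sdays.min())
    for arm, sigma in (("treated", d.sigma_treated), ("control", d.sigma_control)):
        for i in range(d.n_mice):
            mouse_id = f"{d.patient_line}_{arm}_{i + 1}"
            b = rng.normal(0.0, d.tau) if d.tau > 0 else 0.0
            if arm == "treated":
                mean = piecewise_mean(days, d.alpha, d.beta1, d.beta2, d.beta3, d.t1, d.t2)
                latent_s = piecewise_mean(sdays, d.alpha, d.beta1, d.beta2, d.beta3, d.t1, d.t2) + b
            else:
                mean = d.alpha + d.beta_control * days
                latent_s = d.alpha + d.beta_control * sdays + b
            y = mean + b + (rng.normal(0.0, sigma, size=len(days)) if sigma > 0 else 0.0)
            volume = np.clip(y, 0.0, None) ** 3
            dims = _dims_from_volume(volume)
            for day, v, dim in zip(days, volume, dims):
                meas_rows.append((mouse_id, d.patient_line, arm, int(day), dim, dim, dim, v))
            latent_volume = np.clip(latent_s, 0.0, None) ** 3
            base_v = latent_volume[sdays == baseline_day][0]
            noise = (
                np.exp(rng.normal(0.0, d.xtf_noise_sd, size=len(sdays)))
                if d.xtf_noise_sd > 0
                else np.ones(len(sdays))
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(base_v > 0, latent_volume / base_v, 0.0)
            xtf = np.clip(d.baseline_xtf * rel ** d.coupling * noise, 0.0, 1.0)
            for day, x in zip(sdays, xtf):
                xtf_rows.append((f"{mouse_id}_d{int(day)}", mouse_id, d.patient_line, arm, int(day), x))
    measurements = pd.DataFrame(
        meas_rows, columns=["mouse_id", "patient_line", "arm", "day", "h", "w", "d", "volume"]
    )
    xtf_samples = pd.DataFrame(
        xtf_rows, columns=["sample_id", "mouse_id", "patient_line", "arm", "day", "xtf"]
    )
    manifest = {"generator": "simulate_cohort", **asdict(d)}
    return measurements, xtf_samples, manifest


def simulate_study(designs: list[CohortDesign]) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Concatenate cohorts of several patient lines into one study."""
    meas, xtfs, manifests = [], [], []
    for design in designs:
        m, x, man = simulate_cohort(design)
        meas.append(m)
        xtfs.append(x)
        manifests.append(man)
    return (
        pd.concat(meas, ignore_index=True),
        pd.concat(xtfs, ignore_index=True),
        {"generator": "simulate_study", "lines": manifests},
    )
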