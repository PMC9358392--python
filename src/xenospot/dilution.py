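"""In-silico dilution series for xTF linearity and sensitivity testing.

Mirrors the computational mixing experiment used to validate the xTF
metric: human-patient fragment pools are downsampled and merged into a
mouse background at seven target proportions (1, 2, 5, 7, 10, 15, 25%),
five human pools (biological replicates) per proportion, 6.5 million
fragments per constructed sample. Measured xTFs are then compared with the
expected mixture fractions by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GridError, InsufficientPoolError
from .xtf import DbsSample, compute_xtf

__all__ = [
    "DEFAULT_FRACTIONS",
    "DilutionDesign",
    "build_dilution_series",
    "iter_dilution_series",
    "evaluate_linearity",
    "run_dilution_experiment",
]

DEFAULT_FRACTIONS = (0.01, 0.02, 0.05, 0.07, 0.10, 0.15, 0.25)


@dataclass(frozen=True)
class DilutionDesign:
    """Target human proportions, per-sample total and seed for the series."""

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    total_fragments: int = 6_500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_fragments <= 0:
            raise ValueError("total_fragments must be positive")
        for f in self.fractions:
            if not 0.0 < f < 1.0:
                raise ValueError(f"dilution fraction must be in (0, 1), got {f}")

    def human_count(self, fraction: float) -> int:
        """Fragments drawn from the human pool at one dilution point."""
        return int(round(fraction * self.total_fragments))


def _check_pools(human_pools, mouse_pool, design) -> None:
    max_h = max(design.human_count(f) for f in design.fractions)
    for i, pool in enumerate(human_pools):
        if len(pool) < max_h:
            raise InsufficientPoolError(
                f"human pool {i} has {len(pool)} fragments, needs >= {max_h} "
                f"(short by {max_h - len(pool)})"
            )
    if len(mouse_pool) < design.total_fragments:
        raise InsufficientPoolError(
            f"mouse pool has {len(mouse_pool)} fragments, needs >= {design.total_fragments} "
            f"(short by {design.total_fragments - len(mouse_pool)})"
        )


def iter_dilution_series(
    human_pools: Sequence[pd.DataFrame],
    mouse_pool: pd.DataFrame,
    design: DilutionDesign,
) -> Iterator[DbsSample]:
    """Yield constructed dilution samples one at a time (memory-friendly).

    For each (fraction, human pool) cell the sample holds
    ``round(f * total)`` human fragments and the exact complement of mouse
    fragments, drawn without replacement within each pool via the seeded
    generator; pools are reused across samples.
    """
    _check_pools(human_pools, mouse_pool, design)
    rng = np.random.default_rng(design.seed)
    for fraction in design.fractions:
        n_human = design.human_count(fraction)
        n_mouse = design.total_fragments - n_human
        for rep, pool in enumerate(human_pools, start=1):
            h_idx = rng.choice(len(pool), size=n_human, replace=False)
            m_idx = rng.choice(len(mouse_pool), size=n_mouse, replace=False)
            fragments = pd.concat(
                [pool.iloc[h_idx], mouse_pool.iloc[m_idx]], ignore_index=True
            )
            yield DbsSample(
                sample_id=f"dil_f{fraction:g}_rep{rep}",
                arm="dilution",
                fragments=fragments,
                expected_fraction=fraction,
            )


def build_dilution_series(
    human_pools: Sequence[pd.DataFrame],
    mouse_pool: pd.DataFrame,
    design: DilutionDesign,
) -> list[DbsSample]:
    """Materialise the full dilution series as a list of samples."""
    return list(iter_dilution_series(human_pools, mouse_pool, design))


def evaluate_linearity(
    expected: Sequence[float], measured: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between expected fractions and measured xTFs.

    Ties are handled by midranks. A constant measured series has undefined
    correlation and returns ``(nan, nan)``.
    """
    expected = np.asarray(expected, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if len(expected) < 3:
        raise GridError("need >= 3 samples to evaluate linearity")
    if len(np.unique(expected)) < 2:
        raise GridError("need >= 2 distinct expected fractions")
    if len(np.unique(measured)) < 2:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(expected, measured)
    return float(rho), float(p)


def run_dilution_experiment(
    human_pools: Sequence[pd.DataFrame],
    mouse_pool: pd.DataFrame,
    design: Optional[DilutionDesign] = None,
    min_fragment_bp: int = 30,
) -> dict:
    """Build the series, measure each sample's xTF, and report linearity.

    Returns a dict with a per-sample table (``sample_id, expected_fraction,
    xtf, n_fragments``) and the Spearman rho/p of expected vs measured.
    """
    design = design or DilutionDesign()
    rows = []
    for sample in iter_dilution_series(human_pools, mouse_pool, design):
        xtf = compute_xtf(sample, min_fragment_bp=min_fragment_bp)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "expected_fraction": sample.expected_fraction,
                "xtf": xtf,
                "n_fragments": len(sample.fragments),
            }
        )
    table = pd.DataFrame(rows)
    rho, p = evaluate_linearity(table["expected_fraction"], table["xtf"])
    return {"samples": table, "spearman_rho": rho, "spearman_p": p}
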