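"""End-to-end study orchestration: classify -> xTF -> CNA -> growth.

:func:`run_study` drives the whole pipeline from a single
:class:`StudyConfig`, producing per-sample xTF values, baseline-normalised
trajectories and group slopes, absolute copy-number fits and driver calls
for eligible samples, growth-kinetics fits with inflection points, and the
outcome correlations — written as TSV/JSON with provenance (tool version,
config hash, seed) stamped on every table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cna import acn_pipeline, call_driver_cna
from .errors import ConfigError, FitError, NormalisationError, RankError, UndefinedXtfError
from .genome import GenomeLayout
from .growth import (
    compare_growth_rates,
    correlate_outcome,
    estimate_inflection_points,
    time_to_endpoint,
)
from .io import config_hash, read_table, write_json, write_table
from .species import HUMAN_SPECIFIC
from .xtf import (
    XtfSeries,
    compute_xtf,
    filter_blacklist,
    normalize_to_baseline,
    read_bed,
    xtf_change_rate,
    xtf_counts,
)

logger = logging.getLogger("xenospot")

__all__ = ["StudyConfig", "run_study"]


@dataclass
class StudyConfig:
    """Paths and thresholds driving one study run."""

    sample_sheet: str
    out_dir: str
    measurements: Optional[str] = None
    blacklist_human: Optional[str] = None
    blacklist_mouse: Optional[str] = None
    bin_annotation: Optional[str] = None
    gene_regions: Optional[str] = None
    bin_width: int = 30_000
    min_fragment_bp: int = 30
    min_acn_fragments: int = 500_000
    guide_ploidy: Optional[float] = None
    baseline_day: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.min_fragment_bp < 0 or self.min_acn_fragments <= 0:
            raise ConfigError("thresholds must be positive")
        for name in ("sample_sheet", "measurements", "blacklist_human",
                     "blacklist_mouse", "bin_annotation", "gene_regions"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"config field {name!r}: no such file {path}")


def _layout_from_annotation(annotation: pd.DataFrame) -> GenomeLayout:
    lengths = annotation.groupby("chromosome", sort=False)["end"].max().to_dict()
    return GenomeLayout("from_annotation", {k: int(v) for k, v in lengths.items()})


def run_study(config: StudyConfig) -> dict:
    """Execute every eligible pipeline stage and write the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    provenance = {
        "tool_version": __version__,
        "config_hash": config_hash(hashed),
        "seed": config.seed,
    }
    sheet = read_table(config.sample_sheet)
    required = {"sample_id", "mouse_id", "patient_line", "arm", "day", "fragments"}
    missing = required - set(sheet.columns)
    if missing:
        raise ConfigError(f"sample sheet lacks columns: {sorted(missing)}")
    for i, row in sheet.iterrows():
        if not Path(row["fragments"]).exists():
            raise ConfigError(f"sample sheet row {i} ({row['sample_id']}): "
                              f"no such fragment file {row['fragments']}")

    human_bl = read_bed(config.blacklist_human) if config.blacklist_human else None
    mouse_bl = read_bed(config.blacklist_mouse) if config.blacklist_mouse else None
    annotation = read_table(config.bin_annotation) if config.bin_annotation else None
    genes = read_table(config.gene_regions) if config.gene_regions else None
    layout = _layout_from_annotation(annotation) if annotation is not None else None

    # --- per-sample xTF -----------------------------------------------------
    xtf_rows, acn_rows, driver_frames = [], [], []
    for _, row in sheet.iterrows():
        logger.info("sample %s: computing xTF", row["sample_id"])
        fragments = read_table(row["fragments"])
        fragments = filter_blacklist(fragments, human_bl, mouse_bl)
        n_human, n_mouse = xtf_counts(fragments, config.min_fragment_bp)
        try:
            xtf = compute_xtf(fragments, config.min_fragment_bp)
        except UndefinedXtfError:
            xtf = np.nan
        xtf_rows.append(
            {
                "sample_id": row["sample_id"],
                "mouse_id": row["mouse_id"],
                "patient_line": row["patient_line"],
                "arm": row["arm"],
                "day": row["day"],
                "n_human": n_human,
                "n_mouse": n_mouse,
                "xtf": xtf,
            }
        )
        if annotation is not None:
            n_hs = int((fragments["category"] == HUMAN_SPECIFIC).sum())
            if n_hs >= config.min_acn_fragments:
                logger.info("sample %s: fitting absolute copy number", row["sample_id"])
                fit = acn_pipeline(
                    fragments,
                    annotation,
                    layout,
                    bin_width=config.bin_width,
                    guide_ploidy=config.guide_ploidy,
                    min_fragments=config.min_acn_fragments,
                )
                acn_rows.append(
                    {
                        "sample_id": row["sample_id"],
                        "ploidy": fit.ploidy,
                        "cellularity": fit.cellularity,
                        "goodness": fit.goodness,
                        "n_segments": len(fit.segments),
                    }
                )
                if genes is not None:
                    calls = call_driver_cna(fit, genes)
                    calls.insert(0, "sample_id", row["sample_id"])
                    driver_frames.append(calls)

    xtf_table = pd.DataFrame(xtf_rows)
    write_table(xtf_table, out / "xtf.tsv", provenance)

    # --- baseline normalisation + group slopes ------------------------------
    norm_rows, excluded = [], []
    for mouse_id, grp in xtf_table.groupby("mouse_id"):
        series = XtfSeries(mouse_id, list(zip(grp["day"], grp["xtf"])))
        try:
            normalize_to_baseline(series, config.baseline_day)
        except NormalisationError as exc:
            excluded.append({"mouse_id": mouse_id, "reason": str(exc)})
            continue
        for day, value in series.normalised:
            norm_rows.append(
                {
                    "mouse_id": mouse_id,
                    "patient_line": grp["patient_line"].iloc[0],
                    "arm": grp["arm"].iloc[0],
                    "day": day,
                    "xtf_normalised": value,
                }
            )
    norm_table = pd.DataFrame(norm_rows)
    slope_rows = []
    if not norm_table.empty:
        for (line, arm), grp in norm_table.groupby(["patient_line", "arm"]):
            try:
                fit = xtf_change_rate(grp, "xtf_normalised")
            except RankError:
                continue
            slope_rows.append(
                {
                    "patient_line": line,
                    "arm": arm,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "stderr": fit.stderr,
                    "n_points": fit.n_points,
                    "n_mice": fit.n_mice,
                }
            )
    slopes = pd.DataFrame(slope_rows)
    write_table(norm_table, out / "xtf_normalised.tsv", provenance)
    write_table(slopes, out / "xtf_slopes.tsv", provenance)
    if acn_rows:
        write_table(pd.DataFrame(acn_rows), out / "acn_fits.tsv", provenance)
    if driver_frames:
        write_table(pd.concat(driver_frames, ignore_index=True), out / "driver_calls.tsv", provenance)

    # --- growth kinetics ----------------------------------------------------
    growth_summary: dict = {}
    outcome = None
    if config.measurements:
        measurements = read_table(config.measurements)
        group_rows = []
        for line, grp in measurements.groupby("patient_line"):
            logger.info("line %s: fitting growth kinetics", line)
            try:
                result = estimate_inflection_points(grp)
            except (FitError, RankError) as exc:
                growth_summary[str(line)] = {"error": str(exc)}
                continue
            tests = compare_growth_rates(
                result.fit, ("pre_vs_regrowth", "treated_vs_control_baseline")
            )
            growth_summary[str(line)] = {
                "t1": result.t1,
                "t2": result.t2,
                "identifiable": result.identifiable,
                "beta1": result.fit.beta1,
                "beta2": result.fit.beta2,
                "beta3": result.fit.beta3,
                "beta_control": result.fit.beta_control,
                "tau2": result.fit.tau2,
                "sigma2_treated": result.fit.sigma2_treated,
                "sigma2_control": result.fit.sigma2_control,
                "tests": tests.to_dict(orient="records"),
            }
            endpoints = time_to_endpoint(grp)
            merged = endpoints.merge(
                grp[["mouse_id", "arm"]].drop_duplicates(), on="mouse_id"
            )
            for arm, arm_grp in merged.groupby("arm"):
                slope_row = slopes.loc[
                    (slopes["patient_line"] == line) & (slopes["arm"] == arm), "slope"
                ] if not slopes.empty else pd.Series(dtype=float)
                group_rows.append(
                    {
                        "patient_line": line,
                        "arm": arm,
                        "xtf_slope": float(slope_row.iloc[0]) if len(slope_row) else np.nan,
                        "t2": result.t2 if arm == "treated" else np.nan,
                        "time_to_endpoint": float(arm_grp["day"].mean()),
                    }
                )
        if group_rows:
            summary = pd.DataFrame(group_rows)
            write_table(summary, out / "outcome_groups.tsv", provenance)
            outcome = {
                key: {"r": r, "p": p}
                for key, (r, p) in correlate_outcome(summary).items()
            }

    report = {
        "n_samples": len(xtf_table),
        "excluded_mice": excluded,
        "growth": growth_summary,
        "outcome_correlations": outcome,
        "acn_fitted_samples": len(acn_rows),
    }
    write_json(report, out / "report.json", provenance)
    with open(out / "report.txt", "w") as fh:
        fh.write(f"xenospot {__version__} study report (config {provenance['config_hash']})\n")
        fh.write(f"samples: {len(xtf_table)}; ACN fits: {len(acn_rows)}\n")
        if not slopes.empty:
            fh.write("\nxTF slopes per patient line x arm:\n")
            fh.write(slopes.to_string(index=False) + "\n")
        for line, info in growth_summary.items():
            if "t1" in info:
                fh.write(f"\nline {line}: t1={info['t1']:g} t2={info['t2']:g} "
                         f"beta1={info['beta1']:.4f} beta2={info['beta2']:.4f} "
                         f"beta3={info['beta3']:.4f}\n")
        if outcome:
            fh.write(f"\noutcome correlations: {outcome}\n")
    return report
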