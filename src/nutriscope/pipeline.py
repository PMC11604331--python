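"""End-to-end comparison pipeline: read, prepare, score, compare, report.

Outputs (all CSV, plus optional PNG histograms) mirror the standard
monitoring-report shapes: a per-group median/IQR nutrient table, a class
distribution table with percentage-point changes and the top-k most-changed
groups, per-class nutrient medians for those groups, the matched-EAN
sensitivity table, and final-sum histograms.  Re-running with identical
inputs reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import compare as cmp
from .preprocess import preprocess
from .records import FoodGroupTaxonomy, read_snapshot
from .scheme import BoundaryConvention, ScoringScheme
from .scoring import score_table
from .plots import plot_histograms

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Configuration of one comparison run."""

    snapshot_paths: list[Path]
    output_dir: Path
    years: tuple[int, int] = (2018, 2020)
    scheme_path: Optional[Path] = None      # packaged updated scheme when None
    taxonomy_path: Optional[Path] = None    # packaged default taxonomy when None
    top_k: int = Field(default=5, ge=1)
    metric: cmp.ChangeMetric = "total_variation"
    convention: BoundaryConvention = "strict"
    min_group_size: int = Field(default=10, ge=1)
    make_plots: bool = True

    def load_scheme(self) -> ScoringScheme:
        return (
            ScoringScheme.from_yaml(self.scheme_path)
            if self.scheme_path
            else ScoringScheme.default()
        )

    def load_taxonomy(self) -> FoodGroupTaxonomy:
        return (
            FoodGroupTaxonomy.from_yaml(self.taxonomy_path)
            if self.taxonomy_path
            else FoodGroupTaxonomy.default()
        )


@dataclass
class ReportBundle:
    """Paths of everything a pipeline run wrote, plus in-memory results."""

    output_dir: Path
    files: dict[str, Path] = dc_field(default_factory=dict)
    scores: Optional[pd.DataFrame] = None
    summaries: dict[int, cmp.SnapshotSummary] = dc_field(default_factory=dict)
    delta_pp: Optional[pd.DataFrame] = None
    top_groups: list[str] = dc_field(default_factory=list)
    sensitivity: Optional[cmp.MatchedEanReport] = None


def _scheme_digest(path: Optional[Path]) -> str:
    if path is None:
        from importlib.resources import files

        text = (files("nutriscope") / "data" / "scheme_2023.yaml").read_text()
    else:
        text = Path(path).read_text()
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full comparison and write the report bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out_dir)
    scheme = config.load_scheme()
    taxonomy = config.load_taxonomy()
    y1, y2 = config.years
    if y1 == y2:
        raise ValueError("the two snapshot years must differ")

    records = _stage("read")(_read_all)(config, taxonomy)

    prep_rows = []
    prepared = {}
    for year in (y1, y2):
        year_records = [r for r in records if r.year == year]
        if not year_records:
            raise RuntimeError(f"pipeline stage 'read' produced no records for {year}")
        kept, report = _stage("preprocess")(preprocess)(
            year_records, taxonomy, config.min_group_size
        )
        prepared[year] = kept
        prep_rows.append(
            {
                "year": year,
                "input": report.input_count,
                "excluded_not_processed": report.excluded_not_processed,
                "excluded_missing_mandatory": sum(
                    report.excluded_missing_mandatory.values()
                ),
                "excluded_small_group": sum(report.excluded_small_group.values()),
                "fibre_imputed": sum(report.fibre_imputed.values()),
                "retained": report.retained_count,
            }
        )
    prep_df = pd.DataFrame(prep_rows)
    bundle.files["preprocess_report"] = out_dir / "preprocess_report.csv"
    prep_df.to_csv(bundle.files["preprocess_report"], index=False)

    scored = _stage("score")(score_table)(
        prepared[y1] + prepared[y2], scheme, taxonomy, config.convention
    )
    bundle.scores = scored
    bundle.files["scores"] = out_dir / "scores.csv"
    scored.to_csv(bundle.files["scores"], index=False)

    for year in (y1, y2):
        bundle.summaries[year] = _stage("summarize")(cmp.summarize_snapshot)(
            scored, year
        )

    # Table-1-like: per-group median/IQR nutrient contents, both years
    nutrient_tables = []
    for year in (y1, y2):
        t = bundle.summaries[year].nutrient_summary.copy()
        t.columns = [f"{nut}_{stat}" for nut, stat in t.columns]
        t.insert(0, "n", bundle.summaries[year].n)
        t.insert(0, "year", year)
        nutrient_tables.append(t)
    table1 = pd.concat(nutrient_tables).rename_axis("food_group").reset_index()
    bundle.files["nutrient_summary"] = out_dir / "nutrient_summary.csv"
    table1.to_csv(bundle.files["nutrient_summary"], index=False)

    # Supplementary-like: mean and distribution of the final sum
    sum_rows = []
    for year in (y1, y2):
        s = bundle.summaries[year]
        for group, hist in s.histograms.items():
            for final_sum, count in hist.items():
                sum_rows.append(
                    {"food_group": group, "year": year,
                     "final_sum": int(final_sum), "count": int(count)}
                )
    bundle.files["final_sum_distribution"] = out_dir / "final_sum_distribution.csv"
    pd.DataFrame(sum_rows).to_csv(bundle.files["final_sum_distribution"], index=False)

    # Table-2-like: class distributions and percentage-point changes
    delta = _stage("compare")(cmp.pp_change)(bundle.summaries[y1], bundle.summaries[y2])
    bundle.delta_pp = delta
    overall = cmp.overall_change(delta, config.metric)
    bundle.top_groups = cmp.top_k(delta, config.top_k, config.metric)
    table2 = pd.concat(
        {
            f"pct_{y1}": bundle.summaries[y1].class_distribution.loc[delta.index],
            f"pct_{y2}": bundle.summaries[y2].class_distribution.loc[delta.index],
            "delta_pp": delta,
        },
        axis=1,
    )
    table2.columns = [f"{top}_{cls}" for top, cls in table2.columns]
    table2["overall_change"] = overall
    table2["top_k"] = [g in bundle.top_groups for g in table2.index]
    bundle.files["class_distribution"] = out_dir / "class_distribution.csv"
    table2.rename_axis("food_group").reset_index().to_csv(
        bundle.files["class_distribution"], index=False
    )

    # Matched-EAN sensitivity analysis
    sens = _stage("sensitivity")(cmp.matched_ean_sensitivity)(
        scored[scored["year"] == y1], scored[scored["year"] == y2]
    )
    bundle.sensitivity = sens
    bundle.files["ean_sensitivity"] = out_dir / "ean_sensitivity.csv"
    sens.per_group.reset_index().to_csv(bundle.files["ean_sensitivity"], index=False)

    # Table-3-like: per-class medians of the most-changed nutrient, top groups
    rel = cmp.relative_median_change(bundle.summaries[y1], bundle.summaries[y2])
    t3_rows = []
    for group in bundle.top_groups:
        if group not in rel.index or rel.loc[group].abs().isna().all():
            continue
        nutrient = rel.loc[group].abs().idxmax()
        table = cmp.median_by_class(scored, nutrient, group)
        for cls, row in table.iterrows():
            for year in (y1, y2):
                t3_rows.append(
                    {
                        "food_group": group,
                        "nutrient": nutrient,
                        "nutri_class": cls,
                        "year": year,
                        "n": row.get((year, "n")),
                        "median": row.get((year, "median")),
                    }
                )
    bundle.files["median_by_class"] = out_dir / "median_by_class.csv"
    pd.DataFrame(
        t3_rows,
        columns=["food_group", "nutrient", "nutri_class", "year", "n", "median"],
    ).to_csv(bundle.files["median_by_class"], index=False)

    if config.make_plots:
        plot_dir = out_dir / "figures"
        plot_dir.mkdir(exist_ok=True)
        for group in bundle.top_groups:
            hists = {
                year: bundle.summaries[year].histograms[group]
                for year in (y1, y2)
                if group in bundle.summaries[year].histograms
            }
            path = _stage("plots")(plot_histograms)(
                hists,
                group,
                taxonomy.category_for(group),
                scheme,
                plot_dir / f"final_sum_{group}.png",
                display_name=taxonomy.display_name(group),
            )
            bundle.files[f"figure_{group}"] = path

    run_log = {
        "scheme": scheme.name,
        "scheme_sha256_16": _scheme_digest(config.scheme_path),
        "boundary_convention": config.convention,
        "change_metric": config.metric,
        "years": [y1, y2],
        "top_k": config.top_k,
        "min_group_size": config.min_group_size,
        "records_scored": int(len(scored)),
        "matched_eans": int(sens.n_matched),
        "top_groups": bundle.top_groups,
        "preprocess": prep_rows,
    }
    bundle.files["run_log"] = out_dir / "run_log.json"
    bundle.files["run_log"].write_text(json.dumps(run_log, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d files in %s", len(bundle.files), out_dir)
    return bundle


def _read_all(config: PipelineConfig, taxonomy: FoodGroupTaxonomy):
    records = []
    for path in config.snapshot_paths:
        records.extend(read_snapshot(path, taxonomy))
    return records
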