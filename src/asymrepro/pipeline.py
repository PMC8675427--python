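"""End-to-end pipeline: effects in, reproducibility bundle out.

Given a summary-statistics table (read from disk or freshly simulated), the
pipeline runs the full-pool meta-analyses, the leave-one-out reproducibility
rates under the nominal and Bonferroni criteria, the metric/region
summaries, the minimum-sample-size stratification, the effect-size binning,
the dataset-subgroup comparisons, and the per-dataset power tables, and
writes everything (plus a provenance manifest) into one output directory.
"""

from __future__ import annotations

import json
import platform
from dataclasses import replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy

import asymrepro
from asymrepro import regions
from asymrepro.effects import EffectRecord
from asymrepro.io import RunConfig, read_summary_table, records_to_frame, write_summary_table
from asymrepro.meta import MetaResult, random_effects_meta
from asymrepro.power_ppv import power_table
from asymrepro.reproducibility import (
    ReproResult,
    bin_by_effect_size,
    compare_subgroups,
    group_by_measure,
    rates_within_datasets,
    reproducibility_by_measure,
    stratify_by_min_n,
    subgroup_meta_reproducibility,
    summarize_rates,
)
from asymrepro.synthetic import SimulationConfig, simulate_multiverse, study_profile

__all__ = ["run_pipeline", "meta_table", "rates_table", "subgroup_comparison_table", "subgroup_specific_table"]


def _grouping(measure_ids) -> dict[str, str]:
    out = {}
    for m in measure_ids:
        try:
            out[m] = regions.metric_of(m)
        except ValueError:
            out[m] = "ungrouped"
    return out


def meta_table(metas: Mapping[str, MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure_id": m.measure_id,
                "k": m.k,
                "pooled_d": m.pooled_d,
                "se": m.se,
                "z": m.z,
                "p": m.p,
                "tau2": m.tau2,
                "Q": m.Q,
                "method": m.method,
            }
            for m in metas.values()
        ]
    )


def rates_table(repro: Mapping[str, ReproResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"measure_id": r.measure_id, "rate": r.rate, "n_eval": r.n_eval}
            for r in repro.values()
        ]
    )


def subgroup_comparison_table(
    repro: Mapping[str, ReproResult], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Compare per-effect rates between dataset subgroups (shared flags)."""
    split_defs = []
    if "field_strength" in metadata.columns:
        split_defs.append(
            ("3T_vs_1.5T",
             metadata.field_strength == 3.0,
             metadata.field_strength == 1.5)
        )
    if "fs_version" in metadata.columns:
        split_defs.append(
            ("fs5.3_vs_fs5.1",
             metadata.fs_version == "5.3",
             metadata.fs_version == "5.1")
        )
    if {"age_min", "age_max"} <= set(metadata.columns):
        split_defs.append(
            ("child_vs_adult",
             metadata.age_max <= 18,
             metadata.age_min >= 19)
        )
    rows = []
    for label, mask_a, mask_b in split_defs:
        ids_a = metadata.loc[mask_a, "dataset_id"]
        ids_b = metadata.loc[mask_b, "dataset_id"]
        ra = pd.Series(rates_within_datasets(repro, ids_a)).dropna()
        rb = pd.Series(rates_within_datasets(repro, ids_b)).dropna()
        if len(ra) < 2 or len(rb) < 2:
            continue
        cmp = compare_subgroups(ra.to_numpy(), rb.to_numpy(), paired=False)
        rows.append(
            {
                "comparison": label,
                "mean_a": float(ra.mean()),
                "sd_a": float(ra.std(ddof=1)),
                "n_datasets_a": int(mask_a.sum()),
                "mean_b": float(rb.mean()),
                "sd_b": float(rb.std(ddof=1)),
                "n_datasets_b": int(mask_b.sum()),
                "t": cmp.t,
                "df": cmp.df,
                "p_t": cmp.p_t,
                "u": cmp.u,
                "p_u": cmp.p_u,
            }
        )
    return pd.DataFrame(rows)


def subgroup_specific_table(
    records, metadata: pd.DataFrame, crit, method
) -> pd.DataFrame:
    """Subgroup-specific pooled effects: rerun the whole pipeline per subgroup."""
    predicates = {}
    if "field_strength" in metadata.columns:
        predicates["3T"] = lambda row: row["field_strength"] == 3.0
        predicates["1.5T"] = lambda row: row["field_strength"] == 1.5
    if {"age_min", "age_max"} <= set(metadata.columns):
        predicates["child"] = lambda row: row["age_max"] <= 18
        predicates["adult"] = lambda row: row["age_min"] >= 19
    rows = []
    for label, pred in predicates.items():
        try:
            sub = subgroup_meta_reproducibility(
                records, metadata, pred, crit=crit, method=method
            )
        except ValueError:
            continue
        rates = np.array([r.rate for r in sub.values()])
        rows.append(
            {
                "subgroup": label,
                "n_effects": rates.size,
                "mean_rate": float(rates.mean()),
                "sd_rate": float(rates.std(ddof=1)) if rates.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the complete analysis and write the result bundle.

    Returns the bundle as a dict of DataFrames plus the manifest; everything
    is also written under ``config.out_dir`` (TSV tables, JSON manifest, and
    the serialized configuration for provenance).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.input_path is not None:
        records, metadata = read_summary_table(
            config.input_path, column_map=config.column_map
        )
        truth = None
    else:
        sim = SimulationConfig(
            n_datasets=config.n_datasets,
            measure_specs=tuple(
                study_profile(n_measures=config.n_measures, tau=config.tau)
            ),
            seed=config.seed,
            mode=config.mode,
        )
        study = simulate_multiverse(sim)
        records = list(study.effect_table)
        metadata = study.metadata_table
        truth = study.truth_table

    crit = config.criterion()
    by_measure = group_by_measure(records)

    metas = {
        m: random_effects_meta(recs, method=config.method)
        for m, recs in by_measure.items()
    }
    repro = reproducibility_by_measure(records, crit=crit, method=config.method)
    repro_bonf = reproducibility_by_measure(
        records, crit=crit.bonferroni(), method=config.method
    )

    grouping = _grouping(by_measure.keys())
    summary = summarize_rates(list(repro.values()), grouping=grouping)
    summary_bonf = summarize_rates(list(repro_bonf.values()), grouping=grouping)

    strata = stratify_by_min_n(
        records, crit=crit, thresholds=config.thresholds, method=config.method
    )
    bins = bin_by_effect_size(list(metas.values()), bins=config.bins)
    rates = rates_table(repro).merge(bins, on="measure_id")
    rates_b = rates_table(repro_bonf)
    rate_by_bin = (
        rates.groupby("bin", as_index=False)
        .agg(n_effects=("measure_id", "size"), mean_rate=("rate", "mean"))
    )

    subgroup_cmp = subgroup_comparison_table(repro, metadata)
    subgroup_specific = subgroup_specific_table(records, metadata, crit, config.method)

    power_frames = [
        power_table(metas[m], by_measure[m], alpha=config.alpha_single)
        for m in by_measure
    ]
    power = pd.concat(power_frames, ignore_index=True)

    manifest = {
        "package_version": asymrepro.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "method": config.method,
        "criterion": {
            "alpha_meta": crit.alpha_meta,
            "alpha_single": crit.alpha_single,
            "n_effects_for_correction": crit.n_effects_for_correction,
            "min_n": crit.min_n,
        },
        "n_datasets": int(metadata.shape[0]),
        "n_measures": len(by_measure),
    }

    bundle = {
        "meta": meta_table(metas),
        "rates": rates,
        "rates_bonferroni": rates_b,
        "summary": summary,
        "summary_bonferroni": summary_bonf,
        "strata": strata,
        "rate_by_bin": rate_by_bin,
        "subgroup_comparisons": subgroup_cmp,
        "subgroup_specific": subgroup_specific,
        "power": power,
        "manifest": manifest,
    }
    if truth is not None:
        bundle["truth"] = truth

    config.to_yaml(out_dir / "run_config.yaml")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for name in ("meta", "rates", "rates_bonferroni", "summary",
                 "summary_bonferroni", "strata", "rate_by_bin",
                 "subgroup_comparisons", "subgroup_specific"):
        bundle[name].to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    if config.write_detail:
        write_summary_table(records_to_frame(records), out_dir / "effects.tsv")
        bundle["power"].to_csv(out_dir / "power.tsv", sep="\t", index=False)
    return bundle
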