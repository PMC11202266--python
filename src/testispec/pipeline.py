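"""End-to-end orchestration: simulate/load -> classify -> GSG -> sets -> report.

The pipeline is a pure function of (inputs, config, seed): identical inputs
produce byte-identical output tables, and the JSON manifest written next to
them records everything needed to reproduce a run.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import activity, biometrics, genesets, simulate, tissues
from .io import (ExpressionMatrix, InputError, RunConfig, write_manifest)


@dataclasses.dataclass
class ReportBundle:
    """All output tables of one pipeline run."""

    cohort: pd.DataFrame
    hormone_summary: pd.DataFrame
    results: pd.DataFrame              # per-gene log2-ER, p, class, fold
    specificity_summary: pd.DataFrame
    gene_sets: pd.DataFrame
    gsg_calls: pd.DataFrame
    centered: pd.DataFrame


def hormone_summary_table(panel: pd.DataFrame, gsi: pd.Series,
                          groups: pd.Series,
                          config: RunConfig) -> pd.DataFrame:
    """Per-analyte Pearson r with GSI, pubertal/immature fold, and t-test p."""
    r, _, _ = biometrics.correlate_with_index(panel, gsi)
    fold = biometrics.group_fold(panel, groups,
                                 geometric=config.geometric_hormone_fold)
    p = biometrics.group_difference_test(panel, groups, welch=config.welch)
    return pd.DataFrame({"pearson_r": r, "fold": fold, "p_value": p})


def run_pipeline(config: RunConfig | None = None,
                 sim_config: simulate.SimulationConfig | None = None,
                 matrix: ExpressionMatrix | None = None,
                 metadata: pd.DataFrame | None = None,
                 compendium: pd.DataFrame | None = None,
                 annotation: pd.DataFrame | None = None,
                 hormones: pd.DataFrame | None = None,
                 cohort: list | None = None,
                 out_dir: str | Path | None = None) -> ReportBundle:
    """Run every stage; any input left None is simulated.

    Outputs (when out_dir is given): per-fish cohort table, hormone summary,
    per-gene differential table, class-by-specificity summary, functional
    group table, GSG calls, the sample-centered log2 matrix, and a JSON
    manifest of config + seed.
    """
    config = config or RunConfig()
    sim_config = sim_config or simulate.SimulationConfig(rng_seed=config.rng_seed)
    seed = sim_config.rng_seed
    simulated = []

    if metadata is None or cohort is None:
        cohort, metadata = simulate.generate_cohort(sim_config, seed)
        simulated.append("cohort")
    if matrix is None:
        matrix, truth = simulate.generate_testis_matrix(sim_config, seed,
                                                        metadata=metadata)
        simulated.append("expression")
    else:
        truth = None
    if compendium is None:
        compendium, _ = simulate.generate_compendium(
            sim_config, seed,
            gene_ids=matrix.gene_ids
            if len(matrix.gene_ids) >= sim_config.n_compendium_genes else None)
        simulated.append("compendium")
    if hormones is None:
        hormones, _ = simulate.generate_hormones(
            sim_config, seed, gsi=metadata.set_index("fish_id")["gsi"])
        simulated.append("hormones")
    if annotation is None:
        if truth is None:
            raise InputError("annotation required when expression is supplied")
        annotation = simulate.generate_annotation(truth, seed=seed)
        simulated.append("annotation")

    meta = metadata.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise InputError(f"samples without metadata: {missing}")
    groups = biometrics.maturity_groups(meta.loc[matrix.sample_ids], config)

    results = activity.differential_activity(matrix, groups, config)
    calls = tissues.call_gonad_specific(compendium, config)
    gsg_flags = calls["gonad_specific"].reindex(results.index,
                                                fill_value=False)
    summary = activity.summarize_by_specificity(results, gsg_flags)
    sets = genesets.set_shift_test(results["log2_er"], annotation, config,
                                   results=results, gsg_flags=gsg_flags)
    centered = activity.center_to_sample_average(matrix.log2)

    fish_groups = biometrics.maturity_groups(
        metadata.set_index("fish_id"), config)
    hsum = hormone_summary_table(
        hormones, metadata.set_index("fish_id")["gsi"], fish_groups, config)
    cohort_df = biometrics.cohort_to_frame(cohort)
    cohort_df["maturity_group"] = cohort_df["gsi"].map(
        lambda g: biometrics.assign_maturity_group(g, config))

    bundle = ReportBundle(
        cohort=cohort_df,
        hormone_summary=hsum,
        results=results,
        specificity_summary=summary.to_frame(),
        gene_sets=sets,
        gsg_calls=calls,
        centered=centered,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, df, with_index in (
            ("cohort", bundle.cohort, False),
            ("hormone_summary", bundle.hormone_summary, True),
            ("differential", bundle.results, True),
            ("specificity_summary", bundle.specificity_summary, False),
            ("gene_sets", bundle.gene_sets, False),
            ("gsg_calls", bundle.gsg_calls, True),
            ("centered_log2", bundle.centered, True),
        ):
            path = out / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=with_index, float_format="%.6g")
            written[name] = path.name
        write_manifest(out / "manifest.json", config, seed,
                       inputs={name: "simulated" for name in simulated},
                       outputs=written)
    return bundle
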