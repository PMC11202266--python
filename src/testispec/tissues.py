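"""Gonad-specific gene calling from a multi-tissue expression compendium.

A gene is gonad-specific (GSG) when its expression in testis and/or ovary is
at least eight-fold the average over all tissues AND it is not expressed in
any non-gonadal tissue.  The compendium holds tissue-level mean intensities
on the linear scale; replicate-level input is averaged first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import InputError, OVARY, RunConfig, TESTIS


DEFAULT_TARGETS = (TESTIS, OVARY)


def validate_compendium(compendium: pd.DataFrame, floor: float = 1.0
                        ) -> pd.DataFrame:
    """Check shape/uniqueness and apply the intensity floor."""
    if compendium.shape[1] < 2:
        raise InputError("compendium needs at least two tissues")
    if compendium.columns.duplicated().any():
        dup = compendium.columns[compendium.columns.duplicated()][0]
        raise InputError(f"duplicate tissue label: {dup!r}")
    if compendium.index.duplicated().any():
        dup = compendium.index[compendium.index.duplicated()][0]
        raise InputError(f"duplicate gene identifier: {dup!r}")
    arr = compendium.to_numpy(dtype=float)
    if not np.isfinite(np.nan_to_num(arr, nan=0.0)).all():
        raise InputError("compendium contains infinite values")
    arr = np.where(np.isnan(arr) | (arr <= 0), floor, arr)
    return pd.DataFrame(arr, index=compendium.index, columns=compendium.columns)


def average_replicates(replicates: pd.DataFrame, tissue_of: pd.Series
                       ) -> pd.DataFrame:
    """Collapse replicate columns to linear-scale tissue means."""
    return replicates.T.groupby(tissue_of.reindex(replicates.columns)).mean().T


def specificity_score(compendium: pd.DataFrame,
                      target_tissues: tuple[str, ...] = DEFAULT_TARGETS,
                      include_targets_in_average: bool = True) -> pd.Series:
    """Gonad-over-average fold per gene.

    Maximum expression across the target tissues (testis and/or ovary by
    default) divided by the arithmetic mean over all tissues.  The average
    includes the targets themselves unless switched off.
    """
    targets = [t for t in target_tissues if t in compendium.columns]
    if not target_tissues:
        raise InputError("target tissue set must be non-empty")
    if not targets:
        raise InputError(
            f"none of the target tissues {list(target_tissues)} in compendium"
        )
    target_max = compendium[targets].max(axis=1)
    if include_targets_in_average:
        denom = compendium.mean(axis=1)
    else:
        others = [t for t in compendium.columns if t not in targets]
        if not others:
            raise InputError("no non-target tissues to average over")
        denom = compendium[others].mean(axis=1)
    score = target_max / denom
    score.name = "gonad_over_average_fold"
    return score


def call_gonad_specific(compendium: pd.DataFrame,
                        config: RunConfig | None = None,
                        target_tissues: tuple[str, ...] = DEFAULT_TARGETS
                        ) -> pd.DataFrame:
    """Per-gene gonad-specificity calls.

    gonad_specific = (score >= gsg_fold_threshold, inclusive) AND not
    expressed elsewhere.  "Expressed elsewhere" means some non-target tissue
    exceeds the absence threshold max(gsg_absence_floor, gsg_absence_rel x
    the gene's maximum gonadal expression).  The relative term keeps the
    rule scale-robust while remaining monotone: raising a non-target
    tissue's expression can only push a gene towards "expressed elsewhere",
    never rescue it.
    """
    config = config or RunConfig()
    comp = validate_compendium(compendium, floor=config.intensity_floor)
    score = specificity_score(
        comp, target_tissues,
        include_targets_in_average=config.gsg_include_targets_in_average,
    )
    targets = [t for t in target_tissues if t in comp.columns]
    others = [t for t in comp.columns if t not in targets]
    absence_threshold = np.maximum(
        config.gsg_absence_floor,
        config.gsg_absence_rel * comp[targets].max(axis=1),
    )
    if others:
        expressed_elsewhere = comp[others].gt(absence_threshold, axis=0).any(axis=1)
    else:
        expressed_elsewhere = pd.Series(False, index=comp.index)
    gonad_specific = (score >= config.gsg_fold_threshold) & ~expressed_elsewhere
    return pd.DataFrame({
        "gonad_over_average_fold": score,
        "expressed_elsewhere": expressed_elsewhere,
        "gonad_specific": gonad_specific,
    })
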