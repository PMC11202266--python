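"""Coordinated-change detection for annotated functional gene groups.

For each functional group, the member genes' log2 expression ratios are
tested for a significant deviation of their mean from zero; the group is
summarised by a signed mean fold (2^|mean| with the sign of the mean).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import InputError, RunConfig
from .activity import HSA, LSA, adjust_bh, signed_fold

logger = logging.getLogger("testispec")


def set_shift_test(log2_er: pd.Series, annotation: pd.DataFrame,
                   config: RunConfig | None = None,
                   results: pd.DataFrame | None = None,
                   gsg_flags: pd.Series | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-group mean log2-ER shift test.

    annotation: long frame (gene_id, functional_group); multi-membership via
    repeated rows.  Groups with fewer than config.min_set_size members
    present in `log2_er` are excluded.  The default test is a one-sample
    t-test of member log2-ERs against zero; config.set_test='permutation'
    replaces it with a seeded gene-label permutation test of the mean
    (robust when inter-gene correlation inflates the t-test).  Optionally,
    per-gene classes (`results`) and gonad-specificity flags count the
    gonad-specific members among LSA and HSA.  Groups whose members all
    share one identical log2-ER have an undefined (NaN) p-value.
    """
    config = config or RunConfig()
    known = annotation["gene_id"].isin(log2_er.index)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("ignoring %d annotation rows for genes absent from the "
                    "expression data", n_unknown)
    ann = annotation[known]
    rows = []
    er_values = log2_er.to_numpy()
    if config.set_test == "permutation" and rng is None:
        rng = np.random.default_rng(config.rng_seed)
    for group, members in ann.groupby("functional_group", sort=True):
        genes = members["gene_id"].unique()
        if len(genes) < config.min_set_size:
            continue
        vals = log2_er.loc[genes].to_numpy()
        mean = float(vals.mean())
        if np.ptp(vals) == 0:
            p = np.nan  # zero variance: deviation is undefined for the t-test
        elif config.set_test == "permutation":
            p = _permutation_p(vals, er_values, rng, config.n_permutations)
        else:
            p = float(stats.ttest_1samp(vals, 0.0).pvalue)
        row = {
            "functional_group": group,
            "n_genes": int(len(genes)),
            "mean_log2_er": mean,
            "p_value": p,
            "mean_fold": round(float(signed_fold(mean)), 1),
        }
        if results is not None and gsg_flags is not None:
            cls = results.loc[genes, "class"]
            flags = gsg_flags.reindex(genes).fillna(False).astype(bool)
            row["gonad_specific_lsa"] = int(((cls == LSA) & flags).sum())
            row["gonad_specific_hsa"] = int(((cls == HSA) & flags).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty and config.multiple_testing == "bh":
        out["p_value"] = adjust_bh(out["p_value"]).to_numpy()
    return out


def _permutation_p(vals: np.ndarray, universe: np.ndarray,
                   rng: np.random.Generator, n_perm: int) -> float:
    """Two-sided permutation p for a set mean against random gene draws."""
    observed = abs(vals.mean())
    draws = rng.choice(universe, size=(n_perm, len(vals)), replace=True)
    null_means = np.abs(draws.mean(axis=1))
    return float((1 + (null_means >= observed).sum()) / (1 + n_perm))


def mean_of_member_folds(log2_er: pd.Series, genes: list[str]) -> float:
    """Alternative group summary: mean of per-gene signed folds."""
    return float(np.mean([signed_fold(m) for m in log2_er.loc[genes]]))


def rank_sets(results: pd.DataFrame, direction: str,
              alpha: float = 0.05) -> pd.DataFrame:
    """Significant groups of one direction, ordered by |mean fold| descending.

    direction: 'increased' (mean fold > 0) or 'decreased' (< 0).  Ties in
    |fold| keep a stable alphabetical order by group label.
    """
    if direction not in ("increased", "decreased"):
        raise InputError(f"direction must be increased/decreased, got {direction!r}")
    if results.empty:
        return results
    sig = results[results["p_value"] < alpha]
    if direction == "increased":
        sig = sig[sig["mean_fold"] > 0]
    else:
        sig = sig[sig["mean_fold"] < 0]
    sig = sig.sort_values("functional_group", kind="stable")
    return sig.reindex(
        sig["mean_fold"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
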