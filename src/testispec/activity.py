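"""Differential specific activity between pubertal and immature testes.

Transcript abundance per unit of whole-testis RNA ("specific activity")
conflates transcriptional regulation with the changing proportions of the
germinative and interstitial compartments, so genes are labelled HSA / LSA
(higher / lower specific activity) rather than up-/down-regulated.  A gene
is HSA when its log2 expression ratio (pubertal minus immature group mean of
log2 intensities) exceeds the cutoff with p below alpha; LSA symmetrically
below the negative cutoff; otherwise NS.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, InputError, RunConfig
from .biometrics import IMMATURE, PUBERTAL

HSA = "HSA"
LSA = "LSA"
NS = "NS"


def _group_columns(matrix: ExpressionMatrix, groups: pd.Series
                   ) -> tuple[list[str], list[str]]:
    groups = groups.reindex(matrix.sample_ids)
    pub = [s for s in matrix.sample_ids if groups.get(s) == PUBERTAL]
    imm = [s for s in matrix.sample_ids if groups.get(s) == IMMATURE]
    if len(pub) < 2 or len(imm) < 2:
        raise InputError(
            f"need >= 2 samples per group, got {len(pub)} pubertal "
            f"and {len(imm)} immature"
        )
    return pub, imm


def log2_expression_ratio(matrix: ExpressionMatrix, groups: pd.Series
                          ) -> pd.Series:
    """Per-gene log2-ER: mean log2 intensity, pubertal minus immature.

    The difference of log2 group means is the log2 ratio of geometric means,
    the standard effect size for log-scale microarray intensities.
    """
    pub, imm = _group_columns(matrix, groups)
    log2 = matrix.log2
    er = log2[pub].mean(axis=1) - log2[imm].mean(axis=1)
    er.name = "log2_er"
    return er


def log2_ratio_of_linear_means(matrix: ExpressionMatrix, groups: pd.Series
                               ) -> pd.Series:
    """Sensitivity-analysis variant: log2 of the ratio of linear-scale means."""
    pub, imm = _group_columns(matrix, groups)
    vals = matrix.values
    er = np.log2(vals[pub].mean(axis=1) / vals[imm].mean(axis=1))
    er.name = "log2_er"
    return er


def per_gene_test(matrix: ExpressionMatrix, groups: pd.Series,
                  welch: bool = True) -> pd.Series:
    """Per-gene two-sample t-test p-value on log2 intensities.

    Welch's form by default.  Genes constant and equal in both groups get
    p = 1 (no evidence of change, never NaN); constant but unequal groups
    get p = 0.
    """
    pub, imm = _group_columns(matrix, groups)
    log2 = matrix.log2
    a = log2[pub].to_numpy()
    b = log2[imm].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    equal_means = a[:, 0] == b[:, 0]
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    return pd.Series(p, index=matrix.gene_ids, name="p_value")


def signed_fold(log2_er: float | np.ndarray | pd.Series):
    """Signed linear fold: 2^m for m >= 0, -2^(-m) for m < 0.

    Magnitudes are symmetric around 1 and the sign encodes direction, the
    convention used for printed fold tables (log2-ER of -3.036 prints as
    -8.2-fold).
    """
    m = np.asarray(log2_er, dtype=float)
    out = np.where(m >= 0, np.exp2(m), -np.exp2(-m))
    if isinstance(log2_er, pd.Series):
        return pd.Series(out, index=log2_er.index, name="fold")
    if np.isscalar(log2_er) or np.ndim(log2_er) == 0:
        return float(out)
    return out


def adjust_bh(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values."""
    p = p.astype(float)
    n = p.notna().sum()
    order = p.dropna().sort_values()
    ranked = order * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(upper=1.0)
    return adj.reindex(p.index)


def classify(log2_er: pd.Series, p: pd.Series,
             config: RunConfig | None = None) -> pd.DataFrame:
    """HSA/LSA/NS call per gene with signed fold.

    Both criteria are strict: |log2-ER| must exceed the cutoff (default 0.8,
    i.e. 1.75-fold) and p must be below alpha (default 0.05).  Optional BH
    adjustment (config.multiple_testing='bh') is applied before the alpha
    comparison; the unadjusted criteria are the study's own.
    """
    config = config or RunConfig()
    if not log2_er.index.equals(p.index):
        raise InputError("log2_er and p vectors are not aligned")
    p_eff = adjust_bh(p) if config.multiple_testing == "bh" else p
    sig = p_eff < config.alpha
    cls = pd.Series(NS, index=log2_er.index, name="class")
    cls[(log2_er > config.log2er_cutoff) & sig] = HSA
    cls[(log2_er < -config.log2er_cutoff) & sig] = LSA
    return pd.DataFrame({
        "log2_er": log2_er,
        "p_value": p,
        "class": cls,
        "fold": signed_fold(log2_er),
    })


def differential_activity(matrix: ExpressionMatrix, groups: pd.Series,
                          config: RunConfig | None = None) -> pd.DataFrame:
    """Full per-gene table: log2-ER, t-test p, class, signed fold."""
    config = config or RunConfig()
    er = log2_expression_ratio(matrix, groups)
    p = per_gene_test(matrix, groups, welch=config.welch)
    return classify(er, p, config)


def center_to_sample_average(matrix_log2: pd.DataFrame) -> pd.DataFrame:
    """Center each gene's log2 profile to its across-sample average.

    After centering every row mean is zero; this is the transform used for
    expression profiling displays relative to the all-sample average.
    """
    return matrix_log2.sub(matrix_log2.mean(axis=1), axis=0)


@dataclasses.dataclass(frozen=True)
class SpecificitySummary:
    """Class-by-class gene counts with gonad-specific proportions."""

    counts: dict[str, int]            # class -> total genes
    specific: dict[str, int]          # class -> gonad-specific genes

    @classmethod
    def from_counts(cls, hsa: tuple[int, int], lsa: tuple[int, int],
                    ns: tuple[int, int] = (0, 0)) -> "SpecificitySummary":
        return cls(counts={HSA: hsa[0], LSA: lsa[0], NS: ns[0]},
                   specific={HSA: hsa[1], LSA: lsa[1], NS: ns[1]})

    def percent(self, label: str) -> float:
        """Gonad-specific percentage within a class, one decimal."""
        total = self.counts.get(label, 0)
        if total == 0:
            return float("nan")
        return round(100.0 * self.specific[label] / total, 1)

    @property
    def total_differential(self) -> int:
        return self.counts.get(HSA, 0) + self.counts.get(LSA, 0)

    @property
    def total_specific(self) -> int:
        return self.specific.get(HSA, 0) + self.specific.get(LSA, 0)

    @property
    def total_percent(self) -> float:
        if self.total_differential == 0:
            return float("nan")
        return round(100.0 * self.total_specific / self.total_differential, 1)

    @property
    def specificity_ratio(self) -> float:
        """HSA-to-LSA ratio of gonad-specific proportions, one decimal."""
        if min(self.counts.get(HSA, 0), self.counts.get(LSA, 0)) == 0:
            return float("nan")
        p_hsa = self.specific[HSA] / self.counts[HSA]
        p_lsa = self.specific[LSA] / self.counts[LSA]
        if p_lsa == 0:
            return float("inf")
        return round(p_hsa / p_lsa, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in (HSA, LSA):
            rows.append({
                "class": label,
                "all": self.counts.get(label, 0),
                "gonad_specific": self.specific.get(label, 0),
                "percent_gonad_specific": self.percent(label),
            })
        rows.append({
            "class": "Total",
            "all": self.total_differential,
            "gonad_specific": self.total_specific,
            "percent_gonad_specific": self.total_percent,
        })
        return pd.DataFrame(rows)


def summarize_by_specificity(results: pd.DataFrame,
                             gsg_flags: pd.Series) -> SpecificitySummary:
    """Count HSA/LSA genes and their gonad-specific members.

    `gsg_flags` must cover every classified gene (missing flags are a hard
    error; a gene that was never screened against the tissue compendium
    cannot silently count as non-specific).
    """
    flags = gsg_flags.reindex(results.index)
    if flags.isna().any():
        missing = flags.index[flags.isna()][0]
        raise InputError(f"gene {missing!r} has no gonad-specificity flag")
    counts, specific = {}, {}
    for label in (HSA, LSA, NS):
        members = results["class"] == label
        counts[label] = int(members.sum())
        specific[label] = int((members & flags.astype(bool)).sum())
    return SpecificitySummary(counts=counts, specific=specific)


def candidate_screen(matrix: ExpressionMatrix,
                     include_samples: list[str],
                     exclude_samples: list[str],
                     baseline_samples: list[str],
                     config: RunConfig | None = None) -> list[str]:
    """Screen for trigger-candidate genes on a hand-picked sample split.

    A gene is selected when its log2 intensity exceeds the baseline-group
    mean by the log2-ER cutoff in EVERY include-sample and in NO
    exclude-sample.  Used to look for genes switched on in maturing fish
    (and endocrine-primed outliers) but not in fish showing only pituitary
    changes.
    """
    config = config or RunConfig()
    inc, exc, base = map(set, (include_samples, exclude_samples, baseline_samples))
    if (inc & exc) or (inc & base) or (exc & base):
        raise InputError("include/exclude/baseline sample sets must be disjoint")
    if not base:
        raise InputError("baseline sample set must be non-empty")
    if not inc:
        raise InputError("include sample set must be non-empty")
    log2 = matrix.log2
    baseline_mean = log2[list(baseline_samples)].mean(axis=1)
    threshold = baseline_mean + config.log2er_cutoff
    elevated_inc = log2[list(include_samples)].gt(threshold, axis=0).all(axis=1)
    if exclude_samples:
        elevated_exc = log2[list(exclude_samples)].gt(threshold, axis=0).any(axis=1)
    else:
        elevated_exc = pd.Series(False, index=log2.index)
    selected = elevated_inc & ~elevated_exc
    return [g for g in matrix.gene_ids if selected[g]]
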