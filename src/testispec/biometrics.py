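"""Biometric indices, maturity grouping, histology records, hormone statistics.

The maturity axis is the gonadosomatic index (GSI): gonad weight as a
percentage of body weight.  Fish below the immature ceiling (default 0.08 %)
are immature, fish at or above the pubertal floor (default 0.23 %) are
pubertal/maturing, and the gap between the thresholds is indeterminate —
those fish are retained in reports but excluded from two-group statistics.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import InputError, RunConfig


class Stage(enum.IntEnum):
    """Ordered germ-cell stages used for histological staging of the testis."""

    SPA = 1   # spermatogonia A (undifferentiated and differentiated)
    SPB = 2   # spermatogonia B
    SPC = 3   # spermatocytes
    SPT = 4   # spermatids
    SZ = 5    # spermatozoa

    @classmethod
    def parse(cls, label: str) -> "Stage":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise InputError(f"unknown germ-cell stage label: {label!r}") from None


IMMATURE = "immature"
PUBERTAL = "pubertal"
INDETERMINATE = "indeterminate"


@dataclasses.dataclass
class CohortRecord:
    """Per-fish biometrics and testis histology."""

    fish_id: str
    body_weight: float | None = None      # g
    fork_length: float | None = None      # cm
    gonad_weight: float | None = None     # g
    gsi: float | None = None              # percent
    most_advanced_stage: Stage = Stage.SPA
    dominant_stage: Stage = Stage.SPA
    compartment_size: str = "small"       # small | medium | large
    observations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.most_advanced_stage, str):
            self.most_advanced_stage = Stage.parse(self.most_advanced_stage)
        if isinstance(self.dominant_stage, str):
            self.dominant_stage = Stage.parse(self.dominant_stage)
        if self.dominant_stage > self.most_advanced_stage:
            raise InputError(
                f"fish {self.fish_id}: dominant stage {self.dominant_stage.name} "
                f"exceeds most advanced stage {self.most_advanced_stage.name}"
            )
        for field in ("body_weight", "fork_length"):
            v = getattr(self, field)
            if v is not None and v <= 0:
                raise InputError(f"fish {self.fish_id}: {field} must be > 0")
        if self.gonad_weight is not None and self.gonad_weight < 0:
            raise InputError(f"fish {self.fish_id}: gonad_weight must be >= 0")
        if self.gsi is None and None not in (self.gonad_weight, self.body_weight):
            self.gsi = compute_gsi(self.gonad_weight, self.body_weight)


def compute_gsi(gonad_weight: float, body_weight: float) -> float:
    """Gonadosomatic index (%): gonad weight / body weight x 100."""
    if body_weight <= 0:
        raise InputError(f"body weight must be > 0, got {body_weight}")
    if gonad_weight < 0:
        raise InputError(f"gonad weight must be >= 0, got {gonad_weight}")
    return gonad_weight / body_weight * 100.0


def compute_cf(body_weight: float, fork_length: float) -> float:
    """Fulton's condition factor: W / L^3 x 100 (W in g, L in cm)."""
    if body_weight <= 0 or fork_length <= 0:
        raise InputError("body weight and fork length must be > 0")
    return body_weight / fork_length**3 * 100.0


def assign_maturity_group(gsi: float, config: RunConfig | None = None) -> str:
    """Partition GSI into immature / indeterminate / pubertal.

    Immature is strict (< gsi_immature_max); pubertal is inclusive
    (>= gsi_pubertal_min); the gap in between is indeterminate.
    """
    config = config or RunConfig()
    if gsi < 0:
        raise InputError(f"GSI must be >= 0, got {gsi}")
    if gsi < config.gsi_immature_max:
        return IMMATURE
    if gsi >= config.gsi_pubertal_min:
        return PUBERTAL
    return INDETERMINATE


def maturity_groups(meta: pd.DataFrame, config: RunConfig | None = None
                    ) -> pd.Series:
    """Vectorised maturity labels for a metadata frame with a gsi column."""
    return meta["gsi"].map(lambda g: assign_maturity_group(g, config))


# --- cohort filters -------------------------------------------------------

def stage_above(stage: str | Stage) -> Callable[[CohortRecord], bool]:
    """Predicate: most advanced germ-cell stage strictly beyond `stage`."""
    threshold = Stage.parse(stage) if isinstance(stage, str) else stage
    return lambda rec: rec.most_advanced_stage > threshold


def has_observation(flag: str) -> Callable[[CohortRecord], bool]:
    """Predicate: observation notes contain `flag` (substring match)."""
    needle = flag.lower()
    return lambda rec: any(needle in obs.lower() for obs in rec.observations)


def dominant_stage_is(stage: str | Stage) -> Callable[[CohortRecord], bool]:
    target = Stage.parse(stage) if isinstance(stage, str) else stage
    return lambda rec: rec.dominant_stage == target


def filter_cohort(records: Sequence[CohortRecord],
                  predicate: Callable[[CohortRecord], bool]
                  ) -> tuple[list[CohortRecord], int]:
    """Order-preserving subset of the cohort plus its size."""
    subset = [r for r in records if predicate(r)]
    return subset, len(subset)


def read_cohort_tsv(path: str | Path) -> list[CohortRecord]:
    """Read a cohort TSV with the histology-overview columns."""
    df = pd.read_csv(path, sep="\t", dtype={"fish_id": str})
    records = []
    for _, row in df.iterrows():
        obs = row.get("observations")
        obs_t = tuple(s.strip() for s in str(obs).split(";") if s.strip()) \
            if isinstance(obs, str) and obs.strip() else ()

        def _num(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        records.append(CohortRecord(
            fish_id=str(row["fish_id"]),
            body_weight=_num("body_weight"),
            fork_length=_num("fork_length"),
            gonad_weight=_num("gonad_weight"),
            gsi=_num("gsi"),
            most_advanced_stage=row.get("most_advanced_stage", "SPA"),
            dominant_stage=row.get("dominant_stage", "SPA"),
            compartment_size=str(row.get("compartment_size", "small")),
            observations=obs_t,
        ))
    return records


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "fish_id": r.fish_id,
            "body_weight": r.body_weight,
            "fork_length": r.fork_length,
            "gonad_weight": r.gonad_weight,
            "gsi": r.gsi,
            "most_advanced_stage": r.most_advanced_stage.name,
            "dominant_stage": r.dominant_stage.name,
            "compartment_size": r.compartment_size,
            "observations": ";".join(r.observations),
        })
    return pd.DataFrame(rows)


# --- hormone panel statistics ---------------------------------------------

def _panel_wide(panel: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long hormone panel (fish_id, analyte, concentration) wide."""
    for col in ("fish_id", "analyte", "concentration"):
        if col not in panel.columns:
            raise InputError(f"hormone panel needs a {col!r} column")
    if panel.duplicated(["fish_id", "analyte"]).any():
        raise InputError("hormone panel has duplicate (fish, analyte) pairs")
    if (panel["concentration"] < 0).any():
        raise InputError("hormone concentrations must be >= 0")
    return panel.pivot(index="fish_id", columns="analyte", values="concentration")


def correlate_with_index(panel: pd.DataFrame, index: pd.Series,
                         summary_analytes: Iterable[str] | None = None
                         ) -> tuple[pd.Series, float, float]:
    """Pearson product-moment r of each analyte against a per-fish index.

    Returns (per-analyte r, mean r, SD of r) where mean/SD are over
    `summary_analytes` (all analytes when None).  Analytes with fewer than
    three paired observations or zero variance are NaN, never a hard error.
    """
    wide = _panel_wide(panel)
    index = index.astype(float)
    if index.nunique() <= 1:
        raise InputError("index has zero variance")
    out = {}
    for analyte in wide.columns:
        paired = pd.concat([wide[analyte], index], axis=1, join="inner").dropna()
        x, y = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[analyte] = np.nan
            continue
        out[analyte] = stats.pearsonr(x, y).statistic
    r = pd.Series(out, name="pearson_r")
    chosen = r[list(summary_analytes)] if summary_analytes is not None else r
    valid = chosen.dropna()
    mean_r = float(valid.mean()) if len(valid) else float("nan")
    sd_r = float(valid.std(ddof=1)) if len(valid) > 1 else float("nan")
    return r, mean_r, sd_r


def group_fold(panel: pd.DataFrame, groups: pd.Series,
               geometric: bool = False) -> pd.Series:
    """Per-analyte fold of the pubertal group mean over the immature mean.

    Means are arithmetic on the linear concentration scale by default;
    `geometric=True` switches to geometric means (zeros excluded there).
    Indeterminate fish are ignored.  An immature mean of zero yields NaN.
    """
    wide = _panel_wide(panel)
    groups = groups.reindex(wide.index)
    pub = wide[groups == PUBERTAL]
    imm = wide[groups == IMMATURE]
    if pub.empty or imm.empty:
        raise InputError("both maturity groups must be non-empty")
    if geometric:
        def gmean(df):
            return np.exp(np.log(df.where(df > 0)).mean())
        num, den = gmean(pub), gmean(imm)
    else:
        num, den = pub.mean(), imm.mean()
    fold = num / den.replace(0.0, np.nan)
    fold.name = "fold"
    return fold


def group_difference_test(panel: pd.DataFrame, groups: pd.Series,
                          welch: bool = True) -> pd.Series:
    """Two-sample t-test p-value per analyte, pubertal vs immature.

    Welch's unequal-variance form by default (group sizes are unbalanced);
    `welch=False` uses the pooled-variance test.  Analytes with fewer than
    two fish in either group are NaN.  Two constant, equal groups give p = 1.
    """
    wide = _panel_wide(panel)
    groups = groups.reindex(wide.index)
    pub = wide[groups == PUBERTAL]
    imm = wide[groups == IMMATURE]
    out = {}
    for analyte in wide.columns:
        a = pub[analyte].dropna().to_numpy()
        b = imm[analyte].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            out[analyte] = np.nan
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            out[analyte] = 1.0 if a[0] == b[0] else 0.0
            continue
        out[analyte] = stats.ttest_ind(a, b, equal_var=not welch).pvalue
    return pd.Series(out, name="p_value")
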