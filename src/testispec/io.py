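"""Tabular input/output, run configuration, and seed plumbing.

The canonical interchange format is plain TSV (UTF-8, header row, genes in
rows).  Expression values are linear-scale intensities; a configurable floor
is applied on read so that log2 is always defined.  A minimal reader for the
GEO Series Matrix dialect is provided as a convenience for working with
deposited microarray series.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("testispec")

TESTIS = "testis"
OVARY = "ovary"
PITUITARY = "pituitary"


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Analysis thresholds and seed.

    Defaults are the study-wide criteria: log2 expression-ratio cutoff 0.8
    (1.75-fold) with p < 0.05 for calling differential specific activity,
    GSI < 0.08 % for immature and GSI >= 0.23 % for pubertal fish, and the
    eight-fold-over-average rule for gonad-specific genes.
    """

    log2er_cutoff: float = 0.8
    alpha: float = 0.05
    gsi_immature_max: float = 0.08
    gsi_pubertal_min: float = 0.23
    gsg_fold_threshold: float = 8.0
    intensity_floor: float = 1.0
    rng_seed: int = 0
    # non-headline switches
    welch: bool = True                 # pooled-variance t-test when False
    geometric_hormone_fold: bool = False
    multiple_testing: str = "none"     # "none" | "bh"
    min_set_size: int = 10
    set_test: str = "t"                # "t" | "permutation"
    n_permutations: int = 10_000
    gsg_include_targets_in_average: bool = True
    gsg_absence_floor: float = 2.0     # linear intensity
    gsg_absence_rel: float = 0.1       # fraction of the gonad maximum

    def __post_init__(self) -> None:
        if self.log2er_cutoff <= 0:
            raise InputError("log2er_cutoff must be > 0")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")
        if self.gsi_immature_max >= self.gsi_pubertal_min:
            raise InputError(
                "gsi_immature_max must be below gsi_pubertal_min "
                f"(got {self.gsi_immature_max} >= {self.gsi_pubertal_min})"
            )
        if self.gsg_fold_threshold <= 0:
            raise InputError("gsg_fold_threshold must be > 0")
        if self.intensity_floor <= 0:
            raise InputError("intensity_floor must be > 0")
        if self.multiple_testing not in ("none", "bh"):
            raise InputError("multiple_testing must be 'none' or 'bh'")
        if self.set_test not in ("t", "permutation"):
            raise InputError("set_test must be 't' or 'permutation'")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from a YAML/JSON key-value file.

    Absent keys take their defaults; unknown keys are a hard error so typos
    cannot silently disable a threshold.  Keyword overrides are applied on
    top of the file.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise InputError(f"config file {path} must be a key-value mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)


class ExpressionMatrix:
    """Genes x samples matrix of linear-scale intensities.

    Wraps a pandas DataFrame (index = gene ids, columns = sample ids) and
    enforces uniqueness, finiteness, and strict positivity after flooring.
    """

    def __init__(self, values: pd.DataFrame, floor: float = 1.0):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise InputError(f"duplicate gene identifier: {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise InputError(f"duplicate sample identifier: {dup!r}")
        arr = values.to_numpy(dtype=float, copy=True)
        if not np.isfinite(np.nan_to_num(arr, nan=0.0)).all():
            raise InputError("expression matrix contains infinite values")
        # NaN and non-positive cells are raised to the floor; values already
        # strictly positive are left untouched
        arr = np.where(np.isnan(arr) | (arr <= 0), floor, arr)
        self._df = pd.DataFrame(arr, index=values.index.astype(str),
                                columns=values.columns.astype(str))
        self.floor = float(floor)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        """Linear-scale intensities (floored, strictly positive)."""
        return self._df

    @property
    def log2(self) -> pd.DataFrame:
        """Log2 view of the intensities."""
        return np.log2(self._df)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self._df.columns]
        if missing:
            raise InputError(f"unknown sample identifiers: {missing}")
        return ExpressionMatrix(self._df[ids], floor=self.floor)

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self._df.equals(other._df)


def read_expression_tsv(path: str | Path, orientation: str = "genes_in_rows",
                        floor: float = 1.0) -> ExpressionMatrix:
    """Read a TSV expression table (first column = gene ids by default).

    ``orientation='samples_in_rows'`` transposes the parsed table.  Duplicate
    identifiers and non-numeric cells are hard errors naming the offender.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise InputError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gi = bad.any(axis=1).idxmax()
        si = bad.loc[gi].idxmax()
        raise InputError(
            f"non-numeric value {df.loc[gi, si]!r} at gene {gi!r}, column {si!r}"
        )
    if orientation == "samples_in_rows":
        numeric = numeric.T
    return ExpressionMatrix(numeric, floor=floor)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path,
                         index_name: str = "gene_id") -> None:
    df = matrix.values.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, fish_id, tissue, biometrics, gsi).

    GSI is derived from gonad and body weight where absent.  Weights and
    lengths must be strictly positive when present.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "fish_id": str})
    if "sample_id" not in meta.columns:
        raise InputError("metadata must contain a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise InputError(f"duplicate sample identifier: {dup!r}")
    for col in ("body_weight", "fork_length", "gonad_weight"):
        if col in meta.columns:
            vals = pd.to_numeric(meta[col], errors="raise")
            if col != "gonad_weight" and (vals.dropna() <= 0).any():
                raise InputError(f"{col} must be strictly positive")
            if col == "gonad_weight" and (vals.dropna() < 0).any():
                raise InputError("gonad_weight must be nonnegative")
            meta[col] = vals
    if "gsi" not in meta.columns:
        if {"gonad_weight", "body_weight"} <= set(meta.columns):
            meta["gsi"] = meta["gonad_weight"] / meta["body_weight"] * 100.0
        else:
            raise InputError("metadata must provide gsi or gonad/body weights")
    return meta


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read gene annotation (gene_id, functional_group[, gonad_specific]).

    Multi-membership is expressed by repeated gene_id rows; the result keeps
    one row per (gene, group) pair.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in ann.columns or "functional_group" not in ann.columns:
        raise InputError("annotation needs gene_id and functional_group columns")
    if (ann["functional_group"].fillna("") == "").any():
        raise InputError("functional_group labels must be non-empty")
    if ann.duplicated(["gene_id", "functional_group"]).any():
        ann = ann.drop_duplicates(["gene_id", "functional_group"])
    return ann


def read_geo_series_matrix(path: str | Path, floor: float = 1.0
                           ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Parse a GEO Series Matrix file into (ExpressionMatrix, metadata).

    Handles the flat-text dialect: "!"-prefixed key-value header lines and a
    tab-separated table between the series-matrix-table begin/end markers.
    Sample titles (quoted in the header) populate the metadata.  Convenience
    only — the TSV readers are the canonical path.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    titles: list[str] = []
    accessions: list[str] = []
    table: list[list[str]] = []
    in_table = False
    saw_begin = saw_end = False
    for line in lines:
        if line.startswith("!series_matrix_table_begin"):
            in_table, saw_begin = True, True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table, saw_end = False, True
            continue
        if in_table:
            table.append(line.split("\t"))
        elif line.startswith("!Sample_title"):
            titles = [f.strip().strip('"') for f in line.split("\t")[1:]]
        elif line.startswith("!Sample_geo_accession"):
            accessions = [f.strip().strip('"') for f in line.split("\t")[1:]]
    if not (saw_begin and saw_end):
        raise InputError("series matrix table markers not found")
    if not table:
        raise InputError("series matrix table is empty")
    header = [f.strip().strip('"') for f in table[0]]
    ncol = len(header)
    rows, index = [], []
    for raw in table[1:]:
        if len(raw) != ncol:
            raise InputError(
                f"row {raw[0]!r} has {len(raw)} fields, header has {ncol}"
            )
        index.append(raw[0].strip().strip('"'))
        rows.append([float(v) for v in raw[1:]])
    df = pd.DataFrame(rows, index=index, columns=header[1:])
    matrix = ExpressionMatrix(df, floor=floor)
    meta = pd.DataFrame({"sample_id": matrix.sample_ids})
    if titles and len(titles) == len(matrix.sample_ids):
        meta["title"] = titles
    if accessions and len(accessions) == len(matrix.sample_ids):
        meta["geo_accession"] = accessions
    return matrix, meta


def write_manifest(path: str | Path, config: RunConfig, seed: int,
                   inputs: dict[str, str], outputs: dict[str, str]) -> None:
    """Write a JSON manifest sufficient to reproduce a pipeline run."""
    import testispec

    payload = {
        "package": "testispec",
        "version": testispec.__version__,
        "seed": int(seed),
        "config": dataclasses.asdict(config),
        "inputs": inputs,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
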