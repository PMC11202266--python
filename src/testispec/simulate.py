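"""Seeded generators for every input the pipeline consumes, with ground truth.

The generative model for the testis transcriptome is a two-compartment
mixture.  Whole-testis RNA is a blend of a germinative compartment (Sertoli
cells and germ-cell cysts), whose proportion pi rises steeply during
puberty, and an interstitial compartment (Leydig cells, vessels, immune and
connective elements).  The expected intensity of gene g in sample s is

    E[I(g, s)] = pi_s * G_g * r_{g, group(s)} + (1 - pi_s) * S_g

where G_g and S_g are the gene's compartment expression levels, and r is a
transcriptional-regulation multiplier acting in the germinative compartment
(1 for unregulated genes).  Multiplicative log-normal noise is applied on
top.  Genes expressed in only one compartment therefore shift in apparent
"specific activity" purely through compartment growth, even with zero
regulation — the central confound the analysis must acknowledge.

A single global seed fans out to independent per-generator child streams
via numpy's SeedSequence.spawn with fixed child indices (cohort 0, testis
matrix 1, compendium 2, hormones 3), so any generator can be re-run in
isolation and reproduce its slice of a full run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, InputError, OVARY, TESTIS
from .biometrics import CohortRecord, Stage

_CHILD = {"cohort": 0, "testis": 1, "compendium": 2, "hormones": 3}

ANDROGEN_ANALYTES = (
    "androstenedione",
    "4-androsten-11B-OL3",
    "4-androsten-17B-OL3",
    "4-androsten-3-11-17-trione",
    "testosterone",
)
CORTISOL_ANALYTES = ("cortisol", "corticosterone")

OTHER_TISSUES = (
    "liver", "brain", "muscle", "gill", "heart", "head_kidney", "kidney",
    "spleen", "skin", "intestine", "pyloric_caeca", "stomach", "eye",
    "nose", "fin", "blood", "adipose", "pituitary",
)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation conditions.

    Defaults mirror the study cohort: 20 post-smolt males split 14 immature
    (GSI 0.01-0.08 %) and 6 pubertal (GSI 0.23-0.60 %), germinative
    proportion rising from ~0.3 to ~0.8, five androgen-like serum analytes
    correlated with GSI at r = 0.83 and elevated 7.5-9-fold in the pubertal
    group, plus GSI-independent cortisol-like analytes.
    """

    n_genes: int = 2000
    n_immature: int = 14
    n_pubertal: int = 6
    gsi_immature_range: tuple[float, float] = (0.01, 0.08)
    gsi_pubertal_range: tuple[float, float] = (0.23, 0.60)
    # compartment mixture
    pi_immature_mean: float = 0.3
    pi_pubertal_mean: float = 0.8
    pi_jitter_sd: float = 0.05
    frac_germinative: float = 0.25     # germinative-exclusive genes
    frac_interstitial: float = 0.25    # interstitial-exclusive genes
    # (remaining fraction is shared genes with equal compartment levels)
    regulated_fraction: float = 0.05
    regulation_log2_effect: float = 2.0
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    # biometrics
    body_weight_mean: float = 1017.0   # g
    body_weight_sd: float = 82.0
    cf_mean: float = 1.44
    cf_sd: float = 0.08
    oocyte_count: int = 3              # immature fish flagged with oocytes
    tubule_count: int = 2              # immature fish with tubule observations
    # tissue compendium
    n_compendium_genes: int = 1000
    n_gsg_planted: int = 50
    gsg_margin: float = 2.0            # multiple of the 8-fold threshold
    n_decoy_ubiquitous: int = 20
    n_decoy_liver: int = 20
    compendium_background: float = 24.0
    compendium_noise_sd_log2: float = 0.5
    # hormones
    hormone_true_r: float = 0.83
    androgen_folds: tuple[float, ...] = (7.5, 8.0, 8.5, 9.0, 7.8)
    androgen_immature_mean: float = 2.0   # nmol/L
    cortisol_mean: float = 10.0           # nmol/L
    cortisol_noise_sd_log2: float = 0.5
    progesterone_fold: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_immature < 2 or self.n_pubertal < 2:
            raise InputError("need at least two fish per maturity group")
        for lo, hi in (self.gsi_immature_range, self.gsi_pubertal_range):
            if not 0 <= lo < hi:
                raise InputError(f"invalid GSI range ({lo}, {hi})")
        if self.gsi_immature_range[1] > self.gsi_pubertal_range[0]:
            raise InputError("immature GSI range must lie below pubertal range")
        if not 0 < self.pi_immature_mean < 1 or not 0 < self.pi_pubertal_mean < 1:
            raise InputError("germinative proportions must lie in (0, 1)")
        fr = self.frac_germinative + self.frac_interstitial
        if not 0 <= fr <= 1:
            raise InputError("compartment-exclusive fractions must sum within [0, 1]")
        if not 0 <= self.regulated_fraction < 1:
            raise InputError("regulated_fraction must lie in [0, 1)")
        if abs(self.hormone_true_r) >= 1:
            raise InputError("hormone_true_r must satisfy |r| < 1")
        if self.oocyte_count > self.n_immature:
            raise InputError("cannot flag more oocyte fish than immature fish")

    @property
    def frac_shared(self) -> float:
        return 1.0 - self.frac_germinative - self.frac_interstitial


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    genes: pd.DataFrame | None = None      # compartment levels, regulation
    samples: pd.DataFrame | None = None    # per-sample pi, gsi, group
    gsg_flags: pd.Series | None = None     # compendium planted labels
    analytes: pd.DataFrame | None = None   # hormone model parameters


def _rng(config: SimulationConfig, seed: int | None, stage: str
         ) -> np.random.Generator:
    base = config.rng_seed if seed is None else seed
    child = np.random.SeedSequence(base).spawn(max(_CHILD.values()) + 1)
    return np.random.default_rng(child[_CHILD[stage]])


def _group_gsi(config: SimulationConfig, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
    imm = rng.uniform(*config.gsi_immature_range, size=config.n_immature)
    pub = rng.uniform(*config.gsi_pubertal_range, size=config.n_pubertal)
    return imm, pub


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Cohort biometrics, histology and testis sample metadata.

    GSI is uniform within each group's range; body weight and condition
    factor are normal around the cohort means, with fork length derived.
    Pubertal fish carry advanced germ-cell stages and enlarged germinative
    compartments; oocyte observations are planted only among immature fish,
    as are "tubules, high cell division" notes.
    """
    config = config or SimulationConfig()
    rng = _rng(config, seed, "cohort")
    gsi_imm, gsi_pub = _group_gsi(config, rng)
    gsi = np.concatenate([gsi_imm, gsi_pub])
    n = len(gsi)
    weight = np.clip(rng.normal(config.body_weight_mean, config.body_weight_sd, n),
                     100.0, None)
    cf = np.clip(rng.normal(config.cf_mean, config.cf_sd, n), 0.5, None)
    length = np.cbrt(weight / cf * 100.0)
    gonad = gsi * weight / 100.0

    oocyte_ids = rng.choice(config.n_immature, size=config.oocyte_count,
                            replace=False)
    remaining = np.setdiff1d(np.arange(config.n_immature), oocyte_ids)
    tubule_ids = rng.choice(remaining,
                            size=min(config.tubule_count, len(remaining)),
                            replace=False)

    records: list[CohortRecord] = []
    for i in range(n):
        pubertal = i >= config.n_immature
        if pubertal:
            most = Stage(rng.choice([Stage.SPC, Stage.SPT, Stage.SZ]))
            dominant = Stage(rng.choice([s for s in (Stage.SPB, Stage.SPC)
                                         if s <= most]))
            size = "large" if most >= Stage.SPT else "medium"
            obs: tuple[str, ...] = ()
        else:
            most = dominant = Stage.SPA
            if i in tubule_ids:
                size, obs = "medium", ("tubules", "high cell division")
            elif i in oocyte_ids:
                size, obs = "small", ("oocytes",)
            else:
                size, obs = "small", ()
        records.append(CohortRecord(
            fish_id=f"F{i + 1:03d}",
            body_weight=round(float(weight[i]), 1),
            fork_length=round(float(length[i]), 2),
            gonad_weight=round(float(gonad[i]), 4),
            gsi=float(gsi[i]),
            most_advanced_stage=most,
            dominant_stage=dominant,
            compartment_size=size,
            observations=obs,
        ))
    meta = pd.DataFrame({
        "sample_id": [r.fish_id for r in records],
        "fish_id": [r.fish_id for r in records],
        "tissue": TESTIS,
        "body_weight": [r.body_weight for r in records],
        "fork_length": [r.fork_length for r in records],
        "gonad_weight": [r.gonad_weight for r in records],
        "gsi": [r.gsi for r in records],
    })
    return records, meta


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lo: float = 1e-6, hi: float = 1 - 1e-6
                      ) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_testis_matrix(config: SimulationConfig | None = None,
                           seed: int | None = None,
                           metadata: pd.DataFrame | None = None
                           ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-compartment testis expression with planted regulation.

    Gene categories: germinative-exclusive (S_g = 0), interstitial-exclusive
    (G_g = 0), and shared genes with G_g = S_g, so that a shared unregulated
    gene is invariant to compartment proportions.  Regulation acts
    multiplicatively in the germinative compartment of pubertal samples and
    is planted only on germinative-expressed genes.  Noise is multiplicative
    log-normal with the configured log2-scale SD.
    """
    config = config or SimulationConfig()
    rng = _rng(config, seed, "testis")
    if metadata is None:
        gsi_imm, gsi_pub = _group_gsi(config, _rng(config, seed, "cohort"))
        gsi = np.concatenate([gsi_imm, gsi_pub])
        sample_ids = [f"F{i + 1:03d}" for i in range(len(gsi))]
    else:
        gsi = metadata["gsi"].to_numpy(dtype=float)
        sample_ids = list(metadata["sample_id"].astype(str))
    n_samples = len(gsi)
    pubertal = np.arange(n_samples) >= config.n_immature

    pi = np.empty(n_samples)
    pi[~pubertal] = _truncated_normal(rng, config.pi_immature_mean,
                                      config.pi_jitter_sd, int((~pubertal).sum()))
    pi[pubertal] = _truncated_normal(rng, config.pi_pubertal_mean,
                                     config.pi_jitter_sd, int(pubertal.sum()))

    n = config.n_genes
    n_germ = int(round(n * config.frac_germinative))
    n_inter = int(round(n * config.frac_interstitial))
    category = np.array(["shared"] * n, dtype=object)
    category[:n_germ] = "germinative"
    category[n_germ:n_germ + n_inter] = "interstitial"

    base = np.exp2(rng.normal(config.baseline_log2_mean,
                              config.baseline_log2_sd, n))
    G = base.copy()
    S = base.copy()
    G[category == "interstitial"] = 0.0
    S[category == "germinative"] = 0.0

    expressed_germ = np.flatnonzero(category != "interstitial")
    n_reg = int(round(n * config.regulated_fraction))
    if n_reg > len(expressed_germ):
        raise InputError("regulated_fraction exceeds germinative-expressed genes")
    regulated_idx = rng.choice(expressed_germ, size=n_reg, replace=False)
    regulated = np.zeros(n, dtype=bool)
    regulated[regulated_idx] = True
    multiplier = np.where(regulated, np.exp2(config.regulation_log2_effect), 1.0)

    r_matrix = np.where(pubertal[None, :], multiplier[:, None], 1.0)
    expected = pi[None, :] * G[:, None] * r_matrix + (1 - pi[None, :]) * S[:, None]
    if config.noise_sd_log2 > 0:
        noise = np.exp2(rng.normal(0.0, config.noise_sd_log2, expected.shape))
    else:
        noise = 1.0
    intensities = expected * noise

    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame(intensities, index=gene_ids, columns=sample_ids),
        floor=1.0,
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame({
            "category": category,
            "germinative_level": G,
            "interstitial_level": S,
            "regulated": regulated,
            "pubertal_multiplier": multiplier,
        }, index=pd.Index(gene_ids, name="gene_id")),
        samples=pd.DataFrame({
            "sample_id": sample_ids,
            "gsi": gsi,
            "pi": pi,
            "group": np.where(pubertal, "pubertal", "immature"),
        }).set_index("sample_id"),
    )
    return matrix, truth


def generate_compendium(config: SimulationConfig | None = None,
                        seed: int | None = None,
                        gene_ids: list[str] | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Multi-tissue mean-expression compendium with planted gonad-specific genes.

    Planted genes sit at an exact gonad-over-average score of
    gsg_margin x 8 (background tissues are noise-free for these rows so the
    boundary margin 1.0 lands exactly on the inclusive threshold).  Decoys
    include ubiquitously high genes and gonad-high-but-also-liver-high
    genes; the remaining background genes carry log-normal noise.

    When `gene_ids` is supplied (e.g. the gene universe of a simulated
    expression matrix), compendium rows are named by a seeded draw from it,
    so gonad-specificity calls join onto the expression results.
    """
    config = config or SimulationConfig()
    rng = _rng(config, seed, "compendium")
    tissues = [TESTIS, OVARY, *OTHER_TISSUES]
    n_tissues = len(tissues)
    score = config.gsg_margin * 8.0
    if score >= n_tissues:
        raise InputError(
            f"requested score {score} unreachable with {n_tissues} tissues"
        )
    n_planted = config.n_gsg_planted
    n_decoy = config.n_decoy_ubiquitous + config.n_decoy_liver
    n_background = config.n_compendium_genes - n_planted - n_decoy
    if n_background < 0:
        raise InputError("n_compendium_genes too small for planted + decoys")
    b = config.compendium_background

    rows, flags, internal_ids = [], [], []
    sum_others = (n_tissues - 1) * b
    target_value = score * sum_others / (n_tissues - score)
    for i in range(n_planted):
        gonad = TESTIS if i % 2 == 0 else OVARY
        row = {t: b for t in tissues}
        row[gonad] = target_value
        rows.append(row)
        flags.append(True)
        internal_ids.append(f"GSG{i + 1:04d}")
    for i in range(config.n_decoy_ubiquitous):
        level = b * float(np.exp2(rng.uniform(3, 5)))
        rows.append({t: level for t in tissues})
        flags.append(False)
        internal_ids.append(f"UBIQ{i + 1:04d}")
    for i in range(config.n_decoy_liver):
        row = {t: b for t in tissues}
        row[TESTIS] = row["liver"] = target_value
        rows.append(row)
        flags.append(False)
        internal_ids.append(f"LIVR{i + 1:04d}")
    bg = b * np.exp2(rng.normal(0.0, config.compendium_noise_sd_log2,
                                size=(n_background, n_tissues)))
    for i in range(n_background):
        rows.append(dict(zip(tissues, bg[i])))
        flags.append(False)
        internal_ids.append(f"BG{i + 1:05d}")

    if gene_ids is not None:
        if len(gene_ids) < len(rows):
            raise InputError(
                f"need {len(rows)} gene ids for the compendium, got "
                f"{len(gene_ids)}"
            )
        row_ids = list(rng.choice(np.asarray(gene_ids, dtype=object),
                                  size=len(rows), replace=False))
    else:
        row_ids = internal_ids
    compendium = pd.DataFrame(rows, index=pd.Index(row_ids, name="gene_id"),
                              columns=tissues)
    planted = pd.Series(flags, index=compendium.index, name="planted_gsg")
    return compendium, planted


def gsi_mixture_moments(config: SimulationConfig) -> tuple[float, float]:
    """Population mean and variance of GSI under the two-group uniform mixture."""
    n1, n2 = config.n_immature, config.n_pubertal
    w1, w2 = n1 / (n1 + n2), n2 / (n1 + n2)
    (a1, b1), (a2, b2) = config.gsi_immature_range, config.gsi_pubertal_range
    m1, m2 = (a1 + b1) / 2, (a2 + b2) / 2
    v1, v2 = (b1 - a1) ** 2 / 12, (b2 - a2) ** 2 / 12
    mean = w1 * m1 + w2 * m2
    var = w1 * v1 + w2 * v2 + w1 * (m1 - mean) ** 2 + w2 * (m2 - mean) ** 2
    return mean, var


def _androgen_model(config: SimulationConfig, fold: float,
                    mu_i: float | None = None, mu_p: float | None = None
                    ) -> tuple[float, float, float]:
    """Slope, intercept and noise CV for one androgen-like analyte.

    Concentration is linear in GSI, anchored so the pubertal/immature group
    mean ratio equals `fold`, with additive Gaussian noise whose SD is
    proportional to the noise-free level (constant CV).  The CV is solved
    from r^2 = var(signal) / var(total) with var(noise) = cv^2 E[signal^2],
    so the requested population correlation is met by construction.

    mu_i / mu_p default to the population group-mean GSI (range midpoints);
    passing realized sample means instead anchors the fold exactly on a
    particular cohort.
    """
    (a1, b1), (a2, b2) = config.gsi_immature_range, config.gsi_pubertal_range
    if mu_i is None:
        mu_i = (a1 + b1) / 2
    if mu_p is None:
        mu_p = (a2 + b2) / 2
    max_fold = mu_p / mu_i
    if not 0 < fold <= max_fold:
        raise InputError(
            f"fold {fold} outside (0, {max_fold:.2f}] attainable under a "
            "linear-in-GSI model with nonnegative concentrations"
        )
    m_i = config.androgen_immature_mean
    slope = (fold - 1.0) * m_i / (mu_p - mu_i)
    intercept = m_i - slope * mu_i
    mean_gsi, var_gsi = gsi_mixture_moments(config)
    r = config.hormone_true_r
    var_signal = slope**2 * var_gsi
    mean_signal = intercept + slope * mean_gsi
    cv2 = var_signal * (1 - r**2) / (r**2 * (var_signal + mean_signal**2))
    return slope, intercept, float(np.sqrt(cv2))


def generate_hormones(config: SimulationConfig | None = None,
                      seed: int | None = None,
                      gsi: pd.Series | None = None,
                      anchor: str = "population",
                      noise_scale: float = 1.0
                      ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Serum analyte panel: GSI-linked androgens plus GSI-independent steroids.

    Five androgen-like analytes follow the calibrated linear-in-GSI model
    (population Pearson r = hormone_true_r against GSI), progesterone uses a
    smaller fold, and cortisol-like analytes are generated independent of
    GSI (log-normal around cortisol_mean).  Rare negative draws (< ~2 % at
    the default correlation) are clipped to zero to respect nonnegative
    concentrations.

    anchor='sample' anchors the planted group fold on the realized group
    mean GSI of this cohort rather than the population midpoints, so with
    noise_scale=0 the recovered pubertal/immature fold is exact.
    """
    config = config or SimulationConfig()
    if anchor not in ("population", "sample"):
        raise InputError(f"anchor must be 'population' or 'sample', got {anchor!r}")
    rng = _rng(config, seed, "hormones")
    if gsi is None:
        gsi_imm, gsi_pub = _group_gsi(config, _rng(config, seed, "cohort"))
        values = np.concatenate([gsi_imm, gsi_pub])
        fish_ids = [f"F{i + 1:03d}" for i in range(len(values))]
    else:
        values = gsi.to_numpy(dtype=float)
        fish_ids = list(gsi.index.astype(str))

    mu_i = mu_p = None
    if anchor == "sample":
        mu_i = float(values[:config.n_immature].mean())
        mu_p = float(values[config.n_immature:].mean())

    records, truth_rows = [], []
    analyte_folds = list(zip(ANDROGEN_ANALYTES, config.androgen_folds))
    analyte_folds.append(("progesterone", config.progesterone_fold))
    for analyte, fold in analyte_folds:
        slope, intercept, cv = _androgen_model(config, fold, mu_i, mu_p)
        signal = intercept + slope * values
        noise = rng.normal(0.0, 1.0, len(values)) * cv * signal * noise_scale
        conc = np.clip(signal + noise, 0.0, None)
        for fid, c in zip(fish_ids, conc):
            records.append({"fish_id": fid, "analyte": analyte,
                            "concentration": float(c)})
        truth_rows.append({"analyte": analyte, "kind": "gsi_linked",
                           "true_r": config.hormone_true_r, "fold": fold,
                           "slope": slope, "intercept": intercept, "cv": cv})
    for analyte in CORTISOL_ANALYTES:
        conc = config.cortisol_mean * np.exp2(
            rng.normal(0.0, config.cortisol_noise_sd_log2, len(values)))
        for fid, c in zip(fish_ids, conc):
            records.append({"fish_id": fid, "analyte": analyte,
                            "concentration": float(c)})
        truth_rows.append({"analyte": analyte, "kind": "independent",
                           "true_r": 0.0, "fold": 1.0,
                           "slope": 0.0, "intercept": config.cortisol_mean,
                           "cv": np.nan})
    panel = pd.DataFrame(records)
    truth = SyntheticTruth(
        analytes=pd.DataFrame(truth_rows).set_index("analyte"),
        samples=pd.DataFrame({"fish_id": fish_ids, "gsi": values})
        .set_index("fish_id"),
    )
    return panel, truth


def generate_annotation(truth: SyntheticTruth, n_groups: int = 8,
                        seed: int | None = 0) -> pd.DataFrame:
    """Functional-group annotation over simulated genes.

    Groups are sampled within gene categories so that some groups are
    enriched for germinative- or interstitial-exclusive genes (and hence
    show coordinated shifts under compartment growth), while mixed groups
    act as null sets.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    rows = []
    categories = ("germinative", "interstitial", "shared")
    for i in range(n_groups):
        cat = categories[i % len(categories)]
        pool = genes.index[genes["category"] == cat]
        size = int(rng.integers(20, 60))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        for g in members:
            rows.append({"gene_id": g, "functional_group": f"{cat}_set_{i + 1}"})
    return pd.DataFrame(rows)
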