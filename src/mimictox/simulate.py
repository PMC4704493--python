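"""Seeded generators for every input the pipeline consumes.

The screen generator emulates a genome-scale miRNA-mimic viability
screen: 400 mimics x 16 cell lines in biological triplicate on 8x12
plates, with multiplicative lognormal row/position, batch and replicate
noise on luminescence, one negative-control well per plate row, seed
families whose members share a correlated latent phenotype, planted
cell-line groups, and a mix of "private" sensitivities (1-2 responsive
lines, the dominant architecture) and "public" ones (up to 9 lines).
Ground truth is returned alongside the data so every downstream stage can
be scored without external data.  All generators are pure functions of
(config, seed): repeat calls are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (NEGATIVE_CONTROL, MimicAnnotations, PhenocopyPanel,
                        ScreenPlate)
from .errors import ConfigError

_RNA = np.array(list("ACGU"))


# ------------------------------------------------------------------ screen

@dataclass
class ScreenSimConfig:
    """Study-scale defaults for the simulated mimic screen.

    Noise scales are lognormal sigmas on luminescence; ``effect_range``
    is the fractional viability reduction of a planted sensitive
    (mimic, line) cell; ``responsive_count_probs[i]`` is the probability
    that a sensitive mimic responds in exactly i+1 lines (mass on 1-2
    lines with a tail to 9).
    """
    n_mimics: int = 400
    n_lines: int = 16
    n_replicates: int = 3
    n_rows: int = 8
    n_cols: int = 12
    baseline_lum: float = 1e6
    row_effect_sd: float = 0.15
    batch_effect_sd: float = 0.10
    replicate_noise_sd: float = 0.05
    n_line_groups: int = 5
    group_effect_sd: float = 0.08
    line_noise_sd: float = 0.02
    intra_family_rho: float = 0.8
    family_member_fraction: float = 0.6
    duplicate_fraction: float = 0.08
    hit_fraction: float = 0.27
    responsive_count_probs: tuple[float, ...] = (
        0.55, 0.25, 0.07, 0.05, 0.03, 0.02, 0.015, 0.01, 0.005)
    effect_range: tuple[float, float] = (0.5, 0.8)
    control_id: str = NEGATIVE_CONTROL

    def __post_init__(self):
        if not 0 <= self.intra_family_rho <= 1:
            raise ConfigError("intra_family_rho must be in [0, 1]")
        lo, hi = self.effect_range
        if not 0 <= lo <= hi <= 1:
            raise ConfigError("effect_range must lie within [0, 1]")
        if abs(sum(self.responsive_count_probs) - 1) > 1e-9:
            raise ConfigError("responsive_count_probs must sum to 1")
        if len(self.responsive_count_probs) > self.n_lines:
            raise ConfigError("responsive-count support exceeds n_lines")
        if self.n_cols < 2 or self.n_rows < 1:
            raise ConfigError("plate geometry must allow mimics plus controls")
        if self.mimics_per_plate < 1:
            raise ConfigError("plate geometry leaves no room for mimics")

    @property
    def mimics_per_plate(self) -> int:
        # column 1 of every row is reserved for the negative control
        return self.n_rows * (self.n_cols - 1)

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_mimics / self.mimics_per_plate)


@dataclass
class ScreenTruth:
    """Planted ground truth for a simulated screen."""
    sensitive: pd.DataFrame          # bool, mimics x lines
    effects: pd.DataFrame            # fractional viability reduction
    viability: pd.DataFrame          # latent mean relative viability
    line_groups: pd.Series           # cell line -> planted group id
    config: ScreenSimConfig = field(repr=False, default=None)


def _random_sequences(rng: np.random.Generator, cfg: ScreenSimConfig
                      ) -> tuple[list[str], pd.Series]:
    """Mature sequences with seed-family structure and a fraction of
    full-sequence duplicates (distinct reagent ids, one mature miRNA)."""
    n_dup = int(round(cfg.duplicate_fraction * cfg.n_mimics))
    n_base = cfg.n_mimics - n_dup
    # family sizes for the multi-member fraction of base mimics
    n_in_families = int(round(cfg.family_member_fraction * n_base))
    sizes = []
    remaining = n_in_families
    while remaining >= 2:
        size = int(rng.integers(2, 5))
        size = min(size, remaining)
        if size < 2:
            break
        sizes.append(size)
        remaining -= size
    seqs: list[str] = []
    fam_of: list[int] = []
    fam_idx = 0
    for size in sizes:
        seed7 = "".join(rng.choice(_RNA, 7))
        for _ in range(size):
            flank5 = "".join(rng.choice(_RNA, 1))
            flank3 = "".join(rng.choice(_RNA, 14))
            seqs.append(flank5 + seed7 + flank3)
            fam_of.append(fam_idx)
        fam_idx += 1
    while len(seqs) < n_base:  # singletons
        seqs.append("".join(rng.choice(_RNA, 22)))
        fam_of.append(fam_idx)
        fam_idx += 1
    # duplicates copy a random earlier mimic wholesale
    sources = rng.integers(0, n_base, n_dup)
    for src in sources:
        seqs.append(seqs[src])
        fam_of.append(fam_of[src])
    return seqs, pd.Series(fam_of)


def simulate_screen(cfg: ScreenSimConfig | None = None, seed: int = 0
                    ) -> tuple[list[ScreenPlate], ScreenTruth, MimicAnnotations]:
    cfg = cfg or ScreenSimConfig()
    rng = np.random.default_rng(seed)

    mimic_ids = [f"mimic-{i:04d}" for i in range(1, cfg.n_mimics + 1)]
    lines = [f"line-{i:02d}" for i in range(1, cfg.n_lines + 1)]
    groups = pd.Series([i % cfg.n_line_groups for i in range(cfg.n_lines)],
                       index=lines, name="group")

    seqs, fam_of = _random_sequences(rng, cfg)
    ann = MimicAnnotations.from_sequences(pd.Series(seqs, index=mimic_ids))

    # latent per-(mimic, line-group) phenotype, correlated within families
    rho = cfg.intra_family_rho
    fam_base = {f: rng.normal(0, cfg.group_effect_sd, cfg.n_line_groups)
                for f in fam_of.unique()}
    pheno = np.empty((cfg.n_mimics, cfg.n_line_groups))
    for i in range(cfg.n_mimics):
        own = rng.normal(0, cfg.group_effect_sd, cfg.n_line_groups)
        pheno[i] = (np.sqrt(rho) * fam_base[fam_of.iloc[i]]
                    + np.sqrt(1 - rho) * own)

    # planted discrete sensitivities
    effects = np.zeros((cfg.n_mimics, cfg.n_lines))
    n_hits = int(round(cfg.hit_fraction * cfg.n_mimics))
    hit_mimics = rng.choice(cfg.n_mimics, n_hits, replace=False)
    counts = rng.choice(np.arange(1, len(cfg.responsive_count_probs) + 1),
                        size=n_hits, p=cfg.responsive_count_probs)
    line_idx_by_group = [np.flatnonzero(groups.to_numpy() == g)
                         for g in range(cfg.n_line_groups)]
    lo_eff, hi_eff = cfg.effect_range
    for m, c in zip(hit_mimics, counts):
        order = rng.permutation(cfg.n_line_groups)
        chosen: list[int] = []
        for g in order:
            in_group = rng.permutation(line_idx_by_group[g])
            chosen.extend(in_group[:c - len(chosen)])
            if len(chosen) >= c:
                break
        effects[m, chosen[:c]] = rng.uniform(lo_eff, hi_eff, size=c)

    group_of_line = groups.to_numpy()
    viability = (1.0 + pheno[:, group_of_line]
                 + rng.normal(0, cfg.line_noise_sd, (cfg.n_mimics, cfg.n_lines))
                 - effects)
    viability = np.clip(viability, 0.01, None)

    # lay wells onto plates and apply multiplicative luminescence noise
    plates: list[ScreenPlate] = []
    row_labels = [chr(ord("A") + r) for r in range(cfg.n_rows)]
    for li, line in enumerate(lines):
        for rep in range(1, cfg.n_replicates + 1):
            for p in range(cfg.n_plates):
                start = p * cfg.mimics_per_plate
                plate_mimics = list(range(start,
                                          min(start + cfg.mimics_per_plate,
                                              cfg.n_mimics)))
                if not plate_mimics:
                    continue
                batch = float(np.exp(rng.normal(0, cfg.batch_effect_sd)))
                row_fac = np.exp(rng.normal(0, cfg.row_effect_sd, cfg.n_rows))
                rows, cols, ids, lums = [], [], [], []
                for slot, m in enumerate(plate_mimics):
                    r, c = divmod(slot, cfg.n_cols - 1)
                    rows.append(row_labels[r])
                    cols.append(c + 2)  # columns 2..n_cols hold mimics
                    ids.append(mimic_ids[m])
                    lums.append(viability[m, li] * row_fac[r])
                used_rows = sorted({row_labels[divmod(s, cfg.n_cols - 1)[0]]
                                    for s in range(len(plate_mimics))})
                for rl in used_rows:  # one negative control per used row
                    rows.append(rl)
                    cols.append(1)
                    ids.append(cfg.control_id)
                    lums.append(1.0 * row_fac[row_labels.index(rl)])
                noise = np.exp(rng.normal(0, cfg.replicate_noise_sd, len(lums)))
                wells = pd.DataFrame({
                    "row": rows, "column": cols, "mimic_id": ids,
                    "value": cfg.baseline_lum * batch * np.asarray(lums) * noise})
                plates.append(ScreenPlate(f"{line}-r{rep}-p{p + 1}", line, rep,
                                          wells))

    truth = ScreenTruth(
        sensitive=pd.DataFrame(effects > 0, index=mimic_ids, columns=lines),
        effects=pd.DataFrame(effects, index=mimic_ids, columns=lines),
        viability=pd.DataFrame(viability, index=mimic_ids, columns=lines),
        line_groups=groups, config=cfg)
    return plates, truth, ann


# ----------------------------------------------------------------- survival

@dataclass
class SurvivalSimConfig:
    """Expression-threshold-dependent exponential survival.

    Patients above the ``threshold_percentile`` of expression have their
    hazard multiplied by ``hazard_ratio``; censoring is independent
    exponential with rate ``censoring_rate`` (0 disables censoring).
    Baseline hazard defaults to a 30-month median survival.
    """
    n_patients: int = 300
    baseline_hazard: float = math.log(2) / 30.0
    threshold_percentile: float = 60.0
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.01
    expression_mu: float = 0.0
    expression_sigma: float = 1.0

    def __post_init__(self):
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be > 0")
        if not 0 < self.threshold_percentile < 100:
            raise ConfigError("threshold_percentile must be in (0, 100)")
        if self.censoring_rate < 0 or self.baseline_hazard <= 0:
            raise ConfigError("rates must be positive")


@dataclass
class SurvivalTruth:
    threshold_value: float
    high_expression: pd.Series  # sample_id -> above-threshold flag
    config: SurvivalSimConfig = field(repr=False, default=None)


def simulate_survival_cohort(cfg: SurvivalSimConfig | None = None, seed: int = 0
                             ) -> tuple[pd.DataFrame, SurvivalTruth]:
    cfg = cfg or SurvivalSimConfig()
    rng = np.random.default_rng(seed)
    ids = [f"pt-{i:04d}" for i in range(1, cfg.n_patients + 1)]
    expr = rng.lognormal(cfg.expression_mu, cfg.expression_sigma, cfg.n_patients)
    threshold = float(np.percentile(expr, cfg.threshold_percentile))
    high = expr > threshold
    hazard = cfg.baseline_hazard * np.where(high, cfg.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate, cfg.n_patients)
    else:
        t_cens = np.full(cfg.n_patients, np.inf)
    cohort = pd.DataFrame({
        "sample_id": ids,
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
        "expression": expr})
    truth = SurvivalTruth(threshold, pd.Series(high, index=ids), cfg)
    return cohort, truth


# ----------------------------------------------------------------- phenocopy

def simulate_phenocopy_panel(n_lines: int = 13, n_genes: int = 10,
                             planted_gene: int = 0, planted_r: float = 0.8,
                             seed: int = 0, index_line: int = 0
                             ) -> tuple[PhenocopyPanel, dict]:
    """A mimic toxicity profile plus dual-pool siRNA gene profiles with one
    planted phenocopy gene.

    Latent profiles are standard normal per line; the planted gene's pool
    profiles are planted_r-correlated mixtures with the mimic profile,
    other genes are independent.  Profiles map affinely to relative
    viability (0.7 + 0.15 z).  The mimic is strongly toxic in the index
    line, and the planted gene's index-line viability is capped below the
    conventional activity cutoff so it always passes the stage-1 filter.
    """
    if n_lines < 3:
        raise ConfigError("need at least 3 cell lines")
    if not 0 <= planted_r <= 1:
        raise ConfigError("planted_r must be in [0, 1]")
    if not 0 <= planted_gene < n_genes:
        raise ConfigError("planted_gene must index a gene")
    rng = np.random.default_rng(seed)
    lines = [f"line-{i:02d}" for i in range(1, n_lines + 1)]
    genes = [f"gene-{i:02d}" for i in range(1, n_genes + 1)]

    z_mimic = rng.normal(0, 1, n_lines)
    z_mimic[index_line] = -2.5  # the index line is mimic-sensitive

    def to_viability(z):
        return np.clip(0.7 + 0.15 * z, 0.05, 1.5)

    pools: dict[int, pd.DataFrame] = {}
    for pool in (1, 2):
        profiles = np.empty((n_genes, n_lines))
        for g in range(n_genes):
            eps = rng.normal(0, 1, n_lines)
            if g == planted_gene:
                z = planted_r * z_mimic + np.sqrt(1 - planted_r ** 2) * eps
            else:
                z = eps
            profiles[g] = to_viability(z)
        profiles[planted_gene, index_line] = min(
            profiles[planted_gene, index_line], 0.45)
        pools[pool] = pd.DataFrame(profiles, index=genes, columns=lines)

    panel = PhenocopyPanel(
        cell_lines=lines,
        mimic_profile=pd.Series(to_viability(z_mimic), index=lines),
        gene_profiles=pools,
        index_line=lines[index_line])
    truth = {"planted_gene": genes[planted_gene], "planted_r": planted_r}
    return panel, truth


# -------------------------------------------------------- expression response

def _default_down_rate(score: float) -> float:
    return 0.41 if score <= -0.2 else 0.12


def simulate_expression_response(n_genes: int = 4000, target_fraction: float = 0.2,
                                 score_range: tuple[float, float] = (-0.5, -0.02),
                                 down_rate_by_score=None,
                                 background_down_rate: float = 0.05,
                                 expressed_fraction: float = 1.0,
                                 seed: int = 0
                                 ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Predicted-target table with context scores plus per-gene log2
    expression ratios after mimic transfection.

    Predicted targets get context scores uniform on ``score_range`` and go
    2-fold down (log2 ratio <= -1) with probability
    ``down_rate_by_score(score)``; non-targets go down at the background
    rate.  Returns (predictions, log2_ratios for every gene, truth).
    """
    rate_fn = down_rate_by_score or _default_down_rate
    if not 0 <= background_down_rate <= 1:
        raise ConfigError("background_down_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"gene-{i:05d}" for i in range(1, n_genes + 1)]
    n_targets = int(round(target_fraction * n_genes))
    target_idx = rng.choice(n_genes, n_targets, replace=False)
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[target_idx] = True

    scores = rng.uniform(score_range[0], score_range[1], n_targets)
    rates = np.full(n_genes, background_down_rate)
    rates[target_idx] = [rate_fn(s) for s in scores]
    if not ((0 <= rates) & (rates <= 1)).all():
        raise ConfigError("down rates must be in [0, 1]")
    down = rng.uniform(size=n_genes) < rates
    ratios = np.where(down,
                      -1.0 - rng.exponential(0.8, n_genes),
                      np.clip(rng.normal(0, 0.35, n_genes), -0.99, None))

    expressed = rng.uniform(size=n_targets) < expressed_fraction
    predictions = pd.DataFrame({
        "gene_id": [genes[i] for i in target_idx],
        "context_score": scores,
        "is_expressed": expressed,
    }).sort_values("gene_id").reset_index(drop=True)
    log2_ratios = pd.Series(ratios, index=genes, name="log2_ratio")
    truth = {"targets": {genes[i] for i in target_idx},
             "down": pd.Series(down, index=genes),
             "rate_fn": rate_fn,
             "background_down_rate": background_down_rate}
    return predictions, log2_ratios, truth
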