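"""Gene-set overlap testing, context-score response curves, and the
dual-pool phenocopy filter for nominating functional miRNA targets.

Enrichment uses the exact upper-tail hypergeometric probability of the
observed overlap (one-sided; the analyses here test enrichment only).
The phenocopy procedure keeps predicted targets whose depletion is toxic
in the index cell line (relative viability below a cutoff) and nominates
those whose siRNA toxicity profile shows a positive Pearson correlation
with the mimic profile, with r^2 above a threshold, in *both* independent
reagent pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import PhenocopyPanel
from .errors import ConfigError, DataError


# --------------------------------------------------------------- overlap test

@dataclass
class OverlapResult:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float


def hypergeom_overlap(set_a: Iterable, set_b: Iterable,
                      universe: Iterable) -> OverlapResult:
    """Exact P(X >= k) for the overlap k of two sets drawn from a common
    universe, X ~ Hypergeometric(N, K, n).  Computed by summing the pmf
    over the upper support; no normal approximation."""
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    outside = (set_a | set_b) - universe
    if outside:
        raise DataError("elements outside the universe: "
                        + ", ".join(sorted(map(str, outside))[:10]))
    n_univ, k_a, n_b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    support = np.arange(k, min(k_a, n_b) + 1)
    p = float(stats.hypergeom.pmf(support, n_univ, k_a, n_b).sum())
    return OverlapResult(n_univ, k_a, n_b, k, min(p, 1.0))


def target_enrichment(responsive_genes: Iterable, predicted_targets: Iterable,
                      expressed_universe: Iterable) -> OverlapResult:
    """Enrichment of predicted targets among responsive genes within the
    expressed-gene universe."""
    return hypergeom_overlap(responsive_genes, predicted_targets,
                             expressed_universe)


# --------------------------------------------------------- context-score curve

DEFAULT_BIN_EDGES = (0.0, -0.1, -0.2, -0.3, -0.4, -np.inf)


def context_score_curve(predictions: pd.DataFrame,
                        log2_ratios: Mapping[str, float] | pd.Series,
                        fold_threshold: float = 2.0,
                        bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
                        ) -> pd.DataFrame:
    """Probability of >= fold_threshold down-regulation per context-score bin.

    A gene counts as "down" when its log2 expression ratio is
    <= -log2(fold_threshold).  Only expressed predicted targets enter;
    every such target needs a log2 ratio.  Bin j covers
    (edges[j+1], edges[j]] with edges strictly decreasing (scores above
    the first edge are clamped into the first bin).  Empty bins carry
    probability NaN with ``defined`` False.
    """
    if fold_threshold <= 1:
        raise ConfigError("fold_threshold must be > 1")
    edges = np.asarray(bin_edges, dtype=float)
    if not (np.diff(edges) < 0).all():
        raise ConfigError("bin edges must be strictly decreasing")
    ratios = pd.Series(dict(log2_ratios) if not isinstance(log2_ratios, pd.Series)
                       else log2_ratios, dtype=float)
    expressed = predictions.loc[predictions["is_expressed"], ["gene_id", "context_score"]]
    missing = set(expressed["gene_id"]) - set(ratios.index)
    if missing:
        raise DataError(f"{len(missing)} expressed predicted targets lack a log2 ratio")

    scores = expressed["context_score"].to_numpy()
    down = ratios.loc[expressed["gene_id"]].to_numpy() <= -np.log2(fold_threshold)
    rows = []
    for j in range(len(edges) - 1):
        hi, lo = edges[j], edges[j + 1]
        in_bin = (scores > lo) & (scores <= hi)
        if j == 0:
            in_bin |= scores > hi  # clamp scores above the first edge
        n_t = int(in_bin.sum())
        n_d = int(down[in_bin].sum())
        rows.append({"bin": f"({lo:g}, {hi:g}]", "score_high": hi, "score_low": lo,
                     "n_targets": n_t, "n_down": n_d,
                     "probability_down": n_d / n_t if n_t else np.nan,
                     "defined": n_t > 0})
    return pd.DataFrame(rows)


def downregulation_probability(predictions: pd.DataFrame,
                               log2_ratios: Mapping[str, float] | pd.Series,
                               score_max: float = -0.2,
                               fold_threshold: float = 2.0) -> tuple[float, int]:
    """Cumulative P(down | context score <= score_max) over expressed
    predicted targets; returns (probability, n_targets)."""
    if fold_threshold <= 1:
        raise ConfigError("fold_threshold must be > 1")
    ratios = pd.Series(dict(log2_ratios) if not isinstance(log2_ratios, pd.Series)
                       else log2_ratios, dtype=float)
    expressed = predictions.loc[predictions["is_expressed"]]
    sel = expressed.loc[expressed["context_score"] <= score_max, "gene_id"]
    n = len(sel)
    if n == 0:
        raise DataError(f"no expressed targets with context score <= {score_max}")
    missing = set(sel) - set(ratios.index)
    if missing:
        raise DataError(f"{len(missing)} expressed predicted targets lack a log2 ratio")
    down = (ratios.loc[sel] <= -np.log2(fold_threshold)).sum()
    return float(down / n), n


# ------------------------------------------------------------------ phenocopy

def phenocopy_screen(panel: PhenocopyPanel, viability_cutoff: float = 0.5,
                     r2_cutoff: float = 0.35, filter_pool: int = 1
                     ) -> pd.DataFrame:
    """Two-stage phenocopy nomination.

    Stage 1 keeps genes whose siRNA relative viability in the index line
    (profile from ``filter_pool``) is strictly below ``viability_cutoff``.
    Stage 2 nominates the survivors whose profiles correlate positively
    with the mimic profile, with r^2 strictly above ``r2_cutoff``, in both
    pools.  Genes with a constant profile in either pool have undefined
    correlation and are excluded with a reason.
    """
    if len(panel.cell_lines) < 3:
        raise DataError("need >= 3 shared cell lines for correlations")
    if filter_pool not in panel.gene_profiles:
        raise ConfigError(f"filter_pool must be 1 or 2, got {filter_pool}")
    mimic = panel.mimic_profile.to_numpy(dtype=float)
    rows = []
    for gene in panel.genes:
        rec: dict = {"gene_id": gene}
        rec["index_viability"] = float(
            panel.gene_profiles[filter_pool].loc[gene, panel.index_line])
        rec["passes_viability_filter"] = rec["index_viability"] < viability_cutoff
        reason = None
        rs = {}
        for pool in (1, 2):
            prof = panel.gene_profiles[pool].loc[gene].to_numpy(dtype=float)
            if np.ptp(prof) == 0 or np.ptp(mimic) == 0:
                rs[pool] = np.nan
                reason = f"constant profile in pool {pool}"
            else:
                rs[pool] = float(stats.pearsonr(mimic, prof).statistic)
        rec["r_pool1"], rec["r_pool2"] = rs[1], rs[2]
        rec["r2_pool1"], rec["r2_pool2"] = rs[1] ** 2, rs[2] ** 2
        correlated = all(np.isfinite(rs[p]) and rs[p] > 0
                         and rs[p] ** 2 > r2_cutoff for p in (1, 2))
        rec["nominated"] = bool(rec["passes_viability_filter"] and correlated)
        rec["exclusion_reason"] = reason
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id")


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """FDR-adjusted p-values (utility; not applied by default anywhere)."""
    return multipletests(np.asarray(list(p_values), dtype=float),
                         method="fdr_bh")[1]
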