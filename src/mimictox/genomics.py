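"""Feature-preparation rules for expression clustering and copy-number calls."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateDataError


def top_variant_filter(expr: pd.DataFrame, fraction: float = 0.2) -> pd.DataFrame:
    """Keep the round(fraction * n_genes) genes with the largest sample
    variance across samples (genes are rows).  Boundary ties are broken
    toward the lexicographically smaller gene_id; original row order is
    preserved in the output.
    """
    if not 0 < fraction <= 1:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    if expr.shape[1] < 2:
        raise DegenerateDataError("variance undefined with fewer than 2 samples")
    n_keep = int(np.floor(fraction * len(expr) + 0.5))
    variances = expr.var(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-variances[g], str(g)))
    keep = set(order[:n_keep])
    return expr.loc[[g for g in expr.index if g in keep]]


def classify_copy_number(ratios: pd.Series | dict, gain_min: float = 1.5,
                         loss_max: float = 0.5) -> pd.DataFrame:
    """Gene-level CNV calls from sample/reference exon read-depth ratios:
    gain if ratio >= gain_min, loss if ratio <= loss_max (both inclusive),
    neutral otherwise."""
    ratios = pd.Series(dict(ratios) if not isinstance(ratios, pd.Series) else ratios,
                       dtype=float)
    if (ratios < 0).any():
        bad = ratios.index[ratios < 0][0]
        raise DataError(f"negative depth ratio for gene {bad!r}")
    if loss_max >= gain_min:
        raise ConfigError("loss_max must be below gain_min")
    call = np.where(ratios >= gain_min, "gain",
                    np.where(ratios <= loss_max, "loss", "neutral"))
    out = pd.DataFrame({"gene_id": ratios.index, "depth_ratio": ratios.to_numpy(),
                        "call": call})
    return out.reset_index(drop=True)
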