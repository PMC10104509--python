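"""Differential expression over the genotype x bacterium design.

A self-contained moderated t-test on log2 CPM: the per-gene pooled variance
is shrunk toward the median gene variance with a prior degrees-of-freedom
weight, the standard empirical-Bayes idea behind limma-style DE testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

CONTROL = "NB"


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million with a 0.5 pseudocount.

    ``log2((count + 0.5) / (library_size + 1) * 1e6)`` where library size is
    the column sum. Raises on a zero column sum.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = list(counts.columns[lib == 0])
        raise ValueError(f"zero library size in samples: {bad}")
    cpm = (mat + 0.5) / (lib + 1.0) * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.index,
                        columns=counts.columns)


def de_test(log2cpm: pd.DataFrame, meta: pd.DataFrame, genotype: str,
            treatment: str, control: str = CONTROL, d0: float = 4.0,
            alpha: float = 0.05) -> pd.DataFrame:
    """Moderated two-sample t per gene for one treatment-vs-control contrast.

    With per-gene pooled variance s^2 on d residual df and prior variance
    s0^2 = median over genes of s^2, the moderated variance is
    ``(d0 s0^2 + d s^2) / (d0 + d)`` and the p-value comes from a t with
    d0 + d df; ``d0 = 0`` reduces to the ordinary pooled t. log2FC is the
    mean log2 CPM difference; q is BH within this contrast.
    """
    sel_t = meta.index[(meta["genotype"] == genotype) &
                       (meta["treatment"] == treatment)]
    sel_c = meta.index[(meta["genotype"] == genotype) &
                       (meta["treatment"] == control)]
    if len(sel_t) < 2 or len(sel_c) < 2:
        raise ValueError("need >= 2 replicates per arm "
                         f"({genotype}, {treatment} vs {control})")
    X = log2cpm[sel_t].to_numpy()
    C = log2cpm[sel_c].to_numpy()
    n1, n2 = X.shape[1], C.shape[1]
    d = n1 + n2 - 2

    diff = X.mean(axis=1) - C.mean(axis=1)
    ss = ((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((C - C.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / d
    s0_2 = float(np.median(s2))
    s2_mod = (d0 * s0_2 + d * s2) / (d0 + d)

    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(diff == 0.0, 0.0, diff / se)
    t = np.where(np.isfinite(t), t, np.sign(diff) * np.inf)
    p = 2 * stats.t.sf(np.abs(t), d0 + d)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    out = pd.DataFrame({
        "gene": log2cpm.index,
        "genotype": genotype,
        "treatment": treatment,
        "log2fc": diff,
        "p": p,
        "mean_log2cpm": np.concatenate([X, C], axis=1).mean(axis=1),
    })
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def de_all_contrasts(counts: pd.DataFrame, meta: pd.DataFrame,
                     control: str = CONTROL, d0: float = 4.0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Every (genotype, treatment != control) contrast, long format.

    BH correction stays within each contrast, matching per-bacterium
    comparisons.
    """
    log2cpm = normalize_counts(counts)
    frames = []
    for genotype in meta["genotype"].unique():
        treatments = meta.loc[meta["genotype"] == genotype, "treatment"]
        for treatment in treatments.unique():
            if treatment == control:
                continue
            frames.append(de_test(log2cpm, meta, genotype, treatment,
                                  control=control, d0=d0, alpha=alpha))
    if not frames:
        raise ValueError("no treatment contrasts found")
    return pd.concat(frames, ignore_index=True)
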