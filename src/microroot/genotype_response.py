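"""Genotype x treatment panel statistics.

Many-to-one Dunnett comparisons against the uninoculated control (seeded
Monte-Carlo max-|t| adjustment), proportional inhibitor effects, within-
genotype standardization, primordia stage profiles, and one-way linear
models with a Tukey compact-letter display.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, pearson_with_p, rank_sum_test

CONTROL = "NB"
STAGE_ORDER = ("I", "II", "III", "IV", "V", "VI", "VII", "E")


def _arms(table: pd.DataFrame, genotype: str | None,
          control: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    sub = table if genotype is None else table[table["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"no rows for genotype {genotype!r}")
    groups = {t: g["response"].to_numpy(dtype=float)
              for t, g in sub.groupby("treatment")}
    if control not in groups:
        raise ValueError(f"control arm {control!r} missing")
    ctrl = groups.pop(control)
    if not groups:
        raise ValueError("no treatment arms beyond the control")
    for t, v in list(groups.items()) + [(control, ctrl)]:
        if len(v) < 2:
            raise ValueError(f"arm {t!r} has < 2 observations")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite responses in arm {t!r}")
    return ctrl, groups


def dunnett_vs_control(table: pd.DataFrame, genotype: str | None = None,
                       control: str = CONTROL, alpha: float = 0.05,
                       n_mc: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Many-to-one comparisons of each treatment arm against the control.

    Studentized statistics come from the one-way model (pooled residual
    variance); the family-wise adjustment is Monte-Carlo: the null max-|t|
    distribution is simulated with ``n_mc`` draws at the observed arm sizes
    and residual df, and the adjusted p of arm i is
    ``(1 + #{max|t*| >= |t_i|}) / (1 + n_mc)``, floored at the analytic
    pooled-t p so the single-comparison reduction is exact. The ``q``
    column is BH over this family's adjusted p-values; when several
    families are analyzed together apply BH across the pooled adjusted p
    instead (see ``bh_across_families``).
    """
    ctrl, groups = _arms(table, genotype, control)
    names = sorted(groups)
    arms = [groups[t] for t in names]
    n0 = len(ctrl)
    ns = np.array([len(a) for a in arms])
    N = n0 + ns.sum()
    g = len(arms) + 1
    df = N - g

    means = np.array([a.mean() for a in arms])
    diffs = means - ctrl.mean()
    ss_res = sum(((a - a.mean()) ** 2).sum() for a in arms + [ctrl])
    s2 = ss_res / df if df > 0 else 0.0

    if s2 == 0:
        p_unadj = np.where(diffs == 0, 1.0, 1.0 / (1 + n_mc))
        p_adj = p_unadj.copy()
        t_obs = np.where(diffs == 0, 0.0, np.inf * np.sign(diffs))
    else:
        se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
        t_obs = diffs / se
        p_unadj = 2 * stats.t.sf(np.abs(t_obs), df)
        rng = np.random.default_rng(seed)
        zc = rng.standard_normal(n_mc) / np.sqrt(n0)
        zt = rng.standard_normal((n_mc, len(arms))) / np.sqrt(ns)
        s2_null = rng.chisquare(df, n_mc) / df
        t_null = (zt - zc[:, None]) / np.sqrt(
            s2_null[:, None] * (1.0 / ns + 1.0 / n0))
        max_t = np.abs(t_null).max(axis=1)
        max_t.sort()
        exceed = n_mc - np.searchsorted(max_t, np.abs(t_obs), side="left")
        p_adj = (1.0 + exceed) / (1.0 + n_mc)
        p_adj = np.maximum(p_adj, p_unadj)

    out = pd.DataFrame({
        "treatment": names,
        "diff": diffs,
        "t": t_obs,
        "p_unadjusted": np.clip(p_unadj, 0.0, 1.0),
        "p_adjusted": np.clip(p_adj, 0.0, 1.0),
    })
    out["q"] = bh_adjust(out["p_adjusted"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def bh_across_families(results: dict[str, pd.DataFrame],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Recompute q by BH over the pooled adjusted p of several Dunnett
    families (e.g. one per genotype)."""
    frames = []
    for fam, df in results.items():
        d = df.copy()
        d.insert(0, "family", fam)
        frames.append(d)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["q"] = bh_adjust(pooled["p_adjusted"].to_numpy())
    pooled["significant"] = pooled["q"] < alpha
    return pooled


def proportional_molecule_effect(table: pd.DataFrame, genotype: str,
                                 molecule: str, alpha: float = 0.05,
                                 sep: str = "+") -> pd.DataFrame:
    """Proportional effect of an inhibitor molecule per strain context.

    Matches each base treatment ``t`` with ``t<sep><molecule>``; the
    proportion is (mean with molecule - mean without) / mean without, with
    significance from the two-arm rank test and BH across contexts;
    classification into no_change / increase / decrease at q < alpha.
    """
    sub = table[table["genotype"] == genotype]
    groups = {t: g["response"].to_numpy(dtype=float)
              for t, g in sub.groupby("treatment")}
    suffix = f"{sep}{molecule}"
    bases = [t for t in sorted(groups)
             if not t.endswith(suffix) and f"{t}{suffix}" in groups]
    unmatched = [t for t in groups if t != CONTROL
                 and not t.endswith(suffix) and f"{t}{suffix}" not in groups]
    if unmatched:
        warnings.warn(f"no {molecule} arm for: {sorted(unmatched)}; skipped")
    if not bases:
        raise ValueError(f"no matched (treatment, treatment{suffix}) arms")

    rows = []
    for t in bases:
        plain, with_mol = groups[t], groups[f"{t}{suffix}"]
        base_mean = plain.mean()
        if base_mean == 0:
            raise ValueError(f"zero baseline mean in arm {t!r}")
        prop = (with_mol.mean() - base_mean) / base_mean
        rows.append((t, prop, rank_sum_test(with_mol, plain)))
    out = pd.DataFrame(rows, columns=["treatment", "proportion", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["class"] = np.where(out["q"] >= alpha, "no_change",
                            np.where(out["proportion"] > 0, "increase",
                                     "decrease"))
    return out


def standardize_within_genotype(effects: pd.DataFrame,
                                value: str = "effect") -> pd.DataFrame:
    """Z-score treatment effects within each genotype (sample SD).

    Input needs columns genotype, treatment and the value column; raises on
    a genotype with fewer than 2 treatments or zero spread.
    """
    out = effects.copy()
    zs = []
    for g, sub in out.groupby("genotype"):
        v = sub[value].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"genotype {g!r} has < 2 treatments")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero SD across treatments in genotype {g!r}")
        zs.append(pd.Series((v - v.mean()) / sd, index=sub.index))
    out["z"] = pd.concat(zs).sort_index()
    return out


def primordia_stage_profile(table: pd.DataFrame, control: str = CONTROL,
                            alpha: float = 0.05, n_mc: int = 100_000,
                            seed: int = 0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage profile per treatment plus Dunnett on total primordia.

    The table must carry a ``stage`` column with labels in I-VII/E and
    per-plant stage counts in ``response``. Returns (profile with per-stage
    proportions, a ``total`` column and an ``empty`` flag; Dunnett result on
    per-plant total primordia vs the control).
    """
    bad = set(table["stage"]) - set(STAGE_ORDER)
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    if (table["response"] < 0).any():
        raise ValueError("negative primordia counts")

    stage_tot = table.pivot_table(index="treatment", columns="stage",
                                  values="response", aggfunc="sum",
                                  fill_value=0.0)
    stage_tot = stage_tot.reindex(columns=[s for s in STAGE_ORDER
                                           if s in stage_tot.columns],
                                  fill_value=0.0)
    totals = stage_tot.sum(axis=1)
    profile = stage_tot.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    profile["total"] = totals
    profile["empty"] = totals == 0

    per_plant = (table.groupby(["treatment", "replicate", "plant_id"])
                 ["response"].sum().reset_index())
    per_plant["genotype"] = "all"
    dunnett = dunnett_vs_control(per_plant, genotype="all", control=control,
                                 alpha=alpha, n_mc=n_mc, seed=seed)
    return profile.reset_index(), dunnett


def stage_phenotype_correlation(stage_counts: pd.DataFrame,
                                emerged: pd.Series,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Per-stage Pearson correlation with emerged lateral-root counts.

    ``stage_counts`` is treatments x stages (counts); ``emerged`` is the
    per-treatment emerged-LR count. Constant stage vectors are reported
    with missing r/p; BH runs across the testable stages.
    """
    common = stage_counts.index.intersection(emerged.index)
    if len(common) < 3:
        raise ValueError("need >= 3 treatments")
    rows = []
    for stage in stage_counts.columns:
        x = stage_counts.loc[common, stage].to_numpy(dtype=float)
        y = emerged.loc[common].to_numpy(dtype=float)
        try:
            r, p = pearson_with_p(x, y)
        except ValueError:
            r, p = np.nan, np.nan
        rows.append((stage, r, p))
    out = pd.DataFrame(rows, columns=["stage", "r", "p"])
    mask = out["p"].notna()
    out["q"] = np.nan
    out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def tukey_cld(table: pd.DataFrame, group_col: str = "treatment",
              value_col: str = "response",
              alpha: float = 0.05) -> pd.DataFrame:
    """One-way model + all-pairs Tukey HSD + compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    Letters are assigned by the insert-and-absorb algorithm with groups
    processed in descending-mean order, so the output is invariant to the
    input row order.
    """
    arms = {g: sub[value_col].to_numpy(dtype=float)
            for g, sub in table.groupby(group_col)}
    if len(arms) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in arms.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 observations")
    names = sorted(arms, key=lambda g: (-arms[g].mean(), g))
    samples = [arms[g] for g in names]

    if np.ptp(np.concatenate(samples)) == 0:
        pmat = np.ones((len(names), len(names)))
    else:
        res = stats.tukey_hsd(*samples)
        pmat = np.asarray(res.pvalue)

    # insert-and-absorb on descending-mean-ordered groups
    cols: list[set[int]] = [set(range(len(names)))]
    for i, j in combinations(range(len(names)), 2):
        if not np.isfinite(pmat[i, j]) or pmat[i, j] >= alpha:
            continue
        new_cols = []
        for col in cols:
            if i in col and j in col:
                new_cols.extend([col - {i}, col - {j}])
            else:
                new_cols.append(col)
        cols = [c for c in new_cols
                if not any(c < other for other in new_cols)]
        # deduplicate while keeping order
        seen, dedup = [], []
        for c in cols:
            if c not in seen:
                seen.append(c)
                dedup.append(c)
        cols = dedup

    cols.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for li, col in enumerate(cols):
        ch = alphabet[li % len(alphabet)] * (li // len(alphabet) + 1)
        for gi in sorted(col):
            letters[names[gi]] += ch

    rows = [(g, arms[g].mean(), len(arms[g]), letters[g]) for g in names]
    out = pd.DataFrame(rows, columns=[group_col, "mean", "n", "letters"])
    return out.sort_values(group_col, ignore_index=True)
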