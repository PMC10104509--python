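"""Strain x feature phenotype screen statistics.

Per-strain effect estimation against the uninoculated control, feature
deduplication by correlation clustering plus coefficient of variation,
strain-response clustering, and PERMANOVA variance partitioning over strain
annotations (taxonomy, operon presence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as sp_linkage
from scipy.spatial.distance import pdist, squareform

from ._stats import (EXACT_MAX_ARM, bh_adjust, pearson_with_p,
                     rank_sum_exact_p, robust_effect, signed_rank_test)

CONTROL = "NB"


def _wide_by_condition(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """condition -> (plants x features) value matrix, features aligned."""
    wide = table.pivot_table(index=["condition", "replicate", "plant_id"],
                             columns="feature", values="value")
    return {cond: sub.droplevel("condition")
            for cond, sub in wide.groupby(level="condition")}


def estimate_effects(table: pd.DataFrame, alpha: float = 0.05,
                     test: str = "rank_sum",
                     control: str = CONTROL) -> pd.DataFrame:
    """Per (strain, feature) effect vs the uninoculated control.

    The effect is the MAD-standardized median difference; the p-value comes
    from the two-sided rank-sum test (exact enumeration when both arms have
    <= 8 plants, tie-corrected normal approximation otherwise) or, with
    ``test="signed_rank"``, from the one-sample Wilcoxon of strain values
    minus the control median. BH correction is applied jointly across all
    (strain, feature) cells; direction is the sign of the effect gated at
    q < alpha.
    """
    if test not in ("rank_sum", "signed_rank"):
        raise ValueError(f"unknown test {test!r}")
    by_cond = _wide_by_condition(table)
    if control not in by_cond:
        raise ValueError(f"control condition {control!r} missing from table")
    C = by_cond.pop(control)
    features = list(C.columns)
    c_mat = C.to_numpy()

    rows = []
    for strain, X in by_cond.items():
        x_mat = X[features].to_numpy()
        n, n0 = x_mat.shape[0], c_mat.shape[0]
        if test == "rank_sum" and (n > EXACT_MAX_ARM or n0 > EXACT_MAX_ARM):
            with np.errstate(invalid="ignore"):
                pvals = stats.mannwhitneyu(
                    x_mat, c_mat, axis=0, alternative="two-sided",
                    method="asymptotic").pvalue
            pvals = np.asarray(pvals, dtype=float)
        else:
            pvals = np.empty(len(features))
            for j in range(len(features)):
                x, c = x_mat[:, j], c_mat[:, j]
                if test == "signed_rank":
                    pvals[j] = signed_rank_test(x, float(np.median(c)))
                else:
                    pvals[j] = rank_sum_exact_p(x, c)
        for j, feat in enumerate(features):
            x, c = x_mat[:, j], c_mat[:, j]
            pooled = np.concatenate([x, c])
            p = 1.0 if np.all(pooled == pooled[0]) else float(pvals[j])
            if not np.isfinite(p):
                p = 1.0
            rows.append((strain, feat, robust_effect(x, c), p))

    eff = pd.DataFrame(rows, columns=["strain", "feature", "effect", "p"])
    eff["q"] = bh_adjust(eff["p"].to_numpy())
    sign = np.sign(eff["effect"])
    eff["direction"] = np.where(
        (eff["q"] < alpha) & (sign != 0),
        np.where(sign > 0, "+", "-"), "0")
    return eff


def summarize_significance(effects: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-feature fractions of strains moved up/down, and the overall
    fraction of strains with at least one significant feature."""
    per_feature = (effects.assign(
        up=effects["direction"] == "+",
        down=effects["direction"] == "-")
        .groupby("feature")[["up", "down"]].mean()
        .rename(columns={"up": "frac_up", "down": "frac_down"}))
    any_sig = (effects["direction"] != "0").groupby(effects["strain"]).any()
    return per_feature.reset_index(), float(any_sig.mean())


@dataclass
class MarkerSelection:
    """Feature-deduplication result: correlated-feature clusters, CV per
    feature, and one max-CV marker per cluster."""

    clusters: dict[str, int]
    cv: dict[str, float]
    markers: list[str] = field(default_factory=list)
    correlation: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"clusters": self.clusters, "cv": self.cv,
                "markers": self.markers}


def per_strain_means(table: pd.DataFrame) -> pd.DataFrame:
    """(conditions x features) mean value matrix, control included."""
    return table.pivot_table(index="condition", columns="feature",
                             values="value", aggfunc="mean")


def select_marker_features(table: pd.DataFrame, linkage: str = "average",
                           cut: float = 0.3) -> MarkerSelection:
    """Cluster the feature correlation matrix and pick max-CV markers.

    Pearson correlations are computed across per-strain mean feature values
    (control included); features are clustered with the given linkage on
    distance 1 - r and the tree cut at ``cut``. Within each cluster the
    feature with the highest coefficient of variation (SD / |mean| of the
    per-strain means) is the marker; ties break lexicographically. Constant
    features get singleton clusters with a warning.
    """
    M = per_strain_means(table)
    if M.shape[1] < 2:
        raise ValueError("need >= 2 features")
    sds = M.std(ddof=1)
    means = M.mean()
    if (means.abs() < 1e-12).any():
        bad = list(means.index[means.abs() < 1e-12])
        raise ValueError(f"CV undefined (|mean| < 1e-12) for features {bad}")
    cv = (sds / means.abs()).to_dict()

    constant = list(M.columns[sds == 0])
    if constant:
        warnings.warn(f"constant features assigned singleton clusters: {constant}")
    variable = [f for f in M.columns if f not in constant]

    clusters: dict[str, int] = {}
    corr = None
    if len(variable) >= 2:
        corr = M[variable].corr()
        dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, 2.0),
                          checks=False)
        Z = sp_linkage(dist, method=linkage)
        labels = fcluster(Z, t=cut, criterion="distance")
        clusters.update(dict(zip(variable, (int(v) for v in labels))))
    elif variable:
        clusters[variable[0]] = 1
    next_id = max(clusters.values(), default=0)
    for f in constant:
        next_id += 1
        clusters[f] = next_id

    markers = []
    for cid in sorted(set(clusters.values())):
        members = sorted(f for f, c in clusters.items() if c == cid)
        members.sort(key=lambda f: (-cv[f], f))
        markers.append(members[0])
    return MarkerSelection(clusters=clusters, cv=cv, markers=markers,
                           correlation=corr)


def cluster_strain_responses(effects: pd.DataFrame, markers: list[str],
                             k: int = 24,
                             linkage: str = "average") -> pd.Series:
    """Cut the strain tree (Euclidean distance on marker effects) at k
    clusters; deterministic given inputs."""
    mat = effects.pivot(index="strain", columns="feature",
                        values="effect")[markers]
    if k > mat.shape[0]:
        raise ValueError(f"k={k} exceeds {mat.shape[0]} strains")
    Z = sp_linkage(pdist(mat.to_numpy()), method=linkage)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=mat.index, name="cluster")


def correlate_effect_pair(effects: pd.DataFrame, feature_a: str,
                          feature_b: str) -> tuple[float, float]:
    """Pearson r (with two-sided t-transform p) between two features'
    per-strain effects; also serves any pair of per-condition summaries."""
    wide = effects.pivot(index="strain", columns="feature", values="effect")
    for f in (feature_a, feature_b):
        if f not in wide.columns:
            raise KeyError(f"feature {f!r} absent from effects")
    sub = wide[[feature_a, feature_b]].dropna()
    return pearson_with_p(sub[feature_a], sub[feature_b])


@dataclass(frozen=True)
class PermanovaResult:
    r2: float
    f_stat: float
    p: float
    n_perm: int


def permanova_group_effect(effect_matrix: pd.DataFrame,
                           grouping: pd.Series | dict,
                           n_perm: int = 999,
                           seed: int = 0) -> PermanovaResult:
    """PERMANOVA of strain effect vectors over a strain grouping.

    Pseudo-F on Euclidean distances with a label-permutation p-value,
    p = (1 + #{F* >= F}) / (1 + n_perm). Groups with a single member are
    dropped with a warning.
    """
    grouping = pd.Series(grouping)
    common = effect_matrix.index.intersection(grouping.index)
    X = effect_matrix.loc[common].to_numpy(dtype=float)
    labels = grouping.loc[common].to_numpy()

    counts = pd.Series(labels).value_counts()
    small = counts.index[counts < 2]
    if len(small):
        warnings.warn(f"dropping singleton groups: {sorted(small)}")
        keep = ~np.isin(labels, small)
        X, labels = X[keep], labels[keep]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups with >= 2 strains each")

    n, k = len(labels), len(uniq)
    d2 = squareform(pdist(X)) ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    onehot = np.stack([(labels == g) for g in uniq]).astype(float)

    def ss_within(oh: np.ndarray) -> float:
        return float(sum((oh[g] @ d2 @ oh[g]) / (2 * oh[g].sum())
                         for g in range(len(oh))))

    ssw = ss_within(onehot)
    ssb = ss_total - ssw
    f_obs = (ssb / (k - 1)) / (ssw / (n - k)) if ssw > 0 else np.inf
    r2 = ssb / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssw_p = ss_within(onehot[:, perm])
        ssb_p = ss_total - ssw_p
        f_p = (ssb_p / (k - 1)) / (ssw_p / (n - k)) if ssw_p > 0 else np.inf
        if f_p >= f_obs:
            b += 1
    return PermanovaResult(r2=float(r2), f_stat=float(f_obs),
                           p=(1 + b) / (1 + n_perm), n_perm=n_perm)
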