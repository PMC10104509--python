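"""Hierarchical gene filtering: the pipeline's signature computation.

Stage 1 takes the union of wild-type DEG sets over all bacterial
treatments; stage 2 keeps the genes that also respond in the lateral-root
mutants (i.e. genes acting independently of the mutated auxin-signaling
components); stage 3 subdivides the survivors by correlating their
wild-type log2 fold changes across treatments with the lateral-root
phenotype, yielding phenotype-linked positive and negative panels. A
FilterTrace records the gene counts surviving each stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as sp_linkage
from scipy.spatial.distance import squareform

from ._stats import bh_adjust, pearson_with_p


def degsets_from_de(de: pd.DataFrame, q_max: float = 0.05,
                    lfc_min: float = 1.0) -> pd.DataFrame:
    """Significant-gene calls per (genotype, treatment) with sign.

    A gene is called at q < q_max and |log2FC| >= lfc_min; the ``sign``
    column is up/down. Up and down are disjoint per contrast by
    construction (a gene has one log2FC per contrast).
    """
    sig = de[(de["q"] < q_max) & (de["log2fc"].abs() >= lfc_min)].copy()
    sig["sign"] = np.where(sig["log2fc"] > 0, "up", "down")
    return sig[["genotype", "treatment", "gene", "sign", "log2fc"]]


@dataclass
class FilterTrace:
    """Ordered record of (stage name, gene count, gene set) plus the
    parameters used; counts are nonincreasing across stages."""

    stages: list[tuple[str, int, set[str]]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def add(self, name: str, genes: set[str]) -> None:
        if self.stages and not genes <= self.stages[-1][2]:
            raise ValueError(f"stage {name!r} is not a subset of the "
                             "previous stage")
        self.stages.append((name, len(genes), set(genes)))

    @property
    def counts(self) -> list[int]:
        return [n for _, n, _ in self.stages]

    def to_json(self, path=None) -> str:
        payload = {
            "stages": [{"name": n, "count": c, "genes": sorted(g)}
                       for n, c, g in self.stages],
            "params": self.params,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def stage1_wt_union(degsets: pd.DataFrame, wt_genotype: str) -> set[str]:
    """Union over all treatments of the wild-type DEG sets (both signs)."""
    if wt_genotype not in set(degsets["genotype"]):
        if degsets.empty:
            warnings.warn("empty DEG sets; stage 1 is empty")
            return set()
        raise ValueError(f"no contrasts for wild type {wt_genotype!r}")
    genes = set(degsets.loc[degsets["genotype"] == wt_genotype, "gene"])
    if not genes:
        warnings.warn("wild-type DEG sets are empty")
    return genes


def stage2_mutant_filter(stage1: set[str], degsets: pd.DataFrame,
                         mutant_genotypes: list[str],
                         min_mutants: int = 1, min_treatments: int = 1,
                         mode: str = "retain-shared") -> set[str]:
    """Filter the stage-1 set by mutant responses.

    Default (``retain-shared``) keeps a gene iff it is significant
    (direction-agnostic) in >= ``min_mutants`` mutant genotypes for
    >= ``min_treatments`` treatments — i.e. genes whose response does not
    require the mutated components. ``exclude-shared`` keeps the
    complement within stage 1.
    """
    if not mutant_genotypes:
        raise ValueError("need >= 1 mutant genotype")
    if min_mutants > len(mutant_genotypes):
        raise ValueError("min_mutants exceeds available mutant genotypes")
    if mode not in ("retain-shared", "exclude-shared"):
        raise ValueError(f"unknown stage-2 mode {mode!r}")
    mut = degsets[degsets["genotype"].isin(mutant_genotypes) &
                  degsets["gene"].isin(stage1)]
    n_mut = (mut.groupby(["gene", "treatment"])["genotype"].nunique())
    qual_treatments = (n_mut[n_mut >= min_mutants]
                       .reset_index().groupby("gene")["treatment"].nunique())
    if min_treatments > degsets["treatment"].nunique():
        raise ValueError("min_treatments exceeds available treatments")
    shared = set(qual_treatments.index[qual_treatments >= min_treatments])
    return shared if mode == "retain-shared" else stage1 - shared


def wt_lfc_matrix(de: pd.DataFrame, wt_genotype: str,
                  genes: set[str] | None = None) -> pd.DataFrame:
    """Genes x treatments wild-type log2FC matrix."""
    sub = de[de["genotype"] == wt_genotype]
    if genes is not None:
        sub = sub[sub["gene"].isin(genes)]
    return sub.pivot(index="gene", columns="treatment", values="log2fc")


def stage3_phenotype_filter(stage2: set[str], de: pd.DataFrame,
                            phenotype: pd.Series, wt_genotype: str,
                            r_min: float = 0.5, alpha: float = 0.05,
                            trace: FilterTrace | None = None
                            ) -> tuple[set[str], set[str], FilterTrace]:
    """Subdivide the stage-2 set by phenotype correlation.

    For each gene, Pearson r between its wild-type log2FC across treatments
    and the per-treatment phenotype vector (e.g. the standardized lateral
    root density effect); genes with |r| >= r_min and BH q < alpha are
    retained and split by the sign of r. Genes with a constant log2FC
    vector are excluded with a warning.
    """
    if phenotype.nunique() <= 1:
        raise ValueError("constant phenotype vector")
    lfc = wt_lfc_matrix(de, wt_genotype, stage2)
    common = [t for t in lfc.columns if t in phenotype.index]
    if len(common) < 3:
        raise ValueError("need >= 3 treatments with phenotype values")
    lfc = lfc[common]
    ph = phenotype.loc[common].to_numpy(dtype=float)

    rows = []
    degenerate = []
    for gene, vec in lfc.iterrows():
        v = vec.to_numpy(dtype=float)
        try:
            r, p = pearson_with_p(v, ph)
        except ValueError:
            degenerate.append(gene)
            continue
        rows.append((gene, r, p))
    if degenerate:
        warnings.warn(f"{len(degenerate)} genes with constant log2FC "
                      "excluded from stage 3")
    stats_df = pd.DataFrame(rows, columns=["gene", "r", "p"])
    if not stats_df.empty:
        stats_df["q"] = bh_adjust(stats_df["p"].to_numpy())
        keep = stats_df[(stats_df["r"].abs() >= r_min) &
                        (stats_df["q"] < alpha)]
    else:
        keep = stats_df.assign(q=[])
    pos = set(keep.loc[keep["r"] > 0, "gene"])
    neg = set(keep.loc[keep["r"] < 0, "gene"])

    if trace is None:
        trace = FilterTrace()
    trace.params.update({"r_min": r_min, "alpha": alpha})
    trace.add("stage3_phenotype", pos | neg)
    return pos, neg, trace


def run_filter(de: pd.DataFrame, phenotype: pd.Series, wt_genotype: str,
               mutant_genotypes: list[str], q_max: float = 0.05,
               lfc_min: float = 1.0, min_mutants: int = 1,
               min_treatments: int = 1, stage2_mode: str = "retain-shared",
               r_min: float = 0.5, alpha: float = 0.05
               ) -> tuple[set[str], set[str], FilterTrace]:
    """Full three-stage filter; returns (positive, negative, trace)."""
    degsets = degsets_from_de(de, q_max=q_max, lfc_min=lfc_min)
    trace = FilterTrace(params={
        "q_max": q_max, "lfc_min": lfc_min, "min_mutants": min_mutants,
        "min_treatments": min_treatments, "stage2_mode": stage2_mode,
        "wt_genotype": wt_genotype, "mutants": list(mutant_genotypes)})
    s1 = stage1_wt_union(degsets, wt_genotype)
    trace.add("stage1_wt_union", s1)
    s2 = stage2_mutant_filter(s1, degsets, mutant_genotypes,
                              min_mutants=min_mutants,
                              min_treatments=min_treatments,
                              mode=stage2_mode)
    trace.add("stage2_mutant_filter", s2)
    pos, neg, trace = stage3_phenotype_filter(
        s2, de, phenotype, wt_genotype, r_min=r_min, alpha=alpha,
        trace=trace)
    return pos, neg, trace


def _corr_linkage(mat: np.ndarray, axis: int):
    X = mat if axis == 0 else mat.T
    c = np.corrcoef(X)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    dist = squareform(np.clip(1.0 - c, 0.0, 2.0), checks=False)
    return sp_linkage(dist, method="average")


def cluster_filtered_genes(lfc: pd.DataFrame, k: int = 2) -> dict:
    """Two-way average-linkage correlation-distance clustering.

    Rows (genes, sorted by name for determinism) are cut at ``k`` clusters
    (induced / repressed by default); both leaf orders are returned for
    heatmap display.
    """
    lfc = lfc.sort_index()
    if lfc.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    if k > lfc.shape[0]:
        raise ValueError("k exceeds number of genes")
    mat = lfc.to_numpy(dtype=float)
    gene_Z = _corr_linkage(mat, axis=0)
    labels = fcluster(gene_Z, t=k, criterion="maxclust")
    result = {
        "gene_labels": pd.Series(labels, index=lfc.index, name="cluster"),
        "gene_order": [lfc.index[i] for i in leaves_list(gene_Z)],
    }
    if lfc.shape[1] >= 3:
        contrast_Z = _corr_linkage(mat, axis=1)
        result["contrast_order"] = [lfc.columns[i]
                                    for i in leaves_list(contrast_Z)]
    else:
        result["contrast_order"] = list(lfc.columns)
    return result


def high_lfc_subset(panel: set[str], de: pd.DataFrame, wt_genotype: str,
                    threshold: float = 3.0) -> set[str]:
    """Genes whose maximum wild-type log2FC over treatments is >= threshold
    (inclusive)."""
    if not panel:
        raise ValueError("empty gene panel")
    lfc = wt_lfc_matrix(de, wt_genotype, panel)
    mx = lfc.max(axis=1)
    return set(mx.index[mx >= threshold])


def summarize_gene_panel(panel: set[str], log2cpm: pd.DataFrame,
                         meta: pd.DataFrame, control: str = "NB"
                         ) -> dict:
    """Standardized expression summaries for a gene panel.

    Each gene is z-scored across samples; samples are grouped into the
    uninoculated control vs the average over bacterial treatments. Returns
    per-gene group means, the per-gene control -> treated difference, and
    the panel-level group means (the mu printed above such panels).
    """
    missing = panel - set(log2cpm.index)
    if missing:
        raise KeyError(f"panel genes absent from matrix: {sorted(missing)}")
    sub = log2cpm.loc[sorted(panel)]
    mat = sub.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    center = mat.mean(axis=1, keepdims=True)
    z = np.divide(mat - center, sd, out=np.zeros_like(mat), where=sd > 0)
    zdf = pd.DataFrame(z, index=sub.index, columns=sub.columns)

    is_ctrl = meta.loc[zdf.columns, "treatment"] == control
    ctrl_mean = zdf.loc[:, is_ctrl.to_numpy()].mean(axis=1)
    trt_mean = zdf.loc[:, (~is_ctrl).to_numpy()].mean(axis=1)
    return {
        "z": zdf,
        "per_gene": pd.DataFrame({
            "control": ctrl_mean, "treated": trt_mean,
            "difference": trt_mean - ctrl_mean}),
        "mu_control": float(ctrl_mean.mean()),
        "mu_treated": float(trt_mean.mean()),
    }
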