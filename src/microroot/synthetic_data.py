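"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the structure of a binary-interaction root-architecture
screen (a few hundred bacterial strains, ~21 correlated root features, sparse
strain effects), genotype x treatment response panels (Gaussian densities or
Poisson branching counts), and a negative-binomial RNA-seq design over a
wild-type + mutant genotype panel with three planted gene modules:

* ``independent`` -- phenotype-correlated in every genotype (ethylene-like),
* ``wt_only``     -- responds only in the wild type (auxin-dependent-like),
* ``defense``     -- anti-correlated with the phenotype in every genotype.

Every generator takes an explicit seed, uses one private RNG stream, and is
byte-deterministic given its config. The uninoculated control condition is
always labeled ``"NB"`` (no bacteria) and always simulated, so every
downstream contrast is many-vs-one against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

CONTROL = "NB"
MODULES = ("independent", "wt_only", "defense")


def _check_count(name: str, v: int) -> None:
    if not (isinstance(v, (int, np.integer)) and v >= 1):
        raise ValueError(f"{name} must be an integer >= 1, got {v!r}")


def _check_finite(name: str, v: float) -> None:
    if not math.isfinite(v):
        raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Design of the strain x feature phenotype screen."""

    n_strains: int = 391
    n_features: int = 21
    n_plants: int = 10
    n_latent: int = 3
    loading_scale: float = 1.0
    active_fraction: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    feature_baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_strains", "n_features", "n_plants", "n_latent"):
            _check_count(f, getattr(self, f))
        for f in ("loading_scale", "active_fraction", "effect_size",
                  "noise_sd", "feature_baseline"):
            _check_finite(f, getattr(self, f))
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class PanelSimConfig:
    """Design of a genotype x treatment response panel.

    ``genotypes`` maps genotype label -> responsive flag; responsive
    genotypes see the full strain effect, non-responsive ones none of it.
    ``family`` is ``gaussian`` (e.g. lateral root density) or ``poisson``
    (e.g. bifurcation or primordia counts, where the strain effect acts on
    the log mean).
    """

    n_strains: int = 16
    n_plants: int = 10
    genotypes: dict[str, bool] = field(
        default_factory=lambda: {"Col-0": True, "mutantA": False})
    family: str = "gaussian"
    baseline: float = 5.0
    active_fraction: float = 0.5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_count("n_strains", self.n_strains)
        _check_count("n_plants", self.n_plants)
        if self.family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown response family {self.family!r}")
        if not self.genotypes:
            raise ValueError("at least one genotype required")
        for f in ("baseline", "active_fraction", "effect_size", "noise_sd"):
            _check_finite(f, getattr(self, f))
        if self.family == "poisson" and self.baseline <= 0:
            raise ValueError("poisson baseline must be > 0")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Design of the negative-binomial RNA-seq simulation."""

    n_genes: int = 2000
    module_sizes: tuple[int, int, int] = (40, 40, 40)
    genotypes: tuple[str, ...] = (
        "Col-0", "arf7arf19", "nph4", "lbd16", "gnom")
    wild_type: str = "Col-0"
    n_reps: int = 3
    nb_dispersion: float = 0.05
    baseline_mean: float = 200.0
    lfc_scale: float = 1.0
    sensitivity_range: tuple[float, float] = (0.75, 1.25)
    libsize_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        _check_count("n_genes", self.n_genes)
        _check_count("n_reps", self.n_reps)
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if len(self.module_sizes) != 3 or any(s < 0 for s in self.module_sizes):
            raise ValueError("module_sizes must be three nonnegative counts")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.wild_type not in self.genotypes:
            raise ValueError("exactly one genotype must be the wild type "
                             f"({self.wild_type!r} not in genotypes)")

    @property
    def n_null_genes(self) -> int:
        return self.n_genes - sum(self.module_sizes)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``strain_effects`` maps condition label -> e_s (0 for the control and
    all inactive strains); ``module_membership`` partitions genes over the
    three modules plus ``null``; ``gene_sensitivity`` holds a_g so the
    planted log2 fold change of gene g under strain s is a_g * e_s.
    """

    strain_effects: dict[str, float] = field(default_factory=dict)
    active_strains: set[str] = field(default_factory=set)
    module_membership: dict[str, str] = field(default_factory=dict)
    gene_sensitivity: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict, repr=False)

    @property
    def strains(self) -> list[str]:
        return [s for s in self.strain_effects if s != CONTROL]

    def module_genes(self, module: str) -> set[str]:
        return {g for g, m in self.module_membership.items() if m == module}

    def to_json(self, path) -> None:
        payload = {
            "strain_effects": self.strain_effects,
            "active_strains": sorted(self.active_strains),
            "module_membership": self.module_membership,
            "gene_sensitivity": self.gene_sensitivity,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _strain_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _feature_names(n: int) -> list[str]:
    return [f"F{i + 1:02d}" for i in range(n)]


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate the strain x feature phenotype screen.

    Each plant's feature vector is ``baseline + Lambda z_s + eps`` with
    latent loadings Lambda (n_features x n_latent, N(0, loading_scale^2),
    fixed per seed), strain shift ``z_s = e_s u_s`` on a random unit latent
    direction for active strains (e_s = effect_size, in units of the
    residual SD noise_sd), and i.i.d. Gaussian residuals. The control
    condition ``NB`` has e = 0.
    """
    rng = np.random.default_rng(config.seed)
    strains = _strain_names(config.n_strains)
    features = _feature_names(config.n_features)

    loadings = rng.normal(0.0, config.loading_scale,
                          (config.n_features, config.n_latent))
    active = rng.random(config.n_strains) < config.active_fraction
    u = rng.normal(size=(config.n_strains, config.n_latent))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    e = np.where(active, config.effect_size, 0.0)
    # per-condition mean feature shift; control first with zero shift
    shifts = np.vstack([np.zeros(config.n_features),
                        (e[:, None] * u) @ loadings.T])
    conditions = [CONTROL] + strains

    n_cond, n_feat, n_pl = len(conditions), config.n_features, config.n_plants
    noise = rng.normal(0.0, config.noise_sd, (n_cond, n_pl, n_feat))
    values = config.feature_baseline + shifts[:, None, :] + noise

    table = pd.DataFrame({
        "condition": np.repeat(conditions, n_pl * n_feat),
        "genotype": "Col-0",
        "replicate": "R1",
        "plant_id": np.tile(np.repeat([f"p{i + 1}" for i in range(n_pl)],
                                      n_feat), n_cond),
        "feature": np.tile(features, n_cond * n_pl),
        "value": values.ravel(),
    })

    truth = PlantedTruth(
        strain_effects={CONTROL: 0.0, **{s: float(v) for s, v in zip(strains, e)}},
        active_strains={s for s, a in zip(strains, active) if a},
        extras={
            "loadings": loadings,
            "feature_shifts": pd.DataFrame(shifts, index=conditions,
                                           columns=features),
        },
    )
    return table, truth


def simulate_genotype_panel(config: PanelSimConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate a genotype x treatment panel (Gaussian or Poisson family).

    Responsive genotypes see the full planted strain effect e_s (additive on
    the response for the gaussian family, on the log mean for poisson);
    non-responsive genotypes see none of it.
    """
    rng = np.random.default_rng(config.seed)
    strains = _strain_names(config.n_strains)
    active = rng.random(config.n_strains) < config.active_fraction
    signs = rng.choice([-1.0, 1.0], config.n_strains)
    e = np.where(active, config.effect_size * signs, 0.0)
    effects = {CONTROL: 0.0, **{s: float(v) for s, v in zip(strains, e)}}

    rows = []
    for genotype, responsive in config.genotypes.items():
        for cond in [CONTROL] + strains:
            shift = effects[cond] if responsive else 0.0
            if config.family == "gaussian":
                y = rng.normal(config.baseline + shift, config.noise_sd,
                               config.n_plants)
            else:
                lam = config.baseline * np.exp(shift)
                y = rng.poisson(lam, config.n_plants).astype(float)
            rows.append(pd.DataFrame({
                "genotype": genotype,
                "treatment": cond,
                "replicate": "R1",
                "plant_id": [f"p{i + 1}" for i in range(config.n_plants)],
                "response": y,
            }))
    table = pd.concat(rows, ignore_index=True)
    truth = PlantedTruth(
        strain_effects=effects,
        active_strains={s for s, a in zip(strains, active) if a},
        extras={"responsive": dict(config.genotypes), "family": config.family},
    )
    return table, truth


STAGES = ("I", "II", "III", "IV", "V", "VI", "VII", "E")


def simulate_primordia(n_strains: int = 8, n_plants: int = 10,
                       base_rates: dict[str, float] | None = None,
                       active_fraction: float = 0.5,
                       early_log_shift: float = math.log(2.0),
                       coupled_stages: tuple[str, ...] = ("I", "II", "III"),
                       seed: int = 0) -> tuple[pd.DataFrame, PlantedTruth]:
    """Stage-resolved lateral-root primordia counts per plant.

    Counts per developmental stage (I-VII plus emerged, E) are Poisson; for
    active strains the rate of the ``coupled_stages`` (and of E, so early
    priming propagates to emergence) is multiplied by exp(early_log_shift).
    """
    rng = np.random.default_rng(seed)
    rates = dict(base_rates or {s: 2.0 for s in STAGES})
    strains = _strain_names(n_strains)
    active = rng.random(n_strains) < active_fraction
    effects = {CONTROL: 0.0,
               **{s: float(early_log_shift if a else 0.0)
                  for s, a in zip(strains, active)}}
    rows = []
    for cond in [CONTROL] + strains:
        shift = effects[cond]
        for stage in STAGES:
            lam = rates[stage] * (
                np.exp(shift) if stage in coupled_stages or stage == "E" else 1.0)
            counts = rng.poisson(lam, n_plants)
            rows.append(pd.DataFrame({
                "genotype": "Col-0",
                "treatment": cond,
                "replicate": "R1",
                "plant_id": [f"p{i + 1}" for i in range(n_plants)],
                "stage": stage,
                "response": counts.astype(float),
            }))
    truth = PlantedTruth(
        strain_effects=effects,
        active_strains={s for s, a in zip(strains, active) if a},
        extras={"coupled_stages": coupled_stages},
    )
    return pd.concat(rows, ignore_index=True), truth


def simulate_expression(config: ExpressionSimConfig,
                        truth: PlantedTruth) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Negative-binomial counts for a genotype x treatment RNA-seq design.

    Gene means follow ``log2(mu_gs / mu_g0) = a_g e_s`` for independent-
    module genes in every genotype, for wt_only genes in the wild type only,
    and ``-a_g e_s`` for defense genes everywhere; null genes are unshifted.
    Counts are NB(mean mu * L_sample, dispersion phi) with variance
    ``mu + phi mu^2``; library-size factors L are log-normal.

    Returns (counts genes x samples, sample metadata, truth updated with the
    module partition and gene sensitivities).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    strains = [s for s in truth.strain_effects if s != CONTROL]
    if not strains:
        raise ValueError("truth lists no strains beyond the control")

    perm = rng.permutation(config.n_genes)
    membership = {}
    cursor = 0
    for module, size in zip(MODULES, config.module_sizes):
        for i in perm[cursor:cursor + size]:
            membership[genes[i]] = module
        cursor += size
    for i in perm[cursor:]:
        membership[genes[i]] = "null"

    lo, hi = config.sensitivity_range
    a = rng.uniform(lo, hi, config.n_genes) * config.lfc_scale
    sens = {g: (float(a[i]) if membership[g] != "null" else 0.0)
            for i, g in enumerate(genes)}

    base = rng.lognormal(math.log(config.baseline_mean), 0.7, config.n_genes)
    e = np.array([truth.strain_effects[s] for s in strains])
    conditions = [CONTROL] + strains

    meta_rows = []
    cols = []
    counts = np.empty((config.n_genes, 0), dtype=np.int64)
    blocks = []
    mod_vec = np.array([membership[g] for g in genes])
    a_vec = np.array([sens[g] for g in genes])
    phi = config.nb_dispersion
    nb_n = 1.0 / phi

    for genotype in config.genotypes:
        is_wt = genotype == config.wild_type
        for ci, cond in enumerate(conditions):
            e_s = truth.strain_effects[cond]
            lfc = np.zeros(config.n_genes)
            lfc[mod_vec == "independent"] = (a_vec * e_s)[mod_vec == "independent"]
            if is_wt:
                lfc[mod_vec == "wt_only"] = (a_vec * e_s)[mod_vec == "wt_only"]
            lfc[mod_vec == "defense"] = (-a_vec * e_s)[mod_vec == "defense"]
            mu = base * np.power(2.0, lfc)
            for rep in range(config.n_reps):
                L = rng.lognormal(0.0, config.libsize_sigma)
                m = mu * L
                block = rng.negative_binomial(nb_n, nb_n / (nb_n + m))
                blocks.append(block)
                cols.append(f"{genotype}.{cond}.r{rep + 1}")
                meta_rows.append((cols[-1], genotype, cond, f"r{rep + 1}"))

    counts = pd.DataFrame(np.column_stack(blocks), index=genes, columns=cols)
    meta = pd.DataFrame(meta_rows,
                        columns=["sample", "genotype", "treatment", "replicate"]
                        ).set_index("sample")
    out_truth = PlantedTruth(
        strain_effects=dict(truth.strain_effects),
        active_strains=set(truth.active_strains),
        module_membership=membership,
        gene_sensitivity=sens,
        extras={"baseline_mean": base},
    )
    return counts, meta, out_truth


def simulate_gene_sets(truth: PlantedTruth, recall: float = 0.8,
                       precision: float = 0.8, n_decoys: int = 5,
                       seed: int = 0) -> dict[str, set[str]]:
    """Literature-core-like gene sets with controlled recall and precision.

    For each planted module a ``<module>_core`` set samples
    ``round(recall * |module|)`` true members and spikes in non-members so
    the set's precision matches ``precision``. Decoy sets of the same
    typical size are drawn uniformly from the whole universe, giving a
    calibrated null for enrichment type-I checks.
    """
    if not (0 < recall <= 1 and 0 < precision <= 1):
        raise ValueError("recall and precision must be in (0, 1]")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.module_membership)
    if not universe:
        raise ValueError("truth carries no gene module information")
    sets: dict[str, set[str]] = {}
    sizes = []
    for module in MODULES:
        members = sorted(truth.module_genes(module))
        if not members:
            continue
        n_true = round(recall * len(members))
        n_total = round(n_true / precision)
        n_spike = n_total - n_true
        non_members = sorted(set(universe) - set(members))
        if n_spike > len(non_members):
            raise ValueError("precision infeasible given gene counts")
        chosen = list(rng.choice(members, n_true, replace=False))
        chosen += list(rng.choice(non_members, n_spike, replace=False))
        sets[f"{module}_core"] = set(chosen)
        sizes.append(n_total)
    decoy_size = int(np.median(sizes)) if sizes else 40
    for d in range(n_decoys):
        sets[f"decoy_{d + 1:02d}"] = set(
            rng.choice(universe, min(decoy_size, len(universe)), replace=False))
    return sets


def simulate_taxonomy(truth: PlantedTruth, n_groups: int = 10,
                      group_signal: float = 0.0,
                      within_sd: float | None = None,
                      seed: int = 0) -> tuple[pd.DataFrame, PlantedTruth]:
    """Taxonomic groups plus a strain-effect vector with planted structure.

    Strains are assigned to ``n_groups`` balanced groups and the strain
    effect vector is REGENERATED as ``e = sqrt(s) * m_group + sqrt(1-s) * z``
    with standardized group means m and residuals z, so the between-group
    share of Var(e) is ``group_signal`` in expectation (exactly 1 when
    ``group_signal == 1``, where the within term vanishes). An independent
    binary auxin-operon label is emitted with no association to e.

    Returns (annotation table with columns strain/group/operon/effect, a new
    truth carrying the regenerated effects).
    """
    if not 0.0 <= group_signal <= 1.0:
        raise ValueError("group_signal must be in [0, 1]")
    strains = truth.strains
    n = len(strains)
    if n_groups > n:
        raise ValueError("n_groups exceeds number of strains")
    rng = np.random.default_rng(seed)

    order = rng.permutation(n)
    groups = np.empty(n, dtype=int)
    groups[order] = np.arange(n) % n_groups

    gm = rng.normal(size=n_groups)
    gm = (gm - gm.mean()) / gm.std() if n_groups > 1 else gm * 0.0
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std()
    e = math.sqrt(group_signal) * gm[groups] + math.sqrt(1.0 - group_signal) * z
    operon = rng.random(n) < 0.5

    ann = pd.DataFrame({
        "strain": strains,
        "group": [f"T{g + 1:02d}" for g in groups],
        "operon": operon.astype(int),
        "effect": e,
    })
    new_truth = PlantedTruth(
        strain_effects={CONTROL: 0.0,
                        **{s: float(v) for s, v in zip(strains, e)}},
        active_strains={s for s, v in zip(strains, e) if v != 0.0},
        module_membership=dict(truth.module_membership),
        gene_sensitivity=dict(truth.gene_sensitivity),
        extras={"group_signal": group_signal},
    )
    return ann, new_truth


def config_to_dict(config) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
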