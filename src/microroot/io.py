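"""Table readers/writers and schema validation for the pipeline formats:
long phenotype/condition tables (TSV), count matrices (TSV or MatrixMarket),
sample metadata, GMT gene sets, JSON traces."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FEATURE_COLS = ["condition", "genotype", "replicate", "plant_id",
                "feature", "value"]
CONDITION_COLS = ["genotype", "treatment", "replicate", "plant_id",
                  "response"]
CONTROL = "NB"


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_counts(path, genes_path=None, samples_path=None) -> pd.DataFrame:
    """Counts as genes x samples from TSV, or MatrixMarket plus row/column
    name files."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = mmread(path).toarray()
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        return pd.DataFrame(mat, index=genes, columns=samples)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def validate_feature_table(df: pd.DataFrame, control: str = CONTROL) -> list[str]:
    """Schema check; returns a list of failure messages (empty = pass)."""
    problems = []
    missing = [c for c in FEATURE_COLS if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
        return problems
    if control not in set(df["condition"]):
        problems.append(f"control condition {control!r} absent")
    if not pd.api.types.is_numeric_dtype(df["value"]):
        problems.append("value column is not numeric")
    elif df["value"].isna().any() or (~df["value"].abs().lt(float("inf"))).any():
        problems.append("non-finite values present")
    dup = df.duplicated(["condition", "replicate", "plant_id", "feature"])
    if dup.any():
        problems.append(f"{int(dup.sum())} duplicate "
                        "(condition, replicate, plant_id, feature) rows")
    n_plants = df.groupby("condition")["plant_id"].nunique()
    if (n_plants < 3).any():
        few = list(n_plants.index[n_plants < 3])
        problems.append(f"conditions with < 3 plants: {few}")
    return problems


def validate_condition_table(df: pd.DataFrame, control: str = CONTROL) -> list[str]:
    problems = []
    missing = [c for c in CONDITION_COLS if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
        return problems
    for g, sub in df.groupby("genotype"):
        if control not in set(sub["treatment"]):
            problems.append(f"genotype {g!r} lacks control treatment "
                            f"{control!r}")
    if not pd.api.types.is_numeric_dtype(df["response"]):
        problems.append("response column is not numeric")
    elif df["response"].isna().any():
        problems.append("missing responses present")
    return problems


def validate_counts(counts: pd.DataFrame, meta: pd.DataFrame,
                    control: str = CONTROL) -> list[str]:
    problems = []
    if (counts.sum(axis=0) == 0).any():
        problems.append("samples with zero column sum")
    if (counts.to_numpy() < 0).any():
        problems.append("negative counts")
    uncovered = [s for s in counts.columns if s not in meta.index]
    if uncovered:
        problems.append(f"samples without metadata: {uncovered[:5]}")
    else:
        for g, sub in meta.loc[list(counts.columns)].groupby("genotype"):
            if control not in set(sub["treatment"]):
                problems.append(f"genotype {g!r} lacks control samples")
    return problems
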