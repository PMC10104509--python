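"""Hypergeometric enrichment / depletion of gene panels against named core
gene sets (hormone cores, TF lists, defense genes), with BH FDR control."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from ._stats import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets plus a declared universe (all sets are subsets)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, s in self.sets.items():
            if not s <= self.universe:
                raise ValueError(f"set {name!r} is not a subset of the universe")

    @classmethod
    def from_gmt(cls, path, universe: set[str] | None = None) -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{ln}: GMT line needs >= 3 tab-separated "
                        f"fields (name, description, genes), got {len(parts)}")
                name = parts[0]
                if name in sets:
                    raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
                sets[name] = {g for g in parts[2:] if g}
        return cls(sets=sets, universe=universe or set())

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                genes = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\tna\t{genes}\n")


def hypergeometric_test(query: set[str], annotation: set[str],
                        universe: set[str],
                        tail: str = "enrichment") -> dict:
    """One hypergeometric tail test of a query panel against a gene set.

    Enrichment: P(overlap >= k); depletion: P(overlap <= k), given the
    universe size, set size and query size. Expected overlap is
    |query| * |set| / |universe| and fold = k / expected.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not annotation <= universe:
        raise ValueError("annotation set is not a subset of the universe")
    if tail not in ("enrichment", "depletion"):
        raise ValueError(f"unknown tail {tail!r}")
    N, K, n = len(universe), len(annotation), len(query)
    k = len(query & annotation)
    if tail == "enrichment":
        p = float(hypergeom.sf(k - 1, N, K, n))
    else:
        p = float(hypergeom.cdf(k, N, K, n))
    expected = n * K / N
    return {"k": k, "expected": expected,
            "fold": (k / expected) if expected > 0 else float("nan"),
            "p": min(max(p, 0.0), 1.0), "tail": tail}


def enrichment_panel(queries: dict[str, set[str]],
                     collection: GeneSetCollection,
                     tail: str = "enrichment",
                     alpha: float = 0.05) -> pd.DataFrame:
    """All (query, set) tests with BH across the panel.

    Also reports the plotted percentage 100 * k / |query|. An empty query
    yields k = 0 and p = 1.
    """
    rows = []
    for qname, query in queries.items():
        for sname in sorted(collection.sets):
            sset = collection.sets[sname]
            if not query:
                row = {"k": 0, "expected": 0.0, "fold": float("nan"),
                       "p": 1.0, "tail": tail}
            else:
                row = hypergeometric_test(query, sset, collection.universe,
                                          tail=tail)
            rows.append({"query": qname, "set": sname, **row,
                         "percent": (100.0 * row["k"] / len(query))
                         if query else 0.0})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
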