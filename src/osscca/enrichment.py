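"""SNP→gene mapping and hypergeometric over-representation analysis with BH FDR."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "OraResult",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "map_snps_to_genes",
    "hypergeom_tail",
    "bh_fdr",
    "run_ora",
]


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a reference universe.

    Genes outside the universe are removed from each set at
    construction; sets left empty are dropped (and recorded).
    """

    sets: dict[str, list[str]]
    universe: list[str]
    dropped_sets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("duplicate genes in the universe")
        harmonized: dict[str, list[str]] = {}
        dropped = list(self.dropped_sets)
        for name, genes in self.sets.items():
            kept = [g for g in dict.fromkeys(genes) if g in uni]
            if kept:
                harmonized[name] = kept
            else:
                dropped.append(name)
        self.sets = harmonized
        self.dropped_sets = dropped
        if not self.sets:
            raise ValueError("no gene set survives harmonization with the universe")


@dataclass
class OraResult:
    """Per-set overlap counts, hypergeometric p and BH FDR, sorted by p."""

    table: pd.DataFrame  # columns: set, k, K, n, N, p, fdr
    n_selected_effective: int
    n_selected_dropped: int

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def top_set(self) -> str:
        return str(self.table.iloc[0]["set"])


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description and ≥1 gene")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path: str | Path, sets: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column rsID→gene TSV (gene cell may hold 'A/B' multi-mappings)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs rsID and gene columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_annotation(path: str | Path, annotation: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"rsid": list(annotation.keys()), "gene": list(annotation.values())}
    ).to_csv(path, sep="\t", index=False)


def map_snps_to_genes(rsids: Sequence[str], annotation: Mapping[str, str]) -> list[str]:
    """Map rsIDs to genes (slash-separated multi-gene entries split),
    deduplicated in order of first appearance. Uncovered rsIDs are warned
    about; an empty overall mapping is an error."""
    genes: list[str] = []
    uncovered: list[str] = []
    for rsid in rsids:
        entry = annotation.get(rsid)
        if entry is None:
            uncovered.append(rsid)
            continue
        parts = entry if isinstance(entry, (list, tuple)) else str(entry).split("/")
        for g in parts:
            g = g.strip()
            if g and g not in genes:
                genes.append(g)
    if uncovered:
        warnings.warn(f"{len(uncovered)} rsIDs without annotation: {uncovered[:5]}...")
    if not genes:
        raise ValueError("no rsID could be mapped to a gene")
    return genes


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail over-representation probability P(X ≥ k) for
    X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    selected_genes: Sequence[str], collection: GeneSetCollection
) -> OraResult:
    """Hypergeometric over-representation of the selected genes in each set.

    Selected genes outside the universe are dropped (counted); one
    upper-tail test per set, BH adjustment across the tested sets,
    result sorted by ascending p (ties by set name).
    """
    uni = set(collection.universe)
    effective = [g for g in dict.fromkeys(selected_genes) if g in uni]
    dropped = len(dict.fromkeys(selected_genes)) - len(effective)
    if not effective:
        raise ValueError("no selected gene lies in the reference universe")
    N = len(collection.universe)
    n = len(effective)
    sel = set(effective)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(sel.intersection(genes))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_tail(k, K, n, N)})
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table = table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    return OraResult(table=table, n_selected_effective=n, n_selected_dropped=dropped)
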