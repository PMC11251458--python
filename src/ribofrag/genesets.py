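"""Curated gene-set responses across conditions.

Summarizes relative expression of curated subsets (e.g. JNK/p38-associated or
interferon-stimulated genes) across treatments and tests condition
differences with gene-paired t-tests.  Base lists are data inputs (one gene
id per line); response subsets are derived by intersecting a base list with
the significantly changed genes of a differential table.

No multiple-comparison correction is applied across panels; each comparison
is reported as its own per-panel test.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import call_de

__all__ = [
    "GeneSet",
    "PairedComparison",
    "DegenerateInputError",
    "read_geneset",
    "load_packaged_geneset",
    "derive_subset",
    "paired_t",
    "subset_distribution",
]


class DegenerateInputError(ValueError):
    """Raised when a paired test has no variance to work with."""


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    provenance: str = "curated list"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class PairedComparison:
    """Gene-paired t-test between two conditions' per-gene log2FCs."""

    t: float
    pvalue: float
    n: int
    mean_difference: float
    n_dropped: int = 0


def read_geneset(path: str, name: str | None = None,
                 provenance: str = "curated list") -> GeneSet:
    """One gene id per line; lines starting with '#' are header comments."""
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.append(line)
    return GeneSet(name or path, frozenset(members), provenance)


def load_packaged_geneset(name: str) -> GeneSet:
    """Load one of the packaged example lists (synthetic stand-ins)."""
    ref = resources.files("ribofrag.data").joinpath(f"{name}.txt")
    members = [l.strip() for l in ref.read_text().splitlines()
               if l.strip() and not l.startswith("#")]
    return GeneSet(name, frozenset(members), "packaged synthetic example")


def derive_subset(de_table: pd.DataFrame, base_set: GeneSet,
                  rule: Literal["up", "down"] = "up",
                  lfc_min: float = 1.0, alpha: float = 0.05) -> GeneSet:
    """Members of ``base_set`` that are significantly up (or down) regulated.

    Returns an empty-allowed result: when nothing qualifies the set is
    returned with zero members flagged in provenance rather than raising.
    """
    up, down = call_de(de_table, lfc_min=lfc_min, alpha=alpha)
    hits = base_set.members & (up if rule == "up" else down)
    provenance = (f"derived-by-rule: {base_set.name} ∩ {rule}"
                  f"(lfc>{lfc_min}, padj<{alpha})")
    if not hits:
        # bypass the nonempty invariant deliberately: an empty response
        # subset is a finding, not an error
        obj = object.__new__(GeneSet)
        object.__setattr__(obj, "name", f"{base_set.name}_{rule}")
        object.__setattr__(obj, "members", frozenset())
        object.__setattr__(obj, "provenance", provenance + " [empty]")
        return obj
    return GeneSet(f"{base_set.name}_{rule}", frozenset(hits), provenance)


def paired_t(values_a: Iterable[float], values_b: Iterable[float]
             ) -> PairedComparison:
    """Two-sided paired t-test on gene-matched value vectors.

    Pairs with a missing value on either side are dropped (count reported).
    All-identical differences (zero variance) are a degenerate input.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"unpaired inputs: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    dropped = int((~ok).sum())
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {a.size}")
    d = a - b
    if np.allclose(d, d[0]):
        raise DegenerateInputError("all paired differences identical; "
                                   "t statistic undefined")
    res = stats.ttest_rel(a, b)
    return PairedComparison(float(res.statistic), float(res.pvalue),
                            int(a.size), float(d.mean()), dropped)


def subset_distribution(de_tables: Mapping[str, pd.DataFrame],
                        gene_set: GeneSet) -> pd.DataFrame:
    """Per-condition log2FC vectors of a gene set, gene-aligned for pairing.

    Returns a genes x conditions DataFrame (NaN where a gene is absent from
    a table); medians are in ``.median()`` of the result.  Suitable for
    violin-style export and as input to :func:`paired_t` column pairs.
    """
    genes = sorted(gene_set.members)
    data = {}
    for cond, table in de_tables.items():
        data[cond] = [table["log2FoldChange"].get(g, np.nan) for g in genes]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))
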