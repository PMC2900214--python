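"""Non-randomness of pseudogene distribution across COG categories.

The contingency table is categories x {intact, pseudogene}.  The Pearson
chi-squared statistic is tested with a Monte-Carlo simulated p-value: the
null conditions on both margins (which genes are pseudogenes is permuted
while each category keeps its gene count), replicate statistics are
compared with the observed one, and p = (b + 1) / (B + 1) with b the
number of replicates at least as extreme — the add-one estimator, which is
never zero and whose floor at B = 2000 is 1/2001 = 0.0004998.  Per-category
Pearson residuals (obs - exp) / sqrt(exp) localize the signal; a large
positive pseudogene-column residual means pseudogene overrepresentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_io import FeatureSet

__all__ = ["ContingencyTable", "ChiSqResult", "build_table", "pearson_chisq",
           "simulated_pvalue", "residual_report"]


class DegenerateTableError(ValueError):
    pass


@dataclass
class ContingencyTable:
    categories: list[str]
    counts: dict            # category -> (n_intact, n_pseudo)
    n_excluded: int = 0     # genes without a category

    @property
    def n_intact_total(self) -> int:
        return sum(v[0] for v in self.counts.values())

    @property
    def n_pseudo_total(self) -> int:
        return sum(v[1] for v in self.counts.values())

    @property
    def n_total(self) -> int:
        return self.n_intact_total + self.n_pseudo_total

    def as_array(self) -> np.ndarray:
        """(n_categories, 2) array, columns (intact, pseudo)."""
        return np.array([self.counts[c] for c in self.categories], dtype=float)


@dataclass
class ChiSqResult:
    statistic: float
    df: int
    p_simulated: float
    B: int
    b_exceed: int
    residuals: dict         # category -> pseudogene-column residual
    seed: Optional[int] = None
    replicate_tables: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "B": self.B,
                "b_exceed": self.b_exceed, "p": self.p_simulated,
                "seed": self.seed,
                "residuals": {k: float(v) for k, v in self.residuals.items()}}


def build_table(features: FeatureSet) -> ContingencyTable:
    """Partition COG-labeled genes into intact and pseudogene counts.

    Genes without a category are excluded and counted separately.  Fewer
    than two categories present is a validation error.
    """
    counts: dict[str, list[int]] = {}
    excluded = 0
    for f in features:
        if f.ftype not in ("CDS", "pseudogene"):
            continue
        if f.cog_category is None:
            excluded += 1
            continue
        row = counts.setdefault(f.cog_category, [0, 0])
        row[1 if f.ftype == "pseudogene" else 0] += 1
    if len(counts) < 2:
        raise DegenerateTableError(
            f"need >= 2 COG categories with genes, found {len(counts)}")
    cats = sorted(counts)
    return ContingencyTable(cats, {c: tuple(counts[c]) for c in cats}, excluded)


def _expected(obs: np.ndarray) -> np.ndarray:
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    return row @ col / obs.sum()


def pearson_chisq(table: ContingencyTable) -> tuple[float, int]:
    """Pearson statistic sum (obs - exp)^2 / exp and df = n_categories - 1."""
    obs = table.as_array()
    if (obs.sum(axis=0) == 0).any():
        raise DegenerateTableError("a column total is zero")
    if (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("a category has no genes")
    exp = _expected(obs)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, len(table.categories) - 1


def simulated_pvalue(table: ContingencyTable, B: int = 2000,
                     seed: Optional[int] = None,
                     keep_replicates: bool = False) -> ChiSqResult:
    """Monte-Carlo p-value for the Pearson statistic, both margins fixed.

    Null replicates redistribute the pseudogene labels uniformly over genes
    within fixed category sizes (multivariate hypergeometric), i.e. a label
    permutation.  p = (b_exceed + 1) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    stat, df = pearson_chisq(table)
    obs = table.as_array()
    n_per_cat = obs.sum(axis=1).astype(int)
    n_pseudo = int(obs[:, 1].sum())
    exp = _expected(obs)

    rng = np.random.default_rng(seed)
    pseudo_counts = rng.multivariate_hypergeometric(
        n_per_cat, n_pseudo, size=B, method="marginals")
    rep = np.stack([n_per_cat[None, :] - pseudo_counts, pseudo_counts], axis=2)
    rep_stats = ((rep - exp[None, :, :]) ** 2 / exp[None, :, :]).sum(axis=(1, 2))
    b_exceed = int((rep_stats >= stat - 1e-12).sum())
    p = (b_exceed + 1) / (B + 1)

    resid = (obs - exp) / np.sqrt(exp)
    residuals = {c: float(resid[i, 1]) for i, c in enumerate(table.categories)}
    return ChiSqResult(stat, df, p, B, b_exceed, residuals, seed,
                       rep if keep_replicates else None)


def residual_report(result: ChiSqResult) -> list[tuple[str, float]]:
    """Categories sorted by pseudogene-column residual, most
    overrepresented first."""
    return sorted(result.residuals.items(), key=lambda kv: (-kv[1], kv[0]))
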