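"""Rank learned signatures against an immunomodulator gene-set collection.

Each signature's decoder loadings are tested for enrichment of the
immunomodulator set by a two-sided Wilcoxon rank-sum comparison of member vs
non-member loading magnitudes — a loading-scale-free choice, so rescaling a
signature cannot change its rank. Benjamini-Hochberg adjustment is applied
across the K signature-level tests; the summary reports how many of the
testable signatures are significantly associated with immunomodulation
(e.g. "164/258 = 63.6%"-style fractions) and the top-ranking signatures,
which are then profiled per subcategory (co-stimulator, co-inhibitor, ligand,
receptor, cell adhesion, antigen presentation, other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DimensionError
from .models import SignatureModel

SUBCATEGORIES = ("co-stimulator", "co-inhibitor", "ligand", "receptor",
                 "cell adhesion", "antigen presentation", "other")


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional per-gene subcategory labelling."""

    sets: dict[str, list[str]]
    subcategory: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ConfigurationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                self.sets[name] = list(dict.fromkeys(genes))

    def genes(self, name: str) -> list[str]:
        return self.sets[name]

    def subcategory_members(self, label: str) -> list[str]:
        return [g for g, sub in self.subcategory.items() if sub == label]


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> gene...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets)


def read_subcategories(path: str) -> dict[str, str]:
    """Two-column TSV (gene, subcategory) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "subcategory"],
                     comment="#")
    return dict(zip(df["gene"].astype(str), df["subcategory"].astype(str)))


def score_signature_vs_geneset(
    loadings: pd.Series,
    members: Sequence[str],
) -> tuple[float, float]:
    """Two-sided rank-sum test of member vs non-member loading magnitudes.

    Returns ``(statistic, p)`` where the statistic is the normal-approximation
    rank-sum z (exact p is used when both groups are small and tie-free);
    positive sign means member genes carry larger |loading|. Returns
    ``(nan, nan)`` when fewer than 2 members or 2 non-members intersect the
    loading vector — such signatures are flagged untestable upstream.
    """
    member_set = set(members)
    mask = loadings.index.isin(member_set)
    x = np.abs(loadings.values[mask])
    y = np.abs(loadings.values[~mask])
    if len(x) < 2 or len(y) < 2:
        return float("nan"), float("nan")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    # signed standardized statistic: positive when members rank higher
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0
    all_vals = np.concatenate([x, y])
    _, counts = np.unique(all_vals, return_counts=True)
    n = n1 + n2
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sd = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (res.statistic - mu) / sd if sd > 0 else 0.0
    return float(z), float(res.pvalue)


@dataclass
class SignatureRanking:
    """Per-signature enrichment table with BH adjustment and a top-k list."""

    table: pd.DataFrame           # index signature_id; statistic, p, p_adj, rank, testable
    n_significant: int
    n_total: int
    top_k: list[str]
    alpha: float

    @property
    def fraction_significant(self) -> float:
        return fraction_significant(self.n_significant, self.n_total)


def fraction_significant(n_significant: int, n_total: int) -> float:
    """Share of testable signatures called significant, as a percentage
    rounded to one decimal (so 164 of 258 reads 63.6)."""
    if n_total <= 0:
        raise ConfigurationError("n_total must be positive")
    return round(100.0 * n_significant / n_total, 1)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def rank_all_signatures(
    model: SignatureModel,
    gsc: GeneSetCollection,
    set_name: str = "immunomodulators",
    alpha: float = 0.05,
    top_k: int = 5,
) -> SignatureRanking:
    """Test every signature's loadings against the immunomodulator set.

    BH adjustment runs across the K signature-level tests; signatures with a
    degenerate member/non-member split are flagged untestable and excluded
    from the significance denominator. Top-k is ordered by adjusted p, then
    |statistic| (larger first), then signature index — a deterministic order.
    """
    members = gsc.genes(set_name)
    present = set(model.gene_ids) & set(members)
    if not present:
        raise DimensionError(
            f"gene set {set_name!r} shares no genes with the model universe")
    loadings = model.loadings_frame()

    rows = []
    for sig in model.signature_ids:
        stat, p = score_signature_vs_geneset(loadings[sig], members)
        rows.append({"signature": sig, "statistic": stat, "p": p,
                     "testable": np.isfinite(p)})
    table = pd.DataFrame(rows).set_index("signature")
    table["p_adj"] = bh_adjust(table["p"].values)

    order = np.lexsort((
        np.arange(len(table)),
        -np.abs(np.nan_to_num(table["statistic"].values, nan=0.0)),
        np.nan_to_num(table["p_adj"].values, nan=np.inf),
    ))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks

    testable = table["testable"]
    n_total = int(testable.sum())
    n_sig = int((table.loc[testable, "p_adj"] < alpha).sum())
    top = list(table.index[order][:top_k])
    return SignatureRanking(table=table, n_significant=n_sig, n_total=n_total,
                            top_k=top, alpha=alpha)


def subcategory_profile(
    ranking: SignatureRanking,
    model: SignatureModel,
    gsc: GeneSetCollection,
    subcategories: Sequence[str] = SUBCATEGORIES,
) -> pd.DataFrame:
    """Enrichment of each top-k signature against every subcategory.

    Rows are (signature, subcategory); subcategories with fewer than two
    member genes in the model universe are marked untestable. BH adjustment
    is applied within the whole table.
    """
    loadings = model.loadings_frame()
    universe = set(model.gene_ids)
    rows = []
    for sig in ranking.top_k:
        for sub in subcategories:
            members = [g for g in gsc.subcategory_members(sub) if g in universe]
            if len(members) < 2:
                rows.append({"signature": sig, "subcategory": sub,
                             "statistic": np.nan, "p": np.nan, "testable": False})
                continue
            stat, p = score_signature_vs_geneset(loadings[sig], members)
            rows.append({"signature": sig, "subcategory": sub, "statistic": stat,
                         "p": p, "testable": np.isfinite(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].values)
    return table


def make_immuno_collection(
    member_genes: Sequence[str],
    subcategory: Mapping[str, str] | None = None,
    name: str = "immunomodulators",
) -> GeneSetCollection:
    """Convenience constructor for a single immunomodulator set."""
    return GeneSetCollection(sets={name: list(member_genes)},
                             subcategory=dict(subcategory or {}))
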