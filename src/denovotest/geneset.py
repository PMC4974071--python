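"""Hypergeometric gene-set enrichment and differential-expression summary arithmetic.

Over-representation of a curated gene set among a query list (e.g. genes
differentially expressed in a tissue) is tested one-tailed against a
background universe restricted to expressed genes.  Companion helpers compute
the union/concordance arithmetic used when comparing DE lists across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd
from scipy import stats


def hypergeom_enrichment(M: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(M, K, n).

    M: background size; K: genes in the set; n: query size; k: overlap.
    """
    M, K, n, k = int(M), int(K), int(n), int(k)
    if K > M or n > M:
        raise ValueError(f"set size K={K} and query size n={n} must not exceed M={M}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if min(M, K, n, k) < 0:
        raise ValueError("all counts must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def de_union(total_a: int, total_b: int, shared: int) -> int:
    """Union count of two DE lists given their shared-gene count."""
    total_a, total_b, shared = int(total_a), int(total_b), int(shared)
    if shared > min(total_a, total_b):
        raise ValueError(
            f"shared count {shared} exceeds a list total ({total_a}, {total_b})"
        )
    if min(total_a, total_b, shared) < 0:
        raise ValueError("counts must be non-negative")
    return total_a + total_b - shared


def percentage(part: int, whole: int, decimals: int = 1) -> float:
    """100 * part / whole, rounded half-to-even to ``decimals`` places."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    if not 0 <= part <= whole:
        raise ValueError(f"part {part} outside [0, whole={whole}]")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(100) * Decimal(part) / Decimal(whole)).quantize(
        q, rounding=ROUND_HALF_EVEN
    )
    return float(val)


def bh_adjust(p_values) -> list:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    ps = [float(p) for p in p_values]
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, ps[i] * m / (rank_from_top + 1))
        adj[i] = running
    return adj


@dataclass(frozen=True)
class GeneSetTest:
    """One gene-set enrichment test over an expressed-gene background.

    Query genes absent from the background are dropped before counting (the
    background defines the universe); the number dropped is recorded.
    """

    name: str
    M: int
    K: int
    n: int
    k: int
    n_query_dropped: int = 0

    @classmethod
    def from_lists(cls, name, background, gene_set, query) -> "GeneSetTest":
        bg = set(map(str, background))
        gs = set(map(str, gene_set)) & bg
        q_raw = set(map(str, query))
        q = q_raw & bg
        return cls(
            name=str(name),
            M=len(bg),
            K=len(gs),
            n=len(q),
            k=len(q & gs),
            n_query_dropped=len(q_raw) - len(q),
        )

    @property
    def p_value(self) -> float:
        return hypergeom_enrichment(self.M, self.K, self.n, self.k)


def geneset_table(tests, bh: bool = False) -> pd.DataFrame:
    """Tidy table of enrichment tests, optionally BH-adjusted across sets."""
    rows = [
        {
            "set": t.name,
            "M": t.M,
            "K": t.K,
            "n": t.n,
            "k": t.k,
            "dropped_from_query": t.n_query_dropped,
            "p_value": t.p_value,
        }
        for t in tests
    ]
    df = pd.DataFrame(rows)
    if bh and len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"])
    return df


@dataclass(frozen=True)
class DESummary:
    """Per-tissue DE counts plus cross-tissue sharing/concordance arithmetic."""

    total_a: int
    up_a: int
    total_b: int
    up_b: int
    shared: int
    concordant: int

    def __post_init__(self):
        if self.up_a > self.total_a or self.up_b > self.total_b:
            raise ValueError("upregulated count exceeds tissue total")
        if self.shared > min(self.total_a, self.total_b):
            raise ValueError("shared count exceeds a tissue total")
        if self.concordant > self.union:
            raise ValueError("concordant count exceeds union")

    @property
    def down_a(self) -> int:
        return self.total_a - self.up_a

    @property
    def down_b(self) -> int:
        return self.total_b - self.up_b

    @property
    def union(self) -> int:
        return de_union(self.total_a, self.total_b, self.shared)

    def to_dict(self, decimals: int = 1) -> dict:
        return {
            "total_a": self.total_a,
            "up_a": self.up_a,
            "down_a": self.down_a,
            "up_a_percent": percentage(self.up_a, self.total_a, decimals),
            "down_a_percent": percentage(self.down_a, self.total_a, decimals),
            "total_b": self.total_b,
            "up_b": self.up_b,
            "down_b": self.down_b,
            "up_b_percent": percentage(self.up_b, self.total_b, decimals),
            "down_b_percent": percentage(self.down_b, self.total_b, decimals),
            "shared": self.shared,
            "union": self.union,
            "concordant": self.concordant,
            "concordant_percent": percentage(self.concordant, self.union, decimals),
        }
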