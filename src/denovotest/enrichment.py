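"""Poisson enrichment test for de novo mutations in a single gene.

The expected number of de novo mutations of a class in a cohort of trios is
the per-transmission class rate times the number of gene transmissions (two
per proband).  The observed count is compared with a Poisson distribution at
that mean via its upper tail, P(X >= k).  Two models are evaluated: (i)
loss-of-function enrichment alone and (ii) a combined functional statistic,
Fisher's combination of functional-class enrichment with missense clustering.
The better (smaller) p-value is selected and Bonferroni-corrected for the use
of two models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .genes import ClassRates


@dataclass(frozen=True)
class CohortSpec:
    """Trio counts per sub-cohort; the exposure for expected mutation counts."""

    sub_cohorts: tuple

    def __post_init__(self):
        subs = tuple((str(label), int(n)) for label, n in self.sub_cohorts)
        object.__setattr__(self, "sub_cohorts", subs)
        if not subs:
            raise ValueError("cohort must contain at least one sub-cohort")
        for label, n in subs:
            if n <= 0:
                raise ValueError(f"sub-cohort {label!r} must have > 0 trios, got {n}")

    @property
    def n_probands(self) -> int:
        return sum(n for _, n in self.sub_cohorts)

    @property
    def n_transmissions(self) -> int:
        """Transmitted gene copies: two per proband."""
        return 2 * self.n_probands

    @classmethod
    def single(cls, n_trios: int, label: str = "cohort") -> "CohortSpec":
        return cls(sub_cohorts=((label, n_trios),))


# The study cohort behind the published BCL11A assessment: DDD trios, clinical
# exome trios, PARI 2011 trios, and previously published DD trios.
DDD_COMBINED_COHORT = CohortSpec(
    sub_cohorts=(
        ("DDD", 4295),
        ("clinical_exomes", 2206),
        ("PARI_2011", 50),
        ("published_trios", 6138),
    )
)


@dataclass(frozen=True)
class ObservedCounts:
    """Observed de novo counts per aggregated class."""

    lof: int
    missense: int
    inframe_indel: int = 0

    def __post_init__(self):
        for name in ("lof", "missense", "inframe_indel"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")

    @property
    def functional(self) -> int:
        return self.lof + self.missense + self.inframe_indel

    @classmethod
    def from_variant_table(cls, variants: pd.DataFrame) -> "ObservedCounts":
        """Aggregate a parsed variant table (column ``consequence``)."""
        counts = variants["consequence"].value_counts().to_dict() if len(variants) else {}
        lof = sum(counts.get(c, 0) for c in ("nonsense", "splice_site", "frameshift"))
        return cls(
            lof=int(lof),
            missense=int(counts.get("missense", 0)),
            inframe_indel=int(counts.get("inframe_indel", 0)),
        )


def expected_count(class_rate: float, cohort: CohortSpec) -> float:
    """Expected de novo count: rate per transmission x gene transmissions."""
    if class_rate < 0:
        raise ValueError(f"class rate must be >= 0, got {class_rate}")
    return class_rate * cohort.n_transmissions


def poisson_upper_tail(lam: float, k: int) -> float:
    """P(X >= k) for X ~ Poisson(lam); equals 1 when k = 0."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if not isinstance(k, (int,)) or k < 0:
        raise ValueError(f"observed count must be a non-negative integer, got {k!r}")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def fisher_combine(p_values, zero_floor: float | None = None) -> float:
    """Fisher's method: X = -2 sum(ln p_i) ~ chi-square with 2m df under H0.

    Empirical p-values of exactly 0 (a Monte-Carlo sampling artifact) are
    floored at ``zero_floor`` — conventionally 1/(n_sim + 1) of the producing
    simulation — and are an error when no floor is supplied.
    """
    ps = []
    for p in p_values:
        p = float(p)
        if p > 1.0:
            raise ValueError(f"p-value {p} > 1")
        if p <= 0.0:
            if zero_floor is None:
                raise ValueError("p-value of 0 requires an explicit zero_floor")
            p = zero_floor
        ps.append(p)
    if not ps:
        raise ValueError("at least one p-value required")
    x = -2.0 * math.fsum(math.log(p) for p in ps)
    return float(stats.chi2.sf(x, df=2 * len(ps)))


def final_p(p_lof: float, p_combined: float) -> tuple:
    """Select the better model and Bonferroni-correct for testing two.

    Returns ``(p_final, selected_model)`` with ties resolved to ``"lof"``.
    """
    for name, p in (("p_lof", p_lof), ("p_combined", p_combined)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    selected = "lof" if p_lof <= p_combined else "functional+clustering"
    return min(1.0, 2.0 * min(p_lof, p_combined)), selected


class DeNovoEnrichmentModel:
    """De novo burden model for one gene.

    Parameters
    ----------
    class_rates : ClassRates
        Per-class mutation rates (probability per transmission).
    cohort : CohortSpec
        Trio composition; exposure is twice the proband count.
    observed : ObservedCounts
        Observed de novo counts aggregated into LoF / missense / in-frame.
    p_clustering : float, optional
        Missense clustering p-value (e.g. the add-one-smoothed empirical p
        from :class:`~denovotest.clustering.MissenseClusteringModel`).  When
        absent the combined statistic is the functional enrichment p alone.
    """

    def __init__(self, class_rates: ClassRates, cohort: CohortSpec,
                 observed: ObservedCounts, p_clustering: float | None = None):
        self.class_rates = class_rates
        self.cohort = cohort
        self.observed = observed
        self.p_clustering = p_clustering

    @classmethod
    def from_variant_table(cls, class_rates, cohort, variants: pd.DataFrame,
                           p_clustering: float | None = None):
        return cls(class_rates, cohort, ObservedCounts.from_variant_table(variants),
                   p_clustering=p_clustering)

    @classmethod
    def from_gene(cls, gene, rate_table, variants: pd.DataFrame, cohort: CohortSpec,
                  n_sim: int = 1_000_000, seed=None, class_rates=None,
                  missense_weights=None):
        """End-to-end constructor: derive class rates from the gene and rate
        table, and run the missense clustering test when the variant table
        carries at least two positioned missense SNVs (its add-one-smoothed p
        feeds the Fisher combination).  ``class_rates`` / ``missense_weights``
        may be supplied precomputed when testing many cohorts on one gene."""
        from .clustering import MissenseClusteringModel
        from .genes import compute_class_rates, site_weights

        if class_rates is None:
            class_rates = compute_class_rates(gene, rate_table)
        missense = variants[
            (variants["consequence"] == "missense") & variants["coding_pos"].notna()
        ]
        p_clustering = None
        if len(missense) >= 2:
            if missense_weights is None:
                missense_weights = site_weights(gene, rate_table, "missense")
            p_clustering = (
                MissenseClusteringModel(
                    missense_weights, missense["coding_pos"].astype(int).tolist()
                )
                .fit(n_sim=n_sim, seed=seed)
                .p_smoothed
            )
        return cls(class_rates, cohort, ObservedCounts.from_variant_table(variants),
                   p_clustering=p_clustering)

    def fit(self) -> "DeNovoEnrichmentResults":
        lam_lof = expected_count(self.class_rates.lof, self.cohort)
        lam_fun = expected_count(self.class_rates.functional, self.cohort)
        p_lof = poisson_upper_tail(lam_lof, self.observed.lof)
        p_fun = poisson_upper_tail(lam_fun, self.observed.functional)
        if self.p_clustering is None:
            p_combined = p_fun
        else:
            p_combined = fisher_combine([p_fun, self.p_clustering])
        p_fin, selected = final_p(p_lof, p_combined)
        return DeNovoEnrichmentResults(
            model=self,
            lambda_lof=lam_lof,
            lambda_functional=lam_fun,
            p_lof=p_lof,
            p_functional=p_fun,
            p_clustering=self.p_clustering,
            p_combined=p_combined,
            p_final=p_fin,
            selected_model=selected,
        )


@dataclass(frozen=True)
class DeNovoEnrichmentResults:
    """Fitted enrichment test: expected counts, per-model and final p-values."""

    model: DeNovoEnrichmentModel = field(repr=False)
    lambda_lof: float
    lambda_functional: float
    p_lof: float
    p_functional: float
    p_clustering: float | None
    p_combined: float
    p_final: float
    selected_model: str

    def to_frame(self) -> pd.DataFrame:
        gene = self.model.class_rates.meta.get("gene_id", "gene")
        return pd.DataFrame(
            [
                {
                    "gene": gene,
                    "n_probands": self.model.cohort.n_probands,
                    "n_transmissions": self.model.cohort.n_transmissions,
                    "obs_lof": self.model.observed.lof,
                    "obs_functional": self.model.observed.functional,
                    "lambda_lof": self.lambda_lof,
                    "lambda_functional": self.lambda_functional,
                    "p_lof": self.p_lof,
                    "p_functional": self.p_functional,
                    "p_clustering": self.p_clustering,
                    "p_combined": self.p_combined,
                    "p_final": self.p_final,
                    "selected_model": self.selected_model,
                }
            ]
        )

    def summary(self) -> str:
        obs = self.model.observed
        lines = [
            "De novo enrichment test",
            "=" * 55,
            f"gene:                {self.model.class_rates.meta.get('gene_id', 'gene')}",
            f"probands:            {self.model.cohort.n_probands}"
            f"  (transmissions: {self.model.cohort.n_transmissions})",
            f"observed LoF:        {obs.lof:>6d}   expected {self.lambda_lof:.6g}",
            f"observed functional: {obs.functional:>6d}   expected {self.lambda_functional:.6g}",
            "-" * 55,
            f"p (LoF enrichment):            {self.p_lof:.6g}",
            f"p (functional enrichment):     {self.p_functional:.6g}",
            f"p (missense clustering):       "
            + (f"{self.p_clustering:.6g}" if self.p_clustering is not None else "n/a"),
            f"p (combined functional):       {self.p_combined:.6g}",
            f"selected model:                {self.selected_model}",
            f"p (final, two-model Bonferroni): {self.p_final:.6g}",
        ]
        return "\n".join(lines)
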