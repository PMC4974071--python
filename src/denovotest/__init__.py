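"""denovotest: significance framework for de novo mutations in trio cohorts.

Core models (statsmodels-style: construct from data, ``fit()`` returns a
results object with a ``summary()``):

* :class:`~denovotest.enrichment.DeNovoEnrichmentModel` — Poisson burden test
  with Fisher combination of functional enrichment and missense clustering,
  two-model selection and Bonferroni correction.
* :class:`~denovotest.clustering.MissenseClusteringModel` — rate-weighted
  Monte-Carlo test of missense spatial clustering (geometric-mean coding
  distance).
* :class:`~denovotest.phenosim.PhenotypeSimilarityModel` — ontology-based
  phenotype similarity of proband sets with a random-set permutation null.

Supporting modules: :mod:`~denovotest.genes` (gene models, SNV classification,
class rates), :mod:`~denovotest.geneset` (hypergeometric enrichment, DE
summary arithmetic), :mod:`~denovotest.clinical` (clinical matrix summaries,
preference indices, movement bouts), :mod:`~denovotest.simulate` (synthetic
data generators), :mod:`~denovotest.io` (file formats, pipeline driver) and
:mod:`~denovotest.cli`.
"""

from .clustering import ClusteringResults, MissenseClusteringModel
from .enrichment import (
    CohortSpec,
    DDD_COMBINED_COHORT,
    DeNovoEnrichmentModel,
    DeNovoEnrichmentResults,
    ObservedCounts,
)
from .genes import (
    ClassRates,
    GeneModel,
    IndelParams,
    TrinucleotideRateTable,
    build_gene_model,
    classify_snv,
    compute_class_rates,
    site_weights,
)
from .phenosim import (
    ICTable,
    Ontology,
    PhenotypeSimilarityModel,
    PhenotypeSimilarityResults,
    ProbandAnnotations,
)

__version__ = "0.1.0"

__all__ = [
    "ClassRates",
    "ClusteringResults",
    "CohortSpec",
    "DDD_COMBINED_COHORT",
    "DeNovoEnrichmentModel",
    "DeNovoEnrichmentResults",
    "GeneModel",
    "ICTable",
    "IndelParams",
    "MissenseClusteringModel",
    "ObservedCounts",
    "Ontology",
    "PhenotypeSimilarityModel",
    "PhenotypeSimilarityResults",
    "ProbandAnnotations",
    "TrinucleotideRateTable",
    "build_gene_model",
    "classify_snv",
    "compute_class_rates",
    "site_weights",
]
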