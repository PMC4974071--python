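"""Phenotype similarity of proband sets over an ontology (Resnik-style).

Probands are annotated with terms from a rooted DAG ontology (e.g. the Human
Phenotype Ontology).  A term's information content is IC = -ln(usage/N), where
usage counts the probands annotated with the term or any of its descendants
(each proband at most once) and N is the reference cohort size.  The
similarity of two probands is the maximum, over all pairs of their terms, of
the IC of the pair's most informative common ancestor (MICA; ancestor sets
include the term itself).  A set of n probands scores the sum of all pairwise
similarities, and significance is the proportion of randomly drawn n-proband
sets (without replacement within a set) scoring at least as high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class OntologyError(ValueError):
    """Invalid ontology structure."""


class Ontology:
    """A rooted DAG of terms with is_a (child -> parent) edges."""

    def __init__(self, graph: nx.DiGraph):
        if not isinstance(graph, nx.DiGraph):
            raise OntologyError("ontology must be a directed graph")
        if graph.number_of_nodes() == 0:
            raise OntologyError("ontology is empty")
        if not nx.is_directed_acyclic_graph(graph):
            raise OntologyError("cycle detected in ontology")
        roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise OntologyError(f"ontology must have exactly one root, found {roots}")
        self.graph = graph
        self.root = roots[0]
        self._ancestor_cache: dict = {}

    @classmethod
    def from_edges(cls, edges) -> "Ontology":
        """Build from (child, parent) pairs; isolated roots are implied."""
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(str(child), str(parent))
        return cls(g)

    @property
    def terms(self) -> tuple:
        return tuple(self.graph.nodes)

    def __contains__(self, term) -> bool:
        return term in self.graph

    def parents(self, term):
        return tuple(self.graph.successors(term))

    def ancestors(self, term) -> frozenset:
        """Ancestor closure of a term, including the term itself."""
        if term not in self.graph:
            raise OntologyError(f"term {term!r} not in ontology")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached

    def edges(self):
        """Iterate (child, parent) pairs."""
        return self.graph.edges()


@dataclass(frozen=True)
class ProbandAnnotations:
    """Proband id -> non-empty set of ontology terms; N is the cohort size."""

    annotations: dict
    ontology: Ontology = field(repr=False)

    def __post_init__(self):
        clean = {}
        for pid, terms in self.annotations.items():
            terms = frozenset(str(t) for t in terms)
            if not terms:
                raise ValueError(f"proband {pid!r} has no terms")
            for t in terms:
                if t not in self.ontology:
                    raise OntologyError(f"term {t!r} (proband {pid!r}) not in ontology")
            clean[str(pid)] = terms
        if len(clean) < 2:
            raise ValueError("reference cohort must contain at least 2 probands")
        object.__setattr__(self, "annotations", clean)

    @property
    def n_probands(self) -> int:
        return len(self.annotations)

    @property
    def proband_ids(self) -> tuple:
        return tuple(self.annotations)

    def terms_of(self, pid) -> frozenset:
        try:
            return self.annotations[str(pid)]
        except KeyError:
            raise KeyError(f"unannotated proband {pid!r}") from None


def propagate_usage(ontology: Ontology, annotations: ProbandAnnotations) -> dict:
    """Term -> number of probands annotated with the term or a descendant.

    Each proband contributes at most 1 to any term's count, even when several
    of its terms descend from that term (set semantics via ancestor unions).
    """
    counts = {t: 0 for t in ontology.terms}
    for pid in annotations.proband_ids:
        closure = set()
        for t in annotations.terms_of(pid):
            closure |= ontology.ancestors(t)
        for t in closure:
            counts[t] += 1
    return counts


def ic(term, usage_counts: dict, n_probands: int) -> float:
    """Information content IC = -ln(usage/N), natural log."""
    count = usage_counts[term]
    if count > n_probands:
        raise ValueError(f"usage {count} exceeds cohort size {n_probands}")
    if count == 0:
        raise ValueError(f"term {term!r} has zero usage; IC undefined")
    return -math.log(count / n_probands)


class ICTable:
    """Information content per term, derived from propagated usage counts.

    Terms never used in the reference cohort have no defined IC; when queried
    directly they are treated as singleton usage in a cohort of N + 1,
    IC = ln(N + 1) — a conservative convention for external query terms.  As
    MICA candidates, zero-usage ancestors are skipped (they carry no cohort
    evidence), except that a term is always its own MICA candidate.
    """

    def __init__(self, ontology: Ontology, usage_counts: dict, n_probands: int):
        self.ontology = ontology
        self.usage_counts = dict(usage_counts)
        self.n_probands = int(n_probands)
        self._ic = {
            t: -math.log(c / n_probands)
            for t, c in self.usage_counts.items()
            if c > 0
        }
        self._fallback = math.log(n_probands + 1)

    @classmethod
    def from_annotations(cls, ontology: Ontology,
                         annotations: ProbandAnnotations) -> "ICTable":
        return cls(ontology, propagate_usage(ontology, annotations),
                   annotations.n_probands)

    def ic(self, term) -> float:
        if term not in self.ontology:
            raise OntologyError(f"term {term!r} not in ontology")
        val = self._ic.get(term)
        return self._fallback if val is None else val

    def used_ic(self, term) -> float | None:
        """IC if the term has nonzero cohort usage, else None."""
        return self._ic.get(term)

    def mica_ic(self, term_a, term_b) -> float:
        """IC of the most informative common ancestor of two terms."""
        common = self.ontology.ancestors(term_a) & self.ontology.ancestors(term_b)
        best = 0.0 if common else 0.0
        found = False
        for t in common:
            val = self._ic.get(t)
            if val is None:
                continue
            if not found or val > best:
                best, found = val, True
        if term_a == term_b and not found:
            return self.ic(term_a)  # self-MICA of an unused query term
        return best if found else 0.0


def pair_similarity(terms_a, terms_b, ic_table: ICTable) -> float:
    """Max MICA IC over all pairs of the two probands' terms (symmetric)."""
    if not terms_a or not terms_b:
        raise ValueError("both probands must be annotated")
    return max(
        ic_table.mica_ic(a, b) for a in terms_a for b in terms_b
    )


def set_score(proband_ids, annotations: ProbandAnnotations,
              ic_table: ICTable) -> float:
    """Sum of pairwise similarities over all n(n-1)/2 unordered pairs."""
    ids = list(proband_ids)
    if len(ids) < 2:
        raise ValueError("set score requires at least 2 probands")
    total = 0.0
    for i in range(len(ids)):
        ta = annotations.terms_of(ids[i])
        for j in range(i + 1, len(ids)):
            total += pair_similarity(ta, annotations.terms_of(ids[j]), ic_table)
    return total


class PhenotypeSimilarityModel:
    """Permutation test for phenotypic similarity of a proband set.

    Built from a reference cohort of annotated probands; ``fit`` scores a
    query set and compares it with randomly sampled same-size sets drawn
    uniformly without replacement from the full cohort.

    Internally the model precomputes a term-by-term MICA IC matrix and pads
    each proband's terms into an index array, so pairwise similarities and
    permutation scores are vectorised NumPy operations.
    """

    def __init__(self, ontology: Ontology, annotations: ProbandAnnotations):
        self.ontology = ontology
        self.annotations = annotations
        self.ic_table = ICTable.from_annotations(ontology, annotations)
        self._index = None

    # -- vectorised machinery -------------------------------------------------

    def _build_index(self):
        if self._index is not None:
            return self._index
        terms = list(self.ontology.terms)
        t_idx = {t: i for i, t in enumerate(terms)}
        nt = len(terms)
        anc = np.zeros((nt, nt), dtype=bool)
        for t in terms:
            for a in self.ontology.ancestors(t):
                anc[t_idx[t], t_idx[a]] = True
        ic_vec = np.array(
            [self.ic_table.used_ic(t) if self.ic_table.used_ic(t) is not None else -np.inf
             for t in terms]
        )
        # MICA matrix: overwrite in ascending IC order so the max survives.
        mica = np.zeros((nt, nt))
        order = np.argsort(ic_vec)
        for a in order:
            if not np.isfinite(ic_vec[a]):
                continue
            col = anc[:, a]
            mica[np.ix_(col, col)] = ic_vec[a]
        # Unused query terms: their self-MICA uses the fallback IC.
        fb = math.log(self.annotations.n_probands + 1)
        for i in range(nt):
            if not np.isfinite(ic_vec[i]) and mica[i, i] == 0.0:
                mica[i, i] = fb
        # Pad proband term lists to a rectangular index array; the pad index
        # points at an extra all -inf row/column so it never wins the max.
        pids = list(self.annotations.proband_ids)
        kmax = max(len(self.annotations.terms_of(p)) for p in pids)
        mica_pad = np.full((nt + 1, nt + 1), -np.inf)
        mica_pad[:nt, :nt] = mica
        tarr = np.full((len(pids), kmax), nt, dtype=np.int64)
        for r, p in enumerate(pids):
            for c, t in enumerate(sorted(self.annotations.terms_of(p))):
                tarr[r, c] = t_idx[t]
        self._index = {
            "pids": pids,
            "pid_row": {p: r for r, p in enumerate(pids)},
            "mica_pad": mica_pad,
            "tarr": tarr,
        }
        return self._index

    def _pair_sim_rows(self, rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
        """Similarity for aligned arrays of proband rows (vectorised)."""
        idx = self._build_index()
        ta = idx["tarr"][rows_a]  # (P, k)
        tb = idx["tarr"][rows_b]
        sims = idx["mica_pad"][ta[:, :, None], tb[:, None, :]]  # (P, k, k)
        return sims.max(axis=(1, 2))

    def _set_scores(self, sets: np.ndarray) -> np.ndarray:
        """Scores for an array of proband-row sets, shape (n_sets, n)."""
        n = sets.shape[1]
        total = np.zeros(sets.shape[0])
        for i in range(n):
            for j in range(i + 1, n):
                total += self._pair_sim_rows(sets[:, i], sets[:, j])
        return total

    # -- public surface --------------------------------------------------------

    def pair_similarity(self, pid_a, pid_b) -> float:
        return pair_similarity(
            self.annotations.terms_of(pid_a),
            self.annotations.terms_of(pid_b),
            self.ic_table,
        )

    def set_score(self, proband_ids) -> float:
        return set_score(proband_ids, self.annotations, self.ic_table)

    def fit(self, proband_ids, n_samples: int = 100_000,
            seed=None) -> "PhenotypeSimilarityResults":
        """Score a proband set and run the random-set permutation test.

        The default of 100,000 sampled sets follows the published analysis.
        """
        if seed is None:
            raise ValueError("seed is required for a reproducible permutation test")
        ids = [str(p) for p in proband_ids]
        n = len(ids)
        if n < 2:
            raise ValueError("need at least 2 probands")
        if n > self.annotations.n_probands:
            raise ValueError("query set larger than reference cohort")
        idx = self._build_index()
        rows = np.array([idx["pid_row"][p] for p in ids])
        observed = float(self._set_scores(rows[None, :])[0])
        rng = np.random.default_rng(seed)
        n_ref = self.annotations.n_probands
        # sample sets without replacement within each set
        keys = rng.random((int(n_samples), n_ref))
        sampled = np.argpartition(keys, n - 1, axis=1)[:, :n]
        scores = self._set_scores(sampled)
        p = float(np.count_nonzero(scores >= observed - 1e-12) / n_samples)
        return PhenotypeSimilarityResults(
            model=self,
            proband_ids=tuple(ids),
            observed_score=observed,
            n=n,
            n_samples=int(n_samples),
            p_value=p,
            seed=seed,
        )


@dataclass(frozen=True)
class PhenotypeSimilarityResults:
    """Observed set score and its random-set permutation p-value."""

    model: PhenotypeSimilarityModel = field(repr=False)
    proband_ids: tuple
    observed_score: float
    n: int
    n_samples: int
    p_value: float
    seed: object

    def to_dict(self) -> dict:
        return {
            "proband_ids": list(self.proband_ids),
            "observed_score": self.observed_score,
            "n": self.n,
            "n_samples": self.n_samples,
            "p_value": self.p_value,
            "seed": self.seed,
        }

    def summary(self) -> str:
        return "\n".join(
            [
                "Phenotype similarity permutation test",
                "=" * 45,
                f"probands in set:  {self.n}",
                f"reference cohort: {self.model.annotations.n_probands}",
                f"observed score:   {self.observed_score:.4f}",
                f"sampled sets:     {self.n_samples}",
                f"p (permutation):  {self.p_value:.6g}",
                f"seed:             {self.seed}",
            ]
        )


def permutation_p(observed_score: float, n: int, annotations: ProbandAnnotations,
                  ic_table: ICTable, n_samples: int, seed) -> float:
    """Proportion of randomly sampled n-proband sets scoring >= observed.

    Plain-loop reference path over :func:`set_score`; the model class provides
    the vectorised equivalent.
    """
    if n > annotations.n_probands:
        raise ValueError("n exceeds reference cohort size")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    pids = list(annotations.proband_ids)
    hits = 0
    for _ in range(int(n_samples)):
        chosen = rng.choice(len(pids), size=n, replace=False)
        score = set_score([pids[i] for i in chosen], annotations, ic_table)
        if score >= observed_score - 1e-12:
            hits += 1
    return hits / n_samples
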