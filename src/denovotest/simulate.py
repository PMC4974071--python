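"""Synthetic inputs with the statistical structure the analyses assume.

Generators cover every input the pipeline consumes: open reading frames with
exon structure, trinucleotide rate tables, Poisson de novo cohorts (null or
enriched, optionally with positionally clustered missense mutations), random
DAG ontologies with proband annotations (optionally embedding a "syndrome"
subset sharing a rare term), and open-field velocity traces with a known bout
schedule.  Every generator is deterministic given its seed; cohort and trace
outputs embed the seed and the true generating parameters for recovery tests.

A single root seed per run can be fanned out into independent per-generator
substreams with :func:`spawn_seeds`, so adding a generator does not perturb
the draws of the others.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import VelocityTrace
from .genes import (
    BASES,
    GeneModel,
    TrinucleotideRateTable,
    compute_class_rates,
    site_weights,
)
from .phenosim import Ontology, ProbandAnnotations

_STOPS = ("TAA", "TAG", "TGA")


def spawn_seeds(seed, n: int) -> list:
    """Derive n independent child seeds from one root seed."""
    return list(np.random.SeedSequence(seed).spawn(n))


def gen_gene(n_codons: int, gc_content: float = 0.5, seed=None,
             n_exons: int = 1, gene_id: str = "synthetic_gene") -> GeneModel:
    """Random ORF: ATG start, no internal stop, terminal stop codon.

    The sequence draws bases at the requested GC content; internal stop codons
    are resampled.  With ``n_exons > 1`` the CDS is split at random points and
    exons are placed on a synthetic chromosome with fixed-size introns.
    """
    if n_codons < 2:
        raise ValueError("need at least 2 codons (start + stop)")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(list(BASES), size=3, p=p))
            if codon not in _STOPS:
                break
        codons.append(codon)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    seq = "".join(codons)
    L = len(seq)
    if n_exons < 1 or n_exons > L:
        raise ValueError(f"n_exons must be in [1, {L}]")
    if n_exons == 1:
        splits = []
    else:
        splits = sorted(rng.choice(np.arange(1, L), size=n_exons - 1, replace=False))
    widths = np.diff([0] + list(splits) + [L])
    exons, cursor = [], 100
    intron = 500
    for w in widths:
        exons.append((cursor, cursor + int(w)))
        cursor += int(w) + intron
    flank_5 = str(rng.choice(list(BASES)))
    flank_3 = str(rng.choice(list(BASES)))
    return GeneModel(
        gene_id=gene_id,
        strand="+",
        exons=tuple(exons),
        cds_sequence=seq,
        flank_5=flank_5,
        flank_3=flank_3,
    )


def gen_rate_table(mode: str = "uniform", base_rate: float = 3e-9,
                   cpg_multiplier: float = 10.0, seed=None) -> TrinucleotideRateTable:
    """Trinucleotide rate table: uniform, or with CpG transitions elevated.

    ``cpg_elevated`` multiplies C->T rates in CG dinucleotide context (NCG
    contexts) and the reverse-strand equivalent G->A in CGN contexts by
    ``cpg_multiplier``, emulating the dominant hypermutability of real
    context-dependent rate maps.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be > 0")
    rates = {}
    for ctx_t in itertools.product(BASES, repeat=3):
        ctx = "".join(ctx_t)
        for alt in BASES:
            if alt == ctx[1]:
                continue
            r = base_rate
            if mode == "cpg_elevated":
                if ctx[1] == "C" and ctx[2] == "G" and alt == "T":
                    r *= cpg_multiplier
                elif ctx[1] == "G" and ctx[0] == "C" and alt == "A":
                    r *= cpg_multiplier
            elif mode != "uniform":
                raise ValueError(f"unknown mode {mode!r}")
            rates[(ctx, alt)] = r
    return TrinucleotideRateTable(rates)


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative-model settings for a synthetic de novo cohort.

    ``gamma`` multiplies the null per-class rates (1.0 for every class under
    the null); ``cluster_window`` (codons) confines missense positions to one
    randomly placed window for the clustered alternative.
    """

    n_trios: int
    gamma: dict = field(default_factory=dict)
    cluster_window: int | None = None
    seed: object = None

    def __post_init__(self):
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        for cls, g in self.gamma.items():
            if g < 0:
                raise ValueError(f"gamma[{cls!r}] must be >= 0")

    def gamma_for(self, cls: str) -> float:
        return float(self.gamma.get(cls, 1.0))


def simulate_cohort(gene: GeneModel, rates: TrinucleotideRateTable,
                    config: CohortSimConfig, class_rates=None,
                    site_tables: dict | None = None) -> pd.DataFrame:
    """Realise the Poisson generative model for de novo counts in one gene.

    Per class c the count is Poisson(gamma_c x rate_c x 2 x n_trios).  SNV
    positions are drawn from the class-specific rate-weighted site table;
    under the clustered alternative missense positions are drawn from sites
    inside a randomly placed window of ``cluster_window`` codons.  Indel and
    splice events carry no coding position.  Returns a tidy variant table
    whose ``attrs`` record the seed and true generating parameters.

    ``class_rates`` and ``site_tables`` (class -> SiteWeightTable) may be
    supplied precomputed when simulating many cohorts from one gene.
    """
    rng = np.random.default_rng(config.seed)
    if class_rates is None:
        class_rates = compute_class_rates(gene, rates)
    site_tables = site_tables or {}
    transmissions = 2 * config.n_trios
    if config.cluster_window is not None:
        window_nt = 3 * int(config.cluster_window)
        if window_nt > gene.coding_length:
            raise ValueError("cluster window exceeds gene length")
        win_start = int(rng.integers(0, gene.coding_length - window_nt + 1))
        window = (win_start, win_start + window_nt)
    else:
        window = None
    rows = []
    for cls in ("synonymous", "missense", "nonsense",
                "splice_site", "frameshift", "inframe_indel"):
        lam = config.gamma_for(cls) * class_rates.rate(cls) * transmissions
        count = int(rng.poisson(lam))
        if count == 0:
            continue
        if cls in ("synonymous", "missense", "nonsense"):
            table = site_tables.get(cls)
            if table is None:
                table = site_weights(gene, rates, cls)
                site_tables[cls] = table
            pos = np.asarray(table.positions)
            alts = np.asarray(table.alts)
            w = np.asarray(table.weights, dtype=float)
            if cls == "missense" and window is not None:
                mask = (pos >= window[0]) & (pos < window[1])
                if not mask.any():
                    raise ValueError("no missense sites inside the cluster window")
                pos, alts, w = pos[mask], alts[mask], w[mask]
            idx = rng.choice(len(pos), size=count, replace=True, p=w / w.sum())
            for i in idx:
                rows.append(
                    {
                        "gene": gene.gene_id,
                        "coding_pos": int(pos[i]),
                        "ref": gene.ref_base(int(pos[i])),
                        "alt": str(alts[i]),
                        "consequence": cls,
                    }
                )
        else:
            for _ in range(count):
                rows.append(
                    {
                        "gene": gene.gene_id,
                        "coding_pos": pd.NA,
                        "ref": pd.NA,
                        "alt": pd.NA,
                        "consequence": cls,
                    }
                )
    df = pd.DataFrame(
        rows, columns=["gene", "coding_pos", "ref", "alt", "consequence"]
    )
    df["coding_pos"] = df["coding_pos"].astype("Int64")
    df.attrs["seed"] = config.seed
    df.attrs["n_trios"] = config.n_trios
    df.attrs["gamma"] = dict(config.gamma)
    df.attrs["cluster_window"] = window
    df.attrs["class_rates"] = class_rates.to_dict()
    return df


@dataclass(frozen=True)
class OntologySimConfig:
    """Settings for a random ontology plus proband annotations."""

    depth: int = 3
    branching: int = 3
    n_probands: int = 100
    terms_per_proband: int = 3
    syndrome_size: int = 0
    extra_diamond_edges: int = 0
    seed: object = None

    def __post_init__(self):
        if self.depth < 2 or self.branching < 2:
            raise ValueError("depth and branching must each be >= 2")
        if self.n_probands < 2:
            raise ValueError("need at least 2 probands")
        if self.terms_per_proband < 1:
            raise ValueError("terms_per_proband must be >= 1")
        if self.syndrome_size > self.n_probands:
            raise ValueError("syndrome set larger than cohort")


def gen_ontology_and_annotations(config: OntologySimConfig) -> tuple:
    """Random rooted DAG with annotated probands.

    Builds a complete tree of the given depth and branching factor (optionally
    with extra "diamond" edges to a second parent, keeping it a DAG), then
    annotates each proband with terms drawn uniformly from the non-root terms.
    The first ``syndrome_size`` probands additionally share one rare leaf term
    that no background proband carries, emulating a cohort in which a small
    set of probands shares a specific phenotype.
    """
    rng = np.random.default_rng(config.seed)
    # complete tree: term ids T0 (root), T1, ...
    edges = []
    levels = [["T0"]]
    counter = 1
    for _ in range(config.depth):
        nxt = []
        for parent in levels[-1]:
            for _ in range(config.branching):
                term = f"T{counter}"
                counter += 1
                edges.append((term, parent))
                nxt.append(term)
        levels.append(nxt)
    all_terms = [t for lvl in levels for t in lvl]
    # diamond edges: a non-root term gains a second parent from a shallower level
    non_root = all_terms[1:]
    for _ in range(config.extra_diamond_edges):
        child = non_root[rng.integers(len(non_root))]
        child_level = next(i for i, lvl in enumerate(levels) if child in lvl)
        if child_level < 2:
            continue
        shallow = [t for i in range(child_level) for t in levels[i]]
        parent = shallow[rng.integers(len(shallow))]
        existing = {p for c, p in edges if c == child}
        if parent not in existing and parent != child:
            edges.append((child, parent))
    ontology = Ontology.from_edges(edges)
    leaves = levels[-1]
    syndrome_term = leaves[rng.integers(len(leaves))]
    background_pool = [t for t in non_root if t != syndrome_term]
    annotations = {}
    for i in range(config.n_probands):
        pid = f"P{i:05d}"
        k = min(config.terms_per_proband, len(background_pool))
        chosen = set(
            np.asarray(background_pool)[
                rng.choice(len(background_pool), size=k, replace=False)
            ]
        )
        if i < config.syndrome_size:
            chosen.add(syndrome_term)
        annotations[pid] = chosen
    ann = ProbandAnnotations(annotations=annotations, ontology=ontology)
    info = {
        "syndrome_term": syndrome_term,
        "syndrome_probands": [f"P{i:05d}" for i in range(config.syndrome_size)],
        "seed": config.seed,
    }
    return ontology, ann, info


def gen_velocity_trace(duration_frames: int, bout_schedule,
                       noise_sd: float = 0.0, seed=None,
                       moving_speed: float = 3.0, still_speed: float = 0.5,
                       frame_rate: float = 25.0) -> VelocityTrace:
    """Piecewise velocity trace with known movement bouts.

    ``bout_schedule`` is a list of non-overlapping half-open frame intervals
    during which the base speed is ``moving_speed``; elsewhere it is
    ``still_speed``.  Gaussian noise (sd ``noise_sd``) is added and truncated
    at zero.  The schedule and seed are embedded in the trace metadata for
    recovery tests.
    """
    if duration_frames < 2:
        raise ValueError("trace must have at least 2 frames")
    schedule = sorted((int(s), int(e)) for s, e in bout_schedule)
    prev_end = 0
    for s, e in schedule:
        if s < prev_end or e > duration_frames or e <= s:
            raise ValueError(f"invalid or overlapping schedule entry ({s}, {e})")
        prev_end = e
    rng = np.random.default_rng(seed)
    v = np.full(duration_frames, float(still_speed))
    for s, e in schedule:
        v[s:e] = moving_speed
    if noise_sd > 0:
        v = np.clip(v + rng.normal(0.0, noise_sd, size=duration_frames), 0.0, None)
    return VelocityTrace(
        velocities=v,
        frame_rate=frame_rate,
        meta={"schedule": schedule, "seed": seed, "noise_sd": noise_sd,
              "moving_speed": moving_speed, "still_speed": still_speed},
    )
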