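"""Coding gene models, SNV consequence classification, and per-class mutation rates.

A :class:`GeneModel` stores a gene's spliced coding sequence together with its
exon structure.  Every possible single-nucleotide substitution in the coding
sequence can be classified by its effect on the protein (synonymous, missense,
nonsense), and the classification combined with a trinucleotide-context
mutation-rate table yields per-class mutation rates: the expected probability,
per transmitted gene copy and generation, of a de novo mutation of each class.

Coordinate conventions: exons are 0-based half-open genomic intervals, sorted
and non-overlapping; coding positions are 0-based along the spliced CDS in
translation order.  Minus-strand genes are stored already reverse-complemented,
so the CDS always reads 5'->3' in translation order.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_STOP_CODONS = frozenset(_STANDARD.stop_codons)

SNV_CLASSES = ("synonymous", "missense", "nonsense")
INDEL_CLASSES = ("frameshift", "inframe_indel")
ALL_CLASSES = SNV_CLASSES + ("splice_site",) + INDEL_CLASSES


class GeneModelError(ValueError):
    """Invalid gene structure or sequence."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding structure: exons plus spliced CDS in translation order.

    Parameters
    ----------
    gene_id : str
        Stable identifier for the gene/transcript.
    strand : str
        ``"+"`` or ``"-"``.  Minus-strand sequences are stored already
        reverse-complemented so that ``cds_sequence`` is in translation order.
    exons : tuple of (int, int)
        Sorted, non-overlapping 0-based half-open genomic intervals.
    cds_sequence : str
        Spliced coding sequence over {A, C, G, T}; its length must equal the
        summed exon lengths and be at least one codon.
    flank_5, flank_3 : str or None
        Single bases flanking the CDS, giving trinucleotide context at the
        first and last coding positions.  When absent, boundary sites fall
        back to the gene's mean per-site rate during rate aggregation.
    """

    gene_id: str
    strand: str
    exons: tuple
    cds_sequence: str
    flank_5: str | None = None
    flank_3: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise GeneModelError("gene must have at least one exon")
        for s, e in exons:
            if e <= s:
                raise GeneModelError(f"empty or inverted exon [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise GeneModelError(f"overlapping exons [{s1},{e1}) and [{s2},{e2})")
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        if set(seq) - set(BASES):
            raise GeneModelError(
                f"non-ACGT characters in CDS: {sorted(set(seq) - set(BASES))}"
            )
        exon_len = sum(e - s for s, e in exons)
        if exon_len != len(seq):
            raise GeneModelError(
                f"CDS length {len(seq)} does not match summed exon length {exon_len}"
            )
        if len(seq) < 3:
            raise GeneModelError("CDS must be at least one codon long")
        for name in ("flank_5", "flank_3"):
            fl = getattr(self, name)
            if fl is not None:
                fl = fl.upper()
                if fl not in BASES:
                    raise GeneModelError(f"{name} must be a single ACGT base")
                object.__setattr__(self, name, fl)

    @property
    def coding_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def coding_to_genomic(self, coding_pos: int) -> int:
        """Map a 0-based coding position to its genomic coordinate."""
        if not 0 <= coding_pos < self.coding_length:
            raise IndexError(f"coding position {coding_pos} outside CDS")
        remaining = coding_pos
        exon_iter = self.exons if self.strand == "+" else reversed(self.exons)
        for s, e in exon_iter:
            width = e - s
            if remaining < width:
                return s + remaining if self.strand == "+" else e - 1 - remaining
            remaining -= width
        raise AssertionError("unreachable")

    def ref_base(self, coding_pos: int) -> str:
        return self.cds_sequence[coding_pos]

    def context(self, coding_pos: int) -> str | None:
        """Trinucleotide context of a coding position, or None at a CDS edge
        with no flank base supplied."""
        seq = self.cds_sequence
        if coding_pos == 0:
            if self.flank_5 is None:
                return None
            return self.flank_5 + seq[:2]
        if coding_pos == len(seq) - 1:
            if self.flank_3 is None:
                return None
            return seq[-2:] + self.flank_3
        return seq[coding_pos - 1 : coding_pos + 2]


def build_gene_model(gene_id, exons, cds_sequence, strand="+", flank_5=None,
                     flank_3=None) -> GeneModel:
    """Construct and validate a :class:`GeneModel`."""
    return GeneModel(
        gene_id=gene_id,
        strand=strand,
        exons=tuple(tuple(x) for x in exons),
        cds_sequence=cds_sequence,
        flank_5=flank_5,
        flank_3=flank_3,
    )


def classify_snv(model: GeneModel, coding_pos: int, alt: str,
                 stop_lost_class: str = "missense") -> str:
    """Consequence class of a coding SNV under the standard genetic code.

    Stop-gained substitutions are nonsense; substitutions in a reference stop
    codon that retain a stop are synonymous; stop-lost (and therefore also
    start-lost, which the codon table resolves naturally) default to missense.
    """
    L = model.coding_length
    if not 0 <= coding_pos < L:
        raise IndexError(f"coding position {coding_pos} outside CDS of length {L}")
    alt = alt.upper()
    if alt not in BASES:
        raise ValueError(f"alt must be one of {BASES}, got {alt!r}")
    ref = model.ref_base(coding_pos)
    if alt == ref:
        raise ValueError(f"alt base {alt} equals reference at position {coding_pos}")
    codon_start = (coding_pos // 3) * 3
    ref_codon = model.cds_sequence[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        # trailing partial codon (CDS not a multiple of 3): treat as missense
        return "missense"
    within = coding_pos - codon_start
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_stop = ref_codon in _STOP_CODONS
    alt_stop = alt_codon in _STOP_CODONS
    if alt_stop and not ref_stop:
        return "nonsense"
    if ref_stop and alt_stop:
        return "synonymous"
    if ref_stop and not alt_stop:
        return stop_lost_class
    return "synonymous" if _CODON_TO_AA[ref_codon] == _CODON_TO_AA[alt_codon] else "missense"


class RateTableError(ValueError):
    """Malformed trinucleotide rate table."""


class TrinucleotideRateTable:
    """Per-context, per-alternate SNV mutation rates.

    Exactly 192 entries: 64 trinucleotide contexts x 3 alternate bases
    (alternate differs from the context's center base).  Rates are
    probabilities per transmitted chromosome per generation, each in (0, 1).
    """

    def __init__(self, rates: dict):
        expected = {
            (c, a)
            for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
            for a in BASES
            if a != c[1]
        }
        keys = {(str(c).upper(), str(a).upper()) for c, a in rates}
        if keys != expected:
            missing = sorted(expected - keys)[:5]
            extra = sorted(keys - expected)[:5]
            raise RateTableError(
                f"rate table must have exactly 192 (context, alt) entries; "
                f"missing e.g. {missing}, unexpected e.g. {extra}"
            )
        clean = {}
        for (c, a), r in rates.items():
            r = float(r)
            if not 0.0 < r < 1.0:
                raise RateTableError(f"rate for ({c}, {a}) must be in (0, 1), got {r}")
            clean[(c.upper(), a.upper())] = r
        self._rates = clean

    def __getitem__(self, key):
        context, alt = key
        return self._rates[(context.upper(), alt.upper())]

    def items(self):
        return self._rates.items()

    @classmethod
    def uniform(cls, rate: float) -> "TrinucleotideRateTable":
        rates = {
            ("".join(c), a): rate
            for c in itertools.product(BASES, repeat=3)
            for a in BASES
            if a != c[1]
        }
        return cls(rates)


@dataclass(frozen=True)
class IndelParams:
    """Indel rate scaling relative to the nonsense SNV rate.

    ``frameshift_multiplier`` scales the nonsense rate to a frameshift rate;
    ``inframe_fraction`` scales the frameshift rate to an in-frame indel rate.
    Both are conventions (reported-estimate style scalings), echoed in output.
    """

    frameshift_multiplier: float = 1.25
    inframe_fraction: float = 0.1


@dataclass(frozen=True)
class ClassRates:
    """Per-class de novo mutation rates (probability per transmission)."""

    synonymous: float
    missense: float
    nonsense: float
    splice_site: float
    frameshift: float
    inframe_indel: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for cls in ALL_CLASSES:
            if getattr(self, cls) < 0:
                raise ValueError(f"{cls} rate must be >= 0")

    @property
    def lof(self) -> float:
        """Loss-of-function rate: nonsense + canonical splice site + frameshift."""
        return self.nonsense + self.splice_site + self.frameshift

    @property
    def functional(self) -> float:
        """Functional rate: LoF + missense + in-frame indels."""
        return self.lof + self.missense + self.inframe_indel

    def rate(self, cls: str) -> float:
        if cls in ALL_CLASSES:
            return getattr(self, cls)
        if cls == "lof":
            return self.lof
        if cls == "functional":
            return self.functional
        raise KeyError(f"unknown class {cls!r}")

    def to_dict(self) -> dict:
        d = {cls: getattr(self, cls) for cls in ALL_CLASSES}
        d["lof"] = self.lof
        d["functional"] = self.functional
        d["provenance"] = dict(self.meta)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compute_class_rates(model: GeneModel, rates: TrinucleotideRateTable,
                        indel_params: IndelParams | None = None,
                        stop_lost_class: str = "missense",
                        splice_positions_per_intron: int = 4) -> ClassRates:
    """Aggregate context rates over every possible coding SNV into class rates.

    Every (coding position, alternate base) pair is classified with
    :func:`classify_snv` and its trinucleotide-context rate accumulated into
    the matching class.  CDS-edge positions lacking a flank base contribute
    the gene's mean interior per-site rate split evenly across alternates.
    The canonical splice-site rate assumes ``splice_positions_per_intron``
    essential dinucleotide positions per intron (GT donor + AG acceptor = 4),
    each mutating at the gene's mean per-site SNV rate.  Indel class rates are
    scalings of the nonsense rate (see :class:`IndelParams`).
    """
    indel_params = indel_params or IndelParams()
    L = model.coding_length
    totals = {cls: 0.0 for cls in SNV_CLASSES}
    boundary = []  # (class,) for sites with no context
    interior_rate_sum = 0.0
    interior_positions = 0
    for pos in range(L):
        ref = model.ref_base(pos)
        ctx = model.context(pos)
        site_sum = 0.0
        for alt in BASES:
            if alt == ref:
                continue
            cls = classify_snv(model, pos, alt, stop_lost_class=stop_lost_class)
            if ctx is None:
                boundary.append(cls)
            else:
                r = rates[(ctx, alt)]
                totals[cls] += r
                site_sum += r
        if ctx is not None:
            interior_rate_sum += site_sum
            interior_positions += 1
    if interior_positions == 0:
        raise GeneModelError("gene has no positions with trinucleotide context")
    mean_site_rate = interior_rate_sum / interior_positions
    for cls in boundary:
        totals[cls] += mean_site_rate / 3.0
    splice = splice_positions_per_intron * model.n_introns * mean_site_rate
    frameshift = indel_params.frameshift_multiplier * totals["nonsense"]
    inframe = indel_params.inframe_fraction * frameshift
    return ClassRates(
        synonymous=totals["synonymous"],
        missense=totals["missense"],
        nonsense=totals["nonsense"],
        splice_site=splice,
        frameshift=frameshift,
        inframe_indel=inframe,
        meta={
            "gene_id": model.gene_id,
            "coding_length": L,
            "n_introns": model.n_introns,
            "frameshift_multiplier": indel_params.frameshift_multiplier,
            "inframe_fraction": indel_params.inframe_fraction,
            "splice_positions_per_intron": splice_positions_per_intron,
            "stop_lost_class": stop_lost_class,
            "mean_site_rate": mean_site_rate,
        },
    )


@dataclass(frozen=True)
class SiteWeightTable:
    """Per-(coding position, alt) sampling weights for one consequence class.

    Weights are the trinucleotide-context mutation rates of the sites that
    produce the class, so null sampling is rate-weighted.
    """

    positions: tuple
    alts: tuple
    weights: tuple
    coding_length: int
    consequence: str

    def __post_init__(self):
        if not self.positions:
            raise ValueError(f"no sites produce class {self.consequence!r}")
        if any(w <= 0 for w in self.weights):
            raise ValueError("all site weights must be > 0")

    @property
    def total_weight(self) -> float:
        return math.fsum(self.weights)

    def per_position_weights(self) -> dict:
        out = {}
        for p, w in zip(self.positions, self.weights):
            out[p] = out.get(p, 0.0) + w
        return out


def site_weights(model: GeneModel, rates: TrinucleotideRateTable,
                 consequence: str = "missense",
                 stop_lost_class: str = "missense") -> SiteWeightTable:
    """Rate weights of all sites whose substitution yields ``consequence``."""
    if consequence not in SNV_CLASSES:
        raise ValueError(f"consequence must be one of {SNV_CLASSES}")
    positions, alts, weights = [], [], []
    interior_sum, interior_n = 0.0, 0
    pending_boundary = []
    for pos in range(model.coding_length):
        ref = model.ref_base(pos)
        ctx = model.context(pos)
        site_sum = 0.0
        for alt in BASES:
            if alt == ref:
                continue
            cls = classify_snv(model, pos, alt, stop_lost_class=stop_lost_class)
            if cls != consequence:
                if ctx is not None:
                    site_sum += rates[(ctx, alt)]
                continue
            if ctx is None:
                pending_boundary.append((pos, alt))
            else:
                r = rates[(ctx, alt)]
                positions.append(pos)
                alts.append(alt)
                weights.append(r)
                site_sum += r
        if ctx is not None:
            interior_sum += site_sum
            interior_n += 1
    mean_site_rate = interior_sum / interior_n if interior_n else 0.0
    for pos, alt in pending_boundary:
        positions.append(pos)
        alts.append(alt)
        weights.append(mean_site_rate / 3.0 if mean_site_rate > 0 else 1.0)
    order = sorted(range(len(positions)), key=lambda i: (positions[i], alts[i]))
    return SiteWeightTable(
        positions=tuple(positions[i] for i in order),
        alts=tuple(alts[i] for i in order),
        weights=tuple(weights[i] for i in order),
        coding_length=model.coding_length,
        consequence=consequence,
    )
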