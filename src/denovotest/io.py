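"""Readers, writers, run configuration and the pipeline driver.

File dialects at the boundary follow clinical/bioinformatics convention:
exons as BED-like TSV (0-based half-open), CDS as FASTA keyed by gene id,
rate tables as ``context / alt / rate`` TSV, variant tables with 1-based
HGVS-like coding positions (converted to the internal 0-based system at parse
time), ontologies as OBO subsets (id / is_a stanzas) or two-column edge TSVs,
and proband annotations as ``proband_id<TAB>comma,separated,terms``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clustering import MissenseClusteringModel
from .enrichment import CohortSpec, DeNovoEnrichmentModel, ObservedCounts
from .genes import (
    ALL_CLASSES,
    GeneModel,
    TrinucleotideRateTable,
    compute_class_rates,
)
from .phenosim import Ontology, PhenotypeSimilarityModel, ProbandAnnotations

logger = logging.getLogger("denovotest")

SNV_ONLY = ("synonymous", "missense", "nonsense")


# -- gene model ------------------------------------------------------------------


def write_gene_model(model: GeneModel, bed_path, fasta_path, chrom: str = "chr1"):
    rows = [
        {"chrom": chrom, "start": s, "end": e, "gene_id": model.gene_id,
         "strand": model.strand}
        for s, e in model.exons
    ]
    pd.DataFrame(rows).to_csv(bed_path, sep="\t", index=False, header=False)
    desc = []
    if model.flank_5:
        desc.append(f"flank_5={model.flank_5}")
    if model.flank_3:
        desc.append(f"flank_3={model.flank_3}")
    rec = SeqRecord(Seq(model.cds_sequence), id=model.gene_id,
                    description=" ".join(desc))
    SeqIO.write([rec], str(fasta_path), "fasta")


def read_gene_model(bed_path, fasta_path, gene_id: str | None = None) -> GeneModel:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "strand"],
    )
    if gene_id is not None:
        bed = bed[bed["gene_id"] == gene_id]
    if bed.empty:
        raise ValueError(f"no exons found for gene {gene_id!r} in {bed_path}")
    gid = bed["gene_id"].iloc[0]
    strand = bed["strand"].iloc[0]
    exons = tuple(sorted((int(s), int(e)) for s, e in zip(bed["start"], bed["end"])))
    record = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id == gid:
            record = rec
            break
    if record is None:
        raise ValueError(f"gene {gid!r} not found in FASTA {fasta_path}")
    flank_5 = flank_3 = None
    for token in record.description.split():
        if token.startswith("flank_5="):
            flank_5 = token.split("=", 1)[1]
        elif token.startswith("flank_3="):
            flank_3 = token.split("=", 1)[1]
    return GeneModel(
        gene_id=gid, strand=strand, exons=exons, cds_sequence=str(record.seq),
        flank_5=flank_5, flank_3=flank_3,
    )


# -- rate tables -------------------------------------------------------------------


def write_rate_table(table: TrinucleotideRateTable, path):
    rows = [{"context": c, "alt": a, "rate": r} for (c, a), r in sorted(table.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rate_table(path) -> TrinucleotideRateTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"context", "alt", "rate"}
    if not required <= set(df.columns):
        raise ValueError(f"rate table requires columns {sorted(required)}")
    return TrinucleotideRateTable(
        {(str(r.context), str(r.alt)): float(r.rate) for r in df.itertuples()}
    )


# -- variant tables -----------------------------------------------------------------


def parse_variant_table(path, gene_model: GeneModel | None = None) -> pd.DataFrame:
    """Parse a de novo variant TSV into validated internal records.

    Expected columns: ``gene``, ``position`` (1-based coding position; empty
    for events without one, e.g. splice sites), ``ref``, ``alt``, and
    ``consequence`` (one of the class vocabulary).  When a gene model is
    supplied, SNV reference bases are checked against its CDS.
    """
    df = pd.read_csv(path, sep="\t", dtype="string", keep_default_na=False,
                     comment="#")
    required = {"gene", "position", "ref", "alt", "consequence"}
    if len(df) == 0 and not required <= set(df.columns):
        logger.warning("empty variant table %s", path)
        return pd.DataFrame(
            columns=["gene", "coding_pos", "ref", "alt", "consequence"]
        ).astype({"coding_pos": "Int64"})
    if not required <= set(df.columns):
        raise ValueError(f"variant table requires columns {sorted(required)}")
    if len(df) == 0:
        logger.warning("empty variant table %s", path)
    rows = []
    for i, rec in enumerate(df.itertuples(), start=1):
        cons = str(rec.consequence).strip()
        if cons not in ALL_CLASSES:
            raise ValueError(
                f"row {i}: unknown consequence class {cons!r} "
                f"(expected one of {ALL_CLASSES})"
            )
        pos_token = str(rec.position).strip()
        if pos_token in ("", "NA", "."):
            coding_pos = pd.NA
        else:
            try:
                pos_1based = int(pos_token)
            except ValueError:
                raise ValueError(f"row {i}: malformed coding position {pos_token!r}")
            if pos_1based < 1:
                raise ValueError(f"row {i}: coding position must be >= 1")
            coding_pos = pos_1based - 1
        ref = str(rec.ref).strip() or None
        alt = str(rec.alt).strip() or None
        if cons in SNV_ONLY:
            if coding_pos is pd.NA or ref in (None, ".") or alt in (None, "."):
                raise ValueError(f"row {i}: SNV class {cons} requires position/ref/alt")
            if gene_model is not None:
                if coding_pos >= gene_model.coding_length:
                    raise ValueError(
                        f"row {i}: position beyond CDS length {gene_model.coding_length}"
                    )
                actual = gene_model.ref_base(coding_pos)
                if actual != ref:
                    raise ValueError(
                        f"row {i}: ref base {ref} does not match CDS base {actual} "
                        f"at coding position {coding_pos + 1}"
                    )
        rows.append(
            {"gene": str(rec.gene), "coding_pos": coding_pos, "ref": ref,
             "alt": alt, "consequence": cons}
        )
    out = pd.DataFrame(rows, columns=["gene", "coding_pos", "ref", "alt", "consequence"])
    out["coding_pos"] = out["coding_pos"].astype("Int64")
    return out


def write_variant_table(df: pd.DataFrame, path):
    """Write internal variant records with 1-based user-facing positions."""
    out = df.copy()
    out["position"] = (out["coding_pos"] + 1).astype("Int64")
    out = out[["gene", "position", "ref", "alt", "consequence"]]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# -- ontology / annotations -----------------------------------------------------------


def parse_obo_subset(path) -> Ontology:
    """Read an OBO subset (id / is_a stanzas) or a child-parent edge TSV."""
    path = Path(path)
    if path.suffix.lower() == ".obo":
        multi = obonet.read_obo(str(path))
        g = nx.DiGraph()
        g.add_nodes_from(multi.nodes)
        for u, v, key in multi.edges(keys=True):
            if key == "is_a":
                g.add_edge(u, v)
        return Ontology(g)
    df = pd.read_csv(path, sep="\t", comment="#", dtype="string")
    cols = list(df.columns)
    if {"child", "parent"} <= set(cols):
        pairs = zip(df["child"], df["parent"])
    else:  # headerless two-column file
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["child", "parent"], dtype="string")
        pairs = zip(df["child"], df["parent"])
    return Ontology.from_edges(pairs)


def write_ontology_edges(ontology: Ontology, path):
    pd.DataFrame(
        [{"child": c, "parent": p} for c, p in sorted(ontology.edges())]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path, ontology: Ontology) -> ProbandAnnotations:
    df = pd.read_csv(path, sep="\t", dtype="string", comment="#")
    if not {"proband_id", "terms"} <= set(df.columns):
        raise ValueError("annotation table requires columns proband_id, terms")
    ann = {
        str(r.proband_id): {t.strip() for t in str(r.terms).split(",") if t.strip()}
        for r in df.itertuples()
    }
    return ProbandAnnotations(annotations=ann, ontology=ontology)


def write_annotations(annotations: ProbandAnnotations, path):
    rows = [
        {"proband_id": pid, "terms": ",".join(sorted(annotations.terms_of(pid)))}
        for pid in annotations.proband_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- run configuration and pipeline -----------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration (see the packaged YAML example)."""

    gene_bed: str | None = None
    gene_fasta: str | None = None
    gene_id: str | None = None
    rate_table: str | None = None
    variants: str | None = None
    cohort: list = field(default_factory=list)  # [[label, n_trios], ...]
    ontology: str | None = None
    annotations: str | None = None
    probands: list = field(default_factory=list)
    n_sim: int = 1_000_000
    n_samples: int = 100_000
    seed: int | None = None
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = Path(path).parent
        for name in ("gene_bed", "gene_fasta", "rate_table", "variants",
                     "ontology", "annotations"):
            val = getattr(cfg, name)
            if val is not None:
                p = Path(val)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
                setattr(cfg, name, str(p))
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the stages the configuration enables, in dependency order.

    Stages: class rates (gene + rate table), missense clustering (rates stage
    + variants with >= 2 missense SNVs), enrichment (class rates + variants +
    cohort), phenotype similarity (ontology + annotations + probands).  Every
    stochastic stage requires a seed; results and per-stage files land in
    ``outdir`` together with a ``summary.json`` echoing seeds and sizes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    logger.info("run config hash %s", bundle["config_hash"])

    gene = rates = class_rates = None
    if config.gene_bed and config.gene_fasta:
        gene = read_gene_model(config.gene_bed, config.gene_fasta, config.gene_id)
    if config.rate_table:
        rates = read_rate_table(config.rate_table)
    if gene is not None and rates is not None:
        class_rates = compute_class_rates(gene, rates)
        (outdir / "class_rates.json").write_text(class_rates.to_json(indent=2))
        bundle["class_rates"] = class_rates.to_dict()

    variants = None
    if config.variants:
        variants = parse_variant_table(config.variants, gene_model=gene)
        bundle["n_variants"] = int(len(variants))

    p_clustering = None
    if variants is not None and gene is not None and rates is not None:
        missense = variants[
            (variants["consequence"] == "missense") & variants["coding_pos"].notna()
        ]
        if len(missense) >= 2:
            if config.seed is None:
                raise ValueError("clustering stage requires a seed")
            cl = MissenseClusteringModel.from_gene(
                gene, rates, missense["coding_pos"].astype(int).tolist()
            ).fit(n_sim=config.n_sim, seed=config.seed)
            p_clustering = cl.p_smoothed
            (outdir / "clustering.json").write_text(
                json.dumps(cl.to_dict(), indent=2)
            )
            bundle["clustering"] = cl.to_dict()

    if config.cohort:
        if class_rates is None or variants is None:
            raise ValueError(
                "enrichment stage requires gene model, rate table and variants"
            )
        cohort = CohortSpec(sub_cohorts=tuple((l, int(n)) for l, n in config.cohort))
        res = DeNovoEnrichmentModel(
            class_rates, cohort, ObservedCounts.from_variant_table(variants),
            p_clustering=p_clustering,
        ).fit()
        res.to_frame().to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        bundle["enrichment"] = res.to_frame().iloc[0].to_dict()
        logger.info(
            "enrichment: %d probands, p_final=%.3g",
            cohort.n_probands, res.p_final,
        )

    if config.ontology and config.annotations and config.probands:
        if config.seed is None:
            raise ValueError("phenotype similarity stage requires a seed")
        onto = parse_obo_subset(config.ontology)
        ann = read_annotations(config.annotations, onto)
        sim = PhenotypeSimilarityModel(onto, ann).fit(
            config.probands, n_samples=config.n_samples, seed=config.seed
        )
        (outdir / "phenotype_similarity.json").write_text(
            json.dumps(sim.to_dict(), indent=2)
        )
        bundle["phenotype_similarity"] = sim.to_dict()

    (outdir / "summary.json").write_text(json.dumps(bundle, indent=2, default=str))
    return bundle
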