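"""The miRNA regulome: element sets and TAS-element intersection.

The regulome is the compendium of elements that regulate miRNA expression
(pre-miRNA hairpins, miRNA promoters) or are regulated by miRNA activity
(3'-UTR target regions).  This module loads those element sets from their
standard formats (miRBase-dialect GFF3, BED6, TargetScan-dialect UTR
tables), applies the UTR admission filters (unique, unspliced genomic
mapping; length >= 20 nt), and intersects LD-block members with elements
to produce the TAS x element table.

All intervals are 0-based half-open internally; BED is already 0-based,
GFF3 and VCF positions are converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from ._errors import DataError
from .ld import LDBlock

log = logging.getLogger(__name__)

ELEMENT_KINDS = ("pre_mirna", "promoter", "utr3")


@dataclass(frozen=True)
class RegulomeElement:
    """A genomic interval belonging to the miRNA regulome."""

    kind: str  # pre_mirna | promoter | utr3
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    owner: str  # miRNA name (pre_mirna, promoter) or gene symbol (utr3)
    source: str = ""

    def __post_init__(self):
        if self.kind not in ELEMENT_KINDS:
            raise DataError(f"unknown element kind {self.kind!r}")
        if not self.start < self.end:
            raise DataError(
                f"element {self.owner}: empty interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class Mapping:
    """One candidate genomic alignment of a UTR, as aligned segments."""

    chrom: str
    strand: str
    segments: tuple[tuple[int, int], ...]  # 0-based half-open

    @property
    def start(self) -> int:
        return min(s[0] for s in self.segments)

    @property
    def end(self) -> int:
        return max(s[1] for s in self.segments)

    @property
    def spliced(self) -> bool:
        return len(self.segments) > 1


@dataclass
class UTRRecord:
    """A 3'-UTR sequence for one gene in one species.

    Human records pass the admission filter only with a single unspliced
    genomic mapping and a sequence of at least 20 nt; ortholog records are
    sequence-only and used for conservation scoring.
    """

    gene_symbol: str
    species: str  # human | mouse | rat | dog | chicken
    sequence: str
    mappings: list[Mapping] = field(default_factory=list)
    genomic_mapping: Mapping | None = None


#: Minimum admissible UTR length in nt (shorter sequences cannot be
#: reliably aligned to the genome).
MIN_UTR_LENGTH = 20


def filter_utr_mappings(
    records: list[UTRRecord],
) -> tuple[list[UTRRecord], list[tuple[UTRRecord, str]]]:
    """Apply the UTR admission filter.

    Human records are rejected (with a reason) if they map perfectly to
    multiple locations (``multi_mapped``), if any candidate mapping is
    spliced (``spliced``), if the sequence is shorter than 20 nt
    (``too_short``), or if they have no mapping at all (``unmapped``).
    Admitted human records get their unique mapping promoted to
    ``genomic_mapping``.  Non-human records are admitted as-is.  The two
    output lists partition the input.
    """
    admitted: list[UTRRecord] = []
    rejected: list[tuple[UTRRecord, str]] = []
    for rec in records:
        if rec.species != "human":
            admitted.append(rec)
            continue
        if len(rec.mappings) > 1:
            rejected.append((rec, "multi_mapped"))
        elif any(m.spliced for m in rec.mappings):
            rejected.append((rec, "spliced"))
        elif len(rec.sequence) < MIN_UTR_LENGTH:
            rejected.append((rec, "too_short"))
        elif not rec.mappings:
            rejected.append((rec, "unmapped"))
        else:
            rec.genomic_mapping = rec.mappings[0]
            admitted.append(rec)
    return admitted, rejected


def naive_map_utr(sequence: str, genome: dict[str, str]) -> list[Mapping]:
    """Exact-substring mapper for fixture-scale genomes.

    Finds every occurrence of ``sequence`` on both strands of every
    chromosome, each reported as a single-segment mapping.  Only suitable
    for small synthetic genomes; real UTR mappings are an input.
    """
    query = sequence.upper().replace("U", "T")
    rc = str(Seq(query).reverse_complement())
    hits: list[Mapping] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for probe, strand in ((query, "+"), (rc, "-")):
            i = seq.find(probe)
            while i != -1:
                hits.append(Mapping(chrom, strand, ((i, i + len(probe)),)))
                i = seq.find(probe, i + 1)
    return hits


# --------------------------------------------------------------------- io

def load_genome_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def load_mirna_fasta(path: str):
    """Mature miRNA sequences from FASTA; returns a list of MiRNA."""
    from .sites import MiRNA

    return [MiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def load_mirbase_gff3(path: str) -> list[RegulomeElement]:
    """Pre-miRNA (``miRNA_primary_transcript``) intervals from a
    miRBase-dialect GFF3.  Mature ``miRNA`` features are ignored here; only
    the hairpin precursor is a regulome element."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    elements = []
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [""])[0]
        elements.append(
            RegulomeElement("pre_mirna", feat.seqid, feat.start - 1, feat.end,
                            feat.strand, name, source="mirbase")
        )
    return elements


def load_bed(path: str, kind: str, source: str = "") -> list[RegulomeElement]:
    """BED6 intervals as regulome elements of one kind."""
    table = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return [
        RegulomeElement(kind, r.chrom, int(r.start), int(r.end),
                        str(r.strand), str(r.name), source)
        for r in table.itertuples()
    ]


def load_bed_intervals(path: str) -> list[tuple[str, int, int]]:
    """Plain (chrom, start, end) intervals from a BED file (e.g. exons)."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#",
                        usecols=[0, 1, 2], names=["chrom", "start", "end"],
                        dtype={"chrom": str})
    return [(r.chrom, int(r.start), int(r.end)) for r in table.itertuples()]


def load_utr_table(
    path: str, symbol_map: dict[str, str] | None = None
) -> list[UTRRecord]:
    """TargetScan-download-dialect UTR table: tab-delimited
    (sequence ID, species tag, sequence).  Alignment gap characters are
    stripped.  IDs are converted to gene symbols through ``symbol_map``;
    unmapped IDs are kept as-is with one warning."""
    records = []
    unmapped: set[str] = set()
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["seq_id", "species", "sequence"], dtype=str)
    for r in table.itertuples():
        symbol = str(r.seq_id)
        if symbol_map is not None:
            if symbol in symbol_map:
                symbol = symbol_map[symbol]
            else:
                unmapped.add(symbol)
        records.append(
            UTRRecord(symbol, str(r.species), str(r.sequence).replace("-", ""))
        )
    if unmapped:
        log.warning("%d UTR sequence IDs had no gene-symbol mapping and were "
                    "kept verbatim (e.g. %s)", len(unmapped),
                    sorted(unmapped)[0])
    return records


def load_symbol_map(path: str) -> dict[str, str]:
    """Two-column TSV mapping sequence IDs (RefSeq-style) to gene symbols."""
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["seq_id", "symbol"], dtype=str)
    return dict(zip(table.seq_id, table.symbol))


def load_utr_mappings(path: str) -> dict[str, list[Mapping]]:
    """Candidate genomic mappings per UTR: TSV with columns
    (seq_id, chrom, strand, segments) where segments is a comma-separated
    list of 0-based half-open ``start-end`` spans."""
    out: dict[str, list[Mapping]] = {}
    table = pd.read_csv(path, sep="\t", dtype=str)
    for r in table.itertuples():
        segs = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in str(r.segments).split(",")
        )
        out.setdefault(str(r.seq_id), []).append(
            Mapping(str(r.chrom), str(r.strand), segs)
        )
    return out


def utr_elements(records: list[UTRRecord]) -> list[RegulomeElement]:
    """Regulome elements for admitted human UTRs with genomic mappings."""
    out = []
    for rec in records:
        if rec.species == "human" and rec.genomic_mapping is not None:
            m = rec.genomic_mapping
            out.append(
                RegulomeElement("utr3", m.chrom, m.start, m.end, m.strand,
                                rec.gene_symbol, source="utr_table")
            )
    return out


# ------------------------------------------------------------ intersection

@dataclass(frozen=True)
class TAS:
    """A trait-associated SNP: an LD-block member with its provenance."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    r2: float
    minor_allele: str
    maf: float
    index_snp: str
    trait: str
    population: str


def tas_from_blocks(blocks: list[LDBlock]) -> list[TAS]:
    return [
        TAS(m.rsid, m.chrom, m.pos, m.r2, m.minor_allele, m.maf,
            blk.index_snp, blk.trait, blk.population.value)
        for blk in blocks
        for m in blk.members
    ]


def intersect_tas(
    blocks: list[LDBlock],
    elements: list[RegulomeElement],
) -> list[tuple[TAS, RegulomeElement]]:
    """Intersect LD-block member SNPs with regulome elements.

    Emits one pair per (member SNP, containing element); a SNP inside
    several elements (or element kinds) yields several pairs.  Output is
    stable-sorted by (chrom, pos, kind).  Disjoint chromosome naming
    between the two inputs is reported as a warning with per-chromosome
    counts.
    """
    trees: dict[str, IntervalTree] = {}
    for i, el in enumerate(elements):
        trees.setdefault(el.chrom, IntervalTree()).addi(el.start, el.end, i)

    tases = tas_from_blocks(blocks)
    snp_chroms = {t.chrom for t in tases}
    if tases and elements and not (snp_chroms & set(trees)):
        counts = {c: sum(1 for t in tases if t.chrom == c) for c in snp_chroms}
        log.warning(
            "no chromosome shared between SNPs and elements; SNP chromosome "
            "counts: %s; element chromosomes: %s", counts, sorted(trees),
        )

    pairs: list[tuple[TAS, RegulomeElement]] = []
    for tas in tases:
        tree = trees.get(tas.chrom)
        if tree is None:
            continue
        for hit in tree[tas.pos - 1]:  # 1-based SNP -> 0-based point query
            pairs.append((tas, elements[hit.data]))
    pairs.sort(key=lambda p: (p[0].chrom, p[0].pos, p[1].kind, p[0].rsid,
                              p[1].owner))
    return pairs
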