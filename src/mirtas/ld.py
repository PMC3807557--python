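"""Linkage-disequilibrium core.

Assigns each GWAS cohort to one of the four continental 1000-Genomes-style
super-populations, computes pairwise r-squared and minor-allele frequency
from phased haplotypes, and expands each GWAS index SNP into an LD block of
trait-associated SNPs (TASs).

r-squared here is the squared allelic correlation estimated directly from
haplotype frequencies,

    r2 = D^2 / (pA (1 - pA) pB (1 - pB)),   D = pAB - pA pB,

which is exact for phased data and needs no EM step.  Haplotypes missing an
allele at either SNP of a pair are excluded pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import pysam

from ._errors import DataError, PanelLookupError

log = logging.getLogger(__name__)


class SuperPopulation(str, Enum):
    """Continental super-population of a reference haplotype panel."""

    EUR = "EUR"
    AFR = "AFR"
    AMR = "AMR"
    ASN = "ASN"


# Keyword rows for cohort-ancestry matching, in precedence order: the first
# row containing any case-insensitive substring hit wins, and a text that
# matches nothing falls back to EUR.  Keywords with embedded spaces (" UK ",
# "Kinh ") rely on the text being padded with spaces before matching.
ANCESTRY_KEYWORDS: list[tuple[SuperPopulation, tuple[str, ...]]] = [
    (
        SuperPopulation.EUR,
        (
            "Indian", "India", "Europe", "Canadian", "Canada", "Caucasian",
            "White", "Framingham", "Norwegian", "Norway", "French", "France",
            "Iceland", "German", "Germany", "Scandanavia", "Finnish",
            "Finland", " UK ", "Welsh", "Wales", "Irish", "Ireland",
            "Scottish", "Scotland", "Spanish", "Spain", "Iberia", "Toscani",
            "Tuscan", "Utah", "CEPH", "England", "English", "Swiss",
            "Switzerland", "Australia", "Turkish", "Turkey", "Saami",
            "Belgium", "Belgian", "Russia", "Polish", "Poland",
        ),
    ),
    (
        SuperPopulation.AFR,
        (
            "Africa", "Ghani", "Malawi", "Yoruba", "Esan", "Mende", "Sierra",
            "Leone", "Gambia", "Kenya", "Luhya",
        ),
    ),
    (
        SuperPopulation.AMR,
        (
            "Mexico", "Mexican", "Hispanic", "Peru", "Puerto", "Rico",
            "Rican", "Colombia", "Medellin", "Lima",
        ),
    ),
    (
        SuperPopulation.ASN,
        (
            "Asia", "Chin", "Japan", "Thai", "Korea", "Bangladesh", "Taiwan",
            "Indonesia", "Vietnam", "Hong Kong", "Kosrae", "Micronesia",
            "Papua New Guinea", "Han", "Dai", "Kinh ", "Tokyo",
            "Xishuangbanna", "Beijing",
        ),
    ),
]


def assign_superpopulation(ancestry_text: str) -> SuperPopulation:
    """Map free-text cohort ancestry to a super-population code.

    Case-insensitive substring match against the keyword rows in
    :data:`ANCESTRY_KEYWORDS`; the first row with any hit wins and unmatched
    text defaults to EUR.  Total: every string maps to exactly one code.
    """
    padded = f" {(ancestry_text or '').lower()} "
    for pop, keywords in ANCESTRY_KEYWORDS:
        if any(kw.lower() in padded for kw in keywords):
            return pop
    return SuperPopulation.EUR


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one bi-allelic SNP in a haplotype panel (pos is 1-based)."""

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str


@dataclass
class BlockMember:
    """One SNP of an LD block, with its LD and frequency in the panel."""

    rsid: str
    chrom: str
    pos: int
    r2: float
    minor_allele: str
    maf: float


@dataclass
class LDBlock:
    """All panel SNPs in LD (r2 above threshold) with a GWAS index SNP."""

    index_snp: str
    population: SuperPopulation
    trait: str = ""
    members: list[BlockMember] = field(default_factory=list)
    unresolved: bool = False

    def member_rsids(self) -> set[str]:
        return {m.rsid for m in self.members}


class HaplotypePanel:
    """Phased binary allele matrix over bi-allelic SNPs.

    ``matrix`` is haplotype x SNP with entries 0 (reference), 1 (alternate)
    or -1 (missing).  Rows come in pairs (two haplotypes per diploid
    sample); an odd row count is tolerated with a warning.
    """

    def __init__(
        self,
        snps: list[SnpRecord],
        matrix: np.ndarray,
        population: SuperPopulation = SuperPopulation.EUR,
    ):
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2 or matrix.shape[1] != len(snps):
            raise DataError(
                f"haplotype matrix shape {matrix.shape} does not match "
                f"{len(snps)} SNP records"
            )
        if not np.isin(matrix, (-1, 0, 1)).all():
            raise DataError("haplotype matrix entries must be 0, 1 or -1")
        if matrix.shape[0] % 2:
            log.warning(
                "haplotype count %d is odd; expected an even number from "
                "diploid phasing", matrix.shape[0],
            )
        self.snps = list(snps)
        self.matrix = matrix
        self.population = population
        self._index = {s.rsid: i for i, s in enumerate(self.snps)}

    # ------------------------------------------------------------------ io

    @classmethod
    def from_vcf(
        cls, path: str, population: SuperPopulation = SuperPopulation.EUR
    ) -> "HaplotypePanel":
        """Load phased GT fields from a VCF; multi-allelic and non-SNV
        records are dropped with a warning (each locus must be bi-allelic)."""
        snps: list[SnpRecord] = []
        columns: list[list[int]] = []
        n_dropped = 0
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                alts = rec.alts or ()
                if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                    n_dropped += 1
                    continue
                col: list[int] = []
                for sample in rec.samples.values():
                    for allele in sample["GT"]:
                        col.append(-1 if allele is None else int(allele))
                snps.append(
                    SnpRecord(rec.chrom, rec.pos, rec.id or f"{rec.chrom}:{rec.pos}",
                              rec.ref, alts[0])
                )
                columns.append(col)
        if n_dropped:
            log.warning("dropped %d multi-allelic/non-SNV records from %s",
                        n_dropped, path)
        matrix = np.array(columns, dtype=np.int8).T if columns else \
            np.empty((0, 0), dtype=np.int8)
        return cls(snps, matrix, population)

    @classmethod
    def from_matrix_files(
        cls,
        snp_path: str,
        matrix_path: str,
        population: SuperPopulation = SuperPopulation.EUR,
    ) -> "HaplotypePanel":
        """Load the two-file plain-text dialect: a SNP metadata TSV
        (chrom, pos, rsid, ref, alt; 1-based positions) plus a matrix file
        with one whitespace-separated haplotype per line ('.' = missing)."""
        meta = pd.read_csv(snp_path, sep="\t", dtype={"chrom": str})
        snps = [
            SnpRecord(str(r.chrom), int(r.pos), str(r.rsid), str(r.ref), str(r.alt))
            for r in meta.itertuples()
        ]
        rows = []
        with open(matrix_path) as fh:
            for line in fh:
                tokens = line.split()
                if tokens:
                    rows.append([-1 if t == "." else int(t) for t in tokens])
        return cls(snps, np.array(rows, dtype=np.int8), population)

    # ------------------------------------------------------------- queries

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    def column(self, rsid: str) -> np.ndarray:
        try:
            return self.matrix[:, self._index[rsid]]
        except KeyError:
            raise PanelLookupError(f"SNP {rsid!r} not in haplotype panel") from None

    def record(self, rsid: str) -> SnpRecord:
        try:
            return self.snps[self._index[rsid]]
        except KeyError:
            raise PanelLookupError(f"SNP {rsid!r} not in haplotype panel") from None

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index


def compute_r2(panel: HaplotypePanel, snp_a: str, snp_b: str) -> float:
    """Squared allelic correlation between two panel SNPs.

    Monomorphic SNPs (after pairwise exclusion of missing haplotypes) give
    r2 = 0; the result is symmetric in its arguments and lies in [0, 1].
    """
    a = panel.column(snp_a)
    b = panel.column(snp_b)
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep].astype(float), b[keep].astype(float)
    n = a.size
    if n < 2:
        raise DataError(
            f"fewer than 2 complete haplotypes for pair ({snp_a}, {snp_b})"
        )
    p_a = a.mean()
    p_b = b.mean()
    denom = p_a * (1.0 - p_a) * p_b * (1.0 - p_b)
    if denom == 0.0:
        return 0.0
    p_ab = float((a * b).mean())
    d = p_ab - p_a * p_b
    return float(min(1.0, max(0.0, d * d / denom)))


def compute_maf(panel: HaplotypePanel, rsid: str) -> tuple[str, float]:
    """Minor allele base and its frequency (<= 0.5) for one panel SNP.

    At an exact 50/50 split the alternate allele is reported as minor, so
    output is deterministic.
    """
    col = panel.column(rsid)
    rec = panel.record(rsid)
    col = col[col >= 0]
    if col.size == 0:
        raise DataError(f"SNP {rsid!r} has no called haplotypes")
    p_alt = float(col.mean())
    if p_alt <= 0.5:
        return rec.alt, p_alt
    return rec.ref, 1.0 - p_alt


def expand_ld_block(
    assoc,
    panel: HaplotypePanel,
    r2_threshold: float = 0.6,
    window_bp: int = 1_000_000,
) -> LDBlock:
    """Expand a GWAS association into its LD block of TASs.

    Members are the index SNP itself (r2 = 1) plus every panel SNP within
    ``window_bp`` of it whose r2 is *strictly* above ``r2_threshold``; each
    carries its r2, minor allele and MAF in the panel's population.  An
    index SNP absent from the panel yields an empty block flagged
    ``unresolved`` (with a logged warning), never an exception.
    """
    index_rsid = assoc.index_snp
    trait = getattr(assoc, "trait", "")
    if index_rsid not in panel:
        log.warning("index SNP %s absent from %s panel; association skipped",
                    index_rsid, panel.population.value)
        return LDBlock(index_rsid, panel.population, trait, [], unresolved=True)

    idx_rec = panel.record(index_rsid)
    members: list[BlockMember] = []
    for snp in panel.snps:
        if snp.chrom != idx_rec.chrom or abs(snp.pos - idx_rec.pos) > window_bp:
            continue
        if snp.rsid == index_rsid:
            r2 = 1.0
        else:
            r2 = compute_r2(panel, index_rsid, snp.rsid)
            if r2 <= r2_threshold:
                continue
        minor, maf = compute_maf(panel, snp.rsid)
        members.append(BlockMember(snp.rsid, snp.chrom, snp.pos, r2, minor, maf))
    members.sort(key=lambda m: (m.chrom, m.pos))
    return LDBlock(index_rsid, panel.population, trait, members)


def blocks_to_frame(blocks: list[LDBlock]) -> pd.DataFrame:
    """Flatten LD blocks into the per-association member table."""
    rows = []
    for blk in blocks:
        for m in blk.members:
            rows.append(
                {
                    "index_snp": blk.index_snp,
                    "trait": blk.trait,
                    "population": blk.population.value,
                    "member_snp": m.rsid,
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "r2": m.r2,
                    "minor_allele": m.minor_allele,
                    "maf": m.maf,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["index_snp", "trait", "population", "member_snp", "chrom",
                 "pos", "r2", "minor_allele", "maf"],
    )
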