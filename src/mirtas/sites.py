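"""Seed-based miRNA target-site prediction on 3'-UTR sequences.

Implements the canonical seed-match site types, in order of increasing
efficacy: 7mer-1a, 7mer-m8 and 8mer-1a.  A site is a 3'-UTR subsequence
Watson-Crick complementary to the miRNA seed (positions 2-7, extended to
position 8 for m8 types), optionally anchored by an adenosine opposite
miRNA position 1.  In mRNA-sense 5'->3' coordinates:

    8mer-1a  = revcomp(miRNA 2-8) + 'A'
    7mer-m8  = revcomp(miRNA 2-8)
    7mer-1a  = revcomp(miRNA 2-7) + 'A'

Overlapping matches at the same seed location collapse to the single
strongest type.  The module also scores cross-species conservation and
re-predicts sites on allelic-complement UTRs (every reference allele
replaced by the alternate at bi-allelic SNP positions) to call sites
created or abolished by trait-associated variants.

DNA and RNA alphabets are equivalent throughout (T == U); 'N' never
matches anything.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from ._errors import DataError

log = logging.getLogger(__name__)

#: Site types ordered weakest to strongest.
SITE_TYPES = ("7mer-1a", "7mer-m8", "8mer-1a")
_STRENGTH = {t: i for i, t in enumerate(SITE_TYPES)}

#: Span of each site type on the UTR, in nucleotides.
SITE_SPAN = {"7mer-1a": 7, "7mer-m8": 7, "8mer-1a": 8}

ORTHOLOG_SPECIES = ("mouse", "rat", "dog", "chicken")


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: name plus its 5'->3' sequence (RNA or DNA alphabet)."""

    name: str
    mature_sequence: str

    def __post_init__(self):
        if len(self.mature_sequence) < 8:
            raise DataError(
                f"miRNA {self.name!r}: mature sequence shorter than 8 nt"
            )

    @property
    def seq(self) -> str:
        return _rna(self.mature_sequence)


@dataclass(frozen=True)
class SeedPatterns:
    """mRNA-sense (5'->3') match patterns derived from one miRNA seed."""

    eight_mer_1a: str
    seven_mer_m8: str
    seven_mer_1a: str


def seed_patterns(mirna: MiRNA) -> SeedPatterns:
    """Derive the three seed-match patterns from miRNA positions 2-8."""
    seq = mirna.seq
    rc_2_8 = str(Seq(seq[1:8]).reverse_complement_rna())
    rc_2_7 = str(Seq(seq[1:7]).reverse_complement_rna())
    return SeedPatterns(
        eight_mer_1a=rc_2_8 + "A",
        seven_mer_m8=rc_2_8,
        seven_mer_1a=rc_2_7 + "A",
    )


@dataclass(frozen=True)
class TargetSite:
    """A predicted seed-match site in a 3'-UTR.

    ``utr_offset`` is the 0-based start of the site on the UTR sense
    strand; ``conservation`` counts the species (out of human, mouse, rat,
    dog, chicken) whose orthologous UTR carries a same-type site, so 1
    means human-only.
    """

    mirna: str
    gene_symbol: str
    utr_offset: int
    site_type: str
    conservation: int | None = None
    allele_context: str = "reference"

    @property
    def span(self) -> int:
        return SITE_SPAN[self.site_type]

    def key(self) -> tuple[str, int, str]:
        """Identity used when diffing reference vs alternate contexts."""
        return (self.mirna, self.utr_offset, self.site_type)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_sites(
    utr_sequence: str,
    mirnas: list[MiRNA],
    gene_symbol: str = "",
    allele_context: str = "reference",
) -> list[TargetSite]:
    """Predict all seed-match sites of every miRNA in one UTR sequence.

    Matches of different types at the same seed location (an 8mer-1a always
    contains a 7mer-m8 and a 7mer-1a) are collapsed to the strongest type.
    Returned sites are sorted by (offset, miRNA name).
    """
    seq = _rna(utr_sequence)
    sites: list[TargetSite] = []
    for mirna in mirnas:
        pat = seed_patterns(mirna)
        # Keyed by the start of the 6-nt seed core revcomp(2-7), which all
        # three patterns share, so overlapping types collapse correctly.
        best: dict[int, tuple[int, int, str]] = {}
        for site_type, pattern, core_shift in (
            ("7mer-1a", pat.seven_mer_1a, 0),
            ("7mer-m8", pat.seven_mer_m8, 1),
            ("8mer-1a", pat.eight_mer_1a, 1),
        ):
            for off in _find_all(seq, pattern):
                core = off + core_shift
                cand = (_STRENGTH[site_type], off, site_type)
                if core not in best or cand[0] > best[core][0]:
                    best[core] = cand
        for _, off, site_type in best.values():
            sites.append(
                TargetSite(mirna.name, gene_symbol, off, site_type,
                           allele_context=allele_context)
            )
    sites.sort(key=lambda s: (s.utr_offset, s.mirna))
    return sites


def conservation_number(
    site: TargetSite,
    mirna: MiRNA,
    ortholog_utrs: dict[str, str],
) -> int:
    """Count the species whose orthologous UTR carries a same-type site.

    Alignment-free presence test: the site is "conserved" in a species iff
    that species' UTR contains a site of the same type for the same miRNA
    anywhere.  A missing ortholog UTR counts as absent.  Range 1-5.
    """
    n = 1
    for species in ORTHOLOG_SPECIES:
        seq = ortholog_utrs.get(species)
        if not seq:
            continue
        if any(s.site_type == site.site_type
               for s in find_sites(seq, [mirna])):
            n += 1
    return n


def annotate_conservation(
    sites: list[TargetSite],
    mirnas_by_name: dict[str, MiRNA],
    ortholog_utrs: dict[str, str],
) -> list[TargetSite]:
    """Return copies of ``sites`` with their conservation numbers filled in."""
    out = []
    for s in sites:
        n = conservation_number(s, mirnas_by_name[s.mirna], ortholog_utrs)
        out.append(TargetSite(s.mirna, s.gene_symbol, s.utr_offset,
                              s.site_type, n, s.allele_context))
    return out


@dataclass(frozen=True)
class UTRSnp:
    """A bi-allelic SNV expressed on the UTR (transcript) sense strand."""

    rsid: str
    utr_pos: int  # 0-based on the UTR
    ref: str
    alt: str


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


def snp_to_utr_strand(
    rsid: str,
    genomic_pos: int,  # 1-based
    ref: str,
    alt: str,
    utr_start: int,  # 0-based half-open genomic interval of the UTR
    utr_end: int,
    strand: str,
) -> UTRSnp:
    """Project a genomic SNV onto transcript-strand UTR coordinates.

    Minus-strand UTRs get reverse-complemented alleles; positions convert
    from 1-based genomic to 0-based UTR offsets.
    """
    pos0 = genomic_pos - 1
    if not utr_start <= pos0 < utr_end:
        raise DataError(f"SNP {rsid} at {genomic_pos} outside UTR "
                        f"[{utr_start}, {utr_end})")
    if strand == "+":
        return UTRSnp(rsid, pos0 - utr_start, ref.upper(), alt.upper())
    return UTRSnp(
        rsid,
        utr_end - 1 - pos0,
        _COMPLEMENT[ref.upper()],
        _COMPLEMENT[alt.upper()],
    )


#: Widest seed-site span; SNPs at most this far apart can share a site.
CLUSTER_SPAN_NT = 7
#: Enumeration guard: a cluster of k SNPs yields 2^k - 1 alternates.
MAX_CLUSTER_SNPS = 10


def _clusters(snps: list[UTRSnp]) -> list[list[UTRSnp]]:
    """Group SNPs by transitive proximity (gap <= CLUSTER_SPAN_NT)."""
    snps = sorted(snps, key=lambda s: s.utr_pos)
    out: list[list[UTRSnp]] = []
    for snp in snps:
        if out and snp.utr_pos - out[-1][-1].utr_pos <= CLUSTER_SPAN_NT:
            out[-1].append(snp)
        else:
            out.append([snp])
    return out


def enumerate_alternate_sequences(
    utr_sequence: str,
    snps: list[UTRSnp],
) -> list[tuple[str, str, list[UTRSnp]]]:
    """Enumerate allelic-complement UTR sequences.

    SNPs are clustered by transitive proximity (<= 7 nt, the widest site
    span); each cluster of k SNPs yields all 2^k - 1 non-reference allele
    combinations, applied on a reference background elsewhere, so clusters
    vary independently.  Returns (haplotype_label, sequence, snps_applied)
    triples; labels look like ``"rs1=T|rs2=A"``.

    Raises
    ------
    DataError
        If a SNP's reference allele disagrees with the UTR base at its
        position (checked with T/U equivalence), or a cluster exceeds
        MAX_CLUSTER_SNPS SNPs.
    """
    seq = utr_sequence.upper()
    for snp in snps:
        if snp.utr_pos < 0 or snp.utr_pos >= len(seq):
            raise DataError(f"SNP {snp.rsid}: UTR position {snp.utr_pos} "
                            f"outside sequence of length {len(seq)}")
        if _rna(seq[snp.utr_pos]) != _rna(snp.ref):
            raise DataError(
                f"SNP {snp.rsid}: reference allele {snp.ref!r} does not "
                f"match UTR base {seq[snp.utr_pos]!r} at offset {snp.utr_pos}"
            )

    results: list[tuple[str, str, list[UTRSnp]]] = []
    for cluster in _clusters(snps):
        if len(cluster) > MAX_CLUSTER_SNPS:
            raise DataError(
                f"SNP cluster of size {len(cluster)} exceeds the "
                f"{MAX_CLUSTER_SNPS}-SNP enumeration cap"
            )
        for r in range(1, len(cluster) + 1):
            for combo in itertools.combinations(cluster, r):
                chars = list(seq)
                for snp in combo:
                    chars[snp.utr_pos] = snp.alt
                label = "|".join(f"{s.rsid}={s.alt}" for s in combo)
                results.append((label, "".join(chars), list(combo)))
    return results


@dataclass(frozen=True)
class SiteDiff:
    """A target site created or abolished by an alternate haplotype."""

    direction: str  # "created" | "abolished"
    site: TargetSite
    snps: tuple[str, ...]
    haplotype_label: str = ""


def diff_sites(
    reference_sites: list[TargetSite],
    alternate_sites: list[TargetSite],
    haplotype_label: str = "",
    snps: tuple[str, ...] = (),
) -> list[SiteDiff]:
    """Call sites created or abolished by an alternate haplotype.

    Site identity is (miRNA, offset, type) in reference coordinates
    (bi-allelic SNVs never change length).  A type change at one location
    appears as one abolished plus one created diff; a site identical in
    both contexts never appears.
    """
    ref_keys = {s.key(): s for s in reference_sites}
    alt_keys = {s.key(): s for s in alternate_sites}
    diffs = [
        SiteDiff("abolished", ref_keys[k], snps, haplotype_label)
        for k in sorted(ref_keys.keys() - alt_keys.keys())
    ] + [
        SiteDiff("created", alt_keys[k], snps, haplotype_label)
        for k in sorted(alt_keys.keys() - ref_keys.keys())
    ]
    return diffs
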