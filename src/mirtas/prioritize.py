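"""Annotation-based prioritization of miRNA-regulome TASs.

A TAS is most compelling when its LD block offers no competing functional
explanation.  Each block is annotated against independent SNP/interval
sets — coding exons, nonsynonymous variants, transcriptional-regulatory
variants (RegulomeDB-style), eQTLs — plus experimentally validated
miRNA:gene pairs (TarBase-style).  Records are then tiered:

* ``top``       — the block lacks every disqualifying annotation configured
                  for that element kind (exonic for pre-miRNA/promoter
                  TASs; nonsynonymous or transcriptional for target-site
                  TASs);
* ``supported`` — not top, but the predicted miRNA:gene pair is validated,
                  or the TAS is in very strong LD (r2 > 0.9) with its index
                  SNP or is the index SNP itself;
* ``other``     — everything else.

eQTL hits annotate but never disqualify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam
from intervaltree import IntervalTree

from ._errors import ConfigurationError
from .ld import LDBlock
from .regulome import TAS, RegulomeElement

log = logging.getLogger(__name__)

#: Disqualifying annotation flags per element kind.
DEFAULT_POLICY: dict[str, frozenset[str]] = {
    "pre_mirna": frozenset({"has_exonic"}),
    "promoter": frozenset({"has_exonic"}),
    "utr3": frozenset({"has_nonsynonymous", "has_transcriptional"}),
}

#: r2 above which a TAS counts as being in very strong LD with its index SNP.
STRONG_LD_R2 = 0.9

TIERS = ("top", "supported", "other")


@dataclass
class BlockAnnotation:
    """Competing functional annotations of one LD block."""

    index_snp: str
    has_exonic: bool = False
    has_nonsynonymous: bool = False
    has_transcriptional: bool = False
    has_eqtl: bool = False
    tarbase_support: list[tuple[str, str]] = field(default_factory=list)
    strong_ld_rsids: set[str] = field(default_factory=set)

    def flags(self) -> dict[str, bool]:
        return {
            "has_exonic": self.has_exonic,
            "has_nonsynonymous": self.has_nonsynonymous,
            "has_transcriptional": self.has_transcriptional,
            "has_eqtl": self.has_eqtl,
        }


@dataclass(frozen=True)
class PriorityRecord:
    """A TAS x element pair with its block annotation and priority tier."""

    tas: TAS
    element: RegulomeElement
    annotation: BlockAnnotation
    tier: str


def _interval_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if start < end:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def annotate_block(
    block: LDBlock,
    exon_intervals: list[tuple[str, int, int]] = (),
    nonsyn_rsids: set[str] = frozenset(),
    transcriptional_rsids: set[str] = frozenset(),
    eqtl_rsids: set[str] = frozenset(),
    tarbase_pairs: set[tuple[str, str]] = frozenset(),
    predicted_pairs: set[tuple[str, str]] = frozenset(),
) -> BlockAnnotation:
    """Annotate one LD block against the competing-explanation datasets.

    Interval sets are matched by member position (0-based half-open
    containment), SNP sets by rsID.  ``tarbase_support`` is the overlap of
    the block's predicted (miRNA, gene) target pairs with the validated
    set.  The annotation sets are independent inputs: a nonsynonymous hit
    does not imply an exonic hit.
    """
    trees = _interval_trees(exon_intervals)
    ann = BlockAnnotation(index_snp=block.index_snp)
    for m in block.members:
        pos0 = m.pos - 1
        tree = trees.get(m.chrom)
        if tree is not None and tree[pos0]:
            ann.has_exonic = True
        if m.rsid in nonsyn_rsids:
            ann.has_nonsynonymous = True
        if m.rsid in transcriptional_rsids:
            ann.has_transcriptional = True
        if m.rsid in eqtl_rsids:
            ann.has_eqtl = True
        if m.r2 > STRONG_LD_R2 or m.rsid == block.index_snp:
            ann.strong_ld_rsids.add(m.rsid)
    ann.tarbase_support = sorted(set(predicted_pairs) & set(tarbase_pairs))
    return ann


def assign_tier(
    tas: TAS,
    element: RegulomeElement,
    annotation: BlockAnnotation,
    policy: dict[str, frozenset[str]] | None = None,
) -> PriorityRecord:
    """Assign the priority tier of one TAS x element record.

    Raises
    ------
    ConfigurationError
        If the element kind has no entry in the policy.
    """
    policy = DEFAULT_POLICY if policy is None else policy
    if element.kind not in policy:
        raise ConfigurationError(
            f"no tier policy for element kind {element.kind!r}"
        )
    flags = annotation.flags()
    disqualified = any(flags[f] for f in policy[element.kind])
    if not disqualified:
        tier = "top"
    elif annotation.tarbase_support or tas.rsid in annotation.strong_ld_rsids:
        tier = "supported"
    else:
        tier = "other"
    return PriorityRecord(tas, element, annotation, tier)


# ----------------------------------------------------------------- loaders

def load_snp_ids_from_vcf(path: str, info_flag: str | None = None) -> set[str]:
    """rsIDs from a VCF, optionally restricted to records carrying an INFO
    flag (used to subset e.g. a dbSNP-style file to nonsynonymous SNPs)."""
    ids: set[str] = set()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.id is None:
                continue
            if info_flag is not None and info_flag not in rec.info:
                continue
            ids.add(rec.id)
    return ids


def load_snp_ids_from_tsv(path: str, column: str = "rsid") -> set[str]:
    """rsID set from a TSV with a header (RegulomeDB-style or eQTL lists);
    extra columns such as score categories are ignored."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    if column not in table.columns:
        raise ConfigurationError(f"{path!r} lacks column {column!r}")
    return set(table[column].dropna())


def load_tarbase_pairs(path: str) -> set[tuple[str, str]]:
    """Validated (miRNA, gene) pairs from a TarBase-dialect TSV with
    ``mirna`` and ``gene`` columns."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna", "gene"):
        if col not in table.columns:
            raise ConfigurationError(f"{path!r} lacks column {col!r}")
    return {(str(r.mirna), str(r.gene)) for r in table.itertuples()}
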