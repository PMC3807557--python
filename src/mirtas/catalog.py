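"""GWAS-catalog parsing and filtering.

Reads an NHGRI-catalog-style association TSV and keeps rows with a single
index rsID and an association p-value strictly below the genome-wide
suggestive threshold (default 1e-5).  Multi-SNP haplotype rows (more than
one rsID token in the SNP field) are dropped, as are rows whose p-value
cannot be parsed; all drop counts are logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from ._errors import ConfigurationError

log = logging.getLogger(__name__)

_RSID = re.compile(r"rs\d+", re.IGNORECASE)

#: Default column mapping, matching NHGRI GWAS-catalog header names.
DEFAULT_COLUMNS = {
    "snp": "SNPS",
    "p_value": "P-VALUE",
    "trait": "DISEASE/TRAIT",
    "pubmed_id": "PUBMEDID",
    "ancestry": "INITIAL SAMPLE SIZE",
}


@dataclass(frozen=True)
class GWASAssociation:
    """One retained catalog row: an index SNP associated with a trait."""

    index_snp: str
    trait: str
    ancestry_text: str
    p_value: float
    pubmed_id: str
    source_row: int


def parse_catalog(
    path: str,
    p_threshold: float = 1e-5,
    columns: dict[str, str] | None = None,
) -> list[GWASAssociation]:
    """Parse and filter a GWAS association catalog.

    Parameters
    ----------
    path
        Tab-separated catalog with a header row.
    p_threshold
        Rows are kept only if p-value < threshold (strict).
    columns
        Overrides for the logical-to-file column names in
        :data:`DEFAULT_COLUMNS`.

    Raises
    ------
    ConfigurationError
        If a required column is missing from the file header.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for logical, name in colmap.items():
        if name not in table.columns:
            raise ConfigurationError(
                f"catalog {path!r} is missing required column {name!r} "
                f"(role: {logical})"
            )

    kept: list[GWASAssociation] = []
    n_bad_p = n_above = n_multi = n_nosnp = 0
    for i, row in enumerate(table.itertuples(index=False)):
        rowd = dict(zip(table.columns, row))
        try:
            p = float(rowd[colmap["p_value"]])
        except ValueError:
            n_bad_p += 1
            continue
        if not p < p_threshold:
            n_above += 1
            continue
        snp_field = rowd[colmap["snp"]].strip()
        tokens = _RSID.findall(snp_field)
        if len(tokens) > 1:
            n_multi += 1
            continue
        index_snp = tokens[0] if tokens else snp_field
        if not index_snp:
            n_nosnp += 1
            continue
        kept.append(
            GWASAssociation(
                index_snp=index_snp,
                trait=rowd[colmap["trait"]],
                ancestry_text=rowd[colmap["ancestry"]],
                p_value=p,
                pubmed_id=rowd[colmap["pubmed_id"]],
                source_row=i,
            )
        )
    log.info(
        "catalog %s: kept %d rows; dropped %d above p threshold, %d "
        "multi-SNP haplotypes, %d unparseable p-values, %d empty SNP fields",
        path, len(kept), n_above, n_multi, n_bad_p, n_nosnp,
    )
    return kept
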