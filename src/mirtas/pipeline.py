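"""End-to-end pipeline orchestration.

Runs the stages in order — catalog filtering, LD-block expansion,
TAS x element intersection, target-site prediction and allelic diffing,
annotation-based tiering, and the hub Monte Carlo scan — writing one TSV
per stage plus a machine-readable run manifest with funnel counts (the
number of TASs passing each filter), input checksums and the exact
configuration, sufficient to rerun identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigurationError
from .catalog import parse_catalog
from .hubs import HubConfig, SiteIndex, hub_scan
from .ld import (
    BlockMember,
    HaplotypePanel,
    LDBlock,
    SuperPopulation,
    assign_superpopulation,
    blocks_to_frame,
    expand_ld_block,
)
from .prioritize import (
    annotate_block,
    assign_tier,
    load_snp_ids_from_tsv,
    load_snp_ids_from_vcf,
    load_tarbase_pairs,
)
from .regulome import (
    TAS,
    UTRRecord,
    filter_utr_mappings,
    intersect_tas,
    load_bed,
    load_bed_intervals,
    load_mirbase_gff3,
    load_mirna_fasta,
    load_symbol_map,
    load_utr_mappings,
    load_utr_table,
    utr_elements,
)
from .sites import (
    annotate_conservation,
    diff_sites,
    enumerate_alternate_sequences,
    find_sites,
    snp_to_utr_strand,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run.

    ``panels`` maps super-population codes (EUR/AFR/AMR/ASN) to phased
    VCF paths; associations assigned to a population without a panel are
    skipped with a warning.  Parameter defaults are the method's stated
    operating point: p < 1e-5, r2 > 0.6, 8mer/proximity weight 1.5 over
    60 nt, 100,000 Monte Carlo replicates, conservation 5.
    """

    catalog: str = ""
    panels: dict[str, str] = field(default_factory=dict)
    mirna_gff3: str = ""
    promoter_bed: str = ""
    exon_bed: str = ""
    mirna_fasta: str = ""
    utr_table: str = ""
    utr_mappings: str = ""
    symbol_map: str | None = None
    nonsyn_vcf: str | None = None
    nonsyn_info_flag: str | None = None
    transcriptional_tsv: str | None = None
    eqtl_tsv: str | None = None
    tarbase_tsv: str | None = None
    trait_genes: str | None = None
    outdir: str = "mirtas_out"
    p_threshold: float = 1e-5
    r2_threshold: float = 0.6
    window_bp: int = 1_000_000
    strong_ld_r2: float = 0.9
    hub_weight: float = 1.5
    hub_spacing: int = 60
    hub_reps: int = 100_000
    hub_min_conservation: int = 5
    hub_score_mode: str = "site"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def hub_config(self) -> HubConfig:
        return HubConfig(
            weight=self.hub_weight, spacing_nt=self.hub_spacing,
            reps=self.hub_reps, min_conservation=self.hub_min_conservation,
            rng_seed=self.seed, score_mode=self.hub_score_mode,
        )


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- stages

def stage_catalog(config: PipelineConfig) -> pd.DataFrame:
    assocs = parse_catalog(config.catalog, config.p_threshold)
    rows = [
        {
            "index_snp": a.index_snp,
            "trait": a.trait,
            "ancestry": a.ancestry_text,
            "population": assign_superpopulation(a.ancestry_text).value,
            "p_value": a.p_value,
            "pubmed_id": a.pubmed_id,
            "source_row": a.source_row,
        }
        for a in assocs
    ]
    return pd.DataFrame(rows, columns=["index_snp", "trait", "ancestry",
                                       "population", "p_value", "pubmed_id",
                                       "source_row"])


def stage_ld(config: PipelineConfig,
             associations: pd.DataFrame) -> list[LDBlock]:
    panels: dict[str, HaplotypePanel] = {}
    blocks: list[LDBlock] = []
    seen: set[tuple[str, str, str]] = set()
    for row in associations.itertuples():
        key = (row.index_snp, row.trait, row.population)
        if key in seen:  # duplicated catalog rows expand one block
            continue
        seen.add(key)
        pop = row.population
        if pop not in panels:
            path = config.panels.get(pop)
            if path is None:
                log.warning("no haplotype panel configured for %s; "
                            "association %s skipped", pop, row.index_snp)
                blocks.append(LDBlock(row.index_snp, SuperPopulation(pop),
                                      row.trait, [], unresolved=True))
                continue
            panels[pop] = HaplotypePanel.from_vcf(path, SuperPopulation(pop))
        assoc = type("A", (), {"index_snp": row.index_snp,
                               "trait": row.trait})()
        blocks.append(
            expand_ld_block(assoc, panels[pop], config.r2_threshold,
                            config.window_bp)
        )
    return blocks


def blocks_from_frame(frame: pd.DataFrame) -> list[LDBlock]:
    """Reconstruct LD blocks from the ld_blocks.tsv stage output."""
    blocks = []
    for (index_snp, trait, pop), grp in frame.groupby(
            ["index_snp", "trait", "population"], sort=False, dropna=False):
        members = [
            BlockMember(r.member_snp, str(r.chrom), int(r.pos), float(r.r2),
                        str(r.minor_allele), float(r.maf))
            for r in grp.itertuples()
        ]
        blocks.append(LDBlock(index_snp, SuperPopulation(pop),
                              "" if pd.isna(trait) else str(trait), members))
    return blocks


def _load_utrs(config: PipelineConfig):
    symbol_map = (load_symbol_map(config.symbol_map)
                  if config.symbol_map else None)
    records = load_utr_table(config.utr_table, symbol_map)
    mappings = load_utr_mappings(config.utr_mappings)
    # mappings are keyed by the raw sequence ID; attach before renaming
    raw = load_utr_table(config.utr_table, None)
    for rec, rawrec in zip(records, raw):
        if rec.species == "human":
            rec.mappings = mappings.get(rawrec.gene_symbol, [])
    admitted, rejected = filter_utr_mappings(records)
    if rejected:
        log.info("UTR admission filter rejected %d record(s): %s",
                 len(rejected),
                 {r: sum(1 for _, x in rejected if x == r)
                  for r in {x for _, x in rejected}})
    return admitted, rejected


def load_elements(config: PipelineConfig):
    pre = load_mirbase_gff3(config.mirna_gff3)
    prom = load_bed(config.promoter_bed, "promoter", source="epigenomic")
    admitted, _ = _load_utrs(config)
    utr = utr_elements(admitted)
    return pre + prom + utr, admitted


def pairs_to_frame(pairs) -> pd.DataFrame:
    rows = [
        {
            "rsid": t.rsid, "chrom": t.chrom, "pos": t.pos, "r2": t.r2,
            "minor_allele": t.minor_allele, "maf": t.maf,
            "index_snp": t.index_snp, "trait": t.trait,
            "population": t.population, "element_kind": e.kind,
            "element_owner": e.owner, "element_start": e.start,
            "element_end": e.end, "element_strand": e.strand,
        }
        for t, e in pairs
    ]
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "r2",
                                       "minor_allele", "maf", "index_snp",
                                       "trait", "population", "element_kind",
                                       "element_owner", "element_start",
                                       "element_end", "element_strand"])


def stage_sites(
    config: PipelineConfig,
    admitted: list[UTRRecord],
    blocks: list[LDBlock],
) -> tuple[pd.DataFrame, pd.DataFrame, SiteIndex]:
    """Predict reference sites (with conservation), re-predict on allelic
    complements for panel SNPs falling in each admitted UTR, and diff."""
    mirnas = load_mirna_fasta(config.mirna_fasta)
    by_name = {m.name: m for m in mirnas}

    human = [r for r in admitted if r.species == "human"
             and r.genomic_mapping is not None]
    orthologs: dict[str, dict[str, str]] = {}
    for r in admitted:
        if r.species != "human":
            orthologs.setdefault(r.gene_symbol, {})[r.species] = r.sequence

    # collect panel SNPs once (position-keyed) across configured panels
    panel_snps: dict[tuple[str, int], tuple[str, str, str]] = {}
    for pop, path in sorted(config.panels.items()):
        panel = HaplotypePanel.from_vcf(path, SuperPopulation(pop))
        for s in panel.snps:
            panel_snps.setdefault((s.chrom, s.pos), (s.rsid, s.ref, s.alt))

    site_rows, diff_rows = [], []
    all_sites = []
    utr_lengths = {}
    for rec in human:
        m = rec.genomic_mapping
        utr_lengths[rec.gene_symbol] = len(rec.sequence)
        ref_sites = find_sites(rec.sequence, mirnas, rec.gene_symbol)
        ortho = orthologs.get(rec.gene_symbol, {})
        ref_sites = annotate_conservation(ref_sites, by_name, ortho)
        all_sites.extend(ref_sites)
        for s in ref_sites:
            site_rows.append(
                {"mirna": s.mirna, "gene": s.gene_symbol,
                 "offset": s.utr_offset, "site_type": s.site_type,
                 "conservation": s.conservation,
                 "allele_context": s.allele_context})

        utr_snps = []
        for pos in range(m.start, m.end):
            hit = panel_snps.get((m.chrom, pos + 1))
            if hit is None:
                continue
            rsid, ref, alt = hit
            utr_snps.append(
                snp_to_utr_strand(rsid, pos + 1, ref, alt, m.start, m.end,
                                  m.strand))
        if not utr_snps:
            continue
        for label, alt_seq, applied in enumerate_alternate_sequences(
                rec.sequence, utr_snps):
            alt_sites = find_sites(alt_seq, mirnas, rec.gene_symbol,
                                   allele_context=label)
            alt_sites = annotate_conservation(alt_sites, by_name, ortho)
            ref_keyed = [s for s in ref_sites]
            for d in diff_sites(ref_keyed, alt_sites, label,
                                tuple(s.rsid for s in applied)):
                diff_rows.append(
                    {"gene": rec.gene_symbol, "snps": ",".join(d.snps),
                     "haplotype": d.haplotype_label,
                     "direction": d.direction, "mirna": d.site.mirna,
                     "offset": d.site.utr_offset,
                     "site_type": d.site.site_type,
                     "conservation": d.site.conservation})

    sites_frame = pd.DataFrame(
        site_rows, columns=["mirna", "gene", "offset", "site_type",
                            "conservation", "allele_context"])
    diffs_frame = pd.DataFrame(
        diff_rows, columns=["gene", "snps", "haplotype", "direction",
                            "mirna", "offset", "site_type", "conservation"])
    diffs_frame = diffs_frame.sort_values(
        ["gene", "snps", "direction", "mirna", "offset"],
        kind="stable").reset_index(drop=True)
    index = SiteIndex.from_sites(all_sites, utr_lengths)
    return sites_frame, diffs_frame, index


def stage_prioritize(
    config: PipelineConfig,
    blocks: list[LDBlock],
    pairs,
    sites_frame: pd.DataFrame,
) -> pd.DataFrame:
    exon_intervals = (load_bed_intervals(config.exon_bed)
                      if config.exon_bed else [])
    nonsyn = (load_snp_ids_from_vcf(config.nonsyn_vcf,
                                    config.nonsyn_info_flag)
              if config.nonsyn_vcf else set())
    transcriptional = (load_snp_ids_from_tsv(config.transcriptional_tsv)
                       if config.transcriptional_tsv else set())
    eqtls = (load_snp_ids_from_tsv(config.eqtl_tsv)
             if config.eqtl_tsv else set())
    tarbase = (load_tarbase_pairs(config.tarbase_tsv)
               if config.tarbase_tsv else set())

    gene_mirnas: dict[str, set[str]] = {}
    for r in sites_frame.itertuples():
        gene_mirnas.setdefault(r.gene, set()).add(r.mirna)

    pairs_by_block: dict[str, list] = {}
    for t, e in pairs:
        pairs_by_block.setdefault(t.index_snp, []).append((t, e))

    rows = []
    for block in blocks:
        block_pairs = pairs_by_block.get(block.index_snp, [])
        predicted = {
            (mir, e.owner)
            for t, e in block_pairs if e.kind == "utr3"
            for mir in gene_mirnas.get(e.owner, ())
        }
        ann = annotate_block(block, exon_intervals, nonsyn, transcriptional,
                             eqtls, tarbase, predicted)
        for t, e in block_pairs:
            rec = assign_tier(t, e, ann)
            rows.append(
                {"rsid": t.rsid, "index_snp": t.index_snp, "trait": t.trait,
                 "population": t.population, "element_kind": e.kind,
                 "element_owner": e.owner, "r2": t.r2, "maf": t.maf,
                 "minor_allele": t.minor_allele,
                 **ann.flags(),
                 "tarbase_support": ";".join(
                     f"{m}:{g}" for m, g in ann.tarbase_support),
                 "tier": rec.tier})
    frame = pd.DataFrame(
        rows, columns=["rsid", "index_snp", "trait", "population",
                       "element_kind", "element_owner", "r2", "maf",
                       "minor_allele", "has_exonic", "has_nonsynonymous",
                       "has_transcriptional", "has_eqtl", "tarbase_support",
                       "tier"])
    return frame.sort_values(["rsid", "element_kind", "element_owner"],
                             kind="stable").reset_index(drop=True)


def stage_hub(config: PipelineConfig, site_index: SiteIndex) -> pd.DataFrame:
    if not config.trait_genes:
        return pd.DataFrame(columns=["mirna", "trait", "observed",
                                     "n_target_genes", "null_mean",
                                     "null_sd", "p", "significant"])
    lists = pd.read_csv(config.trait_genes, sep="\t", dtype=str)
    trait_gene_lists = {
        trait: sorted(grp["gene"])
        for trait, grp in lists.groupby("trait")
    }
    mirnas = sorted({m.name for m in load_mirna_fasta(config.mirna_fasta)})
    universe = sorted(site_index.utr_lengths)
    return hub_scan(trait_gene_lists, mirnas, universe, site_index,
                    config.hub_config())


# ------------------------------------------------------------- orchestrator

def funnel_counts(
    associations: pd.DataFrame,
    blocks: list[LDBlock],
    pairs_frame: pd.DataFrame,
    diffs_frame: pd.DataFrame,
    prioritized: pd.DataFrame,
) -> dict:
    """Per-stage record counts mirroring the pipeline funnel."""
    unique_tas = len({m.rsid for b in blocks for m in b.members})
    per_kind = {
        kind: int(pairs_frame.loc[pairs_frame.element_kind == kind,
                                  "rsid"].nunique())
        for kind in ("pre_mirna", "promoter", "utr3")
    }
    tier_counts = {}
    for kind in ("pre_mirna", "promoter", "utr3"):
        sub = prioritized[prioritized.element_kind == kind]
        tier_counts[kind] = {
            tier: int((sub.tier == tier).sum())
            for tier in ("top", "supported", "other")
        }
    return {
        "associations_kept": int(len(associations)),
        "blocks_resolved": int(sum(not b.unresolved for b in blocks)),
        "blocks_unresolved": int(sum(b.unresolved for b in blocks)),
        "unique_tas": unique_tas,
        "tas_per_element": per_kind,
        "sites_created": int((diffs_frame.direction == "created").sum())
        if len(diffs_frame) else 0,
        "sites_abolished": int((diffs_frame.direction == "abolished").sum())
        if len(diffs_frame) else 0,
        "tas_diff_snps": int(pd.unique(
            diffs_frame.snps.str.split(",").explode()).size)
        if len(diffs_frame) else 0,
        "tier_counts": tier_counts,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write stage TSVs plus the run manifest.

    Returns the manifest dictionary.  Missing inputs fail before any
    computation; an empty catalog produces empty downstream tables and a
    warning, not an error.
    """
    required = [config.catalog, config.mirna_gff3, config.promoter_bed,
                config.mirna_fasta, config.utr_table, config.utr_mappings,
                *config.panels.values()]
    for path in required:
        if not Path(path).exists():
            raise ConfigurationError(f"input file not found: {path!r}")

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    associations = stage_catalog(config)
    _write(associations, out / "associations.tsv")
    if associations.empty:
        log.warning("catalog produced no associations; downstream tables "
                    "will be empty")

    blocks = stage_ld(config, associations)
    _write(blocks_to_frame(blocks), out / "ld_blocks.tsv")

    elements, admitted = load_elements(config)
    pairs = intersect_tas(blocks, elements)
    pairs_frame = pairs_to_frame(pairs)
    _write(pairs_frame, out / "tas_elements.tsv")

    sites_frame, diffs_frame, site_index = stage_sites(config, admitted,
                                                       blocks)
    _write(sites_frame, out / "sites_ref.tsv")
    _write(diffs_frame, out / "site_diffs.tsv")

    prioritized = stage_prioritize(config, blocks, pairs, sites_frame)
    _write(prioritized, out / "prioritized.tsv")

    hubs = stage_hub(config, site_index)
    _write(hubs, out / "hubs.tsv")

    counts = funnel_counts(associations, blocks, pairs_frame, diffs_frame,
                           prioritized)
    manifest = {
        "tool_version": __version__,
        "rng_seed": config.seed,
        "config": asdict(config),
        "input_checksums": {
            str(p): _md5(str(p)) for p in sorted(set(map(str, required)))
        },
        "counts": counts,
        "normalization": "null scores rescaled by mean-UTR-length ratio "
                         "(test over draw)",
        "conservation_definition": "alignment-free same-type site presence "
                                   "per species",
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    summarize(out)
    return manifest


def summarize(outdir: str | Path) -> str:
    """Render the funnel report from stage outputs; returns the text and
    writes funnel.txt / funnel.tsv next to them."""
    out = Path(outdir)
    manifest = json.loads((out / "run_manifest.json").read_text())
    c = manifest["counts"]
    lines = [
        "pipeline funnel",
        f"  associations kept:        {c['associations_kept']}",
        f"  LD blocks resolved:       {c['blocks_resolved']} "
        f"(+{c['blocks_unresolved']} unresolved)",
        f"  unique TASs:              {c['unique_tas']}",
        f"  TASs in pre-miRNAs:       {c['tas_per_element']['pre_mirna']}",
        f"  TASs in miRNA promoters:  {c['tas_per_element']['promoter']}",
        f"  TASs in 3'-UTRs:          {c['tas_per_element']['utr3']}",
        f"  sites created:            {c['sites_created']}",
        f"  sites abolished:          {c['sites_abolished']}",
    ]
    for kind, tiers in c["tier_counts"].items():
        lines.append(
            f"  tiers[{kind}]: top={tiers['top']} "
            f"supported={tiers['supported']} other={tiers['other']}")
    hubs_path = out / "hubs.tsv"
    if hubs_path.exists():
        hubs = pd.read_csv(hubs_path, sep="\t")
        sig = hubs[hubs.significant == True]  # noqa: E712
        lines.append(f"  significant hubs (p <= 0.01): {len(sig)}")
        for r in sig.head(5).itertuples():
            lines.append(f"    {r.mirna} x {r.trait}: p = {r.p:.4g}")
    text = "\n".join(lines) + "\n"
    (out / "funnel.txt").write_text(text)
    rows = [
        {"stage": "associations_kept", "count": c["associations_kept"]},
        {"stage": "unique_tas", "count": c["unique_tas"]},
        {"stage": "tas_pre_mirna", "count": c["tas_per_element"]["pre_mirna"]},
        {"stage": "tas_promoter", "count": c["tas_per_element"]["promoter"]},
        {"stage": "tas_utr3", "count": c["tas_per_element"]["utr3"]},
        {"stage": "sites_created", "count": c["sites_created"]},
        {"stage": "sites_abolished", "count": c["sites_abolished"]},
    ]
    _write(pd.DataFrame(rows), out / "funnel.tsv")
    return text
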