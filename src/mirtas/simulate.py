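"""Deterministic synthetic fixtures for the whole pipeline.

Generates every input the pipeline consumes — a phased haplotype VCF, a
GWAS-catalog-style TSV, a small genome FASTA, miRBase-dialect GFF3,
promoter/exon BED, a TargetScan-dialect UTR table with ortholog rows and
genomic mappings, and the annotation sets — with planted ground truth
recorded in a manifest, so every stage is testable offline.

LD engineering uses a closed form: with the index SNP at allele frequency
1/2 on ``m`` alternate haplotypes nested inside the index SNP's alternate
set, the pair's r-squared is exactly ``m / (H - m)`` for ``H`` haplotypes,
so a target r2 is planted by choosing ``m = H r2 / (1 + r2)`` (exact
whenever that is an integer, e.g. r2 = 0.6 at H = 200).  Background SNPs
are sampled independently per locus, so between-locus LD is near zero.

Sequence plants are verified: after embedding a seed-match pattern (or a
site-breaking/creating allele), the generator re-runs the site finder and
the site differ over *all* fixture miRNAs and retries until the observed
outcome equals the requested one, so manifest expectations are exact.
All outputs are byte-identical for a fixed spec and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from ._errors import GenerationError
from .sites import MiRNA, diff_sites, find_sites, seed_patterns

log = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
ORTHOLOGS = ("mouse", "rat", "dog", "chicken")


@dataclass(frozen=True)
class PlantedEvent:
    """One ground-truth event: a TAS planted inside a regulome element."""

    name: str
    kind: str  # pre_mirna | promoter | utr3
    effect: str = "none"  # none | abolish | create (utr3 only)
    site_type: str = "8mer-1a"
    conservation: int = 5
    r2: float = 0.95
    disqualify: str | None = None  # exonic | nonsynonymous | transcriptional
    tarbase: bool = False
    utr_strand: str = "+"


def default_events() -> list[PlantedEvent]:
    """The fixture's standard event panel: top-tier candidates of every
    element kind, a strand test, a boundary-LD exclusion, and demoted
    records exercising each disqualifying annotation."""
    return [
        PlantedEvent("pre_top", "pre_mirna", r2=0.8),
        PlantedEvent("prom_top", "promoter", r2=1.0),
        PlantedEvent("utr_abolish_top", "utr3", effect="abolish",
                     site_type="8mer-1a", conservation=5, r2=0.95),
        PlantedEvent("utr_create_top", "utr3", effect="create",
                     site_type="7mer-1a", conservation=1, r2=0.7),
        PlantedEvent("utr_supported", "utr3", effect="abolish",
                     site_type="7mer-m8", conservation=3, r2=0.95,
                     disqualify="nonsynonymous", tarbase=True),
        PlantedEvent("prom_other", "promoter", r2=0.7, disqualify="exonic"),
        PlantedEvent("utr_minus_top", "utr3", effect="abolish",
                     site_type="8mer-1a", conservation=5, r2=1.0,
                     utr_strand="-"),
    ]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study; same spec + seed => same bytes."""

    rng_seed: int = 0
    n_haplotypes: int = 200
    ld_block_length: int = 10_000  # bp allotted to one LD-block locus
    n_background_per_locus: int = 3
    n_mirnas: int = 8
    n_genes: int = 60  # hub gene universe size
    utr_length_range: tuple[int, int] = (200, 400)
    planted_events: list[PlantedEvent] = field(default_factory=default_events)
    n_decoy_loci: int = 2
    boundary_locus: bool = True  # plant a TAS at exactly r2 = 0.6
    hub_trait: str = "stature"
    hub_trait_genes: int = 15
    hub_target_fraction: float = 0.4
    hub_background_fraction: float = 0.05

    def __post_init__(self):
        if self.n_haplotypes < 8 or self.n_haplotypes % 2:
            raise GenerationError("n_haplotypes must be even and >= 8")
        if self.n_genes <= self.hub_trait_genes:
            raise GenerationError("n_genes must exceed hub_trait_genes")


# ----------------------------------------------------------- sequence plants

def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _pattern_dna(mirna: MiRNA, site_type: str) -> str:
    pat = seed_patterns(mirna)
    rna = {"8mer-1a": pat.eight_mer_1a, "7mer-m8": pat.seven_mer_m8,
           "7mer-1a": pat.seven_mer_1a}[site_type]
    return rna.replace("U", "T")


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _plant_site(
    rng: np.random.Generator,
    length: int,
    offset: int,
    mirna: MiRNA,
    site_type: str,
    max_tries: int = 200,
) -> str:
    """Random sequence whose only site for ``mirna`` is the requested type
    at the requested offset (flank collisions are retried away)."""
    pat = _pattern_dna(mirna, site_type)
    for _ in range(max_tries):
        seq = _rand_dna(rng, length)
        seq = seq[:offset] + pat + seq[offset + len(pat):]
        found = find_sites(seq, [mirna])
        if len(found) == 1 and found[0].utr_offset == offset \
                and found[0].site_type == site_type:
            return seq
    raise GenerationError(
        f"could not plant a clean {site_type} site for {mirna.name}"
    )


def _seq_without_site(
    rng: np.random.Generator,
    length: int,
    mirna: MiRNA,
    site_type: str,
    max_tries: int = 200,
) -> str:
    for _ in range(max_tries):
        seq = _rand_dna(rng, length)
        if not any(s.site_type == site_type
                   for s in find_sites(seq, [mirna])):
            return seq
    raise GenerationError(f"could not avoid a {site_type} site")


def _plant_abolishing_utr(
    rng: np.random.Generator,
    length: int,
    offset: int,
    mirna: MiRNA,
    site_type: str,
    all_mirnas: list[MiRNA],
    max_tries: int = 200,
) -> tuple[str, int, str, str]:
    """(reference UTR with the site, SNP offset, ref base, alt base) such
    that the alternate allele abolishes exactly the planted site and
    nothing else, across the whole miRNA set."""
    snp_off = offset + 2  # inside the 6-nt seed core of all three types
    key = (mirna.name, offset, site_type)
    for _ in range(max_tries):
        seq = _plant_site(rng, length, offset, mirna, site_type)
        ref = seq[snp_off]
        for alt in _BASES:
            if alt == ref:
                continue
            alt_seq = seq[:snp_off] + alt + seq[snp_off + 1:]
            diffs = diff_sites(find_sites(seq, all_mirnas),
                               find_sites(alt_seq, all_mirnas))
            if len(diffs) == 1 and diffs[0].direction == "abolished" \
                    and diffs[0].site.key() == key:
                return seq, snp_off, ref, alt
    raise GenerationError(f"could not plant an abolishing SNP for {mirna.name}")


def _plant_creating_utr(
    rng: np.random.Generator,
    length: int,
    offset: int,
    mirna: MiRNA,
    site_type: str,
    all_mirnas: list[MiRNA],
    max_tries: int = 200,
) -> tuple[str, int, str, str]:
    """(reference UTR lacking the site, SNP offset, ref base, alt base)
    such that the alternate allele creates exactly the planted site."""
    snp_off = offset + 2
    key = (mirna.name, offset, site_type)
    for _ in range(max_tries):
        full = _plant_site(rng, length, offset, mirna, site_type)
        alt = full[snp_off]
        for ref in _BASES:
            if ref == alt:
                continue
            ref_seq = full[:snp_off] + ref + full[snp_off + 1:]
            diffs = diff_sites(find_sites(ref_seq, all_mirnas),
                               find_sites(full, all_mirnas))
            if len(diffs) == 1 and diffs[0].direction == "created" \
                    and diffs[0].site.key() == key:
                return ref_seq, snp_off, ref, alt
    raise GenerationError(f"could not plant a creating SNP for {mirna.name}")


# --------------------------------------------------------------- the builder

def _nested_alt_column(
    rng: np.random.Generator, n_hap: int, r2: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """(index column, partner column, achieved r2): index at frequency 1/2,
    partner alternate set nested inside it with m = round(H r2/(1+r2))."""
    perm = rng.permutation(n_hap)
    index = np.zeros(n_hap, dtype=np.int8)
    index[perm[: n_hap // 2]] = 1
    m = int(round(n_hap * r2 / (1.0 + r2)))
    m = max(1, min(n_hap // 2, m))
    partner = np.zeros(n_hap, dtype=np.int8)
    partner[perm[:m]] = 1
    achieved = m / (n_hap - m)
    return index, partner, achieved


@dataclass
class _Snp:
    rsid: str
    chrom: str
    pos0: int  # 0-based genomic
    ref: str
    alt: str
    column: np.ndarray


class FixtureBuilder:
    """Builds the full deterministic plan in memory; writer methods then
    emit each file group.  Everything derives from the spec's seed in
    ``__init__``, so repeated builds are byte-identical."""

    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.rng_seed)
        self._build_mirnas()
        self._build_loci()
        self._build_hub_universe()
        self._assemble_genome()
        self._build_panel()
        self._build_manifest()

    # -- plan ------------------------------------------------------------

    def _build_mirnas(self):
        seen_seeds: set[str] = set()
        self.mirnas: list[MiRNA] = []
        i = 0
        while len(self.mirnas) < self.spec.n_mirnas:
            seq = _rand_dna(self.rng, 22)
            if seq[1:8] in seen_seeds:
                continue
            seen_seeds.add(seq[1:8])
            i += 1
            self.mirnas.append(MiRNA(f"miR-{i}", seq))
        self.hub_mirna = self.mirnas[0]

    def _next_rsid(self) -> str:
        self._rs_counter += 1
        return f"rs{self._rs_counter}"

    def _build_loci(self):
        """Lay out one LD-block locus per planted event plus decoy and
        boundary loci along chr1."""
        spec = self.spec
        L = spec.ld_block_length
        self._rs_counter = 100000
        self.events_plan: list[dict] = []
        self.elements_plan: list[dict] = []  # pre_mirna + promoter + exon
        self.event_utrs: list[dict] = []
        self.snp_plan: list[_Snp] = []
        self.nonsyn_rsids: list[str] = []
        self.transcriptional_rsids: list[str] = []
        self.eqtl_rsids: list[str] = []
        self.tarbase_pairs: list[tuple[str, str]] = []
        self.utr_patch: list[tuple[int, int, str]] = []  # chr1 splices

        loci: list[tuple[str, PlantedEvent | None]] = [
            (ev.name, ev) for ev in spec.planted_events
        ]
        if spec.boundary_locus:
            loci.append(("boundary", PlantedEvent(
                "boundary", "pre_mirna", r2=0.6)))
        for d in range(spec.n_decoy_loci):
            loci.append((f"decoy{d}", None))
        self.n_loci = len(loci)
        self.chr1_len = self.n_loci * L

        for li, (name, ev) in enumerate(loci):
            S = li * L
            index_rsid = self._next_rsid()
            if ev is None:
                self.events_plan.append({"name": name, "kind": None,
                                         "index_snp": index_rsid,
                                         "locus_start": S})
                self._plan_locus_panel(S, index_rsid, None, None)
                continue

            mirna = self.mirnas[1 + li % (len(self.mirnas) - 1)]
            tas_rsid = self._next_rsid()
            plan = {
                "name": name, "kind": ev.kind, "effect": ev.effect,
                "site_type": ev.site_type if ev.kind == "utr3" else None,
                "conservation": ev.conservation if ev.kind == "utr3" else None,
                "index_snp": index_rsid, "tas_snp": tas_rsid,
                "r2_target": ev.r2, "mirna": mirna.name,
                "disqualify": ev.disqualify, "tarbase": ev.tarbase,
                "locus_start": S, "boundary": name == "boundary",
            }

            if ev.kind == "pre_mirna":
                start, end = S + 3000, S + 3085
                self.elements_plan.append(
                    {"kind": "pre_mirna", "chrom": "chr1", "start": start,
                     "end": end, "strand": "+", "owner": mirna.name})
                tas_pos0 = S + 3040
            elif ev.kind == "promoter":
                start, end = S + 2500, S + 3000
                self.elements_plan.append(
                    {"kind": "promoter", "chrom": "chr1", "start": start,
                     "end": end, "strand": "+", "owner": mirna.name})
                tas_pos0 = S + 2750
            else:  # utr3
                gene = f"EVG{li}"
                lo, hi = self.spec.utr_length_range
                length = int(self.rng.integers(lo, hi + 1))
                offset = 50
                if ev.effect == "abolish":
                    utr, snp_off, ref_t, alt_t = _plant_abolishing_utr(
                        self.rng, length, offset, mirna, ev.site_type,
                        self.mirnas)
                else:
                    utr, snp_off, ref_t, alt_t = _plant_creating_utr(
                        self.rng, length, offset, mirna, ev.site_type,
                        self.mirnas)
                ustart = S + 3000
                uend = ustart + length
                if ev.utr_strand == "+":
                    tas_pos0 = ustart + snp_off
                    g_ref, g_alt = ref_t, alt_t
                    self.utr_patch.append((ustart, uend, utr))
                else:
                    tas_pos0 = uend - 1 - snp_off
                    g_ref, g_alt = _COMP[ref_t], _COMP[alt_t]
                    self.utr_patch.append((ustart, uend, _revcomp(utr)))
                orthologs = {}
                for si, species in enumerate(ORTHOLOGS):
                    if si < ev.conservation - 1:
                        orthologs[species] = _plant_site(
                            self.rng, length,
                            int(self.rng.integers(20, length - 30)),
                            mirna, ev.site_type)
                    else:
                        orthologs[species] = _seq_without_site(
                            self.rng, length, mirna, ev.site_type)
                self.event_utrs.append(
                    {"gene": gene, "sequence": utr, "start": ustart,
                     "end": uend, "strand": ev.utr_strand,
                     "orthologs": orthologs})
                plan.update(gene=gene, utr_offset=offset,
                            utr_snp_ref=ref_t, utr_snp_alt=alt_t)
                if ev.tarbase:
                    self.tarbase_pairs.append((mirna.name, gene))
                g_alleles = (g_ref, g_alt)

            plan["tas_pos0"] = tas_pos0
            self.events_plan.append(plan)
            tas_alleles = g_alleles if ev.kind == "utr3" else None
            self._plan_locus_panel(S, index_rsid, (tas_rsid, tas_pos0,
                                                   tas_alleles, ev.r2), ev)
            plan["expected_tier"] = self._expected_tier(ev)

        # one eQTL annotation on a planted TAS: annotates, never demotes
        if self.events_plan and self.events_plan[0].get("tas_snp"):
            self.eqtl_rsids.append(self.events_plan[0]["tas_snp"])

    def _expected_tier(self, ev: PlantedEvent) -> str | None:
        if ev.r2 <= 0.6:
            return None  # excluded from the LD block at the strict threshold
        if ev.disqualify is None:
            return "top"
        m = int(round(self.spec.n_haplotypes * ev.r2 / (1 + ev.r2)))
        achieved = m / (self.spec.n_haplotypes - m)
        if ev.tarbase or achieved > 0.9 or ev.r2 >= 1.0:
            return "supported"
        return "other"

    def _plan_locus_panel(self, S, index_rsid, tas, ev):
        """Panel columns for one locus: engineered index/TAS pair, optional
        disqualifying competitor SNP, and independent background SNPs."""
        H = self.spec.n_haplotypes
        r2 = tas[3] if tas else 0.5
        index_col, partner_col, achieved = _nested_alt_column(self.rng, H, r2)
        self.snp_plan.append(_Snp(index_rsid, "chr1", S + 100, "", "",
                                  index_col))
        if tas is not None:
            tas_rsid, tas_pos0, alleles, _ = tas
            self.snp_plan.append(
                _Snp(tas_rsid, "chr1", tas_pos0,
                     alleles[0] if alleles else "",
                     alleles[1] if alleles else "", partner_col))
            self.events_plan[-1]["r2_achieved"] = achieved
        if ev is not None and ev.disqualify is not None:
            comp_rsid = self._next_rsid()
            # nest the competitor inside the index alternate set so it sits
            # in the block (r2 = m/(H-m) ~ 0.94 with the index SNP)
            m = int(round(H * 0.95 / 1.95))
            comp_col = np.zeros(H, dtype=np.int8)
            comp_col[np.flatnonzero(index_col)[:m]] = 1
            if ev.disqualify == "exonic":
                self.elements_plan.append(
                    {"kind": "exon", "chrom": "chr1", "start": S + 1450,
                     "end": S + 1600, "strand": "+", "owner": "coding"})
            elif ev.disqualify == "nonsynonymous":
                self.nonsyn_rsids.append(comp_rsid)
            else:
                self.transcriptional_rsids.append(comp_rsid)
            self.snp_plan.append(_Snp(comp_rsid, "chr1", S + 1500, "", "",
                                      comp_col))
        for k in range(self.spec.n_background_per_locus):
            freq = self.rng.uniform(0.2, 0.5)
            col = (self.rng.random(H) < freq).astype(np.int8)
            while col.sum() in (0, H):
                col = (self.rng.random(H) < freq).astype(np.int8)
            self.snp_plan.append(_Snp(self._next_rsid(), "chr1",
                                      S + 5000 + 700 * k, "", "", col))

    def _build_hub_universe(self):
        """Gene universe on chr2 for the hub Monte Carlo test, with sites
        for the hub miRNA planted in ``hub_target_fraction`` of the trait
        gene list and ``hub_background_fraction`` of the rest."""
        spec = self.spec
        self.hub_genes: list[dict] = []
        n_trait = spec.hub_trait_genes
        n_trait_targets = int(round(spec.hub_target_fraction * n_trait))
        n_bg = spec.n_genes - n_trait
        n_bg_targets = int(round(spec.hub_background_fraction * n_bg))
        lo, hi = spec.utr_length_range
        pos = 500
        for j in range(spec.n_genes):
            gene = f"HUBG{j:03d}"
            length = int(self.rng.integers(lo, hi + 1))
            in_trait = j < n_trait
            is_target = (j < n_trait_targets) if in_trait else \
                (j - n_trait < n_bg_targets)
            if is_target:
                off = int(self.rng.integers(20, length - 30))
                seq = _plant_site(self.rng, length, off, self.hub_mirna,
                                  "8mer-1a")
                orthologs = {
                    sp: _plant_site(self.rng, length,
                                    int(self.rng.integers(20, length - 30)),
                                    self.hub_mirna, "8mer-1a")
                    for sp in ORTHOLOGS
                }
            else:
                seq = _rand_dna(self.rng, length)
                orthologs = {
                    sp: _seq_without_site(self.rng, length, self.hub_mirna,
                                          "8mer-1a")
                    for sp in ORTHOLOGS
                }
            self.hub_genes.append(
                {"gene": gene, "sequence": seq, "start": pos,
                 "end": pos + length, "in_trait": in_trait,
                 "is_target": is_target, "orthologs": orthologs})
            pos += length + 600
        self.chr2_len = pos + 500
        self.hub_expected = {
            "mirna": self.hub_mirna.name, "trait": spec.hub_trait,
            "n_trait_genes": n_trait, "n_trait_targets": n_trait_targets,
            "universe_size": spec.n_genes, "n_background_targets": n_bg_targets,
        }

    def _assemble_genome(self):
        chr1 = list(_rand_dna(self.rng, self.chr1_len))
        for start, end, seq in self.utr_patch:
            chr1[start:end] = seq
        chr2 = list(_rand_dna(self.rng, self.chr2_len))
        for g in self.hub_genes:
            chr2[g["start"]:g["end"]] = g["sequence"]
        self.genome = {"chr1": "".join(chr1), "chr2": "".join(chr2)}

    def _build_panel(self):
        """Fill reference/alternate alleles from the genome and order SNPs
        by position."""
        for snp in self.snp_plan:
            base = self.genome[snp.chrom][snp.pos0]
            if snp.ref == "":
                snp.ref = base
                others = [b for b in _BASES if b != base]
                snp.alt = others[int(self.rng.integers(len(others)))]
            elif snp.ref != base:
                raise GenerationError(
                    f"planted allele for {snp.rsid} disagrees with genome")
        self.snp_plan.sort(key=lambda s: (s.chrom, s.pos0))

    def _build_manifest(self):
        n_events = sum(1 for e in self.events_plan if e.get("kind"))
        counts = {"pre_mirna": 0, "promoter": 0, "utr3": 0,
                  "created": 0, "abolished": 0}
        for e in self.events_plan:
            if not e.get("kind") or e.get("boundary"):
                continue
            counts[e["kind"]] += 1
            if e.get("effect") == "abolish":
                counts["abolished"] += 1
            elif e.get("effect") == "create":
                counts["created"] += 1
        self.manifest = {
            "rng_seed": self.spec.rng_seed,
            "n_haplotypes": self.spec.n_haplotypes,
            "events": [e for e in self.events_plan if e.get("kind")],
            "decoy_index_snps": [e["index_snp"] for e in self.events_plan
                                 if e.get("kind") is None],
            "expected_counts": counts,
            "hub": self.hub_expected,
            "mirnas": {m.name: m.mature_sequence for m in self.mirnas},
        }

    # -- writers ---------------------------------------------------------

    def write_all(self, outdir: str | Path) -> dict[str, str]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths.update(self.write_haplotype_panel(out))
        paths.update(self.write_regulome(out))
        paths.update(self.write_catalog(out))
        paths.update(self.write_annotations(out))
        manifest = out / "manifest.json"
        manifest.write_text(json.dumps(self.manifest, indent=1,
                                       sort_keys=True) + "\n")
        paths["manifest"] = str(manifest)
        return paths

    def write_haplotype_panel(self, out: Path) -> dict[str, str]:
        path = out / "panel.vcf"
        header = pysam.VariantHeader()
        for chrom, seq in sorted(self.genome.items()):
            header.contigs.add(chrom, length=len(seq))
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                        'Description="Genotype">')
        n_samples = self.spec.n_haplotypes // 2
        samples = [f"S{i:04d}" for i in range(n_samples)]
        for s in samples:
            header.add_sample(s)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for snp in self.snp_plan:
                rec = vcf.new_record(contig=snp.chrom, start=snp.pos0,
                                     alleles=(snp.ref, snp.alt), id=snp.rsid)
                for i, s in enumerate(samples):
                    rec.samples[s]["GT"] = (int(snp.column[2 * i]),
                                            int(snp.column[2 * i + 1]))
                    rec.samples[s].phased = True
                vcf.write(rec)
        return {"panel_vcf": str(path)}

    def write_regulome(self, out: Path) -> dict[str, str]:
        paths = {}
        genome_path = out / "genome.fa"
        with open(genome_path, "w") as fh:
            for chrom, seq in sorted(self.genome.items()):
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        paths["genome_fasta"] = str(genome_path)

        mirna_path = out / "mature_mirnas.fa"
        with open(mirna_path, "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m.name}\n{m.mature_sequence}\n")
        paths["mirna_fasta"] = str(mirna_path)

        gff_path = out / "pre_mirnas.gff3"
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            i = 0
            for el in self.elements_plan:
                if el["kind"] != "pre_mirna":
                    continue
                i += 1
                fh.write(
                    f"{el['chrom']}\t.\tmiRNA_primary_transcript\t"
                    f"{el['start'] + 1}\t{el['end']}\t.\t{el['strand']}\t.\t"
                    f"ID=MI{i:07d};Name={el['owner']}\n")
        paths["mirna_gff3"] = str(gff_path)

        prom_path = out / "promoters.bed"
        with open(prom_path, "w") as fh:
            for el in self.elements_plan:
                if el["kind"] == "promoter":
                    fh.write(f"{el['chrom']}\t{el['start']}\t{el['end']}\t"
                             f"{el['owner']}\t0\t{el['strand']}\n")
        paths["promoter_bed"] = str(prom_path)

        exon_path = out / "exons.bed"
        with open(exon_path, "w") as fh:
            for el in self.elements_plan:
                if el["kind"] == "exon":
                    fh.write(f"{el['chrom']}\t{el['start']}\t{el['end']}\t"
                             f"{el['owner']}\t0\t{el['strand']}\n")
            # decoy exon far from every SNP
            fh.write(f"chr2\t{self.chr2_len - 200}\t{self.chr2_len - 100}\t"
                     f"decoy\t0\t+\n")
        paths["exon_bed"] = str(exon_path)

        utr_path = out / "utrs.tsv"
        map_path = out / "utr_mappings.tsv"
        sym_path = out / "symbol_map.tsv"
        utr_rows, map_rows, sym_rows = [], [], []
        nm = 1000

        def add_gene(gene, seq, orthologs, chrom=None, start=None, end=None,
                     strand="+"):
            nonlocal nm
            nm += 1
            seq_id = f"NM_{nm:06d}"
            sym_rows.append((seq_id, gene))
            utr_rows.append((seq_id, "human", seq))
            for sp, oseq in orthologs.items():
                utr_rows.append((seq_id, sp, oseq))
            if chrom is not None:
                map_rows.append((seq_id, chrom, strand, f"{start}-{end}"))

        for g in self.event_utrs:
            add_gene(g["gene"], g["sequence"], g["orthologs"], "chr1",
                     g["start"], g["end"], g["strand"])
        for g in self.hub_genes:
            add_gene(g["gene"], g["sequence"], g["orthologs"], "chr2",
                     g["start"], g["end"], "+")
        # admission-filter exercise records (never planted, never admitted)
        nm += 1
        sym_rows.append((f"NM_{nm:06d}", "JUNK_SHORT"))
        utr_rows.append((f"NM_{nm:06d}", "human", _rand_dna(self.rng, 15)))
        map_rows.append((f"NM_{nm:06d}", "chr2", "+",
                         f"{self.chr2_len - 400}-{self.chr2_len - 385}"))
        nm += 1
        sym_rows.append((f"NM_{nm:06d}", "JUNK_MULTI"))
        utr_rows.append((f"NM_{nm:06d}", "human", _rand_dna(self.rng, 80)))
        map_rows.append((f"NM_{nm:06d}", "chr2", "+", "10-90"))
        map_rows.append((f"NM_{nm:06d}", "chr2", "-", "110-190"))
        nm += 1
        sym_rows.append((f"NM_{nm:06d}", "JUNK_SPLICED"))
        utr_rows.append((f"NM_{nm:06d}", "human", _rand_dna(self.rng, 80)))
        map_rows.append((f"NM_{nm:06d}", "chr2", "+", "200-240,260-300"))

        with open(utr_path, "w") as fh:
            for row in utr_rows:
                fh.write("\t".join(row) + "\n")
        with open(map_path, "w") as fh:
            fh.write("seq_id\tchrom\tstrand\tsegments\n")
            for row in map_rows:
                fh.write("\t".join(row) + "\n")
        with open(sym_path, "w") as fh:
            for row in sym_rows:
                fh.write("\t".join(row) + "\n")
        paths.update(utr_table=str(utr_path), utr_mappings=str(map_path),
                     symbol_map=str(sym_path))

        trait_path = out / "trait_genes.tsv"
        with open(trait_path, "w") as fh:
            fh.write("trait\tgene\n")
            for g in self.hub_genes:
                if g["in_trait"]:
                    fh.write(f"{self.spec.hub_trait}\t{g['gene']}\n")
        paths["trait_genes"] = str(trait_path)
        return paths

    _ANCESTRY_POOL = (
        "2,000 Norwegian individuals",
        "1,840 European ancestry cases, 2,000 controls",
        "Utah residents of CEPH pedigree descent",
        "French adults from a population-based cohort",
    )

    def write_catalog(self, out: Path) -> dict[str, str]:
        path = out / "gwas_catalog.tsv"
        rows = []
        n_kept = 0
        for i, e in enumerate(self.events_plan):
            anc = self._ANCESTRY_POOL[i % len(self._ANCESTRY_POOL)]
            if e.get("kind"):
                rows.append((e["index_snp"], f"trait_{e['name']}", anc,
                             "3e-8", str(20000 + i)))
                n_kept += 1
            else:  # decoy locus: suggestive-only association, dropped
                rows.append((e["index_snp"], f"trait_{e['name']}", anc,
                             "2e-5", str(20000 + i)))
        # duplicate of the first event row: unique-TAS counts must not move
        first = next(e for e in self.events_plan if e.get("kind"))
        rows.append((first["index_snp"], f"trait_{first['name']}",
                     self._ANCESTRY_POOL[0], "3e-8", "29990"))
        n_kept += 1
        # multi-SNP haplotype row: dropped regardless of p
        rows.append(("rs9000001 x rs9000002", "trait_multi",
                     self._ANCESTRY_POOL[1], "1e-9", "29991"))
        # index SNP absent from the panel: kept, resolves to an empty block
        rows.append(("rs4242424", "trait_ghost", self._ANCESTRY_POOL[2],
                     "1e-8", "29992"))
        n_kept += 1
        # malformed p-value row: dropped with a logged count
        rows.append(("rs9000003", "trait_badp", self._ANCESTRY_POOL[3],
                     "NR", "29993"))
        with open(path, "w") as fh:
            fh.write("SNPS\tDISEASE/TRAIT\tINITIAL SAMPLE SIZE\tP-VALUE\t"
                     "PUBMEDID\n")
            for snp, trait, anc, p, pmid in rows:
                fh.write(f"{snp}\t{trait}\t{anc}\t{p}\t{pmid}\n")
        self.manifest["catalog"] = {
            "n_rows": len(rows), "n_kept_expected": n_kept,
            "unresolved_index": "rs4242424",
        }
        return {"catalog": str(path)}

    def write_annotations(self, out: Path) -> dict[str, str]:
        paths = {}
        nonsyn_path = out / "nonsyn.vcf"
        header = pysam.VariantHeader()
        for chrom, seq in sorted(self.genome.items()):
            header.contigs.add(chrom, length=len(seq))
        header.add_line('##INFO=<ID=NSM,Number=0,Type=Flag,'
                        'Description="nonsynonymous missense">')
        by_id = {s.rsid: s for s in self.snp_plan}
        with pysam.VariantFile(str(nonsyn_path), "w", header=header) as vcf:
            for rsid in self.nonsyn_rsids:
                s = by_id[rsid]
                rec = vcf.new_record(contig=s.chrom, start=s.pos0,
                                     alleles=(s.ref, s.alt), id=rsid)
                rec.info["NSM"] = True
                vcf.write(rec)
        paths["nonsyn_vcf"] = str(nonsyn_path)

        reg_path = out / "transcriptional.tsv"
        with open(reg_path, "w") as fh:
            fh.write("rsid\tcategory\n")
            for rsid in self.transcriptional_rsids:
                fh.write(f"{rsid}\t2b\n")
        paths["transcriptional_tsv"] = str(reg_path)

        eqtl_path = out / "eqtls.tsv"
        with open(eqtl_path, "w") as fh:
            fh.write("rsid\tgene\n")
            for rsid in self.eqtl_rsids:
                fh.write(f"{rsid}\tEVGX\n")
        paths["eqtl_tsv"] = str(eqtl_path)

        tarbase_path = out / "tarbase.tsv"
        with open(tarbase_path, "w") as fh:
            fh.write("mirna\tgene\n")
            for mirna, gene in self.tarbase_pairs:
                fh.write(f"{mirna}\t{gene}\n")
            fh.write(f"{self.mirnas[-1].name}\tDECOYGENE\n")
        paths["tarbase_tsv"] = str(tarbase_path)
        return paths


# ------------------------------------------------------------- module API

def make_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    """Generate the complete fixture suite; returns logical-name -> path."""
    return FixtureBuilder(spec).write_all(outdir)


def make_haplotype_panel(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    return FixtureBuilder(spec).write_haplotype_panel(out)


def make_regulome(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    return FixtureBuilder(spec).write_regulome(out)


def make_gwas_catalog(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    return FixtureBuilder(spec).write_catalog(out)
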