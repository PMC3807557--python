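import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirtas.ld import HaplotypePanel, SnpRecord, SuperPopulation
from mirtas.pipeline import PipelineConfig, run_pipeline
from mirtas.simulate import FixtureSpec, make_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def hand_panel() -> HaplotypePanel:
    """The 8-haplotype worked panel: pA = 1/2, pB = 3/8, pAB = 3/8, so
    r2 = (3/16)^2 / (1/4 * 3/8 * 5/8) = 0.6 exactly."""
    snps = [
        SnpRecord("chr1", 100, "rsA", "A", "G"),
        SnpRecord("chr1", 150, "rsB", "C", "T"),
    ]
    matrix = np.array(
        [[1, 1], [1, 1], [1, 1], [1, 0], [0, 0], [0, 0], [0, 0], [0, 0]],
        dtype=np.int8,
    )
    return HaplotypePanel(snps, matrix, SuperPopulation.EUR)


def random_panel(seed: int = 0, n_snps: int = 20,
                 n_hap: int = 200) -> HaplotypePanel:
    rng = np.random.default_rng(seed)
    snps = [SnpRecord("chr1", 1000 + 10 * i, f"rs{i}", "A", "G")
            for i in range(n_snps)]
    matrix = np.zeros((n_hap, n_snps), dtype=np.int8)
    for j in range(n_snps):
        freq = rng.uniform(0.05, 0.95)
        col = (rng.random(n_hap) < freq).astype(np.int8)
        matrix[:, j] = col
    return HaplotypePanel(snps, matrix, SuperPopulation.EUR)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("fixture")
    make_fixture(FixtureSpec(rng_seed=1), out)
    return out


@pytest.fixture(scope="session")
def fixture_manifest(fixture_dir) -> dict:
    return json.loads((fixture_dir / "manifest.json").read_text())


def fixture_config(fixture_dir: Path, outdir: Path, **overrides) -> PipelineConfig:
    kwargs = dict(
        catalog=str(fixture_dir / "gwas_catalog.tsv"),
        panels={"EUR": str(fixture_dir / "panel.vcf")},
        mirna_gff3=str(fixture_dir / "pre_mirnas.gff3"),
        promoter_bed=str(fixture_dir / "promoters.bed"),
        exon_bed=str(fixture_dir / "exons.bed"),
        mirna_fasta=str(fixture_dir / "mature_mirnas.fa"),
        utr_table=str(fixture_dir / "utrs.tsv"),
        utr_mappings=str(fixture_dir / "utr_mappings.tsv"),
        symbol_map=str(fixture_dir / "symbol_map.tsv"),
        nonsyn_vcf=str(fixture_dir / "nonsyn.vcf"),
        transcriptional_tsv=str(fixture_dir / "transcriptional.tsv"),
        eqtl_tsv=str(fixture_dir / "eqtls.tsv"),
        tarbase_tsv=str(fixture_dir / "tarbase.tsv"),
        trait_genes=str(fixture_dir / "trait_genes.tsv"),
        outdir=str(outdir),
        hub_reps=2000,
        seed=7,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir, tmp_path_factory):
    """One shared end-to-end run on the planted fixture."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = fixture_config(fixture_dir, outdir)
    manifest = run_pipeline(config)
    return outdir, manifest, config
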