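"""Shared fixtures: tiny hand-built datasets and one session-scoped
simulation batch reused by the statistically heavy tests."""

import numpy as np
import pytest

import popdiffscan as pds
from popdiffscan.genodata import (PolarizedGenotypes, PopulationPanel,
                                  VariantRecord)


def make_gts(H, positions=None, samples=None, chrom="1", ancestral_ref=True,
             impq=None):
    """PolarizedGenotypes from a (sites × haplotypes) 0/1/-1 matrix."""
    H = np.asarray(H, dtype=np.int8)
    n_sites, n_haps = H.shape
    assert n_haps % 2 == 0
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_haps // 2)]
    variants = []
    for i, p in enumerate(positions):
        q = impq[i] if impq is not None else None
        variants.append(VariantRecord(chrom, int(p), "A", "T",
                                      ancestral="A" if ancestral_ref else "T",
                                      impq=q))
    return PolarizedGenotypes(variants, H, samples)


@pytest.fixture
def three_pop_panel():
    """8 samples, 3 populations, 2 continents."""
    return PopulationPanel({
        "s0": ("YRI", "AFR"), "s1": ("YRI", "AFR"),
        "s2": ("LWK", "AFR"), "s3": ("LWK", "AFR"),
        "s4": ("CEU", "EUR"), "s5": ("CEU", "EUR"),
        "s6": ("TSI", "EUR"), "s7": ("TSI", "EUR"),
    })


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 biallelic SNPs, 2 samples, with AA and RSQ annotations."""
    text = """\
##fileformat=VCFv4.1
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
1\t100\t.\tA\tT\t.\tPASS\tAA=A;RSQ=0.95\tGT\t0|1\t1|1
1\t200\t.\tG\tC\t.\tPASS\tAA=C;RSQ=0.85\tGT\t0|0\t0|1
1\t300\t.\tC\tA\t.\tPASS\tAA=C\tGT\t1|0\t0|0
"""
    p = tmp_path / "tiny.vcf"
    p.write_text(text)
    return p


@pytest.fixture
def multiallelic_vcf(tmp_path):
    text = """\
##fileformat=VCFv4.1
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
1\t100\t.\tA\tT,G\t.\tPASS\tAA=A\tGT\t0|1\t2|0
1\t200\t.\tG\tC\t.\tPASS\tAA=G\tGT\t0|1\t0|0
"""
    p = tmp_path / "multi.vcf"
    p.write_text(text)
    return p


@pytest.fixture
def panel_file(tmp_path):
    p = tmp_path / "panel.tsv"
    p.write_text("sample\tpopulation\tcontinent\n"
                 "a\tYRI\tAFR\nb\tCEU\tEUR\nc\tCEU\tEUR\nd\tCHB\tASN\n")
    return p


@pytest.fixture
def two_segment_map(tmp_path):
    """Rates 0.5 then 2.0 cM/Mb: cumulative cM 0, 0.5, 2.5."""
    p = tmp_path / "map.txt"
    p.write_text("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n"
                 "0 0.5 0.0\n1000000 2.0 0.5\n2000000 0.0 2.5\n")
    return p


# ---------------------------------------------------------------------------
# session-scoped simulation batches (shared across the heavy tests)
# ---------------------------------------------------------------------------

AF_CLASS_COUNTS = {0.2: 50, 0.4: 55, 0.6: 55, 0.8: 55, 1.0: 55}
N_NEUTRAL = 500
BATCH_SEED = 20_260_919


@pytest.fixture(scope="session")
def benchmark_batch():
    """500 neutral + 270 sweep replicates at the default study
    conditions (λ=10, 100-kb regions, sweeps ending 401 generations
    before sampling); used by the power, recovery and
    haplotype-homogeneity tests."""
    from popdiffscan import powerbench
    return powerbench.run_benchmark(
        n_neutral=N_NEUTRAL, per_class=AF_CLASS_COUNTS, seed=BATCH_SEED,
        hap_stats=True)


@pytest.fixture(scope="session")
def small_neutral_replicates():
    """A handful of neutral replicates for structural checks."""
    m = pds.DemographicModel()
    return [pds.simulate_neutral(m, region_bp=50_000, n_per_pop=30,
                                 seed=900 + i) for i in range(3)]
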