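import random

import pytest

from estmir.datasets import load_barley_species_counts
from estmir.pipeline import run_pipeline
from estmir.reference import parse_mature_fasta
from estmir.simulate import default_config, generate

# the published per-species survey p-values (point mass, M=1929, K=497),
# kept as strings so each comparison can use that value's printed precision
TABLE1_PRINTED_P = {
    "Arabidopsis thaliana": "0.019",
    "Oryza sativa": "0.038",
    "Glycine max": "0.046",
    "Pinus taeda": "0.068",
    "Triticum aestivum": "2.0e-4",
    "Physcomitrella patens": "1.7e-6",
    "Populus trichocarpa": "0.021",
    "Chlamydomonas reinhardtii": "6.3e-8",
    "Selaginella moellendorffii": "0.058",
    "Vitis vinifera": "0.012",
    "Brassica napus": "0.010",
    "Gossypium hirsutum": "0.185",
    "Medicago truncatula": "0.068",
    "Solanum lycopersicum": "0.065",
    "Sorghum bicolor": "0.014",
    "Zea mays": "1.1e-5",
    "Brassica oleracea": "0.268",
    "Brassica rapa": "0.061",
    "Saccharum officinarum": "2.3e-3",
    "Gossypium herbecium": "0.773",
    "Carica papaya": "0.773",
    "Vigna unguiculata": "0.773",
    "Lotus japonicus": "0.597",
    "Gossypium rammindii": "0.079",
}


def printed_tolerance(printed: str) -> float:
    """Half an ulp of the last printed digit (e.g. '0.019' -> 5e-4,
    '2.0e-4' -> 5e-6)."""
    mantissa, _, exp = printed.lower().partition("e")
    decimals = len(mantissa.split(".")[1]) if "." in mantissa else 0
    scale = 10.0 ** int(exp) if exp else 1.0
    return 0.5 * 10.0 ** (-decimals) * scale


@pytest.fixture(scope="session")
def barley_counts():
    return load_barley_species_counts()


@pytest.fixture(scope="session")
def sim_result():
    """One seeded synthetic dataset shared across tests."""
    return generate(default_config(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(sim_result):
    annotations = {c["id"]: c["annotation"] for c in sim_result.manifest["clusters"]}
    categories = {c["id"]: c["category"] for c in sim_result.manifest["clusters"]}
    return run_pipeline(sim_result.reference, sim_result.ests,
                        annotations, categories)


@pytest.fixture(scope="session")
def small_reference():
    fasta = (
        ">tae-miR1137\nACGGGUCGUCUAUGGCUUAGG\n"
        ">osa-miR444d\nUGCAGUUGCUGCCUCAAGCUU\n"
        ">ath-miR156a\nUGACAGAAGAGAGUGAGCAC\n"
        ">zzz-miR156\nUGACAGAAGAGAGUGAGCAC\n"   # duplicate sequence
    )
    return parse_mature_fasta(fasta)


@pytest.fixture
def rng():
    return random.Random(1234)
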