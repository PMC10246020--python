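import numpy as np
import pytest

from gxlite.actions import write_fasta
from gxlite.refdb import build_index
from gxlite.synthetic import default_reference_taxa, simulate_reference_set

MASTER_SEED = 20240901


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def reference_set():
    """The stock simulated reference set (13 taxa, 5 kingdoms)."""
    return simulate_reference_set(MASTER_SEED, default_reference_taxa())


@pytest.fixture(scope="session")
def reference_db(reference_set, tmp_path_factory):
    fa = tmp_path_factory.mktemp("db") / "ref.fa"
    write_fasta(reference_set.records, fa)
    return build_index([fa], reference_set.tax_map, reference_set.taxonomy)


def make_db(records, tax_map, taxonomy, tmp_path):
    """Build a throwaway database from in-memory records."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    fa = tmp_path / "subjects.fa"
    write_fasta(records, fa)
    return build_index([fa], tax_map, taxonomy)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
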