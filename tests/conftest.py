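from pathlib import Path

import pandas as pd
import pytest

from brainprot import GeneratorParams, generate_proteome_dataset, generate_rna_table
from brainprot.dataio import write_table

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def samples_99_path() -> Path:
    return DATA_DIR / "samples_99.tsv"


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    """A 200-protein dataset small enough for I/O and CLI tests."""
    return GeneratorParams(n_proteins=200, markers_per_region=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return generate_proteome_dataset(small_params)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_params, small_dataset) -> Path:
    """On-disk TSVs of the 200-protein dataset for reader/CLI tests."""
    out = tmp_path_factory.mktemp("fixture")
    matrix, annotations, truth = small_dataset
    rna, id_map = generate_rna_table(truth, small_params)
    wide = matrix.values.copy()
    wide.index.name = "protein_id"
    write_table(wide, out / "matrix.tsv", index=True)
    samples = pd.DataFrame(
        [(a.sample_id, a.donor_id, a.region.value) for a in annotations],
        columns=["sample_id", "donor_id", "region"],
    )
    write_table(samples, out / "samples.tsv")
    write_table(rna.ntpm, out / "rna.tsv", index=True)
    write_table(id_map, out / "idmap.tsv")
    return out
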