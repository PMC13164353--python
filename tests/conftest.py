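from importlib import resources

import pandas as pd
import pytest

from acepep import BBDExperiment, DEFAULT_CODING, bundled_candidates, fit_quadratic


@pytest.fixture(scope="session")
def design_table() -> pd.DataFrame:
    """The bundled 17-run hydrolysis-optimization design (natural units)."""
    with resources.as_file(
        resources.files("acepep.data").joinpath("bbd_design.csv")
    ) as p:
        return pd.read_csv(p)


@pytest.fixture(scope="session")
def bbd_fit(design_table):
    design = BBDExperiment.from_natural(design_table, DEFAULT_CODING)
    return fit_quadratic(design)


@pytest.fixture(scope="session")
def candidate_table() -> pd.DataFrame:
    """Seven example candidates with reported subscores and totals."""
    return bundled_candidates()


@pytest.fixture
def write_fasta(tmp_path):
    def _write(text: str, name: str = "toy.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
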