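from pathlib import Path

import pytest

from tcgtscan.sequences import open_genome
from tcgtscan.synthetic import CohortDesign, generate


@pytest.fixture(scope="session")
def design() -> CohortDesign:
    return CohortDesign(seed=11, n_tumor=12, n_normal=12)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, design):
    """A generated synthetic cohort shared across the session."""
    outdir = tmp_path_factory.mktemp("cohort")
    reference, cohort = generate(design, outdir)
    return {"dir": Path(outdir), "reference": reference, "cohort": cohort}


@pytest.fixture(scope="session")
def reference(cohort_dir):
    return cohort_dir["reference"]


@pytest.fixture(scope="session")
def genome(reference):
    return open_genome(reference.genome_path)
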