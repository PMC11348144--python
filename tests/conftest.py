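import numpy as np
import pandas as pd
import pytest

import methylink as ml
from methylink.io_formats import SITE_COLUMNS, MethylomeSample


def make_sample(records, sample_id="S", group="tumor"):
    """Build a MethylomeSample from (chrom, pos, meth, unmeth) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "meth", "unmeth"])
    df["strand"] = "+"
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return MethylomeSample(sample_id=sample_id, group=group, sites=df[SITE_COLUMNS])


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort, shared across tests (read-only)."""
    return ml.simulate(ml.default_config(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    return ml.analyze_dataset(default_dataset)
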