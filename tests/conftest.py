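import warnings

import numpy as np
import pandas as pd
import pytest

from splicescape.events import SpliceEvent
from splicescape.simulate import CohortSpec, build_event, generate_cohort

warnings.filterwarnings("ignore", message="Random effects covariance is singular")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """20 participants/arm, Pre + one post timepoint."""
    return generate_cohort(CohortSpec(n_per_arm=20, timepoints=("Pre", "P15M"), seed=42))


@pytest.fixture()
def se_event() -> SpliceEvent:
    """A skipped exon with two inclusion junctions and one exclusion."""
    return build_event(0)[0]


def make_event(
    event_id="evX",
    etype="SE",
    gene_id="gX",
    strand="+",
    inc_j=("j_i1", "j_i2"),
    exc_j=("j_e",),
    inc_iso=("txI",),
    exc_iso=("txE",),
    alt=(1000, 1200),
    sites=(200, 1000, 1200, 2000),
    chrom="chrS",
):
    return SpliceEvent(
        event_id=event_id,
        etype=etype,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        inclusion_junctions=tuple(inc_j),
        exclusion_junctions=tuple(exc_j),
        inclusion_isoforms=frozenset(inc_iso),
        exclusion_isoforms=frozenset(exc_iso),
        alt_region=tuple(alt),
        splice_sites=tuple(sites),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
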