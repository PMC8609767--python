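import numpy as np
import pandas as pd
import pytest

from gsascar import BinTrack, GenomeAnnotation, load_grch37


@pytest.fixture(scope="session")
def grch37():
    return load_grch37()


@pytest.fixture
def toy_annotation():
    """Two chromosomes with centromeres, small enough for exhaustive checks."""
    return GenomeAnnotation(
        chromosomes=("1", "2"),
        lengths={"1": 200_000_000, "2": 150_000_000},
        centromeres={"1": (100_000_000, 104_000_000), "2": (60_000_000, 63_000_000)},
    )


def make_track(rows, annotation):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "baf", "lrr"])
    return BinTrack(df, annotation)


@pytest.fixture
def make_bins(toy_annotation):
    """Uniform 0.5 Mb bins on the toy genome with constant BAF/LRR."""

    def build(baf=0.5, lrr=0.0, width=500_000):
        rows = []
        for chrom in toy_annotation.chromosomes:
            cs, ce = toy_annotation.centromeres[chrom]
            for start in range(0, toy_annotation.lengths[chrom] - width + 1, width):
                end = start + width
                if start < ce and end > cs:
                    continue
                rows.append((chrom, start, end, baf, lrr))
        return make_track(rows, toy_annotation)

    return build
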