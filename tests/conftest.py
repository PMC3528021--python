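from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lincnv.annotation import AnnotationTrack, Interval
from lincnv.genome import GenomeModel


@pytest.fixture
def rng():
    return np.random.default_rng(20120299)


@pytest.fixture
def toy_genome():
    return GenomeModel({"chr1": 1_000, "chr2": 2_000})


@pytest.fixture
def toy_tracks():
    """The 1 kb worked example: gene [100,300), lincRNA [500,600)."""
    coding = AnnotationTrack("coding", [Interval("chr1", 100, 300, "GENE0001", "protein_coding")])
    lincrna = AnnotationTrack("lincRNA", [Interval("chr1", 500, 600, "LINC0001", "lincRNA")])
    return coding, lincrna


def make_probe_frame(positions, lrr, baf=None, genotype=None, chrom="chr1", gc=None,
                     name_prefix="p"):
    n = len(positions)
    df = pd.DataFrame(
        {
            "name": [f"{name_prefix}_{chrom}_{i:05d}" for i in range(n)],
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "lrr": np.asarray(lrr, dtype=float),
            "baf": np.full(n, 0.5) if baf is None else np.asarray(baf, dtype=float),
            "genotype": ["AB"] * n if genotype is None else list(genotype),
        }
    )
    if gc is not None:
        df["gc"] = np.asarray(gc, dtype=float)
    return df
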