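import numpy as np
import pytest

from lakestream.genotype_data import GenotypeTable, PopulationMap


def make_table(
    pos,
    dosage,
    chrom=None,
    depth=None,
    samples=None,
    ref=None,
    alt=None,
    monomorphic=None,
    ad_ref=None,
    ad_alt=None,
):
    """Hand-build a GenotypeTable from plain lists (test fixture helper)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_var, n_samp = dosage.shape
    if samples is None:
        samples = [f"s{i+1}" for i in range(n_samp)]
    if chrom is None:
        chrom = ["chr1"] * n_var
    if depth is None:
        depth = np.full((n_var, n_samp), 30, dtype=np.int32)
    return GenotypeTable(
        samples=list(samples),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref if ref is not None else ["A"] * n_var, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * n_var, dtype=object),
        dosage=dosage,
        depth=np.asarray(depth, dtype=np.int32),
        ad_ref=None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        ad_alt=None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32),
        monomorphic={c: np.array(v, dtype=np.int64) for c, v in (monomorphic or {}).items()},
    )


@pytest.fixture
def table_builder():
    return make_table


@pytest.fixture
def two_pop_map():
    return PopulationMap({"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"})
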