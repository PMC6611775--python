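import numpy as np
import pandas as pd
import pytest

from uromics import ExpressionMatrix, SimulationConfig, VariantRecord
from uromics import gen_reference, synthetic_reference_catalog


@pytest.fixture(scope="session")
def reference_catalog():
    return synthetic_reference_catalog()


@pytest.fixture(scope="session")
def small_reference():
    """A 60 kb synthetic contig shared by variant/signature tests."""
    cfg = SimulationConfig(seed=101, contig_length=60_000)
    return gen_reference(cfg)


def make_variant(
    contig="chrS",
    pos=100,
    ref="C",
    alt="T",
    callers=(),
    tumor_depth=100,
    tumor_alt=10,
    normal_depth=50,
    normal_alt=0,
    **kwargs,
):
    return VariantRecord(
        contig=contig,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        callers=frozenset(callers),
        tumor_depth=tumor_depth,
        tumor_alt=tumor_alt,
        normal_depth=normal_depth,
        normal_alt=normal_alt,
        **kwargs,
    )


def make_matrix(values, genes=None, samples=None, unit="FPKM", cohort=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    cohort = cohort or {s: "A" for s in samples}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        unit=unit,
        cohort=cohort,
    )
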