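import numpy as np
import pytest

from germtrace.mira_peaks import ArrayDesign, MethylationSampleGroup, SampleMeta


def make_design(n_probes: int, chrom: str = "chr1", spacing: int = 100,
                length: int = 50, chroms=None) -> ArrayDesign:
    """Uniformly spaced probe design on one or more chromosomes."""
    if chroms is None:
        chroms = [chrom] * n_probes
    starts, counter = [], {}
    for c in chroms:
        i = counter.get(c, 0)
        starts.append(i * spacing)
        counter[c] = i + 1
    ids = [f"{c}_p{i}" for i, c in enumerate(chroms)]
    return ArrayDesign(ids, chroms, starts, [s + length for s in starts])


def make_group(design: ArrayDesign, values: np.ndarray,
               treatment: str = "oil") -> MethylationSampleGroup:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    meta = SampleMeta("G1R", "MGC", treatment, "custom")
    return MethylationSampleGroup(
        design=design,
        sample_ids=[f"{treatment}_r{i}" for i in range(values.shape[0])],
        metadata=[meta] * values.shape[0],
        values=values,
    )


@pytest.fixture
def design10() -> ArrayDesign:
    return make_design(10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150327)
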