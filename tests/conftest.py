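import numpy as np
import pytest

from coma import (BuildParams, FixtureSpec, build_profile,
                  load_initial_table, sample_family_msa)


@pytest.fixture(scope="session")
def table():
    return load_initial_table()


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(n_positions=60, n_sequences=20,
                       gap_runs=((20, 4, 0.4),), seed=7)


@pytest.fixture(scope="session")
def small_msa(small_spec):
    return sample_family_msa(small_spec, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_profile(table, small_msa):
    return build_profile(small_msa, table, BuildParams(), name="small")


@pytest.fixture(scope="session")
def profile_pair(table, small_spec):
    rng = np.random.default_rng(11)
    p1 = build_profile(sample_family_msa(small_spec, rng), table, name="pA")
    p2 = build_profile(sample_family_msa(small_spec, rng), table, name="pB")
    return p1, p2


def single_sequence_msa(sequence: str, name: str = "seq"):
    from coma import MultipleAlignment
    return MultipleAlignment(sequence_ids=[name], rows=[sequence])


@pytest.fixture(scope="session")
def single_seq_profile(table):
    msa = single_sequence_msa("ACDEFGHIKLMNPQRSTVWY" * 2, "single")
    return build_profile(msa, table, BuildParams(seg=False), name="single")
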