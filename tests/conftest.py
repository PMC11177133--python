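import numpy as np
import pytest

from svld.ld import GenotypeCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)


def random_nondegenerate_tables(n_tables, rng, max_count=50):
    """Random integer 3x3 tables with both marginals polymorphic."""
    out = []
    while len(out) < n_tables:
        counts = rng.integers(0, max_count + 1, size=(3, 3)).astype(float)
        table = GenotypeCountTable(counts)
        row = table.sv_marginals
        col = table.snp_marginals
        n = counts.sum()
        if n < 2:
            continue
        # reject monomorphic margins (zero dosage variance)
        if max(row) == n or max(col) == n:
            continue
        out.append(table)
    return out


@pytest.fixture(scope="session")
def planted_fixture(tmp_path_factory):
    """The standard planted fixture built once per session."""
    from svld import simulate

    out_dir = tmp_path_factory.mktemp("fixture")
    paths = simulate.build_fixture(
        simulate.default_planted_pairs(), str(out_dir), seed=20231101
    )
    return paths
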