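import pytest

from plegenes import synthetic as syn


@pytest.fixture(scope="session")
def default_spec():
    return syn.SyntheticClusterSpec()


@pytest.fixture(scope="session")
def ple1_gene(default_spec):
    """Default PLE-1 gene unit (sequence, truth) at mutation rate 0."""
    return syn.generate_gene(default_spec, "PLE-1")


@pytest.fixture(scope="session")
def clone_layout():
    """Five-clone, two-cluster reference layout with vector-carrying clones."""
    return syn.generate_reference_clone_set()


@pytest.fixture(scope="session")
def trimmed_inserts(clone_layout):
    from plegenes.assembly import trim_vector

    inserts = {}
    for name, seq in clone_layout.clones:
        res = trim_vector(seq, clone_layout.vector)
        assert res.vector_found
        inserts[name] = res.insert
    return inserts
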