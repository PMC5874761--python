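import pytest

from peptigo import FixtureSpec, RunConfig, generate_bundle, run_quantify
from peptigo.fixtures import reference_count_bundle


def bundle_config(manifest) -> RunConfig:
    paths = manifest.paths
    return RunConfig(
        fasta=str(paths["fasta"]),
        peptides=str(paths["peptides_1"]),
        blast=str(paths["blast"]),
        go_map=str(paths["go_map"]),
        taxon_map=str(paths["taxon_map"]),
        obo=str(paths["obo"]),
        nodes=str(paths["nodes"]),
        names=str(paths["names"]),
        merged=str(paths["merged"]) if paths.get("merged") else None,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A seeded synthetic bundle shared across the suite (read-only)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(FixtureSpec(seed=7), out)


@pytest.fixture(scope="session")
def bundle_result(bundle):
    """The quantification pipeline run once on the shared bundle."""
    return run_quantify(bundle_config(bundle))


@pytest.fixture(scope="session")
def reference_bundle(tmp_path_factory):
    """The hand-shaped bundle with round-number expected counts."""
    out = tmp_path_factory.mktemp("reference_bundle")
    return reference_count_bundle(out)


@pytest.fixture(scope="session")
def reference_result(reference_bundle):
    return run_quantify(bundle_config(reference_bundle))


TINY_OBO = """format-version: 1.2

[Term]
id: GO:0008150
name: biological process
namespace: biological_process

[Term]
id: GO:0003674
name: molecular function
namespace: molecular_function

[Term]
id: GO:0005575
name: cellular component
namespace: cellular_component

[Term]
id: GO:0000002
name: b
namespace: molecular_function
alt_id: GO:0000001
is_a: GO:0003674

[Term]
id: GO:0000003
name: c
namespace: molecular_function
is_a: GO:0000002

[Term]
id: GO:0000004
name: diamond left
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0000005
name: diamond bottom
namespace: molecular_function
is_a: GO:0000002
is_a: GO:0000004

[Term]
id: GO:0000006
name: bp child
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0000009
name: gone
namespace: molecular_function
is_obsolete: true
"""


@pytest.fixture()
def tiny_ontology(tmp_path):
    """Three roots, an MF chain c→b→root, a diamond, an alt_id, an obsolete
    term."""
    from peptigo import read_obo

    path = tmp_path / "tiny.obo"
    path.write_text(TINY_OBO, encoding="utf-8")
    return read_obo(path)
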