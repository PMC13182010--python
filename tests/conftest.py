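import pytest

from ecoprofile import synthetic
from ecoprofile.model import AnnotationTable, GeneAnnotation
from ecoprofile.pipeline import default_data_path
from ecoprofile.transporters import load_transporter_defs
from ecoprofile.machinery import load_machinery_models
from ecoprofile.panels import load_panels, load_complex_markers


def make_table(genome_id, genes):
    """Build an AnnotationTable from (gene_id, kwargs) shorthand."""
    rows = []
    for i, (gid, kw) in enumerate(genes):
        kw = dict(kw)
        if "cog_categories" in kw:
            kw["cog_categories"] = frozenset(kw["cog_categories"])
        if "cog_ids" in kw:
            kw["cog_ids"] = frozenset(kw["cog_ids"])
        rows.append(GeneAnnotation(gene_id=gid, rank=i, **kw))
    return AnnotationTable(genome_id, rows)


@pytest.fixture(scope="session")
def landmarks():
    return synthetic.synthetic_landmarks(seed=7)


@pytest.fixture(scope="session")
def transporter_defs():
    return load_transporter_defs(default_data_path("transporter_defs.yaml"))


@pytest.fixture(scope="session")
def machinery_models():
    return load_machinery_models(default_data_path("machinery_models.yaml"))


@pytest.fixture(scope="session")
def default_panels():
    return load_panels(default_data_path("panels.yaml"))


@pytest.fixture(scope="session")
def oxidative_markers():
    return load_complex_markers(default_data_path("oxidative.yaml"))
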