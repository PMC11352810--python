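import pytest

from faerspv import cleaning, cohort, faers_io, meddra_map
from faerspv import synthetic_data as sd


@pytest.fixture(scope="session")
def dictionary():
    return cohort.load_drug_dictionary()


@pytest.fixture(scope="session")
def queries():
    return meddra_map.load_bundled_queries()


@pytest.fixture(scope="session")
def sim_corpus():
    """Medium synthetic corpus with one strongly planted drug-query pair."""
    config = sd.SimConfig(
        n_reports=1500,
        seed=11,
        planted_rr={("ribociclib", "Toy torsade/QT prolongation"): 8.0},
    )
    return sd.generate_corpus(config)


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory, sim_corpus):
    path = tmp_path_factory.mktemp("corpus")
    sd.write_corpus(sim_corpus, path)
    return path


@pytest.fixture(scope="session")
def loaded_cases(corpus_dir):
    return faers_io.load_corpus(corpus_dir)


@pytest.fixture()
def cleaned_cases(loaded_cases):
    cases, deleted = loaded_cases
    return cleaning.clean_cases(list(cases), deleted)


@pytest.fixture(scope="session")
def fixture_suite():
    return sd.make_fixture_suite()


def assemble(corpus):
    """Join a SyntheticCorpus into case reports without touching disk."""
    return faers_io.assemble_cases(
        corpus.demo, corpus.drug, corpus.reac, corpus.outc, corpus.ther
    )
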