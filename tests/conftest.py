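import pytest

from percentaudit.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A seeded 300-abstract synthetic corpus with ground truth."""
    config = GeneratorConfig(n_abstracts=300, seed=20170)
    records, truths = generate_corpus(config)
    return config, records, truths


@pytest.fixture()
def jsonl_corpus(tmp_path):
    """A 2-record corpus file on disk."""
    path = tmp_path / "corpus.jsonl"
    path.write_text(
        '{"record_id": "a", "journal": "J One", "year": 2017, '
        '"publication_types": ["Journal Article"], "abstract_text": "Mortality was 12.5%."}\n'
        '{"record_id": "b", "journal": "J Two", "year": 2017, '
        '"publication_types": ["Review"], "abstract_text": ""}\n',
        encoding="utf-8",
    )
    return path
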