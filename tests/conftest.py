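import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hypersimp.lexicon import build_lexicon, build_ngram_index  # noqa: E402


TOY_ROWS = [
    ("histamine receptor", "organ", "semantic_type", "Structure"),
    ("histamine", "chemical", "semantic_type", "Substance"),
    ("receptor", "protein", "wordnet", ""),
    ("lymphoma", "cancer", "wordnet", ""),
    ("lymphoma", "neoplastic process", "semantic_type", "Neoplastic Process"),
    ("glucocorticoid", "steroid", "wordnet", ""),
]


@pytest.fixture(scope="session")
def toy_lexicon():
    return build_lexicon(TOY_ROWS)


@pytest.fixture(scope="session")
def toy_index(toy_lexicon):
    return build_ngram_index(toy_lexicon)


@pytest.fixture
def lexicon_tsv(tmp_path):
    path = tmp_path / "lexicon.tsv"
    lines = ["term\thypernym\tsource\tsemantic_type"]
    lines += ["\t".join(row) for row in TOY_ROWS]
    path.write_text("\n".join(lines) + "\n")
    return path
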