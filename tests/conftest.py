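import pytest
from hypothesis import HealthCheck, settings

from chemner.memm import TrainingConfig, train
from chemner.synthetic import GeneratorConfig, adversarial_corpus, generate_corpus
from chemner.tokeniser import naive_tokenise, tokenise

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

RECOVERY_SEED = 1234
ADVERSARIAL_SEED = 4321


@pytest.fixture(scope="session")
def default_split():
    """200 train / 50 test documents at default density — the recovery regime."""
    cfg = GeneratorConfig(n_documents=250, seed=RECOVERY_SEED)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def trained_memm(default_split):
    train_docs, _ = default_split
    return train(train_docs, config=TrainingConfig())


@pytest.fixture(scope="session")
def adversarial_split():
    """120 train / 30 test documents of tokenisation-fragile mentions."""
    cfg = GeneratorConfig(n_documents=150, seed=ADVERSARIAL_SEED)
    return adversarial_corpus(cfg)


@pytest.fixture(scope="session")
def ablation_models(adversarial_split):
    """The same MEMM configuration trained with each tokeniser."""
    train_docs, _ = adversarial_split
    chem = train(train_docs, tokeniser=tokenise, config=TrainingConfig())
    naive = train(train_docs, tokeniser=naive_tokenise, config=TrainingConfig())
    return chem, naive
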