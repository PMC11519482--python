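import numpy as np
import pytest

import emospec as es


@pytest.fixture(scope="session")
def small_corpus() -> es.SequenceDataset:
    """A normalized, split 8-class planted corpus (n=400, noise 0.5)."""
    sspec = es.SynthSpec(noise_sd=0.5, seed=11)
    corpus = es.generate_corpus(sspec, 400)
    ds = es.split_dataset(corpus, 0.2, seed=3, unit="window")
    return es.normalize_dataset(ds)


@pytest.fixture(scope="session")
def small_model(small_corpus) -> es.TrainedEncoder:
    """An autoencoder trained briefly on the small corpus."""
    cfg = es.EncoderConfig()
    cfg.training.max_epochs = 40
    cfg.training.seed = 5
    return es.train(small_corpus, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_episode(length: int, episode_id: str = "ep0",
                 seed: int = 0) -> es.Episode:
    g = np.random.default_rng(seed)
    steps = [es.StepRecord(t, float(g.normal(0.67, 5.6)),
                           float(g.normal(62.4, 19.0)))
             for t in range(length)]
    return es.Episode(episode_id, steps)
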