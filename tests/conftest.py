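import numpy as np
import pytest

from smoco.encoder import EncoderSpec
from smoco.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny strong-effect cohort shared by read-only tests."""
    cfg = PhantomConfig(grid_size=12, n_converter=6, n_nonconverter=6,
                        n_unlabeled=6, images_per_subject=2, effect_size=3.0,
                        noise_sd=0.1, subject_sd=0.1, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def reduced_spec():
    return EncoderSpec.reduced()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def unit_vectors(rng, n, d):
    v = rng.normal(size=(n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# -- independent scalar-loop loss oracles (shared by loss tests) --------------

def oracle_instance_loss(a, p, negs, tau):
    """-log softmax over [positive, negatives], by direct summation."""
    num = np.exp(a @ p / tau)
    den = num + sum(np.exp(a @ n / tau) for n in negs)
    return -np.log(num / den)


def oracle_label_loss(a, p, q_emb, q_lab, lab, tau, form):
    """Label-aware pull term by explicit enumeration of the same-label
    queue subset."""
    same = [i for i, l in enumerate(q_lab) if l == lab]
    if not same:
        return 0.0
    den = np.exp(a @ p / tau) + sum(np.exp(a @ q / tau) for q in q_emb)
    terms = [np.exp(a @ q_emb[i] / tau) / den for i in same]
    if form == "mean-of-logs":
        return -np.mean([np.log(t) for t in terms])
    return -np.log(np.mean(terms))
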