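"""Queue semantics, EMA arithmetic, and loss values against independent
scalar oracles (direct transcriptions of the loss definitions, computed
with plain loops)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smoco.contrastive import (ContrastConfig, MemoryQueue, ema_update,
                               enqueue, label_loss, moco_loss,
                               smoco_batch_loss)
from smoco.nn.autodiff import Tensor

from conftest import oracle_instance_loss, oracle_label_loss, unit_vectors


# -- queue ---------------------------------------------------------------------

def test_enqueue_fifo_eviction_and_label_alignment():
    q = MemoryQueue(4, 2)
    enqueue(q, np.eye(2, 2), ["converter", "non-converter"])
    assert len(q) == 2
    q.enqueue(np.ones((3, 2)), ["unlabeled", "converter", "non-converter"])
    assert len(q) == 4
    # oldest entry ("converter") evicted first
    emb, lab = q.entries()
    assert q.labels == ["non-converter", "unlabeled", "converter",
                        "non-converter"]
    assert q.labels[-1] == "non-converter"
    np.testing.assert_array_equal(emb[0], [0, 1])


def test_enqueue_full_queue_keeps_capacity():
    q = MemoryQueue(1024, 4, prefill=True)
    batch = np.ones((16, 4), dtype=np.float32)
    q.enqueue(batch, ["converter"] * 16)
    assert len(q) == 1024
    assert q.labels[-16:] == ["converter"] * 16


def test_enqueue_errors():
    q = MemoryQueue(4, 2)
    with pytest.raises(ValueError):
        q.enqueue(np.ones((5, 2)), ["unlabeled"] * 5)
    with pytest.raises(ValueError):
        q.enqueue(np.ones((1, 3)), ["unlabeled"])
    with pytest.raises(ValueError):
        q.enqueue(np.ones((1, 2)), ["MCI"])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(1, 5), min_size=1, max_size=12),
       st.integers(2, 8))
def test_queue_is_fifo_under_arbitrary_enqueues(batch_sizes, capacity):
    """Eviction order equals insertion order for any enqueue sequence."""
    q = MemoryQueue(capacity, 1)
    counter = 0
    inserted = []
    for b in batch_sizes:
        b = min(b, capacity)
        vals = np.arange(counter, counter + b, dtype=np.float32)[:, None]
        q.enqueue(vals, [0] * b)
        inserted += list(range(counter, counter + b))
        counter += b
    emb, _ = q.entries()
    expected = inserted[-min(len(inserted), capacity):]
    np.testing.assert_array_equal(emb[:, 0], expected)


# -- scalar losses -------------------------------------------------------------

def test_moco_loss_uniform_similarities():
    a = np.array([1.0, 0.0])
    assert moco_loss(a, a, [a, a, a], tau=0.7) == pytest.approx(np.log(4))


def test_moco_loss_single_negative_value():
    val = moco_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]),
                    [np.array([0.0, 1.0])], tau=1.0)
    assert val == pytest.approx(-np.log(np.e / (np.e + 1)), abs=1e-12)


def test_moco_loss_saturates_and_is_monotone(rng):
    negs = list(unit_vectors(rng, 4, 8))
    p = unit_vectors(rng, 1, 8)[0]
    losses = []
    for scale in (0.0, 0.5, 0.9, 1.0):
        a = scale * p + (1 - scale) * negs[0]
        a = a / np.linalg.norm(a)
        losses.append(moco_loss(a, p, negs, tau=0.2))
    assert all(b < a for a, b in zip(losses, losses[1:]))
    big = 50 * p  # a.p large: loss -> 0
    assert moco_loss(big, p, negs, tau=0.2) < 1e-6


def test_moco_loss_zero_negatives_and_errors(rng):
    v = unit_vectors(rng, 1, 4)[0]
    assert moco_loss(v, v, [], tau=0.2) == 0.0
    with pytest.raises(ValueError):
        moco_loss(v, v, [v], tau=0.0)
    with pytest.raises(ValueError):
        moco_loss(v, np.ones(5), [v], tau=0.2)


def test_label_loss_empty_same_label_subset_is_zero(rng):
    q = MemoryQueue(8, 4)
    q.enqueue(unit_vectors(rng, 3, 4),
              ["unlabeled", "unlabeled", "non-converter"])
    v = unit_vectors(rng, 2, 4)
    assert label_loss(v[0], v[1], q, "converter", tau=0.2) == 0.0


def test_label_loss_unlabeled_anchor_rejected(rng):
    q = MemoryQueue(4, 4)
    v = unit_vectors(rng, 1, 4)[0]
    with pytest.raises(ValueError):
        label_loss(v, v, q, "unlabeled", tau=0.2)


def test_label_loss_uniform_similarity_values():
    """|M|=1 with all similarities equal gives ln(4) in both forms;
    |M| = queue length gives ln(len + 1) for mean-of-logs."""
    a = np.array([1.0, 0.0, 0.0])
    q1 = MemoryQueue(8, 3)
    q1.enqueue(np.stack([a, a, a]), ["converter", "unlabeled", "unlabeled"])
    for form in ("mean-of-logs", "log-of-mean"):
        assert label_loss(a, a, q1, "converter", tau=0.4,
                          label_loss_form=form) == pytest.approx(np.log(4))
    q2 = MemoryQueue(8, 3)
    q2.enqueue(np.stack([a] * 5), ["converter"] * 5)
    assert label_loss(a, a, q2, "converter", tau=0.4) == pytest.approx(
        np.log(6))


def test_label_loss_single_positive_equals_instance_form(rng):
    """With |M|=1 the label loss equals the instance loss whose numerator
    is that queue entry, sharing the same denominator."""
    a, p = unit_vectors(rng, 2, 6)
    q_emb = unit_vectors(rng, 5, 6).astype(np.float32)
    q = MemoryQueue(8, 6)
    q.enqueue(q_emb, ["converter"] + ["unlabeled"] * 4)
    got = label_loss(a, p, q, "converter", tau=0.2)
    qe, _ = q.entries()
    den = np.exp(a @ p / 0.2) + sum(np.exp(a @ z / 0.2) for z in qe)
    expected = -np.log(np.exp(a @ qe[0] / 0.2) / den)
    assert got == pytest.approx(expected, abs=1e-9)


# -- batched loss vs oracle ----------------------------------------------------

@pytest.mark.parametrize("form", ["mean-of-logs", "log-of-mean"])
def test_batch_loss_matches_scalar_oracle(form, rng):
    for trial in range(20):
        d = int(rng.integers(2, 9))
        K = int(rng.integers(1, 17))
        B = int(rng.integers(1, 5))
        tau = float(rng.uniform(0.05, 1.0))
        alpha = float(rng.uniform(0.0, 3.0))
        labels = [str(rng.choice(["converter", "non-converter", "unlabeled"]))
                  for _ in range(B)]
        q_lab = [str(rng.choice(["converter", "non-converter", "unlabeled"]))
                 for _ in range(K)]
        q = MemoryQueue(K, d)
        q.enqueue(unit_vectors(rng, K, d).astype(np.float32), q_lab)
        anchors = unit_vectors(rng, B, d)
        positives = unit_vectors(rng, B, d)
        cfg = ContrastConfig(temperature=tau, alpha=alpha,
                             label_loss_form=form)
        loss, br = smoco_batch_loss(anchors, positives, labels, q, cfg)
        qe, _ = q.entries()
        expected = 0.0
        for i in range(B):
            expected += oracle_instance_loss(anchors[i], positives[i], qe, tau)
            if labels[i] != "unlabeled":
                expected += alpha * oracle_label_loss(
                    anchors[i], positives[i], qe, q_lab, labels[i], tau, form)
        expected /= B
        assert loss.item() == pytest.approx(expected, abs=1e-5)
        assert br["total"] == pytest.approx(expected, abs=1e-5)


def test_batch_loss_alpha_zero_equals_mean_instance(rng):
    q = MemoryQueue(8, 4)
    q.enqueue(unit_vectors(rng, 8, 4).astype(np.float32),
              ["converter"] * 4 + ["non-converter"] * 4)
    anchors = unit_vectors(rng, 3, 4)
    positives = unit_vectors(rng, 3, 4)
    labels = ["converter", "non-converter", "unlabeled"]
    cfg = ContrastConfig(alpha=0.0)
    loss, br = smoco_batch_loss(anchors, positives, labels, q, cfg)
    qe, _ = q.entries()
    inst = np.mean([oracle_instance_loss(anchors[i], positives[i], qe, 0.2)
                    for i in range(3)])
    assert loss.item() == pytest.approx(inst, abs=1e-6)


def test_batch_loss_all_unlabeled_label_term_zero(rng):
    q = MemoryQueue(8, 4)
    q.enqueue(unit_vectors(rng, 8, 4).astype(np.float32), ["converter"] * 8)
    anchors = unit_vectors(rng, 4, 4)
    positives = unit_vectors(rng, 4, 4)
    for alpha in (0.5, 1.0, 5.0):
        _, br = smoco_batch_loss(anchors, positives, ["unlabeled"] * 4, q,
                                 ContrastConfig(alpha=alpha))
        assert br["label"] == 0.0


def test_batch_loss_gradient_matches_finite_differences(rng):
    """Gradients through the batched loss (the training path) agree with
    central finite differences."""
    d, K, B = 4, 6, 2
    q = MemoryQueue(K, d)
    q.enqueue(unit_vectors(rng, K, d).astype(np.float32),
              ["converter", "non-converter", "unlabeled"] * 2)
    a0 = unit_vectors(rng, B, d)
    pos = unit_vectors(rng, B, d)
    labels = ["converter", "non-converter"]
    cfg = ContrastConfig(alpha=1.3)
    t = Tensor(a0, requires_grad=True)
    loss, _ = smoco_batch_loss(t, pos, labels, q, cfg)
    loss.backward()
    eps = 1e-6
    for i in range(B):
        for j in range(d):
            ap = a0.copy(); ap[i, j] += eps
            am = a0.copy(); am[i, j] -= eps
            lp, _ = smoco_batch_loss(ap, pos, labels, q, cfg)
            lm, _ = smoco_batch_loss(am, pos, labels, q, cfg)
            num = (lp.item() - lm.item()) / (2 * eps)
            assert t.grad[i, j] == pytest.approx(num, abs=1e-5)


def test_losses_finite_for_extreme_temperature(rng):
    """Log-sum-exp stability: finite losses at tau = 0.01 for any
    unit-norm inputs."""
    q = MemoryQueue(16, 8)
    q.enqueue(unit_vectors(rng, 16, 8).astype(np.float32),
              ["converter", "non-converter"] * 8)
    anchors = unit_vectors(rng, 4, 8)
    positives = unit_vectors(rng, 4, 8)
    labels = ["converter", "non-converter", "converter", "non-converter"]
    for form in ("mean-of-logs", "log-of-mean"):
        cfg = ContrastConfig(temperature=0.01, label_loss_form=form)
        loss, br = smoco_batch_loss(anchors, positives, labels, q, cfg)
        assert np.isfinite(loss.item())
        assert all(np.isfinite(v) for v in br.values())


# -- EMA -----------------------------------------------------------------------

def test_ema_basic_arithmetic():
    assert ema_update(1.0, 0.0, 0.95) == pytest.approx(0.05)
    x = np.array([2.0, 4.0])
    out = ema_update(x, x.copy(), 0.9)
    np.testing.assert_allclose(out, x)  # fixed point


def test_ema_geometric_convergence():
    theta = np.array([1.0])
    phi = np.array([0.0])
    m = 0.95
    for n in (1, 5, 20):
        phi_n = np.array([0.0])
        for _ in range(n):
            ema_update(theta, phi_n, m)
        assert abs(phi_n[0] - 1.0) == pytest.approx(m ** n, rel=1e-10)


def test_ema_errors():
    with pytest.raises(ValueError):
        ema_update(np.ones(2), np.ones(3), 0.9)
    with pytest.raises(ValueError):
        ema_update(np.ones(2), np.ones(2), 1.0)


def test_contrast_config_validation():
    with pytest.raises(ValueError):
        ContrastConfig(temperature=0.0)
    with pytest.raises(ValueError):
        ContrastConfig(alpha=-1.0)
    with pytest.raises(ValueError):
        ContrastConfig(label_loss_form="sum")
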