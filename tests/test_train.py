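"""Training loops: schedule, determinism, key-network isolation,
checkpointing, rebalancing."""

import numpy as np
import pytest

from smoco.augment import AugmentationPolicy
from smoco.contrastive import ContrastConfig, MemoryQueue
from smoco.encoder import EncoderSpec, build_networks
from smoco.phantom import PhantomConfig, generate_cohort
from smoco.train import (OptimizerConfig, PretrainRun, cosine_lr, finetune,
                         load_checkpoint, supervised_baseline)


def _mini_run(seed=0, epochs=1, alpha=1.0, n=12, batch=6, grid=12,
              policy=None):
    cfg = PhantomConfig(grid_size=grid, n_converter=n // 3,
                        n_nonconverter=n // 3, n_unlabeled=n - 2 * (n // 3),
                        effect_size=2.0, noise_sd=0.3, seed=seed)
    cohort = generate_cohort(cfg)
    spec = EncoderSpec.reduced(projection_dim=8)
    pair = build_networks(spec, seed=seed)
    queue = MemoryQueue(32, 8, prefill=True, rng=np.random.default_rng(seed))
    return PretrainRun(cohort.samples, pair, queue,
                       ContrastConfig(alpha=alpha, queue_size=32),
                       OptimizerConfig(epochs=epochs, batch_size=batch),
                       policy=policy, seed=seed)


def test_cosine_lr_endpoints_and_errors():
    assert cosine_lr(0, 100, 1e-4) == pytest.approx(1e-4)
    assert cosine_lr(50, 100, 1e-4) == pytest.approx(5e-5)
    assert cosine_lr(100, 100, 1e-4) == pytest.approx(0.0, abs=1e-20)
    with pytest.raises(ValueError):
        cosine_lr(0, 0, 1e-4)
    with pytest.raises(ValueError):
        cosine_lr(5, 4, 1e-4)


def test_lr_trace_matches_schedule_exactly():
    run = _mini_run(epochs=2)
    lrs = [run.run_step()["lr"] for _ in range(2 * run.steps_per_epoch)]
    expected = [cosine_lr(s, run.total_steps, 1e-4)
                for s in range(len(lrs))]
    assert lrs == expected


def test_pretrain_same_seed_identical_history():
    h1 = [_mini_run(seed=3).run_epoch() for _ in range(1)]
    h2 = [_mini_run(seed=3).run_epoch() for _ in range(1)]
    assert h1 == h2  # bit-identical floats


def test_no_gradient_reaches_key_network():
    """A gradient step (without the EMA update) leaves every key
    parameter bit-identical."""
    run = _mini_run()
    before = {n: p.data.copy()
              for n, p in run.networks.key.named_parameters()}
    # one manual step: loss/backward/optimizer, deliberately skipping EMA
    batch = run._next_batch()
    from smoco.contrastive import smoco_batch_loss
    from smoco.nn.autodiff import Tensor, no_grad
    from smoco.train import _stack_views
    xa, xp = _stack_views(batch, run.policy)
    za = run.networks.query(Tensor(xa))
    with no_grad():
        zp = run.networks.key(Tensor(xp)).data
    loss, _ = smoco_batch_loss(za, zp, [s.label for s in batch], run.queue,
                               run.contrast)
    loss.backward()
    run.opt.lr = 1e-3
    run.opt.step()
    for n, p in run.networks.key.named_parameters():
        np.testing.assert_array_equal(p.data, before[n])
    # and the query network did move
    assert any(not np.array_equal(p.data, q.data) for (_, p), (_, q) in
               zip(run.networks.query.named_parameters(),
                   build_networks(run.networks.spec, 0).query
                   .named_parameters()))


def test_ema_moves_key_toward_query():
    run = _mini_run(epochs=1)
    run.run_step()
    diffs = [np.abs(p.data - q.data).max() for (_, p), (_, q) in
             zip(run.networks.query.named_parameters(),
                 run.networks.key.named_parameters())]
    assert max(diffs) > 0  # EMA applied but not a full copy


def test_checkpoint_roundtrip_continues_bit_identically(tmp_path):
    run_a = _mini_run(seed=9, epochs=2)
    for _ in range(3):
        run_a.run_step()
    run_a.save(tmp_path / "ck.npz")
    run_b = load_checkpoint(tmp_path / "ck.npz", run_a.samples)
    sa = run_a.run_step()
    sb = run_b.run_step()
    assert sa == sb
    for (n, p), (_, q) in zip(run_a.networks.query.named_parameters(),
                              run_b.networks.query.named_parameters()):
        np.testing.assert_array_equal(p.data, q.data, err_msg=n)
    qa, qb = run_a.queue.entries(), run_b.queue.entries()
    np.testing.assert_array_equal(qa[0], qb[0])
    np.testing.assert_array_equal(qa[1], qb[1])


def test_pretrain_loss_decreases_on_frozen_batch():
    """50 gradient steps on one fixed batch against one fixed queue
    snapshot reduce the combined contrastive loss."""
    from smoco.contrastive import smoco_batch_loss
    from smoco.nn.autodiff import Tensor, no_grad
    from smoco.nn.optim import AdamW
    from smoco.train import _stack_views
    run = _mini_run(n=8, batch=8, epochs=1,
                    policy=AugmentationPolicy.identity())
    batch = run._next_batch()
    labels = [s.label for s in batch]
    xa, xp = _stack_views(batch, run.policy)
    with no_grad():
        zp = run.networks.key(Tensor(xp)).data
    opt = AdamW(run.networks.query.parameters(), lr=1e-3)
    losses = []
    for _ in range(50):
        za = run.networks.query(Tensor(xa))
        loss, _ = smoco_batch_loss(za, zp, labels, run.queue, run.contrast)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    assert losses[-1] < losses[0]


def test_pretrain_validation_errors():
    with pytest.raises(ValueError):
        _mini_run(n=3, batch=6)  # batch larger than dataset
    cfg = PhantomConfig(grid_size=12, n_converter=1, n_nonconverter=1,
                        n_unlabeled=0, seed=0)
    cohort = generate_cohort(cfg)
    spec = EncoderSpec.reduced(projection_dim=8)
    with pytest.raises(ValueError):
        PretrainRun([], build_networks(spec, 0), MemoryQueue(8, 8),
                    ContrastConfig(), OptimizerConfig())


def _labeled_cohort(delta=3.0, sigma=0.1, n_each=8, grid=12, seed=1):
    cfg = PhantomConfig(grid_size=grid, n_converter=n_each,
                        n_nonconverter=n_each, n_unlabeled=0,
                        effect_size=delta, noise_sd=sigma, seed=seed)
    return [s for s in generate_cohort(cfg).samples]


def test_finetune_reduces_training_loss():
    samples = _labeled_cohort()
    pair = build_networks(EncoderSpec.reduced(projection_dim=8), seed=2)
    clf, hist = finetune(pair.query, samples,
                         OptimizerConfig(epochs=5, batch_size=8), seed=2)
    assert hist[-1]["loss"] < hist[0]["loss"]
    assert len(hist) == 5


def test_finetune_default_is_ten_epochs():
    samples = _labeled_cohort(n_each=4, grid=8)
    pair = build_networks(EncoderSpec.reduced(projection_dim=8), seed=0)
    _, hist = finetune(pair.query, samples,
                       OptimizerConfig(epochs=10, batch_size=4), seed=0)
    assert len(hist) == 10
    import inspect

    from smoco import train as tr
    src = inspect.getsource(tr.finetune)
    assert "epochs=10" in src  # default protocol


def test_minibatch_rebalancing_is_exactly_half(monkeypatch):
    """Every rebalanced mini-batch holds 50% converters regardless of the
    4:12 prevalence (verified over 200 recorded batches)."""
    from smoco.nn import autodiff as ad
    cfg = PhantomConfig(grid_size=8, n_converter=4, n_nonconverter=12,
                        n_unlabeled=0, effect_size=1.0, noise_sd=0.3, seed=3)
    samples = generate_cohort(cfg).samples
    recorded = []
    orig = ad.cross_entropy_logits

    def spy(logits, targets):
        recorded.append(targets.copy())
        return orig(logits, targets)

    monkeypatch.setattr(ad, "cross_entropy_logits", spy)
    pair = build_networks(EncoderSpec.reduced(projection_dim=8), seed=3)
    finetune(pair.query, samples, OptimizerConfig(epochs=34, batch_size=4),
             seed=3)
    assert len(recorded) >= 200
    fracs = [t.mean() for t in recorded]
    assert np.allclose(fracs, 0.5)


def test_classifier_training_rejects_bad_sets():
    samples = _labeled_cohort(n_each=4, grid=8)
    pair = build_networks(EncoderSpec.reduced(projection_dim=8), seed=0)
    only_one = [s for s in samples if s.label == "converter"]
    with pytest.raises(ValueError):
        finetune(pair.query, only_one, OptimizerConfig(epochs=1, batch_size=4))
    unl = generate_cohort(PhantomConfig(grid_size=8, n_converter=1,
                                        n_nonconverter=1, n_unlabeled=2,
                                        seed=0)).samples
    with pytest.raises(ValueError):
        supervised_baseline(unl, EncoderSpec.reduced(projection_dim=8),
                            OptimizerConfig(epochs=1, batch_size=2))


def test_supervised_baseline_trains_from_scratch():
    samples = _labeled_cohort(n_each=6, grid=8, seed=4)
    clf, hist = supervised_baseline(
        samples, EncoderSpec.reduced(projection_dim=8),
        OptimizerConfig(epochs=12, batch_size=4, learning_rate=5e-4), seed=4)
    assert len(hist) == 12
    assert np.mean([h["loss"] for h in hist[-3:]]) < hist[0]["loss"]
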