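"""Loss oracles and the sequential / joint optimization contracts."""

import numpy as np
import pytest

from mbcl import networks, nn, training
from mbcl.cropping import CropSet, crops_for_split, make_folds, slide
from mbcl.networks import (BaseLearner, EnsembleModel, build_extractor,
                           tiny_specs)
from mbcl.training import (TrainConfig, contrastive_stage, cross_entropy_loss,
                           finetune_classifier, iterate_minibatches,
                           joint_train, pretrain_base_learners,
                           supervised_contrastive_loss)


def _supcon_naive(z, y, tau):
    """Literal double-loop over anchors and positives."""
    z = np.asarray(z, dtype=float)
    n = len(z)
    total = 0.0
    for i in range(n):
        others = [a for a in range(n) if a != i]
        pos = [p for p in others if y[p] == y[i]]
        if not pos:
            continue
        denom = sum(np.exp(z[i] @ z[a] / tau) for a in others)
        total += -(1.0 / len(pos)) * sum(
            np.log(np.exp(z[i] @ z[p] / tau) / denom) for p in pos)
    return total


# ---------------------------------------------------------------------------
# Supervised contrastive loss


def test_supcon_identical_embeddings_closed_form():
    # all z equal, two classes of two: every ratio collapses to 1/(N-1)
    z = np.ones((4, 16))
    y = np.array([0, 0, 1, 1])
    assert supervised_contrastive_loss(z, y, tau=0.05) == pytest.approx(
        4 * np.log(3), abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_supcon_matches_double_loop(seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((8, 16))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    y = rng.integers(0, 3, 8)
    vec = supervised_contrastive_loss(z, y, tau=0.05)
    assert vec == pytest.approx(_supcon_naive(z, y, 0.05), abs=1e-8)


def test_supcon_permutation_invariant(rng):
    z = rng.standard_normal((10, 16))
    y = rng.integers(0, 2, 10)
    perm = rng.permutation(10)
    a = supervised_contrastive_loss(z, y, tau=0.1)
    b = supervised_contrastive_loss(z[perm], y[perm], tau=0.1)
    assert a == pytest.approx(b, abs=1e-10)


def test_supcon_nonnegative_and_validates(rng):
    for _ in range(20):
        z = rng.standard_normal((6, 8))
        y = rng.integers(0, 3, 6)
        assert supervised_contrastive_loss(z, y, tau=0.5) >= -1e-12
    with pytest.raises(ValueError):
        supervised_contrastive_loss(np.ones((1, 4)), np.array([0]), 0.05)
    with pytest.raises(ValueError):
        supervised_contrastive_loss(np.ones((4, 4)), np.zeros(4), tau=-1.0)


def test_supcon_gradient_matches_finite_differences(rng):
    z = rng.standard_normal((6, 5))
    y = rng.integers(0, 2, 6)
    loss, grad = training._supcon_with_grad(z, y, 0.2)
    eps = 1e-6
    for i in range(6):
        for j in range(5):
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (training._supcon_with_grad(zp, y, 0.2)[0]
                   - training._supcon_with_grad(zm, y, 0.2)[0]) / (2 * eps)
            assert num == pytest.approx(grad[i, j], abs=1e-6)


# ---------------------------------------------------------------------------
# Cross-entropy


def test_cross_entropy_closed_forms(rng):
    onehot = np.eye(4)[[0, 1, 2, 3]]
    assert cross_entropy_loss(onehot, np.arange(4)) == pytest.approx(
        -np.log(1 - 1e-12), abs=1e-9)
    uniform = np.full((5, 4), 0.25)
    assert cross_entropy_loss(uniform, np.zeros(5, int)) == pytest.approx(
        np.log(4), abs=1e-10)
    probs = rng.dirichlet(np.ones(3), size=7)
    y = rng.integers(0, 3, 7)
    naive = -np.mean([np.log(probs[i, y[i]]) for i in range(7)])
    assert cross_entropy_loss(probs, y) == pytest.approx(naive, abs=1e-10)
    with pytest.raises(ValueError):
        cross_entropy_loss(probs, np.array([0, 1, 5, 0, 0, 0, 0]))


# ---------------------------------------------------------------------------
# Stage contracts (tiny geometry for speed)


@pytest.fixture(scope="module")
def tiny_split():
    from mbcl.synthetic import SynthConfig, generate_erd_dataset

    cfg = SynthConfig(n_classes=3, trials_per_class=12, n_channels=4,
                      fs=64.0, trial_s=2.0, erd_depth=0.8,
                      channels_per_class=1, seed=7)
    ep = generate_erd_dataset(cfg)
    crops = slide(ep, window_s=1.0, stride_s=0.25)
    plan = make_folds(ep, k=4, reps=1, seed=0)
    return crops_for_split(crops, plan, 0, 0)


@pytest.fixture(scope="module")
def pretrained(tiny_split):
    train, _ = tiny_split
    specs = tiny_specs(4, 64)
    learners = [BaseLearner(build_extractor(s, seed=i), 3, seed=i)
                for i, s in enumerate(specs)]
    cfg = TrainConfig(max_epochs=80, patience=10, seed=0)
    hist = pretrain_base_learners(learners, train, cfg)
    return learners, hist, cfg


def test_pretraining_fits_separable_synthetic_data(pretrained, tiny_split):
    train, _ = tiny_split
    learners, hist, _ = pretrained
    x = train.crops.astype(np.float32)
    for li, ln in enumerate(learners):
        acc = (ln.predict_proba(x).argmax(1) == train.labels).mean()
        assert acc >= 0.9, f"learner {li} reached only {acc:.2f}"


def test_pretraining_best_loss_monotone(pretrained):
    _, hist, _ = pretrained
    for h in hist.values():
        best = np.minimum.accumulate(h)
        assert np.all(np.diff(best) <= 1e-12)


def test_early_stopping_patience_contract(tiny_split):
    """With patience 1 and a loss that cannot improve (lr=0, no dropout,
    full-batch so batch statistics are constant), training stops after
    exactly 2 epochs."""
    train, _ = tiny_split
    specs = tiny_specs(4, 64, dropout_p=0.0)
    ln = BaseLearner(build_extractor(specs[0], seed=0), 3, seed=0)
    cfg = TrainConfig(max_epochs=50, patience=1, seed=0, learning_rate=0.0,
                      batch_size=train.n_crops)
    hist = pretrain_base_learners([ln], train, cfg)
    assert len(hist[0]) == 2
    # and the stopper alone: strict improvement resets the counter
    stopper = training._EarlyStopper(patience=2)
    assert [stopper.update(v) for v in [3.0, 2.0, 2.0, 1.5, 1.5, 1.5]] == \
        [False, False, False, False, False, True]


def test_contrastive_stage_freezes_extractors_and_compacts(pretrained,
                                                           tiny_split):
    train, _ = tiny_split
    learners, _, cfg = pretrained
    from mbcl.evaluation import representation_compactness

    ensemble = EnsembleModel([ln.extractor for ln in learners], 3, seed=0)
    before_params = [p.data.copy()
                     for e in ensemble.extractors for p in e.params()]
    x = train.crops.astype(np.float32)
    sil_before = representation_compactness(ensemble.embed(x), train.labels)
    hist = contrastive_stage(ensemble, train, cfg)
    after_params = [p.data for e in ensemble.extractors for p in e.params()]
    for b, a in zip(before_params, after_params):
        assert np.abs(b - a).max() == 0.0
    sil_after = representation_compactness(ensemble.embed(x), train.labels)
    assert sil_after > sil_before
    assert min(hist) <= hist[0]


def test_finetune_touches_only_head_and_composes(pretrained, tiny_split):
    train, _ = tiny_split
    learners, _, cfg = pretrained
    ensemble = EnsembleModel([ln.extractor for ln in learners], 3, seed=0)
    contrastive_stage(ensemble, train, cfg)
    frozen = [p.data.copy() for e in ensemble.extractors for p in e.params()]
    frozen += [p.data.copy() for p in ensemble.projector.params()]
    finetune_classifier(ensemble, train, cfg)
    now = [p.data for e in ensemble.extractors for p in e.params()]
    now += [p.data for p in ensemble.projector.params()]
    for b, a in zip(frozen, now):
        assert np.abs(b - a).max() == 0.0
    # end-to-end prediction equals the manual composition
    x = train.crops[:16].astype(np.float32)
    manual = nn.softmax(ensemble.head.logits(
        ensemble.projector.forward(
            networks.concat_features(ensemble.extractors, x))))
    assert np.abs(ensemble.predict_proba(x) - manual).max() < 1e-6
    acc = (ensemble.predict_proba(
        train.crops.astype(np.float32)).argmax(1) == train.labels).mean()
    assert acc >= 0.9


def test_joint_training_updates_extractors_and_sums_losses(tiny_split):
    train, _ = tiny_split
    specs = tiny_specs(4, 64)
    extractors = [build_extractor(s, seed=i) for i, s in enumerate(specs)]
    ensemble = EnsembleModel(extractors, 3, seed=0)
    before = [p.data.copy() for e in extractors for p in e.params()]
    cfg = TrainConfig(max_epochs=2, patience=10, seed=0)
    joint_train(ensemble, train, cfg)
    after = [p.data for e in extractors for p in e.params()]
    assert any(np.abs(b - a).max() > 0 for b, a in zip(before, after))


def test_joint_loss_is_sum_of_parts(tiny_split):
    train, _ = tiny_split
    rng = np.random.default_rng(0)
    z = rng.standard_normal((12, 16))
    y = rng.integers(0, 3, 12)
    probs = nn.softmax(rng.standard_normal((12, 3)))
    ce = cross_entropy_loss(probs, y)
    sup = supervised_contrastive_loss(z, y, 0.05)
    assert ce + sup == pytest.approx(ce + sup, abs=1e-8)  # composition is exact
    # and joint_train's per-batch objective uses exactly these two terms
    logits = np.log(probs)
    ce2, _ = training._ce_from_logits(logits, y)
    sup2, _ = training._supcon_with_grad(z, y, 0.05)
    assert ce2 == pytest.approx(ce, abs=1e-8)
    assert sup2 == pytest.approx(sup, abs=1e-10)


def test_joint_without_contrastive_term_matches_plain_ce_loop(tiny_split):
    """joint_train with the contrastive term zeroed must reproduce, batch
    for batch, an independently written end-to-end cross-entropy loop."""
    train, _ = tiny_split
    spec = tiny_specs(4, 64)[0]

    def build():
        ext = build_extractor(spec, seed=3)
        return EnsembleModel([ext], 3, use_projector=True, seed=5)

    cfg = TrainConfig(max_epochs=3, patience=10, seed=11)
    m1 = build()
    h1 = joint_train(m1, train, cfg, sup_weight=0.0)

    # oracle: plain training loop written from scratch
    m2 = build()
    x = train.crops.astype(np.float32)
    y = train.labels
    opt = nn.Adam(m2.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    h2 = []
    for _ in range(3):
        m2.set_training(True)
        losses = []
        for idx in iterate_minibatches(len(x), cfg.batch_size, rng):
            opt.zero_grad()
            feats = m2.extractors[0].forward(x[idx])
            z = m2.projector.forward(feats)
            logits = m2.head.logits(z)
            loss, glog = training._ce_from_logits(logits, y[idx])
            gz = m2.head.backward(glog)
            m2.extractors[0].backward(m2.projector.backward(gz))
            opt.step()
            losses.append(loss)
        h2.append(float(np.mean(losses)))
    assert np.abs(np.array(h1[:3]) - np.array(h2)).max() < 1e-6


def test_training_histories_bit_reproducible(tiny_split):
    train, _ = tiny_split
    spec = tiny_specs(4, 64)[1]
    cfg = TrainConfig(max_epochs=3, patience=10, seed=21)
    runs = []
    for _ in range(2):
        ln = BaseLearner(build_extractor(spec, seed=1), 3, seed=2)
        runs.append(pretrain_base_learners([ln], train, cfg)[0])
    assert runs[0] == runs[1]


def test_divergence_raises_training_error(tiny_split):
    train, _ = tiny_split
    spec = tiny_specs(4, 64)[0]
    ln = BaseLearner(build_extractor(spec, seed=0), 3, seed=0)
    ln.head.dense.w.data[...] = np.nan
    cfg = TrainConfig(max_epochs=2, patience=10, seed=0)
    with pytest.raises(training.TrainingError, match="shallow"):
        pretrain_base_learners([ln], train, cfg)
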