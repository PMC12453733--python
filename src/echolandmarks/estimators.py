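"""Training protocol: meta-train on 3 views, fine-tune k-shot on the 4th.

The trainable objects follow the scikit-learn estimator conventions
(``fit`` / ``predict`` / ``get_params`` / fitted attributes with a trailing
underscore):

``MetaLandmarkDetector``
    fit() meta-trains one of the four learners episodically on the three
    views other than ``heldout_view`` (3-way), selecting the checkpoint
    with the highest validation mean pixel accuracy; adapt() runs the
    test-time inner loop on a k-shot support set from the held-out view;
    predict() decodes landmark points for new images.
``BaselineLandmarkDetector``
    plain supervised heatmap regression (MSE + Adam) on one view, the
    100-shot reference the few-shot learners are compared against.

Module-level ``meta_train`` / ``fine_tune`` / ``train_baseline`` /
``evaluate`` are thin functional wrappers over these estimators.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .backbone import BackboneConfig, HeatmapNet, ModelParams
from .heatmaps import augment_rotation, decode_points, encode_heatmaps
from .meta import (InnerConfig, MetaState, create_meta_state, inner_adapt,
                   meta_iteration)
from .metrics import (MetricReport, SASParams, build_report, image_metrics,
                      mean_pixel_accuracy)
from .phantoms import TaskEpisode, default_view_specs, sample_episode

__all__ = [
    "MetaLandmarkDetector", "BaselineLandmarkDetector", "RunRecord",
    "meta_train", "fine_tune", "train_baseline", "evaluate",
    "samples_to_batch",
]


def samples_to_batch(samples, sigma: float):
    """Stack samples into (images, target_heatmaps) network batches."""
    xs = np.stack([np.asarray(s.image, dtype=np.float32) for s in samples])
    ys = np.stack([
        encode_heatmaps(s.landmarks, s.image.shape, sigma) for s in samples])
    return xs[:, None], ys


@dataclass
class RunRecord:
    """Log of one training run: losses, validation curve, selection."""

    seed: int
    config: dict = field(default_factory=dict)
    query_losses: list = field(default_factory=list)      # per iteration
    sampled_views: list = field(default_factory=list)     # per iteration
    validation: list = field(default_factory=list)        # (iter, pix acc)
    selected_iteration: int = -1
    selected_accuracy: float = -np.inf


class _DetectorMixin:
    """predict/evaluate shared by the meta and baseline detectors."""

    def _net(self) -> HeatmapNet:
        return HeatmapNet(BackboneConfig(
            width=self.width, image_size=self.image_size))

    def _predict_params(self) -> ModelParams:
        raise NotImplementedError

    def predict(self, images) -> np.ndarray:
        """Decode landmark points, shape (n_images, 4, 2) in (row, col)."""
        net = self._net()
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        hm = net.forward(self._predict_params(), x[:, None])
        return np.stack([decode_points(h) for h in hm])

    def predict_heatmaps(self, images) -> np.ndarray:
        net = self._net()
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        return net.forward(self._predict_params(), x[:, None])

    def evaluate(self, samples, sdr_threshold: float = 5.0,
                 sas_params: SASParams = SASParams(),
                 bin_threshold: float = 0.5) -> MetricReport:
        """Per-image metric report (MDE/SDR/MAE/SAS/Dice/pixel accuracy)."""
        if not samples:
            raise ValueError("empty test set")
        return evaluate(self._net(), self._predict_params(), samples,
                        sigma=self.sigma, sdr_threshold=sdr_threshold,
                        sas_params=sas_params, bin_threshold=bin_threshold)


class MetaLandmarkDetector(_DetectorMixin, BaseEstimator):
    """Few-shot landmark detector meta-trained across echo views.

    Parameters follow the study protocol: inner rate 0.03 with 10
    adaptation steps during meta-training, rate 0.05 with 100 steps at
    test time, Adam with rate 5e-3 for the meta-update, MSE heatmap loss
    with sigma = 7.  ``learner`` selects the update rule: 'fomaml',
    'meta_sgd', 'meta_curvature' or 'anil'.
    """

    def __init__(self, learner: str = "fomaml", heldout_view: str = "PSAX",
                 k_shot: int = 5, n_query: int = 3,
                 meta_iterations: int = 200, val_every: int = 50,
                 inner_lr: float = 0.03, inner_steps: int = 10,
                 test_lr: float = 0.05, test_steps: int = 100,
                 outer_lr: float = 5e-3, outer_optimizer: str = "adam",
                 sigma: float = 7.0, image_size: int = 64, width: int = 4,
                 speckle_level: float = 0.35, augment: bool = False,
                 random_state: int = 0):
        self.learner = learner
        self.heldout_view = heldout_view
        self.k_shot = k_shot
        self.n_query = n_query
        self.meta_iterations = meta_iterations
        self.val_every = val_every
        self.inner_lr = inner_lr
        self.inner_steps = inner_steps
        self.test_lr = test_lr
        self.test_steps = test_steps
        self.outer_lr = outer_lr
        self.outer_optimizer = outer_optimizer
        self.sigma = sigma
        self.image_size = image_size
        self.width = width
        self.speckle_level = speckle_level
        self.augment = augment
        self.random_state = random_state

    # -- protocol -----------------------------------------------------------

    def _train_cfg(self) -> InnerConfig:
        return InnerConfig(inner_lr=self.inner_lr, n_steps=self.inner_steps)

    def _test_cfg(self) -> InnerConfig:
        return InnerConfig(inner_lr=self.test_lr, n_steps=self.test_steps)

    def _episode_batches(self, episode: TaskEpisode, aug_seed=None):
        support, query = list(episode.support), list(episode.query)
        if self.augment and aug_seed is not None:
            support = [augment_rotation(s, rng_seed=int(aug_seed) + i)
                       for i, s in enumerate(support)]
        return (samples_to_batch(support, self.sigma),
                samples_to_batch(query, self.sigma))

    def fit(self, views=None, y=None):
        """Meta-train on every view except ``heldout_view``.

        views: mapping view_id -> ViewSpec (defaults to the built-in
        phantom families).  Episodes are sampled 3-way from the training
        views only; a held-out episode in a meta-train batch is a protocol
        violation and raises.
        """
        specs = views if views is not None else default_view_specs(
            self.image_size, self.speckle_level)
        if self.heldout_view not in specs and views is not None and \
                len(specs) < 3:
            raise ValueError("need at least 3 training views")
        train_specs = {v: s for v, s in specs.items()
                       if v != self.heldout_view}
        if len(train_specs) < 1:
            raise ValueError("no training views left after exclusion")
        self.view_specs_ = dict(specs)

        net = self._net()
        ss = np.random.SeedSequence(self.random_state)
        init_seed, ep_seed, val_seed, aug_seed = (
            int(s) & 0x7FFFFFFF for s in ss.generate_state(4))
        state = create_meta_state(
            net.init_params(init_seed), learner=self.learner,
            outer_lr=self.outer_lr, outer_optimizer=self.outer_optimizer,
            inner_lr_init=self.inner_lr)
        record = RunRecord(seed=self.random_state, config=self.get_params())
        cfg = self._train_cfg()
        ep_rng = np.random.default_rng(ep_seed)
        val_rng = np.random.default_rng(val_seed)
        best_state = state.copy()
        best_iter, best_acc = -1, -np.inf

        for it in range(self.meta_iterations):
            batch = []
            views_this_iter = []
            for view_id, spec in train_specs.items():
                ep = sample_episode(spec, self.k_shot, self.n_query,
                                    int(ep_rng.integers(2**31)))
                if ep.view_id == self.heldout_view:
                    raise RuntimeError(
                        "protocol violation: held-out view sampled during "
                        "meta-training")
                views_this_iter.append(ep.view_id)
                batch.append(self._episode_batches(
                    ep, aug_seed=aug_seed + it if self.augment else None))
            state, q_losses = meta_iteration(net, state, batch, cfg)
            record.sampled_views.append(views_this_iter)
            record.query_losses.append([float(v) for v in q_losses])
            if self.val_every and (it + 1) % self.val_every == 0:
                acc = self._validation_accuracy(net, state, train_specs,
                                                val_rng, cfg)
                record.validation.append((it, float(acc)))
                if acc > best_acc:
                    best_acc, best_iter = acc, it
                    best_state = state.copy()
        if best_iter < 0:  # no validation points (e.g. val_every=0)
            best_state, best_iter, best_acc = state.copy(), \
                self.meta_iterations - 1, np.nan
        record.selected_iteration = best_iter
        record.selected_accuracy = float(best_acc)
        self.meta_state_ = state
        self.best_state_ = best_state
        self.record_ = record
        return self

    def _validation_accuracy(self, net, state, train_specs, val_rng, cfg):
        """Adapt on a fresh validation episode per view, then measure mean
        pixel accuracy of the predicted heatmaps on its query set."""
        accs = []
        for spec in train_specs.values():
            ep = sample_episode(spec, self.k_shot, self.n_query,
                                int(val_rng.integers(2**31)))
            sup, (xq, yq) = self._episode_batches(ep)
            adapted = inner_adapt(net, state, sup, cfg).params
            pred = net.forward(adapted, xq)
            accs.extend(mean_pixel_accuracy(p, t) for p, t in zip(pred, yq))
        return float(np.mean(accs))

    # -- adaptation and inference ------------------------------------------

    def adapt(self, episode_or_samples, use_best: bool = True):
        """Test-time fine-tuning: inner loop only, no outer update."""
        if isinstance(episode_or_samples, TaskEpisode):
            support = list(episode_or_samples.support)
        else:
            support = list(episode_or_samples)
        if not support:
            raise ValueError("empty support set")
        state = self.best_state_ if use_best else self.meta_state_
        batch = samples_to_batch(support, self.sigma)
        self.adapted_params_ = inner_adapt(
            self._net(), state, batch, self._test_cfg()).params
        return self

    def _predict_params(self) -> ModelParams:
        if hasattr(self, "adapted_params_"):
            return self.adapted_params_
        return self.best_state_.theta


class BaselineLandmarkDetector(_DetectorMixin, BaseEstimator):
    """Plain supervised heatmap regressor (the 100-shot reference model).

    MSE loss, Adam with rate 5e-3, minibatch training on a single view;
    the kept checkpoint is the epoch with the highest validation mean
    pixel accuracy.
    """

    def __init__(self, epochs: int = 50, batch_size: int = 16,
                 lr: float = 5e-3, val_fraction: float = 0.15,
                 sigma: float = 7.0, image_size: int = 64, width: int = 4,
                 random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.sigma = sigma
        self.image_size = image_size
        self.width = width
        self.random_state = random_state

    def fit(self, samples, y=None):
        if not samples:
            raise ValueError("no training samples")
        net = self._net()
        ss = np.random.SeedSequence(self.random_state)
        init_seed, shuf_seed = (int(s) & 0x7FFFFFFF
                                for s in ss.generate_state(2))
        params = net.init_params(init_seed)
        rng = np.random.default_rng(shuf_seed)
        n_val = max(1, int(round(self.val_fraction * len(samples))))
        order = rng.permutation(len(samples))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            raise ValueError("too few samples for the validation split")
        train = [samples[i] for i in train_idx]
        xv, yv = samples_to_batch([samples[i] for i in val_idx], self.sigma)

        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(val) for k, val in params.items()}
        t = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        record = RunRecord(seed=self.random_state, config=self.get_params())
        best_params, best_acc, best_epoch = params.copy(), -np.inf, -1
        for epoch in range(self.epochs):
            order = rng.permutation(len(train))
            losses = []
            for start in range(0, len(train), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = samples_to_batch([train[i] for i in idx], self.sigma)
                loss, grads = net.loss_and_grad(params, (xb, yb))
                losses.append(loss)
                t += 1
                upd = {}
                for k, g in grads.items():
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    mh = m[k] / (1 - b1**t)
                    vh = v[k] / (1 - b2**t)
                    upd[k] = params[k] - self.lr * mh / (np.sqrt(vh) + eps)
                params = params.replace(upd)
            pred = net.forward(params, xv)
            acc = float(np.mean([mean_pixel_accuracy(p, tgt)
                                 for p, tgt in zip(pred, yv)]))
            record.query_losses.append([float(np.mean(losses))])
            record.validation.append((epoch, acc))
            if acc > best_acc:
                best_acc, best_epoch = acc, epoch
                best_params = params.copy()
        record.selected_iteration = best_epoch
        record.selected_accuracy = best_acc
        self.params_ = best_params
        self.final_params_ = params
        self.record_ = record
        return self

    def _predict_params(self) -> ModelParams:
        return self.params_


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def meta_train(**params) -> tuple[MetaState, RunRecord, MetaLandmarkDetector]:
    """Meta-train a detector; returns (meta state, run record, estimator)."""
    det = MetaLandmarkDetector(**params).fit()
    return det.best_state_, det.record_, det


def fine_tune(state: MetaState, episode: TaskEpisode, net: HeatmapNet,
              sigma: float = 7.0,
              cfg: InnerConfig | None = None) -> ModelParams:
    """Test-time adaptation: the inner loop only; ``state`` is untouched."""
    if not episode.support:
        raise ValueError("empty support set")
    cfg = cfg or InnerConfig(inner_lr=0.05, n_steps=100)
    batch = samples_to_batch(episode.support, sigma)
    return inner_adapt(net, state, batch, cfg).params


def train_baseline(samples, **params) -> tuple[ModelParams, RunRecord,
                                               BaselineLandmarkDetector]:
    det = BaselineLandmarkDetector(**params).fit(samples)
    return det.params_, det.record_, det


def evaluate(net: HeatmapNet, params: ModelParams, samples,
             sigma: float = 7.0, sdr_threshold: float = 5.0,
             sas_params: SASParams = SASParams(),
             bin_threshold: float = 0.5) -> MetricReport:
    """Decode points for each test sample and compute the full metric suite."""
    if not samples:
        raise ValueError("empty test set")
    rows = []
    for s in samples:
        x = np.asarray(s.image, dtype=np.float32)[None, None]
        hm = net.forward(params, x)[0]
        pred = decode_points(hm)
        ref_hm = encode_heatmaps(s.landmarks, s.image.shape, sigma)
        rows.append(image_metrics(
            pred, s.landmarks, view_id=s.view_id, pred_heatmaps=hm,
            ref_heatmaps=ref_hm, sdr_threshold=sdr_threshold,
            sas_params=sas_params, bin_threshold=bin_threshold))
    return build_report(rows, sdr_threshold=sdr_threshold,
                        sas_params=sas_params)
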