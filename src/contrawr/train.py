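"""Pretraining, probing and evaluation protocol.

The central object is :class:`ContraWR`, a scikit-learn style transformer:
``fit`` runs self-supervised contrastive pretraining on unlabeled epochs
(two augmented views per epoch, online/EMA-target dual networks, Gaussian
kernel triplet loss against the world representation) and ``transform``
maps epochs to frozen d-dimensional representations.  Evaluation follows
the standard protocol: freeze the encoder, fit a multinomial logistic
classifier on the labeled training split and report accuracy on the test
split (:func:`linear_probe`).  :class:`SupervisedStageClassifier` is the
fully supervised reference — the same encoder trained end-to-end from
scratch with a 2-layer classification head — and
:func:`untrained_baseline` supplies the randomly initialized encoder
control.  All splits are at the subject level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import nn
from .augment import AugmentationPolicy, make_views
from .contrastive import ContrastiveConfig, batch_loss_and_grad, ema_update
from .encoder import (
    EncoderSpec,
    build_encoder,
    build_projector,
    encode,
    spectrogram_input,
    stft_spectrogram,
)
from .epochs import EpochDataset

__all__ = [
    "ContraWR",
    "SupervisedStageClassifier",
    "SplitSpec",
    "split_subjects",
    "pretrain",
    "linear_probe",
    "fit_probe",
    "ProbeResult",
    "untrained_baseline",
    "label_fraction_sweep",
]


# -- subject-level splitting --------------------------------------------


@dataclass
class SplitSpec:
    """Disjoint subject-level assignment to pretrain/train/test."""

    pretrain: list[str] = field(default_factory=list)
    train: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups = [set(self.pretrain), set(self.train), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = groups[i] & groups[j]
                if overlap:
                    raise ValueError(f"subjects {sorted(overlap)} appear in two splits")


def split_subjects(
    subject_ids: list[str],
    pretrain_frac: float = 0.6,
    train_frac: float = 0.2,
    test_frac: float = 0.2,
    seed: int = 0,
) -> SplitSpec:
    """Randomly partition subjects into pretrain/train/test by proportion."""
    total = pretrain_frac + train_frac + test_frac
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {total}")
    ids = list(map(str, subject_ids))
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = max(1, round(test_frac * len(ids)))
    n_train = max(1, round(train_frac * len(ids)))
    if n_test + n_train >= len(ids):
        raise ValueError("split leaves no subjects for the pretrain set")
    return SplitSpec(
        test=order[:n_test],
        train=order[n_test : n_test + n_train],
        pretrain=order[n_test + n_train :],
    )


def _as_dataset(X, fs: float | None) -> EpochDataset:
    if isinstance(X, EpochDataset):
        return X
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError(f"expected (n_epochs, C, N) signals, got shape {X.shape}")
    if fs is None:
        raise ValueError("fs must be given when passing a raw signal array")
    return EpochDataset(
        signals=X, fs=fs, subjects=np.array([f"S{i}" for i in range(len(X))])
    )


# -- the self-supervised transformer ------------------------------------


class ContraWR(BaseEstimator, TransformerMixin):
    """Self-supervised spectrogram-encoder pretrainer (ContraWR family).

    Parameters mirror the contrastive configuration: ``mode`` selects the
    negative reference ('contrawr' uniform world mean, 'contrawr_plus'
    instance-aware softmax-weighted mean, 'avg_knn_topx' top-X neighbor
    mean).  Defaults are the desk-scale profile (batch 32, 30 passes,
    lr 1e-3); the full-scale profile of the method is sigma=2, T=2,
    delta=0.2, batch 256, lr 2e-4, weight decay 1e-4, 100 passes.

    ``fit(X)`` ignores labels entirely.  ``transform(X)`` returns the
    frozen online-encoder representations ``h``.

    Attributes (after fit)
    ----------------------
    encoder_, projector_ : online networks (theta)
    target_encoder_, target_projector_ : EMA target networks (phi)
    encoder_params_ : list of the online encoder's parameter arrays
    loss_history_ : per-pass mean triplet loss
    encoder_spec_, fs_, n_channels_ : resolved configuration
    """

    def __init__(
        self,
        mode: str = "contrawr_plus",
        sigma: float = 2.0,
        delta: float = 0.2,
        temperature: float = 2.0,
        ema_lambda: float = 0.99,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        batch_size: int = 32,
        n_epochs: int = 30,
        topx: int | None = None,
        exclude_self: bool = False,
        encoder_spec: EncoderSpec | None = None,
        policy: AugmentationPolicy | None = None,
        fs: float | None = None,
        random_state: int = 0,
        verbose: bool = False,
    ) -> None:
        self.mode = mode
        self.sigma = sigma
        self.delta = delta
        self.temperature = temperature
        self.ema_lambda = ema_lambda
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.topx = topx
        self.exclude_self = exclude_self
        self.encoder_spec = encoder_spec
        self.policy = policy
        self.fs = fs
        self.random_state = random_state
        self.verbose = verbose

    def _config(self) -> ContrastiveConfig:
        return ContrastiveConfig(
            sigma=self.sigma,
            delta=self.delta,
            temperature=self.temperature,
            ema_lambda=self.ema_lambda,
            lr=self.lr,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            mode=self.mode,
            topx=self.topx,
            exclude_self=self.exclude_self,
        )

    def fit(self, X, y=None) -> "ContraWR":
        cfg = self._config()
        data = _as_dataset(X, self.fs).without_labels()  # labels never enter pretraining
        n = len(data)
        if cfg.batch_size > n:
            raise ValueError(
                f"batch_size ({cfg.batch_size}) exceeds the dataset size ({n})"
            )
        spec = self.encoder_spec or EncoderSpec()
        spec.validate_geometry(data.fs, data.n_samples)  # fail fast on bad STFT config
        policy = self.policy or AugmentationPolicy()
        policy.validate_for(data.fs, data.n_channels, data.n_samples)

        seeds = np.random.SeedSequence(self.random_state).generate_state(4)
        init_enc, init_proj, shuffle_seed, aug_seed = (int(s) % 2**31 for s in seeds)
        enc = build_encoder(spec, data.n_channels, init_enc)
        proj = build_projector(spec, init_proj)
        tgt_enc = build_encoder(spec, data.n_channels, init_enc)  # phi starts as a copy of theta
        tgt_proj = build_projector(spec, init_proj)
        theta = nn.collect_params(enc) + nn.collect_params(proj)
        phi = nn.collect_params(tgt_enc) + nn.collect_params(tgt_proj)

        opt = nn.Adam(theta, lr=cfg.lr, weight_decay=cfg.weight_decay)
        shuffle_rng = np.random.default_rng(shuffle_seed)
        aug_rng = np.random.default_rng(aug_seed)

        # the bandpass view component is deterministic per epoch: precompute it
        filtered = None
        if "bandpass" in policy.enabled_ops:
            from .augment import bandpass_batch

            filtered = bandpass_batch(
                data.signals, data.fs, policy.bandpass_low, policy.bandpass_high
            ).astype(np.float32)

        signals32 = data.signals.astype(np.float32, copy=False)
        history: list[float] = []
        for epoch_idx in range(self.n_epochs):
            order = shuffle_rng.permutation(n)
            losses: list[float] = []
            for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                v1 = np.empty((len(idx), data.n_channels, data.n_samples), dtype=np.float32)
                v2 = np.empty_like(v1)
                for row, i in enumerate(idx):
                    v1[row], v2[row] = make_views(
                        signals32[i], data.fs, policy,
                        seed=int(aug_rng.integers(2**31)),
                        filtered=None if filtered is None else filtered[i],
                        validate=False,
                    )
                s12 = stft_spectrogram(np.concatenate([v1, v2]), data.fs, spec)
                s1 = spectrogram_input(s12[: len(idx)])
                s2 = spectrogram_input(s12[len(idx) :])

                h = enc.forward(s1)
                u = proj.forward(h)
                anchors = nn.l2_normalize(u, axis=-1)
                positives = nn.l2_normalize(
                    tgt_proj.forward(tgt_enc.forward(s2)), axis=-1
                )

                loss, ganchors = batch_loss_and_grad(anchors, positives, cfg)
                enc.zero_grad()
                proj.zero_grad()
                gu = nn.l2_normalize_backward(u, ganchors).astype(np.float32)
                enc.backward(proj.backward(gu))
                opt.step(nn.collect_grads(enc) + nn.collect_grads(proj))
                ema_update(theta, phi, cfg.ema_lambda)
                losses.append(loss)
            history.append(float(np.mean(losses)) if losses else float("nan"))
            if self.verbose:
                print(f"[pretrain] pass {epoch_idx + 1}/{self.n_epochs} "
                      f"mean loss {history[-1]:.4f}")

        self.encoder_ = enc
        self.projector_ = proj
        self.target_encoder_ = tgt_enc
        self.target_projector_ = tgt_proj
        self.encoder_spec_ = spec
        self.loss_history_ = history
        self.fs_ = data.fs
        self.n_channels_ = data.n_channels
        return self

    @property
    def encoder_params_(self) -> list[np.ndarray]:
        return nn.collect_params(self.encoder_)

    def transform(self, X) -> np.ndarray:
        """Frozen representations h of shape (n_epochs, d)."""
        data = _as_dataset(X, self.fs if self.fs is not None else getattr(self, "fs_", None))
        return encode(data.signals, data.fs, self.encoder_spec_, self.encoder_)


# -- supervised reference ------------------------------------------------


class SupervisedStageClassifier(BaseEstimator, ClassifierMixin):
    """Encoder + 2-layer fully connected head trained end-to-end.

    The reference model of the evaluation protocol: identical STFT-CNN
    encoder, a ``d -> head_hidden -> K`` head with ELU, cross-entropy loss,
    trained from scratch on the labeled training split only (the pretrain
    split is never used).
    """

    def __init__(
        self,
        encoder_spec: EncoderSpec | None = None,
        head_hidden: int = 128,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        batch_size: int = 32,
        n_epochs: int = 30,
        fs: float | None = None,
        random_state: int = 0,
        verbose: bool = False,
    ) -> None:
        self.encoder_spec = encoder_spec
        self.head_hidden = head_hidden
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.fs = fs
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X, y=None) -> "SupervisedStageClassifier":
        data = _as_dataset(X, self.fs)
        y = np.asarray(data.labels if y is None else y, dtype=int)
        if y.shape != (len(data),):
            raise ValueError("labels must align with the epochs")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("supervised training requires at least 2 classes")
        spec = self.encoder_spec or EncoderSpec()
        spec.validate_geometry(data.fs, data.n_samples)
        k = self.classes_.size
        class_index = {c: i for i, c in enumerate(self.classes_)}
        targets = np.array([class_index[c] for c in y])

        seeds = np.random.SeedSequence(self.random_state).generate_state(3)
        init_enc, init_head, shuffle_seed = (int(s) % 2**31 for s in seeds)
        enc = build_encoder(spec, data.n_channels, init_enc)
        rng = np.random.default_rng(init_head)
        head = nn.Sequential(
            [
                nn.Linear(spec.repr_dim, self.head_hidden, rng),
                nn.ELU(),
                nn.Linear(self.head_hidden, k, rng),
            ]
        )
        params = nn.collect_params(enc) + nn.collect_params(head)
        opt = nn.Adam(params, lr=self.lr, weight_decay=self.weight_decay)
        shuffle_rng = np.random.default_rng(shuffle_seed)

        n = len(data)
        batch = min(self.batch_size, n)
        signals32 = data.signals.astype(np.float32, copy=False)
        history: list[float] = []
        for epoch_idx in range(self.n_epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                s = spectrogram_input(
                    stft_spectrogram(data.signals[idx].astype(np.float32), data.fs, spec)
                )
                logits = head.forward(enc.forward(s))
                logits = logits - logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                t = targets[idx]
                losses.append(float(-np.mean(np.log(p[np.arange(len(idx)), t] + 1e-12))))
                g = p
                g[np.arange(len(idx)), t] -= 1.0
                g /= len(idx)
                enc.zero_grad()
                head.zero_grad()
                enc.backward(head.backward(g.astype(np.float32)))
                opt.step(nn.collect_grads(enc) + nn.collect_grads(head))
            history.append(float(np.mean(losses)))
            if self.verbose:
                print(f"[supervised] pass {epoch_idx + 1}/{self.n_epochs} "
                      f"mean loss {history[-1]:.4f}")

        self.encoder_ = enc
        self.head_ = head
        self.encoder_spec_ = spec
        self.loss_history_ = history
        self.fs_ = data.fs
        return self

    def decision_function(self, X) -> np.ndarray:
        data = _as_dataset(X, self.fs if self.fs is not None else getattr(self, "fs_", None))
        outs = []
        for start in range(0, len(data), 256):
            s = spectrogram_input(
                stft_spectrogram(
                    data.signals[start : start + 256].astype(np.float32),
                    data.fs,
                    self.encoder_spec_,
                )
            )
            outs.append(self.head_.forward(self.encoder_.forward(s)))
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


# -- probing -------------------------------------------------------------


@dataclass
class ProbeResult:
    """Linear-probe outcome: overall accuracy plus diagnostics."""

    accuracy: float
    confusion: np.ndarray  # rows = truth, columns = prediction
    classes: np.ndarray
    per_class_recall: np.ndarray


_PROBE_C_GRID = (0.01, 0.1, 1.0, 10.0)


def fit_probe(
    features_train: np.ndarray,
    y_train: np.ndarray,
    features_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
) -> ProbeResult:
    """Multinomial logistic probe on fixed feature vectors.

    The L2 regularization strength is chosen on a 25% validation fold
    carved from the training features (deterministic given ``seed``), then
    the probe is refit on the full training set.
    """
    y_train = np.asarray(y_train, dtype=int)
    y_test = np.asarray(y_test, dtype=int)
    missing = sorted(set(y_test) - set(y_train))
    if missing:
        raise ValueError(
            f"classes {missing} present in the test set but absent from training"
        )

    def make_clf(c: float):
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=c, max_iter=2000, random_state=seed),
        )

    best_c, best_val = 1.0, -np.inf
    classes_train, class_counts = np.unique(y_train, return_counts=True)
    can_tune = (
        class_counts.min() >= 2
        and classes_train.size > 1
        and int(0.25 * len(y_train)) >= classes_train.size
    )
    if can_tune:
        ftr, fval, ytr, yval = train_test_split(
            features_train, y_train, test_size=0.25, random_state=seed, stratify=y_train
        )
        for c in _PROBE_C_GRID:
            val = make_clf(c).fit(ftr, ytr).score(fval, yval)
            if val > best_val:
                best_c, best_val = c, val
    clf = make_clf(best_c).fit(features_train, y_train)
    pred = clf.predict(features_test)
    classes = np.unique(np.concatenate([y_train, y_test]))
    cm = confusion_matrix(y_test, pred, labels=classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(cm.sum(axis=1) > 0, np.diag(cm) / cm.sum(axis=1), np.nan)
    return ProbeResult(
        accuracy=float(accuracy_score(y_test, pred)),
        confusion=cm,
        classes=classes,
        per_class_recall=recall,
    )


def linear_probe(
    encoder_spec: EncoderSpec,
    encoder_params: list[np.ndarray],
    train_set: EpochDataset,
    test_set: EpochDataset,
    seed: int = 0,
) -> ProbeResult:
    """Frozen-encoder evaluation: encode both splits, fit the logistic probe.

    The supplied parameters are copied into a fresh network, so the
    caller's encoder is never modified.
    """
    if train_set.labels is None or test_set.labels is None:
        raise ValueError("linear_probe requires labeled train and test sets")
    enc = build_encoder(encoder_spec, train_set.n_channels, seed=0)
    nn.set_network_params(enc, nn.clone_params(encoder_params))
    f_train = encode(train_set.signals, train_set.fs, encoder_spec, enc)
    f_test = encode(test_set.signals, test_set.fs, encoder_spec, enc)
    return fit_probe(f_train, train_set.labels, f_test, test_set.labels, seed=seed)


def untrained_baseline(
    encoder_spec: EncoderSpec, n_channels: int, seed: int = 0
) -> list[np.ndarray]:
    """Freshly initialized, never-optimized encoder parameters."""
    return nn.collect_params(build_encoder(encoder_spec, n_channels, seed))


# -- functional wrappers & the label-fraction sweep ----------------------


def pretrain(
    dataset: EpochDataset,
    cfg: ContrastiveConfig | None = None,
    spec: EncoderSpec | None = None,
    policy: AugmentationPolicy | None = None,
    epochs: int = 30,
    seed: int = 0,
    verbose: bool = False,
) -> ContraWR:
    """Thin functional wrapper over :class:`ContraWR.fit`."""
    cfg = cfg or ContrastiveConfig(batch_size=32, lr=1e-3)
    model = ContraWR(
        mode=cfg.mode,
        sigma=cfg.sigma,
        delta=cfg.delta,
        temperature=cfg.temperature,
        ema_lambda=cfg.ema_lambda,
        lr=cfg.lr,
        weight_decay=cfg.weight_decay,
        batch_size=cfg.batch_size,
        n_epochs=epochs,
        topx=cfg.topx,
        exclude_self=cfg.exclude_self,
        encoder_spec=spec,
        policy=policy,
        random_state=seed,
        verbose=verbose,
    )
    return model.fit(dataset)


def label_fraction_sweep(
    dataset: EpochDataset,
    fractions: list[float],
    cfg: ContrastiveConfig | None = None,
    spec: EncoderSpec | None = None,
    policy: AugmentationPolicy | None = None,
    test_frac: float = 0.2,
    seeds: tuple[int, ...] = (0, 1, 2),
    methods: tuple[str, ...] = ("probe", "supervised"),
    pretrain_epochs: int = 30,
    supervised_epochs: int = 30,
    verbose: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy as a function of the labeled-training fraction.

    For each seed the test subjects are held fixed; for each fraction the
    remaining subjects are re-split into labeled training subjects
    (``ceil(fraction * n)``, nested across fractions) and an unlabeled
    pretrain remainder.  Returns the tidy per-run table
    (fraction, method, seed, accuracy) and the mean +/- SD aggregate.
    """
    if dataset.labels is None:
        raise ValueError("the sweep needs a labeled dataset")
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError(f"fractions must lie in (0, 1), got {f}")
    cfg = cfg or ContrastiveConfig(batch_size=32, lr=1e-3, mode="contrawr_plus")
    spec = spec or EncoderSpec()
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        subjects = dataset.subject_ids
        order = [subjects[i] for i in rng.permutation(len(subjects))]
        n_test = max(1, round(test_frac * len(order)))
        test_subjects, rest = order[:n_test], order[n_test:]
        test_set = dataset.subject_subset(test_subjects)
        for frac in fractions:
            n_train = int(np.ceil(frac * len(rest)))
            if n_train < 1:
                raise ValueError(f"fraction {frac} yields fewer than 1 training subject")
            train_subjects = rest[:n_train]
            pretrain_subjects = rest[n_train:]
            if not pretrain_subjects:
                raise ValueError(
                    f"fraction {frac} leaves the pretrain set empty "
                    f"(all {len(rest)} non-test subjects assigned to training)"
                )
            train_set = dataset.subject_subset(train_subjects)
            if "probe" in methods:
                model = pretrain(
                    dataset.subject_subset(pretrain_subjects).without_labels(),
                    cfg=cfg, spec=spec, policy=policy,
                    epochs=pretrain_epochs, seed=seed, verbose=verbose,
                )
                res = linear_probe(
                    model.encoder_spec_, model.encoder_params_,
                    train_set, test_set, seed=seed,
                )
                rows.append((frac, "probe", seed, res.accuracy))
            if "supervised" in methods:
                sup = SupervisedStageClassifier(
                    encoder_spec=spec, n_epochs=supervised_epochs,
                    batch_size=min(cfg.batch_size, len(train_set)),
                    random_state=seed, verbose=verbose,
                ).fit(train_set)
                acc = accuracy_score(test_set.labels, sup.predict(test_set))
                rows.append((frac, "supervised", seed, float(acc)))
    tidy = pd.DataFrame(rows, columns=["fraction", "method", "seed", "accuracy"])
    agg = (
        tidy.groupby(["fraction", "method"])["accuracy"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "accuracy_mean", "std": "accuracy_sd"})
    )
    return tidy, agg
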