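"""Domain-adversarial 1-D convolutional sleep/wake classifier.

The architecture is a shared feature extractor — three blocks of
same-padded 1-D convolution, batch normalisation, ReLU and max pooling
(each pool halves the temporal length) — whose flattened output feeds
two heads:

* a **label head** (dense layer, dropout, 2-way output) predicting
  sleep vs wake, trained only on labeled source-domain windows;
* a **domain head** (gradient reversal, dense layer, 2-way output)
  predicting which device domain a window came from, trained on source
  and target windows alike.

Because the domain head sits behind a gradient-reversal operator, the
extractor is pushed to make the two domains indistinguishable in feature
space while staying informative about sleep — unsupervised domain
adaptation in the adversarial style.  Disabling the domain head
(``use_domain_adversary=False``) gives the plain source-only CNN
baseline.  Target-domain labels are never read during training.

Usage follows the model/results convention of statistical packages::

    model = SleepWakeNet(source_train, target=target_windows,
                         validation=source_val)
    fit = model.fit(TrainConfig(seed=0))
    print(fit.summary())
    probs, hyp = fit.predict_series(series)
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import nn
from .data import WindowSet, extract_windows
from .series import EpochSeries


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The canonical topology is fixed (three conv blocks, pool size 2); the
    widths below are conventional choices for a small 1-D CNN and are all
    adjustable.
    """

    n_blocks: int = 3
    channels: Tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 5
    pool_size: int = 2
    fc_units: int = 128
    dropout_rate: float = 0.5
    lambda_grl: float = 1.0

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one conv block")
        if len(self.channels) != self.n_blocks:
            raise ValueError("channels must list one width per block")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.lambda_grl < 0:
            raise ValueError("lambda_grl must be >= 0")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters for :meth:`SleepWakeNet.fit`."""

    batch_size: int = 256
    max_epochs: int = 20
    learning_rate: float = 1e-3
    early_stop_patience: int = 3
    seed: int = 0
    use_domain_adversary: bool = True
    target_batch_mix: float = 0.5
    class_weighting: str = "none"  # or "inverse-frequency"
    lambda_schedule: str = "ramp"  # or "constant"
    # the adversary must track the optimal domain discriminator for the
    # reversed gradient to be informative; a faster domain head helps
    domain_head_lr_multiplier: float = 3.0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.use_domain_adversary and self.batch_size < 2:
            raise ValueError("adversarial training needs batch_size >= 2")
        if not 0.0 < self.target_batch_mix < 1.0:
            raise ValueError("target_batch_mix must be in (0, 1)")
        if self.class_weighting not in ("none", "inverse-frequency"):
            raise ValueError("class_weighting must be 'none' or 'inverse-frequency'")
        if self.lambda_schedule not in ("ramp", "constant"):
            raise ValueError("lambda_schedule must be 'ramp' or 'constant'")


def pooled_lengths(input_length: int, cfg: ModelConfig) -> List[int]:
    """Temporal length after each conv block (floor halving per pool)."""
    lengths, L = [], input_length
    for _ in range(cfg.n_blocks):
        L = L // cfg.pool_size
        lengths.append(L)
    return lengths


class _Network:
    """The raw parameterised network: extractor plus two heads."""

    def __init__(self, cfg: ModelConfig, input_length: int, seed: int):
        cfg.validate()
        if input_length < cfg.pool_size**cfg.n_blocks:
            raise ValueError(
                f"input_length {input_length} too short for "
                f"{cfg.n_blocks} pooling stages"
            )
        self.cfg = cfg
        self.input_length = input_length
        rng = np.random.default_rng(seed)
        layers, in_ch = [], 1
        for ch in cfg.channels:
            layers += [
                nn.Conv1d(in_ch, ch, cfg.kernel_size, rng),
                nn.BatchNorm1d(ch, n_domains=2),
                nn.ReLU(),
                nn.MaxPool1d(cfg.pool_size),
            ]
            in_ch = ch
        layers.append(nn.Flatten())
        self.extractor = nn.Sequential(layers)
        n_feat = cfg.channels[-1] * pooled_lengths(input_length, cfg)[-1]
        self.label_head = nn.Sequential(
            [
                nn.Dense(n_feat, cfg.fc_units, rng),
                nn.ReLU(),
                nn.Dropout(cfg.dropout_rate, rng),
                nn.Dense(cfg.fc_units, 2, rng),
            ]
        )
        self.grl = nn.GradientReversal(cfg.lambda_grl)
        self.domain_head = nn.Sequential(
            [
                self.grl,
                nn.Dense(n_feat, cfg.fc_units, rng),
                nn.ReLU(),
                nn.Dense(cfg.fc_units, 2, rng),
            ]
        )

    def params(self):
        return (
            self.extractor.params()
            + self.label_head.params()
            + self.domain_head.params()
        )

    def set_bn_domains(self, domains: Optional[np.ndarray]) -> None:
        """Route rows to per-domain batch-norm statistics (None = source)."""
        for layer in self.extractor.layers:
            if isinstance(layer, nn.BatchNorm1d):
                layer.domains = domains

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        with_domain: bool = True,
        domains: Optional[np.ndarray] = None,
    ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
        """Sleep and (optionally) target-domain probabilities per window."""
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.input_length:
            raise ValueError(
                f"window length {x.shape[2]} != model input length "
                f"{self.input_length}"
            )
        self.set_bn_domains(domains)
        feats = self.extractor.forward(x, train=train)
        label_logits = nn.softmax(self.label_head.forward(feats, train=train))
        p_sleep = label_logits[:, 1]
        p_domain = None
        if with_domain:
            p_domain = nn.softmax(self.domain_head.forward(feats, train=train))[:, 1]
        return p_sleep, p_domain

    def features(self, x: np.ndarray, domains: Optional[np.ndarray] = None) -> np.ndarray:
        """Frozen (inference-mode) extractor features, for probing."""
        if x.ndim == 2:
            x = x[:, None, :]
        self.set_bn_domains(domains)
        return self.extractor.forward(x, train=False)

    # -- parameter snapshots for early stopping / checkpointing ---------
    def get_state(self) -> List[np.ndarray]:
        state = [p.copy() for p, _ in self.params()]
        for layer in self.extractor.layers:
            if isinstance(layer, nn.BatchNorm1d):
                state += [layer.run_mean.copy(), layer.run_var.copy()]
        return state

    def set_state(self, state: List[np.ndarray]) -> None:
        k = 0
        for p, _ in self.params():
            p[...] = state[k]
            k += 1
        for layer in self.extractor.layers:
            if isinstance(layer, nn.BatchNorm1d):
                layer.run_mean[...] = state[k]
                layer.run_var[...] = state[k + 1]
                k += 2


class SleepWakeNet:
    """Sleep/wake classifier model bound to its training data.

    Parameters
    ----------
    source : WindowSet
        Labeled source-domain training windows.
    target : WindowSet, optional
        Unlabeled target-domain windows for adversarial adaptation; any
        labels attached are discarded on entry and never read.
    validation : WindowSet, optional
        Labeled source-domain windows for early stopping.
    config : ModelConfig
    """

    def __init__(
        self,
        source: WindowSet,
        target: Optional[WindowSet] = None,
        validation: Optional[WindowSet] = None,
        config: Optional[ModelConfig] = None,
    ):
        if source.labels is None:
            raise ValueError("source windows must be labeled")
        self.source = source
        # leakage guard: target labels are stripped before anything else
        # can touch them — adaptation is strictly unsupervised.
        self.target = target.without_labels() if target is not None else None
        self.validation = validation
        self.config = config or ModelConfig()
        self.input_length = source.L

    def fit(self, train_config: Optional[TrainConfig] = None) -> "SleepWakeFit":
        cfg = train_config or TrainConfig()
        cfg.validate()
        use_da = cfg.use_domain_adversary and self.target is not None
        net = _Network(self.config, self.input_length, seed=cfg.seed)
        opt = nn.Adam(
            net.extractor.params() + net.label_head.params(), lr=cfg.learning_rate
        )
        opt_dom = nn.Adam(
            net.domain_head.params(),
            lr=cfg.learning_rate * cfg.domain_head_lr_multiplier,
        )
        rng = np.random.default_rng(cfg.seed + 1)

        Xs, ys = self.source.windows, self.source.labels.astype(int)
        class_w = None
        if cfg.class_weighting == "inverse-frequency":
            freq = np.bincount(ys, minlength=2) / len(ys)
            class_w = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-12), 0.0)
            class_w /= class_w.mean()

        if use_da:
            n_tgt_batch = max(1, int(round(cfg.batch_size * cfg.target_batch_mix)))
            n_src_batch = max(1, cfg.batch_size - n_tgt_batch)
            Xt = self.target.windows
        else:
            n_src_batch = cfg.batch_size

        history = {"epoch": [], "label_loss": [], "domain_loss": [], "val_loss": []}
        best_state, best_val, best_epoch, since_best = net.get_state(), np.inf, 0, 0
        n_batches = max(1, len(Xs) // n_src_batch)
        # among epochs whose validation loss is within 5% of the best, the
        # latest snapshot is kept: later epochs carry more domain alignment
        # at equal source fit
        snap_tol = 1.05

        for epoch in range(cfg.max_epochs):
            if use_da:
                # the adversary fades in so label features can form before
                # the alignment pressure peaks (standard DANN schedule)
                if cfg.lambda_schedule == "ramp" and cfg.max_epochs > 1:
                    prog = epoch / (cfg.max_epochs - 1)
                    net.grl.lam = self.config.lambda_grl * (
                        2.0 / (1.0 + np.exp(-10.0 * prog)) - 1.0
                    )
                else:
                    net.grl.lam = self.config.lambda_grl
            src_order = rng.permutation(len(Xs))
            if use_da:
                tgt_order = rng.permutation(len(Xt))
            ep_label, ep_domain = 0.0, 0.0
            for b in range(n_batches):
                si = src_order[b * n_src_batch : (b + 1) * n_src_batch]
                xb, yb = Xs[si], ys[si]
                if use_da:
                    ti = tgt_order[(b * n_tgt_batch) % len(Xt) :][:n_tgt_batch]
                    if len(ti) < n_tgt_batch:
                        ti = np.concatenate([ti, tgt_order[: n_tgt_batch - len(ti)]])
                    x = np.concatenate([xb, Xt[ti]])
                    bn_dom = np.concatenate(
                        [np.zeros(len(xb), int), np.ones(n_tgt_batch, int)]
                    )
                else:
                    x = xb
                    bn_dom = None
                net.set_bn_domains(bn_dom)
                feats = net.extractor.forward(x[:, None, :], train=True)

                # label loss: source rows only
                label_logits = net.label_head.forward(feats[: len(xb)], train=True)
                sw = class_w[yb] if class_w is not None else None
                l_loss, dlab = nn.cross_entropy(label_logits, yb, sw)
                dfeat = np.zeros_like(feats)
                dfeat[: len(xb)] = net.label_head.backward(dlab)

                d_loss = 0.0
                if use_da:
                    dom_labels = np.concatenate(
                        [np.zeros(len(xb), int), np.ones(n_tgt_batch, int)]
                    )
                    dom_logits = net.domain_head.forward(feats, train=True)
                    d_loss, ddom = nn.cross_entropy(dom_logits, dom_labels)
                    dfeat += net.domain_head.backward(ddom)  # GRL flips sign here

                net.extractor.backward(dfeat)
                opt.step()
                if use_da:
                    opt_dom.step()
                ep_label += l_loss
                ep_domain += d_loss

            val_loss = self._label_loss(net, self.validation or self.source)
            history["epoch"].append(epoch)
            history["label_loss"].append(ep_label / n_batches)
            history["domain_loss"].append(ep_domain / n_batches)
            history["val_loss"].append(val_loss)
            improved = val_loss < best_val - 1e-6
            if improved:
                best_val = val_loss
                since_best = 0
            if val_loss <= best_val * snap_tol:
                best_state = net.get_state()
                best_epoch = epoch
            if not improved:
                since_best += 1
                if since_best > cfg.early_stop_patience:
                    break

        net.set_state(best_state)
        return SleepWakeFit(
            model=self,
            network=net,
            train_config=cfg,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
            best_val_loss=best_val,
        )

    @staticmethod
    def _label_loss(net: _Network, windows: WindowSet) -> float:
        if windows.labels is None:
            raise ValueError("validation windows must be labeled")
        losses, n = 0.0, 0
        net.set_bn_domains(None)
        for x, y in _batches(windows.windows, windows.labels.astype(int), 2048):
            feats = net.extractor.forward(x[:, None, :], train=False)
            logits = net.label_head.forward(feats, train=False)
            loss, _ = nn.cross_entropy(logits, y)
            losses += loss * len(x)
            n += len(x)
        return losses / n


def _batches(X, y, size):
    for i in range(0, len(X), size):
        yield X[i : i + size], y[i : i + size]


class SleepWakeFit:
    """Results of fitting a :class:`SleepWakeNet`.

    Carries the trained network (restored to the best validation epoch),
    the per-epoch loss history, and prediction helpers.  Inference uses
    only the label head with frozen batch-norm statistics.
    """

    def __init__(self, model, network, train_config, history, best_epoch, best_val_loss):
        self.model = model
        self.network = network
        self.train_config = train_config
        self.history = history
        self.best_epoch = best_epoch
        self.best_val_loss = best_val_loss
        self._adapted = bool(
            train_config.use_domain_adversary and model.target is not None
        )

    # -- inference -------------------------------------------------------
    def predict_proba(
        self, windows: np.ndarray, batch_size: int = 4096, domain_id: int = 0
    ) -> np.ndarray:
        """Per-window sleep probability (inference mode, batch invariant).

        ``domain_id`` selects which domain's frozen batch-norm statistics
        normalise the windows; an adversarially adapted model owns target
        statistics (id 1) learned from unlabeled target data, a
        source-only model has only source statistics (id 0).
        """
        windows = np.asarray(windows, float)
        out = np.empty(len(windows))
        for i in range(0, len(windows), batch_size):
            chunk = windows[i : i + batch_size]
            p, _ = self.network.forward(
                chunk, train=False, with_domain=False,
                domains=np.full(len(chunk), domain_id, dtype=int),
            )
            out[i : i + batch_size] = p
        return out

    def predict_series(
        self,
        series: EpochSeries,
        threshold: float = 0.5,
        domain_id: int = 0,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Sleep probability and thresholded hypnogram for a whole record."""
        ws = extract_windows(
            series, self.model.source.past_epochs, self.model.source.future_epochs
        )
        probs = self.predict_proba(ws.windows, domain_id=domain_id)
        return probs, (probs >= threshold).astype(np.int8)

    @property
    def adapted(self) -> bool:
        """True when the fit used the domain adversary on target data."""
        return self._adapted

    def predictor(self, threshold: float = 0.5, domain_id: int = 0):
        """A ``series -> (probs, hypnogram)`` callable for evaluation."""

        def _predict(series: EpochSeries):
            return self.predict_series(series, threshold=threshold, domain_id=domain_id)

        return _predict

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        cfg, tc = self.model.config, self.train_config
        n_params = sum(p.size for p, _ in self.network.params())
        lengths = pooled_lengths(self.model.input_length, cfg)
        lines = [
            "Sleep/wake domain-adversarial CNN — fit summary",
            "=" * 49,
            f"input length (epochs):     {self.model.input_length}",
            f"conv blocks:               {cfg.n_blocks} "
            f"(channels {list(cfg.channels)}, kernel {cfg.kernel_size})",
            f"temporal lengths per pool: {lengths}",
            f"trainable parameters:      {n_params}",
            f"domain adversary:          "
            f"{'on (lambda=%.2f)' % cfg.lambda_grl if tc.use_domain_adversary and self.model.target is not None else 'off'}",
            f"epochs run:                {len(self.history)} "
            f"(best epoch {self.best_epoch})",
            f"best validation loss:      {self.best_val_loss:.4f}",
            f"final label loss:          {self.history['label_loss'].iloc[-1]:.4f}",
        ]
        if (self.history["domain_loss"] > 0).any():
            lines.append(
                f"final domain loss:         {self.history['domain_loss'].iloc[-1]:.4f}"
            )
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss curves over training epochs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["label_loss"], label="label loss")
        if (self.history["domain_loss"] > 0).any():
            ax.plot(
                self.history["epoch"], self.history["domain_loss"], label="domain loss"
            )
        ax.plot(self.history["epoch"], self.history["val_loss"], label="val loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy")
        ax.legend()
        return ax

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Self-describing checkpoint: config + parameters + seed."""
        meta = {
            "model_config": asdict(self.model.config),
            "train_config": asdict(self.train_config),
            "input_length": self.model.input_length,
            "past_epochs": int(self.model.source.past_epochs),
            "future_epochs": int(self.model.source.future_epochs),
            "best_epoch": int(self.best_epoch),
            "adapted": bool(self.adapted),
            "best_val_loss": float(self.best_val_loss),
        }
        state = self.network.get_state()
        np.savez(
            path,
            meta=json.dumps(meta),
            history=self.history.to_json(),
            **{f"p{i}": s for i, s in enumerate(state)},
        )

    @classmethod
    def load(cls, path) -> "SleepWakeFit":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            history = pd.read_json(io.StringIO(str(z["history"])))
            state = [z[f"p{i}"] for i in range(len(z.files) - 2)]
        mcfg = ModelConfig(**{**meta["model_config"],
                              "channels": tuple(meta["model_config"]["channels"])})
        tcfg = TrainConfig(**meta["train_config"])
        net = _Network(mcfg, meta["input_length"], seed=tcfg.seed)
        net.set_state(state)
        # a placeholder single-window source carries the window scheme
        from .data import WindowSet

        p, f = meta["past_epochs"], meta["future_epochs"]
        dummy = WindowSet(
            windows=np.zeros((1, meta["input_length"])),
            labels=np.zeros(1, np.int8),
            domain_ids=np.zeros(1, np.int8),
            pad_mask=np.zeros((1, meta["input_length"]), bool),
            center_index=np.zeros(1, int),
            past_epochs=p,
            future_epochs=f,
        )
        model = SleepWakeNet(dummy, config=mcfg)
        fit = cls(
            model=model,
            network=net,
            train_config=tcfg,
            history=history,
            best_epoch=meta["best_epoch"],
            best_val_loss=meta["best_val_loss"],
        )
        fit._adapted = bool(meta.get("adapted", False))
        return fit
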