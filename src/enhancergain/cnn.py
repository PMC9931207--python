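"""Convolutional sequence-to-activity scorer.

A stack of same-padding 1-D convolutions (ReLU, max-pool) over one-hot DNA,
followed by a fully connected layer and a sigmoid/softmax output, trained
with Adam on binary cross-entropy. The reference architecture uses five
convolution layers with 320/320/240/240/480 kernels, a 180-unit dense layer
and 1000-bp input; a scaled-down configuration is used for training tests.

Training splits data by chromosome: chr8/chr9 are held out for testing,
chr6 is the validation set, everything else trains. Each training sequence
is presented in both orientations, and at inference the score is the mean
of the forward and reverse-complement passes, which makes strand invariance
an exact identity.

The network is implemented directly in numpy (im2col convolutions with
hand-derived gradients); ``count_parameters`` gives the closed-form
trainable-parameter total for a configuration, and
``solve_reference_architecture`` searches the unpublished hyperparameters
(kernel widths, pool sizes, output units) for a configuration matching a
target parameter count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import reverse_complement

__all__ = [
    "ModelConfig",
    "ScoreThreshold",
    "TrainedScorer",
    "ConvNet",
    "one_hot",
    "count_parameters",
    "solve_reference_architecture",
    "train",
    "calibrate_threshold",
    "delta_score",
    "allele_effect_accuracy",
    "REFERENCE_KERNELS",
    "REFERENCE_DENSE_UNITS",
]

REFERENCE_KERNELS = (320, 320, 240, 240, 480)
REFERENCE_DENSE_UNITS = 180

_ONE_HOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.25, 0.25, 0.25, 0.25),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the convolutional scorer."""

    input_len: int = 200
    conv_kernels: tuple[int, ...] = (32, 32)
    kernel_widths: tuple[int, ...] = (8, 8)
    pool_sizes: tuple[int, ...] = (4, 4)
    dense_units: int = 32
    output_units: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_kernels", tuple(self.conv_kernels))
        object.__setattr__(self, "kernel_widths", tuple(self.kernel_widths))
        object.__setattr__(self, "pool_sizes", tuple(self.pool_sizes))
        if not (
            len(self.conv_kernels) == len(self.kernel_widths) == len(self.pool_sizes)
        ):
            raise ValueError("conv_kernels, kernel_widths, pool_sizes must align")
        for v in (
            self.input_len,
            *self.conv_kernels,
            *self.kernel_widths,
            *self.pool_sizes,
            self.dense_units,
            self.output_units,
        ):
            if v <= 0:
                raise ValueError("all architecture counts must be positive")
        if self.output_units > 2:
            raise ValueError("output_units must be 1 (sigmoid) or 2 (softmax)")

    def layer_lengths(self) -> list[int]:
        """Sequence length after each conv(+pool) block (same-padding conv)."""
        lengths = []
        length = self.input_len
        for p in self.pool_sizes:
            length = length // p
            if length < 1:
                raise ValueError("pooling reduces sequence length below 1")
            lengths.append(length)
        return lengths

    @property
    def flattened_len(self) -> int:
        return self.layer_lengths()[-1] * self.conv_kernels[-1]


@dataclass(frozen=True)
class ScoreThreshold:
    """Activity cutoff calibrated to a target false-positive rate."""

    value: float
    fpr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError("threshold must be a probability")


def count_parameters(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count of a configuration.

    Per convolution layer: in_channels * width * kernels weights + kernels
    biases. The dense layer sees the flattened final feature map; the output
    layer maps dense_units to output_units.
    """
    config.layer_lengths()  # raises if pooling collapses the sequence
    total = 0
    in_ch = 4
    for k, w in zip(config.conv_kernels, config.kernel_widths):
        total += in_ch * w * k + k
        in_ch = k
    total += config.flattened_len * config.dense_units + config.dense_units
    total += config.dense_units * config.output_units + config.output_units
    return total


def solve_reference_architecture(
    target_params: int,
    conv_kernels: Sequence[int] = REFERENCE_KERNELS,
    dense_units: int = REFERENCE_DENSE_UNITS,
    input_len: int = 1000,
    width_bounds: tuple[int, int] = (2, 26),
    pool_bounds: tuple[int, int] = (1, 8),
    output_bounds: tuple[int, int] = (1, 2),
) -> ModelConfig | None:
    """Find hyperparameters whose parameter count equals ``target_params``.

    Kernel counts and dense width are fixed; kernel widths, pool sizes and
    output units are searched deterministically in lexicographic order over
    (output_units, pool_sizes, kernel_widths). Returns the first matching
    configuration or None when no configuration in bounds reaches the
    target exactly.
    """
    kernels = tuple(conv_kernels)
    n_layers = len(kernels)
    wlo, whi = width_bounds
    plo, phi = pool_bounds
    in_ch = [4] + list(kernels[:-1])
    coef = [in_ch[i] * kernels[i] for i in range(n_layers)]
    # suffix bounds for pruning the width search
    suf_min = [0] * (n_layers + 1)
    suf_max = [0] * (n_layers + 1)
    for i in range(n_layers - 1, -1, -1):
        suf_min[i] = suf_min[i + 1] + coef[i] * wlo
        suf_max[i] = suf_max[i + 1] + coef[i] * whi

    def widths_for(residual: int) -> tuple[int, ...] | None:
        chosen: list[int] = []

        def rec(i: int, rem: int) -> bool:
            if i == n_layers:
                return rem == 0
            for w in range(wlo, whi + 1):
                nxt = rem - coef[i] * w
                if suf_min[i + 1] <= nxt <= suf_max[i + 1]:
                    chosen.append(w)
                    if rec(i + 1, nxt):
                        return True
                    chosen.pop()
            return False

        if rec(0, residual):
            return tuple(chosen)
        return None

    for out_units in range(output_bounds[0], output_bounds[1] + 1):
        for pools in itertools.product(range(plo, phi + 1), repeat=n_layers):
            length = input_len
            for p in pools:
                length //= p
            if length < 1:
                continue
            fixed = (
                sum(kernels)
                + length * kernels[-1] * dense_units
                + dense_units
                + dense_units * out_units
                + out_units
            )
            residual = target_params - fixed
            if not suf_min[0] <= residual <= suf_max[0]:
                continue
            widths = widths_for(residual)
            if widths is not None:
                return ModelConfig(
                    input_len=input_len,
                    conv_kernels=kernels,
                    kernel_widths=widths,
                    pool_sizes=pools,
                    dense_units=dense_units,
                    output_units=out_units,
                )
    return None


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a DNA string, (len, 4) in A,C,G,T order; N -> 0.25."""
    try:
        return np.array([_ONE_HOT[b] for b in seq.upper()])
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}") from None


def _rc_onehot(x: np.ndarray) -> np.ndarray:
    """Reverse complement in one-hot space (flip positions and channels)."""
    return x[..., ::-1, ::-1].copy()


class ConvNet:
    """Numpy implementation of the convolutional scorer with Adam training."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: list[np.ndarray] = []
        in_ch = 4
        for k, w in zip(config.conv_kernels, config.kernel_widths):
            scale = np.sqrt(2.0 / (in_ch * w))
            self.params.append(rng.normal(0.0, scale, size=(w * in_ch, k)))
            self.params.append(np.zeros(k))
            in_ch = k
        flat = config.flattened_len
        self.params.append(
            rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, config.dense_units))
        )
        self.params.append(np.zeros(config.dense_units))
        self.params.append(
            rng.normal(
                0.0,
                np.sqrt(1.0 / config.dense_units),
                size=(config.dense_units, config.output_units),
            )
        )
        self.params.append(np.zeros(config.output_units))
        self._adam_m = [np.zeros_like(p) for p in self.params]
        self._adam_v = [np.zeros_like(p) for p in self.params]
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        """Trainable-parameter total counted from the instantiated arrays."""
        return int(sum(p.size for p in self.params))

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _im2col(x: np.ndarray, width: int) -> np.ndarray:
        """(B, L, C) -> (B, L, width*C) with same-padding windows."""
        b, length, ch = x.shape
        pl, pr = (width - 1) // 2, width // 2
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        windows = np.empty((b, length, width, ch))
        for j in range(width):
            windows[:, :, j, :] = xp[:, j : j + length, :]
        return windows.reshape(b, length, width * ch)

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        cfg = self.config
        cache = {"conv": [], "x": x}
        a = x
        pi = 0
        for layer, (k, w, p) in enumerate(
            zip(cfg.conv_kernels, cfg.kernel_widths, cfg.pool_sizes)
        ):
            wmat, bias = self.params[pi], self.params[pi + 1]
            pi += 2
            cols = self._im2col(a, w)
            z = cols @ wmat + bias
            relu = np.maximum(z, 0.0)
            b_, length, ch = relu.shape
            lp = length // p
            r = relu[:, : lp * p, :].reshape(b_, lp, p, ch)
            idx = r.argmax(axis=2)
            pooled = np.take_along_axis(r, idx[:, :, None, :], axis=2)[:, :, 0, :]
            if want_cache:
                cache["conv"].append(
                    {"in": a, "cols": cols, "z": z, "idx": idx, "shape": relu.shape}
                )
            a = pooled
        flat = a.reshape(a.shape[0], -1)
        wd, bd = self.params[pi], self.params[pi + 1]
        wo, bo = self.params[pi + 2], self.params[pi + 3]
        h = np.maximum(flat @ wd + bd, 0.0)
        logits = h @ wo + bo
        if cfg.output_units == 1:
            prob = 1.0 / (1.0 + np.exp(-logits[:, 0]))
        else:
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            prob = (e / e.sum(axis=1, keepdims=True))[:, 1]
        if want_cache:
            cache.update(
                {"flat": flat, "h": h, "logits": logits, "pool_shape": a.shape}
            )
            return prob, cache
        return prob

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward-pass probabilities for a (B, L, 4) one-hot batch."""
        return self._forward(x)

    def _gradients(self, cache, prob, y):
        cfg = self.config
        b = y.shape[0]
        grads = [np.zeros_like(p) for p in self.params]
        if cfg.output_units == 1:
            dlogits = ((prob - y) / b)[:, None]
        else:
            soft = np.stack([1.0 - prob, prob], axis=1)
            onehot = np.stack([1.0 - y, y], axis=1)
            dlogits = (soft - onehot) / b
        pi = 2 * len(cfg.conv_kernels)
        h, flat = cache["h"], cache["flat"]
        wo = self.params[pi + 2]
        grads[pi + 2] = h.T @ dlogits
        grads[pi + 3] = dlogits.sum(axis=0)
        dh = dlogits @ wo.T
        dzh = dh * (h > 0)
        wd = self.params[pi]
        grads[pi] = flat.T @ dzh
        grads[pi + 1] = dzh.sum(axis=0)
        da = (dzh @ wd.T).reshape(cache["pool_shape"])
        for layer in range(len(cfg.conv_kernels) - 1, -1, -1):
            c = cache["conv"][layer]
            p = cfg.pool_sizes[layer]
            w = cfg.kernel_widths[layer]
            b_, length, ch = c["shape"]
            lp = length // p
            drelu = np.zeros((b_, lp, p, ch))
            np.put_along_axis(drelu, c["idx"][:, :, None, :], da[:, :, None, :], axis=2)
            drelu = drelu.reshape(b_, lp * p, ch)
            if lp * p < length:
                drelu = np.pad(drelu, ((0, 0), (0, length - lp * p), (0, 0)))
            dz = drelu * (c["z"] > 0)
            wi = 2 * layer
            wmat = self.params[wi]
            cols2d = c["cols"].reshape(-1, c["cols"].shape[2])
            dz2d = dz.reshape(-1, ch)
            grads[wi] = cols2d.T @ dz2d
            grads[wi + 1] = dz.sum(axis=(0, 1))
            dcols = (dz2d @ wmat.T).reshape(b_, length, w, -1)
            in_ch = dcols.shape[3]
            pl, pr = (w - 1) // 2, w // 2
            dxp = np.zeros((b_, length + pl + pr, in_ch))
            for j in range(w):
                dxp[:, j : j + length, :] += dcols[:, :, j, :]
            da = dxp[:, pl : pl + length, :]
        return grads

    def train_step(self, x, y, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8) -> float:
        prob, cache = self._forward(x, want_cache=True)
        p = np.clip(prob, 1e-12, 1.0 - 1e-12)
        loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
        grads = self._gradients(cache, prob, y)
        self._adam_t += 1
        t = self._adam_t
        for i, g in enumerate(grads):
            self._adam_m[i] = beta1 * self._adam_m[i] + (1 - beta1) * g
            self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g * g
            mhat = self._adam_m[i] / (1 - beta1**t)
            vhat = self._adam_v[i] / (1 - beta2**t)
            self.params[i] -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def loss(self, x, y) -> float:
        p = np.clip(self._forward(x), 1e-12, 1.0 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class TrainedScorer:
    """A trained sequence-to-activity function with its provenance manifest."""

    config: ModelConfig
    net: ConvNet
    training_manifest: dict = field(default_factory=dict)

    def score(self, sequence: str) -> float:
        """Activity probability; mean of forward and reverse-complement passes."""
        return float(self.score_batch([sequence])[0])

    def score_batch(self, sequences: Sequence[str]) -> np.ndarray:
        for s in sequences:
            if len(s) != self.config.input_len:
                raise ValueError(
                    f"sequence length {len(s)} != input_len {self.config.input_len}"
                )
        x = np.stack([one_hot(s) for s in sequences])
        fwd = self.net.predict(x)
        rev = self.net.predict(_rc_onehot(x))
        return (fwd + rev) / 2.0


def _auc_roc(labels: np.ndarray, scores: np.ndarray) -> float:
    """auROC via the rank-sum identity (ties handled by midranks)."""
    from scipy.stats import rankdata

    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for auROC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _auc_pr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Average precision (step-wise area under the PR curve)."""
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("positives required for auPRC")
    return float((precision * y).sum() / n_pos)


TEST_CHROMS = frozenset({"chr8", "chr9"})
VALIDATION_CHROMS = frozenset({"chr6"})


def _split(items, label):
    train, val, test = [], [], []
    for seq, chrom in items:
        if chrom in TEST_CHROMS:
            test.append((seq, label))
        elif chrom in VALIDATION_CHROMS:
            val.append((seq, label))
        else:
            train.append((seq, label))
    return train, val, test


def train(
    config: ModelConfig,
    positives: Sequence[tuple[str, str]],
    negatives: Sequence[tuple[str, str]],
    seed: int = 0,
    epochs: int = 20,
    batch_size: int = 64,
    lr: float = 1e-3,
    patience: int = 3,
) -> tuple[TrainedScorer, dict]:
    """Train the scorer with the chromosome split and report held-out metrics.

    ``positives``/``negatives`` are (sequence, chromosome) pairs. chr8/chr9
    form the test set, chr6 the validation set used for early stopping, and
    all other chromosomes train. Every training sequence is also presented
    as its reverse complement.
    """
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    tr_p, va_p, te_p = _split(positives, 1.0)
    tr_n, va_n, te_n = _split(negatives, 0.0)
    for name, part_p, part_n in (
        ("training", tr_p, tr_n),
        ("validation", va_p, va_n),
        ("test", te_p, te_n),
    ):
        if not part_p or not part_n:
            raise ValueError(
                f"{name} split is missing a class; check chromosome labels"
            )

    def encode_set(items, augment):
        seqs = [s for s, _ in items]
        y = np.array([lab for _, lab in items])
        x = np.stack([one_hot(s) for s in seqs])
        if augment:
            x = np.concatenate([x, _rc_onehot(x)])
            y = np.concatenate([y, y])
        return x, y

    x_tr, y_tr = encode_set(tr_p + tr_n, augment=True)
    x_va, y_va = encode_set(va_p + va_n, augment=False)
    x_te, y_te = encode_set(te_p + te_n, augment=False)

    rng = np.random.default_rng(seed)
    net = ConvNet(config, seed=seed)
    best_val = np.inf
    best_params = [p.copy() for p in net.params]
    stale = 0
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(y_tr))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            losses.append(net.train_step(x_tr[idx], y_tr[idx], lr=lr))
        val_loss = net.loss(x_va, y_va)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = [p.copy() for p in net.params]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    net.params = best_params

    scorer = TrainedScorer(
        config=config,
        net=net,
        training_manifest={
            "seed": seed,
            "epochs_run": len(history),
            "n_train": len(y_tr),
            "n_validation": len(y_va),
            "n_test": len(y_te),
            "test_chroms": sorted(TEST_CHROMS),
            "validation_chroms": sorted(VALIDATION_CHROMS),
        },
    )
    test_fwd = net.predict(x_te)
    test_rev = net.predict(_rc_onehot(x_te))
    test_scores = (test_fwd + test_rev) / 2.0
    metrics = {
        "auroc": _auc_roc(y_te, test_scores),
        "auprc": _auc_pr(y_te, test_scores),
        "best_val_loss": float(best_val),
        "history": history,
    }
    return scorer, metrics


def save_scorer(path, scorer: TrainedScorer) -> None:
    """Persist a trained scorer (self-describing: config JSON + weights)."""
    import json

    from dataclasses import asdict

    np.savez(
        path,
        config=json.dumps(asdict(scorer.config)),
        manifest=json.dumps(scorer.training_manifest, default=str),
        **{f"param_{i}": p for i, p in enumerate(scorer.net.params)},
    )


def load_scorer(path) -> TrainedScorer:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        manifest = json.loads(str(data["manifest"]))
        config = ModelConfig(
            input_len=cfg["input_len"],
            conv_kernels=tuple(cfg["conv_kernels"]),
            kernel_widths=tuple(cfg["kernel_widths"]),
            pool_sizes=tuple(cfg["pool_sizes"]),
            dense_units=cfg["dense_units"],
            output_units=cfg["output_units"],
        )
        net = ConvNet(config, seed=0)
        params = [data[f"param_{i}"] for i in range(len(net.params))]
    net.params = params
    return TrainedScorer(config=config, net=net, training_manifest=manifest)


def calibrate_threshold(
    negative_scores: Sequence[float], fpr: float = 0.1
) -> ScoreThreshold:
    """Smallest cutoff passing at most a ``fpr`` fraction of negatives.

    The threshold is the smallest candidate value t such that
    mean(negatives >= t) <= fpr; when ties make every observed score too
    permissive, the cutoff moves just above the largest score.
    """
    scores = np.asarray(list(negative_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("negative scores required for calibration")
    if scores.size < 10:
        raise ValueError("at least 10 negative scores required")
    srt = np.sort(scores)
    n = srt.size
    for cand in np.unique(srt):
        frac_ge = (n - np.searchsorted(srt, cand, side="left")) / n
        if frac_ge <= fpr:
            return ScoreThreshold(value=float(cand), fpr=fpr)
    return ScoreThreshold(value=float(np.nextafter(srt[-1], np.inf)), fpr=fpr)


def apply_edits(sequence: str, edits: Iterable[tuple[int, str]]) -> str:
    """Return ``sequence`` with (position, new_allele) substitutions applied."""
    chars = list(sequence)
    for pos, allele in edits:
        if not 0 <= pos < len(chars):
            raise IndexError(f"edit position {pos} out of range")
        if allele.upper() == chars[pos].upper():
            raise ValueError(
                f"edit at {pos} equals the reference allele {allele!r}"
            )
        chars[pos] = allele.upper()
    return "".join(chars)


def delta_score(scorer, base_seq: str, edits: Sequence[tuple[int, str]]) -> float:
    """Score change caused by introducing ``edits`` into ``base_seq``."""
    if not edits:
        return 0.0
    edited = apply_edits(base_seq, edits)
    return float(scorer.score(edited) - scorer.score(base_seq))


def allele_effect_accuracy(
    deltas: Sequence[float],
    observed_directions: Sequence[int],
    margins: Sequence[float],
):
    """Accuracy of sign(delta) against observed direction, by score margin.

    At margin m only pairs with |delta| >= m are scored; the returned frame
    reports accuracy (NaN when no pair qualifies) and the coverage fraction.
    """
    import pandas as pd

    d = np.asarray(deltas, dtype=float)
    y = np.asarray(observed_directions, dtype=int)
    if d.shape != y.shape:
        raise ValueError("deltas and observed_directions must align")
    rows = []
    for m in margins:
        mask = np.abs(d) >= m
        if mask.sum() == 0:
            rows.append({"margin": m, "accuracy": np.nan, "coverage": 0.0})
            continue
        acc = float((np.sign(d[mask]) == y[mask]).mean())
        rows.append(
            {"margin": m, "accuracy": acc, "coverage": float(mask.mean())}
        )
    return pd.DataFrame(rows)
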