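"""3D convolutional regressor: declaration, training, and ensembling.

The regressor maps a stacked [edge, edge, edge, 14] voxel block to a single
signed ddG value (kcal/mol).  Architecture (valid padding throughout):

    Conv3D(16, 3x3x3, ReLU) -> Conv3D(24) -> Conv3D(32) -> MaxPool(2x2x2)
    -> Flatten -> Dropout(0.5) -> Dense(24, ReLU) -> Dropout(0.5) -> Linear(1)

Training uses Adam (lr 0.001, beta1 0.9, beta2 0.999), mean-squared-error
loss, batches of eight, Glorot-uniform initialization, and early stopping
when the validation MSE has not improved for ten consecutive epochs; the
weights kept are those of the best validation epoch.  The full predictor is
an ensemble of ten members, one per held-out subset, whose predictions are
averaged.

The engine (forward/backward passes, Adam, dropout) is implemented directly
on NumPy arrays; the closed-form :func:`count_parameters` serves as an
independent check on every instantiated model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .datasets import MutationTable, split_subsets

KERNEL = 3
POOL = 2


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative architecture; defaults follow the published configuration."""

    input_shape: tuple[int, int, int, int] = (16, 16, 16, 14)
    conv_filters: tuple[int, int, int] = (16, 24, 32)
    dense_units: int = 24
    dropout_rate: float = 0.5

    def __post_init__(self):
        d, h, w, c = self.input_shape
        if not (d == h == w) or c < 1:
            raise ValueError(f"input must be cubic with >=1 channel, got {self.input_shape}")
        if any(f <= 0 for f in self.conv_filters) or self.dense_units <= 0:
            raise ValueError("layer widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.spatial_sizes()  # raises on underflow

    def spatial_sizes(self) -> list[int]:
        """Spatial edge after each conv layer and after pooling."""
        s = self.input_shape[0]
        sizes = []
        for i in range(len(self.conv_filters)):
            s -= KERNEL - 1
            if s < 1:
                raise ValueError(
                    f"feature map underflow: conv layer {i + 1} would output edge {s}"
                )
            sizes.append(s)
        if s < POOL:
            raise ValueError(f"feature map edge {s} too small for {POOL}^3 max pooling")
        sizes.append(s // POOL)
        return sizes

    @property
    def flattened(self) -> int:
        return self.spatial_sizes()[-1] ** 3 * self.conv_filters[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule constants; defaults are the published values."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 8
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def count_parameters(spec: NetworkSpec) -> int:
    """Closed-form trainable parameter count of the architecture.

    Per conv layer ``filters x (in_channels x 27 + 1)``; dense
    ``units x (flattened + 1)``; output head ``flattened_dense + 1``.
    The default spec gives 133,273.
    """
    k3 = KERNEL ** 3
    total = 0
    cin = spec.input_shape[3]
    for f in spec.conv_filters:
        total += f * (cin * k3 + 1)
        cin = f
    total += spec.dense_units * (spec.flattened + 1)
    total += spec.dense_units + 1
    return total


# -- layers ------------------------------------------------------------------

def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x: np.ndarray) -> np.ndarray:
    """[N,D,H,W,C] -> [N, P, 27*C] patch matrix (valid 3x3x3 windows)."""
    sw = sliding_window_view(x, (KERNEL, KERNEL, KERNEL), axis=(1, 2, 3))
    n, do, ho, wo, c = sw.shape[:5]
    col = np.ascontiguousarray(np.moveaxis(sw, 4, 7))  # [...,3,3,3,C]
    return col.reshape(n, do * ho * wo, KERNEL ** 3 * c), (do, ho, wo)


def _col2im(dcol: np.ndarray, x_shape) -> np.ndarray:
    """Fold patch-matrix gradients back onto the input tensor."""
    n, d, h, w, c = x_shape
    do, ho, wo = d - 2, h - 2, w - 2
    dcol = dcol.reshape(n, do, ho, wo, KERNEL, KERNEL, KERNEL, c)
    dx = np.zeros(x_shape, dtype=dcol.dtype)
    for i in range(KERNEL):
        for j in range(KERNEL):
            for k in range(KERNEL):
                dx[:, i:i + do, j:j + ho, k:k + wo, :] += dcol[:, :, :, :, i, j, k, :]
    return dx


class ConvNet3D:
    """NumPy implementation of the 3D-CNN regressor declared by a NetworkSpec."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = spec.input_shape[3]
        k3 = KERNEL ** 3
        for li, f in enumerate(spec.conv_filters):
            self.params[f"Wc{li}"] = _glorot_uniform(
                rng, (k3 * cin, f), fan_in=k3 * cin, fan_out=k3 * f
            )
            self.params[f"bc{li}"] = np.zeros(f, dtype=np.float32)
            cin = f
        flat = spec.flattened
        self.params["Wd"] = _glorot_uniform(
            rng, (flat, spec.dense_units), fan_in=flat, fan_out=spec.dense_units
        )
        self.params["bd"] = np.zeros(spec.dense_units, dtype=np.float32)
        self.params["Wo"] = _glorot_uniform(
            rng, (spec.dense_units, 1), fan_in=spec.dense_units, fan_out=1
        )
        self.params["bo"] = np.zeros(1, dtype=np.float32)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward -------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Predict; returns (predictions, cache) with cache for backprop."""
        spec = self.spec
        x = np.ascontiguousarray(x, dtype=np.float32)
        cache: dict = {"train": train}
        a = x
        for li in range(len(spec.conv_filters)):
            col, dims = _im2col(a)
            z = col @ self.params[f"Wc{li}"] + self.params[f"bc{li}"]
            relu_mask = z > 0
            z *= relu_mask
            cache[f"col{li}"] = col
            cache[f"mask{li}"] = relu_mask
            cache[f"in_shape{li}"] = a.shape
            a = z.reshape(a.shape[0], *dims, -1)
        # max pool 2x2x2 (floor), window argmax for exact gradient routing
        n, d, h, w, c = a.shape
        d2, h2, w2 = d // POOL, h // POOL, w // POOL
        a = a[:, : d2 * POOL, : h2 * POOL, : w2 * POOL, :]
        windows = a.reshape(n, d2, POOL, h2, POOL, w2, POOL, c)
        windows = np.moveaxis(windows, (2, 4, 6), (5, 6, 7)).reshape(
            n, d2, h2, w2, c, POOL ** 3
        )
        amax = windows.argmax(axis=-1)
        pooled = np.take_along_axis(windows, amax[..., None], axis=-1)[..., 0]
        cache["pool_argmax"] = amax
        cache["pool_in_shape"] = (n, d, h, w, c)
        flat = pooled.reshape(n, -1)
        if train and spec.dropout_rate > 0:
            keep = 1.0 - spec.dropout_rate
            m1 = (rng.random(flat.shape) < keep).astype(np.float32) / keep
            flat = flat * m1
            cache["drop1"] = m1
        zd = flat @ self.params["Wd"] + self.params["bd"]
        dmask = zd > 0
        hd = zd * dmask
        if train and spec.dropout_rate > 0:
            keep = 1.0 - spec.dropout_rate
            m2 = (rng.random(hd.shape) < keep).astype(np.float32) / keep
            hd = hd * m2
            cache["drop2"] = m2
        cache["flat"] = flat
        cache["dmask"] = dmask
        cache["hd"] = hd
        out = hd @ self.params["Wo"] + self.params["bo"]
        return out[:, 0], cache

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic inference (dropout disabled)."""
        preds = []
        for i in range(0, len(x), batch_size):
            preds.append(self.forward(x[i:i + batch_size], train=False)[0])
        return np.concatenate(preds)

    # -- backward ------------------------------------------------------------

    def backward(self, dout: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        spec = self.spec
        grads: dict[str, np.ndarray] = {}
        dout = dout[:, None].astype(np.float32)
        grads["Wo"] = cache["hd"].T @ dout
        grads["bo"] = dout.sum(axis=0)
        dhd = dout @ self.params["Wo"].T
        if "drop2" in cache:
            dhd = dhd * cache["drop2"]
        dzd = dhd * cache["dmask"]
        grads["Wd"] = cache["flat"].T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        if "drop1" in cache:
            dflat = dflat * cache["drop1"]
        # un-pool
        n, d, h, w, c = cache["pool_in_shape"]
        d2, h2, w2 = d // POOL, h // POOL, w // POOL
        dpooled = dflat.reshape(n, d2, h2, w2, c)
        dwin = np.zeros((n, d2, h2, w2, c, POOL ** 3), dtype=np.float32)
        np.put_along_axis(dwin, cache["pool_argmax"][..., None], dpooled[..., None], axis=-1)
        dwin = dwin.reshape(n, d2, h2, w2, c, POOL, POOL, POOL)
        dwin = np.moveaxis(dwin, (5, 6, 7), (2, 4, 6))
        da = np.zeros((n, d, h, w, c), dtype=np.float32)
        da[:, : d2 * POOL, : h2 * POOL, : w2 * POOL, :] = dwin.reshape(
            n, d2 * POOL, h2 * POOL, w2 * POOL, c
        )
        for li in reversed(range(len(spec.conv_filters))):
            dz = da.reshape(da.shape[0], -1, da.shape[-1])
            dz = dz * cache[f"mask{li}"].reshape(dz.shape)
            col = cache[f"col{li}"]
            w_key = f"Wc{li}"
            grads[w_key] = (
                col.reshape(-1, col.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
            )
            grads[f"bc{li}"] = dz.sum(axis=(0, 1))
            dcol = dz @ self.params[w_key].T
            da = _col2im(dcol, cache[f"in_shape{li}"])
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]):
        self.params = {k: v.copy() for k, v in params.items()}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.cfg = config
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        cfg = self.cfg
        self.t += 1
        bc1 = 1.0 - cfg.beta1 ** self.t
        bc2 = 1.0 - cfg.beta2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = cfg.beta1 * self.m[k] + (1 - cfg.beta1) * g
            self.v[k] = cfg.beta2 * self.v[k] + (1 - cfg.beta2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.epsilon)


@dataclass
class TrainedModel:
    model: ConvNet3D
    history: dict = field(default_factory=dict)

    @property
    def best_epoch(self) -> int:
        return self.history["best_epoch"]

    @property
    def best_val_mse(self) -> float:
        return self.history["best_val_mse"]


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def train_member(train_x: np.ndarray, train_y: np.ndarray,
                 val_x: np.ndarray, val_y: np.ndarray,
                 spec: NetworkSpec | None = None,
                 config: TrainConfig | None = None) -> TrainedModel:
    """Train one network member with Adam, MSE loss, and early stopping.

    Stops once the validation MSE has not improved for ``config.patience``
    consecutive epochs; the returned weights are those of the epoch with the
    lowest validation MSE.  Fully deterministic in ``config.seed``.
    """
    if spec is None:
        spec = NetworkSpec(input_shape=train_x.shape[1:])
    if config is None:
        config = TrainConfig()
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("training and validation sets must be non-empty")
    ss = np.random.SeedSequence(config.seed)
    init_seed, shuffle_seed, drop_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )
    model = ConvNet3D(spec, seed=init_seed)
    opt = _Adam(model.params, config)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    drop_rng = np.random.default_rng(drop_seed)
    train_x = np.ascontiguousarray(train_x, dtype=np.float32)
    val_x = np.ascontiguousarray(val_x, dtype=np.float32)
    train_y = np.asarray(train_y, dtype=np.float32)
    val_y = np.asarray(val_y, dtype=np.float32)

    history = {"train_mse": [], "val_mse": []}
    best_val = np.inf
    best_params = model.copy_params()
    best_epoch = 0
    since_best = 0
    n = len(train_x)
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = train_x[idx], train_y[idx]
            pred, cache = model.forward(xb, train=True, rng=drop_rng)
            loss = _mse(pred, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"pred range [{pred.min()}, {pred.max()}]"
                )
            epoch_losses.append(loss)
            dout = 2.0 * (pred - yb) / len(yb)
            grads = model.backward(dout, cache)
            opt.step(model.params, grads)
        val_mse = _mse(model.predict(val_x), val_y)
        history["train_mse"].append(float(np.mean(epoch_losses)))
        history["val_mse"].append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_params = model.copy_params()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_params(best_params)
    history["best_epoch"] = best_epoch
    history["best_val_mse"] = float(best_val)
    history["stopped_epoch"] = epoch
    history["config"] = config.to_dict()
    return TrainedModel(model=model, history=history)


@dataclass
class ModelEnsemble:
    """k trained members, one per held-out validation subset."""

    members: list[TrainedModel]
    val_subsets: list[list[int]]
    spec: NetworkSpec

    @property
    def best_val_mses(self) -> list[float]:
        return [m.best_val_mse for m in self.members]


def train_ensemble(table: MutationTable, grids: np.ndarray,
                   spec: NetworkSpec | None = None,
                   config: TrainConfig | None = None,
                   k: int = 10) -> ModelEnsemble:
    """Train the k-member ensemble over a paired subset split.

    Member ``i`` is validated on subset ``i`` and trained on the remaining
    subsets; labels are taken from the table's ddG column, grids from the
    aligned ``grids`` array.  Per-member seeds derive from ``config.seed``.
    """
    if config is None:
        config = TrainConfig()
    if len(table) != len(grids):
        raise ValueError("table and grid array lengths differ")
    if spec is None:
        spec = NetworkSpec(input_shape=grids.shape[1:])
    labels = np.array([r.ddg for r in table], dtype=np.float64)
    if np.any(np.isnan(labels)):
        raise ValueError("all records need ddG labels for training")
    subsets = split_subsets(table, k=k, seed=config.seed)
    member_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(config.seed).spawn(k)
    ]
    members = []
    for i in range(k):
        val_idx = np.array(subsets[i], dtype=int)
        train_idx = np.array(sorted(set(range(len(table))) - set(subsets[i])), dtype=int)
        member_cfg = TrainConfig(**{**config.to_dict(), "seed": member_seeds[i]})
        members.append(train_member(
            grids[train_idx], labels[train_idx],
            grids[val_idx], labels[val_idx],
            spec=spec, config=member_cfg,
        ))
    return ModelEnsemble(members=members, val_subsets=subsets, spec=spec)


def predict_ensemble(ensemble: ModelEnsemble, tensors: np.ndarray) -> np.ndarray:
    """Unweighted mean of member predictions, in kcal/mol."""
    tensors = np.asarray(tensors, dtype=np.float32)
    if tensors.shape[1:] != tuple(ensemble.spec.input_shape):
        raise ValueError(
            f"input shape {tensors.shape[1:]} does not match "
            f"spec {ensemble.spec.input_shape}"
        )
    preds = np.stack([m.model.predict(tensors) for m in ensemble.members])
    return preds.mean(axis=0)


# -- persistence -------------------------------------------------------------

def save_ensemble(ensemble: ModelEnsemble, directory):
    """Write member weights (npz) plus a JSON sidecar of spec and metrics."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(ensemble.members):
        np.savez(directory / f"member_{i:02d}.npz", **member.model.params)
    sidecar = {
        "spec": {
            "input_shape": list(ensemble.spec.input_shape),
            "conv_filters": list(ensemble.spec.conv_filters),
            "dense_units": ensemble.spec.dense_units,
            "dropout_rate": ensemble.spec.dropout_rate,
        },
        "val_subsets": ensemble.val_subsets,
        "histories": [
            {k: v for k, v in m.history.items() if k != "config"}
            for m in ensemble.members
        ],
        "configs": [m.history.get("config") for m in ensemble.members],
    }
    (directory / "ensemble.json").write_text(json.dumps(sidecar, indent=2))


def load_ensemble(directory) -> ModelEnsemble:
    from pathlib import Path

    directory = Path(directory)
    sidecar = json.loads((directory / "ensemble.json").read_text())
    spec = NetworkSpec(
        input_shape=tuple(sidecar["spec"]["input_shape"]),
        conv_filters=tuple(sidecar["spec"]["conv_filters"]),
        dense_units=sidecar["spec"]["dense_units"],
        dropout_rate=sidecar["spec"]["dropout_rate"],
    )
    members = []
    for i, history in enumerate(sidecar["histories"]):
        model = ConvNet3D(spec, seed=0)
        with np.load(directory / f"member_{i:02d}.npz") as data:
            model.params = {k: data[k].copy() for k in data.files}
        members.append(TrainedModel(model=model, history=dict(history)))
    return ModelEnsemble(members=members, val_subsets=sidecar["val_subsets"], spec=spec)
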