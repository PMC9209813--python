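"""Training protocol and repeated cross-validated evaluation.

Networks are trained with Adam on the composite MAE + 0.001 * FMAE loss for
a fixed number of epochs (no early stopping), batch size 2, initial learning
rate 1e-3, halving the rate after a patience of epochs without improvement
of the validation loss (floor 1e-6).  Model comparison uses repeated random
resplitting: the corpus is split 90:5:5 into train/validation/test ``k``
times, each repeat training fresh networks and evaluating on its own test
split; metrics are aggregated over all repeats' test images.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .datasets import PairedDataset
from .nets import NetConfig, UNet, build_network
from .nn import Adam, ReduceLROnPlateau
from .objective import LossWeights, MetricsReport, composite_grad, composite_loss, evaluate

__all__ = [
    "TrainConfig",
    "split_dataset",
    "train",
    "predict",
    "evaluate_network",
    "cross_validate",
    "full_scale_protocol",
]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.001
    lr_factor: float = 0.5
    lr_patience: int = 5
    epochs: int = 100
    batch_size: int = 2
    split: tuple[int, int, int] = (90, 5, 5)
    seed: int = 0
    k_repeats: int = 10
    min_lr: float = 1e-6
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if sum(self.split) != 100:
            raise ValueError("split ratios must sum to 100")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid batch size / epoch count")


def split_dataset(
    n: int, ratios: tuple[int, int, int] = (90, 5, 5), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test index sets covering 0..n-1.

    Sizes are round(r_train*n) and round(r_val*n); the test set takes the
    remainder, so the three sets always partition the indices.
    """
    if sum(ratios) != 100:
        raise ValueError("split ratios must sum to 100")
    if n < 20:
        raise ValueError("need at least 20 samples to split 90:5:5 meaningfully")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratios[0] / 100.0 * n))
    n_val = int(round(ratios[1] / 100.0 * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _to_batch(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x[:, None], dtype=np.float32)


def predict(network: UNet, x: np.ndarray, batch_size: int = 4) -> np.ndarray:
    """Run the network over an (n, H, W) stack in inference mode."""
    was_training = network.training
    network.eval()
    outs = []
    for k in range(0, x.shape[0], batch_size):
        outs.append(network(_to_batch(x[k : k + batch_size]))[:, 0])
    network.train(was_training)
    return np.concatenate(outs, axis=0).astype(np.float64)


def _set_loss(network: UNet, x, y, weights: LossWeights, batch_size: int) -> float:
    yp = predict(network, x, batch_size)
    return float(np.mean([composite_loss(yg, pp, weights) for yg, pp in zip(y, yp)]))


def train(
    network: UNet,
    dataset: PairedDataset,
    config: TrainConfig = TrainConfig(),
    val: PairedDataset | None = None,
    progress: bool = False,
) -> tuple[UNet, dict]:
    """Optimize ``network`` on ``dataset``; returns (network, history).

    History records per-epoch mean training loss, validation loss (when a
    validation set is given; otherwise the training loss is monitored for
    the plateau schedule) and the learning rate in force.
    """
    if len(dataset) == 0:
        raise ValueError("empty training set")
    opt = Adam(network.parameters(), lr=config.initial_lr)
    sched = ReduceLROnPlateau(opt, config.lr_factor, config.lr_patience, config.min_lr)
    rng = np.random.default_rng(config.seed)
    history: dict = {"train_loss": [], "val_loss": [], "lr": []}
    w = config.loss_weights
    epochs = range(config.epochs)
    if progress:
        from tqdm import tqdm

        epochs = tqdm(epochs, desc="epochs")
    for _ in epochs:
        network.train()
        order = rng.permutation(len(dataset))
        losses = []
        for k in range(0, len(order), config.batch_size):
            idx = order[k : k + config.batch_size]
            xb = _to_batch(dataset.x[idx])
            yb = dataset.y[idx]
            yp = network(xb)
            batch_losses = [
                composite_loss(yg, pp.astype(np.float64), w)
                for yg, pp in zip(yb, yp[:, 0])
            ]
            loss = float(np.mean(batch_losses))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss} at step {len(losses)}; aborting"
                )
            losses.append(loss)
            grad = np.stack(
                [composite_grad(yg, pp.astype(np.float64), w) for yg, pp in zip(yb, yp[:, 0])]
            )[:, None]
            network.zero_grad()
            network.backward((grad / len(idx)).astype(np.float32))
            opt.step()
        train_loss = float(np.mean(losses))
        if val is not None and len(val):
            monitored = _set_loss(network, val.x, val.y, w, config.batch_size)
            history["val_loss"].append(monitored)
        else:
            monitored = train_loss
            history["val_loss"].append(float("nan"))
        history["train_loss"].append(train_loss)
        history["lr"].append(opt.lr)
        sched.step(monitored)
    return network, history


def evaluate_network(network: UNet, dataset: PairedDataset, batch_size: int = 4) -> MetricsReport:
    """Metrics of network predictions against ground truth on a dataset."""
    yp = np.clip(predict(network, dataset.x, batch_size), 0.0, None)
    return evaluate(dataset.y, yp)


def cross_validate(
    dataset: PairedDataset,
    net_variants: dict[str, NetConfig],
    config: TrainConfig = TrainConfig(),
    progress: bool = False,
) -> dict[str, MetricsReport]:
    """Repeated random-resplit evaluation of several architectures.

    For each of ``config.k_repeats`` repeats the corpus is freshly split
    90:5:5, one fresh network per variant is trained on the repeat's
    training split and evaluated on its test split.  Per-image metrics are
    pooled across repeats and summarized as mean +/- std per variant.
    """
    if config.k_repeats < 2:
        raise ValueError("need k_repeats >= 2 for a std estimate")
    ss = np.random.SeedSequence(config.seed)
    pooled: dict[str, dict[str, list]] = {v: {"yg": [], "yp": []} for v in net_variants}
    for rep in range(config.k_repeats):
        rep_seed = int(ss.spawn(1)[0].generate_state(1)[0] >> 1)
        tr, va, te = split_dataset(len(dataset), config.split, seed=rep_seed)
        assert not (set(tr) & set(te)) and not (set(va) & set(te))  # no leakage
        d_tr, d_va, d_te = dataset.subset(tr), dataset.subset(va), dataset.subset(te)
        for name, net_cfg in net_variants.items():
            name_tag = zlib.crc32(name.encode())  # stable across processes
            net = build_network(
                NetConfig(**{**net_cfg.__dict__, "seed": (rep_seed ^ name_tag) & 0x7FFFFFFF})
            )
            rep_cfg = TrainConfig(**{**config.__dict__, "seed": rep_seed})
            net, _ = train(net, d_tr, rep_cfg, val=d_va, progress=False)
            yp = np.clip(predict(net, d_te.x, config.batch_size), 0.0, None)
            pooled[name]["yg"].append(d_te.y)
            pooled[name]["yp"].append(yp)
        if progress:
            print(f"repeat {rep + 1}/{config.k_repeats} done")
    return {
        name: evaluate(np.concatenate(d["yg"]), np.concatenate(d["yp"]))
        for name, d in pooled.items()
    }


def metrics_table(reports: dict[str, MetricsReport]) -> str:
    """Tab-separated comparison table (one row per architecture)."""
    lines = ["Network\tPCC\tPSNR\tSSIM\tMAE"]
    for name, rep in reports.items():
        lines.append(rep.row(name))
    return "\n".join(lines)


def full_scale_protocol(preset_name: str = "1ust") -> dict:
    """The full-scale experiment configuration (not desk-scale).

    1500 pairs (1-UST) or 500 (8-UST), fi=32 networks, 100 epochs, batch 2,
    10 random resplits, all four variants.  Returned as a configuration
    contract; running it is an explicit, long offline computation.
    """
    from .grid import get_preset

    preset = get_preset(preset_name)
    return {
        "preset": preset_name,
        "n_pairs": preset.n_phantoms,
        "variants": {
            v: NetConfig(variant=v, fi=32, strict_shape=True) for v in ("hd", "fd", "dd", "vanilla")
        },
        "train": TrainConfig(epochs=100, batch_size=2, k_repeats=10),
    }
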