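"""End-to-end orchestration: phantoms -> scans -> pairs -> training -> report.

``run_pipeline`` reproduces, at the configured scale, the complete
experiment: generate a paired dataset for the chosen preset, train the
requested network variants under repeated resplitting, and write a
four-metric comparison table plus side-by-side sparse/restored/ground-truth
image panels.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .datasets import generate_dataset
from .grid import get_preset
from .io import RunConfig, save_checkpoint, save_config, save_dataset
from .nets import NetConfig, build_network
from .train_eval import (
    TrainConfig,
    cross_validate,
    full_scale_protocol,
    metrics_table,
    predict,
    split_dataset,
    train,
)

log = logging.getLogger("patkit")

__all__ = ["run_pipeline"]


def _save_panels(path: Path, x, yp, yg, n_show: int = 3) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_show = min(n_show, x.shape[0])
    fig, axes = plt.subplots(n_show, 3, figsize=(7.5, 2.6 * n_show), squeeze=False)
    for i in range(n_show):
        for j, (img, title) in enumerate(
            [(x[i], "sparse input"), (yp[i], "network output"), (yg[i], "ground truth")]
        ):
            ax = axes[i][j]
            ax.imshow(img, cmap="hot", vmin=0, vmax=1)
            ax.set_axis_off()
            if i == 0:
                ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, progress: bool = False) -> dict:
    """Run the full experiment; returns the metrics reports per variant."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(outdir / "config.yaml", config)

    if config.scale == "full":
        proto = full_scale_protocol(config.preset)
        n_pairs = proto["n_pairs"]
        net_variants = {v: proto["variants"][v] for v in config.variants}
        train_cfg = TrainConfig(
            epochs=proto["train"].epochs,
            batch_size=proto["train"].batch_size,
            k_repeats=proto["train"].k_repeats,
            seed=config.seed,
        )
    else:
        n_pairs = config.n_pairs
        net_variants = {
            v: NetConfig(variant=v, fi=config.fi) for v in config.variants
        }
        train_cfg = TrainConfig(
            epochs=config.epochs,
            batch_size=config.batch_size,
            k_repeats=config.repeats,
            seed=config.seed,
        )

    preset = get_preset(config.preset)
    log.info("generating %d pairs for preset %s", n_pairs, preset.name)
    dataset = generate_dataset(preset, n_pairs, seed=config.seed, progress=progress)
    save_dataset(outdir / "dataset.h5", dataset)

    log.info("cross-validating variants %s", list(net_variants))
    reports = cross_validate(dataset, net_variants, train_cfg, progress=progress)

    table = metrics_table(reports)
    (outdir / "metrics.tsv").write_text(table + "\n")
    (outdir / "metrics.json").write_text(
        json.dumps(
            {
                "reports": {k: r.to_dict() for k, r in reports.items()},
                "seed": config.seed,
                "preset": config.preset,
                "n_pairs": n_pairs,
                "train": {
                    "epochs": train_cfg.epochs,
                    "batch_size": train_cfg.batch_size,
                    "k_repeats": train_cfg.k_repeats,
                    "psnr_convention": "data_range=1",
                },
            },
            indent=2,
        )
    )
    log.info("metrics table:\n%s", table)

    # one representative trained model + image panels from a final split
    tr, va, te = split_dataset(len(dataset), seed=config.seed)
    first = next(iter(net_variants))
    net = build_network(net_variants[first])
    net, _ = train(net, dataset.subset(tr), train_cfg, val=dataset.subset(va), progress=progress)
    save_checkpoint(outdir / f"{first}.npz", net)
    x_te = dataset.x[te]
    yp = np.clip(predict(net, x_te), 0.0, None)
    _save_panels(outdir / "panels.png", x_te, yp, dataset.y[te])
    return reports
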