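"""Paired (sparse input, dense ground truth) dataset generation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import RECON_SIZE, Preset
from .phantoms import FAMILIES, gen_phantom
from .recon import make_pair

__all__ = ["PairedDataset", "generate_dataset"]


@dataclass
class PairedDataset:
    """Stacks of input images ``x`` and ground-truth images ``y`` plus
    provenance metadata (preset name, seed, phantom families)."""

    x: np.ndarray  # (n, 128, 128)
    y: np.ndarray  # (n, 128, 128)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape or self.x.ndim != 3:
            raise ValueError("x and y must be matching (n, H, W) stacks")

    def __len__(self) -> int:
        return self.x.shape[0]

    def subset(self, idx: np.ndarray) -> "PairedDataset":
        return PairedDataset(self.x[idx], self.y[idx], dict(self.meta))


def _families_for(preset: Preset) -> tuple[str, ...]:
    # the 8-UST corpus is vessel-only; the 1-UST corpus cycles all families
    return ("vessel",) if preset.name == "8ust" else FAMILIES


def generate_dataset(
    preset: Preset,
    n: int,
    seed: int,
    families: tuple[str, ...] | None = None,
    progress: bool = False,
) -> PairedDataset:
    """Generate ``n`` training pairs for a preset, cycling phantom families.

    Each pair gets independent child seeds for the phantom and for the scan
    randomness (input scan time, SNR draw, noise), all derived from ``seed``.
    """
    if families is None:
        families = _families_for(preset)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    xs = np.empty((n, RECON_SIZE, RECON_SIZE))
    ys = np.empty_like(xs)
    iterator = range(n)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc=f"{preset.name} pairs")
    for i in iterator:
        s1, s2 = children[i].generate_state(2) >> 1  # keep below 2**31
        phantom = gen_phantom(families[i % len(families)], preset.grid, int(s1))
        x, y = make_pair(phantom, preset, int(s2), dtype=np.float32)
        xs[i] = x.values
        ys[i] = y.values
    return PairedDataset(
        xs, ys, {"preset": preset.name, "seed": int(seed), "families": list(families)}
    )
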