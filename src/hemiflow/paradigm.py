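"""Block-design task paradigm on a TR grid.

A paradigm alternates sustained task and control epochs (here modelled
after a semantic-judgment block design: 30 s blocks at TR = 3 s, with
dummy scans discarded before the retained run starts).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TASK = "task"
CONTROL = "control"


@dataclass(frozen=True)
class BlockParadigm:
    """Timing of an alternating two-condition block design.

    Attributes
    ----------
    tr_s : float
        Repetition time in seconds.
    n_volumes : int
        Number of retained volumes (dummy scans already discarded).
    condition_labels : tuple of str
        Per-volume condition, each ``"task"`` or ``"control"``.
    onsets : dict
        Condition -> tuple of block onset times in seconds, on the
        retained-run clock (t = 0 is the first retained volume).
    block_duration_s : float
        Duration of one block in seconds.
    n_dummy : int
        Dummy volumes acquired before the retained run (metadata only).
    """

    tr_s: float
    n_volumes: int
    condition_labels: tuple
    onsets: dict
    block_duration_s: float
    n_dummy: int = 0

    def __post_init__(self):
        if len(self.condition_labels) != self.n_volumes:
            raise ValueError(
                f"{len(self.condition_labels)} labels for {self.n_volumes} volumes"
            )
        bad = set(self.condition_labels) - {TASK, CONTROL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each retained volume in seconds."""
        return np.arange(self.n_volumes) * self.tr_s

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def boxcar(self, condition: str = TASK) -> np.ndarray:
        """0/1 indicator of ``condition`` per retained volume."""
        if condition not in (TASK, CONTROL):
            raise ValueError(f"unknown condition {condition!r}")
        return np.asarray(
            [1.0 if c == condition else 0.0 for c in self.condition_labels]
        )


def build_paradigm(
    n_blocks_per_condition: int,
    block_duration_s: float,
    tr_s: float,
    n_dummy: int = 0,
) -> BlockParadigm:
    """Construct an alternating task/control block paradigm.

    Blocks strictly alternate starting with a task block.  Volumes
    acquired during the ``n_dummy`` dummy scans are excluded; the
    retained run therefore has ``2 * n_blocks_per_condition *
    block_duration_s / tr_s`` volumes and its clock starts at the first
    retained volume.

    Raises
    ------
    ValueError
        If the block duration is not an integer multiple of the TR, or
        any argument is non-positive (``n_dummy`` may be zero).
    """
    if n_blocks_per_condition <= 0 or block_duration_s <= 0 or tr_s <= 0:
        raise ValueError("block count, block duration and TR must be positive")
    if n_dummy < 0:
        raise ValueError("n_dummy must be >= 0")
    vols_per_block = block_duration_s / tr_s
    if abs(vols_per_block - round(vols_per_block)) > 1e-9:
        raise ValueError(
            f"block duration {block_duration_s} s is not divisible by TR {tr_s} s"
        )
    vols_per_block = int(round(vols_per_block))
    labels = []
    onsets = {TASK: [], CONTROL: []}
    t = 0.0
    for b in range(2 * n_blocks_per_condition):
        cond = TASK if b % 2 == 0 else CONTROL
        onsets[cond].append(t)
        labels.extend([cond] * vols_per_block)
        t += block_duration_s
    return BlockParadigm(
        tr_s=float(tr_s),
        n_volumes=len(labels),
        condition_labels=tuple(labels),
        onsets={k: tuple(v) for k, v in onsets.items()},
        block_duration_s=float(block_duration_s),
        n_dummy=int(n_dummy),
    )
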