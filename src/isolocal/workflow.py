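"""One-seed replicates of the full study workflow.

A replicate generates a 116-sample synthetic library at the study
conditions, splits it 93/23 by banner strata, and scores the five
classifiers under the three modeling regimes — global (all 93 training
samples), AKS subset, and per-test-sample local FD windows.  A single master
seed fans out deterministically to the generator, the split and every
stochastic classifier, so a replicate is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import METHODS, default_specs, run_aks, run_global
from .data import stratified_split
from .evaluate import ConfusionMatrix, metrics
from .local_fd import run_local_fd
from .synthetic import full_config, generate_library

__all__ = ["derive_seeds", "ReplicateResult", "replicate"]


def derive_seeds(seed: int, *stages: str) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(stages))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(stages, children)}


@dataclass
class ReplicateResult:
    seed: int
    matrices: dict[str, dict[str, ConfusionMatrix]]  # mode -> method -> cm
    chosen_n: int
    local_sizes: list[int]

    def accuracy(self, mode: str, method: str) -> float:
        return metrics(self.matrices[mode][method]).accuracy


def replicate(
    seed: int,
    methods: tuple[str, ...] = METHODS,
    pc: int = 2,
    test_fraction: float = 0.2,
) -> ReplicateResult:
    """Run global, AKS and local-FD modeling on one synthetic 93/23 split."""
    seeds = derive_seeds(seed, "library", "split", "classifiers")
    library = generate_library(full_config(seeds["library"]), label=f"synthetic-{seed}")
    split = stratified_split(library, test_fraction=test_fraction, seed=seeds["split"])
    specs = default_specs(seed=seeds["classifiers"], methods=methods)

    matrices = {"global": run_global(split.training, split.testing, specs)}
    matrices["aks"], selection = run_aks(split.training, split.testing, specs, pc=pc)
    matrices["local_fd"], subsets = run_local_fd(
        split.training, split.testing, specs, pc=pc
    )
    return ReplicateResult(
        seed=seed,
        matrices=matrices,
        chosen_n=selection.chosen_n,
        local_sizes=[len(s.subset) for s in subsets],
    )
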