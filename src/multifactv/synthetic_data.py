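"""Planted-module benchmark tensors.

Each synthetic tensor holds K planted modules: a gene set x condition
set x *consecutive* time interval, filled with i.i.d. Uniform(0.6, 1.0)
signal over a zero background.  A fraction ``noise_density`` of all
tensor cells is then overwritten with draws from the same distribution,
emulating sparse spurious interactions.  The full-scale benchmark uses
400 genes x 400 conditions x 50 time points, 40 genes and 40 conditions
per module, 10-point intervals, and densities 0.005 / 0.01 / 0.02.

Gene and condition sets are disjoint across modules by default (overlap
is available via ``disjoint=False``); time intervals are drawn
independently per module and may overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tensor_core import InteractionTensor


@dataclass
class PlantedModuleSpec:
    """Ground-truth description of one planted module (0-based indices)."""

    gene_indices: set[int]
    condition_indices: set[int]
    time_start: int  # inclusive
    time_end: int  # inclusive
    signal_low: float = 0.6
    signal_high: float = 1.0

    def __post_init__(self) -> None:
        if self.time_start > self.time_end:
            raise ValueError("time_start must be <= time_end")

    @property
    def time_indices(self) -> set[int]:
        return set(range(self.time_start, self.time_end + 1))

    def to_dict(self) -> dict:
        return {
            "gene_indices": sorted(self.gene_indices),
            "condition_indices": sorted(self.condition_indices),
            "time_start": self.time_start,
            "time_end": self.time_end,
            "signal_low": self.signal_low,
            "signal_high": self.signal_high,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedModuleSpec":
        return cls(
            set(d["gene_indices"]),
            set(d["condition_indices"]),
            int(d["time_start"]),
            int(d["time_end"]),
            float(d.get("signal_low", 0.6)),
            float(d.get("signal_high", 1.0)),
        )


@dataclass
class GroundTruth:
    modules: list[PlantedModuleSpec]
    noise_density: float
    seed: int | None = None
    dims: tuple[int, int, int] = field(default=(0, 0, 0))

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_density <= 1.0:
            raise ValueError(f"noise_density must lie in [0, 1], got {self.noise_density}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "modules": [m.to_dict() for m in self.modules],
                "noise_density": self.noise_density,
                "seed": self.seed,
                "dims": list(self.dims),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            [PlantedModuleSpec.from_dict(m) for m in d["modules"]],
            float(d["noise_density"]),
            d.get("seed"),
            tuple(d.get("dims", (0, 0, 0))),  # type: ignore[arg-type]
        )


def generate_planted_tensor(
    n1: int = 400,
    n2: int = 400,
    n3: int = 50,
    K: int = 3,
    genes_per_module: int = 40,
    conditions_per_module: int = 40,
    interval_length: int = 10,
    noise_density: float = 0.0,
    seed: int | None = None,
    signal_low: float = 0.6,
    signal_high: float = 1.0,
    disjoint: bool = True,
    time_placement: str = "auto",
    gaussian_noise_sd: float = 0.0,
) -> tuple[InteractionTensor, GroundTruth]:
    """Generate a benchmark tensor with K planted modules and its truth record.

    With ``disjoint=True`` the K gene sets (and condition sets) are
    sampled without replacement from disjoint pools; an infeasible
    request raises.  ``time_placement`` controls the module intervals:
    ``"disjoint"`` places them without overlap (raises when
    ``K * interval_length > n3``), ``"random"`` draws starts
    independently, and ``"auto"`` (default) uses disjoint placement
    whenever it fits and random starts otherwise.  ``gaussian_noise_sd
    > 0`` additionally adds dense N(0, sd^2) noise on top of the sparse
    overwrite corruption.
    """
    if interval_length < 1 or interval_length > n3:
        raise ValueError("interval_length must lie in [1, n3]")
    if time_placement not in ("auto", "disjoint", "random"):
        raise ValueError(f"unknown time_placement {time_placement!r}")
    times_fit = K * interval_length <= n3
    if time_placement == "disjoint" and not times_fit:
        raise ValueError(
            f"cannot place {K} disjoint intervals of length {interval_length} in {n3} time points"
        )
    disjoint_times = times_fit if time_placement == "auto" else time_placement == "disjoint"
    if disjoint and (K * genes_per_module > n1 or K * conditions_per_module > n2):
        raise ValueError(
            f"cannot place {K} disjoint modules of {genes_per_module} genes x "
            f"{conditions_per_module} conditions in a {n1} x {n2} tensor"
        )
    rng = np.random.default_rng(seed)
    a = np.zeros((n1, n2, n3))

    gene_pool = rng.permutation(n1)
    cond_pool = rng.permutation(n2)
    if disjoint_times:
        # partition the time axis into K disjoint interval slots at random
        # offsets: shuffle slot order, then spread the slack between slots
        slack = n3 - K * interval_length
        cuts = np.sort(rng.integers(0, slack + 1, size=K)) if slack > 0 else np.zeros(K, int)
        starts = rng.permutation(cuts + np.arange(K) * interval_length)
    modules: list[PlantedModuleSpec] = []
    for k in range(K):
        if disjoint:
            genes = gene_pool[k * genes_per_module : (k + 1) * genes_per_module]
            conds = cond_pool[k * conditions_per_module : (k + 1) * conditions_per_module]
        else:
            genes = rng.choice(n1, size=genes_per_module, replace=False)
            conds = rng.choice(n2, size=conditions_per_module, replace=False)
        if disjoint_times:
            start = int(starts[k])
        else:
            start = int(rng.integers(0, n3 - interval_length + 1))
        end = start + interval_length - 1
        block = rng.uniform(
            signal_low, signal_high, size=(genes.size, conds.size, interval_length)
        )
        a[np.ix_(genes, conds, np.arange(start, end + 1))] = block
        modules.append(
            PlantedModuleSpec(
                set(int(g) for g in genes),
                set(int(c) for c in conds),
                start,
                end,
                signal_low,
                signal_high,
            )
        )

    if noise_density > 0:
        n_cells = n1 * n2 * n3
        n_noise = int(round(noise_density * n_cells))
        flat_idx = rng.choice(n_cells, size=n_noise, replace=False)
        a.ravel()[flat_idx] = rng.uniform(signal_low, signal_high, size=n_noise)
    if gaussian_noise_sd > 0:
        a += rng.normal(0.0, gaussian_noise_sd, size=a.shape)

    labels = (
        [f"g{r}" for r in range(n1)],
        [f"c{s}" for s in range(n2)],
        [f"t{t}" for t in range(n3)],
    )
    tensor = InteractionTensor(a, labels)
    truth = GroundTruth(modules, noise_density, seed, (n1, n2, n3))
    return tensor, truth


def truth_modules_as_label_sets(
    truth: GroundTruth, labels: tuple[list[str], list[str], list[str]]
) -> list[dict[str, set[str]]]:
    """Map the truth's index sets onto axis labels, one dict per module."""
    out = []
    for m in truth.modules:
        out.append(
            {
                "genes": {labels[0][i] for i in m.gene_indices},
                "conditions": {labels[1][i] for i in m.condition_indices},
                "timepoints": {labels[2][i] for i in m.time_indices},
            }
        )
    return out
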