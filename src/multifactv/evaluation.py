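"""Score discovered modules against a planted ground truth.

Both metrics treat a module as a set of namespaced elements drawn from
three disjoint universes (``gene:``, ``cond:``, ``time:``), so genes,
conditions and time points all contribute.

* **Fscore** — per-pair F1 between element sets, a maximum-weight
  one-to-one matching (Hungarian assignment) of found to truth modules,
  then the mean F1 over truth modules; unmatched truth modules count 0.
* **NMI** — each side is converted to a hard labeling of the element
  universe (module index, or a shared background label for elements in
  no module; an element claimed by several modules goes to the one with
  the largest factor score, falling back to the lowest index), then
  normalized mutual information with the geometric-mean normalization
  ``I(X;Y) / sqrt(H(X) H(Y))``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import normalized_mutual_info_score

from .module_extraction import Module
from .synthetic_data import GroundTruth, PlantedModuleSpec

BACKGROUND = 0  # label shared by elements belonging to no module


def _default_labels(dims: tuple[int, int, int]) -> tuple[list[str], list[str], list[str]]:
    n1, n2, n3 = dims
    return (
        [f"g{r}" for r in range(n1)],
        [f"c{s}" for s in range(n2)],
        [f"t{t}" for t in range(n3)],
    )


def module_elements(module: Module) -> set[str]:
    """Namespaced element set of a found module."""
    return (
        {f"gene:{g}" for g in module.genes}
        | {f"cond:{c}" for c in module.conditions}
        | {f"time:{t}" for t in module.timepoints}
    )


def truth_elements(
    spec: PlantedModuleSpec, labels: tuple[list[str], list[str], list[str]]
) -> set[str]:
    """Namespaced element set of a planted module, mapped onto axis labels."""
    return (
        {f"gene:{labels[0][i]}" for i in spec.gene_indices}
        | {f"cond:{labels[1][i]}" for i in spec.condition_indices}
        | {f"time:{labels[2][i]}" for i in spec.time_indices}
    )


def _set_f1(found: set[str], truth: set[str]) -> float:
    if not found or not truth:
        return 0.0
    inter = len(found & truth)
    if inter == 0:
        return 0.0
    precision = inter / len(found)
    recall = inter / len(truth)
    return 2.0 * precision * recall / (precision + recall)


def module_f1(
    found: Module,
    truth: PlantedModuleSpec,
    labels: tuple[list[str], list[str], list[str]] | None = None,
) -> float:
    """F1 between one found module and one planted module."""
    if labels is None:
        labels = _infer_labels_from_spec(truth)
    return _set_f1(module_elements(found), truth_elements(truth, labels))


def _infer_labels_from_spec(spec: PlantedModuleSpec) -> tuple[list[str], list[str], list[str]]:
    n1 = max(spec.gene_indices, default=-1) + 1
    n2 = max(spec.condition_indices, default=-1) + 1
    n3 = spec.time_end + 1
    return _default_labels((n1, n2, n3))


def _resolve_labels(
    truth: GroundTruth, labels: tuple[list[str], list[str], list[str]] | None
) -> tuple[list[str], list[str], list[str]]:
    if labels is not None:
        return labels
    if truth.dims != (0, 0, 0):
        return _default_labels(truth.dims)
    n1 = max((max(m.gene_indices, default=-1) for m in truth.modules), default=-1) + 1
    n2 = max((max(m.condition_indices, default=-1) for m in truth.modules), default=-1) + 1
    n3 = max((m.time_end for m in truth.modules), default=-1) + 1
    return _default_labels((n1, n2, n3))


def match_modules(
    found: list[Module],
    truth: GroundTruth,
    labels: tuple[list[str], list[str], list[str]] | None = None,
) -> dict:
    """Maximum-weight one-to-one matching between found and truth modules.

    Returns ``{"pairs": [(found_idx, truth_idx, f1), ...],
    "unmatched_found": [...], "unmatched_truth": [...]}`` with 0-based
    positional indices.  Zero-F1 pairs are not reported as matches.
    """
    labels = _resolve_labels(truth, labels)
    found_sets = [module_elements(m) for m in found]
    truth_sets = [truth_elements(m, labels) for m in truth.modules]
    f1 = np.zeros((len(found_sets), len(truth_sets)))
    for i, fs in enumerate(found_sets):
        for j, ts in enumerate(truth_sets):
            f1[i, j] = _set_f1(fs, ts)
    pairs: list[tuple[int, int, float]] = []
    if f1.size:
        rows, cols = linear_sum_assignment(-f1)
        pairs = [(int(i), int(j), float(f1[i, j])) for i, j in zip(rows, cols) if f1[i, j] > 0]
    matched_f = {i for i, _, _ in pairs}
    matched_t = {j for _, j, _ in pairs}
    return {
        "pairs": pairs,
        "unmatched_found": [i for i in range(len(found_sets)) if i not in matched_f],
        "unmatched_truth": [j for j in range(len(truth_sets)) if j not in matched_t],
    }


def fscore(
    found: list[Module],
    truth: GroundTruth,
    labels: tuple[list[str], list[str], list[str]] | None = None,
) -> float:
    """Matched-mean F1 over truth modules (unmatched truth modules score 0)."""
    if not truth.modules:
        raise ValueError("ground truth contains no modules")
    match = match_modules(found, truth, labels)
    return float(sum(f for _, _, f in match["pairs"]) / len(truth.modules))


def _labeling_from_module_sets(
    module_sets: list[set[str]],
    universe: list[str],
    scores: list[dict[str, float]] | None = None,
) -> np.ndarray:
    """Hard labeling of the universe; overlap resolved by score then lowest index."""
    pos = {e: i for i, e in enumerate(universe)}
    label = np.full(len(universe), BACKGROUND, dtype=int)
    best = np.full(len(universe), -np.inf)
    for k, elems in enumerate(module_sets):
        for e in elems:
            i = pos.get(e)
            if i is None:
                raise ValueError(f"module element {e!r} is outside the universe")
            s = scores[k].get(e, 0.0) if scores is not None else 0.0
            if label[i] == BACKGROUND or s > best[i]:
                label[i] = k + 1
                best[i] = s
    return label


def nmi(
    found: list[Module],
    truth: GroundTruth,
    labels: tuple[list[str], list[str], list[str]] | None = None,
    overlap: str = "score",
) -> float:
    """Normalized mutual information between found and truth labelings.

    ``overlap`` controls how an element claimed by several *found*
    modules is assigned: ``"score"`` (default) takes the module whose
    factor value for that element is largest, ``"first"`` the lowest
    module index.  Truth overlaps (possible only on the time axis) are
    resolved by lowest index.  If both labelings are constant the value
    is 1.0 when they agree and 0.0 otherwise.
    """
    if overlap not in ("score", "first"):
        raise ValueError(f"unknown overlap strategy {overlap!r}")
    labels = _resolve_labels(truth, labels)
    universe = (
        [f"gene:{g}" for g in labels[0]]
        + [f"cond:{c}" for c in labels[1]]
        + [f"time:{t}" for t in labels[2]]
    )
    found_sets = [module_elements(m) for m in found]
    scores = [m.scores for m in found] if overlap == "score" else None
    x = _labeling_from_module_sets(found_sets, universe, scores)
    y = _labeling_from_module_sets(
        [truth_elements(m, labels) for m in truth.modules], universe
    )
    if len(set(x)) == 1 and len(set(y)) == 1:
        return 1.0 if np.array_equal(x, y) else 0.0
    if len(set(x)) == 1 or len(set(y)) == 1:
        return 0.0
    return float(normalized_mutual_info_score(y, x, average_method="geometric"))


def evaluation_report(
    found: list[Module],
    truth: GroundTruth,
    labels: tuple[list[str], list[str], list[str]] | None = None,
) -> dict:
    """Full JSON-serializable report: fscore, nmi, per-pair F1 and the matching."""
    match = match_modules(found, truth, labels)
    return {
        "fscore": fscore(found, truth, labels),
        "nmi": nmi(found, truth, labels),
        "n_found": len(found),
        "n_truth": len(truth.modules),
        "matching": match,
    }
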