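"""Turn converged factors into modules by per-column sign correction and thresholding.

For each component k:

1. If the positive entries of ``u_k`` sum to less than the magnitude of
   its negative entries, flip the sign of the whole column (the CP model
   is sign-indeterminate in U and V jointly); likewise for ``v_k``.
2. Gene r joins module k iff ``u_{r,k} >= 0.5 * tau1 * (max(u_k^+) + min(u_k^+))``,
   where ``u_k^+`` is the set of *strictly positive* entries of the
   (possibly flipped) column.  Conditions use the same rule with tau2.
3. Time point t joins iff ``w_{t,k} >= 0.5 * tau3 * (max(w_k) + min(w_k))``
   — over the full column, since W is already nonnegative.

A column with no strictly positive entry contributes an empty set and
the module is flagged degenerate; modules are never dropped, so module
indices always align with factor columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .factorization import FactorSet


@dataclass
class Module:
    """One extracted tricluster: a gene set, condition set and time-point set.

    ``scores`` holds the factor value behind each member label, used to
    resolve overlaps when modules are converted to a hard labeling.
    ``flags`` marks degenerate (empty-axis) modules and whether the time
    set is a contiguous run.
    """

    index: int
    genes: set[str] = field(default_factory=set)
    conditions: set[str] = field(default_factory=set)
    timepoints: set[str] = field(default_factory=set)
    scores: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not (self.genes or self.conditions or self.timepoints)

    def axis_set(self, axis: int) -> set[str]:
        if axis == 1:
            return self.genes
        if axis == 2:
            return self.conditions
        if axis == 3:
            return self.timepoints
        raise ValueError(f"axis must be 1, 2 or 3, got {axis}")

    def to_dict(self) -> dict:
        return {
            "k": self.index,
            "genes": sorted(self.genes),
            "conditions": sorted(self.conditions),
            "timepoints": sorted(self.timepoints),
            "flags": dict(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Module":
        return cls(
            index=int(d["k"]),
            genes=set(d.get("genes", [])),
            conditions=set(d.get("conditions", [])),
            timepoints=set(d.get("timepoints", [])),
            flags=dict(d.get("flags", {})),
        )


def _sign_correct(col: np.ndarray) -> np.ndarray:
    pos = col[col > 0].sum()
    neg = col[col < 0].sum()
    return -col if pos < -neg else col


def _positive_rule_members(col: np.ndarray, tau: float) -> np.ndarray:
    """Indices passing the threshold ``0.5 * tau * (max(col+) + min(col+))``.

    The minimum is taken over the nonnegative entries: exact zeros
    (entities with no support at all, common in clean synthetic data)
    count as the floor of the positive range rather than shifting the
    threshold up to the smallest true member.  On noisy data, where
    exact zeros do not occur, this is identical to the minimum over the
    strictly positive entries.  A column with no strictly positive
    entry yields an empty set.
    """
    pos = col[col > 0]
    if pos.size == 0:
        return np.empty(0, dtype=int)
    thr = 0.5 * tau * (pos.max() + col[col >= 0].min())
    return np.nonzero(col >= thr)[0]


def _full_rule_members(col: np.ndarray, tau: float) -> np.ndarray:
    """Indices passing the threshold over the full column (time rule)."""
    thr = 0.5 * tau * (col.max() + col.min())
    return np.nonzero(col >= thr)[0]


def _contiguous(indices: np.ndarray) -> bool:
    if indices.size <= 1:
        return True
    s = np.sort(indices)
    return bool(np.all(np.diff(s) == 1))


def extract_modules(
    factors: FactorSet,
    labels: tuple[list[str], list[str], list[str]],
    tau1: float = 1.0,
    tau2: float = 1.0,
    tau3: float = 0.75,
) -> list[Module]:
    """Apply sign correction and thresholding to every factor column."""
    for name, tau in (("tau1", tau1), ("tau2", tau2), ("tau3", tau3)):
        if not 0.0 <= tau <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {tau}")
    gene_labels, cond_labels, time_labels = (list(ax) for ax in labels)
    modules: list[Module] = []
    for k in range(factors.K):
        u = _sign_correct(np.asarray(factors.U[:, k], float))
        v = _sign_correct(np.asarray(factors.V[:, k], float))
        w = np.asarray(factors.W[:, k], float)
        gi = _positive_rule_members(u, tau1)
        ci = _positive_rule_members(v, tau2)
        ti = _full_rule_members(w, tau3)
        mod = Module(
            index=k + 1,
            genes={gene_labels[i] for i in gi},
            conditions={cond_labels[i] for i in ci},
            timepoints={time_labels[i] for i in ti},
        )
        for i in gi:
            mod.scores[f"gene:{gene_labels[i]}"] = float(u[i])
        for i in ci:
            mod.scores[f"cond:{cond_labels[i]}"] = float(v[i])
        for i in ti:
            mod.scores[f"time:{time_labels[i]}"] = float(w[i])
        degenerate = gi.size == 0 or ci.size == 0 or ti.size == 0
        if gi.size == 0 or ci.size == 0:
            warnings.warn(
                f"module {k + 1}: no strictly positive factor entries on some axis; "
                "emitting an empty member set",
                RuntimeWarning,
                stacklevel=2,
            )
        mod.flags["degenerate"] = degenerate
        mod.flags["time_contiguous"] = _contiguous(ti)
        modules.append(mod)
    return modules


def build_membership_matrix(
    modules: list[Module],
    axis: int,
    labels: list[str],
) -> np.ndarray:
    """Binary entity x module matrix for one axis.

    ``m[i, k] = 1`` iff ``labels[i]`` belongs to module k on that axis.
    Used e.g. to represent patients by their module memberships before
    clustering them.
    """
    if axis not in (1, 2, 3):
        raise ValueError(f"axis must be 1, 2 or 3, got {axis}")
    m = np.zeros((len(labels), len(modules)), dtype=int)
    pos = {lab: i for i, lab in enumerate(labels)}
    for k, mod in enumerate(modules):
        for lab in mod.axis_set(axis):
            if lab in pos:
                m[pos[lab], k] = 1
    return m


def modules_to_json(modules: list[Module]) -> str:
    return json.dumps([m.to_dict() for m in modules], indent=2)


def modules_from_json(text: str) -> list[Module]:
    return [Module.from_dict(d) for d in json.loads(text)]


def modules_to_tsv(modules: list[Module]) -> str:
    """Flat (module_id, axis, label) table, one member per line."""
    lines = ["module_id\taxis\tlabel"]
    for m in modules:
        for axis_name, members in (
            ("gene", m.genes),
            ("condition", m.conditions),
            ("time", m.timepoints),
        ):
            for lab in sorted(members):
                lines.append(f"{m.index}\t{axis_name}\t{lab}")
    return "\n".join(lines) + "\n"
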