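"""Spot-weight optimization.

Two planning schemes share one objective machinery:

* **single-field optimization (SFO)** — each beam's weights are optimized
  independently so that the beam alone delivers its share of the
  prescription uniformly to its optimization target volume, with
  organ-at-risk penalties;
* **robust minimax (RO)** — the weights of all beams are optimized
  jointly to minimize the worst-case objective over a set of setup/range
  perturbation scenarios, by iterative worst-case scenario selection.

The objective is a weighted sum of one-sided quadratic penalties
(minimum dose, maximum dose) and a two-sided uniform-dose penalty, each
normalized by structure voxel count.  The solver is projected gradient
descent with backtracking line search: weights stay nonnegative after
every iteration and the objective is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .beams import Beam
from .dose import InfluenceMatrix, Spot

ITER_CAP = 500
REL_TOL = 1e-5


class MatrixOperator:
    """Adapter giving a dense influence matrix the operator interface."""

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=float)
        self.n_spots = self.matrix.shape[1]

    @classmethod
    def from_influence(cls, infl: InfluenceMatrix) -> "MatrixOperator":
        return cls(infl.matrix)

    def dose(self, weights: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(weights, dtype=float)

    def adjoint(self, residual: np.ndarray) -> np.ndarray:
        return self.matrix.T @ np.asarray(residual, dtype=float)


@dataclass
class ObjectiveTerm:
    structure: str
    kind: str  # "min" | "max" | "uniform"
    dose: float  # Gy(RBE)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("min", "max", "uniform"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.dose < 0:
            raise ValueError("reference dose must be >= 0")
        if self.weight < 0:
            raise ValueError("term weight must be >= 0")


@dataclass
class ObjectiveSpec:
    """A list of per-structure objective terms."""

    terms: list[ObjectiveTerm]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("objective needs at least one term")
        self.validate_feasible()

    def validate_feasible(self) -> None:
        for s in {t.structure for t in self.terms}:
            mins = [t.dose for t in self.terms if t.structure == s and t.kind == "min"]
            maxs = [t.dose for t in self.terms if t.structure == s and t.kind == "max"]
            if mins and maxs and min(maxs) < max(mins):
                raise ValueError(
                    f"infeasible objective on {s!r}: max-dose cap {min(maxs)} "
                    f"< min-dose target {max(mins)}"
                )

    def structures(self) -> list[str]:
        return sorted({t.structure for t in self.terms})

    def scaled(self, factor: float) -> "ObjectiveSpec":
        """The same terms with all reference doses multiplied by ``factor``."""
        return ObjectiveSpec(
            [ObjectiveTerm(t.structure, t.kind, t.dose * factor, t.weight) for t in self.terms]
        )


def objective_value(doses: Mapping[str, np.ndarray], spec: ObjectiveSpec) -> float:
    """Weighted sum of voxel-count-normalized quadratic penalties."""
    total = 0.0
    for t in spec.terms:
        if t.structure not in doses:
            raise KeyError(
                f"objective references structure {t.structure!r} with no dose; "
                f"have {sorted(doses)}"
            )
        d = np.asarray(doses[t.structure], dtype=float)
        n = d.size
        if t.kind == "min":
            pen = np.maximum(0.0, t.dose - d)
        elif t.kind == "max":
            pen = np.maximum(0.0, d - t.dose)
        else:
            pen = d - t.dose
        total += t.weight * float(pen @ pen) / n
    return total


def _value_and_grad(
    weights: np.ndarray, ops: Mapping[str, object], spec: ObjectiveSpec
) -> tuple[float, np.ndarray]:
    doses = {s: ops[s].dose(weights) for s in spec.structures()}
    value = objective_value(doses, spec)
    grad = np.zeros_like(weights, dtype=float)
    for t in spec.terms:
        d = doses[t.structure]
        n = d.size
        if t.kind == "min":
            r = -2.0 * np.maximum(0.0, t.dose - d)
        elif t.kind == "max":
            r = 2.0 * np.maximum(0.0, d - t.dose)
        else:
            r = 2.0 * (d - t.dose)
        grad += (t.weight / n) * ops[t.structure].adjoint(r)
    return value, grad


def _project(w: np.ndarray) -> np.ndarray:
    return np.maximum(w, 0.0)


def _pgd(
    fg: Callable[[np.ndarray], tuple[float, np.ndarray]],
    w0: np.ndarray,
    iter_cap: int = ITER_CAP,
    rel_tol: float = REL_TOL,
) -> tuple[np.ndarray, list[float]]:
    """Projected gradient descent with backtracking; monotone by construction."""
    w = _project(np.asarray(w0, dtype=float))
    f, g = fg(w)
    history = [f]
    gnorm2 = float(g @ g)
    step = 1.0 if gnorm2 == 0 else max(f, 1e-12) / gnorm2
    for _ in range(iter_cap):
        if gnorm2 == 0:
            break
        accepted = False
        for _ in range(40):
            w_new = _project(w - step * g)
            f_new, g_new = fg(w_new)
            if f_new <= f - 1e-12 or (f_new <= f and not np.array_equal(w_new, w)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = (f - f_new) / max(f, 1e-30)
        w, f, g = w_new, f_new, g_new
        gnorm2 = float(g @ g)
        history.append(f)
        step *= 1.8
        if rel < rel_tol:
            break
    return w, history


@dataclass
class Plan:
    """An optimized plan: beams, spots, nonnegative weights, scheme label."""

    beams: list[Beam]
    spots: list[list[Spot]]
    weights: list[np.ndarray]
    scheme: str
    prescription_gy: float = 33.0
    fractions: int = 5
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.beams) != len(self.spots) or len(self.beams) != len(self.weights):
            raise ValueError("beams, spots and weights must align")
        for sp, w in zip(self.spots, self.weights):
            if len(sp) != len(w):
                raise ValueError("per-beam weight length must equal spot count")
            if np.any(np.asarray(w) < 0):
                raise ValueError("weights must be >= 0")

    @property
    def n_spots(self) -> int:
        return sum(len(s) for s in self.spots)


def _init_weights(ops: Mapping[str, object], spec: ObjectiveSpec, n_spots: int) -> np.ndarray:
    """Uniform weights scaled so the mean target dose hits its reference."""
    target_terms = [t for t in spec.terms if t.kind in ("min", "uniform")]
    if not target_terms:
        return np.ones(n_spots)
    t = target_terms[0]
    w = np.ones(n_spots)
    mean_dose = float(np.mean(ops[t.structure].dose(w)))
    if mean_dose > 0:
        w *= t.dose / mean_dose
    return w


def optimize_sfo(
    per_beam_ops: Sequence[Mapping[str, object]],
    spec: ObjectiveSpec,
    beams: Sequence[Beam] | None = None,
    spots: Sequence[list[Spot]] | None = None,
    scheme: str = "SFO",
    prescription_gy: float = 33.0,
    iter_cap: int = ITER_CAP,
    rel_tol: float = REL_TOL,
) -> Plan:
    """Single-field optimization: each beam solved independently.

    ``spec`` states the per-beam objective (reference doses already at
    the per-beam share of the prescription).  ``per_beam_ops`` maps, for
    each beam, structure name -> dose operator restricted to that
    structure's voxels.
    """
    weights, infos = [], []
    for ops in per_beam_ops:
        n_spots = next(iter(ops.values())).n_spots
        w0 = _init_weights(ops, spec, n_spots)
        w, hist = _pgd(lambda w_: _value_and_grad(w_, ops, spec), w0,
                       iter_cap=iter_cap, rel_tol=rel_tol)
        weights.append(w)
        infos.append({"objective": hist[-1], "iterations": len(hist) - 1,
                      "initial_objective": hist[0], "history": hist})
    if beams is None:
        beams = [Beam(180.0, np.zeros(3)) for _ in per_beam_ops]
    if spots is None:
        # placeholder spot bookkeeping for matrix-only (toy) problems
        spots = [[Spot(b, 0.0, 0.0, 1.0) for _ in w] for b, w in enumerate(weights)]
    return Plan(
        beams=list(beams),
        spots=list(spots),
        weights=weights,
        scheme=scheme,
        prescription_gy=prescription_gy,
        info={"per_beam": infos},
    )


def scenario_objective(
    weights_concat: np.ndarray,
    beam_ops: Sequence[Mapping[str, object]],
    spec: ObjectiveSpec,
    slices: Sequence[slice],
) -> tuple[float, np.ndarray]:
    """Sum over beams of the per-beam objective (SFO-style), with gradient."""
    total = 0.0
    grad = np.zeros_like(weights_concat, dtype=float)
    for ops, sl in zip(beam_ops, slices):
        v, g = _value_and_grad(weights_concat[sl], ops, spec)
        total += v
        grad[sl] = g
    return total, grad


def optimize_robust(
    scenario_beam_ops: Sequence[Sequence[Mapping[str, object]]],
    spec: ObjectiveSpec,
    beams: Sequence[Beam],
    spots: Sequence[list[Spot]],
    scheme: str = "RO",
    prescription_gy: float = 33.0,
    iter_cap: int = ITER_CAP,
    rel_tol: float = REL_TOL,
    outer_cap: int = 8,
) -> Plan:
    """Minimax robust optimization over scenarios.

    ``scenario_beam_ops[s][b]`` maps structure -> operator for scenario s
    and beam b; scenario 0 must be the nominal.  Iterative worst-case
    selection: solve against the current worst-scenario set, re-evaluate
    all scenarios, add the new worst, and repeat until the worst-case
    objective stops improving.
    """
    if not scenario_beam_ops:
        raise ValueError("scenario list is empty")
    n_scen = len(scenario_beam_ops)
    n_beams = len(beams)
    counts = [next(iter(scenario_beam_ops[0][b].values())).n_spots for b in range(n_beams)]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    slices = [slice(offsets[b], offsets[b + 1]) for b in range(n_beams)]

    def fg_for(s: int):
        return lambda w: scenario_objective(w, scenario_beam_ops[s], spec, slices)

    all_fg = [fg_for(s) for s in range(n_scen)]

    w = np.concatenate(
        [
            _init_weights(scenario_beam_ops[0][b], spec, counts[b])
            for b in range(n_beams)
        ]
    )

    def worst(wv: np.ndarray) -> tuple[int, float, np.ndarray]:
        vals_grads = [fg(wv) for fg in all_fg]
        vals = [v for v, _ in vals_grads]
        s = int(np.argmax(vals))
        return s, vals[s], vals_grads[s][1]

    active = [0]
    s0, best_val, _ = worst(w)
    if s0 not in active:
        active.append(s0)
    best_w = w.copy()
    trace = [best_val]
    for _ in range(outer_cap):
        def fg_max(wv: np.ndarray) -> tuple[float, np.ndarray]:
            vals_grads = [all_fg[s](wv) for s in active]
            k = int(np.argmax([v for v, _ in vals_grads]))
            return vals_grads[k]

        w, _ = _pgd(fg_max, w, iter_cap=iter_cap, rel_tol=rel_tol)
        s_new, val_all, _ = worst(w)
        if val_all < best_val:
            best_val, best_w = val_all, w.copy()
        trace.append(best_val)
        if s_new in active:
            break
        if trace[-2] - trace[-1] < rel_tol * max(trace[-2], 1e-30):
            break
        active.append(s_new)

    weights = [best_w[sl].copy() for sl in slices]
    return Plan(
        beams=list(beams),
        spots=list(spots),
        weights=weights,
        scheme=scheme,
        prescription_gy=prescription_gy,
        info={
            "worst_case_objective": best_val,
            "active_scenarios": active,
            "worst_case_trace": trace,
        },
    )
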