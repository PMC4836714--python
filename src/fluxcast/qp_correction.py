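"""Range-weighted quadratic-programming reconciliation of predicted fluxes.

A regression ensemble predicts the 29 fluxes one at a time, so the resulting
vector v-hat generally violates the steady-state mass balances of the
network (and can wander into biologically meaningless territory, e.g. a
negative glyoxylate-shunt flux).  Following the minimization-of-metabolic-
adjustment (MOMA) idea, the prediction is replaced by the feasible vector
closest to it in range-scaled coordinates:

    minimize   sum_i [ (v_i - vhat_i) / (Max_i - Min_i) ]^2
    subject to S v = b_eq,  A v >= b_in   (and optional per-flux boxes)

Dividing each deviation by the observed range of that flux keeps fluxes with
wide dynamic ranges from dominating the objective.  Expanding the square and
dropping the constant gives a standard strictly convex QP with diagonal
Hessian 1/(Max_i - Min_i)^2.  The per-flux Min/Max default to the extremes
observed in the training table; a knockout pins a flux's box to [0, 0].
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._qp_solver import QPInfeasibleError, QPSolution, solve_qp
from .stoichiometry import (
    FLUX_IDS,
    N_FLUXES,
    ConstraintSystem,
    FeasibilityReport,
    FluxVector,
    check_feasibility,
)

__all__ = [
    "FluxBounds",
    "QPProblem",
    "CorrectionResult",
    "QPInfeasibleError",
    "default_bounds",
    "apply_knockout",
    "assemble_qp",
    "correct",
    "rmse",
]

#: relative floor applied to a degenerate (Max == Min) range so the QP stays
#: strictly convex; expressed as a fraction of the largest observed range
DEGENERATE_RANGE_FRACTION = 1e-6


@dataclass
class FluxBounds:
    """Per-flux [Min, Max] ranges; weights for the QP and optional boxes."""

    lower: np.ndarray
    upper: np.ndarray
    use_box: np.ndarray  # bool per flux
    source: str = "dataset-default"
    forced: np.ndarray | None = None  # knockout boxes survive --no-box

    def __post_init__(self):
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        self.use_box = np.asarray(self.use_box, bool)
        if self.forced is None:
            self.forced = np.zeros(N_FLUXES, bool)
        self.forced = np.asarray(self.forced, bool)
        for arr in (self.lower, self.upper, self.use_box, self.forced):
            if arr.shape != (N_FLUXES,):
                raise ValueError(f"bounds arrays must have length {N_FLUXES}")
        if np.any(self.lower > self.upper):
            bad = FLUX_IDS[int(np.argmax(self.lower > self.upper))]
            raise ValueError(f"lower bound exceeds upper bound for {bad}")

    @classmethod
    def unit(cls) -> "FluxBounds":
        """Unit ranges (plain Euclidean projection), boxes off."""
        return cls(
            lower=np.zeros(N_FLUXES),
            upper=np.ones(N_FLUXES),
            use_box=np.zeros(N_FLUXES, bool),
            source="unit",
        )

    def ranges(self) -> np.ndarray:
        """Max - Min with the degenerate-range floor applied."""
        raw = self.upper - self.lower
        biggest = float(raw.max()) if raw.max() > 0 else 1.0
        return np.maximum(raw, DEGENERATE_RANGE_FRACTION * biggest)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "flux_id": FLUX_IDS,
                "min": self.lower,
                "max": self.upper,
                "box_flag": self.use_box.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "user-set") -> "FluxBounds":
        df = df.set_index("flux_id").reindex(list(FLUX_IDS))
        if df[["min", "max"]].isna().any().any():
            missing = [fid for fid in FLUX_IDS if df.loc[fid].isna().any()]
            raise ValueError(f"bounds table missing flux id(s): {missing}")
        box = df["box_flag"] if "box_flag" in df else pd.Series(1, index=df.index)
        return cls(
            lower=df["min"].to_numpy(float),
            upper=df["max"].to_numpy(float),
            use_box=box.to_numpy(bool),
            source=source,
        )


def default_bounds(training: pd.DataFrame, use_box: bool = True) -> FluxBounds:
    """Column-wise extremes of the training table's flux columns."""
    if len(training) < 1:
        raise ValueError("need at least one training row")
    cols = [fid for fid in FLUX_IDS]
    missing = [c for c in cols if c not in training.columns]
    if missing:
        raise ValueError(f"training table lacks flux column(s): {missing}")
    return FluxBounds(
        lower=training[cols].min().to_numpy(float),
        upper=training[cols].max().to_numpy(float),
        use_box=np.full(N_FLUXES, bool(use_box)),
        source="dataset-default",
    )


def apply_knockout(bounds: FluxBounds, flux_id: str) -> FluxBounds:
    """Model a gene deletion by pinning one flux's box to [0, 0].

    Returns a modified copy; the weight of the knocked-out flux falls back to
    the degenerate-range floor, and its box flag is forced on so the QP pins
    the flux to zero (e.g. a *zwf* knockout zeroes v10, the oxidative PP
    entry).
    """
    if flux_id not in FLUX_IDS:
        raise KeyError(f"unknown flux id {flux_id!r}")
    out = copy.deepcopy(bounds)
    i = FLUX_IDS.index(flux_id)
    out.lower[i] = 0.0
    out.upper[i] = 0.0
    out.use_box[i] = True
    out.forced[i] = True
    out.source = f"{bounds.source}+knockout:{flux_id}"
    return out


@dataclass(frozen=True)
class QPProblem:
    """Standard-form strictly convex QP: 1/2 v'Hv + q'v with H diagonal."""

    H_diag: np.ndarray
    q: np.ndarray
    S: np.ndarray
    b_eq: np.ndarray
    A: np.ndarray  # stoichiometric inequalities plus enabled box rows
    b_in: np.ndarray
    n_stoich_inequalities: int


def assemble_qp(
    vhat: FluxVector, cs: ConstraintSystem, bounds: FluxBounds, *, use_boxes: bool = True
) -> QPProblem:
    """Build the QP whose solution is the range-weighted projection of vhat.

    The objective expands to 1/2 v_i^2 w_i - vhat_i w_i v_i (+ constant) with
    w_i = 1/(Max_i - Min_i)^2; the constant and an overall factor of two are
    dropped.  When ``use_boxes`` is true, every flux whose box flag is set
    contributes the rows v_i >= Min_i and -v_i >= -Max_i.
    """
    r = bounds.ranges()
    w = 1.0 / r**2
    q = -bounds_weight_times(vhat.values, w)
    A_rows = [cs.A]
    b_rows = [cs.b_in]
    active_box = (bounds.use_box if use_boxes else np.zeros(N_FLUXES, bool)) | bounds.forced
    if active_box.any():
        idx = np.where(active_box)[0]
        eye = np.zeros((idx.size, N_FLUXES))
        eye[np.arange(idx.size), idx] = 1.0
        A_rows += [eye, -eye]
        b_rows += [bounds.lower[idx], -bounds.upper[idx]]
    return QPProblem(
        H_diag=w,
        q=q,
        S=cs.S,
        b_eq=cs.b_eq,
        A=np.vstack(A_rows),
        b_in=np.concatenate(b_rows),
        n_stoich_inequalities=cs.A.shape[0],
    )


def bounds_weight_times(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.asarray(v, float) * np.asarray(w, float)


def _name_rows(
    rows: list[int], cs: ConstraintSystem, bounds: FluxBounds, use_boxes: bool = True
) -> list[str]:
    """Human-readable names for KKT/LP row indices (equalities first, then
    stoichiometric inequalities, then lower/upper box rows)."""
    labels = list(cs.eq_labels) + list(cs.in_labels)
    active = (bounds.use_box if use_boxes else np.zeros(N_FLUXES, bool)) | bounds.forced
    box_ids = [FLUX_IDS[i] for i in np.where(active)[0]]
    n_box = len(box_ids)
    out = []
    for i in rows:
        if i < len(labels):
            out.append(labels[i])
        elif i < len(labels) + n_box:
            out.append(f"lower box {box_ids[i - len(labels)]}")
        elif i < len(labels) + 2 * n_box:
            out.append(f"upper box {box_ids[i - len(labels) - n_box]}")
        else:
            out.append(f"row {i}")
    return out


@dataclass(frozen=True)
class CorrectionResult:
    corrected: FluxVector
    objective: float
    feasibility: FeasibilityReport
    solver: QPSolution
    used_boxes: bool
    notes: tuple[str, ...] = field(default_factory=tuple)


def correct(
    vhat: FluxVector,
    cs: ConstraintSystem,
    bounds: FluxBounds | None = None,
    tol: float = 1e-6,
    *,
    use_boxes: bool = True,
    auto_relax_boxes: bool = False,
    max_relaxations: int = 5,
) -> CorrectionResult:
    """Project the ML prediction onto the stoichiometric polytope.

    Raises :class:`QPInfeasibleError` (naming unsatisfiable rows) if the
    constraint set is empty, e.g. when user boxes contradict an equality.
    With ``auto_relax_boxes`` the per-flux boxes (never the stoichiometric
    rows) are widened by a geometrically growing, recorded margin until the
    problem becomes feasible or ``max_relaxations`` is exhausted.
    """
    if bounds is None:
        bounds = FluxBounds.unit()
    notes: list[str] = []
    attempt = bounds
    sol = None
    for trial in range(max_relaxations + 1):
        qp = assemble_qp(vhat, cs, attempt, use_boxes=use_boxes)
        try:
            sol = solve_qp(qp.H_diag, qp.q, qp.S, qp.b_eq, qp.A, qp.b_in)
            break
        except QPInfeasibleError as err:
            if not (auto_relax_boxes and use_boxes) or trial == max_relaxations:
                raise QPInfeasibleError(
                    "flux correction infeasible; check user bounds against the "
                    f"stoichiometric rows: {_name_rows(err.rows, cs, attempt, use_boxes)}",
                    rows=err.rows,
                ) from err
            margin = np.maximum(1.0, 0.1 * attempt.ranges()) * 2**trial
            attempt = FluxBounds(
                lower=attempt.lower - margin,
                upper=attempt.upper + margin,
                use_box=attempt.use_box,
                source=f"{attempt.source}+relaxed",
            )
            notes.append(f"boxes relaxed by margin factor 2^{trial}")
    bounds = attempt
    v = FluxVector(sol.x)
    report = check_feasibility(v, cs, tol)
    # objective on the original (un-expanded) scale
    r = bounds.ranges()
    obj = float(np.sum(((sol.x - vhat.values) / r) ** 2))
    return CorrectionResult(
        corrected=v,
        objective=obj,
        feasibility=report,
        solver=sol,
        used_boxes=use_boxes,
        notes=tuple(notes),
    )


def rmse(v: FluxVector, ref: FluxVector) -> float:
    """Root mean squared difference over the 29 fluxes, in flux units."""
    return float(np.sqrt(np.mean((v.values - ref.values) ** 2)))
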