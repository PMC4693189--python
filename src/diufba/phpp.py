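"""Diurnal phenotypic phase plane (PhPP) scans.

Two extended-problem variables — a reaction in either phase, a transfer
amount, or an export amount — are fixed by equality on a grid, and the
diurnal LP is re-solved at each grid point.  The resulting objective
surface exposes the trade-off structure around the unconstrained optimum;
contiguous regions of constant objective gradient correspond to distinct
metabolic modes (e.g. a regime where extra storage still pays off versus
one where surplus is burned in futile cycles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diurnal_core import ExtendedProblem
from .lp_solve import solve_diufba


@dataclass
class PhPPGrid:
    """A solved phase-plane grid.

    ``objective[i, j]`` is the constrained optimum with ``var1`` fixed to
    ``axis1[i]`` and ``var2`` fixed to ``axis2[j]``; infeasible cells are
    NaN with ``feasible[i, j]`` False.  For a one-variable scan ``var2``
    is None and the grid has a single column.
    """

    var1: str
    var2: str | None
    axis1: np.ndarray
    axis2: np.ndarray
    objective: np.ndarray
    feasible: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: axis1, axis2, objective, feasible (+ mode
        if :func:`classify_modes` has annotated the grid)."""
        rows = []
        modes = getattr(self, "modes", None)
        for i, a in enumerate(self.axis1):
            for j, b in enumerate(self.axis2):
                row = {"axis1": a, "axis2": b,
                       "objective": self.objective[i, j],
                       "feasible": bool(self.feasible[i, j])}
                if modes is not None:
                    row["mode"] = int(modes[i, j])
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, path=None):
        """Heat map of the objective surface (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        masked = np.ma.masked_where(~self.feasible, self.objective)
        im = ax.pcolormesh(self.axis2, self.axis1, masked, shading="nearest")
        ax.set_xlabel(self.var2 or "")
        ax.set_ylabel(self.var1)
        fig.colorbar(im, ax=ax, label="objective")
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _axis(range_spec: tuple[float, float, int], label: str) -> np.ndarray:
    lo, hi, m = range_spec
    if m < 1:
        raise ValueError(f"{label}: grid size must be >= 1, got {m}")
    if lo > hi:
        raise ValueError(f"{label}: degenerate range (lo {lo} > hi {hi})")
    return np.linspace(lo, hi, int(m))


def phpp_scan(problem: ExtendedProblem,
              var1: str, range1: tuple[float, float, int],
              var2: str | None = None,
              range2: tuple[float, float, int] | None = None) -> PhPPGrid:
    """Scan the diurnal optimum over one or two fixed variables.

    ``var1``/``var2`` are column names in the ``phase:reaction``,
    ``transfer:species`` or ``export:species`` notation of
    :meth:`ExtendedProblem.column_name`; each grid cell pins the
    variable(s) by equality (lb = ub = value) and re-solves the LP.
    Infeasible cells are recorded as masked, not skipped, so the grid
    shape is stable.
    """
    j1 = problem.column_index(var1)
    axis1 = _axis(range1, "range1")
    if var2 is not None:
        if range2 is None:
            raise ValueError("range2 is required when var2 is given")
        j2 = problem.column_index(var2)
        axis2 = _axis(range2, "range2")
    else:
        j2 = None
        axis2 = np.array([0.0])

    m, n = len(axis1), len(axis2)
    objective = np.full((m, n), np.nan)
    feasible = np.zeros((m, n), dtype=bool)
    lb0, ub0 = problem.v_lb.copy(), problem.v_ub.copy()
    try:
        for j in range(n):          # column-major: deterministic order
            for i in range(m):
                # a pin outside the variable's own bounds is infeasible
                if not (lb0[j1] <= axis1[i] <= ub0[j1]):
                    continue
                if j2 is not None and not (lb0[j2] <= axis2[j] <= ub0[j2]):
                    continue
                problem.v_lb[j1] = problem.v_ub[j1] = axis1[i]
                if j2 is not None:
                    problem.v_lb[j2] = problem.v_ub[j2] = axis2[j]
                sol = solve_diufba(problem)
                if sol.status == "optimal":
                    objective[i, j] = sol.objective_value
                    feasible[i, j] = True
    finally:
        problem.v_lb, problem.v_ub = lb0, ub0
    return PhPPGrid(var1=var1, var2=var2 if var2 is not None else None,
                    axis1=axis1, axis2=axis2,
                    objective=objective, feasible=feasible)


def _forward_gradient(values: np.ndarray, axis_vals: np.ndarray,
                      axis: int) -> np.ndarray:
    """Forward differences along one axis (backward at the last index), so
    a kink in a piecewise-linear surface lands exactly on its grid cell."""
    g = np.full(values.shape, np.nan)
    n = values.shape[axis]
    if n < 2:
        return np.zeros(values.shape)
    d = np.diff(axis_vals)
    sl = [slice(None)] * values.ndim

    def take(idx):
        s = list(sl)
        s[axis] = idx
        return tuple(s)

    fwd = (np.take(values, range(1, n), axis=axis)
           - np.take(values, range(0, n - 1), axis=axis))
    fwd = fwd / d.reshape([-1 if a == axis else 1 for a in range(values.ndim)])
    g[take(slice(0, n - 1))] = fwd
    g[take(n - 1)] = np.take(fwd, -1, axis=axis)
    return g


def classify_modes(grid: PhPPGrid, tolerance: float = 1e-6) -> np.ndarray:
    """Label contiguous regions of constant objective gradient.

    The finite-difference gradient is computed per cell along each
    scanned axis; cells whose gradients agree within ``tolerance`` are in
    the same gradient class, and 4-connected components of each class are
    numbered as metabolic modes (1-based; infeasible cells get 0).  The
    labeling is stored on the grid as ``grid.modes`` and returned.

    Grids smaller than 3 points in every scanned direction carry too
    little slope information: a single region is returned with a warning.
    """
    m, n = grid.objective.shape
    scanned = [m] + ([n] if grid.var2 is not None else [])
    if max(scanned) < 3:
        warnings.warn("grid too small for mode classification; "
                      "returning a single region", stacklevel=2)
        modes = np.where(grid.feasible, 1, 0)
        grid.modes = modes
        return modes

    grads = []
    if m > 1:
        grads.append(_forward_gradient(grid.objective, grid.axis1, axis=0))
    if n > 1:
        grads.append(_forward_gradient(grid.objective, grid.axis2, axis=1))
    gvecs = np.stack(grads, axis=-1)  # (m, n, k)

    # greedy clustering of gradient vectors within tolerance
    classes = np.zeros((m, n), dtype=int)
    reps: list[np.ndarray] = []
    for i in range(m):
        for j in range(n):
            if not grid.feasible[i, j] or np.any(np.isnan(gvecs[i, j])):
                classes[i, j] = -1
                continue
            for c, rep in enumerate(reps):
                if np.all(np.abs(gvecs[i, j] - rep) <= tolerance):
                    classes[i, j] = c
                    break
            else:
                classes[i, j] = len(reps)
                reps.append(gvecs[i, j])

    from scipy.ndimage import label as cc_label

    modes = np.zeros((m, n), dtype=int)
    next_mode = 1
    for c in range(len(reps)):
        mask = classes == c
        labeled, k = cc_label(mask)
        for comp in range(1, k + 1):
            modes[labeled == comp] = next_mode
            next_mode += 1
    grid.modes = modes
    return modes
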