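"""Minimal MILP backend contract and its scipy/HiGHS implementation.

The model container is deliberately dumb: contiguous variable blocks,
append-only rows, a family registry so that callers can audit which
constraint families ended up in the model.  Any solver able to consume a
sparse ``A x`` between row bounds can be plugged in behind :func:`solve`.
"""

from __future__ import annotations

import contextlib
import os
import time
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["MilpModel", "SolveResult", "HighsBackend", "INF"]

INF = float("inf")

# status values returned to callers
OPTIMAL = "optimal"
FEASIBLE = "feasible"  # limit hit but an incumbent exists
NO_SOLUTION = "no_solution"  # limit hit, no incumbent
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
ERROR = "error"


@dataclass
class SolveResult:
    status: str
    x: np.ndarray | None
    objective: float | None
    bound: float | None
    gap: float | None
    runtime: float

    @property
    def has_solution(self) -> bool:
        return self.x is not None


@dataclass
class _VarBlock:
    name: str
    offset: int
    shape: tuple[int, ...]
    kind: str  # "binary" | "integer" | "continuous"

    @property
    def size(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1


class MilpModel:
    """Sparse linear model with named variable blocks and a constraint
    family registry."""

    def __init__(self, name: str = "model"):
        self.name = name
        self.blocks: dict[str, _VarBlock] = {}
        self._lb: list[np.ndarray] = []
        self._ub: list[np.ndarray] = []
        self._int: list[np.ndarray] = []
        self.ncols = 0
        # rows as flat triplet buffers
        self._ri: list[int] = []
        self._ci: list[int] = []
        self._vv: list[float] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self._row_family: list[str] = []
        self.nrows = 0
        # family -> {"kind": "rows"|"bounds"|"alias", "count": int}
        self.families: dict[str, dict] = {}
        self._matrix_cache = None
        self.obj: np.ndarray | None = None
        self.obj_const = 0.0
        self.objective_id: str | None = None

    # -- variables -----------------------------------------------------

    def add_block(self, name: str, shape, kind: str = "binary",
                  lb: float = 0.0, ub: float | None = None) -> _VarBlock:
        if name in self.blocks:
            raise ValueError(f"variable block {name!r} already exists")
        self._matrix_cache = None
        shape = tuple(int(s) for s in shape)
        size = int(np.prod(shape)) if shape else 1
        if ub is None:
            ub = 1.0 if kind == "binary" else INF
        blk = _VarBlock(name, self.ncols, shape, kind)
        self.blocks[name] = blk
        self._lb.append(np.full(size, lb, dtype=float))
        self._ub.append(np.full(size, ub, dtype=float))
        self._int.append(np.full(size, 0.0 if kind == "continuous" else 1.0))
        self.ncols += size
        return blk

    def col(self, name: str, *idx) -> int:
        blk = self.blocks[name]
        return blk.offset + int(np.ravel_multi_index(idx, blk.shape))

    def cols(self, name: str) -> np.ndarray:
        blk = self.blocks[name]
        return np.arange(blk.offset, blk.offset + blk.size)

    def block_values(self, name: str, x: np.ndarray) -> np.ndarray:
        blk = self.blocks[name]
        return x[blk.offset:blk.offset + blk.size].reshape(blk.shape)

    def _bounds_view(self):
        lb = np.concatenate(self._lb) if self._lb else np.empty(0)
        ub = np.concatenate(self._ub) if self._ub else np.empty(0)
        return lb, ub

    def fix_upper(self, name: str, mask: np.ndarray, value: float = 0.0) -> None:
        """Clamp the upper bound of the masked entries of a block."""
        blk = self.blocks[name]
        k = [i for i, b in enumerate(self.blocks.values()) if b.name == name][0]
        arr = self._ub[k]
        arr[np.asarray(mask).ravel()] = value

    def set_bounds(self, name: str, lb=None, ub=None, idx=None) -> None:
        blk_names = list(self.blocks)
        k = blk_names.index(name)
        if idx is None:
            sel = slice(None)
        else:
            blk = self.blocks[name]
            sel = np.ravel_multi_index(tuple(np.asarray(a) for a in idx), blk.shape)
        if lb is not None:
            self._lb[k][sel] = lb
        if ub is not None:
            self._ub[k][sel] = ub

    # -- constraints ---------------------------------------------------

    def add_row(self, cols, vals, lb: float, ub: float, family: str) -> int:
        self._matrix_cache = None
        r = self.nrows
        self._ri.extend([r] * len(cols))
        self._ci.extend(int(c) for c in cols)
        self._vv.extend(float(v) for v in vals)
        self._row_lb.append(lb)
        self._row_ub.append(ub)
        self._row_family.append(family)
        self.nrows += 1
        fam = self.families.setdefault(family, {"kind": "rows", "count": 0})
        fam["count"] += 1
        return r

    def rows_of(self, family: str) -> list[int]:
        return [r for r, f in enumerate(self._row_family) if f == family]

    def row(self, r: int):
        """(cols, vals, lb, ub) of one row, for inspection."""
        cols = [c for rr, c in zip(self._ri, self._ci) if rr == r]
        vals = [v for rr, v in zip(self._ri, self._vv) if rr == r]
        return cols, vals, self._row_lb[r], self._row_ub[r]

    def register_bounds_family(self, family: str, count: int) -> None:
        """Record a constraint family realised purely through variable
        bounds (compatibility masks and similar)."""
        self.families[family] = {"kind": "bounds", "count": int(count)}

    def register_alias_family(self, family: str, target: str) -> None:
        self.families[family] = {"kind": "alias", "count": 0, "target": target}

    # -- objective -----------------------------------------------------

    def set_objective(self, coeffs: np.ndarray, constant: float = 0.0,
                      objective_id: str | None = None) -> None:
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.ncols,):
            raise ValueError("objective length mismatch")
        self.obj = coeffs
        self.obj_const = float(constant)
        self.objective_id = objective_id

    def objective_template(self) -> np.ndarray:
        return np.zeros(self.ncols)

    # -- export --------------------------------------------------------

    def matrix(self):
        if self._matrix_cache is None:
            A = sp.csr_array(
                (np.asarray(self._vv), (np.asarray(self._ri), np.asarray(self._ci))),
                shape=(self.nrows, self.ncols),
            )
            self._matrix_cache = (A, np.asarray(self._row_lb), np.asarray(self._row_ub))
        return self._matrix_cache

    def write_lp(self, path) -> None:
        """Write an LP-format text rendering of the model for inspection."""
        lb, ub = self._bounds_view()
        A, rlb, rub = self.matrix()
        A = A.tocsr()
        names = np.empty(self.ncols, dtype=object)
        for blk in self.blocks.values():
            for k in range(blk.size):
                idx = np.unravel_index(k, blk.shape) if blk.shape else ()
                names[blk.offset + k] = blk.name + "_" + "_".join(str(v) for v in idx)
        with open(path, "w") as fh:
            fh.write("\\ " + self.name + "\nMinimize\n obj:")
            if self.obj is not None:
                nz = np.nonzero(self.obj)[0]
                for c in nz:
                    fh.write(f" {self.obj[c]:+g} {names[c]}")
            fh.write("\nSubject To\n")
            for r in range(self.nrows):
                row = A[[r], :].tocoo()
                terms = " ".join(f"{v:+g} {names[c]}" for c, v in zip(row.coords[1], row.data))
                if rlb[r] == rub[r]:
                    fh.write(f" c{r}: {terms} = {rlb[r]:g}\n")
                else:
                    if rub[r] != INF:
                        fh.write(f" c{r}: {terms} <= {rub[r]:g}\n")
                    if rlb[r] != -INF:
                        fh.write(f" c{r}l: {terms} >= {rlb[r]:g}\n")
            fh.write("Bounds\n")
            for c in range(self.ncols):
                fh.write(f" {lb[c]:g} <= {names[c]} <= {ub[c]:g}\n")
            fh.write("Binaries\n")
            ints = np.concatenate(self._int)
            for c in np.nonzero(ints)[0]:
                fh.write(f" {names[c]}\n")
            fh.write("End\n")


@contextlib.contextmanager
def _muted_fds():
    """Silence HiGHS' direct C-level stdout chatter during a solve."""
    try:
        out_fd = os.dup(1)
        err_fd = os.dup(2)
    except OSError:  # exotic environments without real fds
        yield
        return
    devnull = os.open(os.devnull, os.O_WRONLY)
    try:
        os.dup2(devnull, 1)
        os.dup2(devnull, 2)
        yield
    finally:
        try:  # flush libc buffers so muted chatter cannot leak on restore
            import ctypes
            ctypes.CDLL(None).fflush(None)
        except Exception:
            pass
        os.dup2(out_fd, 1)
        os.dup2(err_fd, 2)
        os.close(devnull)
        os.close(out_fd)
        os.close(err_fd)


class HighsBackend:
    """Solve :class:`MilpModel` instances with HiGHS via scipy.

    The backend cannot accept MIP-start hints; pipeline code that would
    normally pass an incumbent falls back to constraint pinning.
    """

    supports_warm_start = False

    def __init__(self, seed: int = 0):
        # recorded for provenance; HiGHS runs deterministically single-threaded
        self.seed = int(seed)

    def solve(self, model: MilpModel, time_limit: float | None = None,
              mip_gap: float | None = None, relax: bool = False) -> SolveResult:
        if model.obj is None:
            model.set_objective(model.objective_template())
        lb, ub = model._bounds_view()
        A, rlb, rub = model.matrix()
        integrality = np.concatenate(model._int) if model._int else np.empty(0)
        if relax:
            integrality = np.zeros_like(integrality)
        options: dict = {"presolve": True}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        if mip_gap is not None:
            options["mip_rel_gap"] = float(mip_gap)
        t0 = time.perf_counter()
        with _muted_fds():
            res = milp(
                c=model.obj,
                constraints=LinearConstraint(A, rlb, rub),
                integrality=integrality,
                bounds=Bounds(lb, ub),
                options=options,
            )
        dt = time.perf_counter() - t0
        status = {0: OPTIMAL, 1: NO_SOLUTION, 2: INFEASIBLE, 3: UNBOUNDED}.get(res.status, ERROR)
        x = None
        objective = None
        bound = None
        gap = None
        if res.x is not None:
            x = np.asarray(res.x)
            objective = float(res.fun) + model.obj_const
            if status == NO_SOLUTION:
                status = FEASIBLE
        if getattr(res, "mip_dual_bound", None) is not None:
            bound = float(res.mip_dual_bound) + model.obj_const
        if getattr(res, "mip_gap", None) is not None and x is not None:
            gap = float(res.mip_gap)
        return SolveResult(status=status, x=x, objective=objective,
                           bound=bound, gap=gap, runtime=dt)
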