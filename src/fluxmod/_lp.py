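"""Thin wrapper around GLPK (via swiglpk) for the many small LPs this package solves.

All stages of the analysis (biomass maximisation, flux variability, flux-ratio
coupling bounds) solve linear programs over the steady-state polytope
{v : S v = 0, a <= v <= b}.  The problems within one stage differ only in
bounds and objective, so a single GLPK problem object is kept alive and
re-solved with a warm simplex basis; this is orders of magnitude faster than
rebuilding the LP per call and is what makes MCMC sampling with an FBA
viability test in the acceptance loop practical.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import swiglpk as glp

#: generic flux capacity; "unlimited" nutrient uptake is realised as -MAX_FLUX_BOUND
MAX_FLUX_BOUND = 1000.0

#: primal/dual feasibility tolerances passed to the simplex solver
FEASIBILITY_TOL = 1e-9

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
FAILED = "failed"

_STATUS = {
    glp.GLP_OPT: OPTIMAL,
    glp.GLP_FEAS: OPTIMAL,
    glp.GLP_NOFEAS: INFEASIBLE,
    glp.GLP_INFEAS: INFEASIBLE,
    glp.GLP_UNBND: UNBOUNDED,
    glp.GLP_UNDEF: FAILED,
}


class LinearSystem:
    """A stoichiometric equality system S v = 0 with box bounds, solved repeatedly.

    Parameters
    ----------
    A:
        Sparse (or dense) m x n matrix of equality-constraint coefficients.
    lb, ub:
        Initial per-column bounds (length n).
    ids:
        Optional column identifiers, kept for callers' bookkeeping.
    """

    def __init__(self, A, lb, ub, ids=None):
        A = sp.csc_matrix(A)
        self.m, self.n = A.shape
        self.ids = list(ids) if ids is not None else list(range(self.n))
        self._lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(self._lp, glp.GLP_MAX)
        glp.glp_add_rows(self._lp, self.m)
        glp.glp_add_cols(self._lp, self.n)
        for i in range(self.m):
            glp.glp_set_row_bnds(self._lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        self._lb = np.zeros(self.n)
        self._ub = np.zeros(self.n)
        self.set_bounds(np.asarray(lb, dtype=float), np.asarray(ub, dtype=float))
        coo = A.tocoo()
        ne = coo.nnz
        ia = glp.intArray(ne + 1)
        ja = glp.intArray(ne + 1)
        ar = glp.doubleArray(ne + 1)
        for k in range(ne):
            ia[k + 1] = int(coo.row[k]) + 1
            ja[k + 1] = int(coo.col[k]) + 1
            ar[k + 1] = float(coo.data[k])
        glp.glp_load_matrix(self._lp, ne, ia, ja, ar)
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF
        self._parm.tol_bnd = FEASIBILITY_TOL
        self._parm.tol_dj = FEASIBILITY_TOL
        self._obj_support = ()

    def __del__(self):  # pragma: no cover - interpreter shutdown order varies
        try:
            glp.glp_delete_prob(self._lp)
        except Exception:
            pass

    # -- bounds ---------------------------------------------------------
    def set_col_bounds(self, j: int, lo: float, hi: float) -> None:
        j = int(j)
        if lo > hi:
            raise ValueError(f"column {j}: lower bound {lo} exceeds upper {hi}")
        if lo == hi:
            glp.glp_set_col_bnds(self._lp, j + 1, glp.GLP_FX, lo, hi)
        else:
            glp.glp_set_col_bnds(self._lp, j + 1, glp.GLP_DB, lo, hi)
        self._lb[j] = lo
        self._ub[j] = hi

    def set_bounds(self, lb, ub) -> None:
        lb = np.asarray(lb, dtype=float)
        ub = np.asarray(ub, dtype=float)
        changed = np.nonzero((lb != self._lb) | (ub != self._ub))[0]
        for j in changed:
            self.set_col_bounds(int(j), float(lb[j]), float(ub[j]))

    def get_bounds(self):
        return self._lb.copy(), self._ub.copy()

    # -- objective ------------------------------------------------------
    def set_objective(self, c, maximize: bool = True) -> None:
        """Set the objective vector; `c` may be dense or a {col: coef} mapping."""
        for j in self._obj_support:
            glp.glp_set_obj_coef(self._lp, j + 1, 0.0)
        if isinstance(c, dict):
            support = tuple(int(j) for j in c)
            for j, cj in c.items():
                glp.glp_set_obj_coef(self._lp, int(j) + 1, float(cj))
        else:
            c = np.asarray(c, dtype=float)
            support = tuple(int(j) for j in np.nonzero(c)[0])
            for j in support:
                glp.glp_set_obj_coef(self._lp, j + 1, float(c[j]))
        self._obj_support = support
        glp.glp_set_obj_dir(self._lp, glp.GLP_MAX if maximize else glp.GLP_MIN)

    # -- solving --------------------------------------------------------
    def solve(self, extract_vector: bool = True):
        """Solve the current LP. Returns (status, objective, solution vector)."""
        ret = glp.glp_simplex(self._lp, self._parm)
        status = glp.glp_get_status(self._lp)
        if ret != 0 or status == glp.GLP_UNDEF:
            # warm basis went stale; restart from a standard basis
            glp.glp_std_basis(self._lp)
            ret = glp.glp_simplex(self._lp, self._parm)
            status = glp.glp_get_status(self._lp)
        label = _STATUS.get(status, FAILED) if ret == 0 else FAILED
        if label != OPTIMAL:
            return label, np.nan, None
        if not extract_vector:
            return label, glp.glp_get_obj_val(self._lp), None
        x = np.empty(self.n)
        for j in range(self.n):
            x[j] = glp.glp_get_col_prim(self._lp, j + 1)
        return label, glp.glp_get_obj_val(self._lp), x
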