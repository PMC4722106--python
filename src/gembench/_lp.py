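"""Thin linear-programming layer over scipy's HiGHS interface.

All benchmark LPs are steady-state flux problems: minimize ``c @ x``
subject to ``A_eq @ x = b_eq``, optional ``A_ub @ x <= b_ub`` and box
bounds.  Centralising the call keeps solver options (and failure
handling) in one place.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = ["SolverError", "solve_lp"]


class SolverError(RuntimeError):
    """LP solver did not return a usable status."""

    def __init__(self, status: int, message: str):
        self.status = status
        super().__init__(f"LP solver failure (status {status}): {message}")


#: linprog status code for infeasible problems
INFEASIBLE = 2
UNBOUNDED = 3


def solve_lp(
    c,
    A_eq: Optional[sp.spmatrix] = None,
    b_eq=None,
    A_ub: Optional[sp.spmatrix] = None,
    b_ub=None,
    bounds=None,
):
    """Solve an LP; returns ``(x, fun)`` or ``None`` if infeasible.

    Raises :class:`SolverError` for any status other than optimal or
    infeasible (unbounded problems indicate a modelling bug upstream —
    every flux variable is expected to be boxed).
    """
    res = linprog(np.asarray(c, dtype=float), A_ub=A_ub, b_ub=b_ub,
                  A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 0:
        return res.x, res.fun
    if res.status == INFEASIBLE:
        return None
    raise SolverError(res.status, res.message)
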