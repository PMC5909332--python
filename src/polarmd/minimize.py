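"""Limited-memory BFGS minimisation of the potential energy (wraps the
scipy L-BFGS-B implementation behind an RMS-gradient termination surface)."""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize as _scipy_minimize


class LineSearchError(RuntimeError):
    def __init__(self, message, positions, energy):
        super().__init__(message)
        self.positions = positions
        self.energy = energy


def lbfgs_minimize(x0, energy_gradient, history=10, grms_tol=1e-4,
                   max_iterations=1000):
    """Minimise ``energy_gradient(x) -> (E, g)`` over a flat or (N,3) array.

    Terminates when the RMS gradient drops below ``grms_tol``; returns
    (x_min, E_min, info).  Line-search failures raise LineSearchError with
    the last accepted point attached.
    """
    shape = np.shape(x0)
    x0f = np.asarray(x0, dtype=float).ravel()
    nvar = x0f.size
    best = {"x": x0f.copy(), "E": None}

    def fun(xf):
        E, g = energy_gradient(xf.reshape(shape))
        g = np.asarray(g, dtype=float).ravel()
        if best["E"] is None or E < best["E"]:
            best["x"], best["E"] = xf.copy(), E
        return E, g

    def stop(xf):
        _, g = energy_gradient(xf.reshape(shape))
        return np.sqrt(np.mean(np.asarray(g) ** 2)) <= grms_tol

    res = _scipy_minimize(
        fun, x0f, jac=True, method="L-BFGS-B",
        options={"maxcor": history, "maxiter": max_iterations,
                 "gtol": grms_tol, "ftol": 1e-14})
    E, g = energy_gradient(res.x.reshape(shape))
    grms = float(np.sqrt(np.mean(np.asarray(g) ** 2)))
    if grms > grms_tol and not res.success and "ABNORMAL" in str(res.message):
        raise LineSearchError(str(res.message),
                              best["x"].reshape(shape), best["E"])
    info = {"iterations": res.nit, "grms": grms,
            "converged": grms <= grms_tol, "message": str(res.message)}
    return res.x.reshape(shape), float(E), info


def minimize_system(engine, positions, grms_tol=1e-3, max_iterations=500,
                    history=10):
    """Minimise an Engine's potential energy over atomic positions."""

    def eg(x):
        out = engine.evaluate(x)
        return out["potential"], -out["forces"]

    return lbfgs_minimize(positions, eg, history=history,
                          grms_tol=grms_tol, max_iterations=max_iterations)
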