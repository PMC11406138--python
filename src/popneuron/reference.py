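"""Fixed-step reference integration for cross-checking the adaptive solver.

A classical 4th-order Runge-Kutta integrator marching at a small constant
step (0.001 ms by default).  It shares the model's vector field with the
production engine but none of its adaptive step-size machinery, so
agreement between the two localises errors to the integration scheme.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from ._engine import _RHS, DT_RECORD, _stim_args, compile_model
from .membrane import NeuronModel


def rk4_trajectory(model: NeuronModel, protocol, t_stop: float,
                   dt: float = 0.001, v_init: float = -65.0
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate with fixed-step RK4 and sample on the 40 kHz grid.

    Returns (t, V) with t on the same 40 kHz grid the production solver
    records on, so traces can be compared pointwise.  ``dt`` must divide
    the 0.025 ms record interval.
    """
    steps_per_record = int(round(DT_RECORD / dt))
    if abs(steps_per_record * dt - DT_RECORD) > 1e-12:
        raise ValueError("dt must divide the 0.025 ms record interval")
    cmodel = compile_model(model)
    args = (cmodel.v0, cmodel.dv, cmodel.inf_tab, cmodel.tau_tab, cmodel.expo,
            cmodel.seg, cmodel.gbar, cmodel.erev, cmodel.cm_uf,
            *_stim_args(cmodel, protocol))
    n_rec = int(np.floor(t_stop / DT_RECORD + 1e-9)) + 1
    t_out = DT_RECORD * np.arange(n_rec)
    v_out = np.empty(n_rec)
    y = cmodel.initial_vector(v_init)
    v_out[0] = y[0]
    t = 0.0
    for rec in range(1, n_rec):
        for _ in range(steps_per_record):
            k1 = _RHS(y, t, *args)
            k2 = _RHS(y + 0.5 * dt * k1, t + 0.5 * dt, *args)
            k3 = _RHS(y + 0.5 * dt * k2, t + 0.5 * dt, *args)
            k4 = _RHS(y + dt * k3, t + dt, *args)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += dt
        v_out[rec] = y[0]
    return t_out, v_out
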