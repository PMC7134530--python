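"""Independent reference implementations used as test oracles.

These are deliberately written from the printed update equations with plain
Python floats, not by calling the package's tensor code, so they stay
independent of the paths they check.
"""

from __future__ import annotations

import math


def scalar_convlstm_oracle(p: dict, xs: list[float]) -> list[tuple[float, float]]:
    """Scalar LSTM recurrence with peepholes and ReLU state activation.

    `p` maps the weight names (wxf, whf, wcf, bf, wxi, whi, wci, bi, wxc,
    whc, bc, wxo, who, wco, bo) to floats. Returns (h_t, c_t) per step from
    a zero initial state.
    """
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    relu = lambda v: v if v > 0 else 0.0
    h = c = 0.0
    out = []
    for x in xs:
        f = sig(p["wxf"] * x + p["whf"] * h + p["wcf"] * c + p["bf"])
        i = sig(p["wxi"] * x + p["whi"] * h + p["wci"] * c + p["bi"])
        c = f * c + i * relu(p["wxc"] * x + p["whc"] * h + p["bc"])
        o = sig(p["wxo"] * x + p["who"] * h + p["wco"] * c + p["bo"])
        h = o * relu(c)
        out.append((h, c))
    return out


def trilinear_at(grid, z: float, y: float, x: float) -> float:
    """Direct trilinear interpolation of a 3D grid at one fractional index."""
    import numpy as np

    grid = np.asarray(grid, dtype=float)
    out = 0.0
    z0, y0, x0 = int(math.floor(z)), int(math.floor(y)), int(math.floor(x))
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                zi = min(max(z0 + dz, 0), grid.shape[0] - 1)
                yi = min(max(y0 + dy, 0), grid.shape[1] - 1)
                xi = min(max(x0 + dx, 0), grid.shape[2] - 1)
                wz = 1 - abs(z - (z0 + dz))
                wy = 1 - abs(y - (y0 + dy))
                wx = 1 - abs(x - (x0 + dx))
                if wz < 0 or wy < 0 or wx < 0:
                    continue
                out += grid[zi, yi, xi] * wz * wy * wx
    return out
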