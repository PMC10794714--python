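"""Independent oracles shared by the unit and acceptance tests.

Deliberately naive implementations (dense scans, explicit sliding loops)
kept separate from the code paths they check.
"""

import numpy as np
from scipy import ndimage


def nullcline_intersections(rhs, box, res=0.1):
    """Count nullcline intersections by dense sign-change scanning.

    Marks grid cells where both components of the vector field change sign
    and clusters adjacent marks; each cluster is one root of the system.
    """
    g = np.arange(0.0, box + res, res)
    X, Y = np.meshgrid(g, g, indexing="ij")
    dx, dy = rhs(X, Y)
    sx = np.sign(dx)
    sy = np.sign(dy)
    zx = np.zeros(sx.shape, bool)
    zy = np.zeros(sy.shape, bool)
    zx[:-1, :] |= sx[:-1, :] != sx[1:, :]
    zx[:, :-1] |= sx[:, :-1] != sx[:, 1:]
    zy[:-1, :] |= sy[:-1, :] != sy[1:, :]
    zy[:, :-1] |= sy[:, :-1] != sy[:, 1:]
    _, n = ndimage.label(zx & zy, structure=np.ones((3, 3)))
    return n


def brute_force_raw(matrix, template, penalty):
    """Explicit filter sliding over every overlapping placement."""
    d = template.shape[0]
    m = matrix.shape[0]
    big = np.zeros((m + 2 * (d - 1), m + 2 * (d - 1)), dtype=float)
    big[d - 1:d - 1 + m, d - 1:d - 1 + m] = matrix
    best = -np.inf
    for r in range(m + d - 1):
        for c in range(m + d - 1):
            win = big[r:r + d, c:c + d]
            best = max(best, float((win * template).sum()
                                   - (win * penalty).sum()))
    return best
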