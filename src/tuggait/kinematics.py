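"""Per-gait-cycle kinematic measurements shared by the simulator truth channel
and the signal-extraction path.

A gait cycle *c* on one side is the interval ``[hs[c], hs[c+1])``; the swing
that ends it runs from ``to[c+1]`` to ``hs[c+1]`` (``to[i]`` precedes
``hs[i]``).  The window rules below define where each extremum is read so the
two paths measure the same quantity on their respective angle tracks.
"""

from __future__ import annotations

import numpy as np


def _win(t, a, b):
    i0, i1 = np.searchsorted(t, a), np.searchsorted(t, b)
    return slice(i0, max(i1, i0 + 1))


def shank_cycle_kinematics(t, theta, omega, hs, to):
    """Per-cycle shank sagittal extrema and swing peak angular velocity.

    Returns (fwd, bwd, pv) arrays of length ``len(hs) - 1``; cycle *c* reads
    its forward maximum near ``hs[c+1]``, its backward maximum (minimum angle)
    just after ``to[c+1]``, and its peak velocity inside the swing window.
    """
    m = len(hs) - 1
    fwd = np.full(m, np.nan)
    bwd = np.full(m, np.nan)
    pv = np.full(m, np.nan)
    for c in range(m):
        t_to, t_hs = to[c + 1], hs[c + 1]
        sw = t_hs - t_to
        if sw <= 0:
            continue
        bwd[c] = theta[_win(t, t_to - 0.15 * sw, t_to + 0.5 * sw)].min()
        fwd[c] = theta[_win(t, t_hs - 0.5 * sw, t_hs + 0.15 * sw)].max()
        pv[c] = omega[_win(t, t_to, t_hs)].max()
    return fwd, bwd, pv


def arm_cycle_kinematics(t, theta, omega, hs):
    """Per-cycle arm sagittal extrema (anterior-positive) and peak |velocity|.

    The backward extreme sits at the cycle-start heel strike, the forward
    extreme mid-cycle.  Returns (fwd, bwd, pv) of length ``len(hs) - 1``.
    """
    m = len(hs) - 1
    fwd = np.full(m, np.nan)
    bwd = np.full(m, np.nan)
    pv = np.full(m, np.nan)
    for c in range(m):
        a, b = hs[c], hs[c + 1]
        Tc = b - a
        bwd[c] = theta[_win(t, a - 0.25 * Tc, a + 0.25 * Tc)].min()
        fwd[c] = theta[_win(t, a + 0.25 * Tc, b - 0.1 * Tc)].max()
        pv[c] = np.abs(omega[_win(t, a, b)]).max()
    return fwd, bwd, pv


def plane_cycle_stats(t, theta, omega, cycles):
    """Per-cycle range of motion and peak |angular velocity| for one plane.

    ``cycles`` is an iterable of (start, end) intervals; returns (rom, pv)
    arrays of the same length.
    """
    cycles = list(cycles)
    rom = np.full(len(cycles), np.nan)
    pv = np.full(len(cycles), np.nan)
    for i, (a, b) in enumerate(cycles):
        w = _win(t, a, b)
        seg = theta[w]
        rom[i] = seg.max() - seg.min()
        pv[i] = np.abs(omega[w]).max()
    return rom, pv
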