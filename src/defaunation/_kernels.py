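"""Fused detection-likelihood scan.

The detection layer touches every (unit, station, occasion) cell twice per
MCMC sweep; fusing the scan avoids a pile of full-size temporaries. A
numba-compiled version is used when numba is importable, with an
equivalent vectorized numpy fallback.
"""

from __future__ import annotations

import math

import numpy as np


def _det_scan_numpy(ap, be, eff, mask, y):
    lp = ap[:, None, None] + be[:, None, None] * eff[None]
    sp = np.logaddexp(0.0, lp)
    m = mask[None].astype(float)
    s = ((y * lp - sp) * m).sum(axis=2)
    logq = -(sp * m).sum(axis=2)
    return s, logq


try:
    from numba import njit

    @njit(fastmath=True)
    def _det_scan_numba(ap, be, eff, mask, y):  # pragma: no cover - compiled
        n_units, n_stations, n_occ = y.shape
        s = np.zeros((n_units, n_stations))
        logq = np.zeros((n_units, n_stations))
        for i in range(n_units):
            a = ap[i]
            b = be[i]
            for j in range(n_stations):
                acc = 0.0
                q = 0.0
                for k in range(n_occ):
                    if mask[j, k]:
                        lp = a + b * eff[j, k]
                        if lp > 0.0:
                            sp = lp + math.log1p(math.exp(-lp))
                        else:
                            sp = math.log1p(math.exp(lp))
                        q += sp
                        acc += y[i, j, k] * lp - sp
                s[i, j] = acc
                logq[i, j] = -q
        return s, logq

    det_scan = _det_scan_numba
except ImportError:  # pragma: no cover
    det_scan = _det_scan_numpy


def det_scan_reference(ap, be, eff, mask, y):
    """Pure-numpy scan, kept callable for cross-checking the fused kernel."""
    return _det_scan_numpy(ap, be, eff, mask, y)
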