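"""Uniform-grid discrete-time Fourier transform evaluation.

Every transform in the pipeline is a plain DTFT sum

    X_m = Σ_n x_n · exp(sign · j 2π g_n h_m)

between two uniform grids ``g`` (input) and ``h`` (output) whose
densities are fully decoupled — the output grid never depends on the
input length, which is why FFTs are not used directly.  For small
problems the sum is evaluated as an explicit kernel-matrix product; for
large ones the algebraically identical chirp-z factorisation

    g_n h_m = g_0 h_m + n Δg h_0 + n Δg m Δh

reduces it to a Bluestein chirp-z transform (``scipy.signal.czt``),
which is O((N+M) log) instead of O(N·M).  Both paths agree to roughly
machine precision; the crossover is a pure performance threshold.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import czt

__all__ = ["dtft_uniform"]

#: Kernel-size threshold (n_in * n_out) above which the chirp-z path is used.
_CZT_THRESHOLD = 1 << 16


def dtft_uniform(
    x: np.ndarray,
    in_start: float,
    in_step: float,
    out_start: float,
    out_step: float,
    n_out: int,
    sign: int,
) -> np.ndarray:
    """Evaluate the DTFT of ``x`` between two uniform grids.

    Parameters
    ----------
    x
        Input samples on the grid ``in_start + n * in_step``.
    out_start, out_step, n_out
        Output grid ``out_start + m * out_step`` for ``m < n_out``.
    sign
        +1 for an inverse-style transform (``e^{+j2πgh}``), -1 for a
        forward one.

    Returns
    -------
    Complex array of length ``n_out``.
    """
    x = np.asarray(x, dtype=complex)
    n_in = x.size
    s = 2j * np.pi * sign
    if n_in * int(n_out) <= _CZT_THRESHOLD:
        grid_in = in_start + in_step * np.arange(n_in)
        grid_out = out_start + out_step * np.arange(int(n_out))
        return np.exp(s * np.outer(grid_out, grid_in)) @ x
    # chirp-z factorisation
    n = np.arange(n_in)
    y = x * np.exp(s * in_step * out_start * n)
    inner = czt(y, m=int(n_out), w=np.exp(s * in_step * out_step), a=1.0)
    m = np.arange(int(n_out))
    return inner * np.exp(s * in_start * (out_start + out_step * m))
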