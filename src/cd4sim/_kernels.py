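"""Compiled inner loops for rate and RHS evaluation.

The simulator spends essentially all of its time evaluating reaction rates
inside the ODE solver, so the inner loop is JIT-compiled with numba when
available; a numpy implementation in :mod:`cd4sim.model` is the fallback
(and the reference the kernel is tested against).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def reaction_rates_kernel(
    lv,
    n_rxn,
    ma_idx, ma_k,
    h_idx, h_vmax, h_km, h_n, h_driver,
    sub_rxn, sub_idx, sub_st,
    co_rxn, co_idx, co_ka,
    in_rxn, in_idx, in_ki,
):
    rates = np.zeros(n_rxn)
    for i in range(ma_idx.shape[0]):
        rates[ma_idx[i]] = ma_k[i]
    for i in range(h_idx.shape[0]):
        d = lv[h_driver[i]]
        if d <= 0.0 or h_vmax[i] == 0.0:
            frac = 0.0
        else:
            # Hill fraction via log((d/km)^n), stable for large n
            t = h_n[i] * (np.log(d) - np.log(h_km[i]))
            if t > 700.0:
                frac = 1.0
            elif t < -700.0:
                frac = 0.0
            else:
                r = np.exp(t)
                frac = r / (1.0 + r)
        rates[h_idx[i]] = h_vmax[i] * frac
    for i in range(sub_rxn.shape[0]):
        rates[sub_rxn[i]] *= lv[sub_idx[i]] ** sub_st[i]
    for i in range(co_rxn.shape[0]):
        x = lv[co_idx[i]]
        rates[co_rxn[i]] *= x / (co_ka[i] + x)
    for i in range(in_rxn.shape[0]):
        rates[in_rxn[i]] *= in_ki[i] / (in_ki[i] + lv[in_idx[i]])
    return rates


@njit(cache=True)
def rhs_kernel(
    y,
    levels,
    dyn_index,
    keep_mask,
    stoich,
    n_rxn,
    ma_idx, ma_k,
    h_idx, h_vmax, h_km, h_n, h_driver,
    sub_rxn, sub_idx, sub_st,
    co_rxn, co_idx, co_ka,
    in_rxn, in_idx, in_ki,
):
    lv = levels.copy()
    for i in range(dyn_index.shape[0]):
        lv[dyn_index[i]] = y[i]
    for i in range(lv.shape[0]):
        v = lv[i]
        if v < 0.0:
            v = 0.0
        lv[i] = v * keep_mask[i]
    rates = reaction_rates_kernel(
        lv, n_rxn,
        ma_idx, ma_k,
        h_idx, h_vmax, h_km, h_n, h_driver,
        sub_rxn, sub_idx, sub_st,
        co_rxn, co_idx, co_ka,
        in_rxn, in_idx, in_ki,
    )
    return stoich @ rates
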