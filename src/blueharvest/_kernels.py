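"""Fused numba kernel for the size-spectrum substep.

The numpy implementation in :mod:`blueharvest.ecology` is the reference; this
kernel computes the identical update in a single pass over the
``(ncell, ngroup, nbin)`` state, which matters because global runs take
O(10^4) substeps over O(10^3) cells.  ``step_cells`` dispatches here when
numba is importable; a unit test asserts agreement between the two paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False, fastmath=False)
def substep_kernel(B, npp, T, F, dt,
                   widths, active, psi, m_pow_b, m_pow_bm1, m_pow_hm1,
                   eps_pow_n, conv, growth_coef, mort_coef, egg_survival,
                   recruit_k, ea_over_kb, t_ref_k,
                   B_out, harvest, died_tot, recruit_tot, top_loss, food_out):
    nc, ng, nb = B.shape
    for c in range(nc):
        tf = np.exp(-ea_over_kb * (1.0 / (T[c] + 273.15) - 1.0 / t_ref_k))
        einput = conv * npp[c] * eps_pow_n / tf

        # unconstrained assimilation demand
        demand = 0.0
        for g in range(ng):
            for i in range(nb):
                if active[g, i]:
                    demand += growth_coef * tf * m_pow_bm1[i] * B[c, g, i]
        if demand > 0.0:
            food = einput / demand
            if food > 1.0:
                food = 1.0
        else:
            food = 1.0
        food_out[c] = food

        r_sat = einput / ng
        h_c = 0.0
        died_c = 0.0
        rec_c = 0.0
        top_c = 0.0
        for g in range(ng):
            # egg production and recruitment
            egg = 0.0
            for i in range(nb):
                if active[g, i]:
                    egg += psi[g, i] * growth_coef * tf * m_pow_bm1[i] \
                        * B[c, g, i] * food
            egg *= egg_survival
            if egg > 0.0:
                recruit = r_sat * egg / (egg + recruit_k)
            else:
                recruit = 0.0
            rec_c += recruit * dt

            prev_flux = 0.0
            for i in range(nb):
                if not active[g, i]:
                    B_out[c, g, i] = 0.0
                    continue
                gamma = growth_coef * tf * m_pow_b[i] * food * (1.0 - psi[g, i])
                flux = gamma * B[c, g, i] / widths[i]
                b_adv = B[c, g, i] + dt * (prev_flux - flux)
                if i == 0:
                    b_adv += dt * recruit
                if b_adv < 0.0:
                    b_adv = 0.0
                # is this the group's top active bin? flux is lost there
                if i + 1 >= nb or not active[g, i + 1]:
                    top_c += flux * dt
                    prev_flux = 0.0
                else:
                    prev_flux = flux

                z_nat = mort_coef * tf * m_pow_hm1[i]
                z_tot = z_nat + F[c, g, i]
                decay = np.exp(-z_tot * dt)
                b_new = b_adv * decay
                died = b_adv - b_new
                died_c += died
                if z_tot > 0.0:
                    h_c += died * (F[c, g, i] / z_tot)
                B_out[c, g, i] = b_new
        harvest[c] = h_c
        died_tot[c] = died_c
        recruit_tot[c] = rec_c
        top_loss[c] = top_c
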