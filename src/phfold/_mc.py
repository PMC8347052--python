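"""Numba Metropolis kernel for protonation-state sampling.

Single-site-flip Metropolis over the 2^N protonation microstates at each pH
grid point, warm-started from the previous grid point. The chain is
autocorrelated, so the reported standard error is a conservative composite:
the larger of batch-means estimates at two batch lengths (which bracket
unknown correlation times) and a Laplace-smoothed binomial floor (which
covers near-frozen sites whose batches show no variance at all).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: batch counts for the two batch-means scales
N_BATCHES_FINE = 20
N_BATCHES_COARSE = 5


@njit(cache=False)
def _mc_sweep_grid(pk, q_deprot, W, ph_values, kT, n_sweeps, n_burn, seed):
    """Return (theta, theta_se) of shape (n_pH, n_sites).

    Microstate free energy (units of kT):
        G/kT = ln10 * sum_i x_i (pH - pKa_i) + (1/kT) sum_{i<j} W_ij q_i q_j
    with x_i = 1 protonated, q_i = q_deprot_i + x_i.
    """
    ln10 = np.log(10.0)
    n = pk.shape[0]
    n_ph = ph_values.shape[0]
    theta = np.zeros((n_ph, n))
    theta_se = np.zeros((n_ph, n))
    np.random.seed(seed)

    # start fully protonated, appropriate at the acidic end of the sweep
    x = np.ones(n, dtype=np.int64)
    q = q_deprot + x

    n_keep = n_sweeps - n_burn
    fine_len = max(n_keep // N_BATCHES_FINE, 1)
    n_fine = n_keep // fine_len
    fine_acc = np.zeros((n_fine, n))

    for p in range(n_ph):
        ph = ph_values[p]
        fine_acc[:, :] = 0.0
        for sweep in range(n_sweeps):
            for _ in range(n):
                i = np.random.randint(0, n)
                dx = 1 - 2 * x[i]  # +1: deprotonated -> protonated
                e_coup = 0.0
                for j in range(n):
                    if j != i:
                        e_coup += W[i, j] * q[j]
                d_g = ln10 * dx * (ph - pk[i]) + dx * e_coup / kT
                if d_g <= 0.0 or np.random.random() < np.exp(-d_g):
                    x[i] += dx
                    q[i] += dx
            if sweep >= n_burn:
                b = (sweep - n_burn) // fine_len
                if b < n_fine:
                    for i in range(n):
                        fine_acc[b, i] += x[i]
        n_used = n_fine * fine_len
        coarse_group = max(n_fine // N_BATCHES_COARSE, 1)
        n_coarse = n_fine // coarse_group
        for i in range(n):
            mean = 0.0
            for b in range(n_fine):
                fine_acc[b, i] /= fine_len
                mean += fine_acc[b, i]
            mean /= n_fine
            # fine batch means
            var_f = 0.0
            for b in range(n_fine):
                d = fine_acc[b, i] - mean
                var_f += d * d
            if n_fine > 1:
                var_f /= n_fine - 1
            se_f = np.sqrt(var_f / n_fine)
            # coarse batch means (longer batches, larger correlation times)
            se_c = 0.0
            if n_coarse > 1:
                var_c = 0.0
                for bc in range(n_coarse):
                    m = 0.0
                    for b in range(bc * coarse_group, (bc + 1) * coarse_group):
                        m += fine_acc[b, i]
                    m /= coarse_group
                    d = m - mean
                    var_c += d * d
                var_c /= n_coarse - 1
                se_c = np.sqrt(var_c / n_coarse)
            # Laplace-smoothed binomial floor for near-frozen sites
            count = mean * n_used
            p_tilde = (count + 2.0) / (n_used + 4.0)
            se_b = np.sqrt(p_tilde * (1.0 - p_tilde) / n_used)
            theta[p, i] = mean
            theta_se[p, i] = max(se_f, se_c, se_b)
        # x, q carry over as the warm start for the next pH point
    return theta, theta_se
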