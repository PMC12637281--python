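"""Independent brute-force oracles used by the test suite only.

The resonance oracle builds the full tensor-product Hamiltonian
(electron x all nuclei), scans the gap between every pair of sorted
eigenvalues over a dense field window and refines each sign change with
Brent's method -- no pair-block factorization, no Newton iteration, no
shared code path with the simulator it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from spinpol.constants import MU_B_MHZ_PER_MT
from spinpol.spinsim import SpinSystem, spin_operators


def _full_hamiltonian_terms(system: SpinSystem, theta: float, phi: float):
    n_vec = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])
    dims = [int(round(2 * c.I)) + 1 for c in system.couplings]
    dim_total = 2 * int(np.prod(dims)) if dims else 2

    def embed(op, slot):
        # slot 0 = electron, slot j>=1 = nucleus j-1
        mats = [np.eye(2, dtype=complex)] + [np.eye(d, dtype=complex) for d in dims]
        mats[slot] = op
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    s_ops = [embed(op, 0) for op in spin_operators(0.5)]
    c = system.g.matrix() @ n_vec
    h_zeeman_unit = MU_B_MHZ_PER_MT * sum(ci * si for ci, si in zip(c, s_ops))
    h_hyperfine = np.zeros((dim_total, dim_total), dtype=complex)
    h_nuclear_unit = np.zeros((dim_total, dim_total), dtype=complex)
    for j, coupling in enumerate(system.couplings):
        i_ops = [embed(op, j + 1) for op in spin_operators(coupling.I)]
        amat = coupling.tensor.matrix()
        for k in range(3):
            for l in range(3):
                h_hyperfine += amat[k, l] * (s_ops[k] @ i_ops[l])
        gamma = coupling.gamma_MHz_per_mT
        h_nuclear_unit -= gamma * sum(ni * ii for ni, ii in zip(n_vec, i_ops))
    # microwave operator: electron spin along an axis perpendicular to B0
    perp = np.cross(n_vec, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.array([1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    perp2 = np.cross(n_vec, perp)
    sx1 = sum(pi * si for pi, si in zip(perp, s_ops))
    sx2 = sum(pi * si for pi, si in zip(perp2, s_ops))
    geff = float(np.linalg.norm(c))
    return h_zeeman_unit + h_nuclear_unit, h_hyperfine, sx1, sx2, geff, dim_total


def oracle_resonance_fields(
    system: SpinSystem,
    theta: float,
    phi: float,
    mw_frequency_GHz: float,
    window_mT: float = 25.0,
    n_scan: int = 600,
    intensity_floor: float = 1e-4,
):
    """All resonance fields (mT) with intensities, by dense scan + brentq."""
    h_unit, h_fix, sx1, sx2, geff, dim = _full_hamiltonian_terms(system, theta, phi)
    nu_MHz = mw_frequency_GHz * 1e3
    b_center = nu_MHz / (MU_B_MHZ_PER_MT * geff)
    b_grid = np.linspace(b_center - window_mT, b_center + window_mT, n_scan)
    eigvals = np.array([np.linalg.eigvalsh(b * h_unit + h_fix) for b in b_grid])

    def gap(b, i, j):
        w = np.linalg.eigvalsh(b * h_unit + h_fix)
        return w[j] - w[i] - nu_MHz

    roots = []
    for i in range(dim):
        for j in range(i + 1, dim):
            f = eigvals[:, j] - eigvals[:, i] - nu_MHz
            sign_changes = np.nonzero(np.diff(np.sign(f)) != 0)[0]
            for k in sign_changes:
                b_root = optimize.brentq(
                    gap, b_grid[k], b_grid[k + 1], args=(i, j), xtol=1e-10
                )
                w, v = np.linalg.eigh(b_root * h_unit + h_fix)
                m1 = v[:, j].conj() @ sx1 @ v[:, i]
                m2 = v[:, j].conj() @ sx2 @ v[:, i]
                inten = (abs(m1) ** 2 + abs(m2) ** 2) / 2.0
                roots.append((b_root, float(inten)))
    roots = [(b, a) for b, a in roots if a > intensity_floor]
    roots.sort()
    return roots
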