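"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain loops,
direct formulas and numerical quadrature, so they can serve as oracles.
"""

import numpy as np

COULOMB = 332.0636


def brute_gromos_cluster(values: np.ndarray, cutoff: float):
    """Daura clustering by literal re-reading of the algorithm."""
    n = len(values)
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned
                        if j != i and values[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in unassigned
                         if j == best or values[best, j] <= cutoff)
        clusters.append((best, members))
        unassigned -= set(members)
    clusters.sort(key=lambda c: -len(c[1]))
    return clusters


def brute_closest_waters(o_positions: np.ndarray, com: np.ndarray, n: int):
    d = [(float(np.linalg.norm(o - com)), k) for k, o in enumerate(o_positions)]
    d.sort()
    return sorted(k for _, k in d[:n])


def brute_nonbonded(coords, charges, rmin_half, epsilon, excluded, scaled14,
                    scee=1.2, scnb=2.0):
    """Double-loop gas-phase vdW + Coulomb with exclusion/1-4 rules."""
    n = len(coords)
    e_vdw = e_elec = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            se, sv = (1.0 / scee, 1.0 / scnb) if (i, j) in scaled14 else (1.0, 1.0)
            e_elec += se * COULOMB * charges[i] * charges[j] / d
            eps = np.sqrt(epsilon[i] * epsilon[j])
            if eps > 0:
                sr6 = ((rmin_half[i] + rmin_half[j]) / d) ** 6
                e_vdw += sv * eps * (sr6 * sr6 - 2.0 * sr6)
    return e_vdw, e_elec


def quadrature_hct(d, ri, sj, n=4000):
    """Numerical (1/4π)∫|x|⁻⁴ dV over a sphere of radius sj at distance d,
    excluding |x| < ri, by spherical-shell quadrature."""
    tot = 0.0
    if d < sj and sj - d > ri:
        u = np.linspace(ri, sj - d, n)
        tot += np.trapezoid(1.0 / u ** 2, u)
    lo = max(ri, abs(d - sj))
    hi = d + sj
    if hi > lo:
        u = np.linspace(lo, hi, n)
        cosb = (u * u + d * d - sj * sj) / (2.0 * d * u)
        f = np.clip((1.0 - cosb) / 2.0, 0.0, 1.0)
        tot += np.trapezoid(f / u ** 2, u)
    return tot


def born_self_energy(q, radius, eps_in=1.0, eps_out=78.5, kappa=0.0):
    tau = 1.0 / eps_in - np.exp(-kappa * radius) / eps_out
    return -0.5 * COULOMB * q * q * tau / radius


def two_sphere_sasa(r1, r2, d, probe):
    """Analytic accessible area of two intersecting spheres (inflated radii)."""
    a, b = r1 + probe, r2 + probe
    if d >= a + b:
        return 4.0 * np.pi * (a * a + b * b)
    h1 = a - (d * d + a * a - b * b) / (2.0 * d)
    h2 = b - (d * d + b * b - a * a) / (2.0 * d)
    return (4.0 * np.pi * a * a - 2.0 * np.pi * a * h1
            + 4.0 * np.pi * b * b - 2.0 * np.pi * b * h2)


def pearson_r2(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = x - x.mean()
    sy = y - y.mean()
    return float((sx @ sy) ** 2 / ((sx @ sx) * (sy @ sy)))
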