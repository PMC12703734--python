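"""GB-Neck2 generalized-Born parameters and effective-radius machinery.

The model computes per-atom effective Born radii from a pairwise
Hawkins–Cramer–Truhlar (HCT) descreening sum over offset-reduced intrinsic
radii, augmented by a "neck" correction for the solvent-inaccessible
region between nearby atom pairs, and maps the sum through a per-element
tanh rescaling:

    1/R_i = 1/rho~_i - tanh(alpha*Psi - beta*Psi^2 + gamma*Psi^3) / rho_i,
    Psi   = I_i * rho~_i,   rho~_i = rho_i - offset.

The per-element alpha/beta/gamma, screening factors, the 0.195141 Å offset
and the neck scale ship as a versioned data table
(``data/gbneck2_params.json``).  The neck lookup (position d0 and height
m0 of the neck integral for a radius pair) is not tabulated; it is
computed here by direct numerical integration of the two-sphere
solvent-inaccessible geometry with a 1.4 Å probe and cached per radius
pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

#: Amber electrostatic constant, kcal·Å·mol⁻¹·e⁻²
COULOMB_CONSTANT = 332.0636
#: gas constant, kcal/mol/K
GAS_CONSTANT = 1.9872e-3
#: Avogadro's number scaled to Å⁻³·(mol/L)⁻¹ number densities
_NUMBER_DENSITY = 6.02214076e-4


def _load_params() -> dict:
    with resources.files("mnmgbsa.data").joinpath("gbneck2_params.json").open() as fh:
        return json.load(fh)


_PARAMS = _load_params()


def element_screen(element: str) -> float:
    tab = _PARAMS["elements"]
    return tab.get(element.upper(), tab["default"])["screen"]


def mbondi3_radius(element: str, atom_name: str = "") -> float:
    """Intrinsic Born radius in the mbondi3 convention (per-element table)."""
    tab = _PARAMS["mbondi3"]
    return tab.get(element.upper(), tab["default"])


def debye_kappa(salt_molar: float, eps_out: float, temperature: float) -> float:
    """Debye screening parameter κ in Å⁻¹ for a 1:1 salt."""
    if salt_molar <= 0:
        return 0.0
    bjerrum = COULOMB_CONSTANT / (eps_out * GAS_CONSTANT * temperature)  # Å
    kappa2 = 4.0 * np.pi * bjerrum * 2.0 * salt_molar * _NUMBER_DENSITY
    return float(np.sqrt(kappa2))


@dataclass
class GbParameters:
    """Settings of the GB-Neck2 polar solvation model.

    ``kappa`` is the Debye parameter derived from the salt concentration;
    the conventional 0.73 rescaling applied inside the GB exponential is
    kept separate so the physical κ stays inspectable.
    """

    eps_in: float = 1.0
    eps_out: float = 78.5
    salt_molar: float = 0.15
    temperature: float = 298.15
    kappa_scale: float = 0.73
    offset: float = _PARAMS["offset"]
    neck_scale: float = _PARAMS["neck_scale"]
    probe_radius: float = _PARAMS["probe_radius"]
    coulomb: float = COULOMB_CONSTANT
    max_effective_radius: float = 30.0

    def __post_init__(self) -> None:
        if not self.eps_out > self.eps_in >= 1.0:
            raise ValueError("require eps_out > eps_in >= 1")
        if self.offset <= 0:
            raise ValueError("offset must be positive")

    @property
    def kappa(self) -> float:
        return debye_kappa(self.salt_molar, self.eps_out, self.temperature)

    @property
    def kappa_gb(self) -> float:
        """κ as used inside the GB exponential (rescaled)."""
        return self.kappa_scale * self.kappa

    def abg(self, element: str) -> tuple[float, float, float]:
        tab = _PARAMS["elements"]
        e = tab.get(element.upper(), tab["default"])
        return e["alpha"], e["beta"], e["gamma"]


# ---------------------------------------------------------------------------
# HCT pairwise descreening integral
# ---------------------------------------------------------------------------

def hct_integral(d: float, ri: float, sj: float) -> float:
    """Descreening of atom i (inner radius ``ri``) by a scaled sphere of
    radius ``sj`` centered ``d`` away: (1/4π) ∫ |x|⁻⁴ dV over the part of
    the sphere outside radius ``ri``.
    """
    if sj <= 0 or d <= 0:
        return 0.0
    upper = d + sj
    if ri >= upper:
        return 0.0
    lower = max(ri, abs(d - sj))
    val = 0.5 * (
        1.0 / lower - 1.0 / upper
        + (1.0 / (2.0 * d)) * np.log(lower / upper)
        + ((d * d - sj * sj) / (4.0 * d)) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
    )
    if d < sj and ri < sj - d:
        val += 1.0 / ri - 1.0 / (sj - d)
    return float(val)


def hct_integral_array(d: np.ndarray, ri: np.ndarray, sj: np.ndarray) -> np.ndarray:
    """Vectorized :func:`hct_integral` (inputs broadcast together)."""
    d = np.asarray(d, float)
    ri = np.broadcast_to(np.asarray(ri, float), d.shape).copy()
    sj = np.broadcast_to(np.asarray(sj, float), d.shape).copy()
    out = np.zeros_like(d)
    ok = (sj > 0) & (d > 0) & (ri < d + sj)
    dd, rr, ss = d[ok], ri[ok], sj[ok]
    upper = dd + ss
    lower = np.maximum(rr, np.abs(dd - ss))
    val = 0.5 * (
        1.0 / lower - 1.0 / upper
        + (1.0 / (2.0 * dd)) * np.log(lower / upper)
        + ((dd * dd - ss * ss) / (4.0 * dd)) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
    )
    inside = (dd < ss) & (rr < ss - dd)
    val[inside] += 1.0 / rr[inside] - 1.0 / (ss[inside] - dd[inside])
    out[ok] = val
    return out


# ---------------------------------------------------------------------------
# neck correction
# ---------------------------------------------------------------------------

def neck_integral(r: float, rho_i: float, rho_j: float,
                  probe: float = 1.4, n_grid: int = 220) -> float:
    """(1/4π) ∫ |x − x_i|⁻⁴ dV over the two-sphere neck region.

    The neck region consists of points outside both van der Waals spheres
    that a solvent probe cannot reach when only these two atoms exist;
    evaluated on a cylindrical grid exploiting axial symmetry.
    """
    ri_inf, rj_inf = rho_i + probe, rho_j + probe
    z = np.linspace(-rho_i, r + rho_j, n_grid)
    smax = max(ri_inf, rj_inf)
    s = np.linspace(0.0, smax, n_grid)
    zz, ss = np.meshgrid(z, s, indexing="ij")
    di = np.hypot(ss, zz)
    dj = np.hypot(ss, zz - r)
    outside_vdw = (di > rho_i) & (dj > rho_j)
    # distance from each point to the nearest allowed probe-center position
    dist = np.full_like(zz, np.inf)
    free = (di >= ri_inf) & (dj >= rj_inf)
    dist[free] = 0.0
    # projection onto inflated sphere i, valid if it lands outside inflated j
    with np.errstate(divide="ignore", invalid="ignore"):
        scale_i = ri_inf / di
        qi_z, qi_s = zz * scale_i, ss * scale_i
        valid_i = (di < ri_inf) & (np.hypot(qi_s, qi_z - r) >= rj_inf)
        cand_i = np.where(valid_i, ri_inf - di, np.inf)
        scale_j = rj_inf / dj
        qj_z, qj_s = r + (zz - r) * scale_j, ss * scale_j
        valid_j = (dj < rj_inf) & (np.hypot(qj_s, qj_z) >= ri_inf)
        cand_j = np.where(valid_j, rj_inf - dj, np.inf)
    dist = np.minimum(dist, np.minimum(cand_i, cand_j))
    # intersection circle of the two inflated spheres
    if abs(ri_inf - rj_inf) < r < ri_inf + rj_inf:
        zc = (r * r + ri_inf ** 2 - rj_inf ** 2) / (2.0 * r)
        sc2 = ri_inf ** 2 - zc * zc
        if sc2 > 0:
            sc = np.sqrt(sc2)
            dist = np.minimum(dist, np.hypot(ss - sc, zz - zc))
    inaccessible = outside_vdw & (dist > probe)
    integrand = np.where(inaccessible, ss / np.maximum(di, 1e-9) ** 4, 0.0)
    dz = z[1] - z[0]
    dsv = s[1] - s[0]
    return float(0.5 * integrand.sum() * dz * dsv)


@lru_cache(maxsize=512)
def neck_d0_m0(rho_i: float, rho_j: float, probe: float = 1.4,
               ) -> tuple[float, float]:
    """Separation ``d0`` where the neck integral peaks and its value ``m0``."""
    lo = rho_i + rho_j
    hi = rho_i + rho_j + 2.0 * probe
    rs = np.linspace(lo + 1e-3, hi - 1e-3, 25)
    vals = np.array([neck_integral(r, rho_i, rho_j, probe) for r in rs])
    k = int(np.argmax(vals))
    # local refinement
    lo2 = rs[max(k - 1, 0)]
    hi2 = rs[min(k + 1, len(rs) - 1)]
    rs2 = np.linspace(lo2, hi2, 15)
    vals2 = np.array([neck_integral(r, rho_i, rho_j, probe) for r in rs2])
    k2 = int(np.argmax(vals2))
    return float(rs2[k2]), float(vals2[k2])


def neck_value(r: np.ndarray | float, rho_i: float, rho_j: float,
               probe: float = 1.4) -> np.ndarray | float:
    """Analytic neck approximation m0 / (1 + (r−d0)² + 0.3 (r−d0)⁶)."""
    d0, m0 = neck_d0_m0(round(rho_i, 4), round(rho_j, 4), probe)
    x = np.asarray(r, float) - d0
    out = m0 / (1.0 + x * x + 0.3 * x ** 6)
    # no neck once the probe fits between the atoms or the atoms fuse
    out = np.where(np.asarray(r, float) > rho_i + rho_j + 2.0 * probe, 0.0, out)
    return out if np.ndim(r) else float(out)
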