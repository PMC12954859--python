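"""Restraint-driven geometry minimization and superposition RMSD.

This is the self-consistency arm of the toolkit: a restraint dictionary
generated from an ideal geometry should, when used as the sole energy
model (harmonic residuals against the ideals plus a purely repulsive
nonbonded term), minimize that geometry back onto itself.  A large
start-to-final RMSD therefore flags an internally inconsistent
dictionary.

Energies are dimensionless squared residuals scaled by the restraint
e.s.d. values; gradients are analytic throughout (the best-fit-plane
term's gradient is exact by the envelope theorem, since the plane
parameters minimize the same sum of squares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .component_io import ComponentError
from .restraint_gen import (
    ChiralitySign,
    RestraintDictionary,
    wrap_angle,
)

__all__ = [
    "EnergyModel",
    "MinimizeConfig",
    "MinimizationResult",
    "restraint_energy",
    "minimize",
    "kabsch_rmsd",
    "roundtrip_check",
]

#: Simplified van der Waals radii (Angstrom) for the repulsion cutoff.
VDW_RADII = {
    "H": 1.1, "D": 1.1, "B": 1.8, "C": 1.7, "N": 1.55, "O": 1.52,
    "F": 1.47, "Si": 2.1, "P": 1.8, "S": 1.8, "Cl": 1.75, "Se": 1.9,
    "Br": 1.85, "I": 1.98,
}
_DEFAULT_VDW = 1.7

#: Margin (Angstrom^3) below which a signed chiral volume of the correct
#: sign is still penalized; keeps near-planar centres from collapsing.
CHIRAL_VOLUME_MARGIN = 1.0


@dataclass(frozen=True)
class EnergyModel:
    """Term weights and the repulsive-nonbonded parameters."""

    bond_weight: float = 1.0
    angle_weight: float = 1.0
    torsion_weight: float = 1.0
    chirality_weight: float = 1.0
    plane_weight: float = 1.0
    repulsion_weight: float = 1.0
    repulsion_strength: float = 10.0
    vdw_scale: float = 0.8  # cutoff = vdw_scale * (r_i + r_j)

    def __post_init__(self):
        weights = (self.bond_weight, self.angle_weight, self.torsion_weight,
                   self.chirality_weight, self.plane_weight, self.repulsion_weight)
        if any(w < 0 for w in weights):
            raise ComponentError("energy weights must be >= 0")
        if self.vdw_scale <= 0 or self.repulsion_strength < 0:
            raise ComponentError("repulsion parameters must be positive")

    def zero_weights(self) -> bool:
        return all(
            w == 0
            for w in (self.bond_weight, self.angle_weight, self.torsion_weight,
                      self.chirality_weight, self.plane_weight, self.repulsion_weight)
        )


@dataclass(frozen=True)
class MinimizeConfig:
    max_iter: int = 2000
    grad_tol: float = 1e-4  # max |dE/dx|, energy units per Angstrom
    seed: int = 0  # reserved for stochastic extensions; descent is deterministic


@dataclass
class MinimizationResult:
    start_coords: dict[str, tuple[float, float, float]]
    final_coords: dict[str, tuple[float, float, float]]
    rmsd_to_start: float
    n_iterations: int
    final_gradient_norm: float
    converged: bool
    final_energy: float = 0.0
    trace: list = field(default_factory=list)


def _bonded_distances(dictionary: RestraintDictionary, names: list[str]) -> np.ndarray:
    """Matrix of bond-graph distances up to 4 (5 meaning 'farther')."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from((b.atom1, b.atom2) for b in dictionary.bonds)
    n = len(names)
    idx = {name: i for i, name in enumerate(names)}
    dist = np.full((n, n), 5, dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(g, cutoff=4):
        for dst, d in lengths.items():
            dist[idx[src], idx[dst]] = d
    return dist


class _EnergyFunction:
    """Energy + analytic gradient over flattened coordinates."""

    def __init__(self, dictionary: RestraintDictionary, model: EnergyModel,
                 names: list[str], elements: Optional[dict[str, str]] = None):
        self.dictionary = dictionary
        self.model = model
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        elements = elements or {}
        radii = np.array(
            [VDW_RADII.get(elements.get(n, _guess_element(n)), _DEFAULT_VDW)
             for n in names]
        )
        self.cutoffs = model.vdw_scale * (radii[:, None] + radii[None, :])
        self.graph_dist = _bonded_distances(dictionary, names)
        self.plane_index = [
            np.array(sorted(self.index[a] for a in p.atoms))
            for p in dictionary.planes
        ]

    # -- individual terms --------------------------------------------------

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        xyz = x.reshape(-1, 3)
        if not np.all(np.isfinite(xyz)):
            raise ComponentError("non-finite coordinates in energy evaluation")
        grad = np.zeros_like(xyz)
        energy = 0.0
        m, d = self.model, self.dictionary
        ix = self.index

        if m.bond_weight:
            for b in d.bonds:
                i, j = ix[b.atom1], ix[b.atom2]
                v = xyz[j] - xyz[i]
                r = np.linalg.norm(v)
                res = (r - b.ideal) / b.esd
                energy += m.bond_weight * res * res
                g = m.bond_weight * 2.0 * res / b.esd * (v / r)
                grad[i] -= g
                grad[j] += g

        if m.angle_weight:
            for a in d.angles:
                i, j, k = ix[a.atom1], ix[a.atom2], ix[a.atom3]
                theta, (gi, gj, gk) = _angle_and_grad(xyz[i], xyz[j], xyz[k])
                res = (math.degrees(theta) - a.ideal) / a.esd
                energy += m.angle_weight * res * res
                scale = m.angle_weight * 2.0 * res / a.esd * (180.0 / math.pi)
                grad[i] += scale * gi
                grad[j] += scale * gj
                grad[k] += scale * gk

        if m.torsion_weight:
            for t in d.torsions:
                i, j, k, l = ix[t.atom1], ix[t.atom2], ix[t.atom3], ix[t.atom4]
                phi, gs = _dihedral_and_grad(xyz[i], xyz[j], xyz[k], xyz[l])
                phi_deg = math.degrees(phi)
                delta = _torsion_residual(phi_deg, t)
                res = delta / t.esd
                energy += m.torsion_weight * res * res
                scale = m.torsion_weight * 2.0 * res / t.esd * (180.0 / math.pi)
                for idx_, g in zip((i, j, k, l), gs):
                    grad[idx_] += scale * g

        if m.chirality_weight:
            for c in d.chirality:
                if c.sign is ChiralitySign.BOTH:
                    continue
                i0 = ix[c.center]
                i1, i2, i3 = ix[c.neighbor1], ix[c.neighbor2], ix[c.neighbor3]
                u1 = xyz[i1] - xyz[i0]
                u2 = xyz[i2] - xyz[i0]
                u3 = xyz[i3] - xyz[i0]
                vol = float(np.dot(u1, np.cross(u2, u3)))
                s = 1.0 if c.sign is ChiralitySign.POSITIVE else -1.0
                short = CHIRAL_VOLUME_MARGIN - s * vol
                if short <= 0:
                    continue
                energy += m.chirality_weight * short * short
                dvol1 = np.cross(u2, u3)
                dvol2 = np.cross(u3, u1)
                dvol3 = np.cross(u1, u2)
                scale = m.chirality_weight * 2.0 * short * (-s)
                grad[i1] += scale * dvol1
                grad[i2] += scale * dvol2
                grad[i3] += scale * dvol3
                grad[i0] -= scale * (dvol1 + dvol2 + dvol3)

        if m.plane_weight:
            for p, idxs in zip(d.planes, self.plane_index):
                pts = xyz[idxs]
                centroid = pts.mean(axis=0)
                centered = pts - centroid
                _, _, vt = np.linalg.svd(centered)
                normal = vt[-1]
                dev = centered @ normal
                energy += m.plane_weight * float(np.sum(dev * dev)) / (p.esd * p.esd)
                # envelope theorem: plane parameters minimize the sum, so
                # the plane-fixed gradient is the exact total gradient
                g = m.plane_weight * 2.0 / (p.esd * p.esd) * dev[:, None] * normal
                np.add.at(grad, idxs, g - g.mean(axis=0))

        if m.repulsion_weight and m.repulsion_strength:
            n = len(xyz)
            diff = xyz[:, None, :] - xyz[None, :, :]
            dist = np.sqrt(np.sum(diff * diff, axis=-1))
            np.fill_diagonal(dist, np.inf)
            mask = (self.graph_dist >= 4) & (dist < self.cutoffs)
            iu = np.triu_indices(n, k=1)
            pair_mask = np.zeros_like(mask)
            pair_mask[iu] = mask[iu]
            ii, jj = np.nonzero(pair_mask)
            for i, j in zip(ii, jj):
                short = self.cutoffs[i, j] - dist[i, j]
                w = m.repulsion_weight * m.repulsion_strength
                energy += w * short * short
                g = w * 2.0 * short * (-diff[i, j] / dist[i, j])
                grad[i] += g
                grad[j] -= g

        return energy, grad.ravel()


def _guess_element(name: str) -> str:
    """Fallback element guess from an atom name (two-letter symbols first)."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    for k in (2, 1):
        cand = stripped[:k].capitalize()
        if cand in VDW_RADII:
            return cand
    return "C"


def _torsion_residual(phi_deg: float, t) -> float:
    """Signed wrap-aware residual to the nearest symmetry copy of the ideal."""
    if t.alt_ideals is not None:
        deltas = [wrap_angle(phi_deg - v) for v in t.alt_ideals]
        return min(deltas, key=abs)
    step = 360.0 / t.period
    delta = math.fmod(phi_deg - t.ideal, step)
    if delta > step / 2:
        delta -= step
    elif delta <= -step / 2:
        delta += step
    return delta


def _angle_and_grad(x1, x2, x3):
    """Angle at x2 (radians) and its gradient w.r.t. the three positions."""
    u = x1 - x2
    v = x3 - x2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    c = float(np.dot(u, v) / (nu * nv))
    c = max(-1.0, min(1.0, c))
    theta = math.acos(c)
    s = math.sqrt(max(1.0 - c * c, 1e-12))
    dtheta_du = -(v / (nu * nv) - c * u / (nu * nu)) / s
    dtheta_dv = -(u / (nu * nv) - c * v / (nv * nv)) / s
    return theta, (dtheta_du, -(dtheta_du + dtheta_dv), dtheta_dv)


def _dihedral_and_grad(x1, x2, x3, x4):
    """Signed dihedral (radians) about x2-x3 and its analytic gradient."""
    b1 = x2 - x1
    b2 = x3 - x2
    b3 = x4 - x3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    m = np.cross(n1, b2 / nb2)
    phi = -math.atan2(float(np.dot(m, n2)), float(np.dot(n1, n2)))
    # analytic dihedral derivatives (translation/torque-free relations
    # give the interior atoms from the end-atom gradients)
    sq1 = float(np.dot(n1, n1))
    sq2 = float(np.dot(n2, n2))
    g1 = -nb2 / sq1 * n1
    g4 = nb2 / sq2 * n2
    d12 = float(np.dot(b1, b2)) / (nb2 * nb2)
    d32 = float(np.dot(b3, b2)) / (nb2 * nb2)
    g2 = -(1.0 + d12) * g1 + d32 * g4
    g3 = -(1.0 + d32) * g4 + d12 * g1
    return phi, (g1, g2, g3, g4)


def restraint_energy(
    coords: dict[str, tuple[float, float, float]],
    dictionary: RestraintDictionary,
    model: Optional[EnergyModel] = None,
    elements: Optional[dict[str, str]] = None,
) -> tuple[float, dict[str, tuple[float, float, float]]]:
    """Total restraint energy and its per-atom analytic gradient."""
    model = model or EnergyModel()
    needed = dictionary.restrained_atoms()
    missing = needed - set(coords)
    if missing:
        raise ComponentError(f"coordinates missing for atoms: {sorted(missing)}")
    names = sorted(coords)
    fn = _EnergyFunction(dictionary, model, names, elements)
    x = np.array([coords[n] for n in names], float).ravel()
    energy, grad = fn(x)
    g = grad.reshape(-1, 3)
    return energy, {n: tuple(g[i]) for i, n in enumerate(names)}


def minimize(
    coords: dict[str, tuple[float, float, float]],
    dictionary: RestraintDictionary,
    model: Optional[EnergyModel] = None,
    config: Optional[MinimizeConfig] = None,
    elements: Optional[dict[str, str]] = None,
) -> MinimizationResult:
    """Quasi-Newton (L-BFGS-B) descent of the restraint energy.

    Deterministic for identical inputs; converged means the max-component
    gradient norm reached ``grad_tol`` within ``max_iter`` iterations.
    """
    model = model or EnergyModel()
    config = config or MinimizeConfig()
    names = sorted(coords)
    x0 = np.array([coords[n] for n in names], float).ravel()

    fn = _EnergyFunction(dictionary, model, names, elements)
    e0, _ = fn(x0)
    if not math.isfinite(e0):
        raise ComponentError("non-finite energy at starting geometry")

    if model.zero_weights():
        return MinimizationResult(
            start_coords=dict(coords), final_coords=dict(coords),
            rmsd_to_start=0.0, n_iterations=0, final_gradient_norm=0.0,
            converged=True, final_energy=0.0,
        )

    trace: list[tuple[int, float, float]] = []

    def cb(xk):
        e, g = fn(xk)
        trace.append((len(trace) + 1, e, float(np.max(np.abs(g)))))

    res = _scipy_minimize(
        fn, x0, jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": config.max_iter, "gtol": config.grad_tol,
                 "ftol": 1e-14},
    )
    xf = res.x
    ef, gf = fn(xf)
    gnorm = float(np.max(np.abs(gf)))
    final = {n: tuple(xf.reshape(-1, 3)[i]) for i, n in enumerate(names)}
    subset = [n for n in names if n in coords]
    rmsd = kabsch_rmsd(coords, final, subset) if len(subset) >= 3 else 0.0
    return MinimizationResult(
        start_coords=dict(coords),
        final_coords=final,
        rmsd_to_start=rmsd,
        n_iterations=int(res.nit),
        final_gradient_norm=gnorm,
        converged=bool(gnorm < config.grad_tol or res.success),
        final_energy=float(ef),
        trace=trace,
    )


def kabsch_rmsd(
    coordsA: dict[str, tuple[float, float, float]],
    coordsB: dict[str, tuple[float, float, float]],
    atoms: Optional[list[str]] = None,
) -> float:
    """Least-squares rigid-superposition RMSD (proper rotations only).

    The optimal rotation is obtained from the SVD of the covariance of
    the centred point sets, with the determinant sign corrected so no
    reflection is applied.
    """
    if atoms is None:
        atoms = sorted(set(coordsA) & set(coordsB))
    if len(atoms) < 3:
        raise ComponentError("kabsch_rmsd needs at least 3 common atoms")
    P = np.array([coordsA[a] for a in atoms], float)
    Q = np.array([coordsB[a] for a in atoms], float)
    P -= P.mean(axis=0)
    Q -= Q.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack((P, Q)), tol=1e-10) < 2:
        raise ComponentError("kabsch_rmsd needs >= 3 non-collinear atoms")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    diff = (P @ R.T) - Q
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def roundtrip_check(
    dictionary: RestraintDictionary,
    start_coords: dict[str, tuple[float, float, float]],
    model: Optional[EnergyModel] = None,
    config: Optional[MinimizeConfig] = None,
    elements: Optional[dict[str, str]] = None,
) -> MinimizationResult:
    """Minimize a geometry under its own dictionary and report how far it
    moved — the per-component self-consistency check: restraints built
    from an ideal geometry should maintain that geometry."""
    return minimize(start_coords, dictionary, model, config, elements)
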