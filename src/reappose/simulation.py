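"""Quasi-static plane-strain contact solver for flap re-apposition.

The dissected cross-section is solved as a 2D plane-strain finite-strain
problem (the prismatic vessel with axially constrained ends reduces to its
cross-section; out-of-plane stretch is fixed at 1).  Elements are bilinear
quadrilaterals with a mean-dilatation (element-averaged J) treatment of the
volumetric penalty, which avoids locking at the near-incompressible penalty
modulus K = 1e4 * C10 used by default.  Loads are follower pressures on the
luminal surfaces; contact is frictionless penalty contact on three pairs —
expansion member/flap, expansion member/TL wall, flap/FL wall.

The two-step protocol mirrors the bench procedure:

1. :func:`pressurize` — ramp the static aortic pressure on the true- and
   false-lumen surfaces (the bench applied static pressure to the whole
   vessel; the false lumen communicates through the entry/re-entry tears).
   A ``pressurize_false_lumen=False`` switch restricts pressure to the
   true-lumen surfaces for comparison studies.
2. :func:`expand_member` — grow the rigid member radius until every flap
   outer-surface node lies within ``gap_tol_fraction`` of the flap thickness
   from the FL wall (full re-apposition), refining the terminal radius by
   bisection; the radial (re-apposition) pressure is the tributary-length
   weighted average contact pressure on the member.

Rigid-body control: the half model fixes u_x on the symmetry plane; the free
rigid translation along the plane is removed by a mean-u_y Lagrange
multiplier (inertia-relief style), which also transmits the net member force
to the implicit axial supports of the 3D vessel.

Units: mm, Pa internally; pressures reported in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (
    GOHParameters, InvertedElementError, OverflowStateError, MMHG_TO_PA,
    PA_TO_MMHG, _fiber_psi_g_h, _plane_strain_core,
)
from .geometry import (
    CrossSectionMesh, DissectionGeometry, ExpansionMember, FLAP, FL_WALL,
    TL_WALL, LAYERS, build_cross_section,
)


class SolverError(RuntimeError):
    def __init__(self, msg, last_converged_fraction=None):
        super().__init__(msg)
        self.last_converged_fraction = last_converged_fraction


class GeometricFailureError(SolverError):
    pass


@dataclass(frozen=True)
class SolverOptions:
    """Controls for the implicit quasi-static solver (all positive)."""

    load_steps: int = 5                    # initial pressurization increments
    member_step_mm: float = 0.15           # member radius march increment
    newton_tol: float = 1e-7               # relative residual tolerance
    max_newton_iter: int = 60
    step_cap_mm: float = 0.5               # trust-region cap on a Newton update
    contact_penalty_factor: float = 100.0  # x (stiffest mu)/h -> Pa/mm
    gap_tol_fraction: float = 0.01         # re-apposition gap / flap thickness
    kvol_factor: float = 1e4               # volumetric penalty K = factor*C10
    radius_tol_mm: float = 5e-3            # terminal-radius bisection tolerance
    contact_smoothing_mm: float = 5e-4     # C1 regularization depth of the penalty
    flap_drape_bias_mmhg: float = 1.0      # inward flap bias selecting the taut
                                           # drape branch during continuation
    pressurize_false_lumen: bool = True
    member_center: tuple = (0.0, 0.0)
    member_segments: int = 64
    verbose: bool = False

    def __post_init__(self):
        for name in ("load_steps", "member_step_mm", "newton_tol",
                     "max_newton_iter", "contact_penalty_factor",
                     "gap_tol_fraction", "kvol_factor", "radius_tol_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SolverOptions.{name} must be positive")
        if self.gap_tol_fraction > 0.05:
            raise ValueError("gap_tol_fraction must be <= 0.05")


@dataclass
class ReappositionResult:
    """Outcome of one two-step re-apposition simulation."""

    p_aorta_mmhg: float
    radial_pressure_mmhg: float
    member_radius_mm: float
    final_inner_diameter_mm: float
    contact_fraction_history: list
    newton_log: list
    converged: bool
    region: str = ""
    flap_label: str = ""
    warnings: list = field(default_factory=list)
    assumptions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.converged and self.radial_pressure_mmhg < 0:
            raise SolverError("radial pressure must be non-negative")


# ---------------------------------------------------------------------------
# finite-element model
# ---------------------------------------------------------------------------

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
_W2 = np.array([[0.0, -1.0], [1.0, 0.0]])  # +90 degree rotation


def _shape_grads(xi, eta):
    # nodes at (-1,-1),(1,-1),(1,1),(-1,1)
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


class FEModel:
    """Assembled cross-section model: kinematics, materials, loads, contact."""

    def __init__(self, mesh: CrossSectionMesh, materials: dict,
                 options: SolverOptions = SolverOptions()):
        self.mesh = mesh
        self.opt = options
        self.materials = {LAYERS.index(k): v for k, v in materials.items()}
        present = set(np.unique(mesh.layer).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"missing material for layers {[LAYERS[i] for i in missing]}")

        X = mesh.nodes
        el = mesh.elems
        ne = len(el)
        dn = np.stack([_shape_grads(*gp) for gp in _GP])        # (4gp,4n,2)
        Xe = X[el]                                              # (ne,4,2)
        J0 = np.einsum("gai,eaj->egij", dn, Xe)                 # dX/dxi
        detJ0 = J0[..., 0, 0] * J0[..., 1, 1] - J0[..., 0, 1] * J0[..., 1, 0]
        if np.any(detJ0 <= 0):
            raise InvertedElementError(np.nonzero(np.any(detJ0 <= 0, axis=1))[0])
        invJ0 = np.linalg.inv(J0)
        self.G0 = np.einsum("gaj,egij->egai", dn, invJ0)        # dN/dX
        self.w = detJ0                                          # gauss weights (all 1)
        self.V0 = self.w.sum(axis=1)
        cen = Xe.mean(axis=1)
        th = np.arctan2(cen[:, 1], cen[:, 0])
        self.circ = np.stack([-np.sin(th), np.cos(th)], axis=1)  # reference circumferential
        self.kvol = np.array([options.kvol_factor * self.materials[c].c10
                              for c in mesh.layer])
        self.layer_groups = {c: np.nonzero(mesh.layer == c)[0]
                             for c in np.unique(mesh.layer)}

        self.ndof = 2 * mesh.n_nodes
        self.edofs = np.empty((ne, 8), dtype=int)
        self.edofs[:, 0::2] = 2 * el
        self.edofs[:, 1::2] = 2 * el + 1
        self.iK = np.repeat(self.edofs, 8, axis=1).ravel()
        self.jK = np.tile(self.edofs, (1, 8)).ravel()

        # B maps element dof increments to dF (flattened i*2+alpha), per gp
        B = np.zeros((ne, 4, 4, 8))
        for i in range(2):
            for al in range(2):
                for b in range(4):
                    B[:, :, 2 * i + al, 2 * b + i] = self.G0[:, :, b, al]
        self.B = B
        self.wBt = (self.w[..., None, None] * B).transpose(0, 1, 3, 2).copy()

        mu_max = max(2.0 * m.c10 for m in self.materials.values())
        self.k_pen = options.contact_penalty_factor * mu_max / mesh.h

        # fixed dofs: u_x on the symmetry plane
        sym = mesh.boundary_sets.get("symmetry_plane")
        fixed = np.zeros(self.ndof, dtype=bool)
        if sym is not None and len(sym):
            fixed[2 * np.unique(sym)] = True
        self.free = ~fixed
        # rigid y-translation removed by a mean-u_y Lagrange multiplier
        C = np.zeros(self.ndof)
        C[1::2] = 1.0 / mesh.n_nodes
        self.C = C[self.free]

        # pressurized surfaces
        sets = mesh.boundary_sets
        lumen = [sets["tl_lumen_surface"], sets["flap_tl_side"]]
        self.tl_edges = np.vstack([e for e in lumen if len(e)]) \
            if any(len(e) for e in lumen) else np.empty((0, 2), int)
        fl = [sets["flap_fl_side"], sets["fl_wall_inner"]]
        self.fl_edges = np.vstack([e for e in fl if len(e)]) if any(len(e) for e in fl) \
            else np.empty((0, 2), int)

        # member contact candidates: TL luminal nodes, with tributary lengths
        self.lumen_nodes, self.lumen_trib = self._tributary(self.tl_edges)
        # flap/FL contact pair
        self.flap_edges = sets["flap_fl_side"]
        self.flc_nodes, self.flc_trib = self._tributary(self.flap_edges)
        self.master_edges = sets["fl_wall_inner"]
        self.has_flap_contact = len(self.flap_edges) > 0 and len(self.master_edges) > 0

    def _tributary(self, edges):
        if len(edges) == 0:
            return np.empty(0, int), np.empty(0)
        ids, trib = self._tributary_at(edges, self.mesh.nodes)
        return ids, trib

    def _tributary_at(self, edges, coords):
        """Node ids and tributary lengths of an edge chain at given coords."""
        L = np.hypot(*(coords[edges[:, 1]] - coords[edges[:, 0]]).T)
        trib = np.zeros(self.mesh.n_nodes)
        np.add.at(trib, edges[:, 0], 0.5 * L)
        np.add.at(trib, edges[:, 1], 0.5 * L)
        ids = np.unique(edges.ravel())
        return ids, trib[ids]

    # -- internal forces ----------------------------------------------------

    def internal(self, u, tangent: bool = True):
        """Internal force vector, tangent (coo parts), strain energy."""
        el = self.mesh.elems
        ue = u.reshape(-1, 2)[el]                               # (ne,4,2)
        F = np.einsum("eai,egaj->egij", ue, self.G0)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        if np.any(J <= 0):
            raise InvertedElementError(np.nonzero(np.any(J <= 0, axis=1))[0])
        Jbar = (self.w * J).sum(axis=1) / self.V0

        ne = len(el)
        P = np.empty((ne, 4, 2, 2))
        A = np.empty((ne, 4, 2, 2, 2, 2)) if tangent else None
        psi = np.empty((ne, 4))
        for code, idx in self.layer_groups.items():
            m = self.materials[code]
            circ = self.circ[idx][:, None, :]
            Pg, Ag, Jg, eg = _plane_strain_core(m, F[idx], circ, 0.0,
                                                element_ids=idx, want_tangent=tangent)
            P[idx] = Pg
            if tangent:
                A[idx] = Ag
            # energy density: neo-Hookean + ln J correction + fiber
            C11 = np.einsum("egki,egkj->egij", F[idx], F[idx])
            i1 = C11[..., 0, 0] + C11[..., 1, 1] + 1.0
            pf, _, _ = _fiber_psi_g_h(m, eg)
            psi[idx] = m.c10 * (i1 - 3.0) - 2.0 * m.c10 * np.log(Jg) + pf

        G = np.empty_like(F)
        G[..., 0, 0] = F[..., 1, 1]
        G[..., 1, 1] = F[..., 0, 0]
        G[..., 0, 1] = -F[..., 1, 0]
        G[..., 1, 0] = -F[..., 0, 1]
        Up = self.kvol * (Jbar - 1.0)                           # (ne,)
        P = P + Up[:, None, None, None] * G

        f_e = np.matmul(self.wBt, P.reshape(ne, 4, 4, 1)).sum(axis=1)[..., 0]
        fint = np.zeros(self.ndof)
        np.add.at(fint, self.edofs.ravel(), f_e.ravel())
        energy = float((self.w * psi).sum() + (self.V0 * 0.5 * self.kvol
                                               * (Jbar - 1.0) ** 2).sum())
        self._last_Jbar = Jbar
        if not tangent:
            return fint, None, energy

        D = np.zeros((2, 2, 2, 2))
        D[0, 0, 1, 1] = D[1, 1, 0, 0] = 1.0
        D[0, 1, 1, 0] = D[1, 0, 0, 1] = -1.0
        A = A + Up[:, None, None, None, None, None] * D
        K_e = np.matmul(self.wBt, np.matmul(A.reshape(ne, 4, 4, 4), self.B)).sum(axis=1)
        bvol = np.matmul(self.wBt, G.reshape(ne, 4, 4, 1)).sum(axis=1)[..., 0]
        K_e += (self.kvol / self.V0)[:, None, None] * bvol[:, :, None] * bvol[:, None, :]
        return fint, (self.iK, self.jK, K_e.ravel()), energy

    # -- follower pressure --------------------------------------------------

    def pressure_load(self, u, p_tl, p_fl, p_flap_bias=0.0):
        """External pressure force and load-stiffness triplets.

        ``p_flap_bias`` adds extra pressure on the flap's FL-side face only —
        a small inward bias used as a continuation device to select the taut
        drape branch of the slack flap (removed for measured states).
        """
        x = self.mesh.nodes + u.reshape(-1, 2)
        f = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        groups = [(self.tl_edges, p_tl), (self.fl_edges, p_fl)]
        if p_flap_bias:
            groups.append((self.flap_edges, p_flap_bias))
        for edges, p in groups:
            if p == 0.0 or len(edges) == 0:
                continue
            a, b = edges[:, 0], edges[:, 1]
            d = x[b] - x[a]
            fe = 0.5 * p * np.stack([-d[:, 1], d[:, 0]], axis=1)
            for n in (a, b):
                np.add.at(f, 2 * n, fe[:, 0])
                np.add.at(f, 2 * n + 1, fe[:, 1])
            # d fe / d x_b = p/2 * W ; d fe / d x_a = -p/2 * W (both rows a and b)
            blk = 0.5 * p * _W2
            for rn in (a, b):
                for cn, s in ((a, -1.0), (b, 1.0)):
                    for i in range(2):
                        for j in range(2):
                            if blk[i, j] == 0.0:
                                continue
                            rows.append(2 * rn + i)
                            cols.append(2 * cn + j)
                            vals.append(np.full(len(a), s * blk[i, j]))
        if rows:
            rows = np.concatenate([np.asarray(r) for r in rows])
            cols = np.concatenate([np.asarray(c) for c in cols])
            vals = np.concatenate(vals)
        else:
            rows = cols = np.empty(0, int)
            vals = np.empty(0)
        return f, (rows, cols, vals)

    # -- contact ------------------------------------------------------------

    def _penalty(self, pen):
        """C1-regularized penalty law: pressure, slope, stored energy density.

        Quadratic below the smoothing depth, linear beyond; removes the force
        kink at grazing contact that otherwise causes active-set cycling.
        """
        d = self.opt.contact_smoothing_mm
        k = self.k_pen
        pen = np.maximum(pen, 0.0)
        lin = pen >= d
        q = np.where(lin, k * (pen - 0.5 * d), 0.5 * k * pen**2 / d)
        dq = np.where(lin, k, k * pen / d)
        en = np.where(lin, k * ((pen - 0.5 * d) ** 2 / 2.0 + d * d / 24.0),
                      k * pen**3 / (6.0 * d))
        return q, dq, en

    def member_contact(self, u, member: ExpansionMember | None, frozen=None):
        """Penalty contact of the rigid member with the TL luminal nodes.

        With ``frozen`` (an active-node mask from a previous evaluation) the
        active set is held fixed and the penalty is evaluated as a plain
        linear spring — a smooth model used inside one Newton iteration's
        line search (semi-smooth active-set treatment).
        """
        f = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        info = dict(nodes=np.empty(0, int), pressure=np.empty(0),
                    trib=np.empty(0), energy=0.0, frozen=np.empty(0, bool))
        if member is None:
            return f, (np.empty(0, int), np.empty(0, int), np.empty(0)), info
        ids = self.lumen_nodes
        xall = self.mesh.nodes + u.reshape(-1, 2)
        # tributary lengths on the deformed surface (traction-consistent)
        _, trib_def = self._tributary_at(self.tl_edges, xall)
        x = xall[ids]
        c = np.asarray(member.center)
        rel = x - c
        rho = np.hypot(rel[:, 0], rel[:, 1])
        pen = member.radius - rho
        act = (pen > 0) if frozen is None else frozen
        info["frozen"] = act
        self._trib_current = trib_def
        if np.any(act):
            ia = ids[act]
            n = rel[act] / rho[act, None]
            if frozen is None:
                q, dq, en = self._penalty(pen[act])        # contact pressure, Pa
            else:
                d = self.opt.contact_smoothing_mm
                q = self.k_pen * (pen[act] - 0.5 * d)
                dq = np.full(len(q), self.k_pen)
                en = 0.5 * q**2 / self.k_pen
            fa = (q * self.flat_trib(act))[:, None] * n
            np.add.at(f, 2 * ia, fa[:, 0])
            np.add.at(f, 2 * ia + 1, fa[:, 1])
            # d f / d x = L [-dq n n^T + q (I - n n^T)/rho]
            nnT = n[:, :, None] * n[:, None, :]
            eye = np.eye(2)[None]
            dfdx = self.flat_trib(act)[:, None, None] * (
                -dq[:, None, None] * nnT
                + (q / rho[act])[:, None, None] * (eye - nnT))
            for i in range(2):
                for j in range(2):
                    rows.append(2 * ia + i)
                    cols.append(2 * ia + j)
                    vals.append(dfdx[:, i, j])
            info.update(nodes=ia, pressure=q, trib=self.flat_trib(act),
                        energy=float((self.flat_trib(act) * en).sum()))
        if rows:
            rows, cols = np.concatenate(rows), np.concatenate(cols)
            vals = np.concatenate(vals)
        else:
            rows = cols = np.empty(0, int)
            vals = np.empty(0)
        return f, (rows, cols, vals), info

    def flat_trib(self, mask):
        return self._trib_current[mask]

    def flap_gaps(self, u, seg_fixed=None):
        """Signed gap of each flap outer node to the FL-wall inner surface.

        Positive = separated, negative = penetrating.  Also returns the
        projection data needed for contact forces.  ``seg_fixed`` pins the
        slave-to-segment pairing (frozen evaluation).
        """
        X = self.mesh.nodes + u.reshape(-1, 2)
        s = self.flc_nodes
        xa = X[self.master_edges[:, 0]]
        xb = X[self.master_edges[:, 1]]
        d = xb - xa                                        # (m,2)
        L2 = np.maximum((d**2).sum(axis=1), 1e-30)
        xs = X[s]
        if seg_fixed is None:
            # (ns, m) projections, closest segment per slave node
            rel = xs[:, None, :] - xa[None, :, :]
            xi = np.clip((rel * d[None]).sum(axis=2) / L2[None], 0.0, 1.0)
            proj = xa[None] + xi[..., None] * d[None]
            dist2 = ((xs[:, None, :] - proj) ** 2).sum(axis=2)
            jmin = np.argmin(dist2, axis=1)
            ar = np.arange(len(s))
            xi_s = xi[ar, jmin]
            proj_s = proj[ar, jmin]
        else:
            jmin = seg_fixed
            rel = xs - xa[jmin]
            xi_s = np.clip((rel * d[jmin]).sum(axis=1) / L2[jmin], 0.0, 1.0)
            proj_s = xa[jmin] + xi_s[:, None] * d[jmin]
        dmin = d[jmin]
        # master outward normal (solid on left of a->b => rotate -90 deg)
        nrm = np.stack([dmin[:, 1], -dmin[:, 0]], axis=1)
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        gap = ((xs - proj_s) * nrm).sum(axis=1)
        return gap, dict(seg=jmin, xi=xi_s, normal=nrm, slave=s)

    def flap_contact(self, u, frozen=None):
        """Node-to-segment penalty contact between flap and FL wall.

        ``frozen`` holds (active mask, segment assignment) from a previous
        evaluation; with it the pairing is fixed and the penalty is linear,
        making the force smooth within one Newton iteration.
        """
        f = np.zeros(self.ndof)
        empty = (np.empty(0, int), np.empty(0, int), np.empty(0))
        base_info = dict(energy=0.0, gap=np.empty(0),
                         frozen=(np.empty(0, bool), np.empty(0, int)))
        if not self.has_flap_contact:
            return f, empty, base_info
        if frozen is None:
            gap, prj = self.flap_gaps(u)
            pen = np.maximum(0.0, -gap)
            act = pen > 0
            seg_all = prj["seg"]
        else:
            act, seg_all = frozen
            gap, prj = self.flap_gaps(u, seg_fixed=seg_all)
            pen = -gap
        base_info = dict(energy=0.0, gap=gap, frozen=(act, seg_all))
        if not np.any(act):
            return f, empty, base_info
        s = prj["slave"][act]
        seg = seg_all[act]
        xi = prj["xi"][act]
        n = prj["normal"][act]
        xall = self.mesh.nodes + u.reshape(-1, 2)
        _, flc_trib_def = self._tributary_at(self.flap_edges, xall)
        L = flc_trib_def[act]
        if frozen is None:
            q, dq, en = self._penalty(pen[act])
        else:
            d = self.opt.contact_smoothing_mm
            q = self.k_pen * (pen[act] - 0.5 * d)
            dq = np.full(len(q), self.k_pen)
            en = 0.5 * q**2 / self.k_pen
        energy = float((L * en).sum())
        ma, mb = self.master_edges[seg, 0], self.master_edges[seg, 1]
        fs = (q * L)[:, None] * n
        np.add.at(f, 2 * s, fs[:, 0])
        np.add.at(f, 2 * s + 1, fs[:, 1])
        for nodes, wgt in ((ma, -(1.0 - xi)), (mb, -xi)):
            np.add.at(f, 2 * nodes, wgt * fs[:, 0])
            np.add.at(f, 2 * nodes + 1, wgt * fs[:, 1])
        # K = dq L (dg x dg), dg/dxs = n, dg/dxa = -(1-xi) n, dg/dxb = -xi n
        rows, cols, vals = [], [], []
        parts = ((s, np.ones_like(xi)), (ma, -(1.0 - xi)), (mb, -xi))
        for na, wa in parts:
            for nb, wb in parts:
                blk = (dq * L * wa * wb)[:, None, None] * (
                    n[:, :, None] * n[:, None, :])
                for i in range(2):
                    for j in range(2):
                        rows.append(2 * na + i)
                        cols.append(2 * nb + j)
                        vals.append(-blk[:, i, j])  # stiffness of the force pair
        return f, (np.concatenate(rows), np.concatenate(cols),
                   np.concatenate(vals)), dict(energy=energy, gap=gap,
                                               frozen=(act, seg_all))

    # -- Newton solve -------------------------------------------------------

    def solve(self, u0, p_tl, p_fl, member: ExpansionMember | None,
              stab: float = 0.0, u_ref=None, max_iter: int | None = None,
              p_flap_bias: float = 0.0, accept_factor: float = 1e3,
              step_cap: float | None = None, patient: bool = False):
        """Newton iteration to equilibrium at fixed loads; returns (u, log).

        ``stab`` adds grounded springs of that stiffness (per dof) pulling
        toward ``u_ref`` — contact stabilization for snap-through phases;
        callers remove it again by a destabilized polish solve.
        """
        opt = self.opt
        u = u0.copy()
        uref = u0 if u_ref is None else u_ref
        nfree = int(self.free.sum())
        log = []
        u_best, res_best, it_best = None, np.inf, 0

        CC = float(self.C @ self.C)

        def forces(uu, want_tangent, frozen=None):
            fint, trip_i, _ = self.internal(uu, tangent=want_tangent)
            fp, trip_p = self.pressure_load(uu, p_tl, p_fl, p_flap_bias)
            fm, trip_m, mi = self.member_contact(
                uu, member, frozen=None if frozen is None else frozen[0])
            fc, trip_c, ci = self.flap_contact(
                uu, frozen=None if frozen is None else frozen[1])
            R = fint - fp - fm - fc
            if stab > 0.0:
                R = R + stab * (uu - uref)
            ref = max(np.abs(fint).max(), np.abs(fp).max(), np.abs(fm).max(),
                      np.abs(fc).max(), 1e-8 * self.k_pen)
            return R, ref, (trip_i, trip_p, trip_m, trip_c), \
                (mi["frozen"], ci["frozen"])

        def resnorm(R, ref):
            # the multiplier reaction balances the rigid-mode component of R
            Rf = R[self.free]
            Rp = Rf - self.C * (self.C @ Rf) / CC
            return np.abs(Rp).max() / ref

        niter = max_iter if max_iter is not None else opt.max_newton_iter
        for it in range(niter):
            R, ref, (trip_i, trip_p, trip_m, trip_c), frz = forces(u, True)
            res = resnorm(R, ref)
            log.append(res)
            if res < opt.newton_tol:
                return u, log
            if res < res_best:
                res_best, u_best, it_best = res, u.copy(), it
            # penalty-contact chatter: residual stagnates just above tolerance
            chat_it, stale_it = (60, 90) if patient else (10, 30)
            if (it > chat_it and res_best < accept_factor * opt.newton_tol
                    and res > 0.5 * min(log[-10:-1])):
                return u_best, log
            # cycling far from equilibrium: give up early, caller substeps
            if (it - it_best >= stale_it
                    and res_best > accept_factor * opt.newton_tol):
                raise SolverError(
                    f"Newton cycling (best residual {res_best:.3e})")
            rows = np.concatenate([trip_i[0], trip_p[0], trip_m[0], trip_c[0]])
            cols = np.concatenate([trip_i[1], trip_p[1], trip_m[1], trip_c[1]])
            vals = np.concatenate([trip_i[2], -trip_p[2], -trip_m[2], -trip_c[2]])
            if stab > 0.0:
                rows = np.concatenate([rows, np.arange(self.ndof)])
                cols = np.concatenate([cols, np.arange(self.ndof)])
                vals = np.concatenate([vals, np.full(self.ndof, stab)])
            K = sp.coo_matrix((vals, (rows, cols)),
                              shape=(self.ndof, self.ndof)).tocsr()
            Kff = K[self.free][:, self.free]
            Csp = sp.csr_matrix(self.C[None, :])
            Kaug = sp.bmat([[Kff, Csp.T], [Csp, None]], format="csc")
            rhs = np.concatenate([-R[self.free], [-self.C @ u[self.free]]])
            try:
                du = spla.spsolve(Kaug, rhs)
            except RuntimeError as exc:  # singular factorization
                raise SolverError(f"linear solve failed: {exc}")
            if not np.all(np.isfinite(du)):
                raise SolverError("non-finite Newton update")
            step = du[:nfree]
            cap_lim = step_cap if step_cap is not None else opt.step_cap_mm
            cap = np.abs(step).max()
            if cap > cap_lim:
                step = step * (cap_lim / cap)
            # backtracking line search on the residual norm
            alpha = 1.0
            base = res
            u_try = None
            for _ in range(8):
                u_cand = u.copy()
                u_cand[self.free] += alpha * step
                try:
                    Rt, _, _, _ = forces(u_cand, False)
                except (InvertedElementError, OverflowStateError):
                    alpha *= 0.5
                    continue
                res_t = resnorm(Rt, ref)
                # tolerate transient growth; Newton is not monotone in this norm
                if res_t < 3.0 * base or alpha < 0.1:
                    u_try = u_cand
                    break
                alpha *= 0.5
            if u_try is None:
                raise SolverError("line search failed (element inversion)")
            u = u_try
        if res_best < accept_factor * opt.newton_tol:
            return u_best, log
        raise SolverError(f"Newton did not converge in {niter} "
                          f"iterations (residual {log[-1]:.3e})")

    def residual_norm(self, u, p_tl, p_fl, member: ExpansionMember | None,
                      p_flap_bias: float = 0.0) -> float:
        """Projected relative equilibrium residual of a state (diagnostic)."""
        fint, _, _ = self.internal(u, tangent=False)
        fp, _ = self.pressure_load(u, p_tl, p_fl, p_flap_bias)
        fm, _, _ = self.member_contact(u, member)
        fc, _, _ = self.flap_contact(u)
        R = fint - fp - fm - fc
        ref = max(np.abs(fint).max(), np.abs(fp).max(), np.abs(fm).max(),
                  np.abs(fc).max(), 1e-8 * self.k_pen)
        Rf = R[self.free]
        Rp = Rf - self.C * (self.C @ Rf) / float(self.C @ self.C)
        return float(np.abs(Rp).max() / ref)

    def solve_released(self, u0, p_tl, p_fl, member: ExpansionMember | None,
                       stab0: float, u_ref, max_iter: int = 40,
                       p_flap_bias: float = 0.0, accept_factor: float = 1e3,
                       step_cap: float | None = None):
        """Damped solve followed by gradual release of the damping.

        Continuation in the stabilization parameter: converge at ``stab0``,
        then re-converge at stab0/5, stab0/25 and 0, each warm-started.  The
        final state is an equilibrium of the undamped problem.
        """
        u, log = self.solve(u0, p_tl, p_fl, member, stab=stab0, u_ref=u_ref,
                            max_iter=max_iter, p_flap_bias=p_flap_bias,
                            accept_factor=accept_factor, step_cap=step_cap)
        u, lg = self.solve(u, p_tl, p_fl, member, stab=stab0 / 30.0, u_ref=u_ref,
                           max_iter=max_iter, p_flap_bias=p_flap_bias,
                           accept_factor=accept_factor, step_cap=step_cap)
        log = log + lg
        u, lg = self.solve(u, p_tl, p_fl, member, stab=0.0, u_ref=u_ref,
                           max_iter=2 * max_iter, p_flap_bias=p_flap_bias,
                           accept_factor=accept_factor, step_cap=step_cap)
        return u, log + lg

    def solve_robust(self, u0, p_tl, p_fl, member: ExpansionMember | None):
        """Solve, escalating contact stabilization on failure and polishing
        the stabilized solution back to the unstabilized problem.

        A short direct attempt comes first; snap-through phases then run with
        grounded-spring stabilization (level remembered across calls) and are
        polished back to the unstabilized problem.  Returns (u, log, stab_used).
        """
        try:
            u, log = self.solve(u0, p_tl, p_fl, member, max_iter=25)
            return u, log, 0.0
        except (SolverError, InvertedElementError, OverflowStateError):
            pass
        last_exc = None
        start = max(getattr(self, "_stab_level", 0.0), 1e-5 * self.k_pen)
        stab = start
        for _ in range(3):
            try:
                u, log = self.solve(u0, p_tl, p_fl, member, stab=stab,
                                    u_ref=u0, max_iter=40)
            except (SolverError, InvertedElementError, OverflowStateError) as exc:
                last_exc = exc
                stab *= 10.0
                if stab > 1e-2 * self.k_pen:
                    break
                continue
            self._stab_level = stab
            try:  # remove the stabilization bias
                u2, log2 = self.solve(u, p_tl, p_fl, member, max_iter=25)
                return u2, log + log2, 0.0
            except (SolverError, InvertedElementError, OverflowStateError):
                return u, log, stab
        raise SolverError(f"no convergence even with stabilization: {last_exc}")


# ---------------------------------------------------------------------------
# equilibrium state and two-step protocol
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumState:
    """Converged configuration plus running work/energy audit."""

    model: FEModel
    u: np.ndarray
    p_aorta_mmhg: float
    member: ExpansionMember | None = None
    newton_log: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    work_pressure: float = 0.0   # Pa*mm^2 per unit depth
    work_member: float = 0.0
    _f_prev: dict = field(default_factory=dict)

    @property
    def mesh(self):
        return self.model.mesh

    def strain_energy(self) -> float:
        _, _, en = self.model.internal(self.u, tangent=False)
        return en

    def penalty_energy(self) -> float:
        _, _, mi = self.model.member_contact(self.u, self.member)
        _, _, ci = self.model.flap_contact(self.u)
        return mi["energy"] + ci["energy"]

    def jbar_range(self):
        self.model.internal(self.u, tangent=False)
        jb = self.model._last_Jbar
        return float(jb.min()), float(jb.max())

    def max_flap_gap(self) -> float:
        if not self.model.has_flap_contact:
            return 0.0
        gap, _ = self.model.flap_gaps(self.u)
        return float(np.maximum(gap, 0.0).max())

    def contact_fraction(self, tol_mm: float) -> float:
        if not self.model.has_flap_contact:
            return 1.0
        gap, _ = self.model.flap_gaps(self.u)
        return float(np.mean(gap <= tol_mm))

    def inner_diameter(self) -> float:
        """Mean diameter of the deformed TL luminal surface about the member center."""
        ids = self.model.lumen_nodes
        c = np.asarray(self.model.opt.member_center)
        x = self.mesh.nodes[ids] + self.u.reshape(-1, 2)[ids]
        return float(2.0 * np.hypot(*(x - c).T).mean())

    def _accumulate_work(self, u_new, p_tl, p_fl, member):
        """Trapezoidal work increments of pressure and member contact."""
        m = self.model
        fp0 = self._f_prev.get("p")
        fm0 = self._f_prev.get("m")
        fp1, _ = m.pressure_load(u_new, p_tl, p_fl)
        fm1, _, _ = m.member_contact(u_new, member)
        du = u_new - self.u
        if fp0 is not None:
            self.work_pressure += 0.5 * float((fp0 + fp1) @ du)
            self.work_member += 0.5 * float((fm0 + fm1) @ du)
        else:
            self.work_pressure += 0.5 * float(fp1 @ du)
            self.work_member += 0.5 * float(fm1 @ du)
        self._f_prev = {"p": fp1, "m": fm1}


def pressurize(mesh: CrossSectionMesh, materials: dict, p_aorta_mmhg: float,
               options: SolverOptions = SolverOptions(),
               model: FEModel | None = None) -> EquilibriumState:
    """Step 1: ramp the static aortic pressure to equilibrium (follower load).

    Pressure acts on the TL luminal surfaces and, by default, the FL surfaces
    (see module docstring).  Raises :class:`SolverError` carrying the last
    converged load fraction on divergence.
    """
    if p_aorta_mmhg < 0:
        raise ValueError("p_aorta must be >= 0")
    m = model if model is not None else FEModel(mesh, materials, options)
    st = EquilibriumState(model=m, u=np.zeros(m.ndof), p_aorta_mmhg=p_aorta_mmhg)
    p_target = p_aorta_mmhg * MMHG_TO_PA
    if p_target == 0.0:
        st._f_prev = {"p": np.zeros(m.ndof), "m": np.zeros(m.ndof)}
        return st
    frac, dfrac = 0.0, 1.0 / options.load_steps
    u_prev, f_prev = None, None
    stab_m = 1e-5 * m.k_pen
    bias_pa = options.flap_drape_bias_mmhg * MMHG_TO_PA \
        if m.has_flap_contact else 0.0
    while frac < 1.0 - 1e-12:
        f_try = min(1.0, frac + dfrac)
        p_tl = f_try * p_target
        p_fl = p_tl if options.pressurize_false_lumen else 0.0
        u0 = st.u
        if u_prev is not None and frac > f_prev:
            u0 = st.u + (st.u - u_prev) * ((f_try - frac) / (frac - f_prev))
        # damped continuation step with gradual release of the damping;
        # the flap drape bias keeps the slack flap on its taut branch
        bias = f_try * bias_pa
        try:
            u_new, log = m.solve_released(u0, p_tl, p_fl, None, stab_m, st.u,
                                          p_flap_bias=bias)
        except (SolverError, InvertedElementError, OverflowStateError):
            try:
                u_new, log = m.solve_released(st.u, p_tl, p_fl, None,
                                              10 * stab_m, st.u,
                                              p_flap_bias=bias)
            except (SolverError, InvertedElementError, OverflowStateError):
                dfrac *= 0.5
                if dfrac < 1e-3:
                    raise SolverError(
                        f"pressurization diverged at load fraction {frac:.3f}",
                        last_converged_fraction=frac)
                continue
        st._accumulate_work(u_new, p_tl, p_fl, None)
        u_prev, f_prev = st.u.copy(), frac
        st.u = u_new
        st.newton_log.append(("pressurize", f_try, len(log), log[-1]))
        frac = f_try
        if len(log) <= 6:
            dfrac = min(dfrac * 1.5, 1.0 - frac if frac < 1 else dfrac)
    # NOTE: the step-1 state retains the small flap drape bias — the slack
    # flap's position is indeterminate without it, and no reported quantity
    # is read from this state (the bias is removed at every measured
    # configuration during member expansion, where the flap is supported).
    return st


def advance_pressure(state: EquilibriumState, p_new_mmhg: float,
                     options: SolverOptions | None = None) -> EquilibriumState:
    """Ramp the aortic pressure of an equilibrated state (member held fixed).

    Used by warm-started pressure sweeps: the fully apposed terminal state of
    one sweep point is carried to the next pressure, after which only a short
    member adjustment is needed.
    """
    m = state.model
    opt = options if options is not None else m.opt
    bias_pa = opt.flap_drape_bias_mmhg * MMHG_TO_PA if m.has_flap_contact else 0.0
    stab_m = 1e-5 * m.k_pen
    p0, p1 = state.p_aorta_mmhg, p_new_mmhg
    frac, dfrac = 0.0, 0.5
    while frac < 1.0 - 1e-12:
        f_try = min(1.0, frac + dfrac)
        p = (p0 + f_try * (p1 - p0)) * MMHG_TO_PA
        p_fl = p if opt.pressurize_false_lumen else 0.0
        s = stab_m
        done = False
        while s <= 1e-2 * m.k_pen:
            try:
                u_new, log = m.solve(state.u, p, p_fl, state.member, stab=s,
                                     u_ref=state.u, max_iter=50,
                                     p_flap_bias=bias_pa, accept_factor=1e3)
                done = True
                break
            except (SolverError, InvertedElementError, OverflowStateError):
                s *= 10.0
        if not done:
            dfrac *= 0.5
            if dfrac < 1e-3:
                raise SolverError(
                    f"pressure advance diverged at {p0 + frac * (p1 - p0):.1f} mmHg")
            continue
        state._accumulate_work(u_new, p, p_fl, state.member)
        state.u = u_new
        state.newton_log.append(("advance", f_try, len(log), log[-1]))
        frac = f_try
    state.p_aorta_mmhg = p_new_mmhg
    return state


def radial_pressure_from_contact(state: EquilibriumState,
                                 member: ExpansionMember | None = None,
                                 include_noncontacting: bool = False) -> float:
    """Average contact pressure on the expansion member, in mmHg.

    Tributary-length weighted mean over the contacting surface (nodes whose
    contact pressure exceeds 0.1 % of the peak, which drops numerically
    marginal grazing nodes); optionally averaged over the member's full
    perimeter instead.
    """
    member = member if member is not None else state.member
    _, _, info = state.model.member_contact(state.u, member)
    q, trib = info["pressure"], info["trib"]
    if len(q) == 0:
        raise SolverError("empty contact set: member is not in contact")
    act = q > 1e-3 * q.max()
    if include_noncontacting:
        perim = 2 * np.pi * member.radius
        per = perim / 2.0 if state.mesh.geometry.symmetry else perim
        return float((q[act] * trib[act]).sum() / per * PA_TO_MMHG)
    return float((q[act] * trib[act]).sum() / trib[act].sum() * PA_TO_MMHG)


def expand_member(state: EquilibriumState, member: ExpansionMember | None = None,
                  options: SolverOptions | None = None,
                  target_radius: float | None = None) -> ReappositionResult:
    """Step 2: dilate the rigid member until full flap re-apposition.

    The member radius is marched in increments and the smallest radius whose
    equilibrium leaves every flap outer node within the gap tolerance of the
    FL wall is found by bisection.  The radial pressure is the average member
    contact pressure at that radius.

    With ``target_radius`` the member is instead expanded to that radius and
    the contact pressure reported there (verification mode, e.g. rigid-member
    expansion of an intact ring).
    """
    m = state.model
    opt = options if options is not None else m.opt
    geom = state.mesh.geometry
    g_tol = opt.gap_tol_fraction * (geom.flap_thickness_mm if not geom.intact else 1.0)
    history = []

    if member is None:
        member = ExpansionMember(center=opt.member_center, radius=1.0,
                                 n_segments=opt.member_segments)

    # start just inside the deformed lumen, or continue from an existing
    # member contact state (warm-started sweeps)
    if state.member is not None:
        r = state.member.radius
        member = state.member
        warm = True
    else:
        x = state.mesh.nodes[m.lumen_nodes] + state.u.reshape(-1, 2)[m.lumen_nodes]
        rho_min = float(np.hypot(*(x - np.asarray(member.center)).T).min())
        if member.radius > rho_min:
            raise GeometricFailureError(
                "initial member radius interpenetrates the lumen")
        r = max(member.radius, 0.98 * rho_min)
        warm = False

    if target_radius is not None:
        if target_radius <= r:
            raise GeometricFailureError("target_radius must exceed the free lumen radius")
        p_tl_, p_fl_ = _p_tl(state, opt), _p_fl(state, opt)
        stab_t = 1e-5 * m.k_pen
        u_cur, dr = state.u.copy(), min(opt.member_step_mm, 0.1)
        r_cur = r
        while r_cur < target_radius - 1e-12:
            r_try = min(target_radius, r_cur + dr)
            mem = member.with_radius(r_try)
            u_new = None
            s = stab_t
            while s <= 1e-1 * m.k_pen:
                try:
                    u_new, log = m.solve(u_cur, p_tl_, p_fl_, mem, stab=s,
                                         u_ref=u_cur, max_iter=50,
                                         accept_factor=1e3)
                    break
                except (SolverError, InvertedElementError, OverflowStateError):
                    s *= 10.0
            if u_new is None:
                dr *= 0.5
                if dr < 1e-4:
                    raise SolverError(f"expansion diverged near r={r_cur:.3f} mm",
                                      last_converged_fraction=r_cur)
                continue
            state._accumulate_work(u_new, p_tl_, p_fl_, mem)
            u_cur = u_new
            state.u, state.member = u_new, mem
            state.newton_log.append(("expand", r_try, len(log), log[-1]))
            r_cur = r_try
            if len(log) <= 16:
                dr = min(dr * 1.5, 2 * opt.member_step_mm)
        # undamped polish at the target radius
        u_new, log = m.solve(u_cur, p_tl_, p_fl_, state.member, max_iter=120,
                             step_cap=0.05, patient=True, accept_factor=1e4)
        state.u = u_new
        state.newton_log.append(("polish", r_cur, len(log), log[-1]))
        q = radial_pressure_from_contact(state, state.member)
        return ReappositionResult(
            p_aorta_mmhg=state.p_aorta_mmhg, radial_pressure_mmhg=q,
            member_radius_mm=r_cur, final_inner_diameter_mm=state.inner_diameter(),
            contact_fraction_history=[state.contact_fraction(g_tol)],
            newton_log=list(state.newton_log), converged=True,
            region=geom.region, warnings=list(state.warnings),
        )

    if not warm and m.has_flap_contact and state.max_flap_gap() <= g_tol:
        # already fully apposed (e.g. unpressurized zero-gap start)
        res = ReappositionResult(
            p_aorta_mmhg=state.p_aorta_mmhg, radial_pressure_mmhg=0.0,
            member_radius_mm=r, final_inner_diameter_mm=state.inner_diameter(),
            contact_fraction_history=[1.0], newton_log=list(state.newton_log),
            converged=True, region=geom.region,
            warnings=state.warnings + ["flap apposed before member expansion"],
        )
        state.member = member.with_radius(r)
        return res

    r_fl_max = _fl_wall_reach(state)
    dr = opt.member_step_mm
    r_lo, u_lo = r, state.u.copy()
    gap_lo = state.max_flap_gap()
    r_hi = None
    p_tl, p_fl = _p_tl(state, opt), _p_fl(state, opt)
    stab_m = 1e-5 * m.k_pen
    bias_pa = opt.flap_drape_bias_mmhg * MMHG_TO_PA if m.has_flap_contact else 0.0

    def damped(u_start, r_at):
        """One damped continuation solve, escalating damping through snaps;
        falls back to a tight-trust-region grind."""
        mem_ = member.with_radius(r_at)
        s = stab_m
        while s <= 1e-2 * m.k_pen:
            try:
                return m.solve(u_start, p_tl, p_fl, mem_, stab=s,
                               u_ref=u_start, max_iter=50,
                               p_flap_bias=bias_pa, accept_factor=1e3)
            except (SolverError, InvertedElementError, OverflowStateError):
                s *= 10.0
        # tight-trust-region grind: slow but traverses contact cascades
        try:
            return m.solve(u_start, p_tl, p_fl, mem_, stab=stab_m,
                           u_ref=u_start, max_iter=150, p_flap_bias=bias_pa,
                           accept_factor=1e5, step_cap=0.05, patient=True)
        except (SolverError, InvertedElementError, OverflowStateError):
            raise SolverError(f"damped continuation failed at r={r_at:.3f}")

    def polish(u_start, r_at):
        """Undamped equilibrium (drape bias retained); returns (u, log).

        A tight trust region lets plain damped Newton grind through the
        contact-transition cascade at the pressed terminal states."""
        mem_ = member.with_radius(r_at)
        try:
            return m.solve(u_start, p_tl, p_fl, mem_, max_iter=150,
                           p_flap_bias=bias_pa, accept_factor=1e4,
                           step_cap=0.05, patient=True)
        except (SolverError, InvertedElementError, OverflowStateError):
            pass
        try:
            u1, l1 = m.solve_released(u_start, p_tl, p_fl, mem_, 30 * stab_m,
                                      u_start, p_flap_bias=bias_pa,
                                      accept_factor=1e4, step_cap=0.05)
        except (SolverError, InvertedElementError, OverflowStateError):
            raise
        if m.residual_norm(u1, p_tl, p_fl, mem_, p_flap_bias=bias_pa)                 > 5e3 * opt.newton_tol:
            # second grind round from the released state (fine meshes chatter)
            try:
                u1, l2 = m.solve(u1, p_tl, p_fl, mem_, max_iter=250,
                                 p_flap_bias=bias_pa, accept_factor=1e4,
                                 step_cap=0.02, patient=True)
                l1 = l1 + l2
            except (SolverError, InvertedElementError, OverflowStateError):
                pass
        return u1, l1

    # damped march with a geometric approach to closure; recovery halves the
    # radius increment first (cheap) and escalates the damping only when the
    # increment is already small
    while r_hi is None:
        r_try = r_lo + dr
        if r_try > _fl_wall_reach(state):  # wall recedes as the member pushes
            raise GeometricFailureError(
                "member radius exceeded the FL wall reach without re-apposition")
        try:
            u_new, log = damped(u_lo, r_try)
        except (SolverError, InvertedElementError, OverflowStateError):
            dr *= 0.5
            if dr < opt.radius_tol_mm / 4:
                raise SolverError(
                    f"member expansion diverged near r={r_lo:.3f} mm",
                    last_converged_fraction=r_lo)
            continue
        state._accumulate_work(u_new, p_tl, p_fl, member.with_radius(r_try))
        state.u, state.member = u_new, member.with_radius(r_try)
        state.newton_log.append(("expand", r_try, len(log), log[-1]))
        gap = state.max_flap_gap()
        history.append(state.contact_fraction(g_tol))
        if gap <= g_tol:
            r_hi, u_hi, gap_hi = r_try, u_new.copy(), gap
        else:
            r_lo, u_lo, gap_lo = r_try, u_new.copy(), gap
            dr = min(max(1.2 * dr, 0.05), opt.member_step_mm,
                     max(0.35 * gap, 0.03))

    # polish the two bracketing states free of damping and grade their quality
    # (the quality bar sits at the practical chatter floor of penalty contact)
    quality = 5e3 * opt.newton_tol
    def state_quality(uu, r_at):
        return m.residual_norm(uu, p_tl, p_fl, member.with_radius(r_at),
                               p_flap_bias=bias_pa)

    ok = True
    try:
        u_lo, _ = polish(u_lo, r_lo)
        ok &= state_quality(u_lo, r_lo) <= quality
        u_hi, _ = polish(u_hi, r_hi)
        ok &= state_quality(u_hi, r_hi) <= quality
        gap_lo = _gap_at(m, u_lo)
        gap_hi = _gap_at(m, u_hi)
    except (SolverError, InvertedElementError, OverflowStateError):
        ok = False
        state.warnings.append("terminal polish failed; damped states reported")
    # polishing may shift the criterion across a bracket edge: walk the
    # bracket (few short steps) until it straddles gap = g_tol again
    for _ in range(6):
        if not ok:
            break
        if gap_hi > g_tol:
            r_lo, u_lo, gap_lo = r_hi, u_hi, gap_hi
            r_hi = r_hi + 0.03
            try:
                u_hi, _ = polish(u_hi, r_hi)
                ok &= state_quality(u_hi, r_hi) <= quality
                gap_hi = _gap_at(m, u_hi)
            except (SolverError, InvertedElementError, OverflowStateError):
                ok = False
        elif gap_lo <= g_tol and r_lo - 0.03 > r:
            r_hi, u_hi, gap_hi = r_lo, u_lo, gap_lo
            r_lo = r_lo - 0.03
            try:
                u_lo, _ = polish(u_lo, r_lo)
                ok &= state_quality(u_lo, r_lo) <= quality
                gap_lo = _gap_at(m, u_lo)
            except (SolverError, InvertedElementError, OverflowStateError):
                ok = False
        else:
            break
    if ok and not (gap_lo > g_tol >= gap_hi):
        state.warnings.append("criterion bracket not recovered after polish")
    if not ok and not state.warnings:
        state.warnings.append("measured-state residual above quality bar")

    # measure both bracket states; interpolate to the criterion gap = g_tol
    def measure(uu, r_at):
        state.u = uu
        state.member = member.with_radius(r_at)
        try:
            q = radial_pressure_from_contact(state, state.member)
        except SolverError:
            q = 0.0
        return q, state.inner_diameter()

    q_hi, d_hi = measure(u_hi, r_hi)
    if gap_lo > gap_hi and gap_lo > g_tol >= gap_hi:
        q_lo, d_lo = measure(u_lo, r_lo)
        t = (gap_lo - g_tol) / (gap_lo - gap_hi)
        q_star = q_lo + t * (q_hi - q_lo)
        d_star = d_lo + t * (d_hi - d_lo)
        r_star = r_lo + t * (r_hi - r_lo)
    else:
        q_star, d_star, r_star = q_hi, d_hi, r_hi

    state.u, state.member = u_hi, member.with_radius(r_hi)
    history.append(state.contact_fraction(g_tol))
    if q_star > 5.0 * state.p_aorta_mmhg + 100.0:
        # wedged/locked contact state: pressures this size are unphysical
        ok = False
        state.warnings.append("implausible radial pressure; flagged unconverged")
    res = ReappositionResult(
        p_aorta_mmhg=state.p_aorta_mmhg, radial_pressure_mmhg=q_star,
        member_radius_mm=r_star, final_inner_diameter_mm=d_star,
        contact_fraction_history=history, newton_log=list(state.newton_log),
        converged=ok, region=geom.region, warnings=list(state.warnings),
        assumptions=dict(inner_radius_mm=geom.inner_radius_mm,
                         plane_strain_cross_section=True),
    )
    return res


def _p_tl(state, opt):
    return state.p_aorta_mmhg * MMHG_TO_PA


def _p_fl(state, opt):
    return state.p_aorta_mmhg * MMHG_TO_PA if opt.pressurize_false_lumen else 0.0


def _gap_at(model, u):
    if not model.has_flap_contact:
        return 0.0
    gap, _ = model.flap_gaps(u)
    return float(np.maximum(gap, 0.0).max())


def _fl_wall_reach(state):
    """Largest deformed radius of the FL-wall inner surface (geometric guard)."""
    m = state.model
    if not m.has_flap_contact:
        ids = m.lumen_nodes
        x = state.mesh.nodes[ids] + state.u.reshape(-1, 2)[ids]
        return float(np.hypot(*x.T).max()) + 5.0
    ids = np.unique(m.master_edges.ravel())
    x = state.mesh.nodes[ids] + state.u.reshape(-1, 2)[ids]
    return float(np.hypot(*(x - np.asarray(m.opt.member_center)).T).max())


def run_reapposition(geom: DissectionGeometry, materials: dict,
                     p_aorta_mmhg: float, options: SolverOptions = SolverOptions(),
                     h: float = 0.3, mesh: CrossSectionMesh | None = None,
                     model: FEModel | None = None,
                     return_state: bool = False):
    """Two-step re-apposition run: mesh, pressurize, expand, extract.

    Deterministic: identical inputs produce identical results (no stochastic
    elements in the solver).
    """
    mesh = mesh if mesh is not None else build_cross_section(geom, h)
    model = model if model is not None else FEModel(mesh, materials, options)
    state = pressurize(mesh, materials, p_aorta_mmhg, options, model=model)
    result = expand_member(state, options=options)
    lead = materials.get("flap") or materials.get("tl_wall")
    result.flap_label = lead.label if lead is not None else ""
    if return_state:
        return result, state
    return result
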