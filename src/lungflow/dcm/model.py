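"""Fully coupled implicit finite-volume solver of the alveolus model.

Four primary variables per cell — tissue pressure, capillary pressure and
the drug mole fractions in both continua (plus the receptor-ligand complex
concentration in tumor tissue) — are advanced with implicit Euler and a
Newton iteration on the fully coupled residual.  Fluxes use a two-point
approximation on the structured spherical mesh with full upwinding of the
advective terms; the capillary continuum's face-normal permeability comes
from the REV tensor mapped onto the shell (zero radial component for the
planar bed, isotropic for the tumor).  Transfer terms (Starling,
Kedem-Katchalsky) appear with equal magnitude and opposite sign in the two
continua; lymphatic drainage and receptor binding act in the tissue
continuum only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import PHI, RADIAL, THETA, ContinuumMesh
from .parameters import AlveolusParameters
from .transfer import (
    effective_filtration_pressure,
    kedem_katchalsky_flux,
    lymphatic_sinks,
    starling_flux,
)

__all__ = ["DCMState", "AlveolusModel", "NewtonError",
           "linear_concentration_profile"]


class NewtonError(RuntimeError):
    """Newton iteration failed to converge."""


@dataclass
class DCMState:
    """Cell-wise fields of the double-continuum model."""

    p_t: np.ndarray
    p_c: np.ndarray
    x_t: np.ndarray
    x_c: np.ndarray
    C_RL: np.ndarray | None = None  # tumor only
    time: float = 0.0

    def copy(self) -> "DCMState":
        return DCMState(
            p_t=self.p_t.copy(), p_c=self.p_c.copy(),
            x_t=self.x_t.copy(), x_c=self.x_c.copy(),
            C_RL=None if self.C_RL is None else self.C_RL.copy(),
            time=self.time)


def linear_concentration_profile(mesh: ContinuumMesh, x_art: float,
                                 x_ven: float) -> np.ndarray:
    """Initial capillary mole fraction, linear in x between the two caps."""
    xi = (mesh.cell_centroids[:, 0] + mesh.R_out) / (2.0 * mesh.R_out)
    return x_art + (x_ven - x_art) * np.clip(xi, 0.0, 1.0)


class AlveolusModel:
    """One upscaled node's double-continuum model on a spherical mesh."""

    def __init__(
        self,
        mesh: ContinuumMesh,
        params: AlveolusParameters,
        newton_tol: float = 1e-8,
        max_newton_iter: int = 25,
        max_dt_halvings: int = 5,
    ) -> None:
        self.mesh = mesh
        self.params = params
        self.newton_tol = newton_tol
        self.max_newton_iter = max_newton_iter
        self.max_dt_halvings = max_dt_halvings

        n = mesh.n_cells
        self.n = n
        self.nvar = 5 if params.has_receptors else 4
        self._lu = None
        self._jac_dt = None

        ts, cp, tr = params.tissue, params.capillary, params.transfer
        A_d = mesh.face_area / mesh.face_dist
        # tissue: isotropic permeability
        self.T_t = (ts.permeability / ts.viscosity) * A_d
        # capillary: radial vs tangential face-normal permeability
        k_face = np.where(mesh.face_type == RADIAL, cp.k_radial,
                          cp.k_tangential)
        self.T_c = (k_face / cp.viscosity) * A_d
        # diffusive transmissibilities (molar)
        self.D_t = (ts.tissue_fraction * ts.porosity * ts.tortuosity
                    * params.diffusivity_tissue * ts.molar_density) * A_d
        self.D_c = (cp.volume_fraction * params.diffusivity_capillary
                    * cp.molar_density) * A_d

        # outer-boundary tissue Dirichlet faces
        self.Tb_t = (ts.permeability / ts.viscosity) * mesh.bface_area \
            / mesh.bface_dist

        self.dirichlet = mesh.arterial_cells | mesh.venous_cells
        self.free = ~self.dirichlet

        self._i = mesh.face_cells[:, 0]
        self._j = mesh.face_cells[:, 1]
        self._neighbors = self._build_neighbors()
        self._colors = self._distance2_coloring()
        self._bcs = None  # (p_art, p_ven, x_art, x_ven)

        # per-cell transmissibility sums for residual scaling
        Tsum_t = np.zeros(n)
        Tsum_c = np.zeros(n)
        Dsum_t = np.zeros(n)
        Dsum_c = np.zeros(n)
        for arr, T in ((Tsum_t, self.T_t), (Tsum_c, self.T_c),
                       (Dsum_t, self.D_t), (Dsum_c, self.D_c)):
            np.add.at(arr, self._i, T)
            np.add.at(arr, self._j, T)
        np.add.at(Tsum_t, mesh.bface_cell, self.Tb_t)
        self._Tsum_t, self._Tsum_c = Tsum_t, Tsum_c
        self._Dsum_t, self._Dsum_c = Dsum_t, Dsum_c

    # -- setup ---------------------------------------------------------

    def _build_neighbors(self) -> list[list[int]]:
        nb: list[set[int]] = [set((k,)) for k in range(self.n)]
        for a, b in self.mesh.face_cells:
            nb[a].add(b)
            nb[b].add(a)
        return [sorted(s) for s in nb]

    def _distance2_coloring(self) -> list[np.ndarray]:
        """Greedy distance-2 coloring of the cell adjacency graph."""
        n = self.n
        two_hop: list[set[int]] = []
        for k in range(n):
            s: set[int] = set()
            for m in self._neighbors[k]:
                s.update(self._neighbors[m])
            s.discard(k)
            two_hop.append(s)
        color = -np.ones(n, dtype=int)
        for k in range(n):
            used = {color[m] for m in two_hop[k] if color[m] >= 0}
            c = 0
            while c in used:
                c += 1
            color[k] = c
        return [np.flatnonzero(color == c) for c in range(color.max() + 1)]

    def set_capillary_bcs(self, p_art: float, p_ven: float,
                          x_art: float, x_ven: float) -> None:
        """Dirichlet capillary values on the two angular caps."""
        for v in (p_art, p_ven, x_art, x_ven):
            if not math.isfinite(v):
                raise ValueError("non-finite capillary boundary value")
        self._bcs = (p_art, p_ven, x_art, x_ven)
        # BC values only enter the residual's right-hand side; the cached
        # Jacobian stays valid.

    def initial_state(self, x_art: float | None = None,
                      x_ven: float | None = None) -> DCMState:
        """Initial fields: linear capillary profile, drug-free tissue."""
        if self._bcs is None:
            raise ValueError("set_capillary_bcs must be called first")
        p_art, p_ven, xa, xv = self._bcs
        x_art = xa if x_art is None else x_art
        x_ven = xv if x_ven is None else x_ven
        mesh = self.mesh
        xi = (mesh.cell_centroids[:, 0] + mesh.R_out) / (2.0 * mesh.R_out)
        xi = np.clip(xi, 0.0, 1.0)
        p_c = p_art + (p_ven - p_art) * xi
        return DCMState(
            p_t=np.full(self.n, self.params.tissue.boundary_pressure),
            p_c=p_c,
            x_t=np.zeros(self.n),
            x_c=linear_concentration_profile(mesh, x_art, x_ven),
            C_RL=np.zeros(self.n) if self.params.has_receptors else None,
        )

    # -- vector packing ------------------------------------------------

    def pack(self, state: DCMState) -> np.ndarray:
        parts = [state.p_t, state.p_c, state.x_t, state.x_c]
        if self.params.has_receptors:
            parts.append(state.C_RL)
        return np.concatenate(parts)

    def unpack(self, u: np.ndarray, time: float = 0.0) -> DCMState:
        n = self.n
        return DCMState(
            p_t=u[0:n].copy(), p_c=u[n:2 * n].copy(),
            x_t=u[2 * n:3 * n].copy(), x_c=u[3 * n:4 * n].copy(),
            C_RL=u[4 * n:5 * n].copy() if self.nvar == 5 else None,
            time=time)

    # -- physics -------------------------------------------------------

    def _transfer_terms(self, p_t, p_c, x_t, x_c):
        tr = self.params.transfer
        p_eff = effective_filtration_pressure(p_c, p_t, tr.sigma, tr.pi_c,
                                              tr.pi_t)
        q_v, J_v = starling_flux(p_eff, tr.hydraulic_conductivity,
                                 tr.surface_density, tr.molar_density)
        q_x = kedem_katchalsky_flux(x_c, x_t, J_v, tr.diffusive_permeability,
                                    tr.sigma_f, tr.surface_density,
                                    tr.molar_density)
        return p_eff, q_v, J_v, q_x

    def residual(self, u: np.ndarray, u_old: np.ndarray, dt: float,
                 upwind_p: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> np.ndarray:
        """Fully coupled residual [mol/s per cell equation].

        ``upwind_p`` optionally supplies frozen (p_t, p_c) fields from which
        the upwind directions are taken; the Newton iteration freezes the
        directions per sweep (and re-checks them against the converged
        state) so the non-smooth upwind switch never enters the Jacobian.
        """
        if self._bcs is None:
            raise ValueError("set_capillary_bcs must be called first")
        if not np.all(np.isfinite(u)):
            raise ValueError("non-finite value in state vector")
        n = self.n
        mesh = self.mesh
        prm = self.params
        ts, cp = prm.tissue, prm.capillary
        p_art, p_ven, x_art, x_ven = self._bcs
        V = mesh.cell_volumes
        i, j = self._i, self._j

        p_t, p_c = u[0:n], u[n:2 * n]
        x_t, x_c = u[2 * n:3 * n], u[3 * n:4 * n]
        C_RL = u[4 * n:5 * n] if self.nvar == 5 else None
        x_t_old = u_old[2 * n:3 * n]
        x_c_old = u_old[3 * n:4 * n]
        C_RL_old = u_old[4 * n:5 * n] if self.nvar == 5 else None

        # face fluxes (volumetric, i -> j positive)
        F_t = self.T_t * (p_t[i] - p_t[j])
        F_c = self.T_c * (p_c[i] - p_c[j])

        div_t = np.zeros(n)
        div_c = np.zeros(n)
        np.add.at(div_t, i, F_t)
        np.add.at(div_t, j, -F_t)
        np.add.at(div_c, i, F_c)
        np.add.at(div_c, j, -F_c)

        # tissue outer-boundary Dirichlet pressure
        Fb = self.Tb_t * (p_t[mesh.bface_cell] - ts.boundary_pressure)
        np.add.at(div_t, mesh.bface_cell, Fb)

        # fully upwinded advection + diffusion (molar rates)
        pu_t, pu_c = (p_t, p_c) if upwind_p is None else upwind_p
        xup_t = np.where(pu_t[i] >= pu_t[j], x_t[i], x_t[j])
        xup_c = np.where(pu_c[i] >= pu_c[j], x_c[i], x_c[j])
        adv_t = np.zeros(n)
        adv_c = np.zeros(n)
        np.add.at(adv_t, i, F_t * xup_t)
        np.add.at(adv_t, j, -F_t * xup_t)
        np.add.at(adv_c, i, F_c * xup_c)
        np.add.at(adv_c, j, -F_c * xup_c)
        # boundary advective drug outflow (inflow carries x = 0), with the
        # switch taken from the same frozen pressures as the upwinding
        out_b = pu_t[mesh.bface_cell] >= ts.boundary_pressure
        np.add.at(adv_t, mesh.bface_cell,
                  np.where(out_b, Fb * x_t[mesh.bface_cell], 0.0))

        dif_t = np.zeros(n)
        dif_c = np.zeros(n)
        G_t = self.D_t * (x_t[i] - x_t[j])
        G_c = self.D_c * (x_c[i] - x_c[j])
        np.add.at(dif_t, i, G_t)
        np.add.at(dif_t, j, -G_t)
        np.add.at(dif_c, i, G_c)
        np.add.at(dif_c, j, -G_c)

        _, q_v, J_v, q_x = self._transfer_terms(p_t, p_c, x_t, x_c)

        if prm.has_lymphatics:
            ly_fluid, ly_drug = lymphatic_sinks(
                p_t, x_t, ts.lymph_conductivity, ts.lymph_surface_density,
                ts.lymph_pressure, ts.molar_density, ts.lymph_clamped)
        else:
            ly_fluid = ly_drug = 0.0

        if prm.has_receptors:
            c_free = x_t * ts.molar_density
            bind = (ts.k_on * c_free * (ts.receptor_concentration - C_RL)
                    - ts.k_off * C_RL)
        else:
            bind = 0.0

        et_rho = ts.tissue_fraction * ts.molar_density
        ec_rho = cp.volume_fraction * cp.molar_density
        s_t = ts.tissue_fraction * ts.porosity * ts.molar_density
        s_c = cp.volume_fraction * cp.molar_density  # porosity 1

        R_pt = et_rho * div_t + V * ly_fluid - V * q_v
        R_pc = ec_rho * div_c + V * q_v
        R_xt = ((V / dt) * s_t * (x_t - x_t_old)
                + ts.tissue_fraction * ts.molar_density * adv_t
                + dif_t + V * ly_drug - V * q_x)
        if prm.has_receptors:
            R_xt = R_xt + V * ts.tissue_fraction * bind
        R_xc = ((V / dt) * s_c * (x_c - x_c_old)
                + cp.volume_fraction * cp.molar_density * adv_c
                + dif_c + V * ec_rho * prm.decay_rate * x_c + V * q_x)

        # capillary Dirichlet caps: replace continuity/transport rows
        art, ven = mesh.arterial_cells, mesh.venous_cells
        R_pc = np.where(art, p_c - p_art, R_pc)
        R_pc = np.where(ven, p_c - p_ven, R_pc)
        R_xc = np.where(art, x_c - x_art, R_xc)
        R_xc = np.where(ven, x_c - x_ven, R_xc)

        parts = [R_pt, R_pc, R_xt, R_xc]
        if prm.has_receptors:
            parts.append(V * ts.tissue_fraction
                         * ((C_RL - C_RL_old) / dt - bind))
        return np.concatenate(parts)

    # -- scaling -------------------------------------------------------

    def _row_scales(self, dt: float) -> np.ndarray:
        prm = self.params
        ts, cp, tr = prm.tissue, prm.capillary, prm.transfer
        V = self.mesh.cell_volumes
        p_scale = 1e3
        x_scale = 1e-6
        if self._bcs is not None:
            x_scale = max(abs(self._bcs[2]), abs(self._bcs[3]), 1e-12)
        et_rho = ts.tissue_fraction * ts.molar_density
        ec_rho = cp.volume_fraction * cp.molar_density
        trans = tr.hydraulic_conductivity * tr.surface_density \
            * tr.molar_density
        s_pt = (et_rho * self._Tsum_t + V * trans) * p_scale
        if prm.has_lymphatics:
            s_pt = s_pt + V * (ts.lymph_conductivity
                               * ts.lymph_surface_density
                               * ts.molar_density) * p_scale
        s_pc = (ec_rho * self._Tsum_c + V * trans) * p_scale
        flow_t = self._Tsum_t * p_scale
        flow_c = self._Tsum_c * p_scale
        kk = tr.diffusive_permeability * tr.surface_density * tr.molar_density
        s_xt = ((V / dt) * ts.tissue_fraction * ts.porosity * ts.molar_density
                + et_rho * flow_t + self._Dsum_t + V * kk) * x_scale
        s_xc = ((V / dt) * ec_rho + ec_rho * flow_c + self._Dsum_c
                + V * kk + V * ec_rho * prm.decay_rate) * x_scale
        # Dirichlet rows carry raw (value - bc) residuals
        s_pc = np.where(self.dirichlet, p_scale, s_pc)
        s_xc = np.where(self.dirichlet, x_scale, s_xc)
        parts = [s_pt, s_pc, s_xt, s_xc]
        if prm.has_receptors:
            C0 = ts.receptor_concentration
            parts.append(V * ts.tissue_fraction * C0
                         * (1.0 / dt + ts.k_off
                            + ts.k_on * x_scale * ts.molar_density))
        return np.concatenate(parts)

    def _var_scales(self) -> np.ndarray:
        x_scale = 1e-6
        if self._bcs is not None:
            x_scale = max(abs(self._bcs[2]), abs(self._bcs[3]), 1e-12)
        scales = [1e3, 1e3, x_scale, x_scale]
        if self.params.has_receptors:
            scales.append(max(self.params.tissue.receptor_concentration,
                              1e-30))
        return np.repeat(scales, self.n)

    # -- Jacobian ------------------------------------------------------

    def _build_jacobian(self, u: np.ndarray, u_old: np.ndarray, dt: float,
                        upwind_p) -> None:
        """Colored forward-difference Jacobian, factorized with row/column
        equilibration.  Upwind directions are frozen (``upwind_p``), so the
        differenced residual is smooth."""
        n, nvar = self.n, self.nvar
        N = n * nvar
        r0 = self.residual(u, u_old, dt, upwind_p)
        var_scale = self._var_scales()
        rows_of_cell = [
            np.array([v * n + k for v in range(nvar)], dtype=int)
            for k in range(n)
        ]
        affected = [
            np.concatenate([rows_of_cell[m] for m in self._neighbors[k]])
            for k in range(n)
        ]
        rows, cols, vals = [], [], []
        for cells in self._colors:
            for v in range(nvar):
                up = u.copy()
                h = np.empty(len(cells))
                for a, k in enumerate(cells):
                    idx = v * n + k
                    h[a] = 1e-6 * var_scale[idx] + 1e-9 * abs(u[idx])
                    up[idx] += h[a]
                r1 = self.residual(up, u_old, dt, upwind_p)
                dr = r1 - r0
                for a, k in enumerate(cells):
                    rr = affected[k]
                    vv = dr[rr] / h[a]
                    nz = vv != 0.0
                    rows.append(rr[nz])
                    cols.append(np.full(nz.sum(), v * n + k, dtype=int))
                    vals.append(vv[nz])
        J = sp.csc_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(N, N))
        row_scale = self._row_scales(dt)
        Dr = sp.diags(1.0 / row_scale)
        Dc = sp.diags(var_scale)
        self._lu = spla.splu((Dr @ J @ Dc).tocsc())
        self._row_scale = row_scale
        self._col_scale = var_scale
        self._jac_dt = dt

    def _newton(self, u_old: np.ndarray, dt: float) -> np.ndarray:
        """Newton iteration with per-sweep frozen upwind directions.

        Each outer sweep freezes the upwind switch at the current iterate's
        pressures and solves the (smooth) frozen problem with Newton; the
        sweep repeats if the converged state implies different directions.
        The factorized Jacobian is reused across calls (modified Newton)
        and rebuilt on stalling.
        """
        u = u_old.copy()
        scales = self._row_scales(dt)
        n = self.n
        if np.max(np.abs(self.residual(u, u_old, dt)) / scales) \
                <= self.newton_tol:
            return u
        for _sweep in range(4):
            upwind_p = (u[0:n].copy(), u[n:2 * n].copy())
            u = self._newton_frozen(u, u_old, dt, scales, upwind_p)
            # self-consistency: directions at the converged state
            norm_true = np.max(np.abs(self.residual(u, u_old, dt)) / scales)
            if norm_true <= self.newton_tol:
                return u
        raise NewtonError(
            f"upwind directions failed to settle (residual {norm_true:.3e})")

    def _newton_frozen(self, u, u_old, dt, scales, upwind_p,
                       max_builds: int = 6):
        """Newton on the frozen-direction problem, reusing the cached
        factorized Jacobian and refreshing it whenever progress stalls."""
        r = self.residual(u, u_old, dt, upwind_p)
        norm = np.max(np.abs(r) / scales)
        if norm <= self.newton_tol:
            return u
        builds = 0
        just_built = False
        if self._lu is None or self._jac_dt != dt:
            self._build_jacobian(u, u_old, dt, upwind_p)
            builds += 1
            just_built = True
        for _it in range(self.max_newton_iter):
            du = self._col_scale * self._lu.solve(r / self._row_scale)
            step = 1.0
            accepted = False
            for _ in range(6):
                u_try = u - step * du
                try:
                    r_try = self.residual(u_try, u_old, dt, upwind_p)
                except ValueError:
                    step *= 0.5
                    continue
                norm_try = np.max(np.abs(r_try) / scales)
                if norm_try < norm or norm_try <= self.newton_tol:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                if just_built or builds >= max_builds:
                    raise NewtonError(
                        f"line search stalled at residual {norm:.3e}")
                self._build_jacobian(u, u_old, dt, upwind_p)
                builds += 1
                just_built = True
                continue
            slow = norm_try > 0.2 * norm
            u, r, norm = u_try, r_try, norm_try
            if norm <= self.newton_tol:
                return u
            if slow and builds < max_builds:
                self._build_jacobian(u, u_old, dt, upwind_p)
                builds += 1
                just_built = True
            else:
                just_built = False
        raise NewtonError(
            f"no convergence after {self.max_newton_iter} iterations "
            f"(residual {norm:.3e})")

    def step_implicit(self, state: DCMState, dt: float,
                      _depth: int = 0) -> DCMState:
        """Advance one implicit-Euler step; halve dt on Newton failure."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        u_old = self.pack(state)
        try:
            u = self._newton(u_old, dt)
        except NewtonError:
            if _depth >= self.max_dt_halvings:
                raise
            half = self.step_implicit(state, dt / 2.0, _depth + 1)
            return self.step_implicit(half, dt / 2.0, _depth + 1)
        new = self.unpack(u, time=state.time + dt)
        return new

    def step_accounted(
        self, state: DCMState, dt: float, n_substeps: int = 1,
        _depth: int = 0,
    ) -> tuple[DCMState, dict[str, float]]:
        """Advance over ``dt`` and integrate the exchange/sink ledger.

        Performs ``n_substeps`` implicit steps (more if Newton forces dt
        halving), evaluating the transfer rates at each substep's end state
        (their implicit-Euler values), so the returned ledger is discretely
        exact: ``q_x_moles`` equals the drug the tissue continuum received
        from the blood over ``dt``.  Rates in the ledger are averages over
        ``dt``.
        """
        totals = {k: 0.0 for k in (
            "q_x_moles", "q_mass_kg", "lymph_drug_moles", "lymph_fluid_kg",
            "boundary_drug_moles")}
        sub = dt / n_substeps
        for _ in range(n_substeps):
            state, t = self._substep_accounted(state, sub, _depth)
            for k in totals:
                totals[k] += t[k]
        totals["q_x"] = totals["q_x_moles"] / dt
        totals["q_mass"] = totals["q_mass_kg"] / dt
        return state, totals

    def _substep_accounted(self, state, dt, depth):
        u_old = self.pack(state)
        try:
            u = self._newton(u_old, dt)
        except NewtonError:
            if depth >= self.max_dt_halvings:
                raise
            s1, t1 = self._substep_accounted(state, dt / 2.0, depth + 1)
            s2, t2 = self._substep_accounted(s1, dt / 2.0, depth + 1)
            return s2, {k: t1[k] + t2[k] for k in t1}
        new = self.unpack(u, time=state.time + dt)
        r = self.exchange_rates(new)
        ts = self.params.tissue
        totals = {
            "q_x_moles": r["q_x"] * dt,
            "q_mass_kg": r["q_mass"] * dt,
            "lymph_drug_moles": r["lymph_drug"] * dt,
            "lymph_fluid_kg": r["lymph_fluid"] * dt
            * ts.mass_density / ts.molar_density,
            "boundary_drug_moles": r["boundary_drug_outflow"] * dt,
        }
        return new, totals

    # -- derived quantities -------------------------------------------

    def exchange_rates(self, state: DCMState) -> dict[str, float]:
        """Volume-integrated transfer and sink rates at the given state.

        ``q_mass`` [kg/s] and ``q_x`` [mol/s] are the fluid and drug leaving
        the blood compartment (capillary continuum) into the tissue: the
        sink terms fed back to the vascular graph.  Lymphatic, boundary and
        binding rates support the global drug audit.
        """
        prm = self.params
        ts = prm.tissue
        V = self.mesh.cell_volumes
        _, q_v, J_v, q_x = self._transfer_terms(
            state.p_t, state.p_c, state.x_t, state.x_c)
        out = {
            "q_mass": float(np.sum(J_v * V) * prm.transfer.mass_density),
            "q_x": float(np.sum(q_x * V)),
        }
        if prm.has_lymphatics:
            ly_f, ly_x = lymphatic_sinks(
                state.p_t, state.x_t, ts.lymph_conductivity,
                ts.lymph_surface_density, ts.lymph_pressure,
                ts.molar_density, ts.lymph_clamped)
            out["lymph_fluid"] = float(np.sum(ly_f * V))
            out["lymph_drug"] = float(np.sum(ly_x * V))
        else:
            out["lymph_fluid"] = 0.0
            out["lymph_drug"] = 0.0
        # advective drug outflow through the outer tissue boundary
        dp_b = state.p_t[self.mesh.bface_cell] - ts.boundary_pressure
        Fb = self.Tb_t * dp_b
        xb = state.x_t[self.mesh.bface_cell]
        out["boundary_drug_outflow"] = float(
            ts.tissue_fraction * ts.molar_density
            * np.sum(np.where(dp_b >= 0.0, Fb * xb, 0.0)))
        return out

    def inventories(self, state: DCMState) -> dict[str, float]:
        """Total drug moles per compartment."""
        prm = self.params
        ts, cp = prm.tissue, prm.capillary
        V = self.mesh.cell_volumes
        inv = {
            "tissue": float(np.sum(
                V * ts.tissue_fraction * ts.porosity * ts.molar_density
                * state.x_t)),
            "capillary": float(np.sum(
                V * cp.volume_fraction * cp.molar_density * state.x_c)),
        }
        inv["bound"] = (
            float(np.sum(V * ts.tissue_fraction * state.C_RL))
            if state.C_RL is not None else 0.0)
        return inv

    def effective_resistance(self) -> float:
        """Capillary-bed flow resistance between the two caps [Pa s/m^3].

        Solves the capillary continuum's flow problem alone with a unit
        pressure difference across the caps; ``R_eff = dp / Q``.
        """
        n = self.n
        art, ven = self.mesh.arterial_cells, self.mesh.venous_cells
        i, j = self._i, self._j
        rows, cols, vals = [], [], []
        b = np.zeros(n)
        free = ~(art | ven)
        for a_, b_, T in zip(i, j, self.T_c):
            for me, other in ((a_, b_), (b_, a_)):
                if free[me]:
                    rows += [me, me]
                    cols += [me, other]
                    vals += [T, -T]
        diri = np.flatnonzero(~free)
        rows += list(diri)
        cols += list(diri)
        vals += [1.0] * len(diri)
        b[art] = 1.0
        b[ven] = 0.0
        A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        p = spla.spsolve(A, b)
        F = self.T_c * (p[i] - p[j])
        Q = float(np.sum(F[art[i] & ~art[j]]) - np.sum(F[art[j] & ~art[i]]))
        if Q <= 0.0:
            raise ValueError(
                "capillary continuum has no conductance between the caps")
        return 1.0 / Q
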