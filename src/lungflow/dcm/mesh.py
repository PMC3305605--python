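"""Structured spherical finite-volume mesh for the alveolus model.

The healthy model domain is a spherical shell (alveolar lumen inside,
tissue outside), the tumor domain a full sphere.  Cells are spherical
"bricks" on a structured (r, theta, phi) grid with exact volumes and face
areas; phi is periodic, theta faces at the poles have zero area and so act
as natural no-flow boundaries.  The phi grid is offset by half a cell so
that cell centers lie exactly on the -x (arterial) and +x (venous) axes:
the arterial inflow and venous drainage attach as angular caps around those
axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContinuumMesh", "build_dcm_mesh"]

# face types
RADIAL, THETA, PHI = 0, 1, 2


@dataclass
class ContinuumMesh:
    kind: str  # "shell" or "sphere"
    R_in: float
    R_out: float
    resolution: tuple[int, int, int]  # (n_r, n_theta, n_phi)
    cap_half_angle: float  # degrees

    n_cells: int = 0
    cell_volumes: np.ndarray = field(default=None, repr=False)
    cell_centroids: np.ndarray = field(default=None, repr=False)  # cartesian
    cell_r: np.ndarray = field(default=None, repr=False)
    cell_theta: np.ndarray = field(default=None, repr=False)
    cell_phi: np.ndarray = field(default=None, repr=False)

    # interior faces
    face_cells: np.ndarray = field(default=None, repr=False)  # (nf, 2)
    face_area: np.ndarray = field(default=None, repr=False)
    face_dist: np.ndarray = field(default=None, repr=False)
    face_type: np.ndarray = field(default=None, repr=False)

    # outer boundary faces (r = R_out)
    bface_cell: np.ndarray = field(default=None, repr=False)
    bface_area: np.ndarray = field(default=None, repr=False)
    bface_dist: np.ndarray = field(default=None, repr=False)
    bface_patch: list[str] = field(default_factory=list, repr=False)

    # angular-cap cell masks (all radial layers)
    arterial_cells: np.ndarray = field(default=None, repr=False)  # bool
    venous_cells: np.ndarray = field(default=None, repr=False)

    def cell_index(self, ir: int, itheta: int, iphi: int) -> int:
        _, nt, np_ = self.resolution
        return (ir * nt + itheta) * np_ + iphi

    @property
    def domain_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * (self.R_out**3 - self.R_in**3)

    def cell_corners(self) -> tuple[np.ndarray, np.ndarray]:
        """(points, hexahedron connectivity) for VTK export."""
        n_r, nt, np_ = self.resolution
        r_edges = np.linspace(self.R_in, self.R_out, n_r + 1)
        t_edges = np.linspace(0.0, math.pi, nt + 1)
        p_edges = (np.arange(np_ + 1) - 0.5) * (2.0 * math.pi / np_)
        pts = []
        conn = []
        index: dict[tuple[int, int, int], int] = {}

        def pid(i, j, k):
            key = (i, j, k)
            if key not in index:
                r, t, p = r_edges[i], t_edges[j], p_edges[k]
                index[key] = len(pts)
                pts.append((
                    r * math.sin(t) * math.cos(p),
                    r * math.sin(t) * math.sin(p),
                    r * math.cos(t),
                ))
            return index[key]

        for ir in range(n_r):
            for it in range(nt):
                for ip in range(np_):
                    c = [
                        pid(ir, it, ip), pid(ir, it, ip + 1),
                        pid(ir, it + 1, ip + 1), pid(ir, it + 1, ip),
                        pid(ir + 1, it, ip), pid(ir + 1, it, ip + 1),
                        pid(ir + 1, it + 1, ip + 1), pid(ir + 1, it + 1, ip),
                    ]
                    conn.append(c)
        return np.array(pts), np.array(conn, dtype=int)


def build_dcm_mesh(
    kind: str,
    R_in: float,
    R_out: float,
    resolution: tuple[int, int, int] = (3, 4, 8),
    cap_half_angle: float = 30.0,
) -> ContinuumMesh:
    """Build the structured spherical mesh of the alveolus model.

    ``kind='shell'`` needs ``0 < R_in < R_out``; ``kind='sphere'`` needs
    ``R_in = 0``.  Cells whose centroid direction lies within
    ``cap_half_angle`` degrees of the -x (+x) axis form the arterial
    (venous) cap where the capillary continuum receives Dirichlet values
    from the adjacent graph nodes; if the angular resolution is too coarse
    for any centroid to fall inside the cap, the closest ring of cells is
    used instead.  Blood cannot enter or leave through any other boundary.
    """
    if kind not in ("shell", "sphere"):
        raise ValueError(f"unknown mesh kind {kind!r}")
    if kind == "shell" and not 0.0 < R_in < R_out:
        raise ValueError("shell requires 0 < R_in < R_out")
    if kind == "sphere":
        if R_in != 0.0:
            raise ValueError("sphere requires R_in = 0")
    n_r, nt, np_ = resolution
    if n_r < 2 or nt < 2 or np_ < 4:
        raise ValueError("resolution must be at least (2, 2, 4)")
    if not 0.0 < cap_half_angle < 90.0:
        raise ValueError("cap_half_angle must lie in (0, 90) degrees")

    mesh = ContinuumMesh(kind=kind, R_in=R_in, R_out=R_out,
                         resolution=tuple(resolution),
                         cap_half_angle=cap_half_angle)
    r_e = np.linspace(R_in, R_out, n_r + 1)
    t_e = np.linspace(0.0, math.pi, nt + 1)
    dphi = 2.0 * math.pi / np_
    p_e = (np.arange(np_ + 1) - 0.5) * dphi

    r_c = 0.5 * (r_e[:-1] + r_e[1:])
    t_c = 0.5 * (t_e[:-1] + t_e[1:])
    p_c = 0.5 * (p_e[:-1] + p_e[1:])

    n_cells = n_r * nt * np_
    mesh.n_cells = n_cells

    cell_r = np.empty(n_cells)
    cell_t = np.empty(n_cells)
    cell_p = np.empty(n_cells)
    vol = np.empty(n_cells)
    dcos = np.cos(t_e[:-1]) - np.cos(t_e[1:])  # positive
    for ir in range(n_r):
        r3 = (r_e[ir + 1] ** 3 - r_e[ir] ** 3) / 3.0
        for it in range(nt):
            for ip in range(np_):
                c = (ir * nt + it) * np_ + ip
                cell_r[c] = r_c[ir]
                cell_t[c] = t_c[it]
                cell_p[c] = p_c[ip]
                vol[c] = r3 * dcos[it] * dphi
    mesh.cell_volumes = vol
    mesh.cell_r, mesh.cell_theta, mesh.cell_phi = cell_r, cell_t, cell_p
    sin_t = np.sin(cell_t)
    mesh.cell_centroids = np.column_stack([
        cell_r * sin_t * np.cos(cell_p),
        cell_r * sin_t * np.sin(cell_p),
        cell_r * np.cos(cell_t),
    ])

    fc, fa, fd, ft = [], [], [], []

    def cidx(ir, it, ip):
        return (ir * nt + it) * np_ + (ip % np_)

    # radial faces between layers ir and ir+1
    for ir in range(n_r - 1):
        r = r_e[ir + 1]
        for it in range(nt):
            area_base = r * r * dcos[it] * dphi
            for ip in range(np_):
                fc.append((cidx(ir, it, ip), cidx(ir + 1, it, ip)))
                fa.append(area_base)
                fd.append(r_c[ir + 1] - r_c[ir])
                ft.append(RADIAL)
    # theta faces (skip poles: zero area anyway)
    for ir in range(n_r):
        r2 = (r_e[ir + 1] ** 2 - r_e[ir] ** 2) / 2.0
        for it in range(nt - 1):
            theta = t_e[it + 1]
            area = math.sin(theta) * r2 * dphi
            if area <= 0.0:
                continue
            for ip in range(np_):
                fc.append((cidx(ir, it, ip), cidx(ir, it + 1, ip)))
                fa.append(area)
                fd.append(r_c[ir] * (t_c[it + 1] - t_c[it]))
                ft.append(THETA)
    # phi faces (periodic)
    for ir in range(n_r):
        r2 = (r_e[ir + 1] ** 2 - r_e[ir] ** 2) / 2.0
        dtheta = t_e[1] - t_e[0]
        for it in range(nt):
            area = r2 * dtheta
            dist = r_c[ir] * math.sin(t_c[it]) * dphi
            for ip in range(np_):
                fc.append((cidx(ir, it, ip), cidx(ir, it, ip + 1)))
                fa.append(area)
                fd.append(dist)
                ft.append(PHI)

    mesh.face_cells = np.array(fc, dtype=int)
    mesh.face_area = np.array(fa)
    mesh.face_dist = np.array(fd)
    mesh.face_type = np.array(ft, dtype=int)

    # outer boundary faces at r = R_out
    bc, ba, bd, bp = [], [], [], []
    cap = math.radians(cap_half_angle)
    for it in range(nt):
        area_base = R_out * R_out * dcos[it] * dphi
        for ip in range(np_):
            c = cidx(n_r - 1, it, ip)
            bc.append(c)
            ba.append(area_base)
            bd.append(R_out - r_c[n_r - 1])
            # face-center direction vs +-x axis
            ct = math.sin(t_c[it]) * math.cos(p_c[ip])
            if math.acos(max(-1.0, min(1.0, -ct))) <= cap:
                bp.append("arterial_cap")
            elif math.acos(max(-1.0, min(1.0, ct))) <= cap:
                bp.append("venous_cap")
            else:
                bp.append("outer")
    mesh.bface_cell = np.array(bc, dtype=int)
    mesh.bface_area = np.array(ba)
    mesh.bface_dist = np.array(bd)
    mesh.bface_patch = bp

    # angular-cap cell masks over all radial layers
    with np.errstate(invalid="ignore"):
        dirx = np.where(cell_r > 0, mesh.cell_centroids[:, 0] / cell_r, 0.0)
    ang_art = np.arccos(np.clip(-dirx, -1.0, 1.0))
    ang_ven = np.arccos(np.clip(dirx, -1.0, 1.0))
    art = ang_art <= cap + 1e-12
    ven = ang_ven <= cap + 1e-12
    if not art.any():
        art = ang_art <= ang_art.min() + 1e-9
    if not ven.any():
        ven = ang_ven <= ang_ven.min() + 1e-9
    # a cell cannot be on both caps
    both = art & ven
    if both.any():
        art &= ~both
        ven &= ~both
    mesh.arterial_cells = art
    mesh.venous_cells = ven
    return mesh
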