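"""Spherical-head EEG forward model.

The head is three concentric homogeneous spheres (brain, skull, scalp).  The
surface potential of a current dipole inside the innermost sphere is obtained
from the Legendre-series solution of the Laplace problem: for each harmonic
order n the radial two-point boundary-value problem across the shells is
solved exactly (continuity of potential and radial current at each interface,
zero current through the scalp surface), giving the transfer coefficient from
the dipole's n-th multipole term to the scalp potential.

The source space is a uniform grid restricted to a spherical cortical shell,
parcellated by angular sectors into the six macro-regions used throughout the
analysis (frontal, central, parietal, occipital, temporal, limbic).  A loader
for externally supplied leadfield/parcellation CSV files is provided so that
realistic head models can be substituted when available.

Axes: +x right, +y anterior, +z superior, origin at the sphere centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import resolve_montage

ROI_NAMES = ("frontal", "central", "parietal", "occipital", "temporal",
             "limbic")


@dataclass
class HeadModel:
    """Three concentric spheres with radii in mm (scalp > skull > brain) and
    conductivities in S/m (brain, skull, scalp)."""
    radii_mm: tuple = (92.0, 85.0, 80.0)
    conductivities: tuple = (0.33, 0.0042, 0.33)
    montage: str = "10-10-30"

    def __post_init__(self):
        r_scalp, r_skull, r_brain = self.radii_mm
        if not (r_scalp > r_skull > r_brain > 0):
            raise ValueError("radii must satisfy scalp > skull > brain > 0")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        self.channel_labels, self.electrode_dirs = resolve_montage(self.montage)


@dataclass
class SourceSpace:
    coords_mm: np.ndarray          # n_voxels x 3
    roi_labels: np.ndarray         # n_voxels, strings from ROI_NAMES
    spacing_mm: float

    def __post_init__(self):
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        self.roi_labels = np.asarray(self.roi_labels, dtype=object)
        if self.coords_mm.shape[0] != self.roi_labels.shape[0]:
            raise ValueError("coords and roi_labels length mismatch")
        unknown = set(self.roi_labels) - set(ROI_NAMES)
        if unknown:
            raise ValueError(f"unknown ROI labels: {sorted(unknown)}")
        for roi in ROI_NAMES:
            if not (self.roi_labels == roi).any():
                raise ValueError(f"parcellation leaves ROI {roi!r} empty")

    @property
    def n_voxels(self) -> int:
        return self.coords_mm.shape[0]

    def roi_mask(self, roi: str) -> np.ndarray:
        return self.roi_labels == roi


@dataclass
class LeadField:
    """Gain matrix channels x (voxels * 3 orientations), average-referenced.

    Column ordering is voxel-major: (v0,x), (v0,y), (v0,z), (v1,x), ...
    """
    gain: np.ndarray
    channel_labels: tuple
    n_voxels: int
    average_referenced: bool = True

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.shape != (len(self.channel_labels), 3 * self.n_voxels):
            raise ValueError("gain shape inconsistent with labels/voxels")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("non-finite leadfield")

    @property
    def blocks(self) -> np.ndarray:
        """Per-voxel gain blocks, shape (n_voxels, channels, 3)."""
        m = self.gain.shape[0]
        return self.gain.reshape(m, self.n_voxels, 3).transpose(1, 0, 2)


def sector_parcellation(coords_mm: np.ndarray) -> np.ndarray:
    """Assign the six macro-ROIs by angular sector.

    Geometric stand-in for the Brodmann-area groupings: occipital is the
    posterior-inferior sector, temporal the lateral-inferior sectors, limbic a
    medial ring, and the superior cap splits anterior-posterior into frontal,
    central and parietal.
    """
    u = coords_mm / np.linalg.norm(coords_mm, axis=1, keepdims=True)
    ux, uy, uz = u.T
    labels = np.empty(len(u), dtype=object)
    occ = (uy <= -0.55) & (uz <= 0.45)
    tmp = ~occ & (np.abs(ux) >= 0.55) & (uz <= 0.35)
    lim = ~occ & ~tmp & (np.abs(ux) <= 0.25) & (uz <= 0.5)
    rest = ~(occ | tmp | lim)
    labels[occ] = "occipital"
    labels[tmp] = "temporal"
    labels[lim] = "limbic"
    labels[rest & (uy >= 0.2)] = "frontal"
    labels[rest & (uy <= -0.2)] = "parietal"
    labels[rest & (uy > -0.2) & (uy < 0.2)] = "central"
    return labels


def build_source_space(spacing_mm: float = 5.0,
                       head: HeadModel | None = None,
                       shell_fractions: tuple = (0.74, 0.94),
                       parcellation_file=None) -> SourceSpace:
    """Uniform grid in a spherical cortical shell inside the brain sphere.

    ``shell_fractions`` are the inner/outer shell radii as fractions of the
    brain radius.  A ``parcellation_file`` (CSV with x_mm,y_mm,z_mm,roi)
    overrides both the grid and the sector labels.
    """
    if parcellation_file is not None:
        tab = pd.read_csv(parcellation_file)
        need = {"x_mm", "y_mm", "z_mm", "roi"}
        if not need <= set(tab.columns):
            raise ValueError(f"parcellation file must have columns {sorted(need)}")
        return SourceSpace(tab[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
                           tab["roi"].to_numpy(object), spacing_mm)
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    head = head or HeadModel()
    r_brain = head.radii_mm[2]
    r_in, r_out = (f * r_brain for f in shell_fractions)
    half = int(np.floor(r_out / spacing_mm))
    ax = np.arange(-half, half + 1) * spacing_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.linalg.norm(pts, axis=1)
    pts = pts[(r >= r_in) & (r <= r_out)]
    if len(pts) < 6:
        raise ValueError(f"spacing {spacing_mm} mm yields only {len(pts)} voxels")
    return SourceSpace(pts, sector_parcellation(pts), spacing_mm)


def _shell_transfer_coefficients(head: HeadModel, n_max: int) -> np.ndarray:
    """Transfer coefficient u_n: scalp-surface potential per unit coefficient
    of the r^-(n+1) source term, for n = 1..n_max.  Radii normalized by the
    scalp radius."""
    R = head.radii_mm[0]
    r1 = head.radii_mm[2] / R      # brain / inner skull
    r2 = head.radii_mm[1] / R      # outer skull
    s1, s2, s3 = head.conductivities
    u = np.empty(n_max + 1)
    u[0] = 0.0
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3 ; source term: 1 * r^-(n+1) in layer 1
        a = np.zeros((5, 5))
        b = np.zeros(5)
        p1, q1 = r1 ** n, r1 ** -(n + 1)
        p2, q2 = r2 ** n, r2 ** -(n + 1)
        dp1, dq1 = n * r1 ** (n - 1), -(n + 1) * r1 ** -(n + 2)
        dp2, dq2 = n * r2 ** (n - 1), -(n + 1) * r2 ** -(n + 2)
        # potential continuity at r1: A1 p1 + q1 = A2 p1 + B2 q1
        a[0] = [p1, -p1, -q1, 0, 0]; b[0] = -q1
        # current continuity at r1
        a[1] = [s1 * dp1, -s2 * dp1, -s2 * dq1, 0, 0]; b[1] = -s1 * dq1
        # potential continuity at r2
        a[2] = [0, p2, q2, -p2, -q2]; b[2] = 0.0
        # current continuity at r2
        a[3] = [0, s2 * dp2, s2 * dq2, -s3 * dp2, -s3 * dq2]; b[3] = 0.0
        # insulating outer boundary at r = 1
        a[4] = [0, 0, 0, n, -(n + 1)]; b[4] = 0.0
        A1, A2, B2, A3, B3 = np.linalg.solve(a, b)
        u[n] = A3 + B3             # potential at r = 1
    return u


def compute_leadfield(space: SourceSpace, head: HeadModel | None = None,
                      n_terms: int = 80, tail_tol: float = 1e-3) -> LeadField:
    """Three-sphere Legendre-series leadfield, average-referenced.

    Raises if any voxel lies outside the brain compartment or if the series
    tail at the largest voxel radius exceeds ``tail_tol`` of the total.
    """
    head = head or HeadModel()
    R = head.radii_mm[0]
    r_brain = head.radii_mm[2]
    b_mm = np.linalg.norm(space.coords_mm, axis=1)
    if np.any(b_mm >= r_brain):
        raise ValueError("voxel outside the brain compartment")
    if np.any(b_mm < 1e-9):
        raise ValueError("voxel at the sphere centre has undefined orientation "
                         "decomposition; exclude the origin")
    u_dirs = space.coords_mm / b_mm[:, None]            # V x 3
    e_dirs = head.electrode_dirs                        # E x 3
    E, V = len(e_dirs), space.n_voxels
    t = b_mm / R                                        # normalized radii

    un = _shell_transfer_coefficients(head, n_terms)
    # geometric tail estimate at the largest source radius
    tmax = t.max()
    tail = abs(un[n_terms]) * tmax ** (n_terms - 1) * n_terms
    total = sum(abs(un[n]) * tmax ** (n - 1) * n for n in range(1, n_terms + 1))
    if tail > tail_tol * total:
        raise ValueError(
            f"series not converged at n_terms={n_terms} "
            f"(tail fraction {tail / total:.2e}); increase n_terms")

    c = e_dirs @ u_dirs.T                               # E x V, cos(gamma)
    Pm1 = np.ones_like(c)                               # P_0
    P = c.copy()                                        # P_1
    dPm1 = np.zeros_like(c)                             # P'_0
    dP = np.ones_like(c)                                # P'_1
    tn = np.ones(V)                                     # t^(n-1), n=1
    Krad = np.zeros((E, V))
    Ktan = np.zeros((E, V))
    for n in range(1, n_terms + 1):
        w = un[n] * tn                                  # V
        Krad += (n * w) * P
        Ktan += w * dP
        if n < n_terms:
            Pp1 = ((2 * n + 1) * c * P - n * Pm1) / (n + 1)
            dPp1 = dPm1 + (2 * n + 1) * P
            Pm1, P = P, Pp1
            dPm1, dP = dP, dPp1
            tn = tn * t

    # assemble gains: g = Krad (o.uv) + Ktan (o.ue - c (o.uv)), per unit
    # dipole moment, scaled by 1/(4 pi sigma_brain R^2)
    scale = 1.0 / (4.0 * np.pi * head.conductivities[0] * (R * 1e-3) ** 2)
    gain = np.empty((E, V, 3))
    for k in range(3):
        ov = u_dirs[:, k][None, :]                      # 1 x V
        oe = e_dirs[:, k][:, None]                      # E x 1
        gain[:, :, k] = scale * (Krad * ov + Ktan * (oe - c * ov))
    gain = gain.reshape(E, 3 * V)
    if not gain.any():
        raise ValueError("degenerate all-zero leadfield")
    gain = gain - gain.mean(axis=0, keepdims=True)
    return LeadField(gain, tuple(head.channel_labels), V, True)


# ---------------------------------------------------------------------------
# exchange format

def save_leadfield(path_prefix, lf: LeadField, space: SourceSpace) -> None:
    """Write the gain matrix and voxel table as a documented CSV pair."""
    cols = [f"v{v}_{o}" for v in range(lf.n_voxels) for o in "xyz"]
    pd.DataFrame(lf.gain, index=list(lf.channel_labels), columns=cols)\
        .rename_axis("channel").to_csv(f"{path_prefix}_gain.csv")
    pd.DataFrame({"x_mm": space.coords_mm[:, 0],
                  "y_mm": space.coords_mm[:, 1],
                  "z_mm": space.coords_mm[:, 2],
                  "roi": space.roi_labels}).to_csv(
        f"{path_prefix}_voxels.csv", index=False)


def load_leadfield(path_prefix) -> tuple[LeadField, SourceSpace]:
    gain = pd.read_csv(f"{path_prefix}_gain.csv", index_col="channel")
    vox = pd.read_csv(f"{path_prefix}_voxels.csv")
    space = SourceSpace(vox[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
                        vox["roi"].to_numpy(object), spacing_mm=np.nan)
    g = gain.to_numpy(float)
    g = g - g.mean(axis=0, keepdims=True)
    return (LeadField(g, tuple(gain.index), space.n_voxels, True), space)
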