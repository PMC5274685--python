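"""Model-independent trabecular morphometry on binary 3D volumes.

Implements the standard panel used to characterize cancellous bone
microarchitecture from segmented micro-CT volumes:

* BV/TV   - mineralized bone volume fraction (voxel counting);
* Tb.Th   - mean trabecular thickness: the volume-weighted mean
            diameter of maximal inscribed spheres in the bone phase;
* Tb.Sp   - trabecular separation: the same measure on the marrow
            (background) phase;
* Tb.N    - trabecular number; default model-independent form
            1 / (Tb.Th + Tb.Sp), optionally the plate-model form
            (BV/TV) / Tb.Th;
* Conn.D  - connectivity density: first Betti number of the bone
            network per unit total volume, from the voxel Euler
            characteristic with 26-connected foreground / 6-connected
            background;
* SMI     - structure model index 6*V*S'/S^2, with the surface area S
            from a triangulated isosurface and its derivative S' under
            surface offset estimated by central difference at +/- half
            a voxel (plates ~ 0, rods ~ 3, spheres ~ 4).

Local thickness follows the maximal-inscribed-sphere definition: the
Euclidean distance transform gives each voxel's distance to the phase
boundary; spheres are painted in decreasing radius order so every voxel
receives the diameter of the largest sphere that contains it.  Radii are
taken as (EDT - 1/2) voxel so that a slab of t voxels has thickness
exactly t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area


@dataclass
class TrabecularVolume:
    """Binary volume (True = mineralized bone) at isotropic voxel size."""

    voxels: np.ndarray
    voxel_size_um: float = 12.0
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if self.mask is not None and self.mask.shape != self.voxels.shape:
            raise ValueError("mask shape mismatch")

    @property
    def foreground(self) -> np.ndarray:
        if self.mask is None:
            return self.voxels
        return self.voxels & self.mask

    @property
    def voi_voxels(self) -> int:
        return int(self.voxels.size if self.mask is None else self.mask.sum())

    @property
    def total_volume_mm3(self) -> float:
        return self.voi_voxels * (self.voxel_size_um * 1e-3) ** 3


@dataclass
class MorphometryResult:
    """The trabecular panel for one volume of interest."""

    bv_tv: float
    tb_n_per_mm: float
    tb_th_mm: float
    tb_sp_mm: float
    conn_d_per_mm3: float
    smi: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "BV_TV": self.bv_tv,
            "Tb_N_per_mm": self.tb_n_per_mm,
            "Tb_Th_mm": self.tb_th_mm,
            "Tb_Sp_mm": self.tb_sp_mm,
            "Conn_D_per_mm3": self.conn_d_per_mm3,
            "SMI": self.smi,
        }


def compute_bvtv(v: TrabecularVolume) -> float:
    """Bone volume fraction: foreground voxels / VOI voxels."""
    if v.voi_voxels == 0:
        raise ValueError("empty VOI")
    return float(v.foreground.sum() / v.voi_voxels)


def local_thickness_map(mask: np.ndarray, radius_bin: float = 0.25) -> np.ndarray:
    """Local thickness (in voxels) of the True phase of *mask*.

    Every True voxel is assigned the diameter of the largest inscribed
    sphere containing it.  Radii from the distance transform are grouped
    into bins of *radius_bin* voxels to bound the number of sphere
    passes; the induced error is below half a bin.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("requested phase is empty")
    dt = ndimage.distance_transform_edt(mask)
    radii = dt[mask]
    bins = np.unique(np.ceil(radii / radius_bin)) * radius_bin
    thickness = np.zeros(mask.shape)
    for b in bins[::-1]:
        sel = (dt > b - radius_bin) & (dt <= b) & mask
        if not sel.any():
            continue
        r = float(dt[sel].max())
        covered = ndimage.distance_transform_edt(~sel) <= r + 1e-9
        paint = mask & covered & (thickness == 0)
        thickness[paint] = 2.0 * (r - 0.5)
    return thickness


def compute_local_thickness(v: TrabecularVolume, phase: str = "foreground") -> float:
    """Volume-weighted mean local thickness of a phase, in mm.

    ``phase="foreground"`` gives Tb.Th, ``"background"`` gives Tb.Sp.
    """
    if phase == "foreground":
        mask = v.foreground
    elif phase == "background":
        mask = ~v.voxels if v.mask is None else (~v.voxels & v.mask)
    else:
        raise ValueError("phase must be 'foreground' or 'background'")
    if not mask.any():
        raise ValueError(f"{phase} phase is empty")
    th = local_thickness_map(mask)
    return float(th[mask].mean() * v.voxel_size_um * 1e-3)


def compute_tbn(v: TrabecularVolume, model: str = "spacing") -> float:
    """Trabecular number in mm^-1.

    ``model="spacing"`` (default): 1 / (Tb.Th + Tb.Sp), the
    model-independent inverse mean spacing between trabecular mid-axes.
    ``model="plate"``: (BV/TV) / Tb.Th, the classic plate-model form.
    """
    tb_th = compute_local_thickness(v, "foreground")
    if model == "plate":
        return compute_bvtv(v) / tb_th
    if model != "spacing":
        raise ValueError("model must be 'spacing' or 'plate'")
    tb_sp = compute_local_thickness(v, "background")
    return 1.0 / (tb_th + tb_sp)


# ---------------------------------------------------------------------------
# topology


def euler_characteristic(mask: np.ndarray) -> int:
    """Euler characteristic of the closed cubical complex of the True
    voxels (the union of closed unit cubes), chi = V - E + F - C.

    Corner- and edge-touching cubes share cells, so this convention
    corresponds to 26-connected foreground with 6-connected background.
    """
    p = np.asarray(mask, dtype=bool)
    if p.ndim != 3:
        raise ValueError("mask must be 3D")
    c = int(p.sum())

    q = np.pad(p, 1)
    vert = np.zeros(tuple(s + 1 for s in p.shape), dtype=bool)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                vert |= q[dz : dz + p.shape[0] + 1, dy : dy + p.shape[1] + 1, dx : dx + p.shape[2] + 1]
    n_v = int(vert.sum())

    n_e = 0
    n_f = 0
    for axis in range(3):
        # edges along `axis`: incident to 4 voxels across the two perpendicular axes
        pad = [(1, 1)] * 3
        pad[axis] = (0, 0)
        r = np.pad(p, pad)
        perp = [a for a in range(3) if a != axis]
        e = np.zeros([p.shape[a] if a == axis else p.shape[a] + 1 for a in range(3)], dtype=bool)
        for d0 in (0, 1):
            for d1 in (0, 1):
                sl = [slice(None)] * 3
                sl[perp[0]] = slice(d0, d0 + p.shape[perp[0]] + 1)
                sl[perp[1]] = slice(d1, d1 + p.shape[perp[1]] + 1)
                e |= r[tuple(sl)]
        n_e += int(e.sum())
        # faces normal to `axis`: incident to 2 voxels along `axis`
        pad = [(0, 0)] * 3
        pad[axis] = (1, 1)
        s = np.pad(p, pad)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, p.shape[axis] + 1)
        hi[axis] = slice(1, p.shape[axis] + 2)
        n_f += int((s[tuple(lo)] | s[tuple(hi)]).sum())

    return n_v - n_e + n_f - c


def betti_numbers(mask: np.ndarray) -> tuple[int, int, int]:
    """(b0, b1, b2) of the voxel complex: components (26-connected),
    independent loops, and enclosed cavities (6-connected background)."""
    mask = np.asarray(mask, dtype=bool)
    _, b0 = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    bg_labels, n_bg = ndimage.label(~mask)  # 6-connectivity
    border = np.zeros(mask.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    outside = np.unique(bg_labels[border & ~mask])
    b2 = n_bg - outside.size
    chi = euler_characteristic(mask)
    b1 = b0 + b2 - chi
    return int(b0), int(b1), int(b2)


def compute_connd(v: TrabecularVolume) -> float:
    """Connectivity density Conn.D = b1 / TV in mm^-3.

    If the foreground is not a single 26-connected component, the
    largest component is analyzed and this is noted via a warning.
    """
    fg = v.foreground
    if not fg.any():
        raise ValueError("empty foreground")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        warnings.warn(
            f"foreground has {n} components; using the largest for Conn.D", stacklevel=2
        )
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    _, b1, _ = betti_numbers(fg)
    return float(b1 / v.total_volume_mm3)


# ---------------------------------------------------------------------------
# structure model index


def _signed_distance(fg: np.ndarray) -> np.ndarray:
    """Signed distance (voxels) to the binary surface, negative inside.

    The half-voxel correction places the surface midway between the
    outermost foreground and innermost background voxel centres, giving
    the field unit gradient across the boundary (the raw EDT difference
    jumps by 2 there)."""
    p = np.pad(fg, 3)
    out = ndimage.distance_transform_edt(~p) - 0.5
    inn = ndimage.distance_transform_edt(p) - 0.5
    return np.where(p, -inn, out)


def _mesh_quantities(dist: np.ndarray, level: float = 0.0) -> tuple[float, float, float]:
    """(area S, enclosed volume V, offset derivative S' = dS/dr) of an
    isosurface mesh.

    V comes from the divergence theorem over the triangles.  S' equals
    the integrated mean curvature of the offset (Steiner) surface,
    2 * integral of H dA, evaluated discretely as the sum of
    edge length x signed dihedral angle over mesh edges.
    """
    verts, faces, _, _ = marching_cubes(dist, level=level)
    area = float(mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)

    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    normals /= norm
    # every (sorted) vertex pair appears in exactly two faces on a closed mesh
    e_orient = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e_face = np.tile(np.arange(len(faces)), 3)
    key = np.sort(e_orient, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key = key[order]
    paired = np.all(key[0::2] == key[1::2], axis=1)
    f_pairs = e_face[order].reshape(-1, 2)[paired]
    ab = e_orient[order][0::2][paired]
    evec = verts[ab[:, 1]] - verts[ab[:, 0]]
    elen = np.linalg.norm(evec, axis=1)
    ok = elen > 0
    evec = evec[ok] / elen[ok, np.newaxis]
    n1 = normals[f_pairs[ok, 0]]
    n2 = normals[f_pairs[ok, 1]]
    theta = np.arctan2(np.einsum("ij,ij->i", np.cross(n1, n2), evec), np.einsum("ij,ij->i", n1, n2))
    s_prime = float(np.sum(elen[ok] * theta))
    return area, vol, s_prime


def compute_smi(v: TrabecularVolume, smoothing_sigma: float = 1.0) -> float:
    """Structure model index SMI = 6 V S' / S^2 (dimensionless).

    S and V are the area and enclosed volume of the triangulated
    zero-level surface of the signed distance field (Gaussian-smoothed
    by *smoothing_sigma* voxels to suppress voxel faceting, which
    otherwise inflates S); S' = dS/dr under a uniform surface offset
    equals twice the integrated mean curvature and is evaluated
    discretely on the mesh edges.  Computed in voxel units (the voxel
    size cancels).  Ideal values: plate 0, cylinder 3, sphere 4;
    concave structures can be negative.
    """
    fg = v.foreground
    if not fg.any():
        raise ValueError("empty foreground")
    touches = (
        fg[0].any() and fg[-1].any()
        and fg[:, 0].any() and fg[:, -1].any()
        and fg[:, :, 0].any() and fg[:, :, -1].any()
    )
    if touches:
        raise ValueError("foreground touches every volume face; surface is unbounded")
    dist = _signed_distance(fg)
    if smoothing_sigma > 0:
        dist = ndimage.gaussian_filter(dist, smoothing_sigma)
    s0, vol, s_prime = _mesh_quantities(dist, 0.0)
    return 6.0 * vol * s_prime / s0**2


def compute_morphometry(v: TrabecularVolume, tbn_model: str = "spacing") -> MorphometryResult:
    """The full panel for one volume."""
    tb_th = compute_local_thickness(v, "foreground")
    tb_sp = compute_local_thickness(v, "background")
    tb_n = compute_bvtv(v) / tb_th if tbn_model == "plate" else 1.0 / (tb_th + tb_sp)
    return MorphometryResult(
        bv_tv=compute_bvtv(v),
        tb_n_per_mm=tb_n,
        tb_th_mm=tb_th,
        tb_sp_mm=tb_sp,
        conn_d_per_mm3=compute_connd(v),
        smi=compute_smi(v),
        metadata={"tbn_model": tbn_model, "voxel_size_um": v.voxel_size_um},
    )
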