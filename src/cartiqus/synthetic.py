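"""Synthetic RF scans, reflector references, trabecular phantoms, cohorts.

Everything downstream (echo detection, acoustic parameters, bone
morphometry, group statistics) is exercised on data produced here, with
the generating truth recorded alongside, so the whole pipeline is
testable without any measured data.

The acoustic forward model is deliberately simple and fully analytic:

* the transducer emits a Gabor pulse (Gaussian-enveloped cosine at the
  centre frequency, envelope width set by the fractional bandwidth);
* each scan line sees two specular echoes - one from the
  saline-cartilage surface at round-trip delay 2*d_i/c_medium, one from
  the cartilage-bone interface delayed by a further 2*h_i/c_cartilage;
* the surface echo amplitude is r_surface * A_ref; the interface echo is
  r_interface * (1 - r_surface^2) * A_ref further reduced by two-way
  linear-with-frequency attenuation in cartilage evaluated at the
  centre frequency (narrowband approximation - the downstream
  parameters are peak-to-peak amplitudes, not spectra);
* white Gaussian noise is added with SD expressed as a fraction of the
  perfect-reflector peak-to-peak amplitude.

Out of scope by design: full wave propagation, sub-resolution scatterer
speckle, and beam diffraction.  Per-line surface distances d_i and local
thicknesses h_i are independent Normal draws; negative draws are redrawn
(and counted), not truncated.

Trabecular phantoms are binary volumes with analytically known
morphometry: parallel plates (BV/TV = t/p exactly when the axial extent
is a whole number of periods), cubic rod lattices (known number of
independent loops), solid blocks, and tori (first Betti number 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cartiqus.morphometry import TrabecularVolume
from cartiqus.rf_processing import RFScan

_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# transducer and pulse model


@dataclass
class TransducerSpec:
    """Pulse-echo transducer model.

    The emitted pulse is g(t) = A exp(-t^2 / (2 sigma_t^2)) cos(2 pi f0 t)
    with sigma_t set so that the -6 dB (half-amplitude) spectral width
    equals ``fractional_bandwidth * center_frequency``.
    """

    center_frequency: float = 50e6
    fractional_bandwidth: float = 0.5
    sampling_rate: float = 400e6
    pulse_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise ValueError("center_frequency must be positive")
        if not 0 < self.fractional_bandwidth <= 1:
            raise ValueError("fractional_bandwidth must be in (0, 1]")
        if self.sampling_rate < 4 * self.center_frequency:
            raise ValueError("sampling_rate must be >= 4x center frequency")

    @property
    def envelope_sigma_s(self) -> float:
        """Time-domain Gaussian envelope SD in seconds."""
        sigma_f = self.fractional_bandwidth * self.center_frequency / (2.0 * math.sqrt(2 * _LN2))
        return 1.0 / (2.0 * math.pi * sigma_f)

    @property
    def pulse_length_s(self) -> float:
        """Envelope full width at 1/10 maximum, seconds."""
        return 2.0 * math.sqrt(2.0 * math.log(10.0)) * self.envelope_sigma_s

    def pulse(self, t: np.ndarray, t0: float = 0.0, amplitude: float | None = None) -> np.ndarray:
        """Gabor pulse centred at time t0, evaluated at times t (s)."""
        if amplitude is None:
            amplitude = self.pulse_amplitude
        tau = np.asarray(t) - t0
        env = np.exp(-(tau**2) / (2.0 * self.envelope_sigma_s**2))
        return amplitude * env * np.cos(2.0 * math.pi * self.center_frequency * tau)

    def peak_to_peak(self, amplitude: float | None = None) -> float:
        """Peak-to-peak amplitude of the pulse.

        The maximum is exactly A at t = 0; the minimum sits near (not
        exactly at - the envelope pulls it inward) half a carrier
        period away and is located on a fine grid."""
        if amplitude is None:
            amplitude = self.pulse_amplitude
        period = 1.0 / self.center_frequency
        tt = np.linspace(0.25 * period, 0.75 * period, 20001)
        trough = float(self.pulse(tt, amplitude=1.0).min())
        return amplitude * (1.0 - trough)


def simulate_reference(
    t: TransducerSpec,
    standoff_mm: float = 10.0,
    c_medium: float = 1520.0,
    n_samples: int | None = None,
) -> RFScan:
    """Single noiseless A-line from a perfect reflector.

    The echo is a unit-reflectivity Gabor pulse at the round-trip delay
    of the standoff; its peak-to-peak amplitude defines A_ref.
    """
    delay = 2.0 * standoff_mm * 1e-3 / c_medium
    if n_samples is None:
        t_end = delay + 12.0 * t.envelope_sigma_s + 0.5e-6
        n_samples = int(np.ceil(t_end * t.sampling_rate / 64.0)) * 64
    times = np.arange(n_samples) / t.sampling_rate
    rf = t.pulse(times, t0=delay)
    return RFScan(
        rf=rf[np.newaxis, :],
        positions=np.zeros((1, 2)),
        sampling_rate=t.sampling_rate,
        c_medium=c_medium,
        metadata={"kind": "reference", "standoff_mm": standoff_mm},
    )


# ---------------------------------------------------------------------------
# cartilage phantom


@dataclass
class CartilagePhantomSpec:
    """Latent ("true") description of one scanned cartilage site.

    Defaults emulate a 100-line raster over a 0.3 mm x 0.3 mm region of
    healthy rat tibial cartilage: ~10 mm standoff in saline, surface
    roughness a few µm, thickness a quarter millimetre, a few percent
    surface reflectivity and a stronger osteochondral interface.
    """

    n_lines: int = 100
    roi_extent_mm: tuple[float, float] = (0.3, 0.3)
    standoff_mean_mm: float = 10.0
    surface_roughness_sd_um: float = 8.0
    thickness_mean_mm: float = 0.25
    thickness_sd_um: float = 10.0
    r_surface: float = 0.05
    r_interface: float = 0.25
    attenuation_db_cm_mhz: float = 1.0
    c_medium: float = 1520.0
    c_cartilage: float = 1675.0
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if min(self.c_medium, self.c_cartilage) <= 0:
            raise ValueError("sound speeds must be positive")
        for name in ("r_surface", "r_interface"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.thickness_mean_mm > 0:
            raise ValueError("thickness_mean_mm must be positive")
        if self.noise_sd < 0 or self.attenuation_db_cm_mhz < 0:
            raise ValueError("noise_sd and attenuation must be nonnegative")


@dataclass
class GroundTruth:
    """Per-line latent truths recorded by the simulator."""

    d_um: np.ndarray
    h_mm: np.ndarray
    surface_amplitude_ratio: np.ndarray
    interface_amplitude_ratio: np.ndarray
    n_redraws: int = 0

    def __post_init__(self) -> None:
        n = self.d_um.size
        for arr in (self.h_mm, self.surface_amplitude_ratio, self.interface_amplitude_ratio):
            if arr.size != n:
                raise ValueError("ground-truth arrays must share length")
            if not np.all(np.isfinite(arr)):
                raise ValueError("ground-truth values must be finite")

    @property
    def true_uri_um(self) -> float:
        """Population SD of the drawn surface distances."""
        return float(np.sqrt(np.mean((self.d_um - self.d_um.mean()) ** 2)))

    @property
    def true_rc1_pct(self) -> float:
        return float(np.mean(self.surface_amplitude_ratio) * 100.0)

    @property
    def true_rc2_pct(self) -> float:
        return float(np.mean(self.interface_amplitude_ratio) * 100.0)

    @property
    def true_h_mm(self) -> float:
        return float(np.mean(self.h_mm))


def _raster_positions(n_lines: int, extent_mm: tuple[float, float]) -> np.ndarray:
    """Serpentine-free row-major raster of n_lines points over the ROI."""
    side = int(math.ceil(math.sqrt(n_lines)))
    xs = np.linspace(0.0, extent_mm[0], side)
    ys = np.linspace(0.0, extent_mm[1], side)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])[:n_lines]


def _draw_positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int):
    """Normal draws with nonpositive values redrawn; returns (values, redraws)."""
    vals = rng.normal(mean, sd, size=n)
    redraws = 0
    bad = vals <= 0
    while np.any(bad):
        redraws += int(bad.sum())
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = vals <= 0
        if redraws > 100 * n:
            raise RuntimeError("distribution almost entirely nonpositive")
    return vals, redraws


def simulate_rf_scan(
    p: CartilagePhantomSpec, t: TransducerSpec | None = None
) -> tuple[RFScan, GroundTruth]:
    """Simulate the RF scan of one cartilage site.

    Returns the scan and the ground-truth record of the latent per-line
    surface distances, thicknesses and echo amplitude ratios.  The same
    spec and seed always produce bit-identical output.
    """
    if t is None:
        t = TransducerSpec()
    rng = np.random.default_rng(p.seed)

    d_mm, redraw_d = _draw_positive_normal(
        rng, p.standoff_mean_mm, p.surface_roughness_sd_um * 1e-3, p.n_lines
    )
    h_mm, redraw_h = _draw_positive_normal(
        rng, p.thickness_mean_mm, p.thickness_sd_um * 1e-3, p.n_lines
    )

    a_ref_pp = t.peak_to_peak()
    f0_mhz = t.center_frequency / 1e6
    # two-way amplitude attenuation at f0 over thickness h (narrowband)
    atten = 10.0 ** (-2.0 * p.attenuation_db_cm_mhz * (h_mm * 0.1) * f0_mhz / 20.0)
    surf_ratio = np.full(p.n_lines, p.r_surface)
    intf_ratio = p.r_interface * (1.0 - p.r_surface**2) * atten

    t_surface = 2.0 * d_mm * 1e-3 / p.c_medium
    t_interface = t_surface + 2.0 * h_mm * 1e-3 / p.c_cartilage

    t_end = (
        2.0 * (p.standoff_mean_mm + 6.0 * p.surface_roughness_sd_um * 1e-3) * 1e-3 / p.c_medium
        + 2.0 * (p.thickness_mean_mm + 6.0 * p.thickness_sd_um * 1e-3) * 1e-3 / p.c_cartilage
        + 12.0 * t.envelope_sigma_s
        + 0.2e-6
    )
    n_samples = int(np.ceil(t_end * t.sampling_rate / 64.0)) * 64
    times = np.arange(n_samples) / t.sampling_rate

    tau_s = times[np.newaxis, :] - t_surface[:, np.newaxis]
    tau_i = times[np.newaxis, :] - t_interface[:, np.newaxis]
    sig = t.envelope_sigma_s
    w0 = 2.0 * math.pi * t.center_frequency
    amp = t.pulse_amplitude
    rf = surf_ratio[:, np.newaxis] * amp * np.exp(-(tau_s**2) / (2 * sig**2)) * np.cos(w0 * tau_s)
    rf += intf_ratio[:, np.newaxis] * amp * np.exp(-(tau_i**2) / (2 * sig**2)) * np.cos(w0 * tau_i)
    if p.noise_sd > 0:
        rf += rng.normal(0.0, p.noise_sd * a_ref_pp, size=rf.shape)

    overlap = bool(np.min(2.0 * h_mm * 1e-3 / p.c_cartilage) < t.pulse_length_s)
    truth = GroundTruth(
        d_um=d_mm * 1e3,
        h_mm=h_mm,
        surface_amplitude_ratio=surf_ratio,
        interface_amplitude_ratio=intf_ratio,
        n_redraws=redraw_d + redraw_h,
    )
    scan = RFScan(
        rf=rf,
        positions=_raster_positions(p.n_lines, p.roi_extent_mm),
        sampling_rate=t.sampling_rate,
        c_medium=p.c_medium,
        c_cartilage=p.c_cartilage,
        metadata={
            "kind": "cartilage_scan",
            "seed": p.seed,
            "overlap_warning": overlap,
            "n_redraws": truth.n_redraws,
        },
    )
    return scan, truth


# ---------------------------------------------------------------------------
# trabecular phantoms


@dataclass
class TrabecularPhantomSpec:
    """Binary trabecular phantom with analytically known morphometry.

    shape_kind:
      * ``parallel_plates`` - plates of (integer) thickness t stacked
        with period p along axis 0, centred within each period so the
        volume faces fall mid-gap; BV/TV = t/p when the axis-0 extent is
        a whole number of periods.
      * ``rod_lattice`` - cubic lattice of cylindrical rods (radius r,
        cell size a) along all three axes, kept clear of the faces; a
        seeded fraction ``rod_dropout`` of rods is removed so each
        specimen has its own connectivity (the number of independent
        loops of the kept rod graph is recorded in the metadata).
      * ``solid`` - all foreground.
      * ``torus`` - a single solid torus (one independent loop).
    """

    shape_kind: str = "rod_lattice"
    voxel_size_um: float = 12.0
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    plate_thickness: int = 5
    plate_period: int = 25
    rod_radius: float = 3.0
    cell_size: float = 25.0
    rod_dropout: float = 0.05
    torus_major_radius: float = 16.0
    torus_minor_radius: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        kinds = {"parallel_plates", "rod_lattice", "solid", "torus"}
        if self.shape_kind not in kinds:
            raise ValueError(f"shape_kind must be one of {sorted(kinds)}")
        if any(s < 4 for s in self.volume_shape):
            raise ValueError("volume_shape too small")
        if self.shape_kind == "parallel_plates":
            if not 0 < self.plate_thickness < self.plate_period:
                raise ValueError("need 0 < plate_thickness < plate_period")
            if self.plate_period > self.volume_shape[0]:
                raise ValueError("plate_period exceeds volume extent")
        if self.shape_kind == "rod_lattice":
            if not 0 < self.rod_radius < self.cell_size / 2:
                raise ValueError("need 0 < rod_radius < cell_size/2")
            if not 0 <= self.rod_dropout < 0.5:
                raise ValueError("rod_dropout must be in [0, 0.5)")
        if self.shape_kind == "torus":
            need = 2 * (self.torus_major_radius + self.torus_minor_radius) + 4
            if need > min(self.volume_shape[1:]):
                raise ValueError("torus exceeds volume extent")


def _axis_node_positions(extent: int, cell: float, clearance: float) -> np.ndarray:
    n_cells = int(math.floor((extent - 1 - 2 * clearance) / cell))
    if n_cells < 1:
        raise ValueError("cell_size too large for volume extent")
    margin = (extent - 1 - n_cells * cell) / 2.0
    return margin + cell * np.arange(n_cells + 1)


def _lattice_edges(nodes: list[np.ndarray]) -> list[tuple[tuple, tuple]]:
    """All nearest-neighbour node pairs of the cubic lattice."""
    grid = [
        (i, j, k)
        for i in range(len(nodes[0]))
        for j in range(len(nodes[1]))
        for k in range(len(nodes[2]))
    ]
    edges = []
    for node in grid:
        for axis in range(3):
            nb = list(node)
            nb[axis] += 1
            if nb[axis] < len(nodes[axis]):
                edges.append((node, tuple(nb)))
    return edges


def _graph_beta1(edges: list, kept: np.ndarray) -> tuple[int, int, int]:
    """(V, E, b1) of the kept-edge subgraph; b1 = E - V + components."""
    kept_edges = [e for e, k in zip(edges, kept) if k]
    verts = {v for e in kept_edges for v in e}
    parent = {v: v for v in verts}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in kept_edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    n_comp = len({find(v) for v in verts})
    return len(verts), len(kept_edges), len(kept_edges) - len(verts) + n_comp


def _rod_lattice(spec: TrabecularPhantomSpec) -> tuple[np.ndarray, dict]:
    """Cubic lattice of rods painted edge by edge; a seeded fraction of
    rods is dropped to give each specimen an individual topology, the
    way no two trabecular networks are identical."""
    r = spec.rod_radius
    nodes = [_axis_node_positions(s, spec.cell_size, r + 1.0) for s in spec.volume_shape]
    edges = _lattice_edges(nodes)
    rng = np.random.default_rng(spec.seed)
    kept = rng.random(len(edges)) >= spec.rod_dropout

    coords = [np.arange(s, dtype=float) for s in spec.volume_shape]
    vol = np.zeros(spec.volume_shape, dtype=bool)
    for (a, b), keep in zip(edges, kept):
        if not keep:
            continue
        axis = next(ax for ax in range(3) if a[ax] != b[ax])
        perp = [ax for ax in range(3) if ax != axis]
        lo = nodes[axis][a[axis]]
        hi = nodes[axis][b[axis]]
        sel: list = [None, None, None]
        sel[axis] = (coords[axis] >= lo) & (coords[axis] <= hi)
        d2 = [None, None, None]
        for ax in perp:
            d2[ax] = (coords[ax] - nodes[ax][a[ax]]) ** 2
        shapes = [
            np.reshape(arr, tuple(len(arr) if i == ax else 1 for i in range(3)))
            for ax, arr in ((axis, sel[axis]), (perp[0], d2[perp[0]]), (perp[1], d2[perp[1]]))
        ]
        vol |= shapes[0] & (shapes[1] + shapes[2] <= r * r)

    n_v, n_e, b1 = _graph_beta1(edges, kept)
    meta = {
        "n_cells": [len(nd) - 1 for nd in nodes],
        "node_positions": [nd.tolist() for nd in nodes],
        "kept_edges": [e for e, k in zip(edges, kept) if k],
        "n_rods_dropped": int((~kept).sum()),
        "expected_loops": b1,
        "expected_bvtv_thin_rod": 3 * math.pi * r**2 / spec.cell_size**2,
    }
    return vol, meta


def generate_trabecular_phantom(s: TrabecularPhantomSpec) -> TrabecularVolume:
    """Build the binary phantom volume described by *s*."""
    meta: dict = {"shape_kind": s.shape_kind}
    if s.shape_kind == "solid":
        vol = np.ones(s.volume_shape, dtype=bool)
        meta["expected_bvtv"] = 1.0
    elif s.shape_kind == "parallel_plates":
        z = np.arange(s.volume_shape[0])
        offset = (s.plate_period - s.plate_thickness) // 2
        phase = (z - offset) % s.plate_period
        plate = phase < s.plate_thickness
        vol = np.broadcast_to(plate[:, None, None], s.volume_shape).copy()
        meta.update(
            expected_bvtv=s.plate_thickness / s.plate_period,
            expected_tbth_vox=float(s.plate_thickness),
            expected_tbsp_vox=float(s.plate_period - s.plate_thickness),
            expected_tbn_per_vox=1.0 / s.plate_period,
        )
    elif s.shape_kind == "rod_lattice":
        vol, extra = _rod_lattice(s)
        meta.update(extra)
    elif s.shape_kind == "torus":
        zc, yc, xc = [(n - 1) / 2.0 for n in s.volume_shape]
        z, y, x = np.meshgrid(*[np.arange(n, dtype=float) for n in s.volume_shape], indexing="ij")
        rho = np.sqrt((y - yc) ** 2 + (x - xc) ** 2)
        vol = (rho - s.torus_major_radius) ** 2 + (z - zc) ** 2 <= s.torus_minor_radius**2
        meta["expected_loops"] = 1
    else:  # pragma: no cover - guarded by spec validation
        raise ValueError(s.shape_kind)
    if not vol.any():
        raise ValueError("phantom construction produced an empty volume")
    return TrabecularVolume(voxels=vol, voxel_size_um=s.voxel_size_um, metadata=meta)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CartilageEffects:
    """Multiplicative treatment effects on the latent cartilage truth."""

    roughness: float = 1.0
    r_surface: float = 1.0
    r_interface: float = 1.0
    thickness: float = 1.0

    def __post_init__(self) -> None:
        if min(self.roughness, self.r_surface, self.r_interface, self.thickness) <= 0:
            raise ValueError("effect multipliers must be positive")


@dataclass
class BoneEffects:
    rod_radius: float = 1.0
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        if min(self.rod_radius, self.cell_size) <= 0:
            raise ValueError("effect multipliers must be positive")


@dataclass
class BetweenAnimalCV:
    """Between-specimen coefficients of variation of the latent truths."""

    roughness: float = 0.15
    r_surface: float = 0.10
    r_interface: float = 0.10
    thickness: float = 0.05
    rod_radius: float = 0.05
    cell_size: float = 0.03


@dataclass
class CohortSpec:
    """Two-group study design: shared baseline phantoms, group-specific
    multiplicative effects, between-animal variability, one seed."""

    n_per_group: int = 7
    cartilage: dict[str, CartilagePhantomSpec] = field(
        default_factory=lambda: {"site1": CartilagePhantomSpec()}
    )
    trabecular: TrabecularPhantomSpec = field(default_factory=TrabecularPhantomSpec)
    effects: dict[str, CartilageEffects] = field(default_factory=dict)
    bone_effects: BoneEffects = field(default_factory=BoneEffects)
    between_cv: BetweenAnimalCV = field(default_factory=BetweenAnimalCV)
    transducer: TransducerSpec = field(default_factory=TransducerSpec)
    group_names: tuple[str, str] = ("sham", "ovx")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")

    def site_effects(self, site: str) -> CartilageEffects:
        return self.effects.get(site, CartilageEffects())


@dataclass
class SpecimenData:
    specimen_id: str
    group: str
    scans: dict[str, RFScan]
    truths: dict[str, GroundTruth]
    volume: TrabecularVolume
    latent: dict


@dataclass
class CohortData:
    manifest: pd.DataFrame
    specimens: list[SpecimenData]
    reference: RFScan
    spec: CohortSpec


def _cv_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    val, _ = _draw_positive_normal(rng, mean, cv * mean, 1)
    return float(val[0])


def sample_cohort_parameters(c: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw the latent per-specimen truth table for a cohort.

    This is the between-animal layer of the generator: one row per
    specimen, columns for every site's latent roughness, reflectivities
    and thickness, and the bone lattice geometry.  `generate_cohort`
    uses exactly these draws to synthesize the RF scans and volumes, so
    null-hypothesis behaviour of downstream statistics can be studied on
    this table directly without paying for waveform synthesis.
    """
    rng = np.random.default_rng(c.seed if seed is None else seed)
    cv = c.between_cv
    rows = []
    for group in c.group_names:
        treated = group != c.group_names[0]
        for k in range(c.n_per_group):
            row: dict = {"specimen_id": f"{group}_{k + 1:02d}", "group": group}
            for site, base in c.cartilage.items():
                eff = c.site_effects(site) if treated else CartilageEffects()
                row[f"{site}_roughness_um"] = _cv_draw(
                    rng, base.surface_roughness_sd_um * eff.roughness, cv.roughness
                )
                row[f"{site}_r_surface"] = _cv_draw(
                    rng, base.r_surface * eff.r_surface, cv.r_surface
                )
                row[f"{site}_r_interface"] = _cv_draw(
                    rng, base.r_interface * eff.r_interface, cv.r_interface
                )
                row[f"{site}_thickness_mm"] = _cv_draw(
                    rng, base.thickness_mean_mm * eff.thickness, cv.thickness
                )
            bone_eff = c.bone_effects if treated else BoneEffects()
            row["bone_rod_radius_vox"] = _cv_draw(
                rng, c.trabecular.rod_radius * bone_eff.rod_radius, cv.rod_radius
            )
            row["bone_cell_vox"] = _cv_draw(
                rng, c.trabecular.cell_size * bone_eff.cell_size, cv.cell_size
            )
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(c: CohortSpec, out_dir=None) -> CohortData:
    """Synthesize a full two-group cohort.

    Returns the in-memory cohort; when *out_dir* is given, also writes
    one RF container per specimen and site, one volume per specimen, and
    a manifest CSV, and records the paths in the manifest.
    """
    from cartiqus import io_  # deferred: io_ imports h5py/tifffile

    latent = sample_cohort_parameters(c)
    ss = np.random.SeedSequence(c.seed)
    child_seeds = ss.spawn(len(latent) * len(c.cartilage))
    reference = simulate_reference(
        c.transducer, c_medium=next(iter(c.cartilage.values())).c_medium
    )

    specimens: list[SpecimenData] = []
    manifest_rows = []
    seed_iter = iter(child_seeds)
    out = None
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

    for spec_index, (_, row) in enumerate(latent.iterrows()):
        sid, group = row["specimen_id"], row["group"]
        scans: dict[str, RFScan] = {}
        truths: dict[str, GroundTruth] = {}
        mrow: dict = {"specimen_id": sid, "group": group}
        for site, base in c.cartilage.items():
            child = next(seed_iter)
            spec_i = replace(
                base,
                surface_roughness_sd_um=row[f"{site}_roughness_um"],
                r_surface=min(1.0, row[f"{site}_r_surface"]),
                r_interface=min(1.0, row[f"{site}_r_interface"]),
                thickness_mean_mm=row[f"{site}_thickness_mm"],
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            scan, truth = simulate_rf_scan(spec_i, c.transducer)
            scans[site], truths[site] = scan, truth
            if out is not None:
                rf_path = out / f"{sid}_{site}.h5"
                io_.write_rf_container(rf_path, scan, reference, truth)
                key = "rf_path" if len(c.cartilage) == 1 else f"rf_path_{site}"
                mrow[key] = str(rf_path)
        vol_seed = int(
            np.random.SeedSequence([c.seed, 7919, spec_index]).generate_state(1)[0] % (2**31)
        )
        vspec = replace(
            c.trabecular,
            rod_radius=row["bone_rod_radius_vox"],
            cell_size=row["bone_cell_vox"],
            seed=vol_seed,
        )
        volume = generate_trabecular_phantom(vspec)
        if out is not None:
            vol_path = out / f"{sid}_trabecular.tif"
            io_.write_volume(vol_path, volume)
            mrow["volume_path"] = str(vol_path)
        specimens.append(
            SpecimenData(
                specimen_id=sid,
                group=group,
                scans=scans,
                truths=truths,
                volume=volume,
                latent=row.to_dict(),
            )
        )
        manifest_rows.append(mrow)

    manifest = pd.DataFrame(manifest_rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return CohortData(manifest=manifest, specimens=specimens, reference=reference, spec=c)
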