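"""Synthetic voxel head phantoms and their optical properties.

Geometry convention (used everywhere in this package): voxel indices are
0-based; the physical coordinate of voxel ``(i, j, k)`` is its center,
``(i + 0.5, j + 0.5, k + 0.5) * voxel_pitch`` in mm, with the origin at the
grid corner. Label ``0`` is reserved for the exterior (ambient medium,
refractive index ``ambient_n``, default 1.0).

The default six-layer head is a set of concentric ellipsoidal shells,
ordered outside-in scalp -> skull -> CSF -> gray matter -> white matter,
optionally with an ellipsoidal air-cavity inclusion (frontal-sinus-like).
It is an analytic stand-in for an MRI-derived head mesh: the guiding
topology that matters for photon migration — a thin, low-scattering CSF
shell sandwiched between the highly scattering skull and gray matter — is
preserved, while the geometry stays fully parametric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "LayerOpticalProperties",
    "VoxelPhantom",
    "SourceSpec",
    "DetectorSpec",
    "default_head_layers",
    "build_layered_head_phantom",
    "build_slab_phantom",
    "build_homogeneous_cube",
    "surface_patch",
    "save_nifti",
    "load_nifti",
]

OUTSIDE_LABEL = 0

#: Default shell thicknesses in mm (configuration, from standard adult-head
#: anatomy; the innermost region is white matter and takes the remainder).
DEFAULT_SHELL_THICKNESSES = {"scalp": 5.0, "skull": 7.0, "csf": 3.0, "gray_matter": 4.0}


@dataclass(frozen=True)
class LayerOpticalProperties:
    """Optical properties of one tissue layer at the working wavelength.

    Attributes
    ----------
    label : int
        Integer tissue code used in the voxel grid (>= 1; 0 is exterior).
    name : str
        Human-readable tissue name.
    mu_a : float
        Absorption coefficient, 1/mm.
    mu_s : float
        Scattering coefficient, 1/mm.
    g : float
        Scattering anisotropy (mean cosine of deflection), in [-1, 1].
    n : float
        Refractive index, >= 1.
    """

    label: int
    name: str
    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError(f"layer {self.name!r}: mu_a and mu_s must be >= 0")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"layer {self.name!r}: g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError(f"layer {self.name!r}: refractive index must be >= 1")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), 1/mm."""
        return self.mu_s * (1.0 - self.g)


def default_head_layers() -> dict[int, LayerOpticalProperties]:
    """Six-layer adult-head optical properties at 810 nm.

    Absorption/scattering/anisotropy/index per tissue; all tissues share
    n = 1.37 except air cavities (n = 1, non-scattering, non-absorbing).
    """
    layers = [
        LayerOpticalProperties(1, "scalp", 0.045, 19.818, 0.89, 1.37),
        LayerOpticalProperties(2, "skull", 0.011, 17.4545, 0.89, 1.37),
        LayerOpticalProperties(3, "csf", 0.0026, 0.0909, 0.89, 1.37),
        LayerOpticalProperties(4, "gray_matter", 0.028, 7.3, 0.89, 1.37),
        LayerOpticalProperties(5, "white_matter", 0.092, 38.0, 0.87, 1.37),
        LayerOpticalProperties(6, "air_cavities", 0.0, 0.0, 1.0, 1.0),
    ]
    return {lay.label: lay for lay in layers}


@dataclass
class VoxelPhantom:
    """A labelled 3-D voxel volume with per-label optical properties.

    ``labels`` is an integer array indexed ``[ix, iy, iz]``;
    ``layer_table`` maps each non-zero label to its
    :class:`LayerOpticalProperties`. ``ambient_n`` is the refractive index
    of the exterior medium (label 0).
    """

    labels: np.ndarray
    voxel_pitch: float
    layer_table: dict[int, LayerOpticalProperties]
    outside_label: int = OUTSIDE_LABEL
    ambient_n: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be > 0")
        present = set(np.unique(self.labels).tolist())
        known = set(self.layer_table) | {self.outside_label}
        unknown = present - known
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from layer_table")
        inside = self.labels != self.outside_label
        if not inside.any():
            raise ValueError("phantom has no interior voxels")
        # interior must be bounded away from the grid faces by >= 1 voxel
        for ax in range(3):
            lo = np.take(inside, 0, axis=ax)
            hi = np.take(inside, -1, axis=ax)
            if lo.any() or hi.any():
                raise ValueError("interior voxels touch the grid boundary; add margin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical grid extent per axis, mm."""
        return np.asarray(self.labels.shape) * self.voxel_pitch

    def inside_mask(self) -> np.ndarray:
        return self.labels != self.outside_label

    def sorted_labels(self) -> list[int]:
        return sorted(self.layer_table)

    def property_arrays(self) -> dict[str, np.ndarray]:
        """Dense per-label property lookup arrays (index = label).

        Label 0 carries the exterior: mu_a = mu_s = 0, n = ``ambient_n``.
        """
        n_lab = max(self.layer_table) + 1
        mua = np.zeros(n_lab)
        mus = np.zeros(n_lab)
        g = np.ones(n_lab)
        n = np.full(n_lab, self.ambient_n)
        for lab, props in self.layer_table.items():
            mua[lab], mus[lab], g[lab], n[lab] = props.mu_a, props.mu_s, props.g, props.n
        return {"mu_a": mua, "mu_s": mus, "g": g, "n": n}

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates along one axis, mm."""
        return (np.arange(self.labels.shape[axis]) + 0.5) * self.voxel_pitch

    def with_mu_a_override(self, mask: np.ndarray, factor: float) -> "VoxelPhantom":
        """Return a phantom where voxels in ``mask`` get mu_a scaled by ``factor``.

        Implemented by introducing a shadow label per affected tissue so the
        grid stays a pure label volume (used by finite-difference checks).
        """
        labels = self.labels.copy()
        table = dict(self.layer_table)
        next_label = max(table) + 1
        for lab in sorted(set(np.unique(self.labels[mask])) - {self.outside_label}):
            props = table[lab]
            table[next_label] = replace(
                props, label=next_label, name=f"{props.name}_perturbed", mu_a=props.mu_a * factor
            )
            labels[mask & (self.labels == lab)] = next_label
            next_label += 1
        return VoxelPhantom(labels, self.voxel_pitch, table, self.outside_label, self.ambient_n)


@dataclass(frozen=True)
class SourceSpec:
    """Uniform collimated disk source.

    ``center`` is the disk center in mm, ``direction`` the (unit) beam axis,
    ``diameter`` the disk diameter in mm. ``profile`` is fixed: a uniformly
    filled, collimated disk. A ``diameter`` of 0 gives a pencil beam.
    """

    center: tuple[float, float, float]
    direction: tuple[float, float, float]
    diameter: float = 50.8  # 2 inch
    profile: str = "uniform_disk"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("source direction must be unit-norm (within 1e-12)")
        if self.diameter < 0:
            raise ValueError("source diameter must be >= 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class DetectorSpec:
    """Detector acceptance region on the phantom surface.

    In ``sphere_cap`` mode the detector is the intersection of a sphere with
    the head surface: exterior-facing boundary faces whose centers lie
    inside the sphere. In ``depth_crop`` mode it is every surface face
    whose center lies at least ``crop_depth`` mm from the source center
    along the source axis.
    """

    sphere_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sphere_radius: float = 40.0
    mode: str = "sphere_cap"
    crop_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("sphere_cap", "depth_crop"):
            raise ValueError(f"unknown detector mode {self.mode!r}")
        if self.mode == "sphere_cap" and self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be > 0")
        if self.mode == "depth_crop" and self.crop_depth <= 0:
            raise ValueError("crop_depth must be > 0 in depth_crop mode")


# ---------------------------------------------------------------------------
# builders


def _ellipsoid_mask(shape, pitch, center, semi_axes, dtype=np.float32) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside an ellipsoid."""
    idx = [(np.arange(n, dtype=dtype) + dtype(0.5)) * dtype(pitch) for n in shape]
    rx = ((idx[0] - dtype(center[0])) / dtype(semi_axes[0])) ** 2
    ry = ((idx[1] - dtype(center[1])) / dtype(semi_axes[1])) ** 2
    rz = ((idx[2] - dtype(center[2])) / dtype(semi_axes[2])) ** 2
    return (rx[:, None, None] + ry[None, :, None] + rz[None, None, :]) <= 1.0


def build_layered_head_phantom(
    lateral_diameter: float = 155.0,
    voxel_pitch: float = 1.0,
    layer_thicknesses: dict[str, float] | None = None,
    seed: int = 0,
    ap_diameter: float | None = None,
    si_diameter: float | None = None,
    air_cavity: dict | None = None,
    layer_table: dict[int, LayerOpticalProperties] | None = None,
    margin_voxels: int = 2,
) -> VoxelPhantom:
    """Build the six-layer ellipsoidal head phantom.

    The head is a stack of concentric ellipsoidal shells; the x axis is the
    lateral (ear-to-ear) axis and the widest inside-the-head span along it
    equals ``lateral_diameter`` to within one voxel. ``ap_diameter`` and
    ``si_diameter`` (anterior-posterior along y, superior-inferior along z)
    default to 1.22x and 1.10x the lateral diameter.

    ``air_cavity``, if given, is ``{"center": (x,y,z) mm, "semi_axes":
    (a,b,c) mm}`` and carves a frontal-sinus-like air inclusion (label 6).

    ``seed`` is accepted for interface stability (reserved for randomized
    cavity placement); the default build is fully deterministic.
    """
    if layer_thicknesses is None:
        layer_thicknesses = dict(DEFAULT_SHELL_THICKNESSES)
    if layer_table is None:
        layer_table = default_head_layers()
    if voxel_pitch <= 0:
        raise ValueError("voxel_pitch must be > 0")
    order = ["scalp", "skull", "csf", "gray_matter"]
    thick = [float(layer_thicknesses[k]) for k in order]
    if lateral_diameter <= 2 * sum(thick):
        raise ValueError(
            "lateral_diameter must exceed twice the summed shell thicknesses "
            f"({2 * sum(thick):.1f} mm)"
        )
    a_lat = lateral_diameter / 2.0
    a_ap = (ap_diameter / 2.0) if ap_diameter is not None else a_lat * 1.22
    a_si = (si_diameter / 2.0) if si_diameter is not None else a_lat * 1.10
    outer = np.array([a_lat, a_ap, a_si])

    # nested boundary semi-axes, outside-in
    boundaries = [outer.copy()]
    axes = outer.copy()
    for name, t in zip(order, thick):
        axes = axes - t
        if np.any(axes <= 0):
            raise ValueError(f"shell thicknesses exceed the semi-axis at layer {name!r}")
        boundaries.append(axes.copy())

    shape = tuple(int(np.ceil(2 * ax / voxel_pitch)) + 2 * margin_voxels for ax in outer)
    center = tuple(s * voxel_pitch / 2.0 for s in shape)

    labels = np.zeros(shape, dtype=np.int16)
    # paint outside-in so each inner ellipsoid overwrites the outer shell
    shell_labels = [1, 2, 3, 4, 5]  # scalp, skull, csf, gm, wm
    for lab, semi in zip(shell_labels, boundaries):
        labels[_ellipsoid_mask(shape, voxel_pitch, center, semi)] = lab

    if air_cavity is not None:
        cav = _ellipsoid_mask(
            shape, voxel_pitch, air_cavity["center"], air_cavity["semi_axes"]
        )
        labels[cav & (labels != OUTSIDE_LABEL)] = 6

    used = set(np.unique(labels).tolist()) - {OUTSIDE_LABEL}
    table = {lab: layer_table[lab] for lab in used}
    return VoxelPhantom(
        labels,
        voxel_pitch,
        table,
        meta={
            "kind": "layered_head",
            "center_mm": center,
            "outer_semi_axes_mm": outer.tolist(),
            "boundary_semi_axes_mm": [b.tolist() for b in boundaries],
            "lateral_axis": 0,
            "seed": seed,
        },
    )


def build_slab_phantom(
    thickness: float,
    props: LayerOpticalProperties,
    lateral_size: float = 100.0,
    voxel_pitch: float = 1.0,
    normal_axis: int = 0,
    margin_voxels: int = 2,
) -> VoxelPhantom:
    """Single-material slab normal to ``normal_axis``, exterior elsewhere."""
    if thickness <= 0 or lateral_size <= 0 or voxel_pitch <= 0:
        raise ValueError("thickness, lateral_size and voxel_pitch must be > 0")
    n_thick = int(round(thickness / voxel_pitch))
    n_lat = int(round(lateral_size / voxel_pitch))
    if n_thick < 1 or n_lat < 1:
        raise ValueError("slab dimensions smaller than one voxel")
    dims = [n_lat, n_lat, n_lat]
    dims[normal_axis] = n_thick
    shape = tuple(d + 2 * margin_voxels for d in dims)
    labels = np.zeros(shape, dtype=np.int16)
    sl = [slice(margin_voxels, margin_voxels + d) for d in dims]
    labels[tuple(sl)] = props.label
    return VoxelPhantom(
        labels,
        voxel_pitch,
        {props.label: props},
        meta={
            "kind": "slab",
            "normal_axis": normal_axis,
            "entry_mm": margin_voxels * voxel_pitch,
            "exit_mm": (margin_voxels + n_thick) * voxel_pitch,
        },
    )


def build_homogeneous_cube(
    side: float,
    props: LayerOpticalProperties,
    voxel_pitch: float = 1.0,
    margin_voxels: int = 2,
) -> VoxelPhantom:
    """Homogeneous cube of one material (validation geometry)."""
    return build_slab_phantom(side, props, lateral_size=side, voxel_pitch=voxel_pitch,
                              margin_voxels=margin_voxels)


# ---------------------------------------------------------------------------
# surface patches

_FACE_NORMALS = {
    (0, 0): (-1, 0, 0), (0, 1): (1, 0, 0),
    (1, 0): (0, -1, 0), (1, 1): (0, 1, 0),
    (2, 0): (0, 0, -1), (2, 1): (0, 0, 1),
}


def _boundary_faces(phantom: VoxelPhantom):
    """All exterior-facing boundary faces: (ix, iy, iz, axis, dirbit, center xyz)."""
    inside = phantom.inside_mask()
    pitch = phantom.voxel_pitch
    out = []
    for ax in range(3):
        for dirbit, shift in ((0, -1), (1, +1)):
            neigh = np.roll(inside, -shift, axis=ax)
            # margin invariant guarantees no wrap-around artifacts
            faces = inside & ~neigh
            idx = np.argwhere(faces)
            centers = (idx + 0.5) * pitch
            centers[:, ax] += shift * 0.5 * pitch
            cols = np.empty((len(idx), 5), dtype=np.int64)
            cols[:, :3] = idx
            cols[:, 3] = ax
            cols[:, 4] = dirbit
            out.append((cols, centers))
    cols = np.concatenate([c for c, _ in out])
    centers = np.concatenate([c for _, c in out])
    return cols, centers


def surface_patch(phantom: VoxelPhantom, det: DetectorSpec,
                  source: SourceSpec | None = None):
    """Select the exterior-facing boundary faces accepted by a detector.

    Returns ``(faces, centers)`` where ``faces`` is an ``(m, 5)`` integer
    array of ``(ix, iy, iz, axis, dirbit)`` — the tissue voxel and the face
    it exposes (``dirbit`` 0 = negative, 1 = positive axis direction) — and
    ``centers`` the face-center coordinates in mm. Deterministic given
    phantom and spec.
    """
    cols, centers = _boundary_faces(phantom)
    if det.mode == "sphere_cap":
        d = centers - np.asarray(det.sphere_center)
        keep = np.einsum("ij,ij->i", d, d) <= det.sphere_radius**2
    else:
        if source is None:
            raise ValueError("depth_crop mode requires the source spec")
        axis_dir = np.asarray(source.direction, dtype=float)
        depth = (centers - np.asarray(source.center)) @ axis_dir
        keep = depth >= det.crop_depth
    if not keep.any():
        raise ValueError("detector does not touch surface")
    return cols[keep], centers[keep]


def acceptance_mask(phantom: VoxelPhantom, faces: np.ndarray) -> np.ndarray:
    """Boolean ``(nx, ny, nz, 3, 2)`` mask of accepted exit faces."""
    mask = np.zeros(phantom.shape + (3, 2), dtype=np.bool_)
    mask[faces[:, 0], faces[:, 1], faces[:, 2], faces[:, 3], faces[:, 4]] = True
    return mask


# ---------------------------------------------------------------------------
# NIfTI I/O (labelled volume + JSON sidecar with the layer table)


def save_nifti(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write the label volume as NIfTI-1 with a JSON layer-table sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([phantom.voxel_pitch] * 3 + [1.0])
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), affine)
    nib.save(img, str(path))
    sidecar = {
        "outside_label": phantom.outside_label,
        "ambient_n": phantom.ambient_n,
        "layers": [
            {"label": p.label, "name": p.name, "mu_a": p.mu_a,
             "mu_s": p.mu_s, "g": p.g, "n": p.n}
            for p in phantom.layer_table.values()
        ],
    }
    sidecar_path = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    Path(str(sidecar_path) + ".layers.json").write_text(json.dumps(sidecar, indent=2))


def load_nifti(path: str | Path, sidecar: str | Path | None = None) -> VoxelPhantom:
    """Load a labelled volume written by :func:`save_nifti` (or any labelled
    NIfTI with an accompanying ``.layers.json``)."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    pitch = float(img.affine[0, 0])
    if sidecar is None:
        base = path.with_suffix("").with_suffix("")
        sidecar = Path(str(base) + ".layers.json")
    meta = json.loads(Path(sidecar).read_text())
    table = {
        int(d["label"]): LayerOpticalProperties(
            int(d["label"]), d["name"], d["mu_a"], d["mu_s"], d["g"], d["n"]
        )
        for d in meta["layers"]
    }
    labels = np.asarray(img.dataobj, dtype=np.int16)
    return VoxelPhantom(labels, pitch, table,
                        outside_label=int(meta.get("outside_label", 0)),
                        ambient_n=float(meta.get("ambient_n", 1.0)))
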