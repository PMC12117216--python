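"""Absorption-sensitivity Jacobians from detected-packet voxel paths.

First-order perturbation Monte Carlo: for a small change ``d mu_a`` in
voxel ``v``, each detected packet's weight changes by
``-w_i * L_i(v) * d mu_a`` to first order, where ``L_i(v)`` is the packet's
pathlength in that voxel. The Jacobian of total detected intensity is

    J(v) = d I / d mu_a(v) = -sum_i w_i * L_i(v)    [mm]

computed directly from the per-voxel pathlengths the transport engine
records for detected packets — no adjoint solver, no rerun.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import VoxelPhantom
from .transport import DetectedPackets

__all__ = ["JacobianGrid", "absorption_jacobian", "sensitivity_summary"]


@dataclass
class JacobianGrid:
    """Per-voxel sensitivity of detected intensity to absorption changes.

    ``values[v] = dI/dmu_a(v) <= 0`` (mm): increasing absorption anywhere
    never increases detection. ``normalization`` is ``"raw"`` (canonical)
    or ``"per_total_detected"`` (divided by total detected weight, giving
    the relative intensity change per unit ``d mu_a``).
    """

    values: np.ndarray
    voxel_pitch: float
    normalization: str = "raw"

    def save_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_pitch] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))


def absorption_jacobian(
    records: DetectedPackets,
    phantom: VoxelPhantom,
    normalization: str = "raw",
) -> JacobianGrid:
    """Pathlength-weighted absorption Jacobian ``J(v) = -sum_i w_i L_i(v)``.

    Requires the transport run to have recorded per-voxel pathlengths
    (``record_voxel_paths=True``). Deterministic given the records.
    """
    if records.voxel_paths is None:
        raise ValueError(
            "per-voxel paths absent; rerun the simulation with "
            "record_voxel_paths=True in SimulationConfig")
    if tuple(records.grid_shape) != phantom.shape:
        raise ValueError("records and phantom grids differ in shape")
    offsets, vox, lens = records.voxel_paths
    J = np.zeros(int(np.prod(phantom.shape)))
    # expand per-record weights onto their sparse voxel segments
    seg_w = np.repeat(records.weight, np.diff(offsets))
    np.add.at(J, vox, -seg_w * lens)
    J = J.reshape(phantom.shape)
    J[~phantom.inside_mask()] = 0.0
    if normalization == "per_total_detected":
        J = J / records.weight.sum()
    elif normalization != "raw":
        raise ValueError("normalization must be 'raw' or 'per_total_detected'")
    return JacobianGrid(J, phantom.voxel_pitch, normalization)


def sensitivity_summary(
    jac: JacobianGrid,
    phantom: VoxelPhantom,
    masks: dict[str, np.ndarray],
) -> dict[str, float]:
    """Per-region shares of total |J|.

    ``masks`` must partition the inside-the-head voxels: disjoint, and
    their union covers every interior voxel. Shares are >= 0 and sum to 1.
    """
    inside = phantom.inside_mask()
    cover = np.zeros(phantom.shape, dtype=int)
    for m in masks.values():
        if m.shape != phantom.shape:
            raise ValueError("mask shape mismatch")
        cover += m.astype(int)
    if np.any(cover[inside] != 1) or np.any(cover[~inside] != 0):
        raise ValueError("masks must exactly partition the inside-the-head voxels")
    absj = np.abs(jac.values)
    total = absj.sum()
    if total <= 0:
        raise ValueError("Jacobian is identically zero")
    return {name: float(absj[m].sum() / total) for name, m in masks.items()}
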