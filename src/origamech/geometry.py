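"""Rigid-body superposition, ideal helix construction, and local site frames.

The coarse-grained nucleotide geometry used throughout: the stored nucleotide
position is the backbone interaction centre, placed 0.6 nm radially off the
helix axis; the base interaction centre sits 0.56 nm from it along the
backbone->base versor ``a1`` (so essentially on the axis).  Paired strands sit
at opposite azimuth, which makes the duplex pseudo-dyad an exact symmetry of
the ideal helix -- only the rigid *relative* geometry matters for docking, so
these simplifications cancel in superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ArgumentError, DegeneracyError
from .io import Configuration, complement

#: radial offset of the backbone interaction centre from the helix axis (nm)
BACKBONE_RADIUS_NM = 0.6
#: offset of the base interaction centre from the nucleotide position, along a1 (nm)
BASE_SITE_OFFSET_NM = 0.56
#: default helical rise (nm) and twist (degrees) of B-DNA
DEFAULT_RISE_NM = 0.34
DEFAULT_TWIST_DEG = 360.0 / 10.5

_DEGENERACY_SV_NM = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def validate(self) -> None:
        r = self.rotation
        if np.abs(r.T @ r - np.eye(3)).max() >= 1e-10:
            raise ArgumentError("rotation matrix not orthonormal")
        if abs(np.linalg.det(r) - 1.0) >= 1e-10:
            raise ArgumentError("rotation matrix not proper (det != +1)")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal proper rigid motion taking *mobile* onto *reference*.

    Returns the transform minimizing the (weighted) RMSD and the attained
    minimum RMSD in nm.  Reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ArgumentError(
            f"point set length mismatch: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ArgumentError("need at least 3 points of dimension 3")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mobile),) or (w < 0).any() or w.sum() <= 0:
            raise ArgumentError("weights must be nonnegative, matching length, not all zero")
    wsum = w.sum()
    ref_c = (w[:, None] * reference).sum(0) / wsum
    mob_c = (w[:, None] * mobile).sum(0) / wsum
    ref0 = reference - ref_c
    mob0 = mobile - mob_c
    sv = np.linalg.svd(ref0 * np.sqrt(w)[:, None], compute_uv=False)
    if sv[-2] < _DEGENERACY_SV_NM:  # collinear (or all-coincident) reference
        raise DegeneracyError("reference points are collinear or degenerate")
    rot, _ = Rotation.align_vectors(ref0, mob0, weights=w)
    r = rot.as_matrix()
    # recompute the attained minimum from residuals: scipy's rssd loses
    # precision to cancellation near exact fits
    resid = mob0 @ r.T - ref0
    rmsd = float(np.sqrt((w * (resid**2).sum(1)).sum() / wsum))
    t = ref_c - r @ mob_c
    return RigidTransform(r, t), rmsd


@dataclass
class HelixModel:
    """Ideal straight B-DNA duplex in the coarse-grained representation.

    Strand A runs 5'->3' along +z; strand B is its antiparallel complement.
    Arrays are indexed by base pair (0 = first bp of strand A).
    """

    n_bp: int
    sequence: str  # strand A, 5'->3'
    rise: float  # nm
    twist_deg: float
    pos_a: np.ndarray  # (n_bp, 3)
    a1_a: np.ndarray
    a3_a: np.ndarray
    pos_b: np.ndarray  # (n_bp, 3), pos_b[i] pairs pos_a[i]
    a1_b: np.ndarray
    a3_b: np.ndarray
    axis_origin: np.ndarray = None  # type: ignore[assignment]
    axis_direction: np.ndarray = None  # type: ignore[assignment]

    def bp_centers(self) -> np.ndarray:
        return 0.5 * (self.pos_a + self.pos_b)

    def anchors(self) -> np.ndarray:
        """Nucleotide anchor positions, ordered [A0..A(n-1), B0..B(n-1)]."""
        return np.vstack([self.pos_a, self.pos_b])


def build_ideal_helix(
    n_bp: int,
    sequence: str,
    rise: float = DEFAULT_RISE_NM,
    twist: float = DEFAULT_TWIST_DEG,
) -> HelixModel:
    """Construct an ideal duplex with axis along +z starting at the origin."""
    if n_bp < 1:
        raise ArgumentError("n_bp must be >= 1")
    if len(sequence) != n_bp:
        raise ArgumentError(f"sequence length {len(sequence)} != n_bp {n_bp}")
    complement(sequence)  # validates bases
    i = np.arange(n_bp)
    phi = np.deg2rad(twist) * i
    u = np.stack([np.cos(phi), np.sin(phi), np.zeros(n_bp)], axis=1)
    centers = np.stack([np.zeros(n_bp), np.zeros(n_bp), rise * i], axis=1)
    pos_a = centers + BACKBONE_RADIUS_NM * u
    pos_b = centers - BACKBONE_RADIUS_NM * u
    a1_a = -u
    a1_b = u
    z = np.array([0.0, 0.0, 1.0])
    a3_a = np.tile(z, (n_bp, 1))
    a3_b = np.tile(-z, (n_bp, 1))
    return HelixModel(
        n_bp=n_bp,
        sequence=sequence.upper(),
        rise=rise,
        twist_deg=twist,
        pos_a=pos_a,
        a1_a=a1_a,
        a3_a=a3_a,
        pos_b=pos_b,
        a1_b=a1_b,
        a3_b=a3_b,
        axis_origin=np.zeros(3),
        axis_direction=z.copy(),
    )


@dataclass
class LocalFrame:
    """Right-handed orthonormal triad attached to a recognition site."""

    origin: np.ndarray  # (3,) nm
    axis: np.ndarray  # unit vector, site helical axis (scaffold 5'->3')
    reference: np.ndarray  # unit vector perpendicular to axis
    third: np.ndarray  # axis x reference

    def validate(self) -> None:
        m = np.stack([self.reference, self.third, self.axis])
        if np.abs(m @ m.T - np.eye(3)).max() >= 1e-9:
            raise ArgumentError("local frame triad not orthonormal")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Coordinates (x=reference, y=third, z=axis) of global *points*."""
        d = np.atleast_2d(points) - self.origin
        return np.stack(
            [d @ self.reference, d @ self.third, d @ self.axis], axis=1
        )

    def rotated(self, rotation: np.ndarray, translation: np.ndarray) -> "LocalFrame":
        return LocalFrame(
            origin=rotation @ self.origin + translation,
            axis=rotation @ self.axis,
            reference=rotation @ self.reference,
            third=rotation @ self.third,
        )


def estimate_site_frame(
    config: Configuration,
    window: list[tuple[int, int]],
    reference_nucleotide: int,
) -> LocalFrame:
    """Fit the local helical frame of a site window in one frame.

    *window* lists (scaffold, staple) nucleotide index pairs in scaffold
    5'->3' order.  The axis is the principal direction of the bp centers
    (oriented 5'->3'), the origin their centroid, and the in-plane reference
    direction comes from the designated nucleotide's backbone->base versor.
    """
    if len(window) < 3:
        raise DegeneracyError("site window must span at least 3 bp")
    pairs = np.asarray(window, dtype=np.intp)
    centers = 0.5 * (config.positions[pairs[:, 0]] + config.positions[pairs[:, 1]])
    centroid = centers.mean(0)
    dev = centers - centroid
    u_svd, s, vt = np.linalg.svd(dev, full_matrices=False)
    if s[0] < _DEGENERACY_SV_NM:
        raise DegeneracyError("window bp centers are coincident")
    axis = vt[0]
    if axis @ (centers[-1] - centers[0]) < 0:
        axis = -axis
    ref_raw = config.a1[reference_nucleotide]
    ref = ref_raw - (ref_raw @ axis) * axis
    nrm = np.linalg.norm(ref)
    if nrm < 1e-9:
        raise DegeneracyError("reference versor parallel to the site axis")
    ref = ref / nrm
    frame = LocalFrame(origin=centroid, axis=axis, reference=ref, third=np.cross(axis, ref))
    frame.validate()
    return frame
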