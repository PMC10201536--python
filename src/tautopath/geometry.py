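"""Structure observables for a hydrogen-bonded base pair.

A base pair is represented as a :class:`MolecularFrame`: labelled Cartesian
sites, two pivot sites (the backbone-attachment nitrogens, one per base)
and exactly two declared hydrogen bonds named ``B1`` and ``B2``.  The
observables defined here are the ones used throughout the pipeline:

* heavy-atom hydrogen-bond length and its extension over equilibrium,
* strand-separation distance (summed pivot displacement from a reference),
* the signed opening angle theta of the pair, and
* a normalised reaction coordinate along a chain of structures.

Sign convention for theta: positive when bond B2 is the more extended
(the pair opens from the B2 end), negative when B1 opens more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, GeometryError

__all__ = [
    "HBondSpec",
    "MolecularFrame",
    "hbond_length",
    "bond_extension",
    "separation_distance",
    "opening_angle",
    "opening_angle_or_nan",
    "normalized_reaction_coordinate",
]


@dataclass(frozen=True)
class HBondSpec:
    """Declared donor--H...acceptor triplet for one inter-base hydrogen bond."""

    donor: int
    hydrogen: int
    acceptor: int
    label: str
    eq_length: float

    def __post_init__(self):
        if self.label not in ("B1", "B2"):
            raise DomainError(f"hydrogen-bond label must be 'B1' or 'B2', got {self.label!r}")
        if len({self.donor, self.hydrogen, self.acceptor}) != 3:
            raise DomainError("donor, hydrogen and acceptor indices must be distinct")
        if self.eq_length <= 0:
            raise DomainError(f"eq_length must be positive, got {self.eq_length}")


@dataclass
class MolecularFrame:
    """Labelled 3-D structure of a base pair with pivots and declared H-bonds."""

    labels: Sequence[str]
    elements: Sequence[str]
    coords: np.ndarray
    pivot_indices: tuple[int, int]
    hbonds: Sequence[HBondSpec] = field(default_factory=list)
    equilibrium_reference: Optional[np.ndarray] = None
    comment: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DomainError("coords must be an (n, 3) array")
        if len(self.labels) != len(self.coords) or len(self.elements) != len(self.coords):
            raise DomainError("labels, elements and coords must have equal length")
        i, j = self.pivot_indices
        if i == j:
            raise DomainError("pivot indices must be distinct (one per base)")
        labels = [hb.label for hb in self.hbonds]
        if self.hbonds and sorted(labels) != ["B1", "B2"]:
            raise DomainError("exactly two hydrogen bonds labelled B1 and B2 are required")
        if self.equilibrium_reference is not None:
            self.equilibrium_reference = np.asarray(self.equilibrium_reference, dtype=float)
            if self.equilibrium_reference.shape != self.coords.shape:
                raise DomainError("equilibrium_reference must match coords in shape")

    def hbond(self, label: str) -> HBondSpec:
        for hb in self.hbonds:
            if hb.label == label:
                return hb
        raise GeometryError(f"no hydrogen bond labelled {label!r} in this frame")

    @property
    def n_sites(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularFrame":
        """Rigidly transform the frame (and its reference, if any)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        ref = self.equilibrium_reference
        if ref is not None:
            ref = ref @ rotation.T + translation
        return MolecularFrame(
            labels=list(self.labels),
            elements=list(self.elements),
            coords=self.coords @ rotation.T + translation,
            pivot_indices=self.pivot_indices,
            hbonds=list(self.hbonds),
            equilibrium_reference=ref,
            comment=self.comment,
        )


def hbond_length(frame: MolecularFrame, label: str) -> float:
    """Heavy-atom donor-to-acceptor distance of the bond ``label`` in Angstrom.

    The heavy-atom distance (rather than H...acceptor) is insensitive to
    which well the proton occupies, so canonical and tautomeric forms are
    measured on the same footing.
    """
    hb = frame.hbond(label)
    return float(np.linalg.norm(frame.coords[hb.acceptor] - frame.coords[hb.donor]))


def bond_extension(frame: MolecularFrame, label: str) -> float:
    """Bond length minus its equilibrium length (negative when compressed)."""
    hb = frame.hbond(label)
    return hbond_length(frame, label) - hb.eq_length


def separation_distance(frame: MolecularFrame) -> float:
    """Summed displacement of the two pivot sites from the reference frame."""
    if frame.equilibrium_reference is None:
        raise GeometryError("separation_distance requires an equilibrium_reference")
    total = 0.0
    for idx in frame.pivot_indices:
        total += float(np.linalg.norm(frame.coords[idx] - frame.equilibrium_reference[idx]))
    return total


def opening_angle(ext_b1: float, ext_b2: float, lever_arm: float) -> float:
    """Signed base-pair opening angle in degrees.

    theta = arcsin((ext_B2 - ext_B1) / w): positive when B2 opens more
    than B1, negative in the opposite case.
    """
    if lever_arm <= 0:
        raise DomainError(f"lever_arm must be positive, got {lever_arm}")
    ratio = (ext_b2 - ext_b1) / lever_arm
    if abs(ratio) > 1.0:
        raise GeometryError(
            f"extension difference {ext_b2 - ext_b1:.3f} A exceeds the lever arm "
            f"{lever_arm:.3f} A; the opening angle is undefined"
        )
    return float(np.degrees(np.arcsin(ratio)))


def opening_angle_or_nan(ext_b1, ext_b2, lever_arm: float):
    """Vectorised opening angle that yields NaN where the arcsine is undefined.

    Used by the dynamics module, where fully broken bonds routinely push the
    extension difference past the lever arm.
    """
    ratio = (np.asarray(ext_b2, dtype=float) - np.asarray(ext_b1, dtype=float)) / lever_arm
    with np.errstate(invalid="ignore"):
        out = np.degrees(np.arcsin(np.where(np.abs(ratio) <= 1.0, ratio, np.nan)))
    return out


def _bond_difference_descriptor(frame: MolecularFrame) -> np.ndarray:
    """Per-frame reaction-path descriptor: difference of the two donor-to-acceptor
    bond vectors.  The cumulative arc length of this descriptor along a chain of
    frames defines the reaction coordinate."""
    b1 = frame.hbond("B1")
    b2 = frame.hbond("B2")
    v1 = frame.coords[b1.acceptor] - frame.coords[b1.donor]
    v2 = frame.coords[b2.acceptor] - frame.coords[b2.donor]
    return v1 - v2


def normalized_reaction_coordinate(path) -> np.ndarray:
    """Normalised cumulative arc length along a reaction path, in [0, 1].

    ``path`` may be a ``PathImageSet`` (reduced-coordinate images), a plain
    sequence of coordinate vectors, or a sequence of :class:`MolecularFrame`
    objects (in which case the bond-vector-difference descriptor is used).
    Endpoints map exactly to 0 and 1; the result is non-decreasing.
    """
    images = getattr(path, "images", path)
    if len(images) < 2:
        raise DomainError("a reaction path needs at least 2 images")
    if isinstance(images[0], MolecularFrame):
        pts = np.array([_bond_difference_descriptor(f) for f in images], dtype=float)
    else:
        pts = np.asarray(images, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(steps.sum())
    if total == 0.0:
        raise DomainError("degenerate path: all images coincide")
    s = np.concatenate([[0.0], np.cumsum(steps)]) / total
    s[-1] = 1.0
    return s
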