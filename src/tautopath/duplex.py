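"""Coarse-grained double-stranded duplex for steered unzipping dynamics.

Each nucleotide is three beads: a backbone bead plus a near-rigid base
triangle carrying a B1 site and a B2 site separated by the lever arm w.
The two strands face each other across the pair axis; every base pair is
held by two breakable Morse hydrogen bonds (B1 between the B1 sites, B2
between the B2 sites), with B1 the deeper (stronger) of the two under
the default parameters.  Adjacent nucleotides of a strand are coupled by
harmonic stacking springs between their backbone beads and by
base-stacking springs between vertically adjacent bonding sites, which
give the strand its ladder rigidity and let the peel front propagate
pair by pair during unzipping.

Geometry (pair i at height z = i * rise): backbone beads at x = +-x_bb,
bonding sites at x = +-x_site, one site per base at z + w/2 (the
fork-proximal side, toward the pulled terminal pair) and one at z - w/2.
The *deeper* of the two hydrogen bonds is attached on the fork-proximal
side, mirroring the A-T pair where the stronger bond faces the
replication fork; because the placement follows the depth ordering,
exchanging the two Morse depths relabels the model into its exact mirror
image.

The built configuration is the exact mechanical equilibrium: every
spring is at rest length and every Morse bond at its minimum.  The
terminal pair (largest i) is the one pulled apart by the steering
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

from .errors import DomainError

__all__ = ["DuplexModelParams", "Duplex", "build_duplex"]

#: Stiffness of the near-rigid intra-nucleotide triangle springs, eV/A^2.
RIGID_K = 30.0
#: Base-stacking contact between vertically adjacent bonding sites:
#: a breakable Morse term (stacking releases as the duplex peels).
BASE_STACK_DEPTH = 0.10   # eV
BASE_STACK_WIDTH = 1.5    # 1/A
#: Stacking rise between consecutive base pairs, A.
RISE = 3.4
#: Distance from a bonding site to its backbone bead along the pair axis, A.
BACKBONE_OFFSET = 4.0


@dataclass(frozen=True)
class DuplexModelParams:
    """Mechanical parameters of the coarse-grained duplex.

    ``morse_depth_B1 > morse_depth_B2`` is the physical default (B1 is the
    stronger bond of the A-T pair); equal depths are rejected because the
    builder needs an unambiguous depth ordering to orient the pair.
    """

    n_pairs: int = 14
    morse_depth_B1: float = 0.28   # eV
    morse_depth_B2: float = 0.22   # eV
    morse_width: float = 2.0       # 1/A
    hbond_eq_length: float = 2.9   # A
    stacking_k: float = 2.0        # eV/A^2
    lever_arm: float = 4.5         # A between the B1 and B2 attachment sites
    bead_mass: float = 150.0       # amu, every bead
    temperature: float = 310.0     # K
    friction: float = 1.0          # 1/ps
    timestep: float = 0.001        # ps (1 fs)

    def __post_init__(self):
        if self.n_pairs < 2:
            raise DomainError(f"n_pairs must be >= 2, got {self.n_pairs}")
        if self.morse_depth_B1 == self.morse_depth_B2:
            raise DomainError("the two Morse depths must differ (one bond is stronger)")
        for name in ("morse_depth_B1", "morse_depth_B2", "morse_width",
                     "hbond_eq_length", "stacking_k", "lever_arm", "bead_mass",
                     "temperature", "friction", "timestep"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, block: dict) -> "DuplexModelParams":
        unknown = set(block) - set(cls.__dataclass_fields__)
        if unknown:
            raise DomainError(f"unknown duplex parameter(s): {sorted(unknown)}")
        return cls(**block)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "DuplexModelParams":
        return replace(self, **kwargs)


class Duplex:
    """Site positions and bonded terms of the coarse-grained duplex."""

    def __init__(self, params: DuplexModelParams):
        self.params = params
        n = params.n_pairs
        w = params.lever_arm
        x_site = params.hbond_eq_length / 2.0
        x_bb = x_site + BACKBONE_OFFSET

        # the deeper bond sits on the fork-proximal (+z, toward the pulled
        # terminus) side of each pair
        if params.morse_depth_B1 > params.morse_depth_B2:
            proximal_label, distal_label = "B1", "B2"
            proximal_depth, distal_depth = params.morse_depth_B1, params.morse_depth_B2
        else:
            proximal_label, distal_label = "B2", "B1"
            proximal_depth, distal_depth = params.morse_depth_B2, params.morse_depth_B1

        # bead index layout: nucleotide (strand s, pair i) occupies
        # 3 * (s * n + i) + {0: backbone, 1: fork-proximal site, 2: distal site}
        pos = np.zeros((6 * n, 3))
        for s, sign in ((0, -1.0), (1, +1.0)):
            for i in range(n):
                base = 3 * (s * n + i)
                z = i * RISE
                pos[base + 0] = (sign * x_bb, 0.0, z)
                pos[base + 1] = (sign * x_site, 0.0, z + w / 2.0)
                pos[base + 2] = (sign * x_site, 0.0, z - w / 2.0)
        self.positions = pos
        self.n_sites = len(pos)
        self.masses = np.full(self.n_sites, params.bead_mass)

        def bead(s, i, kind):
            return 3 * (s * n + i) + kind

        hi, hj, hk, hr = [], [], [], []

        def harm(a, b, k):
            hi.append(a)
            hj.append(b)
            hk.append(k)
            hr.append(float(np.linalg.norm(pos[a] - pos[b])))

        # near-rigid nucleotide triangles
        for s in range(2):
            for i in range(n):
                b, s1, s2 = bead(s, i, 0), bead(s, i, 1), bead(s, i, 2)
                harm(b, s1, RIGID_K)
                harm(b, s2, RIGID_K)
                harm(s1, s2, RIGID_K)
        # stacking springs between consecutive backbone beads of a strand
        for s in range(2):
            for i in range(n - 1):
                harm(bead(s, i, 0), bead(s, i + 1, 0), params.stacking_k)

        self.harm_i = np.array(hi)
        self.harm_j = np.array(hj)
        self.harm_k = np.array(hk, dtype=float)
        self.harm_r0 = np.array(hr)

        # inter-strand Morse hydrogen bonds (two per pair)
        mi, mj, md, mlab = [], [], [], []
        for i in range(n):
            mi.append(bead(0, i, 1))
            mj.append(bead(1, i, 1))
            md.append(proximal_depth)
            mlab.append(proximal_label)
            mi.append(bead(0, i, 2))
            mj.append(bead(1, i, 2))
            md.append(distal_depth)
            mlab.append(distal_label)
        self.morse_i = np.array(mi)
        self.morse_j = np.array(mj)
        self.morse_depth = np.array(md)
        self.morse_labels = list(mlab)
        self.morse_a = params.morse_width
        self.morse_r0 = params.hbond_eq_length

        # breakable base-stacking contacts between vertically adjacent
        # bonding sites of a strand (fork-proximal site of pair i touches
        # the fork-distal site of pair i+1).  These anchor every site to
        # the stack below it, so the peel front must release contact after
        # contact instead of flipping a base out in one move; the terminal
        # pair's fork-proximal sites carry no such anchor, which is what
        # directs the unzipping to start on the fork-proximal bond.
        si, sj, sr = [], [], []
        for s in range(2):
            for i in range(n - 1):
                a, b = bead(s, i, 1), bead(s, i + 1, 2)
                si.append(a)
                sj.append(b)
                sr.append(float(np.linalg.norm(pos[a] - pos[b])))
        self.stack_i = np.array(si)
        self.stack_j = np.array(sj)
        self.stack_r0 = np.array(sr)
        self.stack_depth = BASE_STACK_DEPTH
        self.stack_a = BASE_STACK_WIDTH

        # per-pair site bookkeeping by bond label
        label_kind = {proximal_label: 1, distal_label: 2}
        self.backbone = {(s, i): bead(s, i, 0) for s in range(2) for i in range(n)}
        self.b1_sites = [(bead(0, i, label_kind["B1"]), bead(1, i, label_kind["B1"]))
                         for i in range(n)]
        self.b2_sites = [(bead(0, i, label_kind["B2"]), bead(1, i, label_kind["B2"]))
                         for i in range(n)]
        self.terminal_pair = n - 1

    # -- energetics ---------------------------------------------------------

    @property
    def n_hbonds(self) -> int:
        return len(self.morse_i)

    def energy(self, pos: np.ndarray) -> float:
        """Total potential energy (eV) of configuration ``pos``."""
        dh = pos[self.harm_i] - pos[self.harm_j]
        rh = np.linalg.norm(dh, axis=1)
        e = 0.5 * np.sum(self.harm_k * (rh - self.harm_r0) ** 2)
        dm = pos[self.morse_i] - pos[self.morse_j]
        rm = np.linalg.norm(dm, axis=1)
        x = np.exp(-self.morse_a * (rm - self.morse_r0))
        e += np.sum(self.morse_depth * (1.0 - x) ** 2)
        ds = pos[self.stack_i] - pos[self.stack_j]
        rs = np.linalg.norm(ds, axis=1)
        xs = np.exp(-self.stack_a * (rs - self.stack_r0))
        e += self.stack_depth * np.sum((1.0 - xs) ** 2)
        return float(e)

    def forces(self, pos: np.ndarray) -> np.ndarray:
        """Forces (eV/A) on every bead, shape (N, 3)."""
        dh = pos[self.harm_i] - pos[self.harm_j]
        rh = np.linalg.norm(dh, axis=1)
        fh = self.harm_k * (rh - self.harm_r0)          # dE/dr, harmonic
        dm = pos[self.morse_i] - pos[self.morse_j]
        rm = np.linalg.norm(dm, axis=1)
        x = np.exp(-self.morse_a * (rm - self.morse_r0))
        fm = 2.0 * self.morse_depth * self.morse_a * x * (1.0 - x)
        ds = pos[self.stack_i] - pos[self.stack_j]
        rs = np.linalg.norm(ds, axis=1)
        xs = np.exp(-self.stack_a * (rs - self.stack_r0))
        fs = 2.0 * self.stack_depth * self.stack_a * xs * (1.0 - xs)

        idx = np.concatenate([self.harm_i, self.harm_j, self.morse_i,
                              self.morse_j, self.stack_i, self.stack_j])
        vec_h = -(fh / rh)[:, None] * dh                # force on the 'i' bead
        vec_m = -(fm / rm)[:, None] * dm
        vec_s = -(fs / rs)[:, None] * ds
        contrib = np.concatenate([vec_h, -vec_h, vec_m, -vec_m, vec_s, -vec_s])
        out = np.zeros_like(pos)
        for c in range(3):
            out[:, c] = np.bincount(idx, weights=contrib[:, c], minlength=self.n_sites)
        return out

    # -- observables --------------------------------------------------------

    def pair_extensions(self, pos: np.ndarray, pair: int) -> tuple[float, float]:
        """(B1, B2) bond extensions (A) of base pair ``pair``."""
        i1, j1 = self.b1_sites[pair]
        i2, j2 = self.b2_sites[pair]
        r1 = float(np.linalg.norm(pos[i1] - pos[j1]))
        r2 = float(np.linalg.norm(pos[i2] - pos[j2]))
        return r1 - self.morse_r0, r2 - self.morse_r0

    def pair_separation(self, pos: np.ndarray, pair: int) -> float:
        """Separation of base pair ``pair``: mean of its two bond extensions.

        In the quasi-static limit both hydrogen bonds extend at the rate
        the strands separate, so the mean extension tracks the imposed
        separation variable of the energy-surface scans while being
        invariant under rigid motion and insensitive to thermal flopping
        of the backbone beads.
        """
        e1, e2 = self.pair_extensions(pos, pair)
        return 0.5 * (e1 + e2)


def build_duplex(params: DuplexModelParams) -> Duplex:
    """Construct the coarse-grained duplex in mechanical equilibrium."""
    return Duplex(params)
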