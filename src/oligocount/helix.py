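"""Helical-symmetry arithmetic and an idealized double-helix builder.

A helical filament is described by the screw operation relating
consecutive protomers: a twist (degrees about the axis) and a rise
(Angstrom along it).  The pitch -- axial distance per full turn -- is
rise * 360 / twist.  An antiparallel two-stranded filament is generated
by applying a two-fold (dyad) rotation, about an axis perpendicular to
the helix axis, to one strand; the dyad flips the axial polarity, so the
two strands run in opposite directions.

The builder is schematic: the radius and the dyad phase are presentation
parameters (the real values are map-derived), and the protomer is
represented by a single centroid pseudo-atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HelicalSymmetry",
    "FilamentModel",
    "pitch",
    "protomers_per_turn",
    "build_double_helix",
    "export_centroids",
]


@dataclass(frozen=True)
class HelicalSymmetry:
    """Per-protomer twist (degrees) and rise (Angstrom) of a helix."""

    twist: float
    rise: float

    def __post_init__(self) -> None:
        if not 0 < self.twist <= 360:
            raise ValueError("twist must be in (0, 360] degrees")
        if self.rise <= 0:
            raise ValueError("rise must be > 0 Angstrom")


@dataclass(frozen=True)
class FilamentModel:
    """Centroid model of a (possibly multi-stranded) helical filament.

    ``strand`` holds 'A'/'B' labels, ``index`` the protomer index within
    its strand, ``xyz`` centroid coordinates in Angstrom, and ``polarity``
    the sign (+1/-1) of each protomer's axial direction.
    """

    strand: np.ndarray
    index: np.ndarray
    xyz: np.ndarray
    polarity: np.ndarray
    symmetry: HelicalSymmetry
    radius: float

    def __len__(self) -> int:
        return len(self.strand)

    def strand_coords(self, strand_id: str) -> np.ndarray:
        sel = self.strand == strand_id
        order = np.argsort(self.index[sel])
        return self.xyz[sel][order]


def pitch(sym: HelicalSymmetry) -> float:
    """Axial distance per 360-degree turn: rise * 360 / twist (Angstrom)."""
    return sym.rise * 360.0 / sym.twist


def protomers_per_turn(sym: HelicalSymmetry) -> float:
    """Number of protomers per full turn: 360 / twist."""
    return 360.0 / sym.twist


def _dyad_matrix(dyad_phase_deg: float) -> np.ndarray:
    """180-degree rotation about the in-plane axis at the given phase."""
    phi = np.deg2rad(dyad_phase_deg)
    u = np.array([np.cos(phi), np.sin(phi), 0.0])
    return 2.0 * np.outer(u, u) - np.eye(3)


def build_double_helix(
    sym: HelicalSymmetry,
    n_per_strand: int,
    radius: float = 20.0,
    dyad_phase: float = 0.0,
    handedness: str = "right",
) -> FilamentModel:
    """Generate centroids of an antiparallel double-stranded helix.

    Strand A protomer i sits at
    ``(R cos(i*twist), R sin(i*twist), i*rise)`` (twist sign set by
    ``handedness``); strand B is strand A transformed by a two-fold
    rotation about the in-plane axis at ``dyad_phase`` degrees, which
    reverses the axial polarity.
    """
    if n_per_strand < 1:
        raise ValueError("n_per_strand must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be > 0 Angstrom")
    if handedness not in ("right", "left"):
        raise ValueError("handedness must be 'right' or 'left'")

    sign = 1.0 if handedness == "right" else -1.0
    i = np.arange(n_per_strand)
    ang = sign * np.deg2rad(sym.twist) * i
    a_xyz = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), sym.rise * i]
    )
    dyad = _dyad_matrix(dyad_phase)
    b_xyz = a_xyz @ dyad.T

    return FilamentModel(
        strand=np.array(["A"] * n_per_strand + ["B"] * n_per_strand),
        index=np.concatenate([i, i]),
        xyz=np.vstack([a_xyz, b_xyz]),
        polarity=np.concatenate(
            [np.ones(n_per_strand), -np.ones(n_per_strand)]
        ).astype(int),
        symmetry=sym,
        radius=float(radius),
    )


def export_centroids(model: FilamentModel, path) -> None:
    """Write one CA pseudo-atom per protomer centroid to a PDB file.

    Strands map to chains A and B; re-reading reproduces the coordinates
    to the PDB format precision (1e-3 Angstrom).
    """
    import gemmi

    if len(model) == 0:
        raise ValueError("cannot export an empty filament model")

    structure = gemmi.Structure()
    structure.name = "filament-centroids"
    gm = gemmi.Model("1")
    for strand_id in ("A", "B"):
        sel = model.strand == strand_id
        if not np.any(sel):
            continue
        chain = gemmi.Chain(strand_id)
        for idx, xyz in zip(model.index[sel], model.xyz[sel]):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(idx) + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    structure.add_model(gm)
    structure.setup_entities()
    structure.write_pdb(str(path))
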