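"""Backbone dihedral geometry and angle normalisation.

The two torsion angles that determine protein backbone conformation are
phi (the dihedral about the N-CA bond, atoms C(i-1)-N(i)-CA(i)-C(i)) and
psi (the dihedral about the CA-C bond, atoms N(i)-CA(i)-C(i)-N(i+1)).
The peptide-bond omega dihedral is essentially fixed near 180 degrees and
is not handled here.

All angles are degrees on the half-open interval (-180, 180], with the
IUPAC sign convention: the dihedral is positive when, looking from the
second atom toward the third, the far bond is rotated clockwise relative
to the near bond.  This matches the ranges reported by DSSP.

Regression targets are not trained on raw degrees but on a normalized
scale v = 0.5 + (theta - mu) / (c * sigma), where mu and sigma are the
training-set mean and standard deviation of the angle type and c is a
span multiplier (default 6, so mu +/- 3 sigma maps onto [0, 1]).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedAngleError",
    "Residue",
    "BackboneChain",
    "TorsionRecord",
    "AngleNormalizer",
    "wrap_angle",
    "dihedral",
    "compute_backbone_torsions",
    "fit_normalizer",
    "angular_difference",
    "target_mask",
    "read_pdb_backbone",
    "build_backbone_chain",
]

# geometric tolerance for degenerate (collinear / coincident) atom placements
_DEGENERATE_TOL = 1e-8


class UndefinedAngleError(ValueError):
    """Raised when a dihedral is geometrically undefined (collinear or
    coincident points)."""


def wrap_angle(theta):
    """Wrap an angle (or array of angles) in degrees onto (-180, 180]."""
    t = np.asarray(theta, dtype=float)
    w = -((-t + 180.0) % 360.0 - 180.0)
    return float(w) if w.ndim == 0 else w


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle, in degrees, defined by four points.

    Parameters are any length-3 coordinate sequences (Angstroms).  The
    angle is about the p2-p3 axis; sign follows the IUPAC convention
    (clockwise positive viewed from p2 toward p3).

    Raises
    ------
    UndefinedAngleError
        If consecutive points coincide or either atom triple is collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < _DEGENERATE_TOL:
        raise UndefinedAngleError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERATE_TOL or np.linalg.norm(n2) < _DEGENERATE_TOL:
        raise UndefinedAngleError("collinear points: dihedral undefined")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(y, np.dot(n1, n2)))
    return wrap_angle(ang)


@dataclass
class Residue:
    """One residue's backbone atoms.  Missing atoms are ``None`` and mark
    the residue as incomplete."""

    name: str                      # 3-letter residue code
    seq_position: str              # author numbering, insertion code preserved
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None

    @property
    def complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None


@dataclass
class BackboneChain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


@dataclass
class TorsionRecord:
    """Observed (phi, psi) for one residue; NaN marks an undefined angle."""

    phi: float = math.nan
    psi: float = math.nan


def compute_backbone_torsions(chain: BackboneChain) -> list[TorsionRecord]:
    """Compute per-residue (phi, psi) from backbone coordinates.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1).  Angles that lack a neighbour (chain termini) or involve an
    incomplete residue are NaN.
    """
    if not chain.residues:
        raise ValueError("chain has no residues")
    out: list[TorsionRecord] = []
    res = chain.residues
    for i, r in enumerate(res):
        rec = TorsionRecord()
        if not r.complete:
            logger.warning(
                "chain %s residue %s (%s) missing backbone atoms; angles undefined",
                chain.chain_id, r.seq_position, r.name)
            out.append(rec)
            continue
        prev = res[i - 1] if i > 0 else None
        nxt = res[i + 1] if i + 1 < len(res) else None
        if prev is not None and prev.c is not None:
            try:
                rec.phi = dihedral(prev.c, r.n, r.ca, r.c)
            except UndefinedAngleError:
                logger.warning("degenerate phi geometry at %s:%s",
                               chain.chain_id, r.seq_position)
        if nxt is not None and nxt.n is not None:
            try:
                rec.psi = dihedral(r.n, r.ca, r.c, nxt.n)
            except UndefinedAngleError:
                logger.warning("degenerate psi geometry at %s:%s",
                               chain.chain_id, r.seq_position)
        out.append(rec)
    return out


@dataclass
class AngleNormalizer:
    """Linear map between degrees and the unitless SVR target scale.

    normalize:   v = 0.5 + (theta - mu) / (span_multiplier * sigma)
    denormalize: theta = wrap(mu + (v - 0.5) * span_multiplier * sigma)

    With the default span multiplier of 6, angles within mu +/- 3 sigma
    land inside [0, 1].
    """

    mu_phi: float
    sigma_phi: float
    mu_psi: float
    sigma_psi: float
    span_multiplier: float = 6.0

    def __post_init__(self):
        if self.sigma_phi <= 0 or self.sigma_psi <= 0:
            raise ValueError("angle standard deviations must be positive")
        if self.span_multiplier <= 0:
            raise ValueError("span_multiplier must be positive")

    def _params(self, which: str) -> tuple[float, float]:
        if which == "phi":
            return self.mu_phi, self.sigma_phi
        if which == "psi":
            return self.mu_psi, self.sigma_psi
        raise ValueError(f"unknown angle type {which!r}")

    def normalize(self, theta, which: str):
        mu, sigma = self._params(which)
        t = np.asarray(theta, dtype=float)
        v = 0.5 + (t - mu) / (self.span_multiplier * sigma)
        return float(v) if v.ndim == 0 else v

    def denormalize(self, v, which: str):
        mu, sigma = self._params(which)
        val = np.asarray(v, dtype=float)
        theta = mu + (val - 0.5) * self.span_multiplier * sigma
        return wrap_angle(theta)


def fit_normalizer(phi_values: Iterable[float], psi_values: Iterable[float],
                   span_multiplier: float = 6.0) -> AngleNormalizer:
    """Fit per-angle mean and sample standard deviation (ddof=1).

    NaN entries (undefined angles) are ignored.  Raises ``ValueError`` on
    fewer than two defined values or zero variance for either angle type.
    """
    stats = {}
    for name, values in (("phi", phi_values), ("psi", psi_values)):
        arr = np.asarray(list(values), dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise ValueError(f"need >= 2 defined {name} values to fit normalizer")
        sd = float(np.std(arr, ddof=1))
        if sd <= 0:
            raise ValueError(f"zero variance in {name} values")
        stats[name] = (float(np.mean(arr)), sd)
    return AngleNormalizer(mu_phi=stats["phi"][0], sigma_phi=stats["phi"][1],
                           mu_psi=stats["psi"][0], sigma_psi=stats["psi"][1],
                           span_multiplier=span_multiplier)


def angular_difference(a, b, mode: str = "circular"):
    """Absolute difference between angles in degrees.

    mode="circular": shortest arc on the circle, in [0, 180].
    mode="linear":   plain |a - b|, ignoring periodicity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "linear":
        d = np.abs(a - b)
    elif mode == "circular":
        d = np.abs(a - b) % 360.0
        d = np.minimum(d, 360.0 - d)
    else:
        raise ValueError(f"unknown difference mode {mode!r}")
    return float(d) if d.ndim == 0 else d


def target_mask(torsions: Sequence[TorsionRecord], which: str,
                extra_trim: int = 0) -> np.ndarray:
    """Boolean mask of residues usable as prediction targets.

    A residue is usable when its angle is geometrically defined; an
    optional ``extra_trim`` additionally drops that many residues from
    each chain end (some benchmark protocols discard a few terminal
    residues beyond the geometrically undefined ones).
    """
    vals = np.array([getattr(t, which) for t in torsions], dtype=float)
    mask = np.isfinite(vals)
    if extra_trim > 0:
        mask[:extra_trim] = False
        if extra_trim <= len(mask):
            mask[len(mask) - extra_trim:] = False
    return mask


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_pdb_backbone(source) -> list[BackboneChain]:
    """Read N/CA/C backbone coordinates from a PDB file (path or handle).

    Uses the first model; HETATM residues are skipped; for alternate
    locations the 'A' (or blank) conformer is kept; insertion codes are
    preserved in ``seq_position``.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Atom import DisorderedAtom

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("chain", source)
    model = next(structure.get_models())
    chains: list[BackboneChain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip():
                continue
            r = Residue(name=res.get_resname(),
                        seq_position=f"{resseq}{icode.strip()}")
            for attr, atname in (("n", "N"), ("ca", "CA"), ("c", "C")):
                if atname not in res:
                    continue
                atom = res[atname]
                if isinstance(atom, DisorderedAtom):
                    ids = atom.disordered_get_id_list()
                    pick = "A" if "A" in ids else ids[0]
                    atom = atom.disordered_get(pick)
                setattr(r, attr, np.array(atom.get_coord(), dtype=float))
            residues.append(r)
        if residues:
            chains.append(BackboneChain(chain_id=ch.get_id(), residues=residues))
    if not chains:
        raise ValueError("no protein chains with backbone atoms found")
    return chains


# ---------------------------------------------------------------------------
# Internal-coordinate chain builder
# ---------------------------------------------------------------------------

# idealised backbone covalent geometry (Angstroms / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d such that |cd|=bond, angle(b,c,d)=angle and
    dihedral(a,b,c,d)=torsion (natural-extension / NeRF construction)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_backbone_chain(phi: Sequence[float], psi: Sequence[float],
                         residue_names: Sequence[str] | None = None,
                         omega: float = 180.0,
                         chain_id: str = "A") -> BackboneChain:
    """Build idealized backbone coordinates from torsion angles.

    ``phi[0]`` and ``psi[-1]`` are ignored (they do not affect internal
    geometry); standard bond lengths and angles are used throughout and
    every peptide bond takes the given omega (trans by default).  Useful
    for constructing toy structures with known torsions.
    """
    n_res = len(phi)
    if len(psi) != n_res or n_res < 1:
        raise ValueError("phi and psi must have equal positive length")
    if residue_names is None:
        residue_names = ["ALA"] * n_res

    # seed the first three atoms in a canonical pose
    coords: list[np.ndarray] = [np.array([0.0, 0.0, 0.0])]  # N1
    coords.append(coords[0] + np.array([_BOND_N_CA, 0.0, 0.0]))  # CA1
    ang = math.radians(_ANGLE_N_CA_C)
    coords.append(coords[1] + _BOND_CA_C * np.array([math.cos(math.pi - ang),
                                                     math.sin(math.pi - ang),
                                                     0.0]))  # C1
    # atom sequence per residue i>0: N(i) [omega], CA(i) [phi], C(i) [psi]
    for i in range(1, n_res):
        coords.append(_place_atom(coords[-3], coords[-2], coords[-1],
                                  _BOND_C_N, _ANGLE_CA_C_N, psi[i - 1]))
        coords.append(_place_atom(coords[-3], coords[-2], coords[-1],
                                  _BOND_N_CA, _ANGLE_C_N_CA, omega))
        coords.append(_place_atom(coords[-3], coords[-2], coords[-1],
                                  _BOND_CA_C, _ANGLE_N_CA_C, phi[i]))
    residues = [
        Residue(name=residue_names[i], seq_position=str(i + 1),
                n=coords[3 * i], ca=coords[3 * i + 1], c=coords[3 * i + 2])
        for i in range(n_res)
    ]
    return BackboneChain(chain_id=chain_id, residues=residues)
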