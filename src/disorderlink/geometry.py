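"""Per-residue and residue-pair structural operators.

Implements the geometric feature set used in the site analysis: the
closest-long-range-contact (CLRC) search with the Cbeta (Calpha for glycine)
distance convention, bond-direction cosines between residue pairs,
backbone phi/psi dihedrals with circular statistics, Shrake-Rupley solvent
accessible surface area with relative accessibility, a Ramachandran-region
3-state secondary-structure assignment (with an optional precomputed 8-state
ingestion backend), and least-squares rigid superposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from scipy.stats import circmean, circstd

from ._tables import BONDI_RADII, DEFAULT_VDW_RADIUS, MAX_ASA_TIEN2013
from .structure_io import ChainStructure, ResidueStructure

PEPTIDE_BOND_MAX = 2.5  # Angstrom; larger C-N distances mark a chain break


@dataclass
class ContactAssignment:
    """Closest long-range contact of residue ``i`` (indices into chain.residues)."""

    i: int
    j: int
    distance: float


@dataclass
class ResidueGeometry:
    asa: float
    rsa: float
    phi: float | None
    psi: float | None
    ss3: str  # one of 'h', 'c', 'e'


@dataclass
class PairCosines:
    c1: float  # N->CA bond direction cosine
    c2: float  # CA->C
    c3: float  # CA->CB, 0.0 when either residue is GLY / lacks CB


# ---------------------------------------------------------------------------
# distances and contacts


def _rep_atom(res: ResidueStructure) -> np.ndarray | None:
    """Cbeta, falling back to Calpha (glycine or missing Cbeta)."""
    xyz = res.atoms.get("CB")
    if xyz is None:
        xyz = res.atoms.get("CA")
    return xyz


def residue_distance(a: ResidueStructure, b: ResidueStructure) -> float | None:
    """Distance between representative atoms (CB, CA for GLY); None if undefined."""
    pa, pb = _rep_atom(a), _rep_atom(b)
    if pa is None or pb is None:
        return None
    return float(np.linalg.norm(pa - pb))


def find_clrc(chain: ChainStructure, i: int, min_separation: int = 5) -> ContactAssignment | None:
    """Closest residue in space with author-numbering separation > min_separation.

    Ties in distance are broken toward the lowest residue index.  Returns
    None when no eligible residue with a defined distance exists.
    """
    contacts = find_all_clrcs(chain, min_separation)
    return contacts.get(i)


def find_all_clrcs(chain: ChainStructure, min_separation: int = 5) -> dict[int, ContactAssignment]:
    """CLRC for every residue of the chain at once (vectorized)."""
    n = len(chain.residues)
    reps = np.full((n, 3), np.nan)
    for k, res in enumerate(chain.residues):
        xyz = _rep_atom(res)
        if xyz is not None:
            reps[k] = xyz
    have = np.all(np.isfinite(reps), axis=1)
    seq = np.array([r.seq_num for r in chain.residues], dtype=float)
    D = cdist(reps, reps)
    eligible = np.abs(seq[:, None] - seq[None, :]) > min_separation
    eligible &= have[:, None] & have[None, :]
    D = np.where(eligible, D, np.inf)
    out: dict[int, ContactAssignment] = {}
    for i in range(n):
        j = int(np.argmin(D[i]))  # argmin takes the lowest index on ties
        if np.isfinite(D[i, j]):
            out[i] = ContactAssignment(i, j, float(D[i, j]))
    return out


def pair_cosines(a: ResidueStructure, b: ResidueStructure) -> PairCosines | None:
    """Cosines between the N-CA, CA-C and CA-CB bond directions of two residues."""

    def _unit(res: ResidueStructure, a1: str, a2: str) -> np.ndarray | None:
        p, q = res.atoms.get(a1), res.atoms.get(a2)
        if p is None or q is None:
            return None
        v = q - p
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            return None
        return v / norm

    cos = []
    for a1, a2 in (("N", "CA"), ("CA", "C")):
        ua, ub = _unit(a, a1, a2), _unit(b, a1, a2)
        if ua is None or ub is None:
            return None
        cos.append(float(np.clip(np.dot(ua, ub), -1.0, 1.0)))
    if a.res_type == "G" or b.res_type == "G":
        c3 = 0.0
    else:
        ua, ub = _unit(a, "CA", "CB"), _unit(b, "CA", "CB")
        c3 = 0.0 if ua is None or ub is None else float(np.clip(np.dot(ua, ub), -1.0, 1.0))
    return PairCosines(cos[0], cos[1], c3)


# ---------------------------------------------------------------------------
# dihedrals


def _dihedral(p0, p1, p2, p3) -> float | None:
    pts = [gemmi.Position(*p) for p in (p0, p1, p2, p3)]
    ang = np.degrees(gemmi.calculate_dihedral(*pts))
    if not np.isfinite(ang):
        return None
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _bonded(prev: ResidueStructure, res: ResidueStructure) -> bool:
    """Consecutive in author numbering and peptide C-N distance below 2.5 A."""
    if res.seq_num - prev.seq_num > 1:
        return False
    c, n = prev.atoms.get("C"), res.atoms.get("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c - n)) <= PEPTIDE_BOND_MAX


def backbone_dihedrals(chain: ChainStructure, i: int) -> tuple[float | None, float | None]:
    """(phi, psi) of residue i in degrees, IUPAC convention; None at breaks/termini."""
    res = chain.residues[i]
    phi = psi = None
    need = ("N", "CA", "C")
    if any(res.atoms.get(a) is None for a in need):
        return None, None
    if i > 0:
        prev = chain.residues[i - 1]
        if _bonded(prev, res) and prev.atoms.get("C") is not None:
            phi = _dihedral(prev.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"])
    if i + 1 < len(chain.residues):
        nxt = chain.residues[i + 1]
        if _bonded(res, nxt) and nxt.atoms.get("N") is not None:
            psi = _dihedral(res.atoms["N"], res.atoms["CA"], res.atoms["C"], nxt.atoms["N"])
    return phi, psi


def circular_stats(angles) -> tuple[float, float]:
    """Circular mean and circular standard deviation, both in degrees.

    The SD is sqrt(-2 ln Rbar) (directional-statistics convention) scaled to
    degrees.  Raises on empty input.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size == 0:
        raise ValueError("circular statistics of an empty angle set")
    mean = float(circmean(arr, high=180.0, low=-180.0))
    if mean <= -180.0:
        mean += 360.0
    sd = float(circstd(arr, high=180.0, low=-180.0))
    return mean, sd


# ---------------------------------------------------------------------------
# accessible surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_asa(
    chain: ChainStructure, probe_radius: float = 1.4, n_points: int = 960
) -> dict[int, float]:
    """Per-residue solvent accessible surface area in A^2.

    Sphere-point sampling over heavy atoms with Bondi van der Waals radii and
    a water-sized probe; each atom's accessible fraction is the share of its
    sample points not buried inside any neighbour's solvent-expanded sphere.
    """
    coords, radii, res_of = [], [], []
    for k, res in enumerate(chain.residues):
        for name, xyz in res.atoms.items():
            elem = res.elements.get(name, name[:1]).upper()
            if elem == "H":
                continue
            r = BONDI_RADII.get(elem)
            if r is None:
                warnings.warn(f"unknown element {elem!r}; using vdW radius "
                              f"{DEFAULT_VDW_RADIUS} A")
                r = DEFAULT_VDW_RADIUS
            coords.append(xyz)
            radii.append(r + probe_radius)
            res_of.append(k)
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    sphere = _sphere_points(n_points)
    n_atoms = len(coords)
    asa_per_res: dict[int, float] = {k: 0.0 for k in range(len(chain.residues))}
    if n_atoms == 0:
        return asa_per_res
    D = cdist(coords, coords)
    for a in range(n_atoms):
        pts = coords[a] + radii[a] * sphere
        neigh = np.where((D[a] < radii[a] + radii) & (np.arange(n_atoms) != a))[0]
        if neigh.size:
            d2 = cdist(pts, coords[neigh], "sqeuclidean")
            buried = np.any(d2 < (radii[neigh] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        asa_per_res[res_of[a]] += frac * 4.0 * np.pi * radii[a] ** 2
    return asa_per_res


def relative_asa(res_type: str, asa: float) -> float | None:
    """ASA normalized by the residue type's theoretical maximum; None for unknown types."""
    ref = MAX_ASA_TIEN2013.get(res_type)
    if ref is None:
        return None
    return asa / ref


# ---------------------------------------------------------------------------
# secondary structure


def assign_ss3(phi: float | None, psi: float | None) -> str:
    """3-state secondary structure from backbone dihedral regions.

    Helix: phi in [-100,-30] and psi in [-80,-5]; sheet: phi in
    [-180,-100] or [160,180] with psi in [80,180] or [-180,-170];
    everything else (including undefined angles) is coil.
    """
    if phi is None or psi is None:
        return "c"
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "h"
    if (-180.0 <= phi <= -100.0 or 160.0 <= phi <= 180.0) and (
        80.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0
    ):
        return "e"
    return "c"


def ss8_to_ss3(ss8: str) -> str:
    """Map an 8-state secondary-structure code to 3 states (H,G,I->h; E,B->e)."""
    ss8 = ss8.upper()
    if ss8 in ("H", "G", "I"):
        return "h"
    if ss8 in ("E", "B"):
        return "e"
    return "c"


def read_dssp_ss(path: str | Path, chain: str) -> dict[tuple[int, str], str]:
    """Read 8-state assignments from a classic columnar .dssp file.

    Returns {(residue number, insertion code): 8-state letter} for the chain;
    use with :func:`ss8_to_ss3` as the precomputed-assignment backend.
    """
    out: dict[tuple[int, str], str] = {}
    in_body = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("  #  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 17:
            continue
        if line[13] == "!":  # chain break record
            continue
        if line[11] != chain:
            continue
        try:
            num = int(line[5:10])
        except ValueError:
            continue
        icode = line[10].strip()
        ss = line[16].strip() or "C"
        out[(num, icode)] = ss
    return out


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Q onto P.

    Returns (rotation matrix R, translation t, rmsd) with det(R) = +1 such
    that Q @ R.T + t approximates P.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(np.vstack([P0, Q0])) < 2:
        raise ValueError("rank-deficient (collinear) coordinate sets")
    rot, rssd = Rotation.align_vectors(P0, Q0)
    R = rot.as_matrix()
    t = pc - qc @ R.T
    rmsd = float(rssd / np.sqrt(n))
    return R, t, rmsd


def chain_geometry(
    chain: ChainStructure,
    ss_lookup: dict[tuple[int, str], str] | None = None,
) -> list[ResidueGeometry]:
    """Precompute ASA/RSA, dihedrals and secondary structure for every residue.

    ``ss_lookup`` optionally supplies precomputed 8-state assignments keyed by
    (residue number, insertion code) — e.g. from :func:`read_dssp_ss` — which
    override the dihedral-region default.
    """
    asa = shrake_rupley_asa(chain)
    out = []
    for i, res in enumerate(chain.residues):
        phi, psi = backbone_dihedrals(chain, i)
        if ss_lookup is not None and (res.seq_num, res.icode) in ss_lookup:
            ss3 = ss8_to_ss3(ss_lookup[(res.seq_num, res.icode)])
        else:
            ss3 = assign_ss3(phi, psi)
        rsa = relative_asa(res.res_type, asa[i])
        out.append(ResidueGeometry(asa[i], rsa if rsa is not None else np.nan, phi, psi, ss3))
    return out
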