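"""Template-Modeling score under a fixed residue correspondence.

TM-score = max over superpositions of (1/Lt) * sum_i 1/(1 + (d_i/d0)^2),
with d0 = 1.24 (Lt - 15)^(1/3) - 1.8, d_i the Calpha distances of aligned
pairs after superposition, Lt the target length and La the number of aligned
pairs.  The score is length-independent by construction and equals 1 for a
perfect match; > 0.5 indicates the same fold.

The residue correspondence here is fixed (taken from the family MSA, or the
identity for same-length comparisons) and only the rigid superposition is
optimized — iterative least-squares refinement with distance-based pair
rejection, seeded from contiguous fragments.  A full search over alternative
alignments (as structure-alignment tools perform) is intentionally not done,
and results should be read as fixed-alignment scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .structure_io import ChainStructure


@dataclass
class TMResult:
    Lt: int
    La: int
    d0: float
    score: float


def d0(Lt: int) -> float:
    """Scaling distance d0 = 1.24 (Lt - 15)^(1/3) - 1.8 A, clamped below at 0.5 A."""
    if Lt > 15:
        val = 1.24 * (Lt - 15) ** (1.0 / 3.0) - 1.8
    else:
        val = -np.inf
    if val <= 0.5:
        warnings.warn(f"d0 formula gives {val:.3f} A for Lt={Lt}; clamping to 0.5 A")
        return 0.5
    return float(val)


def _objective(P: np.ndarray, Q: np.ndarray, R, t, d0_val: float, Lt: int):
    moved = Q @ R.T + t
    d = np.linalg.norm(moved - P, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0_val) ** 2)) / Lt), d


def tm_score(
    target: ChainStructure,
    mobile: ChainStructure,
    pairs: list[tuple[int, int]] | None = None,
) -> TMResult:
    """TM-score of ``mobile`` against ``target`` for a fixed residue correspondence.

    ``pairs`` are (target residue index, mobile residue index) pairs; the
    identity correspondence is used when omitted and both chains have equal
    length.  Pairs lacking a Calpha on either side are dropped.
    """
    if pairs is None:
        if target.n_residues != mobile.n_residues:
            raise ValueError("identity correspondence requires equal-length chains")
        pairs = [(i, i) for i in range(target.n_residues)]
    P, Q = [], []
    for it, im in pairs:
        ca_t = target.residues[it].atoms.get("CA")
        ca_m = mobile.residues[im].atoms.get("CA")
        if ca_t is not None and ca_m is not None:
            P.append(ca_t)
            Q.append(ca_m)
    La = len(P)
    if La < 3:
        raise ValueError("fewer than 3 aligned residue pairs with Calpha coordinates")
    P = np.asarray(P)
    Q = np.asarray(Q)
    Lt = target.n_residues
    d0_val = d0(Lt)
    cutoff = max(2.0 * d0_val, 4.5)

    best = -1.0
    seeds = []
    for frac in (1.0, 0.5, 0.25):
        ell = max(3, int(round(La * frac)))
        step = max(1, ell // 2)
        for start in range(0, La - ell + 1, step):
            seeds.append(np.arange(start, start + ell))
    for seed_idx in seeds:
        idx = seed_idx
        prev_obj = -np.inf
        for _ in range(60):
            try:
                R, t, _ = kabsch_superpose(P[idx], Q[idx])
            except ValueError:
                break
            obj, d = _objective(P, Q, R, t, d0_val, Lt)
            if obj > best:
                best = obj
            keep = np.where(d <= cutoff)[0]
            if keep.size < 3:
                break
            if abs(obj - prev_obj) < 1e-6 and keep.size == idx.size and np.array_equal(keep, idx):
                break
            prev_obj = obj
            idx = keep
    return TMResult(Lt, La, d0_val, best)


def family_tm_scores(
    seed_chain: ChainStructure,
    chains: dict[str, ChainStructure],
    pair_maps: dict[str, list[tuple[int, int]]],
) -> dict[str, TMResult]:
    """TM-scores of every family member against the seed structure."""
    out = {}
    for pid, ch in chains.items():
        try:
            out[pid] = tm_score(seed_chain, ch, pair_maps[pid])
        except (ValueError, KeyError):
            continue
    return out
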