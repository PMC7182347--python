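"""Synthetic families of mutated homologs sharing a backbone.

The generator emulates the inputs of the site analysis without any database
access: an ideal-geometry seed backbone realizing a prescribed secondary-
structure layout, mutated member sequences (BLOSUM-weighted substitutions),
member structures as the noisy seed backbone with disordered segments
removed from the coordinate records and written as REMARK 465 entries,
occasional sequence/structure residue-type mismatches, whole-segment
deletions (alignment gaps), and the alignment itself emitted from the known
residue homology.

The default layout packs two antiparallel strands into a hairpin next to two
helices and routes a long exposed coil loop between them; the disorder
segment sits on that loop.  This plants the qualitative couplings the
analysis is meant to detect: disordered sites are exposed (positive
delta-RSA coupling), their contact distances are larger and noisier
(positive delta-dav and delta-dsd couplings), and they carry no sheet
propensity (negative delta-ss1e coupling).  Coupling magnitudes are
configuration knobs, not constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np

from ._tables import AA1
from .alignment_sites import MSA, write_msa
from .structure_io import (
    ChainStructure,
    FullSequence,
    MissingResidue,
    ResidueStructure,
    write_fasta,
    write_pdb_chain,
)

# ideal backbone geometry (lengths in Angstrom, angles in degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB = 111.0, 116.2, 121.7, 120.8, 110.5

HELIX = (-57.0, -47.0)
STRAND = (-120.0, 130.0)
COIL_EXTENDED = (-80.0, 145.0)  # polyproline-II-like; assigned 'c' by the 3-state scheme
# Torsions of a tight two-residue chain reversal that packs two flanking
# strands into an antiparallel hairpin (CA pair distances ~5 A).
HAIRPIN_TURN = ((49.1, 149.6), (-0.9, 23.9))

# approximate natural amino-acid frequencies for seed sequences
_AA_FREQ = {
    "A": 8.3, "R": 5.5, "N": 4.1, "D": 5.5, "C": 1.4, "Q": 3.9, "E": 6.8,
    "G": 7.1, "H": 2.3, "I": 5.9, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.4, "W": 1.1, "Y": 2.9, "V": 6.9,
}


@dataclass
class FamilyConfig:
    """Parameters of the synthetic homolog-family generator."""

    n_proteins: int = 40
    length: int = 120
    seed: int = 0
    mutation_rate: float = 0.10
    disorder_segments: list[tuple[int, int, float]] | None = None
    coord_noise_core: float = 0.25
    coord_noise_near_disorder: float = 1.2
    mismatch_rate: float = 0.02
    gap_rate: float = 0.05
    segment_jitter: int = 3
    ss_layout: list[tuple[int, int, str]] | None = None

    def resolved_layout(self) -> list[tuple[int, int, str]]:
        return self.ss_layout if self.ss_layout is not None else default_ss_layout(self.length)

    def resolved_segments(self) -> list[tuple[int, int, float]]:
        if self.disorder_segments is not None:
            return self.disorder_segments
        seg = default_disorder_segment(self.resolved_layout(), self.length)
        return [seg] if seg is not None else []

    def validate(self) -> None:
        for p in (self.mutation_rate, self.mismatch_rate, self.gap_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for start, end, p in self.resolved_segments():
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"disorder segment ({start},{end}) outside [1,{self.length}]")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"disorder probability {p} outside [0, 1]")
            if p == 1.0 and self.n_proteins < 20:
                raise ValueError(
                    "disorder probability 1.0 with fewer than 20 proteins: such a "
                    "site can never pass the >=20 residue-count filter as ordered"
                )
        if self.coord_noise_core < 0 or self.coord_noise_near_disorder < 0:
            raise ValueError("coordinate noise must be >= 0")
        layout = self.resolved_layout()
        covered = sorted((s, e) for s, e, _ in layout)
        pos = 1
        for s, e in covered:
            if s != pos:
                raise ValueError(f"ss_layout gap/overlap at position {pos}")
            pos = e + 1
        if pos != self.length + 1:
            raise ValueError("ss_layout does not cover the full chain")


@dataclass
class FamilyTruth:
    """Ground truth recorded before noise: what the analysis should recover."""

    disorder_prob: list[float]      # per site, 1-based order
    ss_label: list[str]             # per site: h/c/e from the layout
    exposure: list[str]             # per site: exposed/intermediate/buried
    planted_signs: dict[str, int] = field(
        default_factory=lambda: {
            "delta_dav": 1, "delta_dsd": 1, "delta_ra1av": 1, "delta_ss1e": -1,
        }
    )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class FamilyData:
    config: FamilyConfig
    truth: FamilyTruth
    seed_chain: ChainStructure
    chains: dict[str, ChainStructure]
    sequences: list[FullSequence]
    msa: MSA
    pdb_dir: Path | None = None
    fasta_path: Path | None = None
    msa_path: Path | None = None
    truth_path: Path | None = None
    seed_pdb_path: Path | None = None


def default_ss_layout(length: int) -> list[tuple[int, int, str]]:
    """Helix / strand-hairpin / exposed-coil-loop / helix layout scaled to ``length``.

    The template at length 120 is helix 1-40, coil 41-44, strand 45-52, turn
    53-54, strand 55-62, exposed coil loop 63-90, helix 91-120.
    """
    if length < 60:
        # short chains: single helix + coil tail, no hairpin
        h = max(10, length // 3)
        return [(1, h, "h"), (h + 1, length, "c")]
    template = [(1, 40, "h"), (41, 44, "c"), (45, 52, "e"), (53, 54, "c"),
                (55, 62, "e"), (63, 90, "c"), (91, 120, "h")]
    if length == 120:
        return template
    scale = length / 120.0
    bounds = [1]
    for _, e, _ in template[:-1]:
        bounds.append(int(round(e * scale)) + 1)
    layout = []
    for k, (_, _, lab) in enumerate(template):
        start = bounds[k]
        end = bounds[k + 1] - 1 if k + 1 < len(template) else length
        if end >= start:
            layout.append((start, end, lab))
    return layout


def default_disorder_segment(
    layout: list[tuple[int, int, str]], length: int, prob: float = 0.55
) -> tuple[int, int, float] | None:
    """A disorder segment covering most of the longest coil run of the layout."""
    coils = [(s, e) for s, e, lab in layout if lab == "c"]
    if not coils:
        return None
    s, e = max(coils, key=lambda t: t[1] - t[0])
    span = e - s
    pad = max(1, span // 8)
    return (s + pad, e - pad, prob)


def _layout_labels(layout: list[tuple[int, int, str]], length: int) -> list[str]:
    labels = ["c"] * length
    for s, e, lab in layout:
        for p in range(s, e + 1):
            labels[p - 1] = lab
    return labels


def _hairpin_turn_positions(layout: list[tuple[int, int, str]]) -> set[int]:
    """Positions of 2-residue coil segments flanked by strands on both sides."""
    turns: set[int] = set()
    for k in range(1, len(layout) - 1):
        s, e, lab = layout[k]
        if lab == "c" and e - s == 1 and layout[k - 1][2] == "e" and layout[k + 1][2] == "e":
            turns.update((s, e))
    return turns


def _nerf(a, b, c, r, theta_deg, chi_deg):
    """Place atom D given three predecessors, bond length, angle and torsion."""
    theta = np.deg2rad(theta_deg)
    chi = np.deg2rad(chi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta), r * np.sin(theta) * np.cos(chi),
                  r * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _sample_torsions(layout, length, rng) -> list[tuple[float, float]]:
    labels = _layout_labels(layout, length)
    turns = _hairpin_turn_positions(layout)
    turn_list = sorted(turns)
    torsions = []
    for p in range(1, length + 1):
        if p in turns:
            torsions.append(HAIRPIN_TURN[turn_list.index(p) % 2])
            continue
        lab = labels[p - 1]
        if lab == "h":
            base, jit = HELIX, 4.0
        elif lab == "e":
            base, jit = STRAND, 4.0
        else:
            base, jit = COIL_EXTENDED, 10.0
        torsions.append((base[0] + rng.uniform(-jit, jit),
                         base[1] + rng.uniform(-jit, jit)))
    return torsions


def _build_backbone(torsions: list[tuple[float, float]]) -> dict[str, np.ndarray]:
    n = len(torsions)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    for i in range(1, n):
        psi_prev = torsions[i - 1][1]
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psi_prev)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, 180.0)
        C[i] = _nerf(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, torsions[i][0])
    O = np.zeros((n, 3))
    for i in range(n):
        psi = torsions[i][1] if i + 1 < n else 135.0
        O[i] = _nerf(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi - 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _place_cb(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Ideal Cbeta for an L-amino acid from its backbone N, CA, C."""
    return _nerf(C, N, CA, B_CA_CB, A_N_CA_CB, 122.6)


@lru_cache(maxsize=1)
def _blosum_substitution_probs() -> dict[str, tuple[str, np.ndarray]]:
    """P(b | a, b != a) proportional to exp(S_blosum62 / 2)."""
    from Bio.Align import substitution_matrices

    S = substitution_matrices.load("BLOSUM62")
    out = {}
    for a in AA1:
        others = [b for b in AA1 if b != a]
        w = np.array([np.exp(S[a, b] / 2.0) for b in others])
        out[a] = ("".join(others), w / w.sum())
    return out


def _seed_sequence(length: int, labels: list[str], rng) -> str:
    letters = np.array(list(_AA_FREQ))
    probs = np.array(list(_AA_FREQ.values()))
    probs = probs / probs.sum()
    seq = [str(rng.choice(letters, p=probs)) for _ in range(length)]
    return "".join(seq)


def build_seed_backbone(config: FamilyConfig) -> ChainStructure:
    """Ideal-geometry seed chain (N, CA, C, O, CB) realizing the SS layout."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    layout = config.resolved_layout()
    labels = _layout_labels(layout, config.length)
    torsions = _sample_torsions(layout, config.length, rng)
    bb = _build_backbone(torsions)
    seq = _seed_sequence(config.length, labels, rng)
    residues = []
    for i in range(config.length):
        atoms = {name: bb[name][i].copy() for name in ("N", "CA", "C", "O")}
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
        if seq[i] != "G":
            atoms["CB"] = _place_cb(bb["N"][i], bb["CA"][i], bb["C"][i])
            elements["CB"] = "C"
        residues.append(ResidueStructure("A", i + 1, "", seq[i], atoms, elements))
    return ChainStructure("SEED", "A", residues, [])


def _member_sequence(seed_seq: str, rate: float, rng) -> str:
    probs = _blosum_substitution_probs()
    out = []
    for a in seed_seq:
        if a in probs and rng.random() < rate:
            letters, w = probs[a]
            out.append(letters[rng.choice(len(letters), p=w)])
        else:
            out.append(a)
    return "".join(out)


def generate_family(config: FamilyConfig, outdir: str | Path | None = None) -> FamilyData:
    """Generate a complete synthetic family (structures, sequences, alignment, truth).

    With ``outdir`` given, writes one PDB per member under ``<outdir>/pdb/``,
    the seed structure, full sequences as FASTA, the alignment as aligned
    FASTA and the ground truth as JSON.  Fully deterministic per config.
    """
    config.validate()
    seed_chain = build_seed_backbone(config)
    seed_seq = "".join(r.res_type for r in seed_chain.residues)
    layout = config.resolved_layout()
    labels = _layout_labels(layout, config.length)
    rng = np.random.default_rng([config.seed, 1])
    L = config.length

    near_disorder = np.zeros(L, dtype=bool)
    for s, e, _ in config.resolved_segments():
        near_disorder[max(0, s - 3) : min(L, e + 2)] = True

    chains: dict[str, ChainStructure] = {}
    sequences: list[FullSequence] = []
    aligned_rows: list[tuple[str, str]] = []
    bb_names = ("N", "CA", "C", "O")
    for k in range(config.n_proteins):
        pid = f"P{k + 1:03d}"
        member_seq = _member_sequence(seed_seq, config.mutation_rate, rng)

        deleted = np.zeros(L, dtype=bool)
        disordered = np.zeros(L, dtype=bool)
        for s, e, p_dis in config.resolved_segments():
            u = rng.random()
            v = rng.random()
            js = int(rng.integers(-config.segment_jitter, config.segment_jitter + 1))
            je = int(rng.integers(-config.segment_jitter, config.segment_jitter + 1))
            lo = max(2, s + js)
            hi = min(L - 1, e + je)
            if u < config.gap_rate:
                deleted[lo - 1 : hi] = True
            elif v < p_dis and lo <= hi:
                disordered[lo - 1 : hi] = True

        sigma = np.where(near_disorder, config.coord_noise_near_disorder,
                         config.coord_noise_core)
        residues: list[ResidueStructure] = []
        missing: list[MissingResidue] = []
        for i in range(L):
            noise = {name: rng.normal(0.0, sigma[i], size=3) for name in bb_names}
            mismatched = rng.random() < config.mismatch_rate
            if deleted[i]:
                continue
            if disordered[i]:
                missing.append(MissingResidue(i + 1, "", member_seq[i]))
                continue
            res_type = member_seq[i]
            if mismatched:
                choices = [b for b in AA1 if b not in (res_type, "G")]
                res_type = choices[int(rng.integers(len(choices)))]
            atoms = {}
            elements = {}
            for name in bb_names:
                atoms[name] = seed_chain.residues[i].atoms[name] + noise[name]
                elements[name] = seed_chain.residues[i].elements[name]
            if res_type != "G":
                atoms["CB"] = _place_cb(atoms["N"], atoms["CA"], atoms["C"])
                elements["CB"] = "C"
            residues.append(ResidueStructure("A", i + 1, "", res_type, atoms, elements))

        chain = ChainStructure(f"S{k + 1:03d}", "A", residues, missing)
        chains[pid] = chain
        full = "".join(member_seq[i] for i in range(L) if not deleted[i])
        sequences.append(FullSequence(pid, full))
        aligned_rows.append(
            (pid, "".join("-" if deleted[i] else member_seq[i] for i in range(L)))
        )

    msa = MSA(aligned_rows)
    disorder_prob = [0.0] * L
    for s, e, p in config.resolved_segments():
        for i in range(s - 1, e):
            disorder_prob[i] = max(disorder_prob[i], p * (1.0 - config.gap_rate))
    exposure = {"h": "intermediate", "e": "buried", "c": "exposed"}
    truth = FamilyTruth(disorder_prob, labels, [exposure[l] for l in labels])

    data = FamilyData(config, truth, seed_chain, chains, sequences, msa)
    if outdir is not None:
        outdir = Path(outdir)
        pdb_dir = outdir / "pdb"
        pdb_dir.mkdir(parents=True, exist_ok=True)
        for pid, chain in chains.items():
            write_pdb_chain(chain, pdb_dir / f"{pid}.pdb")
        data.pdb_dir = pdb_dir
        data.seed_pdb_path = outdir / "seed.pdb"
        write_pdb_chain(seed_chain, data.seed_pdb_path)
        data.fasta_path = outdir / "family.fasta"
        write_fasta(sequences, data.fasta_path)
        data.msa_path = outdir / "family.afa"
        write_msa(msa, data.msa_path)
        data.truth_path = outdir / "truth.json"
        truth.to_json(data.truth_path)
    return data
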