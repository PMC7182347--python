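"""Reading PDB chains with explicit disorder labels, and sequence/structure mapping.

A crystallographic chain is represented as the ordered residues that carry
coordinates plus the residues enumerated in the REMARK 465 missing-residue
section — the operational definition of intrinsic disorder used throughout
this package.  Full-length sequences (database sequences, typically longer
than the crystallized construct) are mapped onto the structure so that each
sequence position is classified as ordered, disordered, mismatch
(sequence/structure residue-type disagreement) or unmapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from ._tables import AA1TO3, three_to_one

ORDERED = "ordered"
DISORDERED = "disordered"
MISMATCH = "mismatch"
UNMAPPED = "unmapped"


@dataclass
class ResidueStructure:
    """One residue with coordinates.

    ``atoms`` maps atom names (N, CA, C, O, CB, ...) to xyz coordinates in
    Angstrom; ``elements`` maps the same names to element symbols.
    """

    chain_id: str
    seq_num: int
    icode: str
    res_type: str  # 1-letter code, 'X' if not mappable to a standard type
    atoms: dict[str, np.ndarray]
    elements: dict[str, str] = field(default_factory=dict)

    def get(self, name: str) -> np.ndarray | None:
        return self.atoms.get(name)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_num, self.icode)


@dataclass
class MissingResidue:
    """One REMARK 465 entry: a residue present in the construct but unresolved."""

    seq_num: int
    icode: str
    res_type: str


@dataclass
class ChainStructure:
    pdb_id: str
    chain_id: str
    residues: list[ResidueStructure]
    missing: list[MissingResidue]
    resolution: float | None = None

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        order = [_res_key_sort(k) for k in keys]
        if order != sorted(order):
            idx = np.argsort(
                np.array([o[0] for o in order])
                + np.array([o[1] for o in order]) / 256.0
            )
            self.residues = [self.residues[i] for i in idx]
        present = {r.key for r in self.residues}
        dup = [m for m in self.missing if (m.seq_num, m.icode) in present]
        if dup:
            raise ValueError(
                f"residues appear both with coordinates and in REMARK 465: "
                f"{[(m.seq_num, m.icode) for m in dup]}"
            )

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass
class FullSequence:
    """Full-length protein sequence, positions 1-based."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"non-standard letters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SeqStructMap:
    """Classification of every sequence position against one chain.

    ``status[p]`` for 1-based position p is one of ordered/disordered/
    mismatch/unmapped; ordered positions carry an index into
    ``chain.residues`` in ``residue_index``, disordered ones an index into
    ``chain.missing`` in ``missing_index``.  Mismatch positions reference
    whichever record they mapped to (type disagreement with the sequence).
    """

    protein_id: str
    status: dict[int, str]
    residue_index: dict[int, int]
    missing_index: dict[int, int]

    def counts(self) -> dict[str, int]:
        out = {ORDERED: 0, DISORDERED: 0, MISMATCH: 0, UNMAPPED: 0}
        for s in self.status.values():
            out[s] += 1
        return out


def _res_key_sort(key: tuple[int, str]) -> tuple[int, int]:
    # blank insertion code orders before 'A'
    num, icode = key
    return (num, 0 if icode in ("", " ") else ord(icode))


# ---------------------------------------------------------------------------
# PDB reading


def _parse_remark_465(lines: list[str], chain: str) -> list[MissingResidue]:
    out = []
    skip_tokens = ("MISSING", "EXPERIMENT", "SSSEQI", "IDENTIFIER",
                   "MODELS", "RES=", "M=MODEL", "NOT LOCATED", "FOLLOWING")
    for line in lines:
        if not line.startswith("REMARK 465"):
            continue
        body = line[10:].rstrip()
        if not body.strip() or any(t in body for t in skip_tokens):
            continue
        entry = _parse_465_entry(line)
        if entry is None:
            warnings.warn(f"skipping malformed REMARK 465 line: {line.rstrip()!r}")
            continue
        ch, res3, num, icode = entry
        if ch == chain:
            out.append(MissingResidue(num, icode, three_to_one(res3)))
    return out


def _parse_465_entry(line: str) -> tuple[str, str, int, str] | None:
    # Fixed wwPDB columns first: resName 16-18, chain 20, sseq 21-26, icode 27.
    try:
        res3 = line[15:18].strip()
        ch = line[19]
        num = int(line[20:26])
        icode = line[26] if len(line) > 26 and line[26] != " " else ""
        if res3 and ch != " ":
            return ch, res3, num, icode
    except (ValueError, IndexError):
        pass
    # Tolerant whitespace fallback: REMARK 465 [M] RES C SSSEQ[I]
    toks = line.split()
    toks = toks[2:]
    if len(toks) == 4 and toks[0].isdigit():  # leading model number
        toks = toks[1:]
    if len(toks) != 3:
        return None
    res3, ch, last = toks
    if len(ch) != 1 or not res3.isalpha():
        return None
    icode = ""
    if last and last[-1].isalpha():
        icode, last = last[-1], last[:-1]
    try:
        num = int(last)
    except ValueError:
        return None
    return ch, res3, num, icode


def _pick_conformers(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve altLoc duplicates: highest occupancy wins, ties prefer 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        alt = atom.altloc or " "
        palt = prev.altloc or " "
        if (atom.occ, alt == "A", -ord(alt)) > (prev.occ, palt == "A", -ord(palt)):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_pdb_chain(path: str | Path, chain: str) -> ChainStructure:
    """Read one chain of a PDB file, including its REMARK 465 disorder records.

    Only the first model is considered; waters and non-peptide ligands are
    skipped.  Residues with alternate conformations keep the
    highest-occupancy conformer.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    gchain = model.find_chain(chain)
    residues: list[ResidueStructure] = []
    if gchain is not None:
        for res in gchain:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if res.het_flag != "A" and not is_aa:
                continue
            atoms: dict[str, np.ndarray] = {}
            elements: dict[str, str] = {}
            for atom in _pick_conformers(res):
                if atom.element.name == "H":
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(pos)):
                    continue
                atoms[atom.name] = pos
                elements[atom.name] = atom.element.name
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                ResidueStructure(chain, res.seqid.num, icode,
                                 three_to_one(res.name), atoms, elements)
            )
    if not residues:
        raise ValueError(f"{path}: no ATOM records for chain {chain!r}")
    missing = _parse_remark_465(list(st.raw_remarks), chain)
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    pdb_id = (st.name or path.stem)[:4].upper()
    return ChainStructure(pdb_id, chain, residues, missing, resolution)


# ---------------------------------------------------------------------------
# PDB writing (used by the synthetic-family generator and round-trip tests)

_REMARK_465_HEADER = [
    "REMARK 465",
    "REMARK 465 MISSING RESIDUES",
    "REMARK 465 THE FOLLOWING RESIDUES WERE NOT LOCATED IN THE",
    "REMARK 465 EXPERIMENT. (M=MODEL NUMBER; RES=RESIDUE NAME; C=CHAIN",
    "REMARK 465 IDENTIFIER; SSSEQ=SEQUENCE NUMBER; I=INSERTION CODE.)",
    "REMARK 465",
    "REMARK 465   M RES C SSSEQI",
]

# canonical heavy-atom output order within a residue
_ATOM_ORDER = {name: i for i, name in enumerate(["N", "CA", "C", "O", "CB"])}


def write_pdb_chain(chain: ChainStructure, path: str | Path) -> None:
    """Write a ChainStructure as a minimal standard PDB file."""
    lines = [f"HEADER    SYNTHETIC PROTEIN                       01-JAN-00   {chain.pdb_id:<4}"]
    if chain.missing:
        lines.extend(_REMARK_465_HEADER)
        for m in chain.missing:
            res3 = AA1TO3.get(m.res_type, "UNK")
            icode = m.icode or " "
            lines.append(f"REMARK 465     {res3:>3} {chain.chain_id}{m.seq_num:>6}{icode}")
    serial = 1
    for res in chain.residues:
        res3 = AA1TO3.get(res.res_type, "UNK")
        names = sorted(res.atoms, key=lambda n: (_ATOM_ORDER.get(n, 99), n))
        for name in names:
            x, y, z = res.atoms[name]
            elem = res.elements.get(name, name[0])
            pad_name = f" {name:<3}" if len(name) < 4 else name
            icode = res.icode or " "
            lines.append(
                f"ATOM  {serial:>5} {pad_name} {res3} {chain.chain_id}"
                f"{res.seq_num:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {elem:>2}"
            )
            serial += 1
    last = chain.residues[-1]
    lines.append(
        f"TER   {serial:>5}      {AA1TO3.get(last.res_type, 'UNK')} "
        f"{chain.chain_id}{last.seq_num:>4}{last.icode or ' '}"
    )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[FullSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [FullSequence(r.id, str(r.seq).upper()) for r in records]


def write_fasta(seqs: list[FullSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Sequence <-> structure mapping


def _structure_records(chain: ChainStructure):
    """Ordered+missing residues interleaved in numbering order."""
    recs = [(r.seq_num, r.icode, r.res_type, ORDERED, i)
            for i, r in enumerate(chain.residues)]
    recs += [(m.seq_num, m.icode, m.res_type, DISORDERED, i)
             for i, m in enumerate(chain.missing)]
    recs.sort(key=lambda t: _res_key_sort((t[0], t[1])))
    return recs


def _try_direct_offsets(seq: str, recs) -> tuple[int, float]:
    """Best constant offset mapping author numbering to sequence positions."""
    L = len(seq)
    numbered = [(num, letter) for num, icode, letter, _, _ in recs if not icode]
    if not numbered:
        return 0, 0.0
    nums = np.array([n for n, _ in numbered])
    letters = np.array([ord(l) for _, l in numbered])
    seq_arr = np.array([ord(c) for c in seq])
    lo = 1 - int(nums.max())
    hi = L - int(nums.min())
    best_off, best_agree = 0, -1.0
    for off in range(lo, hi + 1):
        pos = nums + off
        ok = (pos >= 1) & (pos <= L)
        if not ok.any():
            continue
        agree = float(np.sum(seq_arr[pos[ok] - 1] == letters[ok])) / len(recs)
        if agree > best_agree:
            best_off, best_agree = off, agree
    return best_off, best_agree


def _align_records(seq: str, recs) -> dict[int, int]:
    """Global alignment fallback: record index -> 1-based sequence position."""
    struct_seq = "".join(t[2] for t in recs)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(seq, struct_seq)[0]
    mapping: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            mapping[q0 + k] = t0 + k + 1
    return mapping


def map_sequence_to_structure(seq: FullSequence, chain: ChainStructure) -> SeqStructMap:
    """Classify each sequence position as ordered/disordered/mismatch/unmapped.

    Mapping first tries a constant author-numbering offset; if fewer than 95%
    of structural+missing records agree with the sequence under the best
    offset, falls back to global sequence alignment of the full sequence
    against the structure-derived sequence.
    """
    recs = _structure_records(chain)
    offset, agree = _try_direct_offsets(seq.sequence, recs)
    rec_to_pos: dict[int, int] = {}
    if agree >= 0.95:
        for k, (num, icode, _, _, _) in enumerate(recs):
            if icode:
                continue
            p = num + offset
            if 1 <= p <= len(seq):
                rec_to_pos[k] = p
    else:
        rec_to_pos = _align_records(seq.sequence, recs)

    status = {p: UNMAPPED for p in range(1, len(seq) + 1)}
    residue_index: dict[int, int] = {}
    missing_index: dict[int, int] = {}
    used: set[int] = set()
    n_struct_mapped = 0
    for k, p in rec_to_pos.items():
        if p in used:
            continue
        used.add(p)
        num, icode, letter, kind, idx = recs[k]
        if letter != seq.sequence[p - 1] or letter == "X":
            status[p] = MISMATCH
        elif kind == ORDERED:
            n_struct_mapped += 1
            status[p] = ORDERED
            residue_index[p] = idx
        else:
            status[p] = DISORDERED
            missing_index[p] = idx

    if n_struct_mapped < 0.30 * len(chain.residues):
        raise ValueError(
            f"{seq.id} vs {chain.pdb_id}{chain.chain_id}: only "
            f"{n_struct_mapped}/{len(chain.residues)} structural residues "
            "mappable; wrong sequence/structure pairing?"
        )
    return SeqStructMap(seq.id, status, residue_index, missing_index)
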