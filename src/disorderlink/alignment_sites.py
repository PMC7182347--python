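"""MSA columns as analysis units: occupancy, disorder propensity, entropy.

Each column ("site") of the family alignment is scored by how many of the
member proteins have a residue there (N_res), how many of those residues are
crystallographically resolved (N_ord) versus listed as missing (N_dis), and
the resulting disorder propensity

    delta = (N_dis - N_ord) / N_res,

which runs from -1 (all ordered) to +1 (all disordered).  Residues whose
type disagrees between the full sequence and the structure file count toward
N_res only.  Sequence conservation at a site is measured by the Shannon
entropy of the residue-type distribution, in nats.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .structure_io import DISORDERED, MISMATCH, ORDERED, UNMAPPED, SeqStructMap

GAP = "gap"


@dataclass
class MSA:
    records: list[tuple[str, str]]  # (protein id, aligned sequence with '-')

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class SiteOccupancy:
    """Per-protein status at one MSA column (1-based ``site``)."""

    site: int
    statuses: dict[str, str]  # protein id -> ordered/disordered/mismatch/gap
    letters: dict[str, str]   # protein id -> residue letter (non-gap only)
    residue_refs: dict[str, int] = field(default_factory=dict)  # id -> chain residue idx

    @property
    def n_res(self) -> int:
        return sum(1 for s in self.statuses.values() if s != GAP)

    @property
    def n_dis(self) -> int:
        return sum(1 for s in self.statuses.values() if s == DISORDERED)

    @property
    def n_ord(self) -> int:
        return sum(1 for s in self.statuses.values() if s == ORDERED)


@dataclass
class DisorderPropensity:
    site: int
    delta: float


def read_msa(path: str | Path) -> MSA:
    """Read an alignment in aligned-FASTA or Clustal format (auto-detected)."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(64).lstrip()
    fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MSA([(rec.id, str(rec.seq).upper()) for rec in aln])


def write_msa(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in msa.records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def build_site_occupancy(msa: MSA, maps: dict[str, SeqStructMap]) -> list[SiteOccupancy]:
    """Resolve every alignment cell through its protein's sequence/structure map.

    Non-gap cells are classified by the status of the corresponding ungapped
    sequence position.  Positions the map marks unmapped (no structural or
    missing-residue counterpart, e.g. beyond the crystallized construct)
    still count toward N_res — they are residues present in the alignment —
    but, like mismatches, toward neither N_dis nor N_ord.
    """
    for pid, _ in msa.records:
        if pid not in maps:
            raise KeyError(f"protein {pid!r} in MSA has no sequence/structure map")
    sites = [SiteOccupancy(c + 1, {}, {}) for c in range(msa.length)]
    for pid, aligned in msa.records:
        smap = maps[pid]
        pos = 0
        for c, ch in enumerate(aligned):
            occ = sites[c]
            if ch == "-":
                occ.statuses[pid] = GAP
                continue
            pos += 1
            st = smap.status.get(pos, UNMAPPED)
            occ.statuses[pid] = st
            occ.letters[pid] = ch
            if st == ORDERED:
                occ.residue_refs[pid] = smap.residue_index[pos]
    return sites


def compute_delta(occ: SiteOccupancy) -> DisorderPropensity:
    """Disorder propensity delta = (N_dis - N_ord) / N_res; requires N_res >= 1."""
    if occ.n_res == 0:
        raise ValueError(f"site {occ.site}: no residues, delta undefined")
    return DisorderPropensity(occ.site, (occ.n_dis - occ.n_ord) / occ.n_res)


def filter_sites(sites: list[SiteOccupancy], min_count: int = 20) -> list[SiteOccupancy]:
    """Keep sites with at least ``min_count`` contributing residues (order kept)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [s for s in sites if s.n_res >= min_count]


def residue_entropy(letters) -> float:
    """Shannon entropy -sum(p ln p) in nats of a residue-letter multiset."""
    counts = np.array(list(Counter(letters).values()), dtype=float)
    if counts.size == 0:
        raise ValueError("entropy of empty letter set is undefined")
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p))) + 0.0  # avoid -0.0


def site_table(sites: list[SiteOccupancy]) -> pd.DataFrame:
    """Per-site occupancy summary (site, N_res, N_dis, N_ord, delta, s1)."""
    rows = []
    for occ in sites:
        delta = compute_delta(occ).delta if occ.n_res else np.nan
        s1 = residue_entropy(occ.letters.values()) if occ.letters else np.nan
        rows.append(
            {"site": occ.site, "N_res": occ.n_res, "N_dis": occ.n_dis,
             "N_ord": occ.n_ord, "delta": delta, "s1": s1}
        )
    return pd.DataFrame(rows, columns=["site", "N_res", "N_dis", "N_ord", "delta", "s1"])
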