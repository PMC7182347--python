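"""Per-site aggregation of structural measurements into the feature vector.

For each retained MSA site, the ordered residues contributed by the family
members are pooled and summarized: CLRC distance mean/SD (dav, dsd),
bond-direction cosine statistics (c1, c2, c3 av/sd), ASA/RSA and phi/psi
statistics at the site (index 1) and at the per-protein CLRC residues
(index 2), 3-state secondary-structure propensities and their Shannon
entropies (sss1, sss2), and the residue-type entropies s1 (site letters from
the alignment) and s2 (CLRC residue types).  Angle statistics are circular;
all SDs use the population convention (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_sites import SiteOccupancy, compute_delta, residue_entropy
from .geometry import (
    ContactAssignment,
    PairCosines,
    ResidueGeometry,
    circular_stats,
    pair_cosines,
)
from .structure_io import ChainStructure

FEATURE_COLUMNS = [
    "site", "delta", "n_struct", "s1", "s2", "sss1", "sss2",
    "dav", "dsd",
    "c1av", "c1sd", "c2av", "c2sd", "c3av", "c3sd",
    "a1av", "a1sd", "a2av", "a2sd",
    "ra1av", "ra1sd", "ra2av", "ra2sd",
    "phi1av", "phi1sd", "psi1av", "psi1sd",
    "phi2av", "phi2sd", "psi2av", "psi2sd",
    "ss1h", "ss1c", "ss1e", "ss2h", "ss2c", "ss2e",
]


@dataclass
class SiteFeatureRecord:
    site: int
    delta: float
    n_struct: int
    s1: float | None = None
    s2: float | None = None
    sss1: float | None = None
    sss2: float | None = None
    dav: float | None = None
    dsd: float | None = None
    c1av: float | None = None
    c1sd: float | None = None
    c2av: float | None = None
    c2sd: float | None = None
    c3av: float | None = None
    c3sd: float | None = None
    a1av: float | None = None
    a1sd: float | None = None
    a2av: float | None = None
    a2sd: float | None = None
    ra1av: float | None = None
    ra1sd: float | None = None
    ra2av: float | None = None
    ra2sd: float | None = None
    phi1av: float | None = None
    phi1sd: float | None = None
    psi1av: float | None = None
    psi1sd: float | None = None
    phi2av: float | None = None
    phi2sd: float | None = None
    psi2av: float | None = None
    psi2sd: float | None = None
    ss1h: float | None = None
    ss1c: float | None = None
    ss1e: float | None = None
    ss2h: float | None = None
    ss2c: float | None = None
    ss2e: float | None = None


def _mean_sd(values) -> tuple[float, float] | tuple[None, None]:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return None, None
    return float(arr.mean()), float(arr.std())  # population SD


def _circ_mean_sd(values) -> tuple[float, float] | tuple[None, None]:
    arr = [v for v in values if v is not None and np.isfinite(v)]
    if not arr:
        return None, None
    return circular_stats(arr)


def _ss_propensities(labels) -> tuple[dict[str, float], float] | tuple[None, None]:
    labels = list(labels)
    if not labels:
        return None, None
    n = len(labels)
    props = {t: labels.count(t) / n for t in ("h", "c", "e")}
    p = np.array([v for v in props.values() if v > 0])
    entropy = float(-np.sum(p * np.log(p))) + 0.0  # avoid -0.0
    return props, entropy


def compute_site_features(
    occ: SiteOccupancy,
    chains: dict[str, ChainStructure],
    geometries: dict[str, list[ResidueGeometry]],
    contacts: dict[str, dict[int, ContactAssignment]],
) -> SiteFeatureRecord:
    """Aggregate one site's per-protein measurements into a feature record.

    Only ordered residues contribute structural features; CLRC-indexed
    features additionally require the residue to have a defined CLRC.
    Mismatch and disordered cells contribute their sequence letter to s1 only.
    """
    delta = compute_delta(occ).delta
    rec = SiteFeatureRecord(site=occ.site, delta=delta, n_struct=0)
    if occ.letters:
        rec.s1 = residue_entropy(occ.letters.values())

    dists: list[float] = []
    cos: list[PairCosines] = []
    a1, ra1, phi1, psi1, ss1 = [], [], [], [], []
    a2, ra2, phi2, psi2, ss2 = [], [], [], [], []
    clrc_letters: list[str] = []

    for pid, ridx in sorted(occ.residue_refs.items()):
        chain = chains[pid]
        geo = geometries[pid]
        res = chain.residues[ridx]
        g = geo[ridx]
        rec.n_struct += 1
        a1.append(g.asa)
        ra1.append(g.rsa)
        phi1.append(g.phi)
        psi1.append(g.psi)
        ss1.append(g.ss3)
        ca = contacts[pid].get(ridx)
        if ca is None:
            continue
        other = chain.residues[ca.j]
        go = geo[ca.j]
        dists.append(ca.distance)
        pc = pair_cosines(res, other)
        if pc is not None:
            cos.append(pc)
        a2.append(go.asa)
        ra2.append(go.rsa)
        phi2.append(go.phi)
        psi2.append(go.psi)
        ss2.append(go.ss3)
        clrc_letters.append(other.res_type)

    if rec.n_struct == 0:
        return rec

    rec.dav, rec.dsd = _mean_sd(dists)
    if cos:
        rec.c1av, rec.c1sd = _mean_sd([c.c1 for c in cos])
        rec.c2av, rec.c2sd = _mean_sd([c.c2 for c in cos])
        rec.c3av, rec.c3sd = _mean_sd([c.c3 for c in cos])
    rec.a1av, rec.a1sd = _mean_sd(a1)
    rec.ra1av, rec.ra1sd = _mean_sd(ra1)
    rec.a2av, rec.a2sd = _mean_sd(a2)
    rec.ra2av, rec.ra2sd = _mean_sd(ra2)
    rec.phi1av, rec.phi1sd = _circ_mean_sd(phi1)
    rec.psi1av, rec.psi1sd = _circ_mean_sd(psi1)
    rec.phi2av, rec.phi2sd = _circ_mean_sd(phi2)
    rec.psi2av, rec.psi2sd = _circ_mean_sd(psi2)
    props1, rec.sss1 = _ss_propensities(ss1)
    if props1 is not None:
        rec.ss1h, rec.ss1c, rec.ss1e = props1["h"], props1["c"], props1["e"]
    props2, rec.sss2 = _ss_propensities(ss2)
    if props2 is not None:
        rec.ss2h, rec.ss2c, rec.ss2e = props2["h"], props2["c"], props2["e"]
    if clrc_letters:
        rec.s2 = residue_entropy(clrc_letters)
    return rec


def feature_table(records: list[SiteFeatureRecord]) -> pd.DataFrame:
    """One row per site in fixed column order; absent values are NaN."""
    rows = []
    for rec in records:
        row = {f.name: rec.__dict__[f.name] for f in fields(SiteFeatureRecord)}
        rows.append(row)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return df.astype({c: float for c in FEATURE_COLUMNS if c not in ("site", "n_struct")})


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
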