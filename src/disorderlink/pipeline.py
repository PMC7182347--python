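"""End-to-end orchestration: family in, feature table and reports out.

A run consumes either a real family (directory of PDB files, full-length
FASTA, alignment) or a synthetic-family configuration, and emits a fixed
artifact set: per-site occupancy table, per-site feature table, correlation
report, secondary-structure cross-correlations, resampling significance
results, a family summary (member count, alignment length, retained sites,
TM-score statistics against the seed structure) and a run log.  All outputs
are plain text (TSV/JSON), floats at 6 significant digits, and are a pure
function of inputs + configuration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment_sites as als
from . import site_features as sf
from . import stats as st
from .geometry import chain_geometry, find_all_clrcs
from .structure_io import ORDERED, map_sequence_to_structure, read_fasta, read_pdb_chain
from .synthetic_data import FamilyConfig, generate_family
from .tmscore import tm_score


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``pdb_dir`` + ``fasta`` + ``msa``) or ``family`` must be
    given.  For path inputs, each MSA record id X must have a structure file
    ``<pdb_dir>/X.pdb`` (chain ``chain_id``).
    """

    outdir: str | Path = "run"
    pdb_dir: str | Path | None = None
    fasta: str | Path | None = None
    msa: str | Path | None = None
    chain_id: str = "A"
    family: FamilyConfig | None = None
    min_site_count: int = 20
    separation: int = 5
    compute_tm: bool = True
    seed_protein: str | None = None  # TM target for path inputs; default first record
    subset_size: int = 200
    reps: int = 15
    rounds: int = 10
    stats_seed: int = 0

    def validate(self) -> None:
        paths_given = all(p is not None for p in (self.pdb_dir, self.fasta, self.msa))
        if (self.family is None) == (not paths_given):
            raise ValueError(
                "exactly one of (pdb_dir, fasta, msa) or a family config must be given"
            )
        if self.min_site_count < 1 or self.separation < 1:
            raise ValueError("thresholds must be positive")
        if self.family is None:
            for p in (self.pdb_dir, self.fasta, self.msa):
                if not Path(p).exists():
                    raise FileNotFoundError(str(p))


@dataclass
class RunResult:
    outdir: Path
    site_table: pd.DataFrame
    feature_table: pd.DataFrame
    report: st.CorrelationReport
    ss_cross: pd.DataFrame
    resampling: dict
    summary: dict
    artifacts: dict[str, str] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _msa_pairs(msa, maps, target_id, mobile_id):
    """(target residue idx, mobile residue idx) pairs induced by the MSA."""
    tmap, mmap = maps[target_id], maps[mobile_id]
    aligned = dict(msa.records)
    t_seq, m_seq = aligned[target_id], aligned[mobile_id]
    tpos = mpos = 0
    pairs = []
    for tc, mc in zip(t_seq, m_seq):
        if tc != "-":
            tpos += 1
        if mc != "-":
            mpos += 1
        if tc == "-" or mc == "-":
            continue
        if tmap.status.get(tpos) == ORDERED and mmap.status.get(mpos) == ORDERED:
            pairs.append((tmap.residue_index[tpos], mmap.residue_index[mpos]))
    return pairs


def _seqnum_pairs(target, mobile):
    """Correspondence by matching author residue numbers (synthetic seed route)."""
    t_idx = {(r.seq_num, r.icode): i for i, r in enumerate(target.residues)}
    return [
        (t_idx[(r.seq_num, r.icode)], j)
        for j, r in enumerate(mobile.residues)
        if (r.seq_num, r.icode) in t_idx
    ]


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and write the artifact set under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    artifacts: dict[str, str] = {}

    # --- inputs -----------------------------------------------------------
    seed_chain = None
    if config.family is not None:
        fam = _stage("generate")(generate_family)(config.family, outdir / "family")
        chains = fam.chains
        sequences = {s.id: s for s in fam.sequences}
        msa = fam.msa
        seed_chain = fam.seed_chain
        log.append(f"generator: synthetic family, seed={config.family.seed}, "
                   f"n={config.family.n_proteins}, length={config.family.length}")
    else:
        msa = _stage("read_msa")(als.read_msa)(config.msa)
        sequences = {s.id: s for s in _stage("read_fasta")(read_fasta)(config.fasta)}
        chains = {}
        for pid, _ in msa.records:
            path = Path(config.pdb_dir) / f"{pid}.pdb"
            chains[pid] = _stage("read_pdb")(read_pdb_chain)(path, config.chain_id)
        log.append(f"inputs: {len(chains)} chains, alignment length {msa.length}")

    # --- mapping and occupancy -------------------------------------------
    maps = {}
    for pid, _ in msa.records:
        maps[pid] = _stage("map")(map_sequence_to_structure)(sequences[pid], chains[pid])
    occupancy = _stage("occupancy")(als.build_site_occupancy)(msa, maps)
    nonempty = [o for o in occupancy if o.n_res > 0]
    site_df = als.site_table(nonempty)
    retained = als.filter_sites(occupancy, config.min_site_count)
    if not retained:
        warnings.warn(
            f"no MSA site has at least {config.min_site_count} residues; "
            "feature table will be empty"
        )
    log.append(f"sites: {len(nonempty)} occupied, {len(retained)} with "
               f"N_res >= {config.min_site_count}")

    # --- per-chain geometry -----------------------------------------------
    geometries = {}
    contacts = {}
    for pid in sorted(chains):
        geometries[pid] = _stage("geometry")(chain_geometry)(chains[pid])
        contacts[pid] = find_all_clrcs(chains[pid], config.separation)
    log.append(f"geometry: CLRC separation > {config.separation} (author numbering), "
               "Shrake-Rupley ASA probe 1.4 A / 960 points, "
               "dihedral-region 3-state secondary structure")

    # --- features ----------------------------------------------------------
    records = [
        sf.compute_site_features(occ, chains, geometries, contacts) for occ in retained
    ]
    table = sf.feature_table(records)

    # --- statistics ---------------------------------------------------------
    if len(table):
        report = st.correlate_delta(table)
        ss_cross = st.ss_cross_correlations(table, split="by_delta_sign")
        zero_rows = []
        for which in ("sss1", "sss2"):
            r_all, r_filt = st.exclude_zero_entropy_and_recompute(table, which)
            zero_rows.append({"entropy": which, "r_all_sites": r_all,
                              "r_nonzero_entropy_sites": r_filt})
        zero_df = pd.DataFrame(zero_rows)
        resampling = {}
        for feat in ("dav", "dsd"):
            res = st.majority_vote_sign_test(
                table["delta"], table[feat], subset_size=config.subset_size,
                reps=config.reps, rounds=config.rounds, seed=config.stats_seed,
            )
            resampling[f"delta_vs_{feat}"] = dataclasses.asdict(res)
    else:
        report = st.CorrelationReport(
            pd.DataFrame(columns=["feature", "r", "n_pairs"]),
            pd.DataFrame(columns=["pair", "r", "n_pairs"]),
        )
        ss_cross = pd.DataFrame(columns=["stratum", "ss_type", "r", "n_pairs"])
        zero_df = pd.DataFrame(columns=["entropy", "r_all_sites", "r_nonzero_entropy_sites"])
        resampling = {}
    log.append(f"stats: subset_size={config.subset_size}, reps={config.reps}, "
               f"rounds={config.rounds}, seed={config.stats_seed}; "
               "pairwise NA deletion; zero-entropy threshold 1e-12; "
               "delta=0 counted in the delta>=0 stratum")

    # --- TM-scores ----------------------------------------------------------
    summary = {
        "n_proteins": len(chains),
        "alignment_length": msa.length,
        "n_sites_retained": len(retained),
        "min_site_count": config.min_site_count,
    }
    if config.compute_tm:
        scores = []
        if seed_chain is not None:
            for pid in sorted(chains):
                pairs = _seqnum_pairs(seed_chain, chains[pid])
                try:
                    scores.append(tm_score(seed_chain, chains[pid], pairs).score)
                except ValueError:
                    continue
            target_name = "generated seed backbone"
        else:
            target_id = config.seed_protein or msa.records[0][0]
            for pid in sorted(chains):
                if pid == target_id:
                    continue
                pairs = _msa_pairs(msa, maps, target_id, pid)
                try:
                    scores.append(tm_score(chains[target_id], chains[pid], pairs).score)
                except ValueError:
                    continue
            target_name = target_id
        if scores:
            summary["tm_mean"] = float(np.mean(scores))
            summary["tm_median"] = float(np.median(scores))
            summary["tm_sd"] = float(np.std(scores))
        log.append(f"tmscore: fixed-correspondence score vs {target_name} "
                   "(no alignment search; Calpha distances)")

    # --- artifacts -----------------------------------------------------------
    site_path = outdir / "sites.tsv"
    site_df.to_csv(site_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    feat_path = outdir / "features.tsv"
    sf.write_feature_table(table, feat_path)
    corr_path = outdir / "correlations.tsv"
    report.to_tsv(corr_path)
    with open(corr_path, "a") as fh:
        fh.write("\n# delta vs SS entropy with zero-entropy sites removed\n")
        zero_df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    ss_path = outdir / "ss_cross_correlations.tsv"
    ss_cross.to_csv(ss_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    rs_path = outdir / "resampling.json"
    rs_path.write_text(json.dumps(resampling, indent=2, sort_keys=True) + "\n")
    sum_path = outdir / "summary.tsv"
    with open(sum_path, "w") as fh:
        fh.write("\t".join(summary) + "\n")
        fh.write("\t".join(_fmt(v) for v in summary.values()) + "\n")
    log_path = outdir / "log.txt"
    log_path.write_text("\n".join(log) + "\n")
    for p in (site_path, feat_path, corr_path, ss_path, rs_path, sum_path, log_path):
        artifacts[p.name] = str(p)
    return RunResult(outdir, site_df, table, report, ss_cross, resampling, summary, artifacts)
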