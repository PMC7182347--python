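"""Correlation analysis of disorder propensity against site features.

Pearson correlations of delta with every feature column (with pairwise
deletion of missing values), inter-entropy correlations, secondary-structure
cross-correlations between site and CLRC optionally stratified by the sign
of delta, a zero-entropy exclusion variant (conserved sites with exactly
zero entropy dominate the delta/entropy relationship and can flip its sign),
and a subset-resampling majority-vote sign test: each round draws 15 random
subsets of 200 sites, computes the subset correlation, and takes the
majority sign; unanimous agreement of 10 rounds is reported as p = 2^-10,
in analogy with 10 fair-coin flips.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest, pearsonr

ENTROPY_PAIRS = [
    ("s1", "s2"), ("s1", "sss1"), ("s1", "sss2"),
    ("s2", "sss1"), ("s2", "sss2"), ("sss1", "sss2"),
]


def pearson(x, y) -> float | None:
    """Product-moment correlation with pairwise NA deletion.

    Returns None when fewer than 3 complete pairs remain or either variable
    is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(pearsonr(x, y).statistic)


def _n_pairs(x, y) -> int:
    return int(np.sum(np.isfinite(np.asarray(x, float)) & np.isfinite(np.asarray(y, float))))


@dataclass
class CorrelationReport:
    """Correlations of delta against each feature plus inter-entropy pairs."""

    delta_vs_feature: pd.DataFrame  # columns: feature, r, n_pairs
    entropy_pairs: pd.DataFrame     # columns: pair, r, n_pairs

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# Pearson correlations of delta with site features\n")
            self.delta_vs_feature.to_csv(fh, sep="\t", index=False,
                                         na_rep="NA", float_format="%.6g")
            fh.write("\n# Correlations between entropic parameters\n")
            self.entropy_pairs.to_csv(fh, sep="\t", index=False,
                                      na_rep="NA", float_format="%.6g")


def correlate_delta(table: pd.DataFrame) -> CorrelationReport:
    """Pearson r of delta against every feature column, plus entropy pairs."""
    skip = {"site", "delta", "n_struct"}
    rows = []
    for col in table.columns:
        if col in skip:
            continue
        rows.append({
            "feature": col,
            "r": pearson(table["delta"], table[col]),
            "n_pairs": _n_pairs(table["delta"], table[col]),
        })
    ent_rows = []
    for a, b in ENTROPY_PAIRS:
        if a in table.columns and b in table.columns:
            ent_rows.append({
                "pair": f"{a}:{b}",
                "r": pearson(table[a], table[b]),
                "n_pairs": _n_pairs(table[a], table[b]),
            })
    return CorrelationReport(
        pd.DataFrame(rows, columns=["feature", "r", "n_pairs"]),
        pd.DataFrame(ent_rows, columns=["pair", "r", "n_pairs"]),
    )


def ss_cross_correlations(table: pd.DataFrame, split: str = "none") -> pd.DataFrame:
    """r(ss1t, ss2t) for t in {h, c, e}, overall and optionally by delta sign.

    ``split='by_delta_sign'`` adds strata for delta >= 0 (more disordered;
    delta = 0 belongs here) and delta < 0 (more ordered).  Strata with fewer
    than 3 sites report NA.
    """
    if split not in ("none", "by_delta_sign"):
        raise ValueError(f"unknown split {split!r}")
    strata = {"all": table}
    if split == "by_delta_sign":
        strata["delta>=0"] = table[table["delta"] >= 0]
        strata["delta<0"] = table[table["delta"] < 0]
    rows = []
    for name, sub in strata.items():
        for t in ("h", "c", "e"):
            rows.append({
                "stratum": name,
                "ss_type": t,
                "r": pearson(sub[f"ss1{t}"], sub[f"ss2{t}"]),
                "n_pairs": _n_pairs(sub[f"ss1{t}"], sub[f"ss2{t}"]),
            })
    return pd.DataFrame(rows, columns=["stratum", "ss_type", "r", "n_pairs"])


def exclude_zero_entropy_and_recompute(
    table: pd.DataFrame, which: str = "sss1"
) -> tuple[float | None, float | None]:
    """r(delta, sss) over all sites and over sites with strictly positive entropy.

    Perfectly conserved sites have exactly zero secondary-structure entropy;
    removing them can reverse the sign of the correlation.  Zero is tested
    after rounding at 1e-12.
    """
    if which not in ("sss1", "sss2"):
        raise ValueError("which must be 'sss1' or 'sss2'")
    r_all = pearson(table["delta"], table[which])
    vals = table[which].to_numpy(dtype=float)
    nonzero = table[np.isfinite(vals) & (np.abs(vals) > 1e-12)]
    r_filtered = pearson(nonzero["delta"], nonzero[which]) if len(nonzero) else None
    return r_all, r_filtered


@dataclass
class ResamplingResult:
    subset_size: int
    reps_per_round: int
    rounds: int
    round_signs: list[int] = field(default_factory=list)  # +1 / -1 per round
    unanimous: bool = False
    p_value: float = 1.0
    note: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def majority_vote_sign_test(
    x, y, subset_size: int = 200, reps: int = 15, rounds: int = 10,
    seed: int | None = None,
) -> ResamplingResult:
    """Subset-resampling majority-vote test for the sign of a correlation.

    Each round draws ``reps`` random subsets of ``subset_size`` points
    (without replacement within a subset, fresh draws across subsets),
    computes the Pearson correlation of each, and records the majority sign
    (a zero or undefined subset correlation counts as positive, so with odd
    ``reps`` each round has a definite sign).  If all rounds agree the
    p-value is 2^-rounds; otherwise the two-sided binomial tail under a
    fair-coin null is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < subset_size:
        new_size = max(3, int(0.8 * n))
        warnings.warn(
            f"only {n} complete pairs < subset_size={subset_size}; "
            f"lowering subset size to {new_size}"
        )
        subset_size = new_size
    rng = np.random.default_rng(seed)
    signs = []
    for _ in range(rounds):
        n_pos = 0
        for _ in range(reps):
            idx = rng.choice(n, size=subset_size, replace=False)
            r = pearson(x[idx], y[idx])
            if r is None or r >= 0:
                n_pos += 1
        signs.append(1 if n_pos > reps / 2 else -1)
    unanimous = len(set(signs)) == 1
    if unanimous:
        p = 2.0 ** (-rounds)
        note = "unanimous round signs; p = 2^-rounds"
    else:
        n_pos_rounds = sum(1 for s in signs if s > 0)
        p = float(binomtest(n_pos_rounds, rounds, 0.5).pvalue)
        note = "non-unanimous rounds; two-sided binomial tail p-value"
    return ResamplingResult(subset_size, reps, rounds, signs, unanimous, p, note)


def scatter_plot(table: pd.DataFrame, ycol: str, path: str | Path) -> None:
    """Scatter of a feature against delta (e.g. sss1 or sss2)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["delta"], table[ycol], s=10, alpha=0.6)
    ax.set_xlabel(r"disorder propensity $\delta$")
    ax.set_ylabel(ycol)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
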