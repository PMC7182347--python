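# Methods

## The analysis unit

The pipeline treats one column of a family multiple sequence alignment (an
*MSA site*) as the unit of analysis. Each member protein contributes to a
site either a residue with coordinates (*ordered*), a residue listed in its
structure file's missing-coordinates section (*disordered*, the operational
definition of intrinsic disorder here), a residue whose type disagrees
between full sequence and structure file (*mismatch* — counted in N_res but
classified as neither ordered nor disordered), a residue outside the
crystallized construct (also counted in N_res only), or a gap. Disorder
propensity is δ = (N_dis − N_ord)/N_res ∈ [−1, 1]; sites with N_res < 20 are
discarded to avoid sparse statistics (`min_site_count`, default 20).

Entropies are Shannon entropies −Σ p ln p in nats over empirical
distributions, with 0·ln 0 := 0: s1 over the site's residue letters taken
from the alignment (disordered and mismatched residues included — they are
part of the aligned sequences; gaps excluded), s2 over the residue types of
the per-member closest long-range contacts, sss1/sss2 over the 3-state
secondary-structure labels at site/CLRC. Entropy is therefore non-negative
and bounded by ln 20 (residue types) or ln 3 (secondary structure).

## Sequence ↔ structure mapping

Structure files give author residue numbering; full-length sequences give
1-based positions. The mapper first looks for a constant offset between the
two (best letter agreement over ordered + missing records); if fewer than
95% of records agree under the best offset it falls back to a global
alignment (match +1, mismatch −1, gap −2) of the full sequence against the
structure-derived sequence (ordered and missing residues interleaved in
numbering order). A chain whose type-agreeing structural residues cover less
than 30% of its ATOM records is rejected as a wrong pairing. Alternate
conformations keep the highest-occupancy conformer (ties prefer altLoc 'A');
non-standard residues map to their parent amino acid via a fixed table, and
unmappable types become 'X', which always classifies as mismatch. Only the
first model of a multi-model file is read.

## Structural operators

**CLRC.** For residue i, the closest residue in space with author-numbering
separation > 5 (so residues missing in between still count toward
separation), distances between Cβ atoms with Cα for glycine (or when Cβ is
absent). Exact ties break to the lowest residue index. The search is a
vectorized all-pairs scan restricted to the same chain; tests verify it
against an independent exhaustive scan.

**Bond-direction cosines.** c1, c2, c3 are the cosines between the N→Cα,
Cα→C and Cα→Cβ bond directions of a site residue and its CLRC; c3 is defined
as 0.0 when either residue is glycine or lacks Cβ.

**Dihedrals.** φ/ψ in degrees, IUPAC convention, undefined at termini and
across chain breaks (author-number gap > 1 or peptide C–N distance > 2.5 Å).
Per-site angle statistics are circular: mean by atan2 of the mean sine and
cosine, SD as sqrt(−2 ln R̄) converted to degrees (directional-statistics
convention). Non-angular features use ordinary means and population SDs
(divide by n); with ~20–40 contributions per site the distinction from the
sample SD is immaterial, but the convention is fixed for reproducibility.

**Accessible surface area.** Shrake–Rupley sphere-point sampling: probe
1.4 Å, 960 deterministic golden-spiral points per atom, Bondi van der Waals
radii, heavy atoms only; unknown elements get 1.8 Å with a warning. Relative
accessibility divides by the Tien et al. (2013) theoretical per-residue
maxima. An isolated atom reproduces its analytic sphere area within 2% and
totals are rotation-invariant within 0.5%.

**Secondary structure.** The default backend assigns 3 states from
Ramachandran regions — helix: φ ∈ [−100, −30], ψ ∈ [−80, −5]; sheet:
φ ∈ [−180, −100] ∪ [160, 180], ψ ∈ [80, 180] ∪ [−180, −170]; else coil
(undefined angles ⇒ coil). This keeps the pipeline self-contained; a second
backend ingests precomputed 8-state assignments from classic .dssp files and
maps H,G,I→h, E,B→e, else→c for users who want hydrogen-bond-based labels.

**TM-score.** d0 = 1.24(Lt−15)^⅓ − 1.8 Å, clamped below at 0.5 Å for short
chains where the formula is non-positive. The residue correspondence is
*fixed* (MSA-induced, or identity) and only the rigid superposition is
optimized: iterative least-squares superposition seeded from contiguous
fragments of length L, L/2 and L/4, dropping pairs beyond max(2·d0, 4.5 Å)
and re-superposing until the objective stabilizes, keeping the best value.
This is standard fixed-alignment TM-score practice; no search over
alternative alignments is performed, so reported scores are lower bounds on
what an alignment-searching tool would find.

## Statistics

Pearson correlations use pairwise deletion of missing values and are
reported only for ≥ 3 complete pairs with nonzero variances. The
secondary-structure cross-correlations r(ss1t, ss2t), t ∈ {h, c, e}, are
computed overall and within the δ ≥ 0 ("more disordered"; δ = 0 included
here) and δ < 0 strata. The zero-entropy exclusion recomputes r(δ, sss·)
after removing sites whose entropy is exactly zero (|h| ≤ 1e−12): perfectly
conserved sites cluster on the axis and can dominate — and flip — the sign
of the correlation.

The majority-vote sign test draws, per round, 15 subsets of 200 sites
without replacement (fresh draws per subset, one seeded RNG stream in
documented order), takes each round's sign by majority over the 15 subset
correlations (a zero or undefined subset correlation counts as positive;
with 15 subsets a round always has a definite sign), and runs 10 rounds.
Unanimous rounds are reported as p = 2⁻¹⁰ by the coin-flip analogy;
non-unanimous outcomes get a two-sided binomial tail, flagged in the output.
If fewer complete pairs than the subset size exist, the subset size drops to
⌊0.8·n⌋ with a warning. **Caveat:** because every subset is drawn from the
same dataset, the ten rounds are not independent coin flips — their majority
signs track the sign of the full-sample correlation, so the nominal 2⁻¹⁰
overstates significance for weak correlations. The test is best read as a
sign-stability check; the test suite verifies this actual null behaviour
rather than the idealized coin model.

## The synthetic family generator

The generator emulates the study conditions — clusters of related chains
with disorder recorded as missing residues — without database access.

*Seed backbone.* N, Cα, C, O, Cβ built by sequential natural-extension
(NeRF) placement from ideal bond lengths/angles (N–Cα 1.458, Cα–C 1.525,
C–N 1.329 Å; ω = 180°) and canonical torsions: helix (−57, −47), strand
(−120, 130), coil sampled from an extended polyproline-II-like basin
(−80 ± 10, 145 ± 10) that the 3-state scheme labels coil. A two-residue
turn with torsions ((49.1, 149.6), (−0.9, 23.9)) — found once by
optimizing CA pair distances of an ideal hairpin — packs consecutive strand
segments into an antiparallel hairpin with ~5 Å strand-to-strand contacts.
Cβ is placed with ideal L-chirality; glycine gets none. The default
120-residue layout is helix 1–40, coil 41–44, strand 45–52, turn 53–54,
strand 55–62, exposed coil loop 63–90, helix 91–120, scaled proportionally
for other lengths (≥ 60; shorter chains get helix + coil tail).

*Members.* Each of `n_proteins` (default 40) members gets: i.i.d.
substitutions at `mutation_rate` (default 0.10) with BLOSUM62-weighted
target preferences (P(b|a) ∝ exp(S/2)); Gaussian coordinate noise, σ =
`coord_noise_core` (0.25 Å) in the core and `coord_noise_near_disorder`
(1.2 Å) within ±2 residues of a disorder segment; per disorder segment
(default: one segment covering the central ~3/4 of the longest coil run,
probability 0.55) either a whole-segment deletion (prob `gap_rate` = 0.05 —
the member simply lacks those residues, creating alignment gaps) or, with
the segment's probability, removal of the segment (extent jittered by up to
±3 residues) from the ATOM records into REMARK 465 entries; and residue-type
corruption of ordered residues at `mismatch_rate` = 0.02. The alignment is
emitted from the known positional homology (all members share seed
numbering), so column truth is exact and no aligner is needed. One RNG
stream per family seed in a fixed draw order makes every emitted byte
reproducible.

*Planted couplings and what passing tests mean.* Placing the disorder
segment on the protruding extended coil loop makes high-δ sites exposed
(positive δ–RSA), distant from their CLRCs (positive δ–dav; hairpin strands,
the most ordered sites, have the *smallest* contact distances), noisier
(positive δ–dsd via the larger local noise), and sheet-free (negative
δ–ss1e). These are the qualitative relationships the analysis is designed to
detect; their magnitudes are configuration knobs. The generator does *not*
emulate real side chains, hydrogen bonding, crystal contacts, paralogy,
alignment errors, or sequence-dependent disorder propensity — so passing
sign-recovery tests demonstrates that the pipeline measures what it claims
on data with known truth, not that real proteomes show effects of any
particular size.

## Problem sizes and defaults

Default analyses use families of 40 members × 120 residues (120 retained
sites), which the sign-recovery suite runs over 10 generator seeds; the
resampling test then operates at subset size ⌊0.8·120⌋ = 96 with a warning,
exactly as it would for any dataset smaller than 200 sites. All thresholds
mirror the analysis defaults: site filter ≥ 20 residues, CLRC separation
> 5, resampling 200/15/10.

## Known limitations

- Fixed-correspondence TM-scores (no alignment search) are lower bounds.
- The dihedral-region secondary-structure default disagrees with
  hydrogen-bond-based assignments at helix/strand termini and in irregular
  regions; use the .dssp ingestion backend when those labels matter.
- The resampling p-value inherits the dependence caveat above.
- mmCIF, multi-model NMR ensembles (beyond model 1), ligands and waters are
  out of scope; CLRC search does not cross chain boundaries.
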