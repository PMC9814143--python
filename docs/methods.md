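# Methods

## Fragmentation model

OAD attaches O/OH radicals to a C=C bond and cleaves one of three C–C bonds
around it. All positions are handled in methyl-anchored (n-) coordinates;
Δ-positions convert by Δ = C − n. For a double bond at n-x on a chain of C
carbons, a fragment rule is a tuple (bond site ∈ {−1, 0, +1}, hydrogen delta,
oxygen retention, optional water loss, relative intensity, diagnostic flag):

- site −1 cleaves the n-(x−1)_n-x bond, site 0 the C=C itself, site +1 the
  n-(x+1)_n-(x+2) bond;
- the lost neutral spans the methyl terminus through the cleaved bond:
  C_k H_(2k+1−2u+δH), where k = x + site and u counts the double bonds fully
  contained in the lost fragment;
- oxygen retention subtracts one O from the net loss (the attached oxygen
  stays on the charged fragment); water loss adds H2O to it.

The packaged table (`data/oad_rules.tsv`) defines 20 ion types per double
bond for ordinary acyl/ether/amide chains — 14 distinct fragments plus 6
dehydrated companions. Two are flagged as the essential *fragment pair*:
the oxygen-retaining site −1 cleavage (neutral loss C8H17−O = 97.1381 Da
for n-9) and the hydrocarbon-radical site +1 cleavage (C10H19 =
139.1487 Da). The H/O deltas of the non-diagnostic rows are a mechanistic
reconstruction (aldehyde/radical series with ±H and dehydration around each
cleavage); only the pair is anchored to printed masses, which is sufficient
because candidate discrimination rests on the pair plus peak-set overlap.

Special contexts:

- **Sphingoid Δ4** (n = C−4 on the long-chain base): fragments anomalously
  and weakly because of the neighbouring hydroxyls; a dedicated two-row
  subset mirrors the pair geometry at a 0.01 default intensity, and the
  verification threshold drops from 0.01 % to 0.005 % of the base peak.
  Sphingoid bonds at Δ ≥ 8 use the ordinary rules.
- **Vinyl ethers** (plasmalogens, P- chains): the implicit Δ1′ bond gets two
  configured oxygen-retaining entries at the n-(C−2)_n-(C−1) cleavage. For
  PE P-18:0/18:1 these land at 521.311/522.319, a few mDa from the ion
  values reported for that standard; the discrepancy is a known limitation
  of reconstructing these rows without their original tabulation, and no
  verification decision rests on them.

Head-group ions live in the subclass registry (`data/subclasses.yaml`):
phosphocholine fragment C5H15NO4P+ (184.0733) for PC/LPC/SM, neutral losses
C2H8NO4P for PE/LPE, C3H9O6P for PG, C3H8NO6P for PS, C6H13O9P for PI, and
the m/z 85 acylium marker for acylcarnitines. Relative intensities are
heuristic on a base-peak-=-1 scale: precursor and head ions 1.0 (0.3–0.5
for neutral-loss heads), diagnostic pair 0.10, other C=C ions 0.02–0.05.
Reference peaks colliding within 1e-4 Da merge keeping the maximum —
matching is presence-based, not quantitative.

Masses use pinned IUPAC monoisotopic values with electron-mass correction
on charged species; only singly charged positive adducts ([M+H]+, [M+NH4]+,
[M+Na]+) are supported, matching positive-mode OAD acquisition. All m/z
comparisons against printed values tolerate 0.0005 Da (the printed values
themselves differ from exact sums by ≤ 0.0002 Da, consistent with the
proton-adduct convention).

## Candidate enumeration

Valid assignments are tuples p1 < … < pd with p1 ≥ 3, pd ≤ C−2 and gaps ≥ 2
(no conjugated systems), giving binomial(C−3−d, d) candidates; the bounds
are configurable (`enumeration.min_pos/max_offset/min_gap`) so conjugated
systems can be enabled. Four-acyl lipids (cardiolipins) are out of scope.

## Verification and scoring

A candidate survives only if, for *every* double bond, both pair ions match
within 15 ppm and reach the context-dependent minimum relative intensity
(`matching.require_pair_all_bonds` relaxes this for review workflows).
Survivors are ranked by the reverse dot product over reference peaks with
square-root intensities; measured-only peaks are ignored (reverse contract).

Two design points were genuinely open and are resolved as follows:

- **Joint scoring instead of greedy chain-by-chain resolution.** Pair
  verification is chain-local (the pair masses depend only on that chain's
  own assignment), so chains prune independently, highest double-bond count
  first. Scoring, however, is performed jointly on the cross product of the
  surviving per-chain tuples (capped at 2000 combinations, the largest list
  halved by partial-reference score until it fits): fragment families from
  different chains merge in the spectrum, and only a complete assignment
  predicts the merged pattern. Greedy scoring against partial references
  systematically favours impostor assignments whose family coincides with
  another chain's ions.
- **Exact-tie detection by reference fingerprint.** Neutral losses depend
  only on (k, u), so distinct assignments can produce peak-for-peak
  identical reference spectra (e.g. swapping n-7/n-6 between a 16:1 and an
  18:2 chain). Such candidates are scored once and tie exactly, surfacing
  as an ambiguity (`&` notation over the differing first positions) rather
  than being decided by intensity noise. Score ties use a configurable
  epsilon (default 1e-6) with deterministic tie-breaks: more matched
  reference peaks first, then lexicographic positions.

Chain-specific attribution is *not* claimed when equal-double-bond-count
chains carry different assignments under unknown sn-order (e.g.
16:1(n-7)_18:1(n-9) vs the swap); such results are flagged
`chain-unresolved` and evaluated at the species level (multiset of position
sets). Per spectrum exactly one best annotation is emitted; co-eluting
isomers compete on score.

## Pipeline

Alignment tables are tab-delimited with a header-synonym mapping (covering
current MS-DIAL-style exports); OAD spectra come from MGF (pyteomics) or
mzML (a minimal in-package reader: MS2 scans, 32/64-bit float arrays,
optional zlib). Records and spectra join on the nearest precursor within
0.01 Da and 0.15 min. Outputs are bit-stable tab-delimited tables plus an
optional JSON-lines per-record log. RT is minutes, m/z is Da, internal
indices are 0-based. The `demote_plasmalogen_pc` flag optionally rewrites
"PC P-" to "PC O-" on output (a confidence policy, off by default).

## Synthetic data and evaluation

The simulator emulates the biogenic-standard validation design: ground-truth
species are drawn from natural methylene-interrupted series (n-7/n-9
monoenes; PUFA series starting at n-3/n-6/n-9 with steps of 3, e.g.
22:6(n-3,6,9,12,15,18)) across PC/PE/TG by default, every species carrying
at least one unsaturated chain. Spectra are reference peaks with log-normal
intensity jitter (σ = 0.3), Gaussian m/z error (σ = 3 ppm, well inside the
15 ppm window, emulating a ~30k-FWHM QTOF), and Poisson(50) noise peaks with
exponential intensities (mean 0.5 % of base, capped at 5 %). A truthset is
MGF + alignment + truth tables, regenerated byte-identically from a seed;
all randomness flows through one explicit generator.

PPV = correct top-ranked annotations / annotated records, overall and
stratified by single vs multiple unsaturated chains; attempted-record counts
are reported alongside so either denominator can be used. Ambiguous results
count as correct only when the truth is among the reported tied candidates;
chain-unresolved results are compared at the species level.

What the simulation does *not* emulate: chromatographic peak shapes, isotope
envelopes, CID spectra, intensity structure across rule types (real OAD ion
abundances vary with subclass, chain and adduct; the simulator reuses the
heuristic reference intensities), and detector saturation. Consequently
passing tests demonstrate the combinatorial, mass-arithmetic and ranking
machinery, not instrument-grade accuracy. In particular, with uniform
heuristic intensities, partial-mimic assignments in multi-PUFA lipids are
intensity-proportional to the truth, and under jitter the multiple-moiety
stratum PPV (~60–80 %) sits below what was reported on real data with the
original, measured intensity table; on noise-free spectra PPV is 100 %.

## Problem sizes and numerics

Default test and evaluation sizes: 50-species truthsets for round-trip PPV,
200 species per point for the mass-error degradation curve, enumeration
checks up to C44:6 (1.6M-tuple brute-force cross-check). Peak matching uses
nearest-within-ppm via binary search; degenerate inputs (saturated species,
empty spectra, chains too short for their double bonds) return trivial or
empty results rather than erroring, except where a contract demands an
error (empty reference spectrum, unresolved chains at reference-generation
time).

## Known limitations

- Negative-ion OAD, quantitative intensity prediction, sn-position and E/Z
  determination, cardiolipins/BMP, and spectral deconvolution of co-eluting
  isomers are out of scope.
- Non-diagnostic rule rows and the vinyl-ether/Δ4 subsets are
  reconstructions (see above); users with a measured rule table can drop it
  in via `load_rules`.
- PI/PG head-group losses dominate real OAD spectra of those classes and
  can suppress C=C ions; the engine still requires the pair, so such
  spectra typically return `unresolved` rather than a guess.
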