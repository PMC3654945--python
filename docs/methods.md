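# Methods

`tmsrep` implements a pipeline for establishing homology among the
transmembrane (TM) constituents of transporter proteins and for detecting the
internal repeats left behind by intragenic duplication. This note documents
the models, the tunable parameters and their defaults, what the synthetic
generator does and does not emulate, and the numerical choices made where the
design was open.

## The comparison score (shuffle-null significance)

Two sequences are aligned globally under an affine gap model (default
BLOSUM62; a gap of length L costs `gap_open + L * gap_extend` with
`gap_open = 8`, `gap_extend = 2`; terminal gaps are free). The alignment
quality Q is then referred to a *shuffle null*: the shorter sequence is
replaced by `n_shuffles` (default 1000; 200 in the bundled calibrations)
independent composition-preserving permutations of itself, each re-aligned,
and the comparison score is

    z = (Q - mean(Q_shuffled)) / sd(Q_shuffled)

with the n−1 sample SD. Because the permutations preserve composition, z
measures *order-specific* similarity over and above what residue composition
alone produces. Two segments are called homologous when z ≥ 10 S.D., the
alignment covers ≥ 60 residue pairs, and at least half of every claimed TMS of
both segments lies inside the aligned span. On unrelated random 150-mers the
empirical z distribution is close to standard normal (the bundled calibration
measures mean ≈ 0, SD ≈ 1.0, no pair near 10), so the 10 S.D. rule is an
extremely conservative threshold.

Percent identity and percent similarity use the number of aligned residue-pair
columns as denominator, not the alignment length, so partially overlapping
segments are not diluted by terminal overhangs. A column pair scores as a
"similarity" when its matrix score is positive; the alignment pretty-printer
marks identities `|`, matrix score ≥ 2 `:` and scores in (0, 2) `.`.

The exact gap parameters of the legacy programs this statistic descends from
are not recoverable; the defaults above are recorded in every report (as a
config digest) so results remain reproducible under any setting.

## Synthetic families (what the generator emulates)

Families are grown from a primordial 3-TMS unit: alternating loop/TMS blocks
(defaults: 23-residue helices, 22-residue loops). TMS blocks draw residues
with probability 0.8 from the strongly hydrophobic class (Kyte–Doolittle
value ≥ 1.8, weighted toward Leu/Ile/Val/Phe as in real TM cores) and 0.2
from {Gly, Ser, Thr}; loops draw 0.8 from the polar class (KD ≤ 0, uniform)
and 0.2 hydrophobic. Charged residues never enter TM cores, which matches the
strong exclusion of charge from the membrane interior.

Evolutionary events operate on whole blocks: full-length duplication (the
3→6→12 and 5→10→20 pathways), loss of a terminal TMS plus its outer loop
(6→5, in either N- or C-terminal flavour), loop insertion (the "long
hydrophilic insert between TMSs 3 and 4" scenario, preset `malF_like`), and
tail duplication. Divergence substitutes each site with probability
1 − exp(−d) and draws the replacement with probability ∝ exp(s(a,b)/2) under
the active scoring matrix, which ties detectability directly to the matrix
used for scoring. Indels (Poisson count per lineage, geometric length with
mean 3) are confined to loops, so TMS ground truth stays exact and truth
intervals are re-mapped rather than re-estimated.

Calibration (frozen in `tests/data/divergence_identity_calibration.tsv`):
d = 0.6 per lineage yields ~32% median cross-member inter-half identity for a
3+3 family — the twilight-zone regime in which within-protein repeats are
undetectable but cross-protein half comparisons still succeed. At large d the
measured identity floors at ~20–25% because free-end-gap alignment of two
hydrophobicity-structured segments always finds residual matches.

What the generator does **not** emulate: real amino-acid composition beyond
hydrophobicity structure, signal peptides, re-entrant helices, compositional
drift between paralogue families, or DNA-level evolution. Passing tests
therefore demonstrate that the *statistics and bookkeeping* behave correctly
on sequences with the right hydrophobicity architecture and known history;
they do not certify performance on any particular natural family.

## Topology profiling and TMS calling

Hydropathy is a sliding-window mean (default window 19) of the Kyte–Doolittle
scale; amphipathicity is the Eisenberg hydrophobic moment (window 11, helical
angle 100°). The TMS caller takes maximal runs with windowed hydropathy ≥ τ,
merges runs separated by fewer than `merge_gap` positions, and discards runs
shorter than `min_len`; defaults follow the classic operating point
(τ = 1.6, window 19, min_len 12, merge_gap 4) that assumes a nearly uniformly
hydrophobic TM core.

Generated TMSs carry a 20% small/hydroxyl admixture and erode further under
the substitution kernel (mean KD of a TMS block falls from 2.86 at d = 0 to
1.61 by d = 1), so the pipeline uses a calibrated profile for generator-like
data: window 13, τ = 0.65, min_len 12, merge_gap 8 (`GENERATOR_CALLER`). At
the study divergence d = 0.6 this recovers TMSs with precision ≈ 0.98 and
recall ≈ 0.96 against truth (interval match = reciprocal overlap ≥ 0.5); at
d = 1.0 exactly, recall falls to ≈ 0.9 for *any* setting of the threshold
caller — a real limitation of hydropathy-threshold calling under
similarity-matrix divergence, not a tuning artifact.

Alignment-averaged profiles compute member profiles on ungapped sequences and
project them onto alignment columns (compute-then-project), so gaps never
dilute the window means; columns with > 50% gaps are masked. The consensus
operation reports disagreements between annotation sources rather than
adjudicating them, because predictor conflicts on real proteins are resolved
case by case, not mechanically.

## Repeat scanning

Bundles of consecutive TMSs plus 5-residue flanks are spliced out of each
homologue; the first-half bundles of all members are compared against the
second-half bundles of all members (cross-protein comparisons are the key
manoeuvre — within one protein the halves may have diverged past
detectability). A two-stage scan keeps this desk-scale: all pairs are ranked
by a fast score-only local alignment, and the top k (default 50; 5 in the
bundled analyses) are validated with the shuffle z and the full decision
rule. Every validated pair stores its derived seed so any reported z can be
re-computed exactly.

The sliding-window census (`ancient_rep_scan`) compares the TMS window
starting at c of every record against every downstream same-size window of
every record and counts pairs with z ≥ 10 per category "c-(c+1)-(c+2)". A
category whose window straddles a lineage-specific insertion shows a sharp
drop in qualifying pairs, which localizes the insertion within the topology.

## Superfamily networks

Families are nodes; each demonstrated pairwise comparison is an evidence edge
carrying its z value. Parallel evidence collapses to the maximum z (all
records retained in provenance); components of the graph are superfamilies by
the transitivity of homology. The bundled evidence table for the ABC uptake
porter superfamily stores every filled cell verbatim, distinguishing cells
with an explicit "SD" suffix from bare numbers whose meaning is undocumented;
both the inclusive (z ≥ 0) and strict (z ≥ 10) analyses are first-class
because with all evidence the 33 represented families form a single
component, while the strict subgraph splits — the sub-threshold cells are
load-bearing for full connectivity. Exports (TSV edgelist, SIF, GraphML) are
round-trip safe; layout is delegated to external viewers.

## Ancestral reconstruction

Guide trees are neighbor-joining (midpoint-rooted, label-order tie-breaks) on
Kimura-corrected p-distances, d = −ln(1 − p − 0.2p²), capped with a warning
beyond the correction domain (p ≳ 0.85). Reconstruction is marginal: per
column, Felsenstein-pruning likelihoods with transition matrices from the
eigendecomposition of a time-reversible rate matrix, root posterior =
π-weighted root conditional likelihood, root residue = argmax with
alphabetical tie-break. Columns with > 50% gaps are flagged and excluded from
the root sequence; gap and unknown characters enter the pruning as missing
data. The bundled model derives exchangeabilities from the scoring matrix
(S_ab = exp(s(a,b)/2)) with uniform equilibrium frequencies — the same kernel
under which the synthetic families diverge — and is scaled to mean rate 1;
any time-reversible 20-state model can be substituted.

For the ancestral-boost comparison the family is sliced at a TMS index, each
half set is aligned independently with MAFFT (halves are the units compared,
so they are re-aligned per half rather than carved from a full-family MSA),
rows whose gap fraction exceeds 1.5× the median are dropped, each half's root
is reconstructed, and the two roots are compared by shuffle z alongside a
sample of extant cross-half pairs. On deeply diverged synthetic families the
root-vs-root score exceeds the median extant score in essentially every
replicate: reconstruction averages away independent lineage noise on both
sides simultaneously.

## Structural superposition

CA traces are parsed from fixed-column PDB ATOM records (first altloc kept).
Rigid fitting is least-squares via SVD with reflection correction
(det R = +1 always); the iterative variant drops *all* pairs beyond the
cutoff (default 2 Å) each round and refits until no pair exceeds it —
dropping all at once matches the published pruning description and converges
in a few rounds; one-at-a-time pruning is available. The RMSD sequence across
iterations is non-increasing because each refit is optimal on a subset of the
previous pair set. Fewer than 3 surviving pairs raises "superposition not
credible". Pairings may come from a global sequence alignment of the two
chains; secondary-structure-weighted pairing is out of scope, so retained
pair counts can differ slightly from structure-viewer implementations.

## Problem sizes in the bundled analyses

The calibration and recovery analyses shipped with the package use: 500–1000
random pairs at 200 shuffles for the null; families of n = 50 (repeat
recovery, 12–20 replicates), n = 25 (unrelated-family nulls and ancestral
boost, 10–20 replicates), and 100 independent proteins for TMS recovery —
sizes at which every reported rate is stable across seeds while the whole
suite runs on a single core in minutes. Larger runs only sharpen the same
estimates.

## Known limitations

- The shuffle z on hydrophobicity-structured segments is inflated relative to
  unstructured sequence (two unrelated TM bundles share composition *and*
  periodicity); the unrelated-family null analyses quantify this — the
  highest unrelated-bundle z observed is ~8, still below the 10 S.D. rule.
- Hydropathy-threshold TMS calling degrades beyond d ≈ 1 (see above);
  externally predicted annotations can be imported instead.
- Marginal reconstruction here has no among-site rate variation and no joint
  reconstruction; with very few members it approaches a consensus (a warning
  is emitted for n = 2).
- NJ + midpoint rooting assumes rough clock-likeness; for strongly
  rate-heterogeneous families the root placement, and hence the
  reconstruction, can be biased.
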