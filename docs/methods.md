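# Methods

## Model and assumptions

The mapping problem is combinatorial, not physical: a mimotope is treated
as a string over the 20 amino acids, the antigen surface as an undirected
graph over its surface residues, and an epitope candidate as a set of
simple paths on that graph whose residues are "identical" to contiguous
mimotope stretches under a physicochemical tolerance. Three assumptions
drive the design:

- **Similarity, not identity.** Mimotopes bind the same antibody as the
  epitope while differing in sequence, so residue comparison happens in a
  five-dimensional eigen-descriptor space; two amino acids with property
  distance PD ≤ 8 are interchangeable for matching purposes.
- **Gaps are free but must be geometrically realizable.** Some mimotope
  residues exist only to let the peptide adopt its bound conformation.
  Gap positions therefore carry no score penalty; instead a gap of g
  residues may only bridge seed termini whose backbone N atoms are at
  most (g+1) × 3.5 Å apart — the span of g+1 peptide steps in a fully
  extended chain. Both bounds are inclusive.
- **Longer and cleaner is better.** The final prediction unions (i) every
  seed connection whose matched positions are all exact (per-position
  PD = 0, which with distinct descriptor vectors means residue identity)
  with (ii) the overall longest connections whose average PD is in (0, 2].
  "Overall longest" is the global maximum matched length (gaps excluded)
  across all connections of the whole mimotope set, ties included; clause
  (i) admits any length ≥ the minimum seed length.

## Parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `pd_cutoff` | 8.0 | PD | inclusive residue-identity bound; raising it grows the seed set monotonically |
| `adjacency` | 4.0 | Å | surface-graph edge cutoff |
| `adjacency_metric` | `ca` | — | α-carbon pair distance; `any-atom` uses minimum heavy-atom distance |
| `nn_step` | 3.5 | Å | extended-chain N-to-N step per gap residue |
| `avg_pd_max` | 2.0 | PD | average-PD bound for the longest-connection clause |
| `surface_fraction` | 0.05 | — | strict SASA fraction of the Gly-X-Gly maximum defining "surface" |
| `epitope_delta` | 10.0 | Å² | strict ΔSASA bound defining the true epitope of a complex |
| `min_seed_len` | 2 | residues | shortest admissible seed |
| `probe_radius` | 1.4 | Å | SASA probe |

A note on `min_seed_len`: single-residue seeds would make gap bridging
degenerate (every matching residue pair chains through a gap) and blow up
the enumeration, so the floor is 2. Mimotopes are matched in N→C
orientation against paths traversed in either graph direction; reversed
*mimotope* reading is not attempted. Duplicate mimotope sequences are
dropped with a logged count — the selection rule is frequency-blind.

The `ca` adjacency default follows the stated 4 Å α-carbon rule literally.
Note that α-carbons of sequence neighbours sit ~3.8 Å apart while
non-bonded contacts are usually farther, so this metric yields
chain-like surface graphs; the `any-atom` option gives the denser contact
graphs other mappers use. Both are exposed; none of the shipped defaults
depend on the choice.

### Descriptor table provenance

The packaged 20×5 eigen-descriptor matrix is the published
multidimensional-scaling decomposition of 237 physicochemical amino-acid
properties (columns verified unit-norm). The five eigenvalue weights
packaged here — 524.3, 148.8, 85.7, 51.3, 35.9 — are this package's own
calibration of that analysis: they reproduce the published distance
scale, placing the finest amino-acid grouping near PD 9.5 and making
cutoffs in the 8–10 range discriminate mid-scale (85 of 190 unordered
pairs match at 8, median pair distance 8.6, maximum 15.5). Users with
the original eigenvalue table can supply it via
`load_descriptor_table`: a TSV whose first line is
`# lambda l1 l2 l3 l4 l5` followed by `aa E1..E5` rows. Absolute PD
values only affect which pairs fall under the cutoff; every geometric
and combinatorial guarantee of the pipeline is independent of them.

## Numerical choices

- **SASA** is Shrake–Rupley via biotite with element (Bondi) van-der-Waals
  radii, Fibonacci sphere sampling at a fixed 960 points per atom, and
  hydrogens discarded at parse time — fully deterministic. Tests
  cross-check against mdtraj's independent implementation (same radii
  convention, same probe) and agree within 1%.
- **Parsing**: first model only, highest-occupancy altloc, waters and
  non-polymer HETATM dropped, MSE treated as Met; other modified polymer
  residues are kept as SASA obstacles but are non-matchable and excluded
  from the surface map. Residue numbering is preserved exactly.
- **True epitope**: ΔSASA = SASA(antigen chains alone, complex
  coordinates) − SASA(complex); no relaxation of the antigen-alone term.
  ΔSASA is non-negative up to sphere-sampling noise (tests allow −0.1 Å²).
- **Exactness**: "average PD of 0" is implemented as *every* per-position
  PD equal to 0.0, avoiding float-tolerance games; all distance and
  cutoff comparisons are inclusive (≤ for matching/adjacency/gap span,
  strict > for the surface and ΔSASA thresholds, per their definitions).
- **Hypergeometric p-value** is the inclusive upper tail P(X ≥ k)
  computed through `scipy.stats.hypergeom`; tests verify it against a
  `math.comb` sum and subset enumeration.
- **Wilcoxon signed-rank** (one-sided, a > b) drops zero differences and
  mid-ranks ties; for ≤ 25 non-zero pairs the p-value is exact via a
  dynamic program over the 2ⁿ sign assignments (valid under mid-ranking),
  else the normal approximation with continuity correction.
- **Zero-denominator conventions**: sensitivity, precision and MCC return
  0 when undefined, so empty predictions score worst without crashing;
  the p-value of an empty prediction is 1.
- **Enumeration guards**: the seed DFS and the connection chaining raise
  a hard `SeedExplosionError` beyond configurable ceilings (10⁵ seeds per
  start position, 2×10⁶ connections) rather than silently truncating;
  the remedy is a lower `pd_cutoff`.
- The evaluation universe defaults to all residues of the selected
  antigen chains; a surface-only universe is a flag away
  (`mimotree eval --surface-only`).

## Synthetic fixtures: what they do and do not show

`make_toy_antigen` builds backbone-only (N, CA, C, O) single chains on
three geometries — extended (everything exposed), helical, and a
serpentine lattice fold at 3.4 Å spacing whose interior cells are
genuinely inaccessible to a 1.4 Å probe (buried core residues with
SASA = 0). The default chain is 40 residues with a contiguous 12-residue
epitope at positions 15–26. The epitope alphabet {A,C,K,W} is chosen to
be mutually non-matching at PD 8 and the flank alphabet {G,P} cannot
match it at all, so exact matches off the planted epitope are impossible
by construction. `make_mimotopes` derives peptides as epitope windows
(laid out to jointly cover the epitope) with PD-bounded substitutions and
inserted gap runs, and records the ground-truth alignment.

These fixtures exercise every branch of the algorithm — surface
selection, burial, seed search in both graph directions, gap bridging,
both selection clauses — under a known answer. They do *not* emulate side
chains, real packing densities, sequence-similar decoy patches,
conformational change between bound and unbound antigen, or
target-unrelated peptides in panning output; passing them demonstrates
algorithmic correctness, not benchmark-level predictive performance on
real antigens.

Measured with the shipped defaults (10 mimotopes, 20 replicates per
condition): recovery of the planted epitope is 1.000 with exact windows,
0.988 at a 20% substitution rate with one 2-residue gap per mimotope,
and 0.904 at a 40% rate — monotone in the noise level, as asserted by
the acceptance tests. Problem sizes throughout the suite (≤ 12-node
oracle graphs, 40–64-residue toys) were chosen so exhaustive
enumeration oracles remain exact references.

## Known limitations

- The published ten-case antigen–antibody benchmark cannot ship with the
  package; the evaluation pipeline (`run`/`truth`/`eval`) reproduces its
  protocol, but the per-case numbers require the user to supply the
  complex structures and mimotope sets.
- Exhaustive chain enumeration in `connect_seeds` is exponential in the
  number of compatible seeds; real antigens with permissive cutoffs can
  hit the guard ceiling, and the correct response (lowering `pd_cutoff`)
  trades recall for feasibility.
- No mimotope conformer modelling, docking, paratope analysis, or
  score-weighted (non-set) ensemble fusion.
- mmCIF input is out of scope; convert to PDB first.
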