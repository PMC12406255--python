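# Methods

This note documents the models, numerical choices and known limitations
behind each module, in the order a grafting campaign uses them.

## Structure model and parsing

Structures are parsed with gemmi and flattened to chain → residue → atom.
Only amino-acid residues carrying a C-alpha survive (waters, ligands and
backbone-less residues are dropped) so that every retained residue can
participate in superposition. Two numbering systems coexist and are never
mixed silently: `seq_id` is the author's residue number (used when
reporting epitope locations, e.g. "starts at residue 28"), `label_id` is a
gap-free 1..n index per chain (used for all internal geometry). Alternate
locations resolve to the highest-occupancy conformer, ties by file order;
insertion-coded residues are kept as distinct residues in file order.
Norleucine (`NLE`) maps to the one-letter code `Z`, other non-standard
amino acids to `X`, so synthesized scaffold variants round-trip through
PDB files. PDB output enforces the format's hard limits (99,999 atoms,
8-column coordinate fields) rather than writing corrupt records.

## Secondary structure from C-alpha geometry

Many small-peptide entries (NMR ensembles, older X-ray) lack complete
backbones, so assignment uses C-alpha distances only, in the spirit of
P-SEA. A 5-residue window starting at residue *i* is helical when

* d(i, i+2) ∈ [5.0, 6.0] Å,
* d(i, i+3) ∈ [4.8, 5.8] Å,
* d(i, i+4) ∈ [5.8, 7.0] Å.

Assignment proceeds in three passes:

1. **Core vote** — a residue is helical if ≥3 of the 5 windows covering
   it are helical (all of them near chain ends, where fewer than 3
   windows exist). The vote smooths single-residue dropouts.
2. **Window extension** — a helical window that touches a core run claims
   all five of its residues. Without this, run boundaries erode: a
   residue at a helix–loop junction is covered by exactly one all-helix
   window, and the bare vote demotes it even on noise-free geometry.
3. **Terminal refinement** — a residue adjacent to a helix run is
   promoted when ≥2 of its three individual helix distances into the run
   hold. The ideal-helix d(i,i+3) of 5.05 Å sits only 0.25 Å above the
   window's lower bound, so at realistic coordinate noise (σ ≈ 0.2 Å,
   distance noise ≈ σ√2) a single boundary window fails ~30% of the
   time; requiring 2-of-3 individual distances recovers these residues
   without ever promoting loop residues (measured false-positive rate 0
   on the synthetic fixtures).

Strand (`E`) needs d(i, i+2) ∈ [6.6, 7.4] Å with a pseudo-bond angle
≥120°; everything else is coil. Helix runs shorter than 4 residues are
demoted — a shorter "helix" cannot anchor a framework alignment. All
thresholds live in `SecStructParams` and are overridable. The labels
depend only on internal distances and angles, hence are rigid-motion
invariant by construction. No hydrogen-bond energies, no 3₁₀/π subtypes.

## Motifs, disulfides, curation

A helix–loop–helix motif is any pair of consecutive maximal helix runs
separated by a 1–12 residue gap; beyond 12 the connector is no longer one
turn. Disulfides: cysteine pairs with Sγ–Sγ ≤ 2.3 Å (canonical bond
2.05 Å plus slack), falling back to Cβ–Cβ ≤ 4.5 Å when a model lacks Sγ;
pairing is greedy nearest-first, and a cysteine within threshold of two
partners keeps the nearest with a logged warning. Connectivity is
reported in the field's Roman-numeral convention (cysteines numbered by
sequence position). The curation rule — length in [10, 50] inclusive and
≥2 cysteines — is a pure function of those two attributes and yields
machine-readable failure codes; deduplication keeps one candidate per
distinct sequence, ties to the lexicographically smallest source id.

## Superposition and ranking

`kabsch` is the SVD solution of the orthogonal Procrustes problem with
the determinant sign correction (proper rotations only); collinear
inputs are solved but flagged ill-conditioned. The test suite checks it
against an independently implemented quaternion-eigenvalue (Horn)
oracle, which computes the minimal residual from the largest eigenvalue
of the 4×4 key matrix without ever forming a rotation.

`framework_align` is the scaffold-matching score. The correspondence is
built from helix residues only, order-preserving (helix 1 onto helix 1,
helix 2 onto helix 2 — the scaffolds of interest align N→C, so
antiparallel matching is not attempted). For each helix pair the shorter
helix slides along the longer; both offsets are optimized jointly and
exhaustively, which is exact and cheap at peptide scale (offset ranges
of a few residues). Loops are excluded from the fit; when the loop
lengths match, the post-transform loop RMSD is reported as a separate
diagnostic. Exact parity with any specific alignment program is a
non-goal: reported RMSDs are algorithm-specific, and reproduction of a
published helix-framework RMSD is accepted within ±0.5 Å.

`ce_style_align` chains 8-residue fragment pairs whose internal distance
matrices agree (mean absolute difference ≤ 3.0 Å) into the longest
mutually consistent N→C path. Distance-matrix similarity is blind to
register shifts on self-similar chains — an α-helix is invariant under
its own screw symmetry — so chain admissibility additionally requires
rigid compatibility (Kabsch RMSD over the union of the two fragments
below the same threshold), ties prefer the most rigidly consistent
predecessor, and among maximal-length paths the one with the lowest
fitted RMSD wins. All alignment modes use C-alpha coordinates only;
all-atom RMSD, flexible alignment and TM-scores are out of scope.

Ranking sorts candidates by framework RMSD ascending, ties by aligned
length (longer first) then source id; candidates without a motif are
skipped with a logged reason.

## Grafting and the packaged design series

A splice replaces a 1-based inclusive span of the scaffold sequence with
an insert; the chimera inherits terminal modifications and the disulfide
count (sequence-level metadata, deliberately not re-derived from
structure). If a splice removes cysteines the count is clamped to the
remaining pairs with a warning; inserts that add cysteines warn without
changing the count. Multi-region grafts are sequential splices; the
packaged config lists them C-terminal-first so every span can be written
in the original scaffold's own numbering.

The packaged `vhti_pepitem_designs.toml` encodes the VhTI–pepitem series: the
scaffold is the synthesized 27-residue VhTI variant (native residues
5–31, Met→norleucine at the oxidation-prone position, acetyl/amide
termini, two disulfides), five designs place epitope registers into the
loop span 9–14, and one design distributes the full epitope over both
helices and the loop in three splices. Registers are explicit per design
rather than generated, because the synthesized series includes one
register with an internal deletion and two that retain a scaffold
residue at the splice boundary — not expressible as contiguous windows
of the epitope, which is what `enumerate_designs` generates.

## Masses

Neutral masses are computed from elemental composition (pyteomics
residue compositions; `Z` = C₆H₁₁NO, isobaric with Leu/Ile):
Σ residues + H₂O, +C₂H₂O for N-acetyl (+42.01057 Da mono), −OH+NH₂ for
C-amide (−0.98402 Da), −H₂ per disulfide (−2.01565 Da); [M+H]⁺ adds
1.00728 Da. Both monoisotopic and average masses are reported; the
reference convention is monoisotopic [M+H]⁺. Published calculated-mass
columns for such series are not always internally consistent — in the
reference series two entries match the monoisotopic convention to
<0.05 Da while the others sit ~0.1 Da below it, so the regression
tolerance across the whole series is 0.2 Da, with 0.1 Da enforced on the
two convention-consistent entries. No isotope envelopes, fragment masses
or retention-time prediction.

## Conservation profiles

Input must be a pre-aligned, equal-length sequence set (homolog
retrieval and MSA construction are out of scope). Per column: residue
frequencies (gap counted separately, so the 21-vector sums to 1),
Shannon entropy over the gap-renormalized 20-residue distribution,
information content IC = log₂20 − entropy clipped at 0, consensus with
alphabetical tie-break, and gap fraction. The WebLogo small-sample
correction e_n = 19/(2·ln2·n) is available behind a flag but off by
default. The logo matrix export provides both bit heights (freq × IC)
and raw frequencies, since either convention is common for published
logos.

## Assay statistics

* `percent_inhibition` = 100·(1 − treated/untreated); negative values
  mean enhanced migration and are legitimate results.
* `migration_index` = treated/epitope-treated control (control ≡ 1.0).
* `fit_ec50`: Y = bottom + (100 − bottom)/(1 + 10^(log₁₀c − log₁₀EC50)),
  top fixed at 100 (% of untreated control) and Hill slope fixed at 1.
  The fit is pooled unweighted least squares in linear response space,
  parameterized in log₁₀EC50, with a deterministic 5-point multi-start
  across the measured concentration range; bottom is bounded to
  [0, 100] because it is a migrated-cell fraction of the control. A
  series whose fitted span is below 5% is reported `converged=False`
  ("no inhibition signal") rather than returning a meaningless EC50.
* `fit_decay`: Y = (Y0 − plateau)·e^(−kt) + plateau with plateau bounded
  in [0, 100]; half-life = ln2/k. Series with no resolvable decay within
  the measured window report `converged=False`, and
  `half_life_label(t_max)` renders them as ">t_max", matching how stable
  peptides are reported.
* `teer` = (R_monolayer − R_blank) × area (Ω·cm²); negative values are
  returned (they flag a measurement problem, not a computation error).
* `papp` = (C_abl·V_abl)/(area·C_lum·t) in cm/s, with V_abl in cm³.

## Synthetic fixtures and what they do (not) show

Geometric fixtures use canonical α-helix parameters (1.5 Å rise,
100°/residue, 2.3 Å radius) joined by a circular-arc loop with C-alpha
spacing near 3.8 Å; the second helix runs antiparallel at a 10 Å hairpin
separation, pulled closer when a short loop could not otherwise bridge
it (a zero-length loop that would clash is an error). Disulfide Sγ atoms
are planted at exactly 2.05 Å after noise/transform so staple geometry is
exact by construction. Every generator is a pure function of
(parameters, seed).

The statistical generators emulate the assay designs of a grafting
campaign: concentration–response data from the constrained
three-parameter model on an 8-point, 10-fold-bracketed dilution series
(0.1–1000 nM around a 10 nM EC50) in quadruplicate — matching the four
independent measurements typical of the transwell EC50 experiments —
with additive Gaussian noise of 5 percentage points; serum decay on the
standard front-loaded schedule 0, 1, 2, 4, 8, 16, 24, 48 h; alignments
with i.i.d. per-column residue distributions.

What passing closed-loop tests show: the analysis operations recover
planted ground truth under geometric noise and rigid motion, and the
fits are statistically efficient (they match brute-force oracles). What
they do not show: real deposited structures have irregular helices,
missing atoms and non-canonical geometry that the canonical-parameter
fixtures do not emulate; real assay noise is not i.i.d. Gaussian; and
the alignment generator has no phylogenetic correlation between
sequences. Under the simulated EC50 conditions above, the median
relative EC50 error over seeded assays sits almost exactly at the 15%
mark (the estimator matches a brute-force grid search, so this is the
information content of an 8-point quadruplicate design at that noise,
not an optimizer artifact) — single-assay EC50s at these noise levels
carry real uncertainty, consistent with the large SDs such experiments
report.

## Known limitations

* Secondary structure: no hydrogen-bond model; π/3₁₀ helices fold into
  `H` or `C` by distance accident.
* The local library search stands in for database-scale structure
  retrieval; hit counts from live databases are irreproducible by
  design and out of scope, as are structure prediction, interaction
  profiling and all wet-lab procedures.
* Grafting treats designs as sequences; whether a chimera folds with the
  intended disulfide connectivity is a question for synthesis and
  structure determination, not this package.
* The CE-style aligner targets peptide-scale chains; its exhaustive
  fragment enumeration is quadratic and not tuned for whole proteomes.
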