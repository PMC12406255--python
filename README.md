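# scaffoldmatch

Structure-inspired scaffold matching and molecular grafting for
disulfide-stabilized helix–loop–helix (HLH) peptides.

## The problem

A bioactive epitope carved out of a folded protein — here the archetype is
pepitem, the 14-mer `SVTEQGAELSNEER` released from 14-3-3ζ, an endogenous
inhibitor of lymphocyte transendothelial migration — is usually unstructured
and short-lived in serum once it is synthesized as a free peptide. Molecular
grafting rescues it: find a small, conformationally rigid natural peptide
whose backbone matches the epitope's conformation in the parent protein,
splice the epitope into the matching region, and keep the scaffold's
disulfide staples and terminal protection. The α-hairpinin trypsin
inhibitor VhTI (two helices stapled by disulfides with I–IV, II–III
cysteine connectivity) is the canonical scaffold for HLH epitopes.

`scaffoldmatch` implements the desk half of that campaign for structural
bioinformaticians and peptide chemists:

* **Curation** — screen a structure library for scaffold candidates:
  10–50 residues, ≥2 cysteines, duplicates removed, HLH motif and
  disulfide connectivity annotated (`curate`).
* **Conformational matching** — rank candidates against the query epitope
  by helix-framework-constrained RMSD: the superposition
  (Kabsch, C<sub>α</sub>) is computed over helix residues only, with the
  helix-register offsets optimized exhaustively, so the loop is free to
  differ (`match`). A CE-style sequence-independent whole-chain alignment
  is available for global comparisons.
* **Grafting** — enumerate chimera designs that splice epitope windows
  into scaffold spans, with N-acetylation, C-amidation, norleucine
  substitution and disulfide bookkeeping (`graft`).
* **Peptide chemistry** — monoisotopic and average masses of the modified
  chimeras, for checking synthesis targets against MS (`mass`).
* **Assay statistics** — the downstream wet-lab calculations: % inhibition
  vs untreated control, migration index, EC50 by the constrained
  three-parameter fit (top = 100, Hill slope = 1), serum half-life by
  one-phase decay, TEER and apparent permeability P<sub>app</sub>
  (`fit-ec50`, `fit-decay`, `teer`, `papp`, `inhibition`).
* **Synthetic fixtures** — seeded generators for HLH backbones with
  planted disulfides, scaffold libraries with known truth tables, and
  simulated assay data (`simulate`), so every analysis step has a
  closed-loop test.

## The core calculations

**Framework RMSD.** For query and candidate HLH motifs with helices
H1, H2, the score is

    min over window offsets (o1, o2) of
        RMSD_Kabsch( Cα[H1_q ∪ H2_q], Cα[H1_c(o1) ∪ H2_c(o2)] )

where the shorter helix of each pair slides along the longer one and both
offsets are chosen jointly. Loop residues never enter the fit; their
post-transform RMSD is reported separately when lengths match.

**Modified-peptide mass.** Neutral monoisotopic mass is computed from
elemental composition: Σ residue compositions + H₂O, then
+C₂H₂O (acetyl, +42.01057), −OH+NH₂ (amide, −0.98402), −H₂ per disulfide
(−2.01565); norleucine (`Z`) uses the C₆H₁₁NO residue composition.
[M+H]⁺ adds 1.00728.

**Dose–response.** Y = bottom + (100 − bottom)/(1 + 10^(log₁₀c − log₁₀EC50)),
fit by pooled unweighted least squares with a deterministic multi-start.

## Worked example

Build the packaged VhTI–pepitem chimera series and compute its masses:

```sh
scaffoldmatch graft --config src/scaffoldmatch/data/vhti_pepitem_designs.toml \
    --out designs.fasta
scaffoldmatch mass --fasta designs.fasta --out masses.tsv
```

`designs.fasta` starts with

```
>VhTI-pep_1 n_term=acetyl c_term=amide n_disulfides=2
EQCKVZCYAQGAELSPELLRRCLDNCEK
>VhTI-pep_2 n_term=acetyl c_term=amide n_disulfides=2
EQCKVZCYAQGAELPELLRRCLDNCEK
```

— the pepitem loop epitope (`QGAELS` and shorter/shifted registers, bold
region) spliced into the loop of the 27-residue VhTI scaffold variant.
`masses.tsv`:

```
name        mono_neutral  mono_mh    avg_neutral  avg_mh
VhTI-pep_1  3247.5246     3248.5319  3249.7240    3250.7313
VhTI-pep_2  3160.4926     3161.4999  3162.6466    3163.6539
VhTI-pep_3  3218.4981     3219.5054  3220.6828    3221.6900
VhTI-pep_4  3176.4875     3177.4948  3178.6460    3179.6533
VhTI-pep_5  3176.4875     3177.4948  3178.6460    3179.6533
VhTI-pep_6  2950.1838     2951.1910  2952.1530    2953.1603
Pepitem     1547.7063     1548.7136  1548.5676    1549.5749
```

`mono_mh` is the monoisotopic [M+H]⁺ a MALDI-TOF instrument should see for
the folded (two-disulfide), acetylated, amidated chimera — e.g. 2951.2 Da
for the 26-mer VhTI-pep 6. Note VhTI-pep 4 and 5 are isobaric: their
epitope registers (`QGAELS` vs `EQGALS`) are the same residue multiset.

Curating a small synthetic library:

```sh
scaffoldmatch simulate library --n 6 --seed 1 --out lib
scaffoldmatch curate lib --out candidates.tsv
```

```
source  chain  length  n_cys  pass   reasons      motif             disulfides
syn000  A      9       2      False  too_short    .                 I–II
syn001  A      10      2      True   .            .                 I–II
syn002  A      50      2      True   .            1-22/23-27/28-50  I–II
syn003  A      51      2      False  too_long     1-23/24-28/29-51  I–II
syn004  A      14      0      False  too_few_cys  .                 .
syn005  A      20      4      True   .            1-7/8-12/13-20    I–IV, II–III
```

(empty fields shown as `.` for alignment)

Length bounds are inclusive (10 and 50 pass; 9 and 51 fail), the motif
column gives helix/loop/helix spans in chain-internal numbering, and the
connectivity column numbers cysteines I, II, … by sequence position.

The full pipeline (`scaffoldmatch run --library … --query … --designs …`)
chains curate → match → graft → mass and writes a manifest with the config
hash and seed, so reruns are verifiably identical.

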