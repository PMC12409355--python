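# Methods

## Scope and model

`ringscan` characterizes type III CRISPR-Cas loci from pre-computed
inputs: it consumes genome annotations and profile-HMM hit tables, never
runs a search engine, and never translates DNA. The biological model is
the standard one for type III systems: a Cas10-anchored interference
complex whose Palm/cyclase domain (GGDD-type tetrad) synthesizes cyclic
oligoadenylates (cA₃/cA₄/cA₆) or SAM-AMP; cOA-sensing effectors (CARF or
SAVED sensor domains fused to toxic domains) in the same locus; and ring
nucleases — small dedicated cOA-degrading enzymes of families Crn1
(which subsumes the Csx14 profiles), Crn2 (whose viral homologue is the
anti-CRISPR AcrIII-1), Crn3, Csx16 and Csx20, with Csx15 carried as a
candidate of uncertain activity.

## Locus geometry

Coordinates are 1-based inclusive bp throughout (GFF3 native). The cas
span is grown from the Cas10 anchor by transitive closure over cas-core
genes with intergenic gaps ≤ `chain_gap` (default 500 bp — typical
intra-operon spacing; an assumption, configurable). The RN/effector
search neighborhood is the span extended by `window` = 6000 bp per side,
clipped to the contig; membership is ≥ 1 bp overlap, measured from the
span edges (the cas operon, not the Cas10 gene alone), strand ignored,
contigs linear. A gene overlapping two neighborhoods joins the locus
with the smaller gap to its cas span, ties broken toward the smaller
locus id. Loci with overlapping spans merge (union span, best-scoring
Cas10 as anchor, neighborhood re-derived).

## Annotation rules

* Hits are used at e-value ≤ `evalue_ceiling` (default 10⁻⁴ — the
  thresholds used with any particular HMM library are not standardized,
  so this is a documented assumption, configurable per run).
* RN calls require protein length ≤ 250 aa. This is the cross-annotation
  guard: CARF-domain effectors are larger and can hit RN profiles
  through their sensor domain. When a gene qualifies as both effector
  and RN, the effector wins above 250 aa; at ≤ 250 aa the RN wins only
  if its bit score beats the effector's.
* Family per gene is the best bit score; ties break by smaller e-value,
  then alphabetical family. Profile names map through the catalogue
  (Csx14 → Crn1).
* The conserved-residue screen mechanizes what is usually manual
  curation. A reference alignment per family is reduced to retained
  columns (gap fraction ≤ `g_max` = 0.2, tolerating ragged ends); the
  consensus is the modal residue per retained column, and conserved
  columns are those whose modal residue reaches frequency ≥ `t_cons`
  among non-gap rows (default 1.0 — absolute conservation). Candidates
  are globally aligned to the consensus (BLOSUM62, gap open 10 / extend
  1, terminal gaps penalized) and fail if any conserved column is
  mismatched or deleted. Failures stay in the output with
  `screen_status=fail`; every statistic counts only non-failed RNs.
  The same screen is applied to cellular and phage candidates, and the
  250 aa cutoff applies in both scans (a single code path, by decision).
* Cas10 cyclase = any of GGDD/GGDE/SGDD anywhere in the sequence; HD
  nuclease = His followed by Asp within 4 residues in the N-terminal
  third. Both are configurable regex sets, since domain calling on real
  Cas10s is done upstream by dedicated profiles.
* Signal inference is the union of effector-family signals under a
  shipped mapping: Csx1/Can1/Can2/Cami1/Cam1/CalpL/Csx23 → cA₄,
  Csm6/Csm6-2 → cA₆, NucC/TIR-SAVED → cA₃, CorA-class → SAM-AMP.
  Csx23, NucC and TIR-SAVED assignments follow companion
  characterizations and are marked provisional in the source. Unmapped
  families yield `unknown` with a warning, never an error.
* Subtypes are read from a CCTyper-style table (matched by contig and
  span overlap); a manual-override TSV keyed by locus id wins. The
  association of RNs with cA₄ effectors is reported, not enforced: a
  locus pairing an RN with a non-cA₄ effector appears in the statistics
  rather than being suppressed, because that association is an empirical
  observation, not a rule.

## Synthetic survey generator

The generator emulates the statistical structure of a large prokaryotic
survey at desk scale so that every filter has planted positives and
negatives. What it emulates: genomes with 0–3 loci (weights
0.30/0.50/0.15/0.05); cas operons of Cas10 plus 2–4 accessory genes;
0–2 effectors per locus (13% effector-less; 15% of effector loci carry
a second family) with family weights making Csx1 the most common
effector; RN presence conditioned on the primary effector family
(0.34/0.66/0.66/0.30/0.81 for Csx1/Can1/Can2/Cami1/Cam1, 0.39 for other
cA₄ effectors, 0 for cA₆/cA₃/SAM-AMP effectors, 0.33 for effector-less
loci); 1.4% of loci carrying two RNs (≈ 4% of RN-positive loci); RN
family weights proportional to 78/68/44/37/18/7 for
Csx20/Csx16/Crn1/Crn3/Csx15/Crn2; 8% cyclase-negative Cas10s, with
III-C/III-F subtypes always cyclase-negative; orphan Csx15 genes planted
in locus-free genomes so that about 25% of Csx15 carriers lack a locus
(`n_orphan_rns="auto"`); and phage proteomes where ~30% of phages carry
one RN with family weights 36:4:2 (Crn2:Csx20:Csx16).

Planted failure modes, as absolute counts for exact verification: long
CARF decoys (> 250 aa, hitting both an RN and an effector profile; must
fall to the length rule), missing-residue decoys (one conserved position
substituted; must fail the screen), out-of-window RN genes (> 6 kbp past
the cas span; must never join a locus) and the orphan RNs above.
Spurious hits are drawn per gene at a configured rate with e-values
log-uniform on [10⁻³, 10] — above the default ceiling, so they are
separable; a `hard_noise` mode overlaps the ranges for stress testing.

Reference alignments are generated, not biological: 20 sequences per
family, length 110–170, exactly 6 absolutely conserved gap-free columns;
every other column is forced polymorphic so the conserved set recovered
from the alignment equals the planted one. Planted RNs are the consensus
with 1–8 substitutions at non-conserved positions (no indels, so the
screen's alignment step cannot mis-map a conserved column on a true
positive). Cas10 sequences are drawn from a His-free alphabet with
motifs inserted deliberately, making the cyclase and HD flags exactly
verifiable.

What the generator does **not** emulate: sequence evolution (proteins
are random strings outside planted motifs and family cores), codon
structure, overlapping genes, multi-contig assemblies (one contig per
genome; boundary clipping is still exercised by loci near contig ends),
CRISPR arrays, or phage genome organization. Passing tests therefore
demonstrate that the *decision logic* — windowing, chaining, length and
conservation filters, counting — is correct, not that the profile
searches upstream are sensitive or specific on real sequences.

## Numerical and degenerate-input choices

* All randomness flows from a single integer seed through independent
  named streams (families / genomes / phage), so datasets are
  byte-identical across runs and the phage set is reproducible whether
  or not the cellular survey is generated first.
* Decoys are planted at most one per kind per locus; requesting more
  decoys than loci aborts, as does a contig too short for its loci.
* Locus spacing guarantees disjoint neighborhoods (> 12 kbp between
  spans), so planted membership truth is unambiguous.
* Empty inputs yield empty, schema-valid outputs (headers only); an
  alignment profile with no conserved columns is unusable and aborts
  rather than passing everything.
* A failed CLI stage leaves its partial output under
  `<stage>.partial`, never mixed with complete results.

## Acceptance problem sizes

`scripts/acceptance.py` uses 200 genomes for the clean-recovery and
decoy surveys, 20 × 12 genomes for the counting identity, 100 random
fixtures per brute-force oracle, 500 single-effector loci for
association recovery, and a 400-genome default survey with 60 phages —
sizes at which the binomial error of the recovered proportions is a few
percentage points and the whole script runs in well under a minute.

## Known limitations

* The conserved-residue sets of real RN families are curated by experts
  from biological alignments; the automated screen is a faithful
  mechanization of that procedure, not a reproduction of any published
  residue list.
* Subtype calling itself is out of scope (consumed from CCTyper-style
  input), as are HMM training, tree inference, structural validation and
  the discovery of novel RN families.
* Effector-intrinsic RN activity (e.g. Csm6 degrading its own cA₆) is
  reflected only through the association statistics, not modelled as an
  annotation.
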