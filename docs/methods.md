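# Methods

## Problem setting

A peptide bound in the MHC class I groove contacts the molecule through a
small set of *anchor* positions (p2, p3, p5 and p9 for 9-mers on the mouse
allele H-2Db) and exposes the remaining *TCR-facing* positions (p1, p4, p6,
p7, p8) to the T-cell receptor. Heteroclitic epitope design exploits this
separation: anchor substitutions tune MHC affinity without changing the
surface the TCR sees, while TCR-facing substitutions (classically at p4)
change what the TCR sees without disturbing MHC binding. `pepscaffold`
derives an allele's best-fitting anchor set from data and applies it as a
reusable scaffold.

## Motif model

Given n same-length strong-binder peptides, the profile at position p over
the 20-letter alphabet is

    f[p][a] = Σ_i w_i · 1{x_i[p] = a} / Σ_i w_i

with Henikoff & Henikoff (1994) position-based sequence weights w_i: at
each column, a residue observed in s sequences among r distinct residues
contributes 1/(r·s) to each of those sequences; per-peptide sums are
rescaled to mean 1. This down-weights redundant sequences without any
clustering threshold and is fully deterministic. Weighting is the default
and can be disabled (uniform weights).

Pseudocounts follow standard profile practice:

    prob[p] = (α·f[p] + β·g[p]) / (α + β),
    g[p][a] = Σ_b f[p][b] · q(a|b)

with β the configurable pseudocount strength (default 50; β = 0 gives raw
frequencies, the mode used by count-based test oracles) and
α = effective_n − 1 where effective_n is the mean number of distinct
residues per column (the classic Henikoff heuristic for effective sample
size). The conditional profile q(a|b) is recovered from BLOSUM62: BLOSUM
scores are rounded half-bit log-odds, so 2^(s_ab/2) is proportional to the
pair target frequency over the background product; taking a flat background
and normalizing each column gives a deterministic q(a|b). This
reconstruction trades the exact Henikoff target frequencies (not shipped by
the installed libraries) for a transparent, dependency-free derivation; the
difference is a smooth monotone rescaling of the pseudo-frequency profile
and does not affect argmax-based consensus extraction.

Information content is the flat-background Kullback–Leibler form used by
Shannon sequence logos: info[p] = log2(20) − H(prob[p]), bounded in
[0, log2 20 ≈ 4.32] bits. Logo letter heights are prob · info.

The **anchor consensus** fixes, at each anchor position, the residue with
maximal corrected probability; exact ties break lexicographically by
residue letter with a logged warning (ties are measure-zero for real data
but must be deterministic). Non-anchor positions render as lowercase 'x'.

## Design operations

*Grafting* replaces the wild-type residue with the motif residue at every
anchor and nothing else; the substitution list records exactly the anchors
where the two differed, in ascending position order. Grafting is idempotent
and provably never decreases the PWM log-odds of the peptide (each replaced
term becomes the column maximum).

*Point substitution* produces single-residue heteroclitic variants;
identity substitutions are rejected as no-ops. Non-natural residues are
tokens from a registry (single character, must not collide with the 20
natural letters; 'X' is refused as it means ambiguity in sequence formats).
The NAL residue — tryptophan-derived, exact chemistry unspecified — ships
as token '1' with label "NAL"; the label deliberately carries the chemical
ambiguity rather than resolving it.

*Saturation libraries* enumerate an alphabet at one position; the member
carrying the wild-type residue is the wild type itself with an empty
substitution list, so the 20-natural-residue p4 library has exactly 20
distinct members, one of them wt.

*Conservativeness* of a substitution is flagged by BLOSUM62 score > 0
(identity = conservative, non-natural = unknown). Published qualitative
conservativeness calls do not all follow one criterion — e.g. F→L and V→A
both score 0 under BLOSUM62 yet are labelled differently in the literature
this package accompanies — so the flag is descriptive metadata in design
reports, never a gate.

## Binding comparison

The PWM log-odds score Σ_p log2(prob[p][x_p]/(1/20)) ranks peptides by
motif fit. It is a surrogate ranking, not an affinity model: no mapping to
nM is attempted, and rankings never mix log-odds with affinity records.
Affinity fold change is wt_nM / variant_nM, so "fold increase in binding
affinity" is > 1 when the variant's IC50-like value is lower. The direction
convention is stated in output headers because the reciprocal is an easy
confusion. Peptides containing non-natural residues cannot be PWM-scored
(no column for the token); they require a user-supplied affinity, mirroring
the fact that standard predictors cannot score them either.

## Assay formulas

* ELISpot SFC = mean(duplicate wells) − negative control, floored at 0:
  the subtraction is stated by assay convention without negative handling,
  and a negative count is biologically meaningless; flooring is logged per
  record. The negative control is per-record (per mouse), the most
  conservative reading of "minus the negative control".
* Cross-reactivity % = 100 · SFC_challenge / SFC_self; the self response
  defines 100, and a zero self response makes the quantity not-evaluable
  rather than infinite.
* Tumor volume = A·B²/2 (A = largest, B = smallest caliper diameter);
  inverted inputs are auto-swapped with a warning.
* Cytotoxicity: the CFSE/PI readout is reported as standard specific lysis,
  100·(dead/total − spontaneous)/(1 − spontaneous), floored at 0. The
  upstream assay kit does not print its formula; this correction is the
  field default and is recorded here as an assumption.
* Immunoscore = (GrzB − FOXP3)/CD3 on densities (cells/mm²); positive =
  cytotoxic, negative = immunosuppressive, zero = balanced. CD3 = 0 is
  not-evaluable. Marker densities exceeding CD3 are flagged with a warning,
  not an error (staining is on serial sections, so mild violations occur).
* Necrosis % = 100 · necrotic area / total tumoral mass area.
* Group summaries are mean ± SEM (sd/√n, ddof = 1); singleton groups report
  SEM as not-evaluable ('.').

Survival analysis, ANOVA and multiple-comparison corrections are out of
scope by design: the analytics emit tidy tables consumable by standard
statistics packages.

## Synthetic-data generators

All generators are pure functions of their parameters and seed (NumPy
`default_rng`), and their parameter tables are the oracles for recovery
tests.

* **Strong binders**: each position is an independent categorical draw.
  Anchors give the dominant residue its stated frequency — defaults
  A@p2 0.7, L@p3 0.7, N@p5 0.8, L@p9 0.8, encoding the canonical H-2Db
  consensus so the end-to-end demo recovers `xALxNxxxL` — with the
  remaining mass spread over the background (default uniform); non-anchor
  positions are pure background. Default n = 250, the scale of a strong-
  binder set pooled from a few proteins by a prediction server. With these
  defaults the consensus is recovered in ≥ 99 of 100 seeded replicates.
* **ELISpot**: duplicate well counts are negative binomial around
  (intended mean + negative-control mean) with excess-variance parameter d
  (var = m + d·m²); d = 0 degenerates to the exact means, the noiseless
  limit in which recovered cross-reactivity equals the specified ratios
  exactly. Default 6 mice per group, background 5 spots.
* **Tumor growth**: largest diameter grows exponentially from 2 mm at rate
  0.25/day (treated arm: rate × treatment factor), smallest diameter is
  0.8 × largest, lognormal measurement noise (sd 0.1 on the log scale),
  measurements every two days from day 7; volume > 1500 mm³ flags a death
  event, and the noiseless crossing day has a closed form used as a test
  oracle.
* **IHC densities**: lognormal with mean equal to the specified group ×
  region mean (draws are m·exp(σZ − σ²/2)), so immunoscore signs propagate
  from the means.

What the generators do **not** emulate: real binder sets have correlated
positions and length mixtures; real spot counts have plate and operator
effects; real tumors grow sub-exponentially at large volumes and regress
under effective therapy; real IHC has spatial structure. Passing tests
therefore demonstrate the correctness of the arithmetic and the
recoverability of planted structure, not biological fidelity.

## Pipeline determinism and provenance

A run is fully described by a serializable config (allele and anchors,
binder source, motif parameters, design targets, seed); the single seed
drives all randomness. Artifacts carry a header with tool version, config
hash (SHA-256 over the config minus the output directory, so the same run
written elsewhere hashes identically) and seed; the log contains no
timestamps, making reruns byte-identical. On failure, partial artifacts are
removed. TSV outputs use '.' for not-evaluable values; FASTA output wraps
at 60 columns and carries provenance as ';' comment lines, which the
package reader skips (standard parsers read the records themselves
unmodified).

## Problem sizes in tests

The test suite uses binder sets of 15–500 peptides, 25–100 seeded motif-
recovery replicates, 200–500 random cases for design invariants, and
simulation sizes of 200–2000 draws for recovery checks — small enough to
run the full suite in a few seconds on one CPU while keeping Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

* The PWM scorer is a motif-fit surrogate, not an affinity predictor; it
  should not be used to claim nM-scale effects.
* The BLOSUM62 pseudocount profile is reconstructed from rounded scores,
  not the original target frequencies (see above).
* Non-natural residues are tokens only: no chemistry, no similarity-based
  scoring unless a registry similarity row is supplied.
* Anchor maps other than the 9-mer H-2Db default must be supplied
  explicitly; nothing is inferred for other alleles or lengths.
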