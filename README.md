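# pepscaffold

Tumor-associated antigens (TAAs) are self-proteins, so the T-cell response
against them is blunted by immune tolerance. One way around this is the
*heteroclitic* peptide: a variant of a natural epitope engineered to be more
immunogenic while still eliciting T cells that cross-react with the
wild-type peptide on tumor cells. `pepscaffold` implements the design side
of this strategy for MHC class I 9-mers:

* **Anchor-consensus motif building.** From a set of strong-binder peptides
  for an allele (e.g. mouse H-2Db), build a position weight matrix with
  Henikoff & Henikoff sequence weighting and BLOSUM62 pseudocounts, compute
  per-position information content (Shannon-logo bits against a flat 1/20
  background), and read off the consensus at the anchor positions. For
  H-2Db 9-mers (anchors p2, p3, p5, p9) this yields the scaffold template
  `xALxNxxxL` — alanine at p2, leucine at p3 and p9, asparagine at p5,
  wildcards at the TCR-facing positions p1, p4, p6, p7, p8.
* **Scaffold grafting and variant libraries.** Graft the motif onto a
  wild-type epitope (substituting only anchors, never TCR-facing residues),
  apply single heteroclitic substitutions such as Y4W or D4C — including
  registered non-natural residues like the tryptophan-derived NAL — and
  enumerate p4 saturation (MIX) libraries of all 20 natural residues.
* **Binding comparison.** A PWM log-odds scorer
  (sum over positions of log2(p / (1/20))) for motif-fit ranking, and
  affinity fold-change arithmetic over IC50-like nM values
  (`fold = wt_nM / variant_nM`, > 1 means the variant binds more strongly).
* **Immunoassay analytics.** ELISpot spot-forming counts
  (duplicate mean − negative control, floored at 0) and cross-reactivity
  percentages (self-restimulation = 100), caliper tumor volume `A·B²/2`,
  specific lysis with spontaneous-death correction, the IHC immunoscore
  `(GrzB − FOXP3)/CD3` with its sign interpretation, percent necrotic area,
  and mean ± SEM group summaries.
* **Seeded synthetic data** for every stage, so the whole pipeline runs and
  is tested at desk scale with no external predictor or wet-lab data.

## Worked example

```python
from pepscaffold import (
    GeneratorSpec, H2DB_ANCHORS, anchor_consensus, build_pwm, fold_change,
    graft, parse_peptide, sample_binders, sequence_weights,
)

binders = sample_binders(GeneratorSpec(seed=7, n=250))   # strong-binder set
pwm = build_pwm(binders, sequence_weights(binders))
motif = anchor_consensus(pwm, H2DB_ANCHORS)
print(motif.display)                                      # xALxNxxxL

e7 = graft(parse_peptide("RAHYNIVTF"), motif, H2DB_ANCHORS)
print(e7.designed, e7.notation)                           # RALYNIVTL ('H3L', 'F9L')

trp2 = graft(parse_peptide("SVYDFFVWL"), motif, H2DB_ANCHORS)
print(trp2.designed, trp2.notation)                       # SALDNFVWL ('V2A', 'Y3L', 'F5N')

print(round(fold_change(6990.0, 19.6), 1))                # 356.6
```

The consensus motif fixes the four H-2Db anchors; grafting it onto the
HPV16-E7 49–57 epitope changes 2 of the 4 anchors (H3L, F9L) and onto the
Trp2 180–188 epitope 3 of 4 (V2A, Y3L, F5N), while every TCR-facing residue
is preserved — the designed peptide presents the same surface to the T-cell
receptor from an optimized MHC anchor frame. The fold change says the Trp2
scaffold binds H-2Db about 357× more strongly than the wild type
(19.6 vs 6990 nM predicted IC50).

The `examples/` directory has one short script per capability (motif
building, scaffold design, fold-change analysis, assay analytics, the full
pipeline). A thin CLI mirrors the library:

```bash
pepscaffold design --wt RAHYNIVTF --motif xALxNxxxL
pepscaffold simulate --what binders --n 250 --seed 7 --out binders.fasta
pepscaffold motif --peptides binders.fasta --out motif_out/
pepscaffold run --config config.yaml
```

## Layout

```
src/pepscaffold/   alphabet, peptide, motif, design, binding, assays,
                   simulate, pipeline, io, cli
tests/             unit + property tests (hypothesis), acceptance suite
examples/          runnable narrative scripts
docs/methods.md    models, parameter choices, assumptions, limitations
```
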