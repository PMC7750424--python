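# spyield

Antibody signal-peptide amino-acid analysis and production-rate prediction.

Recombinant antibody yield in transient mammalian expression depends not only
on the construct but on the amino acids available to make it. `spyield` is a
small analysis package for three linked questions a protein-production lab
runs into:

1. **What do antibody signal peptides use?** Signal peptides (SPs) — the short
   N-terminal tags that route antibody chains into the secretory pathway —
   differ by V-gene family. The package parses SP sequences from FASTA,
   profiles their essential amino-acid (EAA) usage as a *variety/total* pair
   (distinct EAA types / EAA residues, over the nine human EAAs
   F, H, I, K, L, M, T, V, W), and derives per-family consensus sequences from
   pre-aligned repertoires.
2. **Can the medium even supply the protein?** Treating synthesis as pure
   stoichiometry, the medium supplies `s_a` molecules of amino acid `a` and
   each antibody copy consumes `d_a` residues, so amino acid `a` alone
   supports `s_a / d_a` copies. The smallest ratio names the limiting amino
   acid and the theoretical maximum yield (Liebig's law of the minimum). The
   report also flags amino acids absent from the medium and non-essential
   amino acids whose biosynthetic precursor is missing too (S → C, G;
   D → N; E → Q, P, R).
3. **Can amino-acid counts predict production?** Variant production rates,
   normalized to a reference construct (100%), are classed low (< 20%),
   medium (20–70%) or high (> 70%) and predicted from the 20 amino-acid
   counts x with a one-vs-rest L2-regularized logistic model,

       P(y_k | x) = 1 / (1 + exp(−(β₀ₖ + βₖ·x))),   k ∈ {low, medium, high},

   one sigmoid per class (not a softmax), predicting the highest-scoring
   class. The regularization strength is tuned by 20-fold cross-validation
   (95%/5%) maximizing weighted precision, samples are inverse-frequency
   weighted, data are split 118:30:20 into a model set and two test sets, and
   the whole protocol runs in triplicate against a stratified dummy baseline,
   scored by mean pairwise (one-vs-one) ROC AUC and weighted F1.

Because the underlying 168-variant production table is not public, the
package ships a synthetic generator that emulates its statistical shape
(counts around a representative antibody composition, a planted linear
effect on a latent production score, rates up to ~250% with Gaussian noise,
a deliberate minority of high producers) so the whole pipeline is testable
end to end, including parameter recovery.

## Worked example

```python
>>> import spyield as sp

>>> prof = sp.eaa_profile("MDWTWILFLVAAATRVHS")   # the IgE signal peptide
>>> str(prof)
'8/12'

>>> media, demand = sp.media_fixture()            # DMEM supply, antibody demand
>>> report = sp.capacity(media, demand)
>>> report.limiting_eaa[0], report.max_copies_1e18("W")
('W', 1.88)
>>> report.zero_supply
('A', 'D', 'E', 'N', 'P')
>>> report.precursor_gaps
(('N', 'D'), ('P', 'E'))
```

So the IgE SP uses 8 distinct essential amino-acid types across 12 EAA
residues; in one litre of DMEM, tryptophan (0.47 × 10²⁰ molecules against 25
residues per antibody) is the limiting essential amino acid, capping yield at
1.88 × 10¹⁸ antibody copies; five non-essential amino acids are absent
entirely, and asparagine and proline cannot be back-filled because their
precursors (aspartate, glutamate) are absent as well.

The predictor, end to end on synthetic data:

```python
>>> ds = sp.generate_variants(sp.GeneratorConfig(n_variants=500, seed=1))
>>> model = sp.fit(ds.records, seed=1)
>>> X, y = sp.production_model.records_to_xy(ds.records)
>>> round(sp.pairwise_auc(y, model.normalized_scores(X)), 3)
0.956
>>> sp.recovered_sign_agreement(model, ds.planted_coefficients)
1.0
```

The fitted model separates the three production classes (pairwise AUC 0.956)
and recovers the sign of every planted amino-acid effect of at least 0.5 SD.

A command-line interface wraps the same stages:

```sh
spyield reproduce-tables --out reports/        # regenerate the fixture reports
spyield capacity media.csv demand.csv --out .  # limiting amino-acid analysis
spyield simulate --n 168 --seed 7 --out sim/   # synthetic dataset + truth
spyield evaluate sim/dataset.csv --seed 7 --out eval/   # triplicate protocol
```

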