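# conscore

Conservation and variation scores for multiple-sequence-alignment columns,
and the machinery to compare them empirically.

When homologous protein sequences are aligned, columns under strong
evolutionary constraint — catalytic residues, structural cores, binding
sites — stay conserved, and a *conservation score* quantifies that per
column. Dozens of such scores exist, built on very different ideas:
residue frequencies, Shannon/relative/Jensen-Shannon entropy, reduced
stereochemical alphabets, substitution-matrix sum-of-pairs similarity, von
Neumann entropy, and phylogenetic trees. `conscore` implements 23 of the
classical methods behind one registry, plus:

* a **method-comparison pipeline**: per-alignment Spearman correlation
  matrices between methods, their average `C̄`, the distance `D = 1 − C̄`,
  hierarchical clustering (average/single/complete linkage) and bootstrap
  node support over alignments (Newick output);
* a **catalytic-site benchmark**: per-alignment ROC/AUC of each score as a
  catalytic-site predictor, with alignment-size-capped subsets;
* a **synthetic-data generator** producing CSA-like alignment collections
  with planted catalytic, conservative-mutation and background columns, so
  the whole pipeline is testable without external data.

The package is aimed at sequence-analysis researchers who want to choose a
conservation score — or understand why two scores disagree on a site.

## The scores

All methods operate on *analyzable* columns (no gaps, no B/X/Z) and are
reported in conservation orientation (larger = more conserved); methods
whose native formulation measures variability are negated at the reporting
boundary. With `p_k` the residue distribution at site `k` (Henikoff-
Henikoff weighted for methods suffixed `w`), `q` the BLOSUM62 background,
and `M_K`, `M_V`, `M_M`, `M_L` the BLOSUM62-derived matrix family:

| family | methods |
|---|---|
| symbol frequency | `wu70` (d_k/p_k(α₀)), `lockless99` (binomial log-odds deviation from q), `pei01var(w)` (‖p_k − q‖₂) |
| stereochemical properties | `taylor86` (smallest covering set of 61), `zvelebil87` (0.9 − 0.1·n_dis) |
| symbol entropy | `shannon(w)` (S₂₀(p_k)), `wang06w` (KL(p_k‖q)), `capra07w` (Jensen-Shannon, base 2) |
| grouped / stereochemically sensitive entropy | `mirny99` (entropy over 6 groups), `williamson95` (KL vs alignment over 9 groups), `caffrey04w` (von Neumann entropy of diag(p_k)·M_f) |
| substitution matrix | `karlin96`, `sander91sp` (distance-weighted sum of pairs, M_K), `valdar01` (weighted pairs, M_V), `pei01sp(w)` (p_kᵀ M_K p_k), `thompson97` (distance to mean profile vector), `mihalek07` (pair relative entropy vs M_M), `liu08w` (similarity to the majority residue, M_L) |
| phylogeny | `mihalek04` (real-valued evolutionary trace on a UPGMA tree), `zhang08` (same with von Neumann group entropies), optional `mayrose04` adapter for an external Rate4Site executable |

`shannon` merges the Sander91/Shenkin91/Gerstein95 variants, which are
monotone transforms of one another within an alignment and therefore
identical to every rank-based comparison used here.

## Worked example

```python
import conscore as cs

alignment, annotations = cs.make_worked_example()   # 10 sequences, 10 columns
table = cs.score_alignment(alignment, annotations)  # all 23 methods
report = cs.ranking_contrast_report(table, "worked_example", 1)
print(report.to_string(index=False))
```

Column 1 of this alignment holds 40% Val and 20% each of Leu/Ile/Met — a
classic *conservative mutation* site, chemically one hydrophobic group.
The report prints each method's within-alignment normalized rank of that
column (1.0 = judged the most conserved site in the alignment):

```
      method cluster  value
     mirny99            1.0
    pei01spw            0.9
  zvelebil87            0.9
      liu08w            0.9
  sander91sp            0.9
    karlin96            0.9
  thompson97            0.9
     pei01sp            0.9
    valdar01            0.9
williamson95            0.8
    taylor86            0.2
        wu70            0.1
   pei01varw            0.1
  lockless99            0.1
    pei01var            0.1
     shannon            0.1
    shannonw            0.1
     wang06w            0.1
    capra07w            0.1
  caffrey04w            0.1
   mihalek07            0.1
   mihalek04            0.1
     zhang08            0.1
```

The split is the package's core scientific point: every substitution-
matrix method ranks the site near the top (V/L/I/M are similar under
BLOSUM62; `mirny99` even calls it perfectly conserved, value 1.00), while
every frequency/entropy method ranks it near the bottom (the majority
residue covers only 40% of the column). Which behaviour is right depends
on the application — for catalytic-site prediction, where conservative
mutations are rarely tolerated, the frequency family wins.

## Command line

```bash
conscore simulate --out-dir data/ --n-alignments 20 --seed 1
conscore score data/*.fasta --annotations data/annotations.tsv --out scores.tsv
conscore compare --scores scores.tsv --n-boot 1000 --seed 1 --out-dir comparison/
conscore evaluate data/*.fasta --scores scores.tsv --caps 10,50,168 --out auc.tsv
conscore report --scores scores.tsv --alignment-id sim0000 --column 7 --out rank.tsv
```

`compare` writes the average-correlation and distance matrices as TSV and
the bootstrap-annotated dendrogram as Newick.

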