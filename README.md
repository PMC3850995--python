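# contactbench

A toolkit for evaluating protein residue–residue contact predictions, for
developers of contact predictors and assessors of blind-prediction
experiments. It extracts true contact maps from experimental structures,
reads CASP RR-format prediction files, and computes both the standard
ranked-list accuracy metrics and coarser-grained metrics — neighbourhood
accuracy, greedy cluster accuracy and count, and pooled ROC/AUC — that
measure how well predictions identify *areas of interaction* rather than
individual residue pairs. A synthetic-data generator with exactly planted
accuracies makes the whole pipeline testable without external data.

## The metrics

**Contacts.** Residues *i*, *j* are in contact when their representative
atoms (Cβ; Cα for glycine) lie strictly within 8 Å. Contacts are binned by
sequence separation *s* = |j − i|: short [6, 12), medium [12, 24),
long [24, ∞). Pairs with *s* < 6 are not evaluated.

**Top-L/n accuracy.** For a target of length L, take the ⌊L/n⌋
highest-scored predicted pairs of a separation class (n ∈ {1, 5, 10}) and
report the fraction that are true contacts — e.g. 10 true contacts among
the top 20 predictions gives 0.50. Dataset values are per-target means with
SE = s/√N from the sample standard deviation.

**Neighbourhood accuracy.** A predicted pair (x, y) counts as correct if
some true contact (u, v) satisfies |x − u| ≤ δ and |y − v| ≤ δ (δ ∈ {1, 2}
typical). δ = 0 reduces to exact accuracy.

**Greedy clustering.** Scanning the ranked selection, a pair (x, y) becomes
a cluster representative only if |x − xᵢ| > 8 or |y − yᵢ| > 8 for every
earlier representative (xᵢ, yᵢ). The representative count measures how many
distinct interaction areas a predictor identifies; representatives are
scored with neighbourhood accuracy at δ = 2.

**Pooled ROC/AUC.** Each target's top-L (or L/n) selection is pooled across
the dataset with exact-contact labels; TPR/FPR are swept over decision
thresholds and AUC is the trapezoidal area.

## Worked example

```python
from contactbench import (
    ChainModel, PlantSpec, SelectionSpec, build_contact_map,
    exact_accuracy, generate_predictions, generate_structure,
    greedy_cluster, neighbourhood_accuracy, select_top,
)

structure = generate_structure(ChainModel(length=100, seed=42))
truth = build_contact_map(structure)           # Cβ/Cα < 8 Å contacts
preds = generate_predictions(
    truth, PlantSpec(m=20, p_exact=0.5, p_near=0.25, seed=1)
)

selected = select_top(preds, truth, SelectionSpec(divisor=5, sep_class="long"))
print(exact_accuracy(selected, truth).value)             # 0.5
print(neighbourhood_accuracy(selected, truth, 2).value)  # 0.75
print(greedy_cluster(selected).count)                    # 9
```

The top L/5 = 20 long-range predictions contain the 10 planted true
contacts, so exact accuracy is 0.5; the 5 planted near misses sit at
Chebyshev offset 2 from true contacts, so accuracy at δ = 2 rises to 0.75;
the greedy scan keeps 9 well-separated representatives out of the 20 ranked
pairs.

The same pipeline runs from the shell on real data:

```sh
contactbench eval --rr method.rr --pdb target.pdb --chain A \
    --fasta target.fasta --format markdown
contactbench benchmark --rr-dir submissions/ --truth-dir truth/ --format tsv
contactbench simulate --out sim/ --n-targets 5 --length 80 --seed 1
```

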