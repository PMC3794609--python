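# tissueranker

Mutations in a human gene usually cause phenotypes in only a few tissues.
`tissueranker` predicts which tissues those are for a hub protein by asking
where the hub's protein complex — the hub plus its direct interaction
partners in a protein–protein interaction network — shows the most
*coordinated expression*: the tissue where hub and partners rise and fall
together across replicate samples is the tissue where the complex is most
likely active, and where deregulating the hub is most likely to hurt.

## Method

For a complex *C* with hub *H* and interactors *I₁…Iₙ*, and a tissue *t*
with *nₜ* replicate samples, the coordination score is the mean Pearson
correlation between the hub's expression profile and each interactor's
profile over the samples of that tissue:

    ρ̄(C, t) = (1/n) Σᵢ PCC(e_H,t , e_Iᵢ,t)

Because replicate counts differ strongly between tissues, ρ̄ is
Fisher-transformed, z = atanh(ρ̄), and standardized by the reciprocal
standard error of a Fisher-transformed correlation,

    z(C, t) = atanh(ρ̄(C, t)) · √(nₜ − 3),

so scores from small and large tissues are comparable (an empirical
per-tissue z-score is available as an alternative).  Tissues are then
ranked per complex by decreasing score.

Rankings are evaluated against a gold standard of (gene, disease) →
tissue-category associations by rank-threshold ROC: each category's score
is minus its predicted rank, and the trapezoidal AUC (with midpoint tie
handling) equals the Mann–Whitney probability that a true disease tissue
outranks a non-disease tissue.  Two controls frame the result: a
single-protein baseline that ranks tissues by the Welch t statistic of the
hub's own expression (tissue vs the rest), and a randomization null that
shuffles each tissue's gene-to-expression assignment and reruns the whole
pipeline.  The package also builds genome-wide tissue distance matrices
(1 − PCC of mean tissue profiles) and unrooted neighbor-joining trees.

## Worked example

The package ships a synthetic-fixture generator that plants a latent
coordination factor for each of 8 hub complexes in one designated tissue
(population hub–interactor correlation 0.9) while keeping all tissue means
equal, so only co-expression — not differential expression — carries the
signal:

```sh
tissueranker simulate --out demo/fixture --seed 7
tissueranker rank --network demo/fixture/network.tsv \
    --expression demo/fixture/expression.tsv \
    --metadata demo/fixture/metadata.tsv --out demo/rank
# wrote coordination matrix (9 complexes x 6 tissues) and rankings to demo/rank
```

`demo/rank/rankings.tsv` lists tissues per complex in decreasing score;
HUB00 was planted in tissue00 and recovers it at rank 1 with a clear
margin (z = 3.53 vs 0.34 for the runner-up):

```
complex  rank  tissue    score
HUB00    1     tissue00  3.530615719240884
HUB00    2     tissue03  0.33808971933801174
HUB00    3     tissue04  0.11348418067846117
```

Benchmarking against the fixture's gold standard reproduces the expected
ordering — complex-based ranking beats the single-protein baseline, which
sits near the shuffling null at chance level:

```sh
tissueranker benchmark --network demo/fixture/network.tsv \
    --expression demo/fixture/expression.tsv \
    --metadata demo/fixture/metadata.tsv \
    --gold demo/fixture/gold_standard.tsv \
    --categories demo/fixture/tissue_categories.tsv \
    --null-reps 25 --seed 7 --out demo/bench
# overall AUC 1.000 | baseline AUC 0.775 | null mean AUC 0.500 (sd 0.101, 25 reps)
```

An overall AUC of 1.000 means every planted tissue category outranks every
unplanted one; the baseline's 0.775 reflects only chance structure (its
expectation is 0.5 — tissue means are equal by construction), and the
null's 0.500 confirms the shuffle destroys the signal.  Finally,

```sh
tissueranker tree --expression demo/fixture/expression.tsv \
    --metadata demo/fixture/metadata.tsv --out demo/tree
# wrote 6-tissue distance matrix and tree to demo/tree
```

writes the 1 − PCC tissue distance matrix and its neighbor-joining tree in
Newick format.

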