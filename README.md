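# genedecay

Inference of gene loss and relaxed selection from coding-sequence
alignments.

`genedecay` is built for comparative studies of *pseudogenization* — the decay
of protein-coding genes after their function is lost — of the kind used to
show that whales have lost most of their taste receptor genes. Given per-gene
codon alignments, a species tree, and a species manifest, it:

1. **scans** each gene for ORF-disrupting mutations: frame-shifting indels
   (length not a multiple of 3) and premature stop codons in the reference
   reading frame;
2. **groups** identical disruptions across species and classes their sharing
   (`S` = shared across toothed and baleen whales, `S*` = toothed only,
   `S#` = baleen only, `U` = unshared), then **dates** each shared loss by
   Dollo parsimony — the branch above the most recent common ancestor of all
   carriers;
3. **quantifies selection** with pairwise dN/dS by the modified
   Nei–Gojobori method (transition/transversion-weighted site counting,
   pathway-averaged difference counting, Jukes–Cantor correction, Z-tests of
   neutrality, one-sample t-tests of group means);
4. **fits branch models**: maximum-likelihood ω = dN/dS per branch class
   under the GY94 codon model with Felsenstein pruning, and compares nested
   models (one-ratio, stem-two-ratio, crown-two-ratio, stem-plus-crown,
   toothed-vs-baleen) by chi-square likelihood-ratio tests;
5. **reconstructs ancestral sequences** (marginal empirical-Bayes posteriors
   under nucleotide HKY) so a clade's inferred ancestor can be analyzed as an
   observed tip;
6. **simulates** codon alignments along a phylogeny with per-branch ω and
   explicit *gene-death events* — after a loss point the lineage and its
   descendants evolve neutrally at the nucleotide level, accumulate stop
   codons, and pick up frame-shift-biased indels — with an exact truth log,
   so the whole chain is testable without any sequence downloads.

## The model in brief

The GY94 generator over the 61 sense codons has off-diagonal rates

    q_ij = 0                          (codons differ at >1 position)
    q_ij = π_j                        (synonymous transversion)
    q_ij = κ π_j                      (synonymous transition)
    q_ij = ω π_j                      (nonsynonymous transversion)
    q_ij = ω κ π_j                    (nonsynonymous transition)

scaled to one expected substitution per codon per unit branch length.
Branch-class models assign one ω per class of branches; nested fits are
compared with 2ΔlnL ~ χ²(df), one degree of freedom per freed ω.
Pairwise distances use d = −(3/4)·ln(1 − 4p/3) with analytic variance
9p(1−p)/((3−4p)²m) and Z = (dN − dS)/√(varN + varS).

## Worked example

Simulate the canned fixture suite (a 12-taxon whale-shaped tree with a gene
lost on the stem whale branch), then run the study:

```bash
genedecay simulate --out fixtures
genedecay scan --alignment fixtures/stem_loss.fasta --reference Cow \
    --manifest fixtures/stem_loss.manifest.tsv --tree fixtures/stem_loss.nwk \
    --gene G1 | head -6
```

```
gene	kind	ref_start_1based	length	carriers	class	loss_branch
G1	premature_stop	37	3	Lacu,Lalb,Ttru	S*	node8
G1	premature_stop	64	3	Bede,Bmys,Bomu,Bphy	S#	node15
G1	frameshift_deletion	66	4	Pcat	U	Pcat
G1	frameshift_deletion	120	1	Bacu,Bede,Bmys,Bomu,Bphy,Gmel,Lacu,Lalb,Npho,Pcat,Ttru	S	node3
G1	premature_stop	142	3	Lacu,Lalb	S*	node9
```

The 1-bp deletion at reference position 120 is carried by every whale but
not the outgroup, with identical coordinates in toothed and baleen species
(class `S`), so it is assigned to `node3` — the stem whale branch — dating
the loss before the toothed/baleen split. The `S*`/`S#` rows are
post-divergence hits shared within one clade (assigned to branches inside
it), and `U` rows are private to a single species.

Fit the branch-model ladder on the same gene and test for relaxation:

```bash
genedecay fit --alignment fixtures/stem_loss.fasta --reference Cow \
    --tree fixtures/stem_loss.nwk --manifest fixtures/stem_loss.manifest.tsv \
    --scheme crown_two_ratio --fix-branch-lengths --out alt.json
genedecay fit ... --scheme one_ratio --fix-branch-lengths --out null.json
genedecay lrt --null null.json --alt alt.json
```

A whole study (many genes, status matrix, dN/dS table, model-comparison
table) runs from one YAML config with `genedecay run --config study.yaml`;
the status matrix uses the cell vocabulary `+ − . S S* S# U`.

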