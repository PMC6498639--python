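# ssdfate

Evolutionary fates of small-scale duplicate (SSD) genes, inferred from
tissue-expression divergence.

After a small-scale duplication, a gene pair can be retained by four
mechanisms: **conservation** (both copies keep the ancestral expression
profile), **neofunctionalization** (one copy diverges; "parent" or "child"
names the diverged copy), **subfunctionalization** (the ancestral profile
is divided between the copies), or **specialization** (both copies and
their combined profile diverge).  `ssdfate` implements the phylogenetic
expression-comparison approach used to classify these fates in grasses
(*Brachypodium distachyon*, *Oryza sativa japonica*, *Sorghum bicolor*)
from nine-tissue RNA-seq TPM profiles, together with every surrounding
pipeline stage:

- **Family reconstruction** — ancestral gene-family sizes on a species tree
  by asymmetric Wagner parsimony (configurable gain/loss penalties), and
  extraction of 1 → 2 duplication events with a single-copy ancestral
  proxy in a sister species.
- **Parent/child polarity** — prioritised majority voting over ortholog
  evidence sources (default priority OrthoMCL > i-ADHoRE > TribeMCL).
- **Retention classification** — on log2(TPM+1) profiles, the Euclidean
  distances E<sub>P,A</sub>, E<sub>C,A</sub> and E<sub>P+C,A</sub>
  (combined copies) are compared against a cutoff E<sub>div</sub>
  calibrated as a quantile (default 0.95) of the distance distribution of
  single-copy ortholog pairs E<sub>S1,S2</sub>:

  | E<sub>P,A</sub> ≤ E<sub>div</sub> | E<sub>C,A</sub> ≤ E<sub>div</sub> | E<sub>P+C,A</sub> ≤ E<sub>div</sub> | call |
  |---|---|---|---|
  | yes | yes | – | conservation |
  | one of the two | | – | neofunctionalization (diverged copy) |
  | no | no | yes | subfunctionalization |
  | no | no | no | specialization |

- **Duplication mechanism** — DNA- vs RNA-mediated calls from exon counts
  (multi-exon parent with single-exon child ⇒ retroposition).
- **Statistics** — expected-count χ² enrichment of DNA/RNA mechanisms per
  retention class, age-class tests, tissue-specificity τ, exact two-tailed
  binomial primary-tissue enrichment with Bonferroni correction, and
  Pearson tests of expression divergence against K<sub>a</sub>,
  K<sub>s</sub>, K<sub>a</sub>/K<sub>s</sub> (records with
  K<sub>s</sub> ≥ 3 excluded).
- **Synthetic data** — a seed-deterministic generator that emulates every
  input with known truth, so the full pipeline is testable end to end
  without any downloads (see `docs/methods.md`).

## Worked example

The core classifier follows the model/results idiom:

```python
from ssdfate import SimulationConfig, run_synthetic

dataset, result, scores = run_synthetic(SimulationConfig(seed=0))
print(result.retention.summary())
```

```
Retention-mechanism classification
==================================================
Trios classified:   400    excluded: 0
E_div = 2.7699  (quantile, q=0.95, 3000 ortholog pairs)
--------------------------------------------------
conservation                    93  ( 23.2%)
neofunctionalization_parent     50  ( 12.5%)
neofunctionalization_child      50  ( 12.5%)
subfunctionalization            93  ( 23.2%)
specialization                 114  ( 28.5%)
==================================================
```

The synthetic study plants 100 trios per mechanism; E_div = 2.77 is the
0.95 quantile of the 3000 simulated single-copy ortholog distances, and
the classified counts track the planted 100/100/100/100 design
(`scores["recall"]` here: conservation 0.92, neofunctionalization 0.96,
subfunctionalization 0.92, specialization 0.99; polarity accuracy 0.9975).

The counts-level analyses run directly from the bundled grass tables:

```bash
ssdfate tables --bundled
```

```
Pooled retention percentages:
  conservation            60.6%
  neofunctionalization    23.8%
  subfunctionalization     0.4%
  specialization          15.2%
Child bias of neofunctionalization:
  B. distachyon            72%
  O. sativa japonica       70%
  S. bicolor               89%
Observed (expected) counts and chi-square P by mechanism:
  conservation                 464 (455.98)  28 (36.02)   P = 0.17
  neofunctionalization_parent  39 (38.00)  2 (3.00)   P = 0.55
  neofunctionalization_child   126 (134.39)  19 (10.61)   P = 0.01
  specialization               80 (80.63)  7 (6.37)   P = 0.79
```

Conservation dominates (60.6% of 901 pooled pairs), neofunctionalization
is strongly child-biased (72–89% of neofunctionalized genes are child
copies), and RNA-mediated duplicates are over-represented among
child-neofunctionalized pairs (19 observed vs 10.61 expected, P = 0.01) —
the signature linking retroposition to the acquisition of new functions
by child copies.

The CLI also exposes `simulate`, `run`, `reconstruct`, `polarity`,
`classify`, `mechanism` and `report` subcommands over dataset
directories; see `ssdfate --help`.

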