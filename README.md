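# pathcombo

Predicting synergistic anticancer drug combinations from gene expression.

Tumor cells cultured long-term in a targeted drug (a tyrosine-kinase
inhibitor or a rapalogue) acquire resistance by rewiring their signaling.
`pathcombo` implements a transcriptomics pipeline for choosing a second
drug that blocks that rewiring: it scores signaling-pathway activation in
drug-exposed cells against pooled drug-free controls, intersects the most
strongly upregulated pathways to find the proteins involved in as many of
them as possible, maps those proteins to available inhibitors, and
provides the wet-lab analytics (IC20/IC50 fitting and Bliss-independence
scoring) needed to verify whether the suggested combinations actually act
synergistically.

It is aimed at computational biologists analyzing bulk expression
profiles of drug-adapted cell lines, and at anyone who needs a
self-contained, testable implementation of pathway activation scoring
plus Bliss synergy analysis.

## The model

For a pathway *p* and a case sample, the **pathway activation strength** is

```
PAS_p = Σ_n ARR_np · log10(CNR_n)
```

where `CNR_n` is the case-to-normal ratio — gene *n*'s expression divided
by the geometric mean of its expression across the matched control
samples — and `ARR_np ∈ {−1, −0.5, 0, 0.5, 1}` is the gene's fixed
activator/repressor role in the pathway (+1 activator, −1 repressor,
±0.5 leaning, 0 ambivalent). Expression is quantile-normalized first;
PAS > 0 means the pathway is upregulated versus control.

Targets are predicted per condition (cell line × drug × timepoint) by
taking the top decile of pathways by PAS (k = ⌈0.1·P⌉) and ranking genes
by the number of selected pathways that contain them; genes with the
maximal count are the candidate targets, and any mapped inhibitor of a
top-ranked gene becomes a suggested combination partner.

Combinations are validated in a fixed-IC20 design: the partner is held at
its IC20 while the original drug is titrated. With single-agent
inhibition `Y1` and partner inhibition `Y2`, the Bliss independence null
expects combined inhibition `Y1 + Y2 − Y1·Y2`; the synergy score is 100 ×
the mean per-dose excess over that null, with score > 5 called
synergistic, < −5 antagonistic, and additive otherwise.

## Worked example

A miniature study ships in `examples/`: SKOV-3 cells after 16 weeks of
Sorafenib, two drug-free controls, and a four-pathway knowledge base.
From the repository root:

```bash
pathcombo run --config examples/config.yaml
```

prints the four artifact paths, and `results/demo/summary.txt` reads:

```
pathways: 4  genes: 11  case samples: 1  controls: 2
skov3_sorafenib_w16: top pathways 2; candidate targets [PLCG1]; suggested partners [U73122]
```

The PAS table (`results/demo/pas.tsv`) shows what drove the call:

```
pathway	sample	pas	coverage_fraction
PLC_SIGNALING	skov3_sorafenib_w16	0.7390717016	1
RAS_MAPK	skov3_sorafenib_w16	1.488180132	1
NOTCH_SIGNALING	skov3_sorafenib_w16	-0.1505957411	1
CELL_CYCLE	skov3_sorafenib_w16	-0.2007444832	1
```

RAS/MAPK and phospholipase-C signaling are upregulated in the
Sorafenib-exposed sample (positive PAS); the top half (fraction 0.5 of 4
pathways) is selected, and PLCG1 — a member of both — is the unique
maximal-count candidate (count 2). Through the alias table
(PLCG1 → PLC) it matches the phospholipase-C inhibitor U73122, which is
suggested as the combination partner; Sorafenib itself is excluded as the
baseline drug.

Dose–response analytics run on plate tables (`pathcombo ic`,
`pathcombo synergy`), and `pathcombo simulate --seed 7 --out-dir study/`
writes a complete synthetic study — expression, pathways, drug map and
MTT plates with known planted ground truth — whose config can be fed
straight back into `pathcombo run`.

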