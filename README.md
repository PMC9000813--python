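# nucsig

Mining and detection of **taxon-diagnostic nucleotide signatures** — short
DNA windows (typically 20–50 bp) that identify a whole genus in mixed,
processed or degraded material where full-length barcodes no longer amplify.

## The problem and who this is for

Regulatory and forensic labs often need to ask "does this powder / pill /
extract contain plant material from genus X?" rather than "which species is
this voucher?". Standard DNA barcodes (ITS2, *psbA–trnH*, ...) are a few
hundred bp and routinely fail on such samples because processing shears the
DNA. The practical alternative is a *nucleotide signature*: a window **w**
over the IUPAC nucleotide alphabet that is

* **intragenus-conserved** — present without variation in every ingroup
  sequence: `conservation_fraction(w) = |{s ∈ I : w ⊑ s}| / |I| ≥ τ`
  (default τ = 1), and
* **intergeneric-specific** — at Hamming distance
  `d(w) = min over all full-length placements of w in any outgroup sequence
  (both strands)` of at least `d_min` (default 1: "at least one variation"),

retrieved from query sequences directly or from a short (~150 bp) PCR
product spanning it. The two criteria pull in opposite directions: longer
windows lose conservation, shorter ones lose specificity. Because
conservation is anti-monotone and Hamming specificity monotone in window
length, the *shortest* window satisfying both is well defined, and per
anchor position it can be found by binary search. `nucsig` implements that
search, the supporting primitives (conserved-region discovery, outgroup
scoring, in-silico PCR, detection), and seeded synthetic-data generators
with planted ground truth. The packaged worked example is the *Ephedra*
ITS2 assay: a 55-bp relatively conserved fragment, the nested candidate
ladder S1–S7, the selected 23-bp genus-level signature
`GTCCGGTCCGCCTCGGCGGTGCG`, and the MH-1F/MH-1R primer pair.

## Worked example

```python
from nucsig import SignatureMiner, evaluate_candidates
from nucsig.fixtures import ladder_windows
from nucsig.mining import audit_table
from nucsig.synth import demo_scenario

ingroup, outgroup, truth = demo_scenario(seed=0)   # 12 ingroup, 4 outgroup records
miner = SignatureMiner(min_len=15, max_len=55, d_min=1).fit((ingroup, outgroup))
print(miner.signature_)

evs = evaluate_candidates(ladder_windows(), ingroup, outgroup)
print(audit_table(evs)[["sequence", "length", "conserved", "min_distance", "specific"]]
      .to_string(index=False, max_colwidth=28))

print(miner.predict(["ACGT" * 40, "TT" + miner.signature_ + "GG"]))
```

prints

```
GTCCGGTCCGCCTCGGCGGTGCG
                    sequence  length  conserved  min_distance  specific
TCGGGGGGACGGCCTTGACCGTCCG...      55      False           2.0      True
GGGGGACGGCCTTGACCGTCCGGTC...      45      False           2.0      True
GCCTTGACCGTCCGGTCCGCCTCGG...      35      False           2.0      True
GACCGTCCGGTCCGCCTCGGCGGTG...      30      False           2.0      True
 CCGTCCGGTCCGCCTCGGCGGTGCGGT      27      False           1.0      True
     GTCCGGTCCGCCTCGGCGGTGCG      23       True           1.0      True
        CCGGTCCGCCTCGGCGGTGC      20       True           0.0     False
[False  True]
```

Reading the table: the five longest candidates are no longer fully
conserved in the ingroup (one ingroup record varies outside the signature
region), the 20-mer occurs exactly in the outgroup (`min_distance 0` — not
specific), and the 23-mer is the unique window passing both criteria. The
miner returns exactly that 23-mer, and `predict` flags which queries
contain it.

The same operations are available from the shell:

```bash
nucsig fixtures --check                 # validate the packaged worked example
nucsig simulate ingroup  --seed 1 --n 12 --out ingroup.fa
nucsig simulate outgroup --seed 2 --period 23 --out outgroup.fa
nucsig mine --ingroup ingroup.fa --outgroup outgroup.fa --out audit.tsv --json result.json
nucsig detect --queries queries.fa --signature GTCCGGTCCGCCTCGGCGGTGCG
nucsig pcr --template templates.fa --fwd TCATCGAGTCTTTGAACGC --rev ATGCGAAGGTCCCCTTTT
```

Exit codes: 0 success, 1 usage error, 2 data error.

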