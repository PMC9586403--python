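# loxscreen

Quantifying how point mutations in a loxP site change its recognition by Cre
recombinase, from competitive excision amplicon sequencing.

## The problem

Cre excises DNA between two compatible lox sites. A lox site is two 13-bp
recombinase-binding elements (RBEs) flanking an 8-bp spacer; loxP and lox2272
have identical RBEs but incompatible spacers, so a cassette carrying a
loxP pair *and* a lox2272 pair supports two mutually exclusive excision
events. If the loxP pair carries mutations in its right RBE, its ability to
compete against the wild-type lox2272 pair measures how well Cre still
recognizes it. The per-variant statistic is the **cleavage rate between loxP**:

```
cleavage rate (%)     = 100 · n_loxP / (n_loxP + n_lox2272)
non-cleavage rate (%) = 100 · n_uncleaved / (n_uncleaved + n_loxP + n_lox2272)
```

where the counts are read pairs classified by which diagnostic marker tags
they retain (both = uncleaved, marker A only = loxP-excised, marker B only =
lox2272-excised). Variants spanning cleavage rates from under 1% to ~60%
make tunable sparse-labeling drivers: a mutant loxP with a 1% rate labels
~1% of cells in a Cre-expressing population.

The mutant library itself is made by biased (doped) oligo synthesis: each of
the 13 right-RBE positions keeps the wild-type base with probability x/100,
so the number of substitutions y per molecule is binomial,

```
P(y) = C(13, y) · (x/100)^(13−y) · ((100−x)/100)^y
```

At x = 84.7 the mode is y = 2 and ~30% of molecules are double mutants.

`loxscreen` implements the full pipeline — library design model, synthetic
cassette/read simulator with ground truth, exact-match read classifier, and a
qPCR standard-curve validation path — as a tested Python package with
numbered analysis drivers.

## Worked example

```python
import loxscreen as lx

# the design model at the study's retention rate
d = lx.substitution_count_distribution(lx.DesignSpec(retention_pct=84.7))
print(round(d[2], 4), d.argmax())       # 0.2939 2

# simulate a 3-variant screen and estimate rates from the reads
truth = [
    lx.TruthRecord(lx.RbeVariant("TATACGAAGTTAT"), 0.035, 0.50, 2000),   # WT
    lx.TruthRecord(lx.RbeVariant("GATGTCAAGATAG"), 0.035, 0.173, 2000),
]
paths = lx.generate_fastq(truth, "scratch/demo", seed=1)
est = lx.estimate_library(paths["r1"], paths["r2"], paths["markers"])
print(est[["variant_sequence", "cleavage_rate_pct", "passes_cutoff"]])
```

prints (sampling noise of a depth-2000 multinomial draw):

```
  variant_sequence  cleavage_rate_pct  passes_cutoff
0    GATGTCAAGATAG          18.655550           True
1    TATACGAAGTTAT          50.025786           True
```

i.e. the 6-substitution variant diverts only ~19% of excision events to the
loxP pair while the wild type splits them 50/50, and both exceed the
\>500-read reliability cutoff.

The numbered drivers under `analysis/` run the same machinery at study
scale and narrate what they find:

```
python analysis/01_design_library.py   # spectrum + coverage of the doped library
python analysis/02_simulate_reads.py   # FASTQ + truth for the 50 reference variants
python analysis/03_classify_reads.py   # ranked estimates, recovery vs truth
python analysis/04_qpcr_validation.py  # standard curves, concordance R², Cre test
python analysis/05_report.py           # end-to-end report under one config
```

Tables land under `results/`; bulky FASTQ under `scratch/`. A packaged
50-variant reference table (`loxscreen.reference`) provides realistic truth
rates (17.3%–34.6%, 2–6 substitutions) for simulations.

## Layout

- `src/loxscreen/design.py` — doping model, variant-space enumeration, coverage, composition
- `src/loxscreen/simulate.py` — cassette assembly, excision products, outcome draws, FASTQ
- `src/loxscreen/classify.py` — anchor/marker read classification and rate estimation
- `src/loxscreen/qpcr.py` — standard curves, copy quantification, concordance
- `src/loxscreen/workflow.py` — RunConfig, end-to-end driver, group summaries
- `docs/methods.md` — model assumptions, parameter choices, limitations
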