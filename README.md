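# tdmdscreen

Screening for **target-RNA-directed miRNA degradation (TDMD) triggers** in
AGO-CLASH chimeric sequencing data.

Most miRNA-target encounters silence the target. In TDMD the logic is
inverted: a target site with extensive complementarity to the miRNA's 3'
half — in addition to seed pairing — reshapes Argonaute so that the
Dora/ZSWIM8 ubiquitin ligase marks it for decay, destroying the *miRNA*
instead. Sites that do this are called *triggers*. CLASH (crosslinking,
ligation and sequencing of hybrids) captures miRNA-target pairs as single
chimeric reads, so comparing chimera libraries from ligase-knockout versus
control cells lets one screen transcriptome-wide for triggers: their
hybrids are stabilized, hence enriched, when TDMD is blocked.

This package provides that screen as a library plus a `tdmd-screen` CLI:
read cleanup with UMI-based duplicate collapse, chimera splitting and
transcriptome mapping, intermolecular duplex folding under a documented
nearest-neighbor-style energy model, the four structural TDMD criteria,
the two abundance criteria, small-RNA quantification (18-nt prefix rule,
isomiR length distributions, median-of-ratios normalization), target
repression analytics (seed-match target sets, cumulative fold-change
curves, exact/asymptotic Mann-Whitney tests, organ-normalized
correlation), and a synthetic-data generator that plants triggers and
single-criterion decoys with verifiable ground truth.

## The screen

For each merged miRNA x target site, the minimum-energy antiparallel
duplex is computed and the site is a **candidate** iff all four hold
(miRNA positions 1..L from the 5' end):

1. *seed* — positions 2–8 all paired, G:U wobbles allowed;
2. *3' pairing* — the last 8 positions all paired, or a run of ≥ 9
   consecutive pairs reaching into that window;
3. *central loop* — the unpaired stretch between seed helix and 3' helix
   (max over strands) is > 0 and < 7 nt;
4. *energy* — duplex ΔG ≤ −16 kcal/mol.

A candidate is a **high-confidence trigger** if, additionally, its hybrid
abundance in the knockout is > 100 RPM and > 4-fold the control
(RPM + 0.1 pseudocount). Every threshold lives in one `ScreenConfig`.

See `docs/methods.md` for the energy model, all conventions and the
synthetic-data design.

## Worked example

Fold one duplex (a let-7 site with a 3-nt central loop region):

```text
$ tdmd-screen fold --mirna UGAGGUAGUAGGUUGUAUAGUU --target AACUAUACAACAAGCCUACCUCA
5'-UGAGGUAGUAGGUUGUAUAGUU-3'  (miRNA)
   ||||||||...|||||||||||
dG = -29.9 kcal/mol, 19 pairs
```

The diagram marks Watson-Crick pairs `|`, wobbles `:`, unpaired `.`:
seed (2–8) and the entire 3' half are paired around a 3-nt loop, and
−29.9 kcal/mol clears the −16 threshold — a TDMD-compatible geometry.

Simulate a down-scaled scenario and screen it end-to-end:

```bash
tdmd-screen simulate --outdir demo --seed 3 --config small.yaml
tdmd-screen screen \
    --fastqs control_1:control=demo/control_1.fastq ... ko_3:ko=demo/ko_3.fastq \
    --mirnas demo/mirnas.fasta --transcripts demo/transcripts.fasta \
    --adapter3 AGATCGGAAGAGCACACGTCTG --out demo/candidates.tsv
```

The high-confidence rows of `candidates.tsv` from that run:

```text
  mirna transcript  site_start  site_end    dg       ko_rpm  fold_change
mir-002    tx-0052         391       446 -42.4 11870.332801     7.905565
mir-003    tx-0011         450       499 -34.4  9021.452929     6.898287
mir-001    tx-0057         454       503 -36.9  8676.134156     8.955986
mir-004    tx-0036         233       289 -34.9  6733.716062     5.148980
mir-005    tx-0022         513       558 -28.9  5697.759744     6.535012
```

exactly the five planted triggers recorded in `demo/truth.json` — ΔG well
below −16, knockout abundance far above 100 RPM, enrichment above 4 —
while all ten planted decoys (seed-mismatch, seed-only, perfect
complement, 7-nt loop, weak-energy, low-abundance, no-enrichment) are
rejected, each by the criterion it was built to fail.

The full pipeline is also available programmatically:

```python
from tdmdscreen import run_simulated_screen
result, truth = run_simulated_screen(seed=1)
assert {(t.mirna_id, t.transcript_id) for t in result.high_confidence} \
       == truth.trigger_keys
```

## Layout

| module | contents |
| --- | --- |
| `tdmdscreen.io_formats` | FASTA/FASTQ (via Biopython), hyb-style 15-column tables, TSV count matrices |
| `tdmdscreen.preprocess` | adapter trimming, UMI duplicate collapse, length filter |
| `tdmdscreen.hybrid_caller` | chimera splitting, k-mer mapping, 3' extension, site aggregation |
| `tdmdscreen.duplex_fold` | exact duplex-folding DP and pairing profiles |
| `tdmdscreen.screen` | the four structural + two abundance criteria, `ScreenConfig` |
| `tdmdscreen.quant` | 18-nt prefix counting, length distributions, RPM, size factors, baseMean/log2FC |
| `tdmdscreen.repression` | seed-match targets, CFC curves, Mann-Whitney, organ correlation |
| `tdmdscreen.synthetic` | scenario generator with planted triggers/decoys and truth records |
| `tdmdscreen.pipeline` / `tdmdscreen.cli` | orchestration, reports, `tdmd-screen` subcommands |
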