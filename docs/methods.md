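# Methods

`tdmdscreen` implements, as a tested and reusable pipeline, a screen for
target-RNA-directed miRNA degradation (TDMD) triggers in AGO-CLASH chimeric
sequencing data, together with the small-RNA quantification and
target-repression analyses that support such a screen. This note records
the models, parameter choices and numerical conventions, and what the
synthetic data do and do not establish.

## Pipeline overview

A CLASH chimeric read is a single sequencing read containing a mature miRNA
ligated to a fragment of its bound target RNA. The screen processes
replicate chimera libraries from two conditions — `control` and `ko`
(knockout of the Dora/ZSWIM8 ubiquitin ligase, which blocks TDMD and
stabilizes TDMD-regulated miRNAs) — through fixed stages:

1. **preprocess** — 3' adapter trimming (exact suffix/prefix overlap of at
   least 5 nt); collapse of PCR duplicates keyed on the full
   (5' UMI, insert, 3' UMI) triple, where the UMIs are the 4 random
   nucleotides at each read end; removal of inserts shorter than 18 nt.
   The order trim → collapse → length-filter is fixed.
2. **hybrid calling** — each insert of at least 30 nt is split into a
   miRNA arm (an 18-nt-anchored prefix match at the read 5' end, or the
   full mature sequence at the 3' end; longest match wins, ties by id) and
   a target fragment (at least 12 nt), which is mapped to the transcriptome
   by exact substring match via a 12-mer index. Up to 3 nt of untemplated
   miRNA tailing may be shaved from the fragment's miRNA-proximal end if
   the full fragment does not map. Mapped intervals are extended 25 nt at
   the 3' end (clamped to the transcript) to compensate for fragment
   trimming; fragments hitting several transcripts are assigned to the
   transcript with the most unambiguous support (ties by id).
3. **aggregation** — records with the same (miRNA, transcript) whose site
   intervals lie within 10 nt are merged (union interval, summed counts).
   Per-condition abundance is reads-per-million: 10^6 × site molecules /
   total clean molecules of that condition's libraries (a config flag
   switches the denominator to hybrid molecules only). The enrichment is
   `(RPM_ko + 0.1) / (RPM_control + 0.1)`; the 0.1-RPM pseudocount keeps
   sites absent from the control finite while letting them pass the
   fourfold filter.
4. **duplex folding and classification** — each merged site sequence is
   folded against its miRNA (model below) and the four structural criteria
   are evaluated; the high-confidence filter then requires KO abundance
   > 100 RPM and enrichment > 4.

## Duplex energy model

Folding considers pure antiparallel intermolecular duplexes: no
intramolecular structure, no pseudoknots, free end overhangs. Admissible
pairs are Watson-Crick (AU, GC) and, by default, G:U wobbles. The energy
of a structure is

    E = init + Σ stacks + Σ loop penalties        (kcal/mol)

with pair weights w(GC) = 3.0, w(AU) = 2.0, w(GU) = 1.0; every stacked
adjacent pair (p, q) contributes −(w(p) + w(q))/2; a bulge of b nt costs
3.0 + 0.5·b; an internal loop of (l1, l2) costs
2.0 + 0.5·(l1 + l2) + 0.5·|l1 − l2|; duplex initiation costs +4.1; and
the unpaired stretch between consecutive pairs is capped at 10 nt per
strand. These weights reproduce the familiar stability ordering
GC > AU > GU with plausible magnitudes (a perfect 22-mer duplex of average
composition lands near −40 kcal/mol) while keeping every parameter
documented and the optimum exactly computable. The dynamic program is
globally optimal for this model — verified against brute-force enumeration
of all antiparallel pairings — which is the accuracy claim made here; no
claim is made of fidelity to any particular published nearest-neighbor
parameter set, and the −16 kcal/mol screening threshold is to be read
within this model.

Numerical conventions: energies are computed in integer tenths of kcal/mol
(model parameters are rounded to the 0.1 grid), so optima and ties are
exact. Ties are broken toward more pairs, then toward the
lexicographically smaller pair list via a deterministic smallest-cell
backpointer rule. When no admissible pair exists the result is the empty
structure with dG = 0; otherwise the minimum-energy non-empty structure is
returned even when initiation leaves its dG positive (such duplexes are
far from the −16 kcal/mol criterion in any case).

## Structural criteria

Evaluated on the minimum-energy duplex, miRNA positions numbered 1..L from
the 5' end:

- **seed** — positions 2–8 all paired; G:U wobbles count as paired.
- **3' pairing** — all of the last 8 positions paired (more than seven
  consecutive pairs inside an 8-nt window forces exactly 8), or a run of
  at least 9 consecutive paired positions that touches the last-8 window.
  The anchor to the window is configurable strictness: a purely central
  9-run (e.g. positions 2–10) does not satisfy a 3'-end criterion here.
- **central loop** — helices are maximal runs of stacked pairs; the loop
  between the seed-proximal helix and the nearest helix 3' of it is
  measured on both strands, and its size is the larger of the two counts
  (the conservative reading that still rejects perfect duplexes). The
  criterion is 1 ≤ loop ≤ 6: a perfect duplex (loop 0, siRNA-like) and a
  seed-only structure (no 3' helix, loop = ∞) both fail. A single helix
  that runs from the seed into the last-8 window counts as loop (0, 0).
- **energy** — dG ≤ −16.0 kcal/mol. "Lower than 16 kcal/mol" is read on
  the thermodynamic sign convention (more stable than −16); the sign is
  explicit in the config.

Boundary behavior (loop 0/7 rejected, 1/6 accepted; 7-run rejected; 9-run
touching accepted; dG −15.9 rejected) is pinned by tests.

## Quantification and differential analysis

Small-RNA reads are assigned to a miRNA iff their first 18 nt equal the
miRNA's first 18 nt — 5'-anchored and deliberately tolerant of 3'
tailing/trimming isomiRs, whose 18–26-nt length distribution is itself an
analysis output. Reads matching several identical 18-nt prefixes count
once for each and are flagged. Normalization is reads-per-million and
median-of-ratios size factors (reference = genewise geometric mean over
samples, restricted to genes positive in all samples). Differential
results report baseMean (mean of size-factor-normalized counts) and
log2((mean_ko + 0.5)/(mean_control + 0.5)); genes below baseMean 200
(miRNA) or 100 (mRNA) are filtered, boundary inclusive. Dispersion
estimation and Wald testing are intentionally out of scope: downstream
claims rest on fold direction and rank tests, so effect sizes plus the
Mann-Whitney machinery below replace a full GLM.

## Repression analytics

Canonical target prediction scans annotated 3'UTRs for 8mer, 7mer-m8 and
7mer-A1 sites (Watson-Crick only; sites in the CDS do not count). The five
compared gene groups are all predicted targets, conserved predicted targets
(supplied externally or labeled by the generator — cross-species
conservation is not computable here), CLASH-identified targets, their
overlap, and non-targets. Repression is displayed as cumulative
distributions of per-gene log2 fold changes and tested with the two-sided
Mann-Whitney U test: an exact, tie-aware permutation null (dynamic program
over doubled midranks) when the smaller sample has ≤ 8 observations and
the pooled sample is small enough to tabulate (≤ 1000), otherwise the
normal approximation with continuity and tie correction. The exact path
reproduces full enumeration exactly, including tied data.

The organ-level analysis normalizes each entity's whole-body abundance by
its mean across organs and pools Pearson correlation over (miRNA, trigger)
pairs, with the two-tailed P from the t transform on n − 2 df; the
correlation is computed on linear normalized abundances by default, with a
log2 flag.

## Synthetic data

The default scenario is a desk-scale CLASH screen: 3 + 3 chimera
libraries of ~2×10^5 raw reads, ~50 miRNAs (21–23 nt, unique 18-nt
prefixes), ~200 random transcripts with 3'UTR annotations, 5 planted
triggers and 10 decoys. Reads are 4-nt UMI + [miRNA + fragment, order
Bernoulli(0.5)] + 4-nt UMI + adapter; per-site molecule counts are
negative binomial (dispersion 0.2, variance m + 0.2 m²) per library; PCR
emits 1 + Poisson(0.5) copies per molecule; fragments carry up to 4 nt of
5' jitter and up to 8 nt of 3' trimming (recovered by the 25-nt
extension). KO libraries multiply trigger-site means by the planted
enrichment (8-fold).

Planted sites invert the classifier's criteria: the target site is the
reverse complement of the miRNA with a designed central loop (1–6 nt, on
either strand), a 3' helix in full-window or 9-run mode, and optional G:U
substitutions. The ten decoys span every single-criterion failure mode:
seed mismatches, seed-only sites, a perfect complement (loop 0), a 7-nt
loop, two wobble-weakened sites that pass all structural geometry but stay
above −16 kcal/mol, one structurally valid site below 100 RPM and one with
no KO enrichment. Every plant is verified at generation time by running
the actual fold-and-classify path on the windows the pipeline will see:
triggers must classify as candidates with dG at least 2 kcal/mol below the
threshold, and each decoy must fail its designated criterion; miRNA
assignments are retried until the contract holds.

Two design choices go beyond the minimal recipe:

- **Generic interaction sites.** ~100 ordinary (non-TDMD, seed-type)
  miRNA-target sites with log-normal abundance carry the bulk of the
  hybrid mass, as in real CLASH where most chimeras are canonical
  interactions. Without them every planted site would sit at tens of
  thousands of RPM, making a below-100-RPM decoy unconstructible and the
  abundance filter vacuous.
- **Recoverability verification of count draws.** With NB dispersion 0.2
  over 3 + 3 libraries, the realized KO/control fold of a planted trigger
  has a log-sd of ~0.37, so about 3% of draws at 8-fold planted enrichment
  fall below the 4-fold filter by noise alone. Because the generator's
  contract is that planted truth is discoverable (that is what makes
  end-to-end recovery a well-posed test), count vectors are redrawn — with
  a 10% guard band — until triggers clear both abundance filters and the
  abundance/enrichment decoys fail their designated one. The NB marginals
  are otherwise untouched (~3% of mass truncated); setting
  `verify_recoverable=False` disables this, and the
  enrichment-median property (realized enrichment within ±30% of planted,
  across replicates) is tested on the unverified draws.

Small-RNA libraries model the TDMD tailing/trimming phenotype: trigger
miRNAs are 3'-modified (1–3 nt extension or trim) with probability 0.15 in
the control condition and 0.05 after trigger knockout; non-trigger miRNAs
stay at 0.05. miRNA count matrices for fold-change recovery use NB
dispersion 0.01 and means of 10³–5×10³ — deep small-RNA libraries from
clonal cell lines are tight at high expression, and a pre-hoc power
calculation shows this gives the ±25% recovery property a ≥98%
per-replicate margin with 3 + 3 samples, so the test checks estimator
correctness rather than replicate luck. mRNA matrices use dispersion 0.1
with target means multiplied by 2^(−δ), δ = 0.3 by default.

What the synthetic data do **not** contain: sequencing errors, UMI errors,
realistic transcript length/composition, mismatch-tolerant mapping
scenarios, intramolecular structure competing with the duplex, or
non-exact chimera breakpoints beyond the modeled jitter. Passing tests
therefore demonstrate the correctness of the algorithms under the stated
generative assumptions, not performance on real libraries.

## Statistical test design

The null calibration of the rank test (type-I rate at P < 0.05 within
5% ± 2 points) is checked over 300 replicates rather than 100: a
100-replicate block estimates the rate with sd ≈ 2.2 points, so the ±2
band would fail roughly one run in four on sampling noise alone, whereas
300 replicates (sd ≈ 1.3) make the same absolute band an informative,
stricter check. Power is checked at δ = 0.3, sd 0.4, 500 targets vs 5000
non-targets, P < 0.01, over 100 replicates.

## Determinism

All generators are bit-reproducible from (config, seed) via seeded
`numpy` `SeedSequence` streams; the pipeline itself is deterministic, with
every tie-break (miRNA match, transcript assignment, fold reconstruction,
output ordering) fixed and documented above. Problem sizes used by the
test-suite and the acceptance script (library depth 2×10^5 reads, 20
scenario seeds, 500 enumeration pairs, 100–300 statistical replicates) are
the package's chosen desk-scale defaults.

## Known limitations

- The energy model is a documented simplification: no dangling ends,
  coaxial stacking, or Turner-parameter fidelity; absolute dG values are
  model-relative.
- Fragment mapping is exact-match only; real libraries would need a
  mismatch-tolerant aligner in front of the same interfaces.
- Seed-only TDMD-like degradation is explicitly not modeled; the screen
  will not find triggers that lack 3' pairing.
- UMI collapse has no error tolerance (no 1-mismatch merging), matching
  exact-sequence collapsing.
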