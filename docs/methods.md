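# Methods

## Model

An archaeal C/D box sRNA presents two guide regions, each able to form a
bulge-free antiparallel duplex with a 16S or 23S rRNA window of equal
length.  Guide position i (1-based, 5'→3') pairs with window position
L−i+1.  By convention the guide includes the first nucleotide of its
downstream D/D' box as its 3'-terminal residue, because that position can
participate in the duplex.  The methylated nucleotide is the partner of
the guide nucleotide five positions upstream of the box start (the
"N plus five" rule); with the box-inclusive guide definition this is guide
position L−5, hence always window position 6, i.e. rRNA position
`target_start + 5`.  A guide must therefore be at least 6 nt long.

Base pairs are classed Watson–Crick (A:U, G:C), wobble (G:U) or mismatch;
the classification is symmetric in the two residues.

## Significance and productivity

A duplex is **significant** (strict mode) when

* the run of consecutive WC pairs covering the +5 column is ≥ 9
  (`min_consecutive_wc`),
* the whole duplex has ≤ 1 mismatch (`max_mismatch`) and ≤ 2 G:U pairs
  (`max_gu`), and bulges are never allowed.

One deliberate reading: the +5 column itself *bridges* the run — the run
of WC pairs may pass through it regardless of that pair's own class, and
the bridged column counts toward the run length.  Rationale: duplexes with
a single mismatch exactly at the predicted site demonstrably form (they
are the significant-but-non-productive class), yet a literal
"nine consecutive WC pairs including the site" could never admit them.
The +5 pair class alone then decides **productivity**: methylation is
called only with a WC pair at the site; a mismatch there yields a
non-productive call and a G:U there is non-productive plus an
`uncertain_site_GU` flag (wobble-compromised sites were historically
excluded as not robust rather than called unmethylated).  This gives the
accounting identity `significant = productive + non-productive` that the
pipeline asserts on every run.

**Relaxed mode** exists only for the double-guide rescue: a guide with no
strict hit is rescanned allowing G:U pairs to extend the run
(`relaxed_run_counts_gu`, default true) with ≤ 1 mismatch overall
(`relaxed_max_mismatch`); a relaxed hit is kept only if its site lies
within 100 nt (inclusive) of the partner guide's kept site on the same
molecule.  The justification is thermodynamic: two simultaneous anchored
interactions stabilize a weaker duplex.  Both relaxed knobs are exposed
because the informal description of the relaxation ("G:U pairs and/or a
single mismatch") underdetermines the rule.

Best-hit policy: one retained prediction per guide, ordered by longest
covering run, then fewest G:U + mismatches, then 16S before 23S, then
5'-most window — fully deterministic.  `--multi-target` additionally
reports the remaining passing hits (dual-target guides).

## Box annotation

Boxes are found by IUPAC-aware consensus matching (C/C': RUGAUGA, D/D':
CUGA) with per-box mismatch budgets, default 1/1/1/0 for C/D'/C'/D — the
D box is the best-conserved element, so it gets no budget.  The
arrangement search is exhaustive over candidate box quadruples with both
guides in 6–20 nt (warned outside 9–13); the score is total box
mismatches, ties broken by guide lengths closest to 11 nt, then leftmost
arrangement.  Sequences over 100 nt are rejected (C/D box sRNAs are
shorter; anything longer is something else).

k-turn screening is a sequence-level proxy: the juxtaposed boxes must
present the tandem sheared pairs C-box G3·D-box A4 and C-box A4·D-box G3
plus the adjacent non-canonical U5·U2 pair under the consensus register.
It is advisory (recorded, never a rejection): genuine k-turn formation
depends on structure, and curation practice for marginal boxes is not
fully specifiable.

## Conservation analysis

Per-species predictions are projected through alignment column maps
(1-based, strictly increasing, round-trip checked).  Conservation counts
**productive** interactions only — a non-productive duplex leaves no
methyl mark to conserve.  Per molecule the pipeline reports events,
distinct positions, single-species and multi-species positions
(`positions = single + multi` asserted), and both multi-species ratios
(over events and over distinct positions) since either denominator is
defensible.  Hotspots are windowed event counts (default 9-nt window, odd
required, truncated at the ends, no wraparound).  Redundant-target groups
key on species coordinates, not alignment columns, because redundancy is
a within-genome phenomenon of duplicated/rearranged sRNA genes.

Double-guide geometry: two kept sites on the same molecule ≤ 100 nt apart
are `double_local`, farther `double_distant`, different molecules
`cross_molecule`.  Secondary-structure distance is the shortest path in
the graph whose edges are backbone adjacencies and base pairs (dot-bracket
with up to four bracket layers, or CT input).  `double_distant` calls with
structure distance ≤ 10 edges (configurable; no principled threshold
exists for "close in structure space") are chaperone candidates; with no
structure available they are returned undecided with a warning.

## Synthetic data

The generator emulates a multi-species study: ancestor 16S (1500 nt) and
23S (3000 nt) molecules diverge per species by substitutions (rate 0.05 —
high enough to be realistic, low enough that orthologous sites stay
alignable) and indels (rate 0.005), with the true alignment emitted.
Guides are reverse complements of rRNA windows positioned so the +5 rule
lands on a chosen site; the window-start residue is set to G so the
guide's 3'-terminal C doubles as the D/D' box first nucleotide.  Planted
classes: clean, decoy (dinucleotide-shuffled guides), empty-guide,
site-mismatch (X:X at the +5 partner → significant but non-productive),
site-G:U, and relaxed-only (a mid-run wobble that breaks the strict run
but survives the anchored rescue).  Default class fractions (33 % decoy,
13 % empty-guide, 3 % site-mismatch, 1 % site-G:U) mirror the composition
of the seven-species reference survey bundled in `cdsrna.survey`
(~1/3 of sRNAs without rRNA targets, 16/735 site-mismatched interactions);
`frac_shared_sites` (default 0.15) plants conserved target columns across
≥ 2 species, near the survey's ~17 % multi-species share.

Ground truth is *realized*: after all planting, every guide is rescanned
against the finished sequences with the same two-pass logic, so rare
accidents (a later plant's substitutions creating an equal-scoring duplex
elsewhere, a decoy hitting by chance) are recorded as truth rather than
causing spurious test failures.  Clean plants are additionally verified at
generation time (annotator recovers the layout; the strict best hit is the
planted site) with resampling, so recovery on clean datasets is exact.
Same seed ⇒ byte-identical outputs; the seeded determinism is part of the
public contract.

What the generator does **not** emulate: realistic rRNA secondary
structure, biased codon/GC landscapes, transcription or read-level noise,
and genuinely homologous (rather than independently planted) guide
sequences.  Passing recovery tests therefore demonstrates correctness of
the annotation/scanning/aggregation machinery under the stated rules, not
performance on curation-grade experimental data, where box divergence and
borderline duplexes require the reviewable `borderline` report.

## Numerical and procedural choices

* Coordinates 1-based inclusive everywhere (TSV/GFF3 included).
* All input sequences normalized to RNA (T→U, uppercase) at the boundary;
  gap character `-` only (`.` is an error unless explicitly mapped).
* Ties anywhere are broken toward the 5'-most / lexicographically first
  option so reruns are byte-identical.
* The scan inner loop is vectorized with a 4×4 pair-class table and
  cumulative-product run extension; tests compare it against a plain-loop
  brute-force oracle over hundreds of random instances.
* Problem sizes in the test-suite and acceptance script (e.g. 4 species ×
  63 sRNAs ≈ 500 guides, 200 oracle instances, 100 random structures) are
  chosen to give tight statistical checks in seconds on one CPU.

## Known limitations

* The strict/relaxed rule set is an explicit operationalization of
  informally stated curation practice; per-dataset manual curation can
  differ, which is why every threshold is a config knob.
* tRNA and 5S rRNA targets are supported only generically (any FASTA can
  be scanned); no tRNA-specific logic.
* No thermodynamic (nearest-neighbour ΔG) scoring; duplex quality is
  purely pair-class based.
* Secondary-structure figures are not rendered; a per-column density plot
  (`patterns.plot_density`) stands in.
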