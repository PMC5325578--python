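# Methods

## Model and procedure

Plant miRNAs guide AGO1 slicing of target mRNAs between the target
nucleotides paired with miRNA positions 10 and 11. Degradome (PARE)
sequencing captures 5'-monophosphorylated mRNA decay fragments; a read's
5' end is therefore evidence of a cleavage position, and a miRNA target
is supported when tags accumulate exactly where a predicted duplex places
the slicing site. The pipeline is:

1. **Preprocessing.** Reads are truncated at the first exact occurrence
   of the 3' adapter's first 8 nt. Reads containing N are filtered; a
   read is low quality when ≥ 3 bases have Phred < 20 (FASTA input skips
   this clause) or when its trimmed length falls outside 20–21 nt, the
   fragment size produced by MmeI-based degradome protocols. The
   accounting identity `N-filtered + low-quality + clean = raw` holds on
   every input. Survivors are collapsed to unique tags with raw counts
   and normalized to TP100M = `raw_count / clean_total × 1e8`. polyN tags
   (one base > 70% of the sequence, strictly) are a classification label,
   not a filter: they stay in the clean-tag accounting under their own
   class and are excluded from target calling.
2. **Classification.** Each unique tag gets exactly one label by a
   priority rule: tier-1 structural ncRNA (rRNA/tRNA/snRNA/snoRNA,
   Rfam-like), then tier-2 (GenBank-like), then the polyN rule, then
   transcript matches (sense, else antisense), else `other`. Matching is
   exact: 20–21 nt tags are short enough that a k-mer substring index is
   both correct and fast, and degradome practice maps tags perfectly.
   ncRNA matching is orientation-insensitive; transcript target mapping
   is sense-only (cleavage fragments are sense-strand), reports every
   occurrence of multi-mapping tags, and never resolves them.
3. **Duplex scoring.** Antiparallel alignment of the miRNA against a
   transcript window, miRNA position 1 pairing the window's 3' end.
   Penalties: mismatch 1, G:U 0.5, each gapped/bulged position 1, all
   doubled when the miRNA position lies in 2–13; at most one single-nt
   gap (missing target base) or bulge (extra target base) per duplex.
   Candidates need score ≤ 7 (exposed as `--max-score`) and strict
   Watson–Crick pairs at miRNA positions 10 and 11 — G:U, gaps, and
   bulges between 10 and 11 are all rejected there. The search scans
   every window at every gap placement (no heuristic seeding); window
   scoring is vectorized with numpy and the few passing windows are
   reconstructed in Python. A bulge between positions j and j+1 is
   charged at position j for the doubling rule.
4. **Cleavage calling.** A candidate becomes a call when ≥ 1 tag starts
   exactly at its predicted site; alignments predicting the same (miRNA,
   transcript, site) keep the lowest score. Categories follow the
   five-class ladder — 4: exactly 1 raw tag; 0: >1 tags, unique
   transcript maximum; 1: >1 tags, tied maximum; 2: above the median;
   3: at or below the median — with maximum and median taken over raw
   counts of *occupied* positions only (zeros included would pin the
   median at 0 and empty category 3) and ties resolved in ladder order.
   Site location (5UTR/CDS/3UTR) comes from a CDS sidecar; transcripts
   without annotation are treated as all-CDS.
5. **Significance.** Empirical p-value per call: R composition-preserving
   shuffles of the miRNA (default R = 100, seeded); a shuffle succeeds
   when it attains, anywhere in the transcript set at a tag-supported
   position, a call with score ≤ the observed score and category ≤ the
   observed category; p = (1 + k)/(1 + R), the add-one estimator that
   avoids p = 0. The null re-search considers gapless duplexes only —
   gapped plant targets are rare, the restriction keeps R×transcriptome
   re-scans cheap, and because it can only under-count null successes it
   is mildly anti-conservative; interpret borderline p-values
   accordingly. No multiple-testing correction is applied; the CLI
   exposes the raw threshold (`--pval`).
6. **Two-library comparison.** Target Venn counts with percentages of
   the union; pair-level partition where a library's record is
   *overlapped* when its (miRNA, target) key occurs anywhere in the other
   library and *independent* otherwise. Records are multisets (one pair
   can be recorded at several cleavage sites), so the two libraries'
   overlap counts need not be equal and both are reported. Percentages
   use half-up rounding to 2 decimals.
7. **Expression.** 2^−ΔΔCt with replicates averaged on the Ct scale
   (technical, then biological) before the deltas — the common
   convention.

## Synthetic data

The simulator emulates a plant degradome experiment: random ACGT
transcriptomes in which each planted site's target window is the reverse
complement of its miRNA with configured edits applied (mismatch / G:U /
bulge at chosen miRNA positions; G:U edits force a G on the miRNA side);
signal reads start exactly at the base paired with miRNA nt 10 and extend
20 or 21 nt 3'-ward (seeded coin flip); every read carries the 3'
adapter. Background decay tags are uniform over positions, and any
background placement that would reach a planted site's count on the same
transcript is re-rolled, so the truth table's expected categories stay
exact under noise. Contaminant classes give the filters deterministic
work: ncRNA fragments drawn from generated references, polyN reads built
above the 70% rule, N-reads with exactly one N, low-quality reads with 3
Phred-2 bases. Expected duplex scores in the truth table are computed by
the scoring code from the planted pair states, never hand-entered.

Defaults (the study conditions of the validation suite): 20 transcripts
of 600–1200 nt, all-CDS; 5 miRNAs of 21 nt with 2 sites each; planted
depths 5–30 reads (~200 signal tags); zero noise for round-trip tests and
noise_rate 0.02/nt with ~9% total contaminants for the realistic tests.
What the simulator does **not** model: real RNA decay gradients,
sequencing errors, expression-level heterogeneity, UTR-biased tag
distributions, and paralogous target families. Passing round-trip tests
therefore demonstrates correctness of the computation, not sensitivity or
specificity on real degradome data.

## Numerical and design choices

* All positions are 1-based with closed intervals; a tag's position is
  its 5'-most base on the transcript sense strand. Comparisons run after
  mapping U→T; transcript FASTA is DNA, miRNA FASTA may use U.
* Scores are exact multiples of 0.5 (no floating-point comparisons at
  risk); outputs print them to one decimal.
* `>1 raw tags` means count ≥ 2 strictly; count = 1 is category 4
  regardless of peak structure. Category comparisons use raw counts, not
  TP100M.
* Penalty doubling at position 1 follows the general rule (positions
  outside 2–13 are single-weight), the standard treatment.
* Problem sizes in the test and acceptance suites (20 transcripts × ~1 kb,
  5 miRNAs, R = 50–100 shuffles, 20 p-value replicates) are chosen as the
  smallest sizes at which every behaviour under test is exercised with
  comfortable margins; all suites complete in well under a minute.
* The packaged target tables (`data/targets_cl.tsv`, `targets_dl.tsv`,
  `category_totals.tsv`) are transcriptions of published mulberry
  drought/control degradome results used only as tally ground truth;
  the pipeline never reads them.

## Known limitations

* Exact matching only — no mismatch/indel read mapping; real libraries
  with sequencing errors would lose a small fraction of tags.
* The gapless permutation null (above) and the absence of
  multiple-testing correction mirror common degradome practice but are
  choices, not necessities; both are isolated behind
  `empirical_pvalue`.
* Whether the original pipelines allowed G:U at positions 10/11 is not
  determinable from published tables; the strictest reading (pure
  Watson–Crick) is implemented.
* Translational repression and thermodynamic (ΔG) scoring are out of
  scope: degradome evidence only.
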