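# Methods

This note documents the models, the synthetic world, the numerical
choices, and the limits of what a green test establishes.

## Sequence model and coordinates

All coordinates are 1-based inclusive, so a window named `p_48-60` covers
residues 48..60 of protein `p` and its length is `end − start + 1`. Only
the 20 canonical residues are accepted; records containing B, J, O, U, X
or Z are rejected at ingest because every encoder downstream assumes the
20-letter alphabet. Window enumeration is exhaustive over lengths 5–30
(configurable), ordered by start then length; the count obeys
Σ_{l=min}^{max} max(0, L − l + 1), i.e. 26 L − 429 at the defaults for
L ≥ 30.

## Peptide masses

`peptide_mass` sums residue masses plus one water using Biopython's
average (default) or monoisotopic tables. C-terminal amidation replaces
the free-acid −OH with −NH₂, shifting the average mass by −0.985 Da; it is
off by default because published peptide-panel masses are free-acid values,
and `MassOptions.synthesized()` turns it on for resin-amidated peptides.
The average masses reproduce the published panel within ±0.3 Da; the
tolerance used in tests is ±0.5 Da to accommodate slightly different mass
tables among calculators. No support for modified residues, fluorophore
adducts, or isotopic distributions.

## Encoders

* **Amino-acid and dipeptide composition** — fractions over the window;
  names fixed in alphabetical order so outputs are bit-identical across
  calls.
* **k-skip bigrams** — for each skip s in 0..k (default k = 3) every
  ordered pair (i, i+s+1) is counted; counts are pooled over skips into a
  single 400-entry vector and normalized once. k = 0 reproduces dipeptide
  composition exactly. Pooling (rather than per-skip blocks) keeps the
  feature space at 400 entries.
* **Z-scales** — the packaged 5-dimensional extended z-scale descriptor
  table; per-window aggregation is the mean (default) or mean plus
  population SD, using 3 or 5 scales. The table is a static constant:
  reproducibility without downloads.

## mRMR

Greedy difference-form (MID) ranking: the first feature maximizes mutual
information with the label; each next maximizes MI(f; y) minus the mean MI
with the already-selected set. Continuous features are discretized into 5
equal-width bins (constant columns collapse to one bin, MI 0); MI is
computed exactly from the contingency table, in nats. Ties break to the
lowest feature index, making the ranking fully deterministic and
oracle-checkable. Note one consequence of determinism: if a feature
duplicates the label *exactly*, a duplicated copy of it ties with
label-independent noise at score 0 and the tie rule places the duplicate
first; the redundancy penalty only strictly defers duplicates of
imperfect features.

## Predictor architectures

**Z-scale / PCA / PLS (first round).** Window z-scale means → PCA (full
SVD, n_components = min(5, n_features) by default) → PLS regression
(≤ 2 latent components) against the 0/1 labels. The raw PLS prediction is
read out as a class posterior through a logistic calibration fitted on the
training responses (the usual PLS-DA read-out); raw regression values
shrink confident in-class members toward 0.5 and would understate them.
The [0,1] response is clipped and discretized at fixed cuts 0.25/0.5/0.75
into scores 0–3; score ≥ 2 ("likely CPP") is the round-1 keep rule. The
order PCA-then-PLS is a documented choice; the two stages are nearly
redundant at this feature dimension. Degenerate training sets whose
z-features are all constant raise a fit error.

**Composition SVM.** RBF kernel with library defaults (C = 1,
gamma = "scale"); the label contract is CPP ⇔ decision value ≥ τ with
τ = 0.0. The optional motif boost (+β, default 0.5, on the decision-value
scale) is this package's explicit, documented substitute for
motif-augmented SVM screening: it rewards peptides containing an NLS
consensus or sled motif and affects no other peptide.

**Skip-gram / mRMR / random forest.** Skip-gram vectors restricted to the
mRMR top n_select (default 100 of 400) train a
`RandomForestClassifier` (default 200 trees) with an explicit seed;
confidence is the literal fraction of trees voting CPP (not averaged leaf
probabilities), so it is a vote share in [0, 1]. Peptides shorter than
2 aa have no skip-gram features and are rejected.

All three models persist as single versioned joblib archives.

## Two-round consensus and region calling

Round 1 keeps windows with z-scale score ≥ 2. Round 2 evaluates only
round-1 passers: windows shorter than `svm_min_len` (default 10, the input
limit of composition-style predictors) fail with an explicit reason code
rather than being silently dropped; the rest must be SVM-positive at τ and
have forest confidence ≥ `rf_cutoff` (default 0.7 — "below 0.7" excluded,
boundary kept). Motif annotation is attached to round-1 passers, the set
the workflow actually screens for motifs.

Region calling counts, per residue, the candidate windows covering it.
Coverage splits into contiguous covered stretches; within each stretch,
residues with coverage ≥ `min_cov_fraction` (0.5) of that stretch's peak
are kept, sub-threshold gaps ≤ `max_gap` (5) are merged, and runs shorter
than `min_region_len` (10) are dropped. Thresholding against the *local*
peak rather than the protein-wide maximum is deliberate: proteins
typically carry several CPP-dense regions of unequal density, and a global
threshold would erase every region weaker than half the strongest. The
parameters are inventions (no published rule exists) and are exposed.

Candidate ranking is likewise an invention (the original selection was
expert judgment): the combined score is the mean of zscale_score/3,
sigmoid(svm_decision) and rf_confidence; ties break by (start, length).

## Synthetic world

The generators stand in for non-redistributable CPP training collections
and database protein inputs.

* **CPP class**: length uniform 5–30; per-peptide K/R count drawn
  uniformly from the integers within [0.30 L, 0.60 L], so the basic
  fraction is guaranteed inside the configured range; K vs R equiprobable.
  Basic positions are *stratified* — one per length block — so the
  cationic character runs along the whole peptide, as in Tat or
  penetratin; uniform placement can produce peptides whose entire charge
  sits at one end with a background-like tail, which no windowed predictor
  should be expected to call. Optional amphipathic mode plants a
  hydrophobic residue (L/I/V/F/M) every 3–4 positions. Non-basic positions
  are drawn from the background table renormalized without K/R.
* **Non-CPP class**: i.i.d. draws from a packaged SwissProt-like residue
  frequency table.
* **Planted proteins**: background sequence with 15–30 aa CPP-class
  segments (non-amphipathic by default, so recovery tests measure the
  charge signal all three predictors share) at seeded, non-overlapping
  positions separated by ≥ 10 residues; ground-truth intervals are
  recorded.

Everything is a pure function of the seed. What the synthetic world does
*not* emulate: the sequence diversity of curated CPP databases
(amphipathic helices, proline-rich and hydrophobic CPP families),
homology structure between training and screening sequences, and real
protein domain composition. A green recovery test therefore establishes
that the pipeline detects planted cationic signal against an i.i.d.
background — not that it reproduces any published tool's accuracy, scores
or per-protein candidate counts, which depend on unavailable trained
weights and training sets.

## Numerical and degenerate-case choices

* Fixed seeds everywhere; default documented seeds are 1 (first-round
  training world) and 7 (consensus training world, forest seed).
* Equal-width 5-bin MI discretization; logistic calibration with C = 10;
  PCA full SVD — all deterministic on CPU.
* Empty window lists, empty candidate sets and segment-free proteins
  return empty results, never errors; infeasible segment packing and
  single-class training sets raise validation errors.
* The RF confidence of a background peptide rises steeply as arginines
  are appended (≈ 0.20 → 0.59 over four appends in the default world) but
  drifts slightly down once a long pure poly-R tail pushes the
  composition outside the training regime; the monotonicity stress test
  covers the in-regime range (0–4 appends).

## Known limitations

* The three architectures reproduce the *contracts* of the published
  screening stack, not the original tools' trained weights; printed
  per-peptide scores and per-protein candidate counts are explicitly
  out of scope.
* NLS scanning is grammar-based (consensus + user-supplied known regions);
  no importin-binding energetics or profile-based NLS predictors.
* Known NLS regions must be supplied as intervals; there is no database
  client, by design (fully offline).
* Region calls on real proteins include any basic-rich stretch dense in
  accepted windows; they are relative-density calls, not binding-site
  predictions.
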