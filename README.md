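# shortlist

Nestedness analysis for sets of collections of cultural items — movie
collections, personal libraries, technological repertoires, or any other
presence/absence data of the collections × items kind familiar from
ecology's species × site matrices.

The package is built around the *shortlist effect*: smaller collections are
more selective, so when success is driven by intrinsic appeal
(content-biased selection), appealing items end up in collections of every
size while unappealing ones are relegated to the biggest — and the set of
collections becomes *nested*. That link turns nestedness from a curiosity
into a measuring instrument: how much an individual item contributes to the
nestedness of its corpus tells you how much its success is aligned with its
appeal, and flags the exceptions — *hidden gems* (high appeal, low
frequency) and *accidental hits* (the converse).

## What it computes

- **NODF** (Nestedness metric based on Overlap and Decreasing Fill, 0–100):
  all row pairs and column pairs of the canonically ordered matrix score
  the percentage of the sparser line's 1s that overlap the fuller line's
  1s, zero without strictly decreasing fill; axis averages are combined.
- **Significance** against the column-proportional, row-fixed (R1) null:
  row totals preserved exactly, 1s placed proportionally to original column
  totals; one-sided empirical p over 200 simulations by default.
- **Nestedness contributions**: per item i, the z-score
  c_i = (N − ⟨N*_i⟩)/σ_i comparing observed NODF to its distribution when
  item i's column is redrawn cell-by-cell with probability
  (n_i/C + n_c/I)/2, all other items held at their true values.
- **The adoption model**: P(i, c) = (e·k_c + e·p_i + s·a_i·(1−k_c))/(2e+s)
  — capacity, encounter and shortlist forces — plus the 320-condition
  parameter sweep relating selection (the appeal–prevalence correlation ρ)
  to mean NODF.
- **The empirical pipeline**: dataset filters, Spearman frequency–rating
  correlation, the shortlist interaction test (logistic regression,
  ΔAIC > 2 with sign-reversed size × appeal interaction), drift scores
  (|residual| of rating on frequency), and the nested contribution
  regression with a negative drift weight as the hypothesis test.
- **A synthetic-data generator** emulating a ratings dump with planted
  hidden gems and accidental hits, so the whole chain is testable against
  known ground truth.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

```python
import numpy as np
import shortlist as sl

m = sl.PresenceMatrix(
    np.array([[1, 1, 1, 1],
              [1, 1, 0, 0],
              [1, 0, 1, 0],
              [1, 0, 0, 0]]),
    collection_ids=["alice", "bob", "carol", "dan"],
    item_ids=["matrix", "alien", "brazil", "primer"],
)
print(sl.nodf(m).nodf_total)            # 83.33333333333333
print(sl.nodf_significance(m, n_sims=200, seed=0).p_empirical)  # 0.4229
```

Of the six row pairs, five show decreasing fill with perfect overlap
(score 100) and one is a tie (score 0), giving 500/6 = 83.33 on each axis.
A 4×4 matrix is far too small for significance: the R1 null reaches
similar scores easily (null mean 70.3 ± 13.8, p ≈ 0.42).

The full chain on synthetic data with known ground truth:

```python
spec = sl.SyntheticSpec(n_users=250, n_items=120, rho=0.5,
                        n_gems=4, n_hits=4, seed=7)
ratings, truth = sl.generate_ratings(spec)          # 12,226 ratings
report = sl.run_pipeline(ratings, seed=7, n_sims=50, n_rand=40,
                         min_items_per_collection=2)
```

This prints (via the returned report):

- `nodf` 47.87 with empirical p ≈ 0.0196 — the set of collections is
  significantly nested;
- `content_bias_spearman` 0.59 — frequency tracks ratings, i.e.
  content-biased selection;
- the shortlist test: appeal main effect +0.71, size × appeal interaction
  −1.42, ΔAIC = 51.6, `hit=True` — appeal buys less entry into large
  collections, exactly the shortlist signature;
- the contribution regression: drift weight −0.544 (95% CI −0.84 to
  −0.25), ΔAIC = 10.6, `hit=True` — items whose ratings depart from what
  their frequency predicts contribute less to nestedness.

Evaluating detection against the planted truth
(`sl.evaluate_detection`): planted gems and hits out-drift
frequency-matched ordinary items (mean drift 1.85 vs 0.56), and their
nestedness contributions sit below those controls (rank separation
−0.14); the hidden gems average c_i = −0.11 against +1.37 for ordinary
items.

## Command line

Every step is also a subcommand of the `shortlist` executable:

```sh
shortlist simulate --e 1 --s 1 --rho 0.5 --size 200 --seed 1 --out m.csv
shortlist nodf m.csv
shortlist significance m.csv --n-sims 200 --seed 1 --out sig.json
shortlist contributions m.csv --n-rand 100 --seed 1 --out contrib.csv
shortlist synth --seed 1 --out ratings.csv --truth truth.csv
shortlist pipeline ratings.csv --seed 1 --out report.json
shortlist sweep --out sweep.csv --summary-out summary.csv
```

Matrices travel as dense 0/1 CSV/TSV or sparse "collection item" triplet
text; ratings as long CSV (`user_id,item_id,rating[,year][,genre]`). All
outputs echo their seeds and parameters.

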