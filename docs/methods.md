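# Methods

## Model and procedure

`rnascan` quantifies where an RNA secondary-structure model is both richly
base-paired and conformationally stable. It takes two aligned per-nucleotide
inputs — the pairing state from a structure model and a Shannon-entropy (SE)
track derived upstream from base-pairing probabilities — and runs four
deterministic stages:

1. **Windowed base-pair content (BPC).** For each nucleotide *i*, the percent
   of base-paired positions in the window `[i−h, i+h]` (width `W = 2h+1`),
   intersected with `[1, N]`. Windows truncate at the transcript ends and the
   denominator is the actual window size, so every nucleotide keeps a value;
   no padding or edge-dropping.
2. **SE smoothing.** The local median of the SE track over the same windows,
   computed over non-missing values only; a window with no data yields a
   missing value.
3. **Dual-threshold filter.** Cutoffs are percentiles of the observed BPC and
   smoothed-SE distributions (default: the 50th percentile of each, i.e. the
   global medians). A nucleotide is a *structure count* iff
   `BPC > bpc_cutoff` **and** `SE_smooth < se_cutoff`, both strict. Raising
   the BPC percentile or lowering the SE percentile tightens the filter
   monotonically.
4. **Binning.** Non-overlapping bins `[1..B], [B+1..2B], …` tile the RNA; the
   final bin truncates at *N* and its percentage is normalized by its actual
   length. `% structure content = 100 · counts / bin length`. The ranked
   table sorts descending by percentage, ties broken by ascending bin start.

The method assumes the structure model and the entropy track describe the
same conformational ensemble of the same molecule; it makes no thermodynamic
assumptions of its own and attaches no significance model to the bins — the
ranking is descriptive.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `window` (W) | 51 | nt | must be odd so the window is symmetric about its centre; even values are rejected. 51 nt suits kilobase-scale transcripts; the worked examples use 11 nt for a 120-nt RNA, keeping the same ~1:10 window-to-length ratio. |
| `bin_size` (B) | 100 | nt | granularity of the ranked report; independent of W. |
| `bpc_percentile` | 50 | — | lower cutoff on windowed BPC; realized value recomputed per RNA. |
| `se_percentile` | 50 | — | upper cutoff on smoothed SE. |
| `lower` / `upper` | 1 / N | nt | visualization bounds only; thresholds are always computed globally over the full transcript, so zooming does not change which nucleotides count. |

## Numerical choices

- **Percentile rule:** linear interpolation between order statistics
  (`numpy.percentile` default). Fixed and documented so cutoffs are
  bit-reproducible; at (50, 50) they equal the global medians exactly.
- **Strict inequalities:** "above"/"below" are `>` and `<`. Consequence: a
  constant BPC or SE vector yields zero structure counts, since nothing is
  strictly beyond its own median. This is intended — a flat signal carries no
  contrast to rank.
- **Missing SE:** the sentinel `-999` and NaN tokens mark no-data positions.
  They are excluded from window medians and from the percentile pool, and a
  nucleotide whose smoothed SE is missing can never be a structure count:
  absence of evidence is not low entropy. An all-missing SE input is an error.
- **Exact BPC arithmetic:** windowed BPC uses integer cumulative sums of the
  paired indicator, so it equals the naive per-window count to the last bit.
  SE smoothing uses a centred rolling median (pandas) verified exactly
  against a naive per-window recomputation in the test suite.
- **Coordinates:** 1-based, closed intervals everywhere, matching the CT
  convention; all output files use 1-based positions.
- **Pseudoknots:** bracket tiers `() [] {} <>` in dot-bracket input are
  matched independently, and pseudoknotted pairs count toward BPC — BPC is
  percent double-stranded regardless of knotting. The dot-bracket writer
  assigns crossing pairs greedily to the first non-crossing tier.
- **Degenerate inputs:** empty structures, asymmetric pairing, self-pairs,
  out-of-range partners, duplicate entropy positions and negative entropies
  are all rejected at parse time with messages naming the offending line or
  pair.

## Synthetic fixtures

The `fixtures` module generates both inputs with known ground truth. An RNA is
tiled with helix and loop segments; helices pair outside-in in nested order
(first with last, second with second-last), so the per-position paired state
is exact and the structures are pseudoknot-free by construction. Entropy is
piecewise-constant per segment plus optional zero-mean Gaussian noise
truncated at zero, seeded for reproducibility. The canonical two-regime
fixture (120 nt: a fully paired low-SE hairpin half at 0.05 entropy units,
an unpaired high-SE half at 0.8, noise SD 0.01) gives maximal contrast
between regimes; its scan uses W=11, B=30 to keep the window-to-length ratio
comparable to the kilobase defaults.

These fixtures are geometric, not energetic: they do not emulate
thermodynamically plausible helix lengths, bulges, or the correlation
structure of real SHAPE-derived entropy tracks, and real data carry missing
stretches and noisier regime boundaries. Passing tests therefore demonstrate
algorithmic correctness (windowing, thresholds, binning, I/O), not biological
calibration of the default percentiles.

## Design choices

- Thresholds are always computed over the full transcript, never restricted
  to the visualization bounds, so zooming is purely graphical.
- High-BPC/high-SE (conformationally variable) regions get no separate
  caller; the BPC and smoothed-SE track outputs exist precisely so such
  regions can be read off the intermediate plots.
- The heat strip uses a fixed 0–100 % colour scale (viridis), not
  data-rescaled, so plots of different RNAs are directly comparable.
- CT parsing accepts the common 6-column table and uses only the index and
  partner columns; sequence letters are carried through unvalidated, since
  only pairing matters to BPC.
- One RNA per invocation; no batch mode.
- Outputs are staged in a temporary directory and moved into place on
  success, so a failed run leaves no partial files.

## Limitations

- No base-pair-probability matrix input: SE must be computed upstream.
- No significance model for bins; rankings are relative within one RNA.
- The dot-bracket writer supports at most four mutually crossing tiers.
- No BED/WIG genome-browser export (a natural extension point in
  `reporter`).
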