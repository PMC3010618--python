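# flexcompare

Quantify similarity of protein flexibility characteristics with signal- and
image-processing methods:

* **1D signals** (density of independent degrees of freedom along the
  backbone, or hydrophobicity profiles built from sequences) are compared
  with **dynamic time warping** (forward dynamic programming, squared-
  difference local cost).
* **2D rigidity-susceptibility images** — per-pair variances of the rigidity
  state (rigidly correlated −1 / uncorrelated 0 / flexibly correlated +1)
  over an ensemble of constraint-network realizations — are compared by
  **image registration**: gap interpolation by neighbor averaging, bicubic
  resizing, a similarity transform (scale + rotation + translation) fitted
  to control points and refined by local search, then a mean-squared pixel
  distance over mutually defined pixels (divided by m²) paired with a
  normalized union-gap count. Each pair is measured in both base/moving
  role assignments and the two measures are arithmetically averaged.

A synthetic generator produces block-structured rigidity ensembles,
susceptibility images, and piecewise 1D signals with controllable family
structure, so the whole pipeline is testable without external model outputs.

## CLI

The console script `flexcompare` exposes the workflow:

```sh
# synthetic family: ensembles, susceptibility matrices, signals
flexcompare simulate --spec spec.yaml --outdir sim/

# susceptibility image from a rigidity-state ensemble
flexcompare susceptibility --ensemble sim/member0_ensemble.tsv --out sus0.tsv

# hydrophobicity signal from FASTA (Kyte-Doolittle by default)
flexcompare hydro-signal --fasta protein.fasta --out hydro.tsv

# all-pairs DTW table for 1D signals
flexcompare compare-signals --signals sim/member0_idf.tsv \
    --signals sim/member1_idf.tsv --out dtw.tsv

# register two susceptibility images (both directions, symmetrized measures)
flexcompare compare-images --base sus0.tsv --moving sus1.tsv \
    --control-points cp.txt --out pair.tsv

# full family comparison from a YAML config
flexcompare family --config family.yaml --outdir out/

# deterministic end-to-end demo (3-member synthetic family, m=200)
flexcompare demo --seed 0 --outdir demo/
```

All file formats are plain delimited text: signals one value per line,
matrices dense whitespace/comma-delimited with `NaN` gap sentinels (an
off-scale `--gap-threshold` is also accepted on read), ensembles as
blank-line-separated integer blocks, control points as 4-column
`x_moving y_moving x_base y_base` rows (1-based, x = column), and distance
tables with one column per protein pair and rows `euclidean` /
`gap_measure`.

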