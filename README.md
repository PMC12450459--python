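# desmomap

Quantification of desmosomal plaque architecture from single-molecule
localization microscopy (SMLM/dSTORM) data, and geometric modelling of
desmoplakin isoform orientation in the plaque.

Desmosomes are cell–cell junctions with mirror symmetry across their
midline: each of the two cells contributes one plaque, so a labelled
desmoplakin (DP) domain appears as two parallel line-like plaques in a
super-resolution image.  The **plaque-to-plaque (PtP) distance** — the
separation of the two plaques, measured across the junction — encodes how
far the labelled domain sits from the midline.  DP has three splice
isoforms (DPI, DPIa, DPII) that differ only in rod length (888, 448, 290
residues), and the position of the DP tail domain in the plaque tracks rod
length, while the head domain stays membrane-proximal.

The package provides:

* **`desmomap.synthetic`** — a generator of ground-truth paired-plaque
  geometries, localization tables (uniform emitters along each plaque,
  Gaussian transverse thickness, isotropic localization noise, Poisson
  background) and rendered images (histogram or Gaussian mode, default
  4 nm/pixel).
* **`desmomap.pipeline`** — the measurement chain: ROI excision,
  orientation from intensity second moments, cross-junction line scans
  averaged along the junction, Gaussian smoothing + min-max normalization,
  prominence-based peak finding with sub-pixel parabolic refinement, and
  per-group summaries.  Every desmosome that fails quality control is kept
  with a reason.
* **`desmomap.angle`** — the aligned-angle model.  With L the head-to-tail
  protein length and PtP_tail, PtP_head the measured group means,

      θ = arcsin( ((PtP_tail − PtP_head) / 2) / L ),

  where L = rod_aa · (130/888 nm) + 16 nm + 16 nm.  Uncertainty on θ is
  propagated by a first-order delta method, cross-checked by Monte Carlo.
* **`desmomap.stats`** — the group-comparison battery with an explicit
  decision tree: Shapiro–Wilk, Brown–Forsythe; one-way ANOVA + Tukey when
  variances are homogeneous, Welch ANOVA + Dunnett T3 when they are not;
  unpaired two-tailed t-test for two groups.  Every branch decision is
  recorded in an audit trail.
* **`desmomap` CLI** — `simulate`, `measure`, `angle`, `report`, `run-all`.

## Worked example

Simulate tail- and head-labelled desmosome groups at the observed
separations, measure them, run the statistics, and fit the angle model:

```sh
desmomap run-all --out demo --seed 1
```

prints (abridged):

```
  DPI_tail: n=12, 196.3 ± 7.3 nm (mean ± s.d.)
  DPIa_tail: n=12, 137.6 ± 7.7 nm (mean ± s.d.)
  DPII_tail: n=12, 117.5 ± 9.1 nm (mean ± s.d.)
  DPI_head: n=12, 72.7 ± 7.4 nm (mean ± s.d.)
  DPIa_head: n=7, 58.1 ± 9.3 nm (mean ± s.d.)
  DPII_head: n=12, 65.6 ± 9.6 nm (mean ± s.d.)
  DPI: L=162.0 nm, theta=22.4 ± 2.0 deg
  DPIa: L=97.6 nm, theta=24.0 ± 3.9 deg
  DPII: L=74.5 nm, theta=20.4 ± 5.4 deg
```

Each group line is the per-desmosome PtP distance summary recovered by the
pipeline from rendered images (true separations 192/143/118 nm for tails,
70/60/65 nm for heads).  The isoform lines give the head-to-tail length L
and the angle of alignment θ fitted from the *measured* group means — all
three isoforms co-align at a similar acute angle, the central claim the
model encodes.  The θ s.d. here propagates the small simulated-group
scatter; with the observed biological group s.d. values (26/12 nm etc.)
the same model yields θ = 22.1° ± 5.5°, 25.2° ± 7.3°, 20.8° ± 8.4°.

The angle model alone:

```sh
desmomap angle --ptp-tail 192 --ptp-head 70 --isoform DPI --sd-tail 26 --sd-head 12
# isoform  L_nm  theta_deg  theta_sd_deg
#     DPI 162.0  22.122...      5.468...
```

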