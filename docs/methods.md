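# Methods

This note records the models implemented in `hdxconf`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that were genuinely open.

## EX2 exchange model

Backbone amide exchange is simulated in the EX2 limit: each residue *i*
exchanges independently with observed rate `k_obs,i = k_int,i / PF_i`, and
its deuterium fraction after labeling time *t* is

    D_i(t) = (1 − bx) · (1 − exp(−k_int,i · 10^(−logPF_i) · t)),

where `bx` is the back-exchange fraction lost during quench and
chromatography and `logPF_i ≥ 0` is the log10 protection factor of the
state being simulated. A peptide's true uptake is the sum of `D_i` over
residues `start+1 … end`, excluding prolines (no amide hydrogen) and the
peptide's first residue (its label is lost to fast back-exchange); the same
convention defines the max-uptake denominator `len − n_Pro − 1`.

Simplifications, deliberately accepted:

* **Intrinsic rates** come from a configurable per-residue-type lookup
  with a single default of 1 s⁻¹ rather than the full sequence-dependent
  (Bai–Englander) tabulation. Protection factors are what the pipeline is
  sensitive to; a realistic *spread* of observed rates matters, their
  sequence provenance does not.
* **EX1 is not modelled.** Bimodal isotope envelopes would require
  spectrum-level simulation, which the whole package deliberately stays
  above: the observable is the centroid mass.
* **Noise enters at the peptide level** (Gaussian on the centroid, in Da),
  matching how centroid-resolution measurement actually behaves; no
  per-residue noise, no m/z-domain or chromatographic effects.
* The analysis stages never correct for back-exchange. The generator
  still exposes `bx` so its effect on power can be studied.

### Study-design defaults

The simulated experiment mirrors a standard differential HDX-MS design:
exposures 0/30/360/900/2700 s, 4 technical replicates, centroid noise
0.1 Da (a well-behaved peptide on a modern Q-TOF), back-exchange 0.25.
Baseline protection is drawn per residue from logPF ~ U[2, 3.5], giving
observed timescales of 100–3300 s — inside the sampled window, which is
the point of a benchmark: kinetics the time course cannot see test
nothing. Protection *differences* are placed in contiguous blocks
(default ~15 residues), because real protection changes span
secondary-structure elements rather than scattered single residues.

The peptide-map generator tiles the sequence with overlapping peptides
(mean length 10, mean stride 2), yielding a redundancy near 5, typical of
a well-covered membrane-protein experiment.

What passing tests on these synthetics do **not** show: robustness to
EX1 behaviour, to correlated replicate drift, to misassigned isotope
envelopes, or to peptides whose retention/mobility windows overlap — none
of which are modelled.

## The two-stage significance test

Peptide-level differences between two conditions (ΔD = B − A per labeled
exposure, in Da) are screened by a hybrid two-gate test with no fitted
model:

1. **Per-exposure gate.** The peptide's average SEM is multiplied by the
   two-sided Student-t quantile at confidence `ci1 = 0.95` with
   `df = n_replicates − 1`; an exposure is significant when
   `|ΔD| ≥` that value (ties count), and the peptide advances only when
   significant exposures form a strict majority — 3 of 4 at the standard
   design. The strict-majority rule is the generalisation used for
   exposure counts other than four.
2. **Summed gate.** `|Σ ΔD| ≥ (avgSEM × n_exposures) × t(ci2 = 0.99,
   df = n_exposures − 1)`.

A peptide is significant only when both gates pass. Only labeled
exposures (t > 0) enter either stage. The two gates compound: under a
null simulation (no protection difference anywhere, ~1000 peptides) the
realised false-positive fraction is far below the nominal 5% (typically
zero), which is the price the design pays for not modelling the
exposure-to-exposure correlation structure.

**SEM pooling across conditions** is genuinely ambiguous in the
literature this test descends from, so both readings are implemented and
labelled in the output: `"quadrature"` (default) takes the SEM of the
difference, `√(SEM_A² + SEM_B²)` per exposure, averaged over exposures —
the statistically standard choice; `"literal-average"` averages all
per-condition SEMs over exposures. Likewise, whether stage 2's degrees of
freedom count the 0 s point is not settled; the default is
`n_labeled_exposures − 1` (df = 3 at the standard design) with a
`df_stage2` override.

No multiple-testing correction is applied beyond the two gates
(`statsmodels`-style FDR can be bolted on by the user); differences are
tested in Da, with relative-uptake testing available since visual maps
usually colour relative uptake.

### Residue projection

Each residue covered by at least one peptide receives the mean (or
median/min/max) of the covering peptides' summed ΔD, excluding every
peptide's first residue. Residues with no coverage are explicitly flagged
`covered = False` with NaN values — "no data" is never encoded as zero.
Prolines are *not* excluded from the projection by default (an
`exclude_prolines` option exists): the projection reports where signal
was measured, not which amide carried it.

## Conformational geometry

* **Dihedrals** use the standard four-atom signed torsion (IUPAC sign,
  verified against an independent implementation); angles live on
  (−180°, 180°], differences are wrapped absolute values on [0°, 180°].
  Undefined angles (termini, missing backbone atoms) are flagged, never
  zero-filled.
* **Superposition** is the Kabsch/SVD solution with the reflection
  corrected (det always +1), on atoms paired by (chain, residue number,
  atom name) — no sequence alignment is performed, so mutant/wild-type
  pairs must share numbering and cross-protein comparisons need a
  user-supplied correspondence. Cα-only is the default selection because
  domain-level rigid-body comparisons are the use case; backbone mode is a
  flag away.
* **Screw decomposition** extracts the rotation axis from the skew part of
  the rotation (eigenvector route near 180°), the angle from the trace,
  the pitch as the translation component along the axis, and an axis point
  by least squares on the in-plane fixed-point equation. Angles below
  1e-6° are reported as pure translations with no axis rather than an
  arbitrary one.
* **Helix axes** are the dominant singular direction of centred Cα
  (≥ 5 required), sign fixed N→C; inter-helix angles are reported both as
  the acute angle in [0°, 90°] and oriented in [0°, 180°]. A fit whose
  first singular value does not clearly dominate warns rather than failing
  silently.
* **Site displacement** superposes conformation B onto A over a static
  (scaffold) selection and measures the site-Cα-centroid displacement,
  total and along a normal vector; `"auto"` derives the normal as the
  two-fold screw axis of the protomer→protomer transform of a homodimer —
  for a membrane-embedded symmetric dimer that axis is the membrane
  normal. On a monomer, `"auto"` is refused with instructions rather than
  guessed.
* **Buried interface area** is `SASA(side alone) − SASA(side in complex)`
  per side, by Shrake–Rupley sphere sampling (1000 points/atom, probe
  1.4 Å) with the ProtOr heavy-atom radius set; atoms without a tabulated
  radius fall back to 1.80 Å with a warning. Hydrogens are ignored
  (crystal structures lack them); only the highest-occupancy alternate
  conformer is read, waters are dropped.
* **Toy hinge structures** are built analytically from internal
  coordinates (idealised bond lengths/angles, NeRF chain extension), so
  construction and measurement are exact mutual inverses to machine
  precision — that exactness is what makes them useful oracles.

### Domain definitions for the UraA analysis

The shipped `data/uraa_domains.yaml` (scaffold TM5–7 + TM12–14, transport
TM1–4 + TM8–11, spacer helices ≈113–120 and ≈321–329, binding site
E241/H245/E290) is an explicit **reconstruction**: the deposited entries
do not come with printed residue ranges. Every range is user-editable, and
analyses of the deposited conformational series (8OMZ wide inward-open,
5XLS occluded, 3QE7 inward-open) require the user to download those
entries — they are not redistributed with the package. Whether the
reported binding-site elevation is the total displacement or its
membrane-normal component is ambiguous in prose descriptions of elevator
motions, so both are always reported.

## Assay estimators

* **Homologous competition.** Bounded nonlinear least squares (via lmfit)
  of `CPM = Bmax·[hot]/([hot] + [cold] + K_D) + background`, replicates
  fitted jointly as points (SEM-weighting optional), `K_D > 0` enforced by
  bounds, `auto` initialisation background = min, Bmax = span, K_D = hot
  concentration. Standard errors come from the local curvature;
  non-convergence is an explicit failure state and flat data are flagged
  non-identifiable instead of returning a meaningless K_D. The printed
  equation keeps a background term even where a quench background has
  been pre-subtracted, so fitting the term is the default and both
  behaviours are supported.
* **Labeling efficiency** is the exact band-intensity ratio
  `[St_lab/(St_lab+St_unlab)] / [C_lab/(C_lab+C_unlab)] × 100`, invariant
  to uniform lane rescaling; a zero control fraction is an error, a zero
  labeled sample band gives 0%.
* **Melting temperature** is the interior maximum of the first derivative
  of the Savitzky–Golay-smoothed melt curve (window 5 points, order 2 —
  defaults chosen because no canonical smoothing exists for this readout),
  with parabolic refinement around the grid peak. A derivative that is
  flat, or maximal at a ramp endpoint, is reported as "no transition
  detected" rather than a number. The estimator is invariant to affine
  transforms of the fluorescence axis.

The melt generator's default noise (5 fluorescence units on a ~900-unit
transition) reproduces a triplicate Tm SEM of ≈0.2 °C, matching the
precision routinely reported for CPM-dye DSF; recovery is therefore
quoted for triplicate means.

## Problem sizes

Simulated checks use ~1000 peptides for null-rate estimation, 300-residue
proteins (~150 peptides) for power and map concordance, 200 seeded curves
for K_D bias and 20 triplicate experiments for Tm recovery — sizes at
which the measured fractions are stable across seeds while the whole
verification suite runs in seconds.

## Known limitations

* No back-exchange correction, EX1 analysis, or per-residue rate fitting
  from peptide data.
* Atom pairing by identity only; no structure-based alignment for
  cross-protein comparisons.
* The UraA domain ranges are reconstructions (above).
* The two-stage test inherits the field convention of treating the
  averaged SEM as exposure-independent; heteroscedastic exposures are
  averaged, not modelled.
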