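# hdxconf

Differential hydrogen–deuterium exchange mass spectrometry (HDX-MS)
analysis and conformational geometry for elevator-type transport
proteins — built around the analysis of the *E. coli* uracil permease
UraA, but generic in every part.

Elevator transporters move their substrate by sliding a rigid *transport*
domain against a static *scaffold* domain; the short interdomain linkers
("spacer helices" flanked by hinge residues) steer that motion. Probing
such mechanisms takes two kinds of quantitative analysis, and this package
provides both, plus the assay fits that usually accompany them:

* **Peptide-level HDX-MS** — parse DynamX-style state tables, filter by
  identification confidence, compute uptake from centroid masses, run the
  hybrid **two-stage significance test** on condition differences, and
  project results to residue-level maps.
* **Conformational geometry** — backbone φ/ψ hinge maps, Kabsch domain
  superpositions, **screw-axis decomposition** of domain motions, helix
  axes and inter-helix angles, binding-site displacement along a membrane
  normal, buried interface areas and contact residues.
* **Assay quantification** — homologous-competition radioligand binding
  (K_D), cysteine-alkylation labeling efficiency, and DSF melting
  temperatures.

Every analysis stage is testable without external data: the
`hdxconf.synthetic` module generates all input classes with known ground
truth (per-residue EX2 exchange with state-dependent protection factors, a
redundant peptide map, noisy centroid tables; toy hinge structures built
analytically from internal coordinates; binding and melting curves).

## The statistics at the core

For each peptide, the uptake difference between conditions ΔD(t) = D_B −
D_A (Da) at the labeled exposures is gated twice:

    test value 1 = avgSEM · t(0.975, n_rep − 1)        (per exposure)
    test value 2 = avgSEM · n_exp · t(0.995, n_exp − 1) (on Σ ΔD)

with avgSEM the per-peptide average of √(SEM_A² + SEM_B²) over exposures.
An exposure is significant when |ΔD| ≥ test value 1; a peptide passes
stage 1 when significant exposures form a strict majority (3 of 4 at the
standard design), and is called significant only if additionally
|Σ ΔD| ≥ test value 2. The compounded gates keep the realised
false-positive rate far below the nominal levels — see
[docs/methods.md](docs/methods.md) for the model, conventions, and every
default.

## Worked example

```sh
python examples/differential_hdx.py
```

```
peptide map: 156 peptides, 100.0% coverage, redundancy 5.15
two-stage test: 45 of 156 peptides significant (95%/99% confidence gates)
residue map: 299 residues covered, 88 look protected in the variant
```

A 300-residue synthetic protein gains one log-unit of protection over 20%
of its residues (contiguous blocks) in the "variant" state. At the
default experimental design (0/30/360/900/2700 s, 4 replicates, 0.1 Da
centroid noise) the two-stage test flags 45 of 156 peptides, and the
residue projection marks 88 residues as protected (negative summed
uptake difference with a significant-peptide majority). Other examples:
`examples/hinge_geometry.py` (hinge localisation and screw-axis recovery
on a synthetic two-helix pair) and `examples/assay_fits.py` (K_D,
labeling efficiency, Tm).

The same workflows are available from the shell:

```sh
hdxconf simulate hdx --out-dir sim --seed 1
hdxconf hdx diff sim/state_table.csv --state-a reference --state-b variant --out-dir run
hdxconf hinge compare a.pdb b.pdb --selections selections.yaml
```

Analyses of the deposited UraA conformational series (PDB 8OMZ, 5XLS,
3QE7) are supported via `hdxconf deposited <dir>` after downloading those
entries; coordinate files are not redistributed with the package, and the
shipped domain definitions (`src/hdxconf/data/uraa_domains.yaml`) are
documented reconstructions.

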