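# oligoms

Tandem-MS toolkit for chemically modified oligonucleotides (phosphorothioate
backbones, LNA/cEt bridged sugars, methylated bases):

- **chem** — elemental-formula arithmetic, a JSON-extensible monomer registry,
  and a modification-aware sequence grammar (`*` = phosphorothioate,
  `.` = phosphodiester; codes like `A`, `mC`, `lG`, `eT`).
- **fragments** — exhaustive theoretical fragment catalogues: all eight
  terminal backbone-cleavage ion types (a/b/c/d/w/x/y/z), neutral losses,
  base losses from *any* ion type, internal (J) fragments with grouped
  isomeric styles, adducts, charged base loss, multi-charge enumeration with
  m/z cutoffs.
- **isotopes** — exact fine-structure isotope patterns and sulfur-atom
  counting from the resolved ³⁴S / monoisotopic area ratio.
- **assign** — peak-list assignment at ppm tolerance, taxonomy
  classification (precursor / backbone-retained / plain cleavage / +neutral
  loss / +base loss / internal / adduct / unassigned), sequence coverage,
  fragmentation efficiency `100·ΣF/(ΣF+P)`, and linear recalibration.
- **twodms** — 2DMS acquisition simulation with multi-scan accumulation
  (m scans averaged per t₁ increment), low-rank transient denoising,
  magnitude-mode 2D FFT, line extraction (autocorrelation / fragment /
  precursor lines), SNR measurement, harmonic prediction, and
  electron-capture physics utilities.
- **io / cli** — CSV/TSV/mzXML peak lists, HDF5 2D maps, and a synthetic
  fixture generator with ground truth.

## CLI

```sh
# fragment catalogue for a gapmer-style sequence
oligoms calc --sequence "eG*eC*T*A*T*G*C*A*eG*eC" --max-charge 8 --out catalogue.csv

# synthetic spectrum + assignment round trip
oligoms fixture --sequence "G*C*A*T*G*C" --max-charge 3 --decoys 10 \
    --seed 7 --out peaks.csv --truth-out truth.csv
oligoms assign --peaks peaks.csv --sequence "G*C*A*T*G*C" --tol-ppm 5 \
    --report report.json

# isotope fine structure and sulfur counting
oligoms isotopes --formula C40H52N10O25P4S4 --charge 2 --out pattern.csv
oligoms sulfur --pattern pattern.csv --charge 2

# 2DMS simulation pipeline
oligoms sim2d --config sim.json --seed 1 --out raw.h5
oligoms process2d --map raw.h5 --denoise-rank 10 --out processed.h5
oligoms extract --map processed.h5 --line autocorrelation --out auto.csv
```

Custom monomers are supplied as a JSON registry
(`[{"code", "name", "base_formula", "nucleoside_formula", "bridge_delta",
"base_code"}, ...]`) via `--registry`; entries override the built-in DNA /
5-methyl-C / LNA (`l` prefix) / cEt (`e` prefix) set.

## Notes

- Negative-ion mode throughout; m/z is the deprotonated `[M − zH]ᶻ⁻` axis.
- Monoisotopic masses and isotopic abundances are pinned in
  `oligoms.constants` for bit-stable tests.
- Coverage conventions: bonds hit / (n−1) by default; `residues` divides by n.
- The sulfur estimator refuses to answer (raises `ResolutionError`) when the
  resolution model cannot separate the ³⁴S and ¹³C₂ fine peaks.
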