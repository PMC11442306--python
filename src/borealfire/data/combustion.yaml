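# Per-PFT fire emission fractions (fraction of the burned pool combusted to
# CO2) and mortality fractions (fraction of the burned live pool killed and
# transferred to litter).
#
# SYNTHETIC PLACEHOLDER VALUES: no published per-PFT combustion table is
# bundled with this package.  The ordering follows the usual combustion
# ranking (litter > leaf > soil > stem ~ root); override any entry from your
# run configuration for quantitative work.
needleleaf_evergreen:
  emission_frac: {leaf: 0.70, stem: 0.20, root: 0.18, litter: 0.82, soil: 0.28}
  mortality_frac: {leaf: 0.25, stem: 0.40, root: 0.25}
needleleaf_continental:
  emission_frac: {leaf: 0.70, stem: 0.20, root: 0.18, litter: 0.82, soil: 0.28}
  mortality_frac: {leaf: 0.25, stem: 0.40, root: 0.25}
broadleaf:
  emission_frac: {leaf: 0.55, stem: 0.15, root: 0.12, litter: 0.75, soil: 0.20}
  mortality_frac: {leaf: 0.30, stem: 0.35, root: 0.25}
grass:
  emission_frac: {leaf: 0.85, stem: 0.80, root: 0.15, litter: 0.85, soil: 0.10}
  mortality_frac: {leaf: 0.10, stem: 0.10, root: 0.30}
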