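# Methods

## Model

A material is represented by its elemental weight fractions *wᵢ* (mass
basis) and mass density ρ. All metrics are evaluated on the normalized
fractions wᵢ/Σwᵢ, so tabulated rows carrying rounding residue (the packaged
reference rows sum to between 0.991 and 1.001) give the same answer as
their exactly normalized counterparts; a deviation of more than 1% from
unity is logged as a warning.

- **⟨Z/A⟩ and electron density.** ⟨Z/A⟩ = Σ wᵢ Zᵢ/Aᵢ and
  nₑ = ρ·N_A·⟨Z/A⟩ with N_A = 6.02214076×10²³ mol⁻¹ (the CODATA-exact
  value) and IUPAC standard atomic weights (5–8 significant figures,
  packaged in `data/elements.csv`). These constants reproduce the bundled
  published per-tissue values to better than 0.1% wherever those values are
  internally consistent.
- **Effective atomic number.** Z_eff = (Σ aₙ Zₙ^p)^(1/p) with p = 2.94
  (configurable), where aₙ = wₙ(Zₙ/Aₙ)/Σᵢwᵢ(Zᵢ/Aᵢ) is the fraction of all
  electrons contributed by element n. The 2.94 exponent is the standard
  empirical choice for the photoelectric-dominated diagnostic range; the
  form collapses to Z exactly for a single element at any exponent and is
  bounded by the smallest and largest Z present.
- **Attenuation.** The mixture rule (μ/ρ)_mix(E) = Σ wᵢ(μ/ρ)ᵢ(E) on a
  default grid of 10–150 keV at 1 keV steps (the clinically used
  mammography/CT range; only the range, not the spacing, is physically
  meaningful). Elemental values are interpolated log-log linearly, which is
  exact at tabulation points and exact everywhere for power-law data.
- **CT number.** HU(E) = 1000·(μ − μ_water)/μ_water at a single effective
  energy (default 70 keV). Real scanners integrate over a spectrum; this
  monoenergetic estimate ranks materials and predicts signs but is not a
  protocol-specific prediction, so measured HU values are stored as data
  and never fitted.

## Data

- **Compositions, recipes, densities, T1/T2, HU** (`data/*.csv`) transcribe
  the published characterization dataset of a five-tissue heterogeneous
  breast phantom at full printed precision: gram-denominated recipes, TMM
  and ICRU-reference weight fractions, densities (skin 1.09, adipose 0.95,
  fibroglandular 1.02, pectoral muscle 1.04, carcinoma 0.44 g/cm³),
  relaxation times at 0.5 T, and measured/literature CT numbers. The ICRU
  rows are labeled as transcribed from this dataset, not from any
  identified ICRU report edition. One literature CT-number entry that gives
  only a plausible range (−29 to 150 HU for muscle) has no mean ± SD and is
  omitted. Literature rows carry anonymous tags (L1–L3) distinguishing
  distinct sources.
- **Elemental mass attenuation** (`data/xcom_mac.csv`): 13 elements
  (H→Ca), 27 energies over 5–200 keV, total coefficient with coherent
  scattering. H, C, N, O, Al, Si rows follow the standard published
  tabulations (O cross-checked through the liquid-water table via the
  mixture rule), densified onto the grid by the same log-log rule the
  package uses. Na, Mg, P, S, Cl, K, Ca rows are smooth
  photoelectric-power-law + Compton models anchored at their 10 keV totals,
  accurate to a few percent — these elements never exceed a weight fraction
  of 0.008 in any packaged tissue, so their contribution to a mixture curve
  is well below 0.1%. All packaged elements have Z ≤ 20 with no absorption
  edge above 5 keV, so every elemental and mixture curve is strictly
  decreasing over the default grid. Curve comparisons between TMM and
  reference tissues are therefore quantitative in shape and qualitative in
  fine detail; no headline number in the reports depends on the attenuation
  table.
- **Surrogate formulas.** Recipe components without a unique formula get
  fixed surrogates (sucrose for sugar, agarobiose repeat unit for agar,
  vinyl-alcohol repeat unit for PVA, an average octylphenol-ethoxylate
  formula with fractional stoichiometry for the X-100 surfactant, the C12
  homolog for benzalkonium chloride, trilinolein/triolein/triacontanyl
  palmitate for safflower oil, olive oil, and beeswax). With these, the
  recipe path reproduces the tabulated major-element fractions (w > 0.05)
  within 0.1% for the carcinoma and within 10% for all tissues; the
  tabulated compositions remain authoritative for characterization. The
  recipe source lists "glycerol" in one table and "glycol" in a fabrication
  step; the database uses glycerol. Trace-element mismatches (e.g. the skin
  rows imply an Na/Cl source absent from the printed recipe, and the
  nitrogen fraction is not exactly matched by the C12 benzalkonium homolog)
  are inherent to the published inputs and are left as-is.

## Published-value audit and flagged cells

`reporting.reported_value_report` recomputes every cell of the bundled
published characterization table. Values (nₑ, Z_eff) match when within 0.5%
relative; an error-percentage cell matches when within max(0.02 pp, 1%) of
the error implied by *any* pairing of published/recomputed phantom and
reference values, since the published error columns were evidently formed
from unrounded intermediates. Every cell is classified `matched` or
`mismatched-documented`; the documented set comprises:

- carcinoma electron densities: the published phantom value implies
  ρ ≈ 1.08 g/cm³ and the reference value ρ ≈ 1.0, both inconsistent with
  the printed 0.44 g/cm³, which the package will not silently replace
  (a `--config` density override reproduces the published scale). The
  derived 2.93% headline error inherits this, as does the published
  carcinoma Z_eff error (4.46, not derivable even from the published pair).
- pectoral-muscle Z_eff cells (0.829 / 0.8184): physically impossible
  (below the minimum Z present, clearly typographical) along with their
  error cells; the recomputed values are ≈7.22 / 7.38.
- the fibroglandular reference electron density, which duplicates the
  adipose cell; the printed error column (0.0315%, recomputed 0.0318%) is
  treated as authoritative.

Flagged rows are excluded from the headline maxima, which recompute to
0.62% (electron density, attained by adipose) and 5.76% (Z_eff, attained by
fibroglandular) — the latter matching the published maximum.

## Synthetic data and what the tests show

`synthetic_data` draws reproducible random recipes (single seeded
generator, no global state) over the same 14-compound palette as the
reference recipes, with masses uniform on 0.5–200 g and densities on
0.9–1.1 g/cm³ — the bench scale of the real recipes. Ground truth comes
from independent oracle paths that expand compounds into explicit
atom/electron counts and never reuse the weight-fraction algebra; pipeline
and oracle agree to 1e-9 relative over 100 seeds. Synthetic attenuation
tables are exact power laws, making interpolation closed-form testable.
The generator emulates composition bookkeeping only: the characterization
pipeline is deterministic, so there is no measurement-noise model, and
passing tests certify the algebra and data plumbing, not fabrication
reproducibility or scanner behavior.

## Numerical choices

- Compositions are normalized inside every metric; results are invariant
  under input rescaling, and electron density is exactly linear in ρ.
- Log-log interpolation raises on energies outside an element's tabulated
  support rather than extrapolating.
- Reports round for display exactly as the published table does (nₑ to 6
  significant figures, errors to 3) while always emitting full-precision
  columns alongside; CLI and library write byte-identical CSVs.
- The acceptance script's quantities are closed-form evaluations on
  ~5–9-element compositions; everything (suite + script) runs in seconds.

## Limitations

- Monoenergetic HU only; no spectrum weighting, scatter, or dose.
- Trace-element attenuation rows are modeled, not transcribed (see above).
- No solution chemistry: surrogate formulas ignore hydration, purity, and
  homolog distributions.
- MRI relaxation and measured HU are curated data, not simulated physics.
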