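# Methods

## Models

**Michaelis–Menten kinetics.** Initial velocities follow
v = V·S/(Kₘ+S). Velocities are taken in caller-declared units; when they
are per-mg specific activities (µmol·min⁻¹·mg⁻¹), the fitted V *is* the
specific activity and k_cat (s⁻¹) = V·M/6×10⁴ for an enzyme of molar
mass M (g/mol). Catalytic efficiency is the identity k_cat/Kₘ, never an
independent parameter. Substrate rankings sort by efficiency
(descending, stable for ties) and report the max–min spread; fold changes
are ratios of specific activities (or efficiencies) with the SE
propagated from the two fits assuming independence.

**Equilibrium binding.** Quench titrations follow
F(L) = F₀ − Σᵢ Aᵢ·L/(K_Dᵢ+L) for one or two *independent, non-interacting*
sites (sign configurable for enhancement data). For two-site fits the
nested one-site model is also fitted and compared with an F-test on the
residual sums of squares at α = 0.05; an insignificant improvement
raises a warning rather than silently reporting two sites.

**SPR kinetics.** One or two independent Langmuir sites. Per site i at
analyte concentration C, association follows
R_i(t) = Rmaxᵢ·C/(C+K_Dᵢ)·(1 − e^{−(k_aᵢC+k_dᵢ)t}) and dissociation
R_i(t) = R_i(t_assoc)·e^{−k_dᵢ(t−t_assoc)}; the total response is the sum
over sites. K_D ≡ k_d/k_a is enforced as an identity. Fitting is
*global*: one (k_a, k_d, Rmax) set per site shared across all analyte
concentrations, which is what makes the rate constants identifiable when
individual curves saturate. Mass-transport limitation, baseline drift
and surface regeneration are not modelled.

**Trajectory statistics.** Frames are rigidly superposed
(Kabsch/SVD with reflection correction, det(R) = +1) onto an iterated
mean reference (two refinement passes) before any fluctuation analysis.
RMSF_a = √⟨‖x_a(t) − ⟨x_a⟩‖²⟩; the per-residue value is the RMS over the
residue's atoms (mass-unweighted), and a Cα-only profile is reported
separately. Equilibration of an RMSD series is declared at the first
index from which every forward windowed mean stays within ±band of the
terminal windowed mean, requiring the equilibrated stretch to span at
least one window beyond the terminal one; otherwise the series is "not
equilibrated" (None).

**Contact matrices.** Entry (i, j) is the per-frame minimum heavy-atom
distance between residues i and j, averaged over the frame window, with
contacts defined by a 5 Å cutoff on that average ("mean-then-threshold").
The phrase "distances averaged over the simulation time" is ambiguous
about the order of averaging and thresholding, so the per-frame contact
*frequency* at the cutoff is computed as well and an adjacency in either
convention can be requested. The distance reducer is pluggable
(min | Cα | centroid); hydrogens are excluded from min-distances by
default. The sequence-neighbour band (|i−j| ≤ 1) stays in the matrix but
is excluded from network edges — backbone contacts are trivial and would
dominate the FIR clusters.

**SASA and buried area.** Shrake–Rupley quadrature with a deterministic
golden-spiral point set (960 points default, single-sphere accuracy
better than 0.5%), Bondi van der Waals radii and a 1.4 Å water probe.
Buried interface = SASA(D1) + SASA(D2) − SASA(complex), averaged over
frames; non-negative up to quadrature tolerance.

**Networks.** Nodes are residues annotated with motif id, butterfly
region and FIR group; edges are the contact-matrix adjacency minus
sequence neighbours, weighted by mean distance. Butterfly regions follow
head > tail > body-wings precedence: any edge touching motif 1 is head,
otherwise any edge touching motifs 8–10 is tail, otherwise an edge with
both ends in motifs 2–7 is body-wings. "Clusters" of the 20-FIR
subnetwork are its connected components — a reproducible, layout-free
substitute for the visual hubs of a force-directed drawing; a
modularity-community mode exists but is not the default. Network diffs
partition the mapped edge union into only-in-A / only-in-B / shared and
tally differing edges per region.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis stages
assume, with known ground truth:

- saturating velocity curves with multiplicative Gaussian noise
  (CV-parameterised), matching the roughly constant relative error of
  colourimetric assays;
- one/two-site sensograms with additive Gaussian noise in response
  units, matching instrument noise that does not scale with signal;
- hyperbolic quench titrations (multiplicative noise);
- two-rigid-domain Cα pseudo-trajectories: compact serpentine-grid
  chains of 30 residues at 3.8 Å consecutive spacing, one chain per
  domain (chains A and B), with per-frame centroid separation drawn from
  a Gaussian, isotropic per-atom jitter with per-residue SDs, and
  optional forced residue–residue contacts placed exactly at a target
  distance in the noise-free geometry (repositioning beyond a
  displacement bound is rejected as infeasible).

It does **not** emulate force-field physics, solvent, secondary
structure, side chains, or domain size: the pseudo-domains are an order
of magnitude smaller than real PTP domains. Consequently passing tests
demonstrate that the *estimators and statistics* are correct and
recover known truth at realistic noise, not that real DLAR/PTP99A
trajectories would yield particular values. Two published quantities are
out of reach at desk scale for exactly this reason: the buried interface
areas (2328.3 / 2036 Å²) require the authors' homology models, and
per-substrate k_cat/Kₘ truth values beyond the published orderings are
not available. At the 3.74 nm separation the compact pseudo-domains do
not touch, so their buried area is ≈ 0; the analysis driver demonstrates
the measure on a touching geometry instead.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| assay noise CV | 0.02 | typical colourimetric replicate scatter; the study reports none |
| pNPP Kₘ | 2.0 mM | typical PTP-domain pNPP Kₘ; study reports activities only |
| assay design | 12 concs, 0.05–20×Kₘ, 3 replicates | spans below/above Kₘ so both parameters are identified |
| sensogram noise | 1% of ΣRmax (additive) | Biacore-like baseline noise |
| SPR Rmax | 100 / 60 RU | typical peptide-analyte scales; not published |
| analyte range | 50–700 µM, 600 s per phase | the published experimental design |
| contact cutoff | 5 Å | the standard residue-contact convention used in the study |
| SASA probe / points | 1.4 Å / 960 | water probe; <0.5% single-sphere error |
| separation SD | 0.1 nm | realistic equilibrated inter-domain breathing; the published ±0.02 nm is the SE of the mean |
| per-residue jitter | 0.3 Å | equilibrated-backbone fluctuation scale |
| neighbour exclusion | \|i−j\| ≤ 1 | backbone contacts are uninformative |

## Numerical choices

- All least-squares fits (lmfit) use bounded parameters and several
  deterministic data-driven starts (max-velocity / half-max heuristics
  for Michaelis–Menten; dissociation log-slopes and association
  half-time for SPR), keeping the lowest-RSS solution. Rate and K_D
  parameters are fitted in log₁₀ space for positivity and scale-free
  steps; SEs are delta-method transforms of the linearised covariance at
  the optimum (no bootstrap).
- Fitted binding sites are reported in ascending-K_D order
  (zero-amplitude sites last), so fits are invariant to site
  relabelling. The "first" (D1) site of the two-site SPR scenarios is
  the *weaker* site, i.e. the larger fitted K_D.
- Assay data without saturation curvature are flagged "unsaturated"
  (fit not converged) instead of extrapolating Vmax; SPR data with a
  flat dissociation and an unsaturated association raise "kinetics
  unidentifiable".
- Michaelis–Menten fits on degenerate designs (<4 distinct
  concentrations) and titrations with <5 concentrations are rejected up
  front.
- The frame window of every trajectory statistic is an explicit
  parameter (full trajectory by default): published analyses use
  different windows in different places, so no implicit window is safe.

## Scenario choices

- For the insulin-receptor SPR scenario only the first-site K_D
  (1.65 µM) is published. The generator keeps the cuticle-scenario k_a
  scales (k_d = k_a·K_D) and gives the second site the stronger
  affinity reported qualitatively for the D2 site (0.2 µM).
- Motif ranges and FIR identities are user-supplied YAML configuration;
  construct-specific residue numbering tables are inputs, never
  hard-coded. The packaged `demo_motifs`/`demo_firs` annotations cover
  the synthetic 30-residue pseudo-domain only.
- Domain templates are Cα-only. Full-atom templates would only add
  chemistry the downstream statistics ignore; the contact/RMSF/SASA code
  itself is element-aware and handles multi-atom residues.

## Known limitations

- The SPR model omits mass transport and drift; strongly
  transport-limited data would bias k_a downward.
- Forced-contact calibration is exact in the noise-free geometry; jitter
  and separation noise inflate the realised mean distance slightly
  (within ~0.1 Å at the default noise scales).
- Superposition absorbs six rigid degrees of freedom, deflating RMSF by
  ≈ √(1 − 6/3N); for the 60-atom pseudo-system that is ~1.7%, visible in
  the σ√3 recovery checks.
- GraphML export stringifies list-valued graph attributes (the frame
  window) for format compliance; node/edge attributes round-trip
  losslessly.
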