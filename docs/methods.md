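# Methods

## Model structure

A vascularized tumor is idealized as *m* identical cylindrical
representative units (RUs). Each RU is the annulus between a central
capillary (radius r_b = 11 µm, from a 5% vascular volume fraction) and the
symmetry radius r_o = 50 µm (100 µm inter-capillary distance). All balances
are written per unit cylinder length; the height cancels everywhere, and the
tumor volume is V = m × V_RU. RUs are identical by construction and couple
only through (i) the shared well-mixed blood compartment, whose exchange
area scales with V, and (ii) the volume-dependent permeability P(V).

**Extracellular species.** Free immunotoxin (C_efT), free shed antigen
(C_efR), and the shed antigen–immunotoxin complex (C_ecR) are
ECS-referenced concentrations (nM) on a radial grid. Each diffuses with the
single measured interstitial diffusivity D = 2.5×10⁻⁸ cm²/s (a
molecular-weight-scaled variant was considered and rejected: the spread
between 42 and 106 kDa is < 20% on a M^(−1/3) scaling and is not separately
measurable here), reacts by mass action (k_a = k_d/K_D), degrades
first-order (χ_efT, χ_efR, χ_ecR), and exchanges with blood at the vessel
wall through the Robin condition
φ_e·D·∂C/∂r = P_f·C_blood − P_b·C_ecs, with P_f = P_b = P(V) for every
species. The outer boundary is sealed (symmetry between neighboring
capillaries). The complex's wall exchange can be switched off, which
reproduces the predecessor model in which only free species crossed back.

**Permeability switch.** P(V) = P_low + (P_high − P_low)·S(V),
S(V) = 1/(1+e^{a(V−V_c)}), with P_high = 8.0×10⁻⁶ and P_low = 7.1×10⁻⁷
cm/s, V_c = 250 mm³, a = 0.04 mm⁻³. P is evaluated on the instantaneous
total volume V(t), continuously. This is the mechanism that makes steady
shed-antigen levels rise with tumor size.

**Cells.** Three types per shell at fixed total density ρ\* = 5×10⁸
cells/cm³: un-intoxicated (ρ1), intoxicated (ρ2), dead (ρ3). Type-1 cells
hold their surface receptor total at R\* by synthesis (equivalently: a
constant synthesis rate balancing the basal endocytosis + shedding loss —
the two formulations coincide because free and bound receptors leave at the
same rates). Type-2 cells stop synthesis but continue endocytosis and
shedding; type-3 cells shed and bind only. Per-cell toxin pools: surface
B, endosomal T_en (dT_en/dt = k_e·B − (χ_ce + k_t)·T_en), cytosolic T_cc
(dT_cc/dt = k_t·T_en − χ_cc·T_cc). Intoxication converts type 1 to type 2
at κ = κ_max·T_cc/(T_0 + T_cc); death (Δ) and clearance (Χ) follow
irreversibly.

**Population closure.** Proliferation Γ(V)·ρ1 with Γ(V) = Γ0·e^{−αV} and
clearance Χ·ρ3 produce a local net volume production rate
g = (Γρ1 − Χρ3)/ρ\*; cells advect out of (or into) the RU at g carrying the
local composition, which keeps ρ1+ρ2+ρ3 = ρ\* exactly, and
dV/dt = V·⟨g⟩ (area-weighted over shells). The full equation listing of the
original formulation is not published; this closure is the reconstruction
that reduces exactly to dV/dt = Γ(V)·V in the untreated limit and to
dV/dt = −Χ·V when all cells are dead.

**State representation.** Type-1 per-cell pools are propagated as per-cell
means (valid because type-1 cells only leave, proportionally). Type-2/3
pools are propagated as per-tissue-volume totals (e.g. W2B = ρ2·B2), which
keeps the equations linear and removes the ρ→0 singularities of mean-field
bookkeeping; intoxicating cells carry their per-cell load into the type-2
totals, dying cells carry surface pools into type-3. Endosomal/cytosolic
toxin of cells that die is removed with them (no type-3 internal pools).

**Blood.** Three well-mixed pools (toxin, shed antigen, complex) in a
plasma volume of 1.0 mL — the value that, with a 20 g body mass, reproduces
both published dose conversions (200 µg/kg of 64 kDa → 62 nM; 160 µg/kg of
63 kDa → 51 nM). Toxin and shed antigen are eliminated first-order from
their blood half-lives (24/13 min and 3/5 min). The intact ~106 kDa complex
sits above the renal filtration cutoff and has **no intrinsic elimination**
by default; mass-action binding operates in plasma, so the complex
disappears by dissociating (k_d) into its rapidly cleared constituents, by
re-forming, or by permeating into the tumor. Both choices are configurable
(`blood.blood_binding`, `blood.t_half_complex_blood_min`). This is the one
genuinely unconstrained piece of the blood model; with the opposite extreme
(complex eliminated as fast as the free toxin) antigen shedding becomes
strictly detrimental at high antigen density, which contradicts the
qualitative behavior the model family was built to exhibit.

**Dosing.** Boluses are instantaneous jumps of the blood toxin
concentration at hard integration breakpoints (default 3 doses, 48 h
apart). Treatment scenarios start at V0 = 110 mm³ at the first dose; the
"day-12" endpoint (two days after the third injection when injections fall
on experiment days 6/8/10) is t = 144 h after the first dose. Before
dosing, the shed-antigen subsystem is equilibrated at V0 by a direct linear
solve (tumors shed before treatment); toxin fields start at zero.

## Parameters

Rates are stored in hr⁻¹, concentrations in nM, per-cell pools in
molecules/cell, lengths in cm internally (µm at interfaces), permeabilities
entered in cm/s. The presets carry the published values for the two
systems; the derived quantities k_a = k_d/K_D and Ω = k_t/(χ_ce+k_t) are
never set independently. χ_cc (cytosolic toxin degradation) has no
published value and defaults to 0 (cytosolic toxin persists until the cell
dies); this makes intoxication cumulative and is the main sensitivity of
the treated endpoints. The unit bridge between per-cell counts and ECS
molarity is C[nM] = count·ρ·10¹²/(N_A·φ_e); with R\* = 10⁶ and the SS1P
density it puts the total surface receptor pool at 8.30×10³ nM — the scale
of the binding-site barrier.

## Numerics

Finite-volume discretization on uniform annular shells (default 25);
conservative by construction (the area-weighted rate sum equals the wall
influx exactly, tested to 1e-10). The wall Robin condition is applied with
the half-cell diffusion conductance γ = φ_e·D/(Δr/2) in series with the
permeability — the naive form (wall value ≈ first shell center) leaves an
O(Δr) error that is visible (≈3%) at 25 shells because the wall boundary
layer is steep (Biot number ≈ 12); the series form brings 25→50-shell
changes below 0.2%. Stiff integration uses BDF with rtol 1e-6 and a
block-structured sparse Jacobian pattern; atol is scale-aware per state
block (1e-9 nM for concentrations, relaxed for counts/densities).
Tightening rtol to 1e-8 moves day-12 volumes by < 1e-5 relative. Small
negative excursions are clipped at output; excursions beyond 1e-3 of each
block's scale raise an error. Integration stops (terminal event) when
V < 1e-8 mm³ — far below a single cell — and the state is held; this is a
guard against step-size underflow in fully regressed tumors, not a model
feature. The no-toxin shed-antigen subsystem is linear, so its steady state
is a direct (n+1)×(n+1) solve sharing the integrator's discrete operator.

A deliberate consequence of the measured D and fitted P: the steady
shed-antigen profile is *not* radially flat (the wall conductance P/φ_e
exceeds the diffusion conductance D/L). The uniform-balance formula
C\* = k_s·R\*_ecs/(χ_efR + k_perm), k_perm = 2 r_b P/((r_o²−r_b²)φ_e),
therefore describes the **vessel-wall** concentration (exact total-flux
argument, verified within 3%), while the volume-averaged ECS level sits
~3–4× higher. Both are reported.

## Calibration

All concentration/volume fits use log-space residuals weighted by the
per-point lognormal scale (observations span decades; errors are
multiplicative) and bounded trust-region least squares on log-transformed
parameters. The shedding fit frees k_s alone by default (permeability held
at preset values — the procedure used for the CD25 system) and multi-starts
when ≥3 parameters are freed; non-identifiability is flagged by Jacobian
condition number and bound-hugging. The internalization assay is modeled as
surface label B(0)=1 internalized at k_e or released at k_d, with readout
I/(I+B) (internalized fraction of cell-associated label). Case-resampling
bootstrap confidence intervals are available for any fitter. On noiseless
self-generated data every fitter recovers its generating parameters to
≪1%; at 10% lognormal noise with 2×10-point scans, k_s is recovered within
a few percent.

## Synthetic data

Generators mirror the structure of the three experimental designs
(shed-antigen vs. volume scans in ECS and blood; tumor-volume time courses
with/without treatment; internalization time courses). They are pure
functions of (design, σ, seed): σ = 0 reproduces the forward model
bit-for-bit, and ECS/blood scans at the same seed receive independent noise
streams. Defaults: σ = 0.1 lognormal — the scale of the scatter in the
underlying in-vivo measurements, not a fitted value. What passing recovery
tests show is self-consistency of the forward model and estimator, not that
the model is correct for real tumors; real data add model misspecification
(heterogeneous perfusion, immune clearance, measurement artifacts) that the
generator deliberately omits.

## Problem sizes used in the shipped checks

Analytic identities are closed-form. Recovery checks use 2×10-point scans.
Conservation audits integrate the sealed-wall system for 12 days at
rtol 1e-10 (relative drift < 1e-9 observed). The well-mixed cross-check
multiplies D by 10⁶, flattens the permeability switch, and compares against
an independently coded 0-D compartment model (< 1% on volume, blood, and
mean ECS toxin). Scenario orderings use the standard 3×62 nM schedule with
a 7-point R\* grid at day 12.

## Known limitations

* Without the original supplementary equation listing, the cell-flux /
  volume closure, the type-2/3 bookkeeping, and the blood fate of the
  complex are reconstructions. The reconstructed model is markedly more
  potent than the published fits suggest: the standard 3×62 nM SS1P
  scenario regresses the simulated tumor essentially to zero by day 12,
  and the R\* value at which shedding turns from harmful to beneficial
  lands near 1.2×10⁶ rather than between 2×10⁵ and 5×10⁵. Orderings that
  compare scenarios across that crossover (the three-way shedding-toggle
  ordering at R\* = 10⁶, and the SS1P-vs-LMB-2 endpoint similarity, which
  contrasts sub-cell volumes in the eradication tail) therefore do not all
  reproduce, while the remaining directional structure (optimum R\* in
  [10⁴,10⁵], shedding harmful at low R\* and strongly beneficial at 10⁷,
  both endocytosis-rate interactions, the dose-sensitivity contrast) does.
* No interstitial pressure or convection; no lymphatics; all RUs perfused
  identically; no immune contribution to killing; no antigen-negative
  subpopulations or resistance; blood PK is one-compartment per species.
* κ acts only on type-1 cells; type-2 internal pools are bookkeeping.
* Parameters are mouse-scale throughout; nothing here supports human dose
  projection.
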