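# Methods

## Scope and model

`allonet` implements a two-modality analysis of mutation-induced
conformational change: (i) weighted isomorphous difference electron
density with per-residue IADDAT scoring from paired room-temperature
crystallographic amplitude sets; (ii) residue-level differential
hydrogen–deuterium exchange from peptide centroid masses; (iii) a
combined response network with Jaccard and hypergeometric overlap
statistics against externally supplied residue sectors. A synthetic
generator produces ground-truthed paired inputs for every stage.

## Difference maps and IADDAT

**Scaling.** Mutant amplitudes are placed on the reference scale by a
single least-squares scalar k = ΣF_mut·F_WT / ΣF_mut², applied to F and
σF. A full scaling model (per-bin or anisotropic, as refinement suites
apply) is deliberately out of scope: difference amplitudes are dominated
by local features and insensitive to the smooth residual; a
resolution-binned variant can be added behind the same interface if
needed. Common reflections are joined on (h, k, l) after mapping to the
reciprocal-space asymmetric unit (gemmi) for non-P1 inputs.

**Weighting.** Each difference ΔF = F_mut − k·F_WT receives

w = [1 + σ²(ΔF)/⟨σ²(ΔF)⟩ + α·ΔF²/⟨ΔF²⟩]⁻¹

with σ²(ΔF) = σ²_mut + σ²_WT and means over all common reflections. The
first term down-weights poorly measured differences; the α-term
(default α = 0.05) suppresses outlier amplitudes. Degenerate all-zero
means drop the corresponding term, so with σ = 0 and α = 0 all weights
are exactly 1.

**Phases and synthesis.** Phases are computed from the reference (WT)
model by direct summation with the 4-Gaussian-plus-constant atomic
scattering-factor tables (International Tables vol. C, via gemmi's
element data), a uniform isotropic B (default 15 Å²), occupancy
weighting, and no bulk-solvent correction — a documented limitation that
is immaterial for difference features, and applied identically in the
generator and the analyser. The map is synthesised as
ρ(x) = (1/V)·Σ_h w·ΔF_h·e^{iφ_h}·e^{−2πi h·x} with Friedel completion on
an FFT grid with spacing ≤ d_min/3 (grid dimensions also satisfy
n ≥ 2·max|index| + 2, so no aliasing; Parseval's identity holds to
machine precision and is asserted in tests). Amplitudes in electrons
give density in e⁻/Å³.

**IADDAT.** Every voxel with |Δρ| above the threshold (default
0.04 e⁻/Å³ for absolute-scale maps; for external maps of unknown scale
the threshold is in native map units and must be set by the user) and
within 1.5 Å (periodic minimum-image distance) of a protein heavy atom
(non-hydrogen, non-water; all altloc positions count) is assigned to the
residue of the nearest such atom, with equidistant ties going to the
lower (chain, residue number). The residue score is the sum of assigned
|Δρ| divided by the residue's heavy-atom count; `denominator` also
accepts per-assigned-voxel averaging or the raw sum, since the published
protocol does not name its denominator. Voxels, not local maxima, are
integrated — that is what "integration of absolute difference density
above threshold" means. Scores are normalized to a 0–1 scale by the
maximum; a display cap (default 0.3) is applied only to a separate
display field. IADDAT is scored against the reference model (the phase
source) so that density at deleted-atom positions is attributed to the
right residue.

## HDX-MS reduction

**Exchangeable amides.** For a peptide of length L the number of
exchange-reporting backbone amides is (L−1) minus prolines at positions
2..L minus one more when position 2 is not proline (its amide
back-exchanges too fast to retain label). Equivalently: the non-proline
positions from 3 to L.

**Percent deuteration.** With a fully-deuterated control,
%D = 100·(m_t − m₀)/(m_FD − m₀), which cancels back-exchange and any
affine mass-axis miscalibration. Without one, uptake is normalized by
n_amides · Δm(H→D) · x_D₂O with the labelling D₂O fraction defaulting to
0.90. Replicate %D values are averaged (sample sd reported). Values
outside [0, 100] by ≤ 5 points are retained with a warning (ordinary
noise); larger excursions fail QC and are dropped with a logged count.

**Differences and projection.** Mutant−WT differences are an inner join
on (span, timepoint); the sign convention is mutant − WT (positive =
faster exchange in the mutant). The residue-level track assigns each
residue the 1/n_amides-weighted mean of Δ%D over all peptides whose
*exchange-reporting amide positions* cover it: the first two residues
and prolines of a peptide carry no deuterium label, and painting them
with the peptide value only smears the track (span-based painting
remains available via `coverage="span"`). Short peptides therefore
dominate, residues covered by no amide are missing (not zero), and an
optional centred moving average smooths the track. |Δ%D| ≤ 5 points is
flagged neutral for display — a visual band, not a significance test.
The commercial tool whose residue-level output this replaces does not
disclose its deconvolution; the algorithm name is recorded in the track
metadata. The projection is a local weighted average, not a
deconvolution: it cannot reproduce discontinuities sharper than the
peptide length, which is why recovery is assessed against smooth planted
tracks (see below).

**Spanning selection and coverage.** A greedy weighted set cover
(maximise newly-covered/length; ties to the shorter, then
earlier-starting peptide; final pruning pass so no selected peptide is
removable) reproduces "shortest peptides that still span the sequence".
Shared coverage across states is the union of spans observed in every
state, as a percentage of the sequence. The network pipeline projects
from **all** peptides by default: redundant overlap is what allows
residue-level inference, and a minimal 1× tiling would leave systematic
holes at each peptide's non-reporting first residues
(`use_selected_peptides=True` restores the restricted variant).

## Network construction and overlap statistics

Residue sets are thresholded with strict inequalities: normalized IADDAT
> 0.13 (the legend value 0–1 scale), |Δ%D| > 7 points at 300 s. Missing
residues are never included. Per-mutant sets are pooled by union into
the combined network.

The hypergeometric test is one-sided upper-tail,
p = P(K ≥ |X∩Y|) for K ~ Hypergeom(N, |Y|, |X|), computed by summing the
exact log-factorial pmf (gammaln); it matches exhaustive enumeration to
< 10⁻¹⁴ for all populations up to N = 12 and an independent library
implementation at large N. The population defaults to the measurable
universe — residues both modelled in the crystal structure and covered
by peptides shared across all states — with a plain 1..L override; the
network and sectors are clipped to the population before testing, and
the population and tail convention are reported with every result. An
exact discrete upper-tail p is conservative; the mid-p variant
(P(K > k) + P(K = k)/2) is reported alongside for calibration
diagnostics, while raw p remains the inferential quantity.

## Synthetic generator

All randomness derives from one seed through named substreams
(structure, edit, reflections per dataset, peptides, HDX noise), so each
stage is independently reproducible and same-seed runs are
byte-identical.

**Crystal.** A single-chain helical poly-Ala-like model (rise 1.5 Å,
twist 100°, six heavy atoms per residue including CB/CG side-chain
pseudo-atoms, 0.15 Å seeded jitter) in an orthogonal P1 cell with ≥ 4 Å
padding. The mutation-like edit deletes the side-chain atoms at the
mutated site, places one ordered water at their centroid, and displaces
each tendril side-chain atom by exactly `shift_A` (default 0.5 Å) in a
random direction — emulating the correlated side-chain
disappearance/water appearance/neighbour perturbation seen in real
difference maps. Amplitudes are |F_calc| from the same direct summation
as the analyser, with proportional Gaussian noise (σF = noise_frac·F)
and reported uncertainties.

**HDX.** Pepsin-like peptide maps are drawn as six independent random
fragmentation passes (lengths 5–15), giving the ~4–5× redundancy typical
of local-HDX experiments; degenerate (proline-heavy) fragments are
omitted. Per-residue WT uptake follows a two-parameter logistic in
log-time, %D(t) = D_max·t/(t + t₅₀), with D_max = 80 % and t₅₀
log-uniform in [20, 5000] s — kinetic realism is not a goal; only the
300 s difference structure matters. The mutant adds the planted
per-residue Δ%D (defined at 300 s, scaled by a smooth saturating factor
equal to 1 at 300 s). Peptide %D is the mean over the peptide's
reporting amides, noised per replicate (n = 2 at 30 s and 300 s, n = 1
otherwise), and converted to centroid masses as the exact inverse of the
analyser's FD-corrected formula, with undeuterated and FD control rows
emitted. Planted differences occupy contiguous ±2-residue segments
around each perturbed site (exchange perturbations act on
secondary-structure elements, not lone residues); recovery of arbitrary
tracks is assessed with smooth Gaussian-bump profiles (sd ≈ 4 residues),
since a peptide-mean projection cannot reproduce a step discontinuity.

**Default study conditions** (the "benchmark" preset): 40 residues,
mutation site 25, tendril {10, 12, 30}, d_min = 2.0 Å, σF/F = 5 %, HDX
noise 1.5 percentage points, planted Δ%D of +20 at the site and ∓15 on
the tendril segments. At these conditions the pipeline recovers the
planted network (Jaccard ≥ 0.5 in ≥ 80 % of seeds), flags a sector
containing the planted tendril at p < 0.05 in ≥ 90 % of seeds, and
yields calibrated null p-values for random same-size sectors — all
asserted in the test suite at those replicate counts (25 and 100 seeds,
sized to keep the default run in minutes on one CPU).

## What passing tests do and do not show

The generator validates the analysis chain: formula correctness against
closed forms and brute-force oracles, generator/analyser inverse
consistency, and detection power under known, planted truth. It does not
emulate real crystallographic systematics (bulk solvent, anisotropy,
radiation damage, non-isomorphism beyond the planted edit) or real HDX
complications (EX1 kinetics, peptide misassignment, carryover), so
passing tests certify the software, not any biological conclusion about
a particular protein.

## Numerical notes

- Strict `>` thresholds everywhere; voxel–atom distance uses `≤ radius`.
- Equidistant voxel assignment ties break to the lower (chain, resnum).
- Normalization of an all-zero track is the identity.
- Reflections present in only one dataset are dropped and counted in a
  report; peptides observed in one state only are excluded from
  differences but listed in the coverage report.
- The weight formula's mean-normalised terms are dropped when their
  denominators are exactly zero (noise-free synthetic data).
- F(000) is generated and carried; it only shifts the map mean and
  cancels in differences.
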