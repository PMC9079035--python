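# Methods

## The dilution–replenishment model

Centromere identity in *Drosophila* is carried by nucleosomes containing the
histone H3 variant CID (the fly CENP-A ortholog). CID nucleosomes are not
duplicated with the DNA: at each S phase the pre-existing complement is
partitioned onto the two newly replicated sister centromeres, and new CID is
deposited during exit from the following mitosis (anaphase → telophase in
the fast syncytial cycles). Writing `e ∈ [0, 1]` for the *loading
efficiency* — the fraction of the replication-diluted half restored per
nuclear cycle (NC) — the expected centromeric intensity per nucleus obeys

    I_{k+1} = 0.5 · I_k + e · 0.5 · I_k          ⇒   I_n / I_0 = ((1 + e)/2)^n .

`e = 1` gives constancy of the per-nucleus signal across cycles; `e = 0`
gives pure two-fold dilution (50% after one cycle, 25% after two, 1/2⁷ ≈
0.8% after seven). `predict_relative_intensity` iterates the recursion
exactly as the stochastic simulator steps it, so a zero-noise simulation
reproduces the analytic value bit for bit; the printed limiting cases are
exact in either formulation.

**Stochastic variant.** Per cycle the retained fraction is drawn from a
truncated normal on [0, 1] with mean 0.5 and CV `partition_cv`, and the
loading increment has mean `e · 0.5 · I` with CV `loading_cv` (truncated
normal multiplier on [0, 2]). Both truncations are symmetric about the
mean, so the noise is mean-preserving by construction. In the embryo
simulation the two sisters receive complementary fractions `r` and `1 − r`
of the mother's complement, so partitioning conserves total signal.

**Estimation.** A consecutive-cycle intensity ratio estimates `(1 + e)/2`,
so the point estimate from observed per-embryo ratios is
`ê = 2 · mean(ratio) − 1`, clamped to [0, 1]. The confidence interval is a
percentile bootstrap over embryos (default 2000 resamples). The estimator
is deliberately simple — the ratios are approximately unbiased for the
per-cycle retention, and embryos (not nuclei) are the unit of replication.

**Per-cycle loss inversion.** Given an endpoint fraction `f` after `n`
cycles, the per-cycle loss is `1 − f^(1/n)` (geometric mode, default —
the underlying process is multiplicative) or `(1 − f)/n` (linear mode).
Both are reported because summary statements about "percent lost per
cycle" in the literature do not always say which convention they use, and
the two differ noticeably after ≥7 cycles.

## Synthetic embryo generator

The generator emulates the surface of a syncytial blastoderm embryo from
NC11 onward, with the statistical structure the quantification assumes:

- **Choreography.** Nuclei sit on a jittered lattice; the count doubles at
  every mitosis. Each cycle spans 9 frames at 60 s cadence (3 interphase,
  1 prophase, 2 prometaphase, 1 metaphase, 1 anaphase, 1 telophase — a
  stylized ~9-min blastoderm cycle). Centromeric foci (default 8 per
  nucleus, one per chromosome arm complement) congress into a compact
  cluster during prometaphase/metaphase, split into two half-intensity
  sister groups that move apart during anaphase, and the loading ramp
  (linear over the anaphase→telophase window) restores each daughter to
  `(r + e/2) · I_mother`, `r` the partition draw. Daughters are then
  re-seated on the next cycle's lattice; the teleport between telophase
  and the next interphase is a stylization the measurements never see,
  because quantification frames lie at the prometaphase/metaphase
  transition.
- **Catastrophic anaphases.** With probability `catastrophe_rate_per_mitosis`
  (default 0.01, a control-like rate) a nucleus fails chromosome
  separation: its centromeric signal stays normal up to the failure, it is
  labelled `catastrophic` for that cycle, produces no daughters, and its
  rows end after telophase (the real nuclei drop into the embryo
  interior).
- **Photometry.** The centromere channel is a sum of 2-D Gaussian foci
  (σ = 1.2 px) on diffuse background; each focus has a Gaussian axial
  profile peaking at 1 in its home plane (σ_z = 0.7 planes), and all foci
  of a nucleus share that plane. With this normalization the flux
  recovered by a maximum-intensity projection equals the ground-truth
  amplitude up to 4σ tail truncation, which is what makes projected
  ground truth and projected measurement directly comparable. The
  chromatin channel holds soft-edged nuclear discs. Pixels are
  `Poisson(rate) · gain + offset + N(0, read_noise)`, rounded to uint16.
- **Defaults.** 144×144 px field, 12 z sections at 0.5 µm, 60 s frame
  interval, 8 nuclei at NC11, 3 cycles, 90 000 photons of centromeric
  signal per nucleus over background 20 photons/px, gain 1, offset 100,
  read noise 2. The brightness places single-nucleus photometric error at
  a few percent, the precision regime implied by per-embryo cycle-ratio
  scatter of ~0.07–0.10 s.d. observed in comparable live-imaging data;
  field size and z count were chosen once for tractable stack sizes
  (~17 MB per embryo) and are stated here as the package's own choice.
- **Fixed fields** draw the nucleus count near `n₀ · 2^(target − start)`
  and per-nucleus intensities from the stochastic recursion run over the
  requested number of elapsed cycles, so an aged zero-loading field sits
  at exactly `1/2^n` of a fully replenishing one in expectation.
- **qPCR plates** encode planted copy numbers as
  `Ct = anchor − log2(copies/reference_copies)` plus Gaussian per-well
  noise, with −RT and no-template wells undetermined unless contamination
  is planted.

What the generator does **not** emulate: embryo curvature, optical
sectioning beyond the per-focus axial Gaussian, depth-dependent
attenuation, photobleaching, chromatin texture, spatial cycle-time
gradients, or segmentation-hostile nuclear crowding. Tests passing on this
synthetic data therefore validate the measurement logic (photometry,
background correction, exclusion rules, statistics), not the robustness of
dot detection on real microscopy.

## Quantification chain

1. **z window.** A constant window of `n_planes` (default 8, in the 8–12
   convention) sections is chosen by centring on the z centroid of
   above-background signal pooled over the series; the per-frame centroid
   window is also computed, and an embryo whose per-frame window start
   ranges over more than `max_drift_planes` (default 2) is flagged and
   excluded as drifting. Frames with essentially no above-background
   signal are pinned to the global window — they carry no drift
   information. Ties fall to the lowest start index.
2. **Maximum projection** over the window, per frame and channel.
3. **Quantification frames**: first anaphase frame of each mitosis minus
   two time points (2 min before anaphase onset at 60 s cadence), when
   centromere clustering is minimal and no loading occurs.
4. **ROI.** Dots are detected inside the nuclear footprint (Otsu component
   of the chromatin projection, falling back to a disc at the tracked
   centroid) with a difference-of-Gaussians band-pass (σ = 1, 2 px)
   thresholded at the image-wide DoG median + k·MAD (k = 6; for
   noise-free images the MAD is floored at a 1e-9 relative scale so the
   threshold still separates signal from numerical ripple). The inner ROI
   is the smallest axis-aligned ellipse covering every dot pixel plus a
   2 px margin — 1 px leaves enough PSF tail in the background shell to
   over-subtract ~3% of the flux, 2 px brings noise-free recovery inside
   2%. The background shell is 3 iterations of 8-connected binary
   dilation minus the inner ellipse (connectivity made explicit because
   "expand by three pixels" does not determine it), with pixels
   overlapping any neighbour's inner ROI removed.
5. **Corrected intensity** = integrated inner intensity − shell mean ×
   inner pixel count; exactly invariant to additive offsets and
   equivariant to gain.

Exclusions mirror standard practice: nuclei fated to a catastrophic
anaphase at the scored mitosis (`catastrophic`), whole embryos with z
drift (`z_drift_embryo`), ROIs clipped by the field border (`border`,
configurable), and nuclei with no detectable dots (`no_dots`). All appear
in the output with their reason rather than being silently dropped.

Quantification uses the max projection by default, matching how such data
are conventionally analysed; a 3-D mode (`integrate_z=True`, photometry on
the z sum over the selected window) exists but is off by default.
Measurements are taken on the centromere channel only, with the chromatin
channel providing footprints.

## Statistics

Per embryo, included nuclei are averaged within each cycle; ratios of
cycle means are formed per embryo and aggregated as mean ± sample s.d.
(n − 1) across embryos.  A pooled-nuclei aggregation
(`pooled_cycle_ratios`, all nuclei of a condition pooled before
averaging — the natural mode for fixed-embryo population comparisons) is
provided as an alternative; per-embryo remains the default because
embryos are the independent replication unit. The identity `NC13/NC11 = (NC13/NC12)·(NC12/NC11)`
holds exactly per embryo. Display normalization sets each embryo's NC12
mean to 100 and is idempotent and scale-invariant. Per-centromere loading
curves divide pre-anaphase values by two (sister pairs) and pass
anaphase/telophase values through. Catastrophe fractions are exact
rationals (catastrophic / entering metaphase) converted to float at the
end. Treatment comparisons use a two-sided Welch t test by default (the
variant is configurable); no multiple-testing correction is applied, and
this is intentional — single planned comparisons are reported as such.

## qPCR

Technical replicates are averaged on the Ct scale before transformation
(the conventional ΔCt workflow); the relative level is
`efficiency^−(Ct_target − Ct_ref)` with efficiency fixed at 2.0 per cycle
by default (an explicit parameter, since assay-specific efficiencies were
not available). Absolute copies multiply by the assumed reference
abundance (Act5C, 15 million transcripts per embryo) and are rounded to 2
significant figures by default, reflecting the precision of that
assumption. Percent-of-control is a ratio of relative levels and is
invariant to the run's Ct anchor; it is computed from replicate-averaged
Cts by default, with a per-replicate-pair variant
(`percent_of_control_per_replicate`) exposed — the two coincide at zero
Ct noise and differ only at second order otherwise. "Not detected" propagates as a distinct
state, never as zero. QC flags: genomic-DNA contamination when a −RT well
amplifies within 3 cycles of the +RT mean, reagent contamination when any
no-template well amplifies, and near-detection-limit when the +RT mean Ct
exceeds 33.

## Numerical choices and degenerate inputs

- All RNG draws flow from explicitly passed `numpy.random.Generator`
  objects; the pipeline fans a single global seed out to per-embryo child
  seeds via `SeedSequence.spawn`, so identical seeds give byte-identical
  stacks, tables and reports.
- z-window ties break to the lowest start index; uint16 rendering rounds
  to nearest; clamping of `ê` to [0, 1] happens after averaging, so noise
  around the boundary does not bias the mean before inversion.
- Identical zero-variance groups in the t test return (t = 0, p = 1)
  rather than NaN.
- Empty background shells, missing reference cycles, empty embryo sets,
  non-positive copy numbers and out-of-range model parameters raise
  errors naming the offending object.

## Known limitations

- Maximum-projection photometry carries a small signal-dependent bias at
  low SNR (the projected background max soft-thresholds dim PSF tails);
  at the default brightness this contributes ≲1% per-cycle ratio bias,
  visible in the parameter-recovery results as ê a few thousandths low.
- The per-cycle loss "percent" from endpoint inversion depends on the
  assumed cycle count and mode (geometric vs linear); the package reports
  both rather than claiming one.
- Dot detection is tuned for well-separated nuclei with compact metaphase
  clusters; it is not a general spot detector for crowded interphase
  fields.
- The simulation study sizes used by the test suite (50 embryos per
  loading-efficiency setting, three nuclear cycles each) were chosen as a
  realistic imaging-campaign scale for a parameter-recovery study.
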